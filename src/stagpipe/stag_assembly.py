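"""Concatenated hypothetical-genome construction.

Each retained marker locus becomes a *STAG*: the trimmed tag sequence with the
polymorphic position replaced by the IUPAC ambiguity code for its two alleles.
STAGs are concatenated in ascending allele-ID order (numeric-aware) to give
every individual a positionally homologous pseudo-contig — homozygotes
contribute the called allele's base at the SNP site, heterozygotes the
ambiguity code, and missing calls an N-run of the full tag length so columns
stay aligned.  The per-column majority over individuals is the population
consensus: the hypothetical genome used for all downstream homology work.

Because every individual's concatenation has identical locus order and
per-locus length by construction, the consensus is purely columnar; no
general multiple-sequence alignment is needed (a gap-tolerant global
alignment of these sequences is the identity on columns).

The :class:`ConcatRegistry` records each STAG's offset and length inside the
concatenated genome and is the single coordinate authority for mapping hit
intervals back to tags.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .marker_qc import CALL_HET, CALL_HOM_ALT, CALL_HOM_REF, CALL_MISSING, MarkerLocus

__all__ = [
    "IUPAC_AMBIGUITY",
    "IUPAC_SETS",
    "Stag",
    "RegistryEntry",
    "ConcatRegistry",
    "HypotheticalGenome",
    "StagOverlap",
    "MappedInterval",
    "natural_sort_key",
    "build_stag",
    "build_stags",
    "concat_individual",
    "build_consensus",
    "gc_content",
    "map_to_stags",
]

# two-base ambiguity codes; keys are unordered base pairs
IUPAC_AMBIGUITY = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

IUPAC_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# consensus tie-break order: unambiguous bases first, then the two-base
# ambiguity codes alphabetically; N is never chosen unless a column is all-N
CONSENSUS_ALPHABET = "ACGT" + "".join(sorted(IUPAC_AMBIGUITY.values()))


_NATURAL_RE = re.compile(r"(\d+)")


def natural_sort_key(allele_id: str):
    """Numeric-aware sort key ("2" < "10"); falls back to lexicographic parts."""
    return tuple(
        int(part) if part.isdigit() else part
        for part in _NATURAL_RE.split(str(allele_id))
    )


@dataclass(frozen=True)
class Stag:
    """One trimmed tag with an IUPAC ambiguity base at the SNP site.

    ``alleles`` keeps the (reference, alternate) SNP bases so individual
    haplotype sequences can be reconstituted from genotype calls.
    """

    allele_id: str
    sequence: str
    snp_offset: int
    ambiguity_base: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if self.sequence[self.snp_offset] != self.ambiguity_base:
            raise ValueError(
                f"STAG {self.allele_id!r}: sequence does not carry the ambiguity "
                f"base at the SNP offset"
            )
        expected = IUPAC_AMBIGUITY.get(frozenset(self.alleles))
        if expected != self.ambiguity_base:
            raise ValueError(
                f"STAG {self.allele_id!r}: ambiguity base {self.ambiguity_base!r} "
                f"does not encode alleles {self.alleles}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def allele_sequence(self, which: int) -> str:
        """Sequence of allele 0 (reference) or 1 (alternate)."""
        s = self.sequence
        return s[: self.snp_offset] + self.alleles[which] + s[self.snp_offset + 1 :]


class RegistryEntry(NamedTuple):
    allele_id: str
    offset: int
    length: int


@dataclass
class ConcatRegistry:
    """Ordered STAG offsets within the concatenated genome."""

    entries: list[RegistryEntry]

    def __post_init__(self) -> None:
        pos = 0
        for e in self.entries:
            if e.offset != pos:
                raise ValueError(
                    f"registry entry {e.allele_id!r}: offset {e.offset} breaks "
                    f"contiguity (expected {pos})"
                )
            if e.length <= 0:
                raise ValueError(f"registry entry {e.allele_id!r}: non-positive length")
            pos += e.length
        self._offsets = [e.offset for e in self.entries]

    @classmethod
    def from_lengths(cls, pairs: Iterable[tuple[str, int]]) -> "ConcatRegistry":
        entries = []
        pos = 0
        for allele_id, length in pairs:
            entries.append(RegistryEntry(allele_id, pos, length))
            pos += length
        return cls(entries)

    @property
    def total_length(self) -> int:
        if not self.entries:
            return 0
        last = self.entries[-1]
        return last.offset + last.length

    @property
    def junctions(self) -> list[int]:
        """Internal STAG boundaries (offsets of every entry but the first)."""
        return self._offsets[1:]

    def entry_at(self, position: int) -> RegistryEntry:
        if not 0 <= position < self.total_length:
            raise ValueError(f"position {position} outside genome [0, {self.total_length})")
        idx = bisect.bisect_right(self._offsets, position) - 1
        return self.entries[idx]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("allele_id\toffset\tlength\n")
            for e in self.entries:
                fh.write(f"{e.allele_id}\t{e.offset}\t{e.length}\n")

    @classmethod
    def from_tsv(cls, path) -> "ConcatRegistry":
        entries = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("allele_id"):
                raise ValueError(f"{path}: not a registry TSV")
            for line in fh:
                aid, off, length = line.rstrip("\n").split("\t")
                entries.append(RegistryEntry(aid, int(off), int(length)))
        return cls(entries)


@dataclass
class HypotheticalGenome:
    """Population consensus of the concatenated STAGs."""

    consensus: str
    registry: ConcatRegistry
    n_individuals: int
    gc_content: float

    def __post_init__(self) -> None:
        if len(self.consensus) != self.registry.total_length:
            raise ValueError("consensus length disagrees with registry total")


class StagOverlap(NamedTuple):
    allele_id: str
    local_start: int
    local_end: int


class MappedInterval(NamedTuple):
    overlaps: list[StagOverlap]
    spans_junction: bool


def build_stag(locus: MarkerLocus) -> Stag:
    """Replace the SNP base with the IUPAC code for the locus's allele pair."""
    ref_base, alt_base = locus.alleles
    if ref_base == alt_base:
        raise ValueError(f"locus {locus.allele_id!r}: alleles are identical")
    key = frozenset((ref_base, alt_base))
    if key not in IUPAC_AMBIGUITY:
        raise ValueError(
            f"locus {locus.allele_id!r}: allele pair {ref_base}/{alt_base} is not "
            f"two distinct unambiguous bases"
        )
    amb = IUPAC_AMBIGUITY[key]
    seq = locus.allele_seqs[0]
    stag_seq = seq[: locus.snp_offset] + amb + seq[locus.snp_offset + 1 :]
    return Stag(
        allele_id=locus.allele_id,
        sequence=stag_seq,
        snp_offset=locus.snp_offset,
        ambiguity_base=amb,
        alleles=(ref_base, alt_base),
    )


def build_stags(loci: Iterable[MarkerLocus]) -> list[Stag]:
    """Build STAGs and sort them ascending by allele ID (numeric-aware)."""
    stags = [build_stag(locus) for locus in loci]
    stags.sort(key=lambda s: natural_sort_key(s.allele_id))
    return stags


def concat_individual(
    stags: Sequence[Stag], calls: Mapping[str, int]
) -> tuple[str, ConcatRegistry]:
    """Concatenate one individual's tag sequences in the given STAG order.

    ``calls`` maps allele_id → genotype code.  Homozygotes emit the called
    allele, heterozygotes the ambiguity sequence, missing calls an N-run of
    the tag length.  Allele IDs in ``calls`` that match no STAG are an error.
    """
    ids = [s.allele_id for s in stags]
    if sorted(ids, key=natural_sort_key) != ids:
        raise ValueError("stags must be sorted ascending by allele ID")
    unknown = set(calls) - set(ids)
    if unknown:
        raise ValueError(f"calls reference unknown allele IDs: {sorted(unknown)[:5]}")
    parts = []
    for stag in stags:
        call = calls.get(stag.allele_id, CALL_MISSING)
        if call == CALL_HOM_REF:
            parts.append(stag.allele_sequence(0))
        elif call == CALL_HOM_ALT:
            parts.append(stag.allele_sequence(1))
        elif call == CALL_HET:
            parts.append(stag.sequence)
        elif call == CALL_MISSING:
            parts.append("N" * len(stag))
        else:
            raise ValueError(f"invalid call code {call} at {stag.allele_id!r}")
    registry = ConcatRegistry.from_lengths((s.allele_id, len(s)) for s in stags)
    return "".join(parts), registry


def build_consensus(
    individual_sequences: Sequence[str], registry: ConcatRegistry
) -> HypotheticalGenome:
    """Per-column majority consensus over positionally homologous sequences.

    The consensus at each column is the most frequent non-N symbol; ties are
    broken by the fixed order A < C < G < T < two-base ambiguity codes
    (alphabetical).  A column is N only when every individual is missing.
    """
    if not individual_sequences:
        raise ValueError("no individual sequences")
    length = registry.total_length
    for i, seq in enumerate(individual_sequences):
        if len(seq) != length:
            raise ValueError(
                f"individual {i}: sequence length {len(seq)} != registry total {length}"
            )
    mat = np.frombuffer(
        "".join(s.upper() for s in individual_sequences).encode("ascii"), dtype=np.uint8
    ).reshape(len(individual_sequences), length)
    counts = np.zeros((len(CONSENSUS_ALPHABET), length), dtype=np.int32)
    for k, sym in enumerate(CONSENSUS_ALPHABET):
        counts[k] = (mat == ord(sym)).sum(axis=0)
    best = counts.argmax(axis=0)  # argmax takes the first maximum: the tie-break order
    consensus_arr = np.frombuffer(
        CONSENSUS_ALPHABET.encode("ascii"), dtype=np.uint8
    )[best]
    all_n = counts.sum(axis=0) == 0
    consensus_arr = np.where(all_n, ord("N"), consensus_arr)
    consensus = consensus_arr.tobytes().decode("ascii")
    gc = gc_content(consensus) if not all_n.all() else 0.0
    return HypotheticalGenome(
        consensus=consensus,
        registry=registry,
        n_individuals=len(individual_sequences),
        gc_content=gc,
    )


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes and N are excluded from both sides."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def map_to_stags(registry: ConcatRegistry, query_interval: tuple[int, int]) -> MappedInterval:
    """Map a genome interval to the STAGs it overlaps, in STAG-local coordinates.

    ``spans_junction`` is true iff the interval overlaps more than one STAG.
    """
    start, end = query_interval
    if start >= end:
        raise ValueError(f"empty or inverted interval [{start}, {end})")
    if start < 0 or end > registry.total_length:
        raise ValueError(
            f"interval [{start}, {end}) outside genome [0, {registry.total_length})"
        )
    idx = bisect.bisect_right(registry._offsets, start) - 1
    overlaps: list[StagOverlap] = []
    while idx < len(registry.entries) and registry.entries[idx].offset < end:
        e = registry.entries[idx]
        lo = max(start, e.offset) - e.offset
        hi = min(end, e.offset + e.length) - e.offset
        overlaps.append(StagOverlap(e.allele_id, lo, hi))
        idx += 1
    return MappedInterval(overlaps=overlaps, spans_junction=len(overlaps) > 1)
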