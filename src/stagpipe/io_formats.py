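"""Readers and writers for the external formats the pipeline touches.

Covers DArT-style two-row-per-locus SNP marker tables (CSV plus a YAML
dialect descriptor), FASTA, BED 4+, GFF3 gene features, and 12-column BLAST
tabular hits.  All coordinates are normalised at this boundary to 0-based
half-open intervals; BLAST tabular (1-based inclusive) and GFF3 (1-based
inclusive) are converted on read and back on write.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .marker_qc import (
    CALL_HET,
    CALL_HOM_ALT,
    CALL_HOM_REF,
    CALL_MISSING,
    MarkerLocus,
)

__all__ = [
    "MarkerTable",
    "MarkerDialect",
    "GeneFeature",
    "RawBlastHit",
    "read_marker_table",
    "write_marker_table",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "read_gene_features",
    "write_gff3",
    "write_bed",
]

_IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN")


class MalformedInputError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# Marker tables
# ---------------------------------------------------------------------------

@dataclass
class MarkerTable:
    """Ordered collection of marker loci genotyped on a fixed individual panel."""

    loci: list[MarkerLocus]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        if not self.individual_ids:
            raise ValueError("individual_ids must be non-empty")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual_ids must be unique")
        seen: set[str] = set()
        for locus in self.loci:
            if locus.allele_id in seen:
                raise ValueError(f"duplicate allele ID {locus.allele_id!r}")
            seen.add(locus.allele_id)
            if locus.calls.size != len(self.individual_ids):
                raise ValueError(
                    f"locus {locus.allele_id!r} has {locus.calls.size} calls for "
                    f"{len(self.individual_ids)} individuals"
                )

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class MarkerDialect:
    """Column layout of a two-row-per-locus marker CSV.

    Each locus occupies two consecutive rows sharing one allele ID: first the
    reference-allele sequence, then the alternate.  The SNP descriptor column
    holds strings like ``"24:C>T"`` (0-based offset, ref>alt).  Per-sample
    columns carry allele presence per row: ``1`` present, ``0`` absent, ``-``
    no call; the two rows combine into a diploid genotype.  ``sample_cols``
    of ``None`` means every column not otherwise named is a sample.
    """

    allele_id_col: str = "AlleleID"
    sequence_col: str = "AlleleSequence"
    snp_col: str = "SNP"
    depth_col: str = "AvgReadDepth"
    sample_cols: tuple[str, ...] | None = None
    restriction_motif: str = "TGCAG"

    @classmethod
    def from_yaml(cls, path) -> "MarkerDialect":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "sample_cols" in data and data["sample_cols"] is not None:
            data["sample_cols"] = tuple(data["sample_cols"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "allele_id_col": self.allele_id_col,
            "sequence_col": self.sequence_col,
            "snp_col": self.snp_col,
            "depth_col": self.depth_col,
            "sample_cols": list(self.sample_cols) if self.sample_cols else None,
            "restriction_motif": self.restriction_motif,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _parse_snp_descriptor(desc: str, allele_id: str) -> tuple[int, str, str]:
    try:
        pos_part, change = desc.split(":")
        ref, alt = change.split(">")
        offset = int(pos_part)
    except (ValueError, AttributeError) as exc:
        raise MalformedInputError(
            f"locus {allele_id!r}: cannot parse SNP descriptor {desc!r}"
        ) from exc
    if len(ref) != 1 or len(alt) != 1:
        raise MalformedInputError(
            f"locus {allele_id!r}: SNP descriptor {desc!r} must name single bases"
        )
    return offset, ref.upper(), alt.upper()


def _presence_pair_to_call(ref_p: str, alt_p: str, allele_id: str) -> int:
    pair = (ref_p.strip(), alt_p.strip())
    if "-" in pair or "" in pair:
        return CALL_MISSING
    table = {
        ("1", "0"): CALL_HOM_REF,
        ("1", "1"): CALL_HET,
        ("0", "1"): CALL_HOM_ALT,
        ("0", "0"): CALL_MISSING,
    }
    try:
        return table[pair]
    except KeyError:
        raise MalformedInputError(
            f"locus {allele_id!r}: invalid presence pair {pair}"
        ) from None


def read_marker_table(path, dialect: MarkerDialect = MarkerDialect()) -> MarkerTable:
    """Read a two-row-per-locus marker CSV into a :class:`MarkerTable`."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise MalformedInputError(f"{path}: empty marker table")
        fieldnames = list(reader.fieldnames)
        rows = list(reader)

    meta = {dialect.allele_id_col, dialect.sequence_col, dialect.snp_col, dialect.depth_col}
    missing_cols = meta - set(fieldnames)
    if missing_cols:
        raise MalformedInputError(f"{path}: missing columns {sorted(missing_cols)}")
    if dialect.sample_cols is not None:
        sample_cols = list(dialect.sample_cols)
        if not set(sample_cols) <= set(fieldnames):
            raise MalformedInputError(f"{path}: declared sample columns absent")
    else:
        sample_cols = [c for c in fieldnames if c not in meta]
    if not sample_cols:
        raise MalformedInputError(f"{path}: no sample columns")

    # pair consecutive rows by allele ID, preserving file order
    groups: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in rows:
        aid = row[dialect.allele_id_col]
        if aid not in groups:
            groups[aid] = []
            order.append(aid)
        groups[aid].append(row)

    loci: list[MarkerLocus] = []
    for aid in order:
        pair = groups[aid]
        if len(pair) != 2:
            raise MalformedInputError(
                f"allele ID {aid!r}: expected 2 rows, found {len(pair)}"
            )
        seq_a = pair[0][dialect.sequence_col].upper()
        seq_b = pair[1][dialect.sequence_col].upper()
        if len(seq_a) != len(seq_b):
            raise MalformedInputError(
                f"allele ID {aid!r}: allele sequences of unequal length"
            )
        diffs = [i for i, (a, b) in enumerate(zip(seq_a, seq_b)) if a != b]
        if len(diffs) != 1:
            raise MalformedInputError(
                f"allele ID {aid!r}: allele sequences differ at {len(diffs)} "
                f"positions; a bi-allelic SNP locus requires exactly one"
            )
        offset, ref_base, alt_base = _parse_snp_descriptor(
            pair[0][dialect.snp_col], aid
        )
        if diffs[0] != offset:
            raise MalformedInputError(
                f"allele ID {aid!r}: SNP descriptor offset {offset} inconsistent "
                f"with sequence difference at {diffs[0]}"
            )
        if {seq_a[offset], seq_b[offset]} != {ref_base, alt_base}:
            raise MalformedInputError(
                f"allele ID {aid!r}: SNP descriptor bases {ref_base}>{alt_base} "
                f"inconsistent with sequences"
            )
        if seq_a[offset] == ref_base:
            ref_row, alt_row = pair[0], pair[1]
            ref_seq, alt_seq = seq_a, seq_b
        else:
            ref_row, alt_row = pair[1], pair[0]
            ref_seq, alt_seq = seq_b, seq_a
        calls = np.array(
            [
                _presence_pair_to_call(ref_row[c], alt_row[c], aid)
                for c in sample_cols
            ],
            dtype=np.int8,
        )
        depths = []
        for row in pair:
            try:
                depths.append(float(row[dialect.depth_col]))
            except ValueError as exc:
                raise MalformedInputError(
                    f"allele ID {aid!r}: unparseable depth {row[dialect.depth_col]!r}"
                ) from exc
        loci.append(
            MarkerLocus(
                allele_id=aid,
                allele_seqs=(ref_seq, alt_seq),
                snp_offset=offset,
                calls=calls,
                mean_read_depth=float(np.mean(depths)),
                restriction_motif_present=ref_seq.startswith(
                    dialect.restriction_motif
                ),
            )
        )
    return MarkerTable(loci=loci, individual_ids=sample_cols)


def write_marker_table(
    table: MarkerTable, path, dialect: MarkerDialect = MarkerDialect()
) -> None:
    """Write a :class:`MarkerTable` in the two-row CSV dialect (read round-trips)."""
    if dialect.sample_cols is not None and list(dialect.sample_cols) != list(
        table.individual_ids
    ):
        raise ValueError("dialect sample columns disagree with table individuals")
    meta_cols = [
        dialect.allele_id_col,
        dialect.sequence_col,
        dialect.snp_col,
        dialect.depth_col,
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(meta_cols + list(table.individual_ids))
        for locus in table.loci:
            ref, alt = locus.alleles
            desc = f"{locus.snp_offset}:{ref}>{alt}"
            ref_presence = []
            alt_presence = []
            for call in locus.calls:
                if call == CALL_MISSING:
                    ref_presence.append("-")
                    alt_presence.append("-")
                else:
                    ref_presence.append("1" if call in (CALL_HOM_REF, CALL_HET) else "0")
                    alt_presence.append("1" if call in (CALL_HOM_ALT, CALL_HET) else "0")
            depth = f"{locus.mean_read_depth:g}"
            writer.writerow(
                [locus.allele_id, locus.allele_seqs[0], desc, depth] + ref_presence
            )
            writer.writerow(
                [locus.allele_id, locus.allele_seqs[1], desc, depth] + alt_presence
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered name→uppercase-sequence mapping.

    Rejects empty files, duplicate record names and non-IUPAC characters.
    Case information is folded away (masking state is not preserved here).
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise MalformedInputError(f"{path}: duplicate sequence name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC_CHARS
        if bad:
            raise MalformedInputError(
                f"{path}: record {rec.id!r} has non-IUPAC characters {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise MalformedInputError(f"{path}: no FASTA records")
    return records


def write_fasta(records: dict[str, str], path, line_width: int = 60) -> None:
    if not records:
        raise ValueError("refusing to write an empty FASTA")
    if line_width < 1:
        raise ValueError("line_width must be positive")
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawBlastHit:
    """One row of 12-column BLAST tabular output, coordinates as in the file
    (1-based inclusive; sstart>send encodes a minus-strand subject)."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


def read_blast_tab(path) -> list[RawBlastHit]:
    hits: list[RawBlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise MalformedInputError(
                    f"{path}:{lineno}: expected ≥12 tab-separated columns, "
                    f"found {len(fields)}"
                )
            try:
                hit = RawBlastHit(
                    qseqid=fields[0],
                    sseqid=fields[1],
                    pident=float(fields[2]),
                    length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise MalformedInputError(
                    f"{path}:{lineno}: unparseable numeric field ({exc})"
                ) from exc
            if not math.isfinite(hit.evalue) or hit.evalue < 0:
                raise MalformedInputError(f"{path}:{lineno}: invalid E-value")
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Gene features (BED / GFF3)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """A gene interval on a reference genome, 0-based half-open."""

    species: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    gene_name: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_features(path, format: str, species: str) -> list[GeneFeature]:
    """Read gene features from BED 4+ or GFF3 (``gene``-type rows only).

    All coordinates are normalised to 0-based half-open.
    """
    features: list[GeneFeature] = []
    if format == "BED":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 4:
                    raise MalformedInputError(
                        f"{path}:{lineno}: BED 4+ requires a name column"
                    )
                start, end = int(f[1]), int(f[2])
                strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "+"
                features.append(
                    GeneFeature(species, f[0], start, end, strand, f[3], f[3])
                )
    elif format == "GFF3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise MalformedInputError(
                        f"{path}:{lineno}: GFF3 requires 9 columns"
                    )
                if f[2] != "gene":
                    continue
                start = int(f[3]) - 1  # GFF3 is 1-based inclusive
                end = int(f[4])
                strand = f[6] if f[6] in ("+", "-") else "+"
                attrs = _parse_gff3_attributes(f[8])
                gene_id = attrs.get("ID", f"{f[0]}:{start}-{end}")
                gene_name = attrs.get("Name", gene_id)
                features.append(
                    GeneFeature(species, f[0], start, end, strand, gene_id, gene_name)
                )
    else:
        raise ValueError(f"unknown annotation format {format!r} (expected BED or GFF3)")
    return features


def write_gff3(features: list[GeneFeature], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in features:
            fh.write(
                f"{g.chrom}\tstagpipe\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.gene_name}\n"
            )


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end, name[, score, strand]) tuples as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
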