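"""Marker quality control for bi-allelic restriction-site-anchored SNP tags.

A tag locus is a pair of equal-length allele sequences (usually 69 bp, anchored
at the 5' end by the restriction-site remnant) that differ at exactly one
position, genotyped across a population of diploid individuals.  Loci are
screened on three statistics before they enter the concatenated hypothetical
genome:

* **missing rate** — proportion of individuals without a genotype call
  (the complement of the platform's "call rate");
* **polymorphic information content (PIC)** — informativeness of the locus
  derived from its allele frequency;
* **mean read depth** — sequencing support per locus.

Genotype calls are coded as small integers: ``0`` homozygous reference,
``1`` heterozygous, ``2`` homozygous alternate, ``-1`` missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, NamedTuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .io_formats import MarkerTable

__all__ = [
    "CALL_HOM_REF",
    "CALL_HET",
    "CALL_HOM_ALT",
    "CALL_MISSING",
    "MarkerLocus",
    "QcThresholds",
    "LocusStats",
    "Rejection",
    "pic",
    "locus_stats",
    "filter_markers",
    "write_rejection_log",
]

CALL_HOM_REF = 0
CALL_HET = 1
CALL_HOM_ALT = 2
CALL_MISSING = -1

_IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN")


@dataclass
class MarkerLocus:
    """One bi-allelic tag locus.

    ``allele_seqs`` holds the (reference, alternate) allele sequences; they
    must be equal length and differ at exactly ``snp_offset`` (0-based).
    ``calls`` is an int8 array over the table's individuals using the call
    codes above.
    """

    allele_id: str
    allele_seqs: tuple[str, str]
    snp_offset: int
    calls: np.ndarray
    mean_read_depth: float = 0.0
    restriction_motif_present: bool = False

    def __post_init__(self) -> None:
        ref, alt = self.allele_seqs
        ref, alt = ref.upper(), alt.upper()
        self.allele_seqs = (ref, alt)
        if len(ref) != len(alt):
            raise ValueError(
                f"locus {self.allele_id!r}: allele sequences of unequal length "
                f"({len(ref)} vs {len(alt)})"
            )
        bad = set(ref + alt) - _IUPAC_CHARS
        if bad:
            raise ValueError(
                f"locus {self.allele_id!r}: non-IUPAC characters {sorted(bad)}"
            )
        diffs = [i for i, (a, b) in enumerate(zip(ref, alt)) if a != b]
        if diffs != [self.snp_offset]:
            raise ValueError(
                f"locus {self.allele_id!r}: allele sequences must differ at "
                f"exactly the SNP offset {self.snp_offset}; they differ at {diffs}"
            )
        if not (0 <= self.snp_offset < len(ref)):
            raise ValueError(
                f"locus {self.allele_id!r}: SNP offset {self.snp_offset} outside sequence"
            )
        if self.mean_read_depth < 0:
            raise ValueError(f"locus {self.allele_id!r}: negative read depth")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if not np.isin(self.calls, (CALL_HOM_REF, CALL_HET, CALL_HOM_ALT, CALL_MISSING)).all():
            raise ValueError(f"locus {self.allele_id!r}: invalid call codes")

    @property
    def alleles(self) -> tuple[str, str]:
        """(reference base, alternate base) at the SNP position."""
        return (
            self.allele_seqs[0][self.snp_offset],
            self.allele_seqs[1][self.snp_offset],
        )

    @property
    def tag_length(self) -> int:
        return len(self.allele_seqs[0])


@dataclass(frozen=True)
class QcThresholds:
    """Screening thresholds.

    ``max_missing`` is inclusive (a locus missing in exactly this proportion
    of individuals is retained); ``min_pic`` and ``min_depth`` are strict
    lower bounds, matching how the source platform states them.
    """

    max_missing: float = 0.25
    min_pic: float = 0.025
    min_depth: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must lie in [0, 1]")
        if not 0.0 <= self.min_pic <= 0.375:
            raise ValueError("min_pic must lie in [0, 0.375]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")


class LocusStats(NamedTuple):
    missing_rate: float
    alt_allele_freq: float
    pic_value: float


@dataclass(frozen=True)
class Rejection:
    allele_id: str
    missing_rate: float
    pic: float
    depth: float
    verdict: str
    reason: str


def pic(p: float, method: str = "botstein") -> float:
    """Polymorphic information content of a bi-allelic locus.

    Parameters
    ----------
    p:
        Allele frequency of either allele (the statistic is symmetric).
    method:
        ``"botstein"`` (default): PIC = 1 − (p² + q²) − 2p²q², the standard
        bi-allelic form, maximal at 0.375 for p = 0.5.
        ``"het"``: expected heterozygosity 1 − p² − q², maximal at 0.5 —
        some genotyping platforms report this quantity under the PIC label.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} outside [0, 1]")
    q = 1.0 - p
    het = 1.0 - (p * p + q * q)
    if method == "het":
        return het
    if method == "botstein":
        return het - 2.0 * p * p * q * q
    raise ValueError(f"unknown PIC method {method!r}")


def locus_stats(locus: MarkerLocus, pic_method: str = "botstein") -> LocusStats:
    """Missing rate, alternate-allele frequency and PIC for one locus.

    The allele frequency is computed from genotype calls over non-missing
    diploid individuals: each heterozygote contributes one copy of each
    allele.  A locus with no non-missing calls has no defined frequency.
    """
    calls = locus.calls
    n = calls.size
    if n == 0:
        raise ValueError(f"locus {locus.allele_id!r}: no calls")
    missing = int((calls == CALL_MISSING).sum())
    observed = calls[calls != CALL_MISSING]
    if observed.size == 0:
        raise ValueError(
            f"locus {locus.allele_id!r}: all calls missing; allele frequency undefined"
        )
    alt_copies = int(observed.sum())  # het=1, hom_alt=2 alt copies each
    alt_freq = alt_copies / (2 * observed.size)
    return LocusStats(missing / n, alt_freq, pic(alt_freq, method=pic_method))


def filter_markers(
    table: "MarkerTable",
    thr: QcThresholds = QcThresholds(),
    pic_method: str = "botstein",
) -> tuple["MarkerTable", list[Rejection]]:
    """Apply the three screening rules, preserving input order.

    A locus is retained iff missing_rate ≤ max_missing AND pic > min_pic AND
    mean_read_depth > min_depth.  The rejection log records, for every locus,
    its statistics and (for dropped loci) the first rule that fired, in the
    order missing → pic → depth.
    """
    from .io_formats import MarkerTable  # local import: avoids module cycle

    kept = []
    log: list[Rejection] = []
    for locus in table.loci:
        stats = locus_stats(locus, pic_method=pic_method)
        reasons = []
        if stats.missing_rate > thr.max_missing:
            reasons.append("missing")
        if not stats.pic_value > thr.min_pic:
            reasons.append("pic")
        if not locus.mean_read_depth > thr.min_depth:
            reasons.append("depth")
        if reasons:
            log.append(
                Rejection(
                    locus.allele_id,
                    stats.missing_rate,
                    stats.pic_value,
                    locus.mean_read_depth,
                    "dropped",
                    reasons[0],
                )
            )
        else:
            kept.append(locus)
            log.append(
                Rejection(
                    locus.allele_id,
                    stats.missing_rate,
                    stats.pic_value,
                    locus.mean_read_depth,
                    "retained",
                    "",
                )
            )
    return MarkerTable(loci=kept, individual_ids=list(table.individual_ids)), log


def write_rejection_log(log: Iterable[Rejection], path) -> None:
    with open(path, "w") as fh:
        fh.write("allele_id\tmissing_rate\tpic\tdepth\tverdict\treason\n")
        for r in log:
            fh.write(
                f"{r.allele_id}\t{r.missing_rate:.6g}\t{r.pic:.6g}\t"
                f"{r.depth:.6g}\t{r.verdict}\t{r.reason}\n"
            )
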