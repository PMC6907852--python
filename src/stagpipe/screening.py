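"""Screening cascade for homology hits of the concatenated genome.

Concatenating restriction-site-anchored tags creates a characteristic
artifact: every tag starts with the restriction-site remnant (Pst I leaves
``TGCAG``), so a local alignment that runs across a tag junction can pick up
a fresh copy of the motif and look like one long genuine homology.  A hit is
classified a junction false positive when all three hold:

(i)   its length exceeds the tag length (69 bp by default),
(ii)  its query sequence begins with the restriction motif, and
(iii) the motif prefix continues for at least ``k_min`` bases immediately
      after a junction the hit spans.

Under a uniform random base model a k-base motif prefix recurs at a junction
with probability (1/4)^k — 1 in 4 for ``T``, 1 in 16 for ``TG`` … 1 in 1024
for the full ``TGCAG``.  Run-ons of one or two bases are too probable to be
diagnostic (and two-base ``TG`` run-ons are confounded by dinucleotide
repeats), hence the default ``k_min`` of 3.

Surviving hits are annotated with overlapping genes; genes supported in at
least ``n_species_required`` species by non-repetitive, non-false-positive
tag homologies form the evolutionarily conserved gene set.  Per-species
summaries mirror the hits / unique-tags / aligned-bp / %-of-genome layout
used for multi-species homology tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .homology_search import HomologyHit
from .io_formats import GeneFeature
from .stag_assembly import ConcatRegistry, map_to_stags

__all__ = [
    "FPVerdict",
    "ConservedGene",
    "ConservedGeneSet",
    "SpeciesSummary",
    "motif_runon_probability",
    "junction_runon",
    "classify_false_positive",
    "simulate_junction_runons",
    "associate_genes",
    "select_conserved_genes",
    "summarize_species",
    "write_verdicts_tsv",
    "write_conserved_tsv",
    "write_summary_tsv",
    "read_orthology_map",
    "write_orthology_map",
]

logger = logging.getLogger(__name__)

DEFAULT_MOTIF = "TGCAG"


@dataclass(frozen=True)
class FPVerdict:
    """Per-hit junction false-positive classification."""

    hit_index: int
    is_false_positive: bool
    crit_length_gt_tag: bool
    crit_starts_with_motif: bool
    crit_internal_motif: bool
    junction_runon_k: int
    runon_probability: float


def motif_runon_probability(k: int, motif: str = DEFAULT_MOTIF) -> float:
    """Chance that the first ``k`` motif bases recur at a junction under the
    uniform random base model: (1/4)^k."""
    if not motif:
        raise ValueError("motif must be non-empty")
    if not 0 <= k <= len(motif):
        raise ValueError(f"prefix length {k} outside [0, {len(motif)}]")
    return 0.25**k


def junction_runon(
    hit: HomologyHit,
    genome: str,
    registry: ConcatRegistry,
    motif: str = DEFAULT_MOTIF,
) -> int:
    """Longest motif prefix continuing across a junction inside the hit.

    For each registry junction strictly inside the hit's query interval, the
    run-on is the number of leading motif bases found immediately after the
    junction (truncated at the hit's end); the maximum over spanned junctions
    is returned, 0 for hits within a single STAG.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    qs, qe = hit.query_start, hit.query_end
    motif = motif.upper()
    best = 0
    for j in registry.junctions:
        if not qs < j < qe:
            continue
        limit = min(len(motif), qe - j)
        k = 0
        while k < limit and genome[j + k].upper() == motif[k]:
            k += 1
        best = max(best, k)
    return best


def classify_false_positive(
    hit: HomologyHit,
    genome: str,
    registry: ConcatRegistry,
    motif: str = DEFAULT_MOTIF,
    k_min: int = 3,
    tag_length: int = 69,
    hit_index: int = 0,
) -> FPVerdict:
    """Apply the three junction false-positive criteria to one hit."""
    motif = motif.upper()
    length_gt = hit.length > tag_length
    qseq = genome[hit.query_start : hit.query_end].upper()
    starts_with = qseq.startswith(motif)
    k = junction_runon(hit, genome, registry, motif)
    internal = k >= k_min
    return FPVerdict(
        hit_index=hit_index,
        is_false_positive=length_gt and starts_with and internal,
        crit_length_gt_tag=length_gt,
        crit_starts_with_motif=starts_with,
        crit_internal_motif=internal,
        junction_runon_k=k,
        runon_probability=0.25**k,
    )


def simulate_junction_runons(
    n: int, motif: str = DEFAULT_MOTIF, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Simulate ``n`` random junction extensions and return their motif
    run-on lengths (for empirical validation of the (1/4)^k model)."""
    if rng is None:
        rng = np.random.default_rng()
    motif = motif.upper()
    L = len(motif)
    draws = rng.integers(0, 4, size=(n, L))
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)[draws]
    target = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    match = bases == target
    # run-on length = index of first mismatch
    ks = np.where(match.all(axis=1), L, match.argmin(axis=1))
    return ks.astype(np.int64)


def associate_genes(
    hits: Sequence[HomologyHit],
    features_by_species: Mapping[str, Sequence[GeneFeature]],
) -> None:
    """Fill ``gene_ids`` on each hit with every gene overlapping its subject
    interval by ≥1 bp on the same chromosome (strand-agnostic), in place.

    Species without features leave their hits unannotated, with a warning.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for species, feats in features_by_species.items():
        for g in feats:
            trees.setdefault((species, g.chrom), IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )
    warned: set[str] = set()
    for hit in hits:
        if hit.species not in features_by_species:
            if hit.species not in warned:
                logger.warning(
                    "no gene annotation for species %r; hits left unannotated",
                    hit.species,
                )
                warned.add(hit.species)
            continue
        tree = trees.get((hit.species, hit.subject_chrom))
        if tree is None:
            hit.gene_ids = []
            continue
        hit.gene_ids = sorted(
            {iv.data for iv in tree.overlap(hit.subject_start, hit.subject_end)}
        )


@dataclass
class ConservedGene:
    group_id: str
    species_support: dict[str, dict]  # species -> {gene_id, stag_ids, best_evalue}


@dataclass
class ConservedGeneSet:
    genes: list[ConservedGene]
    n_species_required: int

    @property
    def group_ids(self) -> set[str]:
        return {g.group_id for g in self.genes}


def select_conserved_genes(
    hits_by_species: Mapping[str, Sequence[HomologyHit]],
    stag_repetitive: Mapping[str, bool],
    verdicts_by_species: Mapping[str, Sequence[FPVerdict]],
    n_species_required: int = 3,
    orthology: Mapping[str, str] | None = None,
    gene_names: Mapping[str, str] | None = None,
    registry: ConcatRegistry | None = None,
    min_stag_overlap_bp: int = 10,
) -> ConservedGeneSet:
    """Multi-species intersection of non-repetitive, non-false-positive
    gene-associated homologies.

    Per species: false-positive hits are dropped, gene-associated hits kept,
    and genes whose only supporting STAGs are repetitive are removed.  Genes
    are matched across species by ortholog group (``orthology`` maps gene_id
    → group), falling back to exact gene-name match and finally to the raw
    gene_id.  Groups present in at least ``n_species_required`` per-species
    sets are returned with their supporting non-repetitive STAGs and best
    E-value per species.

    When ``registry`` is given, a STAG counts as supporting a hit only if
    the hit covers at least ``min_stag_overlap_bp`` of it (capped at the hit
    length): ungapped extension routinely overshoots a tag junction by a few
    chance-matching bases, and such slivers are artifacts of concatenation,
    not homologies of the neighbouring tag.  Without a registry every
    back-mapped STAG counts.
    """
    if len(hits_by_species) < n_species_required:
        raise ValueError(
            f"{len(hits_by_species)} species present but "
            f"{n_species_required} required"
        )
    orthology = orthology or {}
    gene_names = gene_names or {}

    def group_of(gene_id: str) -> str:
        return orthology.get(gene_id, gene_names.get(gene_id, gene_id))

    def supporting_stags(hit: HomologyHit) -> list[str]:
        if registry is None:
            return list(hit.stag_ids)
        threshold = min(min_stag_overlap_bp, hit.length)
        mapped = map_to_stags(registry, (hit.query_start, hit.query_end))
        return [
            ov.allele_id
            for ov in mapped.overlaps
            if ov.local_end - ov.local_start >= threshold
        ]

    # group_id -> species -> {gene_id, stag_ids, best_evalue}
    support: dict[str, dict[str, dict]] = {}
    for species, hits in hits_by_species.items():
        verdicts = verdicts_by_species.get(species, [])
        fp_idx = {v.hit_index for v in verdicts if v.is_false_positive}
        per_gene: dict[str, dict] = {}
        for i, hit in enumerate(hits):
            if i in fp_idx or not hit.gene_ids:
                continue
            nonrep = [
                s for s in supporting_stags(hit)
                if not stag_repetitive.get(s, False)
            ]
            for gid in hit.gene_ids:
                rec = per_gene.setdefault(
                    gid, {"gene_id": gid, "stag_ids": set(), "best_evalue": None,
                          "has_nonrep": False}
                )
                if nonrep:
                    rec["has_nonrep"] = True
                    rec["stag_ids"].update(nonrep)
                    if rec["best_evalue"] is None or hit.evalue < rec["best_evalue"]:
                        rec["best_evalue"] = hit.evalue
        for gid, rec in per_gene.items():
            if not rec["has_nonrep"]:
                continue  # only repetitive STAG support: gene dropped
            grp = group_of(gid)
            entry = support.setdefault(grp, {})
            prev = entry.get(species)
            if prev is None or (
                rec["best_evalue"] is not None
                and rec["best_evalue"] < prev["best_evalue"]
            ):
                entry[species] = {
                    "gene_id": gid,
                    "stag_ids": sorted(rec["stag_ids"]),
                    "best_evalue": rec["best_evalue"],
                }

    genes = [
        ConservedGene(group_id=grp, species_support=sup)
        for grp, sup in sorted(support.items())
        if len(sup) >= n_species_required
    ]
    return ConservedGeneSet(genes=genes, n_species_required=n_species_required)


@dataclass
class SpeciesSummary:
    """Per-species homology summary (hits / unique tags / aligned bp per
    category, and the proportion of the genome covered)."""

    species: str
    categories: dict[str, dict]  # {non_repeat, repetitive, gene_associated}
    pct_of_genome: float

    @property
    def total_hits(self) -> int:
        return sum(c["n_hits"] for c in self.categories.values())


def _union_bp(intervals: list[tuple[int, int]]) -> int:
    ivs = sorted(intervals)
    total = 0
    cur_s, cur_e = None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def summarize_species(
    hits: Sequence[HomologyHit],
    verdicts: Sequence[FPVerdict],
    stag_repetitive: Mapping[str, bool],
    genome_len: int,
    species: str = "",
) -> SpeciesSummary:
    """Categorise one species' hits (false positives excluded) and total them.

    Categories: ``gene_associated`` (≥1 gene), else ``repetitive`` (any
    supporting STAG repetitive), else ``non_repeat``.  Aligned bp per
    category is the union of query intervals (overlaps collapsed); the
    percentage of the genome is the collapsed union over all categories.
    """
    fp_idx = {v.hit_index for v in verdicts if v.is_false_positive}
    cats = {
        name: {"n_hits": 0, "n_unique_stags": 0, "total_aligned_bp": 0,
               "_stags": set(), "_ivs": []}
        for name in ("non_repeat", "repetitive", "gene_associated")
    }
    all_ivs: list[tuple[int, int]] = []
    for i, hit in enumerate(hits):
        if i in fp_idx:
            continue
        if hit.gene_ids:
            cat = "gene_associated"
        elif any(stag_repetitive.get(s, False) for s in hit.stag_ids):
            cat = "repetitive"
        else:
            cat = "non_repeat"
        c = cats[cat]
        c["n_hits"] += 1
        c["_stags"].update(hit.stag_ids)
        c["_ivs"].append((hit.query_start, hit.query_end))
        all_ivs.append((hit.query_start, hit.query_end))
    for c in cats.values():
        c["n_unique_stags"] = len(c.pop("_stags"))
        c["total_aligned_bp"] = _union_bp(c.pop("_ivs"))
    pct = 100.0 * _union_bp(all_ivs) / genome_len if genome_len else 0.0
    return SpeciesSummary(species=species, categories=cats, pct_of_genome=pct)


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def write_verdicts_tsv(verdicts: Sequence[FPVerdict], path, species: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(
            "species\thit_index\tis_false_positive\tcrit_length_gt_tag\t"
            "crit_starts_with_motif\tcrit_internal_motif\tjunction_runon_k\t"
            "runon_probability\n"
        )
        for v in verdicts:
            fh.write(
                f"{species}\t{v.hit_index}\t{int(v.is_false_positive)}\t"
                f"{int(v.crit_length_gt_tag)}\t{int(v.crit_starts_with_motif)}\t"
                f"{int(v.crit_internal_motif)}\t{v.junction_runon_k}\t"
                f"{v.runon_probability:.6g}\n"
            )


def write_conserved_tsv(conserved: ConservedGeneSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tspecies\tgene_id\tsupporting_stags\tbest_evalue\n")
        for gene in conserved.genes:
            for species in sorted(gene.species_support):
                rec = gene.species_support[species]
                ev = rec["best_evalue"]
                fh.write(
                    f"{gene.group_id}\t{species}\t{rec['gene_id']}\t"
                    f"{','.join(rec['stag_ids'])}\t"
                    f"{'' if ev is None else format(ev, '.3g')}\n"
                )


SUMMARY_COLUMNS = [
    "species",
    "non_repeat_hits", "non_repeat_stags", "non_repeat_bp",
    "repetitive_hits", "repetitive_stags", "repetitive_bp",
    "gene_hits", "gene_stags", "gene_bp",
    "total_hits", "total_stags", "total_bp",
    "pct_of_genome",
]


def write_summary_tsv(summaries: Sequence[SpeciesSummary], path) -> None:
    """Species summary table: per category the hit count, unique-tag count
    and aligned bp, plus totals and %-of-genome."""
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for s in summaries:
            row = [s.species]
            total_hits = total_stags = total_bp = 0
            for cat in ("non_repeat", "repetitive", "gene_associated"):
                c = s.categories[cat]
                row += [
                    str(c["n_hits"]),
                    str(c["n_unique_stags"]),
                    str(c["total_aligned_bp"]),
                ]
                total_hits += c["n_hits"]
                total_stags += c["n_unique_stags"]
                total_bp += c["total_aligned_bp"]
            row += [str(total_hits), str(total_stags), str(total_bp),
                    f"{s.pct_of_genome:.2f}"]
            fh.write("\t".join(row) + "\n")


def read_orthology_map(path) -> dict[str, str]:
    """Two-column TSV: gene_id <tab> ortholog_group."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene_id, group = line.split("\t")[:2]
            out[gene_id] = group
    return out


def write_orthology_map(mapping: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(mapping):
            fh.write(f"{gene_id}\t{mapping[gene_id]}\n")
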