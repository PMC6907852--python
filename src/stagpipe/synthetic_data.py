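"""Deterministic synthetic data emulating a restriction-tag genotyping study.

The generators produce everything the pipeline consumes — reference genomes
with planted genes and dinucleotide repeat tracts, tag loci anchored at
restriction-motif sites, and diploid population genotypes with missing calls
— together with ground-truth records, so parameter-recovery tests can check
the pipeline end to end against known plantings.

Scale defaults are desk-scale versions of the original study design (a 90
individual population genotyped at ~69 bp Pst I-anchored tags, compared
against three annotated reference species): a few hundred loci and
0.1–0.2 Mb references keep full runs under a minute while preserving the
study's structure.  Genotypes follow Hardy–Weinberg proportions at each
locus's allele frequency — the simplest population model consistent with
bi-allelic SNP data.  All randomness flows through one integer seed;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    GeneFeature,
    MarkerDialect,
    MarkerTable,
    write_fasta,
    write_gff3,
    write_marker_table,
)
from .marker_qc import CALL_MISSING, MarkerLocus
from .screening import write_orthology_map

__all__ = [
    "ReferenceBundle",
    "ScenarioBundle",
    "generate_reference",
    "sample_tag_loci",
    "simulate_population",
    "make_conserved_scenario",
]

DEFAULT_MOTIF = "TGCAG"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


@dataclass
class ReferenceBundle:
    """One synthetic reference genome with its annotation and truth records."""

    species: str
    sequences: dict[str, str]
    genes: list[GeneFeature]
    repeat_tracts: list[tuple[str, int, int, str]]  # chrom, start, end, unit
    seed: int | None = None


def generate_reference(
    seed: int | None = None,
    n_chroms: int = 1,
    chrom_len: int = 100_000,
    n_genes: int = 10,
    n_repeat_tracts: int = 5,
    gene_len: tuple[int, int] = (2_000, 5_000),
    repeat_units: tuple[str, ...] = ("AC", "TG", "CT"),
    repeat_copies: int = 15,
    species: str = "synthA",
    rng: np.random.Generator | None = None,
) -> ReferenceBundle:
    """Uniform-random reference with non-overlapping genes and planted
    perfect dinucleotide repeat tracts."""
    if chrom_len < 1_000:
        raise ValueError("chrom_len must be at least 1 kb")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_features = n_genes + n_repeat_tracts
    max_feat = max(gene_len[1], 2 * repeat_copies)
    if n_features * (max_feat + 100) > n_chroms * chrom_len:
        raise ValueError("requested features exceed chromosome capacity")

    sequences = {
        f"chr{i + 1}": _random_seq(rng, chrom_len) for i in range(n_chroms)
    }
    # partition each chromosome into equal slots; one feature per slot
    slots: list[tuple[str, int, int]] = []
    per_chrom = -(-n_features // n_chroms)
    for chrom in sequences:
        width = chrom_len // per_chrom
        for k in range(per_chrom):
            slots.append((chrom, k * width, (k + 1) * width))
    order = rng.permutation(len(slots))
    genes: list[GeneFeature] = []
    tracts: list[tuple[str, int, int, str]] = []
    for idx in range(n_genes):
        chrom, lo, hi = slots[order[idx]]
        length = int(rng.integers(gene_len[0], gene_len[1] + 1))
        length = min(length, hi - lo - 2)
        start = lo + int(rng.integers(0, hi - lo - length))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"{species}_g{idx + 1:03d}"
        genes.append(GeneFeature(species, chrom, start, start + length, strand, gid, gid))
    for idx in range(n_repeat_tracts):
        chrom, lo, hi = slots[order[n_genes + idx]]
        unit = repeat_units[int(rng.integers(0, len(repeat_units)))]
        tract = unit * repeat_copies
        start = lo + int(rng.integers(0, max(1, hi - lo - len(tract))))
        seq = sequences[chrom]
        sequences[chrom] = seq[:start] + tract + seq[start + len(tract):]
        tracts.append((chrom, start, start + len(tract), unit))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return ReferenceBundle(species, sequences, genes, tracts, seed)


def _plant(sequences: dict[str, str], chrom: str, pos: int, payload: str) -> None:
    seq = sequences[chrom]
    sequences[chrom] = seq[:pos] + payload + seq[pos + len(payload):]


def sample_tag_loci(
    reference: dict[str, str],
    motif: str = DEFAULT_MOTIF,
    n_loci: int = 200,
    tag_len: int = 69,
    mut_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    genes: list[GeneFeature] | None = None,
    repeat_tracts: list[tuple[str, int, int, str]] | None = None,
) -> tuple[list[MarkerLocus], dict]:
    """Sample tag loci at restriction-motif occurrences in the reference.

    Each locus is ``tag_len`` bases starting at a motif occurrence; one
    random offset past the motif becomes the SNP, with a random alternate
    base.  ``mut_rate`` mutates non-SNP tag positions away from the
    reference (0 keeps every tag an exact substring).  Allele IDs ascend
    with genomic position.  The truth dict records each locus's source
    interval and any gene / repeat-tract overlaps.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    motif = motif.upper()
    sites: list[tuple[str, int]] = []
    for chrom in sorted(reference):
        seq = reference[chrom].upper()
        start = seq.find(motif)
        while start != -1:
            if start + tag_len <= len(seq):
                sites.append((chrom, start))
            start = seq.find(motif, start + 1)
    if len(sites) < n_loci:
        raise ValueError(
            f"reference contains {len(sites)} usable motif occurrences; "
            f"{n_loci} loci requested"
        )
    chosen_idx = sorted(rng.choice(len(sites), size=n_loci, replace=False))
    loci: list[MarkerLocus] = []
    truth_sites = []
    for rank, si in enumerate(chosen_idx):
        chrom, pos = sites[si]
        tag = list(reference[chrom][pos : pos + tag_len].upper())
        if mut_rate > 0:
            for j in range(len(motif), tag_len):
                if rng.random() < mut_rate:
                    tag[j] = "ACGT"[int(rng.integers(0, 4))]
        snp_offset = int(rng.integers(len(motif) + 1, tag_len))
        ref_base = tag[snp_offset]
        alt_base = "ACGT".replace(ref_base, "")[int(rng.integers(0, 3))]
        ref_seq = "".join(tag)
        alt_seq = ref_seq[:snp_offset] + alt_base + ref_seq[snp_offset + 1 :]
        allele_id = f"1{rank + 1:06d}"
        loci.append(
            MarkerLocus(
                allele_id=allele_id,
                allele_seqs=(ref_seq, alt_seq),
                snp_offset=snp_offset,
                calls=np.zeros(0, dtype=np.int8),
                restriction_motif_present=True,
            )
        )
        linked_genes = [
            g.gene_id
            for g in (genes or [])
            if g.chrom == chrom and g.start < pos + tag_len and pos < g.end
        ]
        linked_repeats = [
            (c, s, e)
            for (c, s, e, _u) in (repeat_tracts or [])
            if c == chrom and s < pos + tag_len and pos < e
        ]
        truth_sites.append(
            {
                "stag_id": allele_id,
                "chrom": chrom,
                "start": pos,
                "end": pos + tag_len,
                "snp_offset": snp_offset,
                "genes": linked_genes,
                "repeat_overlap": bool(linked_repeats),
            }
        )
    truth = {"sites": truth_sites, "motif": motif, "tag_len": tag_len}
    return loci, truth


def simulate_population(
    loci: list[MarkerLocus],
    n_individuals: int = 90,
    allele_freqs: np.ndarray | float | None = None,
    missing_rate: float = 0.05,
    depth_mean: float = 90.0,
    depth_sd: float = 15.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MarkerTable, dict]:
    """Diploid genotypes under Hardy–Weinberg proportions, with missing calls.

    ``allele_freqs`` gives the alternate-allele frequency per locus (scalar
    broadcast, or Uniform(0.1, 0.9) draws when omitted).  Calls are masked
    missing independently at ``missing_rate``; per-locus mean read depth is
    Normal(depth_mean, depth_sd) truncated below at 1.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_loci = len(loci)
    if allele_freqs is None:
        freqs = rng.uniform(0.1, 0.9, size=n_loci)
    else:
        freqs = np.broadcast_to(np.asarray(allele_freqs, float), (n_loci,)).copy()
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")

    out_loci: list[MarkerLocus] = []
    for locus, f in zip(loci, freqs):
        probs = [(1 - f) ** 2, 2 * f * (1 - f), f**2]
        calls = rng.choice(3, size=n_individuals, p=probs).astype(np.int8)
        miss = rng.random(n_individuals) < missing_rate
        calls[miss] = CALL_MISSING
        depth = max(1.0, float(rng.normal(depth_mean, depth_sd)))
        out_loci.append(
            MarkerLocus(
                allele_id=locus.allele_id,
                allele_seqs=locus.allele_seqs,
                snp_offset=locus.snp_offset,
                calls=calls,
                mean_read_depth=depth,
                restriction_motif_present=locus.restriction_motif_present,
            )
        )
    individual_ids = [f"ind{i + 1:03d}" for i in range(n_individuals)]
    table = MarkerTable(loci=out_loci, individual_ids=individual_ids)
    truth = {
        "n_individuals": n_individuals,
        "missing_rate": missing_rate,
        "allele_freqs": {
            locus.allele_id: float(f) for locus, f in zip(loci, freqs)
        },
    }
    return table, truth


@dataclass
class ScenarioBundle:
    """Multi-species bundle with planted conserved, private and repeat-borne
    tag homologies, plus the ground truth needed to score recovery."""

    species: list[str]
    references: dict[str, dict[str, str]]
    annotations: dict[str, list[GeneFeature]]
    orthology: dict[str, str]
    marker_table: MarkerTable
    dialect: MarkerDialect
    truth: dict

    def write(self, outdir) -> dict:
        """Emit every file in the dialects the readers accept; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict = {"references": {}, "annotations": {}}
        for sp in self.species:
            ref_path = outdir / f"reference_{sp}.fasta"
            write_fasta(self.references[sp], ref_path)
            gff_path = outdir / f"genes_{sp}.gff3"
            write_gff3(self.annotations[sp], gff_path)
            paths["references"][sp] = str(ref_path)
            paths["annotations"][sp] = str(gff_path)
        paths["markers"] = str(outdir / "markers.csv")
        write_marker_table(self.marker_table, paths["markers"], self.dialect)
        paths["dialect"] = str(outdir / "dialect.yaml")
        self.dialect.to_yaml(paths["dialect"])
        paths["orthology"] = str(outdir / "orthology.tsv")
        write_orthology_map(self.orthology, paths["orthology"])
        paths["truth"] = str(outdir / "truth.json")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def make_conserved_scenario(
    seed: int = 0,
    n_species: int = 3,
    n_conserved: int = 5,
    n_private: int = 20,
    n_background: int = 30,
    n_repeat_decoys: int = 1,
    chrom_len: int = 120_000,
    gene_len: int = 3_000,
    tag_len: int = 69,
    motif: str = DEFAULT_MOTIF,
    n_individuals: int = 90,
    missing_rate: float = 0.05,
    depth_mean: float = 100.0,
    depth_sd: float = 10.0,
) -> ScenarioBundle:
    """Build a multi-species recovery scenario with known ground truth.

    ``n_conserved`` ortholog groups get a dedicated tag planted inside the
    group's gene in *every* species; ``n_private`` genes exist in exactly one
    species each (round-robin) and carry their own planted tag there;
    ``n_repeat_decoys`` genes are shared across species but supported only
    by a tag that is half dinucleotide repeat, so repeat masking must remove
    them from conserved support.  ``n_background`` tags are planted nowhere.
    """
    if n_species < 2:
        raise ValueError("a conserved-gene scenario needs at least 2 species")
    rng = np.random.default_rng(seed)
    motif = motif.upper()
    species = [f"sp{chr(ord('A') + i)}" for i in range(n_species)]

    # --- construct the tag set -------------------------------------------
    def new_tag(payload: str | None = None, snp_hi: int | None = None) -> tuple[str, str, int]:
        body = payload if payload is not None else _random_seq(rng, tag_len - len(motif))
        seq = motif + body
        hi = snp_hi if snp_hi is not None else tag_len
        snp = int(rng.integers(len(motif) + 1, hi))
        ref = seq[snp]
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        return seq, alt, snp

    tags: list[dict] = []  # role, seq, alt, snp
    for i in range(n_conserved):
        seq, alt, snp = new_tag()
        tags.append({"role": "conserved", "group": f"OG{i + 1:03d}",
                     "seq": seq, "alt": alt, "snp": snp})
    for i in range(n_private):
        seq, alt, snp = new_tag()
        tags.append({"role": "private", "host": species[i % n_species],
                     "index": i, "seq": seq, "alt": alt, "snp": snp})
    for i in range(n_repeat_decoys):
        # tract long enough for the tandem detector, short enough that the
        # low-complexity scan leaves the unique prefix seedable
        unique_len = tag_len - len(motif) - 18
        payload = _random_seq(rng, unique_len) + "AC" * 9
        seq, alt, snp = new_tag(payload, snp_hi=len(motif) + 1 + unique_len)
        tags.append({"role": "repeat_decoy", "group": f"OGrep{i + 1}",
                     "seq": seq, "alt": alt, "snp": snp})
    for i in range(n_background):
        seq, alt, snp = new_tag()
        tags.append({"role": "background", "seq": seq, "alt": alt, "snp": snp})

    order = rng.permutation(len(tags))
    loci: list[MarkerLocus] = []
    for rank, ti in enumerate(order):
        t = tags[ti]
        aid = f"1{rank + 1:06d}"
        t["stag_id"] = aid
        ref_seq = t["seq"]
        alt_seq = ref_seq[: t["snp"]] + t["alt"] + ref_seq[t["snp"] + 1 :]
        loci.append(
            MarkerLocus(
                allele_id=aid,
                allele_seqs=(ref_seq, alt_seq),
                snp_offset=t["snp"],
                calls=np.zeros(0, dtype=np.int8),
                restriction_motif_present=True,
            )
        )

    # --- per-species references with planted genes -----------------------
    references: dict[str, dict[str, str]] = {}
    annotations: dict[str, list[GeneFeature]] = {}
    orthology: dict[str, str] = {}
    planted: list[dict] = []
    for s_idx, sp in enumerate(species):
        host_tags = [
            t for t in tags
            if t["role"] in ("conserved", "repeat_decoy")
            or (t["role"] == "private" and t.get("host") == sp)
        ]
        n_genes = len(host_tags)
        ref = generate_reference(
            rng=rng,
            n_chroms=1,
            chrom_len=chrom_len,
            n_genes=n_genes,
            n_repeat_tracts=3,
            gene_len=(gene_len, gene_len),
            species=sp,
        )
        gene_list = list(ref.genes)
        assign = rng.permutation(n_genes)
        # every concatenation junction in the query continues with the
        # restriction motif, so following each planting with bases that
        # differ from the motif position-by-position guarantees the planted
        # homology ends at the tag boundary — otherwise a few chance-matching
        # subject bases extend the hit past the junction and the (correct)
        # junction false-positive screen discards genuine planted support
        barrier = "".join("T" if c != "T" else "C" for c in motif)
        for t, gi in zip(host_tags, assign):
            g = gene_list[gi]
            pos = g.start + (g.end - g.start - tag_len) // 2
            _plant(ref.sequences, g.chrom, pos, t["seq"] + barrier)
            if t["role"] in ("conserved", "repeat_decoy"):
                orthology[g.gene_id] = t["group"]
            planted.append(
                {
                    "stag_id": t["stag_id"],
                    "species": sp,
                    "chrom": g.chrom,
                    "start": pos,
                    "end": pos + tag_len,
                    "gene_id": g.gene_id,
                    "role": t["role"],
                }
            )
        references[sp] = ref.sequences
        annotations[sp] = gene_list

    # --- population genotypes --------------------------------------------
    # scenario genotypes use a depth distribution comfortably above the
    # screening threshold: the scenario isolates conserved-gene recovery,
    # depth attrition being exercised by the QC stage on its own
    table, pop_truth = simulate_population(
        loci,
        n_individuals=n_individuals,
        missing_rate=missing_rate,
        depth_mean=depth_mean,
        depth_sd=depth_sd,
        rng=rng,
    )

    truth = {
        "seed": seed,
        "planted_homologies": planted,
        "planted_conserved_genes": sorted(
            t["group"] for t in tags if t["role"] == "conserved"
        ),
        "planted_repeat_groups": sorted(
            t["group"] for t in tags if t["role"] == "repeat_decoy"
        ),
        "planted_repeat_stags": sorted(
            t["stag_id"] for t in tags if t["role"] == "repeat_decoy"
        ),
        "private_gene_count": n_private,
        "population_params": pop_truth,
    }
    return ScenarioBundle(
        species=species,
        references=references,
        annotations=annotations,
        orthology=orthology,
        marker_table=table,
        dialect=MarkerDialect(restriction_motif=motif),
        truth=truth,
    )
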