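"""End-to-end pipeline driver: qc → stags → consensus → mask → search/ingest
→ false-positive screen → conserved genes → summaries.

Every stage reads its inputs from the previous stage's files and writes its
outputs before the next stage starts, so the chained driver is equivalent to
invoking the stages one by one on the intermediate files.  A machine-readable
manifest (package version, config hash, seed, output paths) is written at the
end; reruns with identical config and inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .homology_search import (
    HomologyHit,
    ScoringScheme,
    ingest_hits,
    read_hits_tsv,
    seed_extend_search,
    write_hits_tsv,
)
from .io_formats import (
    MarkerDialect,
    read_blast_tab,
    read_fasta,
    read_gene_features,
    read_marker_table,
    write_fasta,
    write_marker_table,
)
from .marker_qc import QcThresholds, filter_markers, write_rejection_log
from .repeat_masking import (
    RepeatReport,
    apply_mask,
    classify_stag_repetitiveness,
    find_tandem_repeats,
    low_complexity_mask,
    read_mask_bed,
    write_mask_bed,
)
from .screening import (
    associate_genes,
    classify_false_positive,
    read_orthology_map,
    select_conserved_genes,
    summarize_species,
    write_conserved_tsv,
    write_summary_tsv,
    write_verdicts_tsv,
)
from .stag_assembly import (
    ConcatRegistry,
    build_consensus,
    build_stags,
    concat_individual,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Defaults follow the screening parameters the tag-concatenation protocol
    prescribes: call-ratio 0.25, PIC > 0.025, depth > 60, motif TGCAG, tag
    length 69, +1/−3 scoring with an E-value ceiling of 1e−10, junction
    run-on threshold k_min = 3, three species required for conservation.
    """

    markers: str = ""
    dialect: str | None = None
    references: dict = field(default_factory=dict)   # species -> FASTA path
    annotations: dict = field(default_factory=dict)  # species -> {path, format}
    blast_hits: dict = field(default_factory=dict)   # species -> tabular path
    orthology: str | None = None
    external_mask: str | None = None
    outdir: str = "stagpipe_out"

    max_missing: float = 0.25
    min_pic: float = 0.025
    min_depth: float = 60.0
    pic_method: str = "botstein"

    restriction_motif: str = "TGCAG"
    tag_length: int = 69

    tandem_min_unit: int = 1
    tandem_max_unit: int = 4
    tandem_min_copies: float = 5
    tandem_min_span: int = 10
    lc_window: int = 64
    lc_threshold: float = 2.0
    repeat_min_overlap_bp: int = 1

    match: int = 1
    mismatch: int = -3
    evalue_max: float = 1e-10
    word_size: int = 11
    xdrop: int = 20

    k_min: int = 3
    n_species_required: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        QcThresholds(self.max_missing, self.min_pic, self.min_depth)  # range checks
        ScoringScheme(self.match, self.mismatch, evalue_max=self.evalue_max,
                      word_size=self.word_size, xdrop=self.xdrop)
        if not self.restriction_motif or set(self.restriction_motif.upper()) - set("ACGT"):
            raise ValueError("restriction_motif must be a non-empty ACGT string")
        if self.tag_length <= len(self.restriction_motif):
            raise ValueError("tag_length must exceed the motif length")
        if not 0 <= self.k_min <= len(self.restriction_motif):
            raise ValueError("k_min must lie within the motif length")
        if self.n_species_required < 1:
            raise ValueError("n_species_required must be positive")
        if self.lc_window < 4:
            raise ValueError("lc_window must be at least 4")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(self.max_missing, self.min_pic, self.min_depth)

    @property
    def scoring_scheme(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch, evalue_max=self.evalue_max,
                             word_size=self.word_size, xdrop=self.xdrop)

    def marker_dialect(self) -> MarkerDialect:
        if self.dialect:
            return MarkerDialect.from_yaml(self.dialect)
        return MarkerDialect(restriction_motif=self.restriction_motif)


# ---------------------------------------------------------------------------
# stage functions: each reads the previous stage's files and writes its own
# ---------------------------------------------------------------------------

def stage_qc(config: PipelineConfig, outdir: Path) -> Path:
    dialect = config.marker_dialect()
    table = read_marker_table(config.markers, dialect)
    filtered, log = filter_markers(table, config.qc_thresholds, config.pic_method)
    write_rejection_log(log, outdir / "qc_rejections.tsv")
    out = outdir / "markers_filtered.csv"
    write_marker_table(filtered, out, dialect)
    logger.info("qc: retained %d of %d loci", len(filtered), len(table))
    return out


def stage_build(config: PipelineConfig, outdir: Path) -> tuple[Path, Path]:
    dialect = config.marker_dialect()
    table = read_marker_table(outdir / "markers_filtered.csv", dialect)
    stags = build_stags(table.loci)
    by_id = {locus.allele_id: locus for locus in table.loci}
    sequences = []
    registry = None
    for idx in range(len(table.individual_ids)):
        calls = {aid: int(by_id[aid].calls[idx]) for aid in by_id}
        seq, registry = concat_individual(stags, calls)
        sequences.append(seq)
    genome = build_consensus(sequences, registry)
    fasta_path = outdir / "consensus.fasta"
    write_fasta({"GP-H-Genome": genome.consensus}, fasta_path)
    registry_path = outdir / "registry.tsv"
    genome.registry.to_tsv(registry_path)
    with open(outdir / "consensus_stats.json", "w") as fh:
        json.dump(
            {
                "length_bp": genome.registry.total_length,
                "gc_content": genome.gc_content,
                "n_individuals": genome.n_individuals,
                "n_stags": len(genome.registry.entries),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return fasta_path, registry_path


def stage_mask(config: PipelineConfig, outdir: Path) -> Path:
    consensus = read_fasta(outdir / "consensus.fasta")["GP-H-Genome"]
    registry = ConcatRegistry.from_tsv(outdir / "registry.tsv")
    intervals = find_tandem_repeats(
        consensus,
        min_unit=config.tandem_min_unit,
        max_unit=config.tandem_max_unit,
        min_copies=config.tandem_min_copies,
        min_span=config.tandem_min_span,
    )
    intervals += low_complexity_mask(consensus, config.lc_window, config.lc_threshold)
    if config.external_mask:
        intervals += read_mask_bed(config.external_mask)
    report = RepeatReport.build(intervals, len(consensus))
    write_mask_bed(report.intervals, outdir / "mask.bed")
    report.to_tsv(outdir / "repeat_report.tsv")
    report.to_json(outdir / "repeat_report.json")
    masked = apply_mask(consensus, report.intervals, mode="soft")
    write_fasta({"GP-H-Genome": masked}, outdir / "consensus_masked.fasta")
    rep = classify_stag_repetitiveness(
        registry, report.intervals, config.repeat_min_overlap_bp
    )
    with open(outdir / "stag_repetitiveness.tsv", "w") as fh:
        fh.write("allele_id\trepetitive\n")
        for aid, flag in rep.items():
            fh.write(f"{aid}\t{int(flag)}\n")
    return outdir / "mask.bed"


def _read_repetitiveness(outdir: Path) -> dict[str, bool]:
    out: dict[str, bool] = {}
    with open(outdir / "stag_repetitiveness.tsv") as fh:
        next(fh)
        for line in fh:
            aid, flag = line.rstrip("\n").split("\t")
            out[aid] = bool(int(flag))
    return out


def stage_search(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    registry = ConcatRegistry.from_tsv(outdir / "registry.tsv")
    genome_len = registry.total_length
    # read with case preserved: masked FASTA is written soft-masked
    masked = _read_fasta_preserve_case(outdir / "consensus_masked.fasta")["GP-H-Genome"]
    scheme = config.scoring_scheme
    paths: dict[str, Path] = {}
    for species, ref_path in sorted(config.references.items()):
        if species in config.blast_hits:
            records = read_blast_tab(config.blast_hits[species])
            hits = ingest_hits(records, registry, genome_len,
                               config.evalue_max, species)
        else:
            subject = read_fasta(ref_path)
            hits = seed_extend_search(masked, subject, scheme, species, registry)
        out = outdir / f"hits_{species}.tsv"
        write_hits_tsv(hits, out)
        paths[species] = out
        logger.info("search: %s -> %d hits", species, len(hits))
    return paths


def _read_fasta_preserve_case(path) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
    if name is not None:
        records[name] = "".join(parts)
    return records


def stage_screen(config: PipelineConfig, outdir: Path) -> None:
    consensus = read_fasta(outdir / "consensus.fasta")["GP-H-Genome"]
    registry = ConcatRegistry.from_tsv(outdir / "registry.tsv")
    for species in sorted(config.references):
        hits = read_hits_tsv(outdir / f"hits_{species}.tsv")
        verdicts = [
            classify_false_positive(
                hit, consensus, registry,
                motif=config.restriction_motif,
                k_min=config.k_min,
                tag_length=config.tag_length,
                hit_index=i,
            )
            for i, hit in enumerate(hits)
        ]
        write_verdicts_tsv(verdicts, outdir / f"fp_verdicts_{species}.tsv", species)


def _read_verdicts(path):
    from .screening import FPVerdict

    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                FPVerdict(
                    hit_index=int(f[1]),
                    is_false_positive=bool(int(f[2])),
                    crit_length_gt_tag=bool(int(f[3])),
                    crit_starts_with_motif=bool(int(f[4])),
                    crit_internal_motif=bool(int(f[5])),
                    junction_runon_k=int(f[6]),
                    runon_probability=float(f[7]),
                )
            )
    return out


def stage_genes(config: PipelineConfig, outdir: Path) -> Path:
    features = {}
    for species, spec in config.annotations.items():
        if isinstance(spec, str):
            path, fmt = spec, "GFF3"
        else:
            path, fmt = spec["path"], spec.get("format", "GFF3")
        features[species] = read_gene_features(path, fmt, species)
    missing = set(config.references) - set(features)
    if missing:
        logger.warning("no annotation for species: %s", sorted(missing))

    hits_by_species = {}
    verdicts_by_species = {}
    for species in sorted(config.references):
        hits = read_hits_tsv(outdir / f"hits_{species}.tsv")
        associate_genes(hits, features)
        write_hits_tsv(hits, outdir / f"hits_annotated_{species}.tsv")
        hits_by_species[species] = hits
        verdicts_by_species[species] = _read_verdicts(
            outdir / f"fp_verdicts_{species}.tsv"
        )
    repetitive = _read_repetitiveness(outdir)
    orthology = read_orthology_map(config.orthology) if config.orthology else {}
    gene_names = {
        g.gene_id: g.gene_name for feats in features.values() for g in feats
    }
    annotated = {sp: h for sp, h in hits_by_species.items() if sp in features}
    if len(annotated) < config.n_species_required:
        raise PipelineError(
            "genes",
            f"only {len(annotated)} annotated species but "
            f"{config.n_species_required} required",
        )
    registry = ConcatRegistry.from_tsv(outdir / "registry.tsv")
    conserved = select_conserved_genes(
        annotated,
        repetitive,
        verdicts_by_species,
        n_species_required=config.n_species_required,
        orthology=orthology,
        gene_names=gene_names,
        registry=registry,
    )
    out = outdir / "conserved_genes.tsv"
    write_conserved_tsv(conserved, out)
    return out


def stage_summarize(config: PipelineConfig, outdir: Path) -> Path:
    registry = ConcatRegistry.from_tsv(outdir / "registry.tsv")
    repetitive = _read_repetitiveness(outdir)
    summaries = []
    for species in sorted(config.references):
        hits = read_hits_tsv(outdir / f"hits_annotated_{species}.tsv")
        verdicts = _read_verdicts(outdir / f"fp_verdicts_{species}.tsv")
        summaries.append(
            summarize_species(hits, verdicts, repetitive,
                              registry.total_length, species)
        )
    out = outdir / "species_summary.tsv"
    write_summary_tsv(summaries, out)
    return out


_STAGES = [
    ("qc", stage_qc),
    ("build", stage_build),
    ("mask", stage_mask),
    ("search", stage_search),
    ("screen", stage_screen),
    ("genes", stage_genes),
    ("summarize", stage_summarize),
]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fn in _STAGES:
        logger.info("running stage %s", name)
        try:
            fn(config, outdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "stagpipe_version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
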