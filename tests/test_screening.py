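import numpy as np
import pytest

from stagpipe.homology_search import HomologyHit
from stagpipe.io_formats import GeneFeature
from stagpipe.screening import (
    FPVerdict,
    associate_genes,
    classify_false_positive,
    junction_runon,
    motif_runon_probability,
    select_conserved_genes,
    simulate_junction_runons,
    summarize_species,
    write_summary_tsv,
    SUMMARY_COLUMNS,
)
from stagpipe.stag_assembly import ConcatRegistry


def make_genome(tags):
    """Concatenate motif-anchored tag sequences into (genome, registry)."""
    registry = ConcatRegistry.from_lengths(
        (str(i + 1), len(t)) for i, t in enumerate(tags)
    )
    return "".join(tags), registry


def make_hit(qs, qe, species="sp", chrom="chr1", ss=None, evalue=1e-20,
             genes=(), stags=()):
    ss = 100 if ss is None else ss
    return HomologyHit(
        query_start=qs, query_end=qe, species=species, subject_chrom=chrom,
        subject_start=ss, subject_end=ss + (qe - qs), strand="+",
        raw_score=float(qe - qs), evalue=evalue, pct_identity=100.0,
        stag_ids=list(stags), gene_ids=list(genes),
    )


TAG_A = "TGCAG" + "A" * 64          # 69 bp, motif-anchored
TAG_B = "TGCAG" + "C" * 64
TAG_C = "TGCAG" + "G" * 64


class TestMotifRunonProbability:
    @pytest.mark.parametrize("k,expected", [
        (0, 1.0), (1, 0.25), (2, 1 / 16), (3, 1 / 64), (4, 1 / 256), (5, 1 / 1024),
    ])
    def test_uniform_base_model(self, k, expected):
        assert motif_runon_probability(k) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            motif_runon_probability(-1)
        with pytest.raises(ValueError):
            motif_runon_probability(6)


class TestJunctionRunon:
    def test_full_motif_after_junction(self):
        genome, reg = make_genome([TAG_A, TAG_B])
        hit = make_hit(30, 80)  # crosses junction at 69, 11 bases beyond
        assert junction_runon(hit, genome, reg) == 5

    def test_hit_ending_at_junction(self):
        genome, reg = make_genome([TAG_A, TAG_B])
        hit = make_hit(10, 69)
        assert junction_runon(hit, genome, reg) == 0

    def test_truncated_runon(self):
        # hit extends exactly 2 bases past the junction into "TG..."
        genome, reg = make_genome([TAG_A, TAG_B])
        hit = make_hit(30, 71)
        # brute-force prefix oracle over the two bases present
        assert genome[69:71] == "TG"
        assert junction_runon(hit, genome, reg) == 2

    def test_mismatching_continuation(self):
        genome, reg = make_genome([TAG_A, "GGCAG" + "T" * 64])
        hit = make_hit(30, 80)
        assert junction_runon(hit, genome, reg) == 0

    def test_maximum_over_multiple_junctions(self):
        genome, reg = make_genome([TAG_A, "TGTTT" + "C" * 64, TAG_C])
        hit = make_hit(30, 150)  # spans junctions at 69 (k=2) and 138 (k=5)
        assert junction_runon(hit, genome, reg) == 5


class TestClassifyFalsePositive:
    def test_chimeric_hit_flagged(self):
        genome, reg = make_genome([TAG_A, TAG_B])
        hit = make_hit(0, 80)  # 80 bp, starts with motif, k=5
        v = classify_false_positive(hit, genome, reg)
        assert v.is_false_positive
        assert v.crit_length_gt_tag and v.crit_starts_with_motif and v.crit_internal_motif
        assert v.junction_runon_k == 5
        assert v.runon_probability == pytest.approx(1 / 1024)

    def test_within_stag_hit_not_flagged(self):
        genome, reg = make_genome([TAG_A, TAG_B])
        v = classify_false_positive(make_hit(0, 69), genome, reg)
        assert not v.is_false_positive
        assert not v.crit_length_gt_tag

    def test_short_runon_excluded(self):
        # 75 bp junction-spanning hit whose continuation is only "TG"
        genome, reg = make_genome([TAG_A, "TGTTT" + "C" * 64])
        hit = make_hit(0, 75)
        v = classify_false_positive(hit, genome, reg)
        assert v.junction_runon_k == 2
        assert not v.is_false_positive

    def test_kmin_configurable(self):
        genome, reg = make_genome([TAG_A, "TGTTT" + "C" * 64])
        hit = make_hit(0, 75)
        v = classify_false_positive(hit, genome, reg, k_min=2)
        assert v.is_false_positive


def test_simulated_runon_frequencies_match_model(rng):
    """Empirical run-on frequencies on random junction extensions agree with
    (1/4)^k within 3 binomial standard errors."""
    n = 10_000
    ks = simulate_junction_runons(n, rng=rng)
    for k in range(1, 6):
        p = 0.25**k
        observed = (ks >= k).mean()
        se = (p * (1 - p) / n) ** 0.5
        assert abs(observed - p) <= 3 * se


class TestAssociateGenes:
    def _features(self):
        return {
            "sp": [
                GeneFeature("sp", "chr1", 150, 500, "+", "gA", "gA"),
                GeneFeature("sp", "chr1", 160, 520, "-", "gB", "gB"),
            ]
        }

    def test_overlap_associates(self):
        hit = make_hit(0, 69, ss=100)  # subject [100, 169)
        associate_genes([hit], self._features())
        assert hit.gene_ids == ["gA", "gB"]

    def test_half_open_adjacency_does_not_associate(self):
        hit = make_hit(0, 50, ss=100)  # subject [100, 150)
        associate_genes([hit], self._features())
        assert hit.gene_ids == []

    def test_missing_species_warns_not_errors(self, caplog):
        hit = make_hit(0, 69, species="other")
        with caplog.at_level("WARNING"):
            associate_genes([hit], self._features())
        assert "other" in caplog.text


class TestSelectConservedGenes:
    def _inputs(self):
        # gene gX supported by non-repetitive STAG in all 3 species;
        # gene gY supported only via a repetitive STAG in spC
        hits = {
            sp: [
                make_hit(0, 69, species=sp, genes=[f"{sp}_gX"], stags=["s1"]),
                make_hit(69, 138, species=sp, genes=[f"{sp}_gY"], stags=["s2"]),
            ]
            for sp in ("spA", "spB", "spC")
        }
        orthology = {f"{sp}_gX": "OGX" for sp in ("spA", "spB", "spC")}
        orthology |= {f"{sp}_gY": "OGY" for sp in ("spA", "spB", "spC")}
        repetitive = {"s1": False, "s2": False}
        return hits, orthology, repetitive

    def test_fully_supported_gene_included(self):
        hits, orthology, repetitive = self._inputs()
        out = select_conserved_genes(hits, repetitive, {}, 3, orthology)
        assert out.group_ids == {"OGX", "OGY"}
        assert set(out.genes[0].species_support) == {"spA", "spB", "spC"}

    def test_repetitive_only_support_does_not_count(self):
        hits, orthology, repetitive = self._inputs()
        repetitive["s2"] = True
        out = select_conserved_genes(hits, repetitive, {}, 3, orthology)
        assert out.group_ids == {"OGX"}

    def test_false_positive_hits_dropped(self):
        hits, orthology, repetitive = self._inputs()
        verdicts = {
            "spA": [FPVerdict(0, True, True, True, True, 5, 1 / 1024)]
        }
        out = select_conserved_genes(hits, repetitive, verdicts, 3, orthology)
        assert out.group_ids == {"OGY"}  # OGX lost its spA support

    def test_monotone_in_species_requirement(self):
        hits, orthology, repetitive = self._inputs()
        del hits["spC"][0]  # OGX supported in 2 species only
        out3 = select_conserved_genes(hits, repetitive, {}, 3, orthology)
        out2 = select_conserved_genes(hits, repetitive, {}, 2, orthology)
        assert out3.group_ids <= out2.group_ids
        assert out3.group_ids == {"OGY"}
        assert out2.group_ids == {"OGX", "OGY"}

    def test_too_few_species_rejected(self):
        hits, orthology, repetitive = self._inputs()
        with pytest.raises(ValueError, match="required"):
            select_conserved_genes(
                {"spA": hits["spA"]}, repetitive, {}, 3, orthology
            )


class TestSummarizeSpecies:
    def test_hits_vs_unique_stags(self):
        hits = [make_hit(0, 69, stags=["s1"]) for _ in range(3)]
        s = summarize_species(hits, [], {}, genome_len=690)
        assert s.categories["non_repeat"]["n_hits"] == 3
        assert s.categories["non_repeat"]["n_unique_stags"] == 1

    def test_no_hits_all_zero(self):
        s = summarize_species([], [], {}, genome_len=690)
        assert s.total_hits == 0
        assert s.pct_of_genome == 0.0

    def test_pct_of_genome_hand_arithmetic(self):
        # one 69 bp non-gene, non-repetitive hit on a 690 bp genome
        s = summarize_species([make_hit(0, 69, stags=["s1"])], [], {}, 690)
        assert s.pct_of_genome == pytest.approx(10.0)

    def test_categories_and_fp_exclusion(self):
        hits = [
            make_hit(0, 69, genes=["g"], stags=["s1"]),
            make_hit(69, 138, stags=["s2"]),
            make_hit(138, 207, stags=["s3"]),
            make_hit(0, 80, stags=["s1", "s2"]),  # will be excluded as FP
        ]
        verdicts = [FPVerdict(3, True, True, True, True, 5, 1 / 1024)]
        s = summarize_species(hits, verdicts, {"s2": True}, genome_len=207)
        assert s.categories["gene_associated"]["n_hits"] == 1
        assert s.categories["repetitive"]["n_hits"] == 1
        assert s.categories["non_repeat"]["n_hits"] == 1
        assert s.total_hits == 3

    def test_overlap_collapsed_in_pct(self):
        hits = [make_hit(0, 69, stags=["s1"]), make_hit(0, 69, stags=["s1"])]
        s = summarize_species(hits, [], {}, genome_len=690)
        assert s.pct_of_genome == pytest.approx(10.0)

    def test_summary_tsv_structure(self, tmp_path):
        s = summarize_species([make_hit(0, 69, stags=["s1"])], [], {}, 690, "spA")
        p = tmp_path / "summary.tsv"
        write_summary_tsv([s], p)
        header, row = p.read_text().splitlines()
        assert header.split("\t") == SUMMARY_COLUMNS
        assert row.split("\t")[0] == "spA"
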