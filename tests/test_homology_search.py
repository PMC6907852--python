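import math

import numpy as np
import pytest

from stagpipe.homology_search import (
    HomologyHit,
    ScoringScheme,
    evalue,
    ingest_hits,
    karlin_params,
    read_hits_tsv,
    revcomp,
    seed_extend_search,
    write_hits_tsv,
)
from stagpipe.io_formats import RawBlastHit
from stagpipe.stag_assembly import ConcatRegistry


def bisection_lambda(match, mismatch, pm=0.25, lo=1e-6, hi=5.0, iters=200):
    """Independent bisection oracle for the Karlin root."""
    def f(lam):
        return pm * math.exp(lam * match) + (1 - pm) * math.exp(lam * mismatch) - 1

    for _ in range(iters):
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestKarlinParams:
    def test_lambda_matches_bisection_oracle(self):
        lam, _ = karlin_params(ScoringScheme(1, -3))
        assert lam == pytest.approx(bisection_lambda(1, -3), abs=1e-9)
        # residual of the sum condition
        f = 0.25 * math.exp(lam) + 0.75 * math.exp(-3 * lam) - 1
        assert abs(f) < 1e-12

    def test_lambda_monotone_in_mismatch_penalty(self):
        lam_mild, _ = karlin_params(ScoringScheme(1, -1))
        lam_harsh, _ = karlin_params(ScoringScheme(1, -3))
        assert lam_mild == pytest.approx(bisection_lambda(1, -1), abs=1e-9)
        assert lam_mild < lam_harsh

    def test_positive_drift_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(1, 1)
        with pytest.raises(ValueError, match="positive root"):
            karlin_params(ScoringScheme(3, -1))  # expected score +0.25

    def test_k_matches_published_ungapped_constant(self):
        # the published ungapped K for +1/−3 on uniform background is 0.711
        _, k = karlin_params(ScoringScheme(1, -3))
        assert k == pytest.approx(0.711, rel=0.01)

    def test_k_closed_form_for_unit_scores(self):
        # for +1/−1 the ladder computation reduces to (q − p)² / q
        _, k = karlin_params(ScoringScheme(1, -1))
        assert k == pytest.approx((0.75 - 0.25) ** 2 / 0.75, rel=1e-6)


class TestEvalue:
    def test_linear_in_subject_length(self):
        s = ScoringScheme().resolved()
        assert evalue(50, 100, 2000, s) == pytest.approx(2 * evalue(50, 100, 1000, s))

    def test_score_increase_shrinks_e_exponentially(self):
        s = ScoringScheme().resolved()
        ratio = evalue(40, 100, 1000, s) / evalue(50, 100, 1000, s)
        assert ratio == pytest.approx(math.exp(10 * s.lambda_), rel=1e-9)

    def test_matches_direct_formula(self):
        s = ScoringScheme().resolved()
        expected = s.k_param * 500 * 10_000 * math.exp(-s.lambda_ * 62)
        assert evalue(62, 500, 10_000, s) == pytest.approx(expected, rel=1e-12)

    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            evalue(10, 0, 100, ScoringScheme())


class TestSeedExtendSearch:
    def test_planted_tag_recovered_exactly(self, rng):
        query = random_seq(rng, 2000)
        tag = query[690:759]  # a 69 bp "tag" slice of the query
        subject = random_seq(rng, 100_000)
        pos = 40_000
        subject = subject[:pos] + tag + subject[pos + 69 :]
        hits = seed_extend_search(query, {"chr1": subject}, species="sp")
        assert len(hits) == 1
        (h,) = hits
        assert h.query_start <= 690 and h.query_end >= 759
        assert h.subject_start <= pos and h.subject_end >= pos + 69
        assert h.pct_identity == pytest.approx(100.0)
        assert h.evalue < 1e-10
        assert h.strand == "+"

    def test_reverse_strand_planting(self, rng):
        query = random_seq(rng, 2000)
        tag = query[0:69]
        subject = random_seq(rng, 50_000)
        pos = 12_345
        subject = subject[:pos] + revcomp(tag) + subject[pos + 69 :]
        hits = seed_extend_search(query, {"chr1": subject})
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].subject_start <= pos and hits[0].subject_end >= pos + 69

    def test_strand_symmetry(self, rng):
        query = random_seq(rng, 1000)
        subject = random_seq(rng, 20_000)
        pos = 5_000
        subject = subject[:pos] + query[100:190] + subject[pos + 90 :]
        fwd = seed_extend_search(query, {"c": subject})
        rev = seed_extend_search(query, {"c": revcomp(subject)})
        assert len(fwd) == len(rev) == 1
        L = len(subject)
        assert rev[0].subject_start == L - fwd[0].subject_end
        assert rev[0].subject_end == L - fwd[0].subject_start
        assert rev[0].raw_score == fwd[0].raw_score
        assert {fwd[0].strand, rev[0].strand} == {"+", "-"}

    def test_masked_query_not_seeded(self, rng):
        query = random_seq(rng, 500)
        subject = random_seq(rng, 5_000)
        pos = 2_000
        subject = subject[:pos] + query[100:169] + subject[pos + 69 :]
        masked = query[:100] + query[100:169].lower() + query[169:]
        assert seed_extend_search(masked, {"c": subject}) == []

    def test_ambiguity_matches_its_base_set(self, rng):
        query = random_seq(rng, 400)
        tag = query[50:119]
        # consensus-style query: one position replaced by an ambiguity code
        q_amb = query[:80] + "Y" + query[81:]
        subject = random_seq(rng, 5_000)
        base = "C" if query[80] not in "CT" else query[80]
        planted = tag[:30] + base + tag[31:]
        subject = subject[:1000] + planted + subject[1000 + 69 :]
        hits = seed_extend_search(q_amb, {"c": subject})
        assert len(hits) == 1
        assert hits[0].pct_identity == pytest.approx(100.0)

    def test_word_size_exceeding_query_rejected(self):
        with pytest.raises(ValueError, match="word size"):
            seed_extend_search("ACGT", {"c": "ACGTACGT"})

    def test_random_pair_yields_no_hits_at_threshold(self, rng):
        query = random_seq(rng, 2_000)
        subject = random_seq(rng, 20_000)
        assert seed_extend_search(query, {"c": subject}) == []

    def test_evalue_calibration_at_permissive_thresholds(self, rng):
        """On random query/subject pairs the observed hit count at threshold
        E* stays within twice the Karlin–Altschul expectation E*·replicates,
        for E* in {1, 0.1}."""
        replicates = 20
        scheme = ScoringScheme(evalue_max=1.0, word_size=9)
        counts = {1.0: 0, 0.1: 0}
        for _ in range(replicates):
            query = random_seq(rng, 10_000)
            subject = random_seq(rng, 100_000)
            hits = seed_extend_search(query, {"c": subject}, scheme)
            for e_star in counts:
                counts[e_star] += sum(h.evalue <= e_star for h in hits)
        for e_star, n in counts.items():
            assert n <= 2 * e_star * replicates, (e_star, n)


class TestIngestHits:
    def _registry(self):
        return ConcatRegistry.from_lengths([(str(i + 1), 69) for i in range(4)])

    def _rec(self, **kw):
        base = dict(
            qseqid="GP", sseqid="chr1", pident=100.0, length=69, mismatch=0,
            gapopen=0, qstart=1, qend=69, sstart=100, send=168,
            evalue=1e-30, bitscore=69.0,
        )
        base.update(kw)
        return RawBlastHit(**base)

    def test_evalue_threshold_applied(self):
        reg = self._registry()
        hits = ingest_hits([self._rec(evalue=1e-9)], reg, reg.total_length)
        assert hits == []

    def test_coordinate_conversion(self):
        reg = self._registry()
        (h,) = ingest_hits([self._rec()], reg, reg.total_length)
        assert (h.query_start, h.query_end) == (0, 69)
        assert h.stag_ids == ["1"]
        assert not h.spans_junction
        assert h.strand == "+"

    def test_junction_spanning_record(self):
        reg = self._registry()
        (h,) = ingest_hits(
            [self._rec(qstart=65, qend=75, length=11)], reg, reg.total_length
        )
        assert h.spans_junction
        assert h.stag_ids == ["1", "2"]

    def test_minus_strand_normalised(self):
        reg = self._registry()
        (h,) = ingest_hits([self._rec(sstart=168, send=100)], reg, reg.total_length)
        assert h.strand == "-"
        assert (h.subject_start, h.subject_end) == (99, 168)

    def test_query_exceeding_genome_rejected(self):
        reg = self._registry()
        with pytest.raises(ValueError, match="exceeds"):
            ingest_hits([self._rec(qend=1000)], reg, reg.total_length)


def test_hits_tsv_round_trip(tmp_path):
    reg = ConcatRegistry.from_lengths([("1", 69), ("2", 69)])
    hit = HomologyHit(
        query_start=10, query_end=75, species="sp", subject_chrom="chr2",
        subject_start=500, subject_end=565, strand="-", raw_score=55.0,
        evalue=3.2e-21, pct_identity=98.46, stag_ids=["1", "2"],
        spans_junction=True, gene_ids=["gA"],
    )
    p = tmp_path / "hits.tsv"
    write_hits_tsv([hit], p)
    (back,) = read_hits_tsv(p)
    assert back == hit
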