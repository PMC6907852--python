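import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stagpipe.marker_qc import CALL_HET, CALL_HOM_ALT, CALL_HOM_REF, CALL_MISSING
from stagpipe.stag_assembly import (
    ConcatRegistry,
    Stag,
    build_consensus,
    build_stag,
    build_stags,
    concat_individual,
    gc_content,
    map_to_stags,
    natural_sort_key,
)

from conftest import make_locus


def brute_force_ownership(registry, interval):
    """Per-base ownership oracle: walk every base of the interval."""
    owner = []
    for e in registry.entries:
        owner += [e.allele_id] * e.length
    start, end = interval
    hits = {}
    for pos in range(start, end):
        aid = owner[pos]
        offset = next(e.offset for e in registry.entries if e.allele_id == aid)
        local = pos - offset
        lo, hi = hits.get(aid, (local, local))
        hits[aid] = (min(lo, local), max(hi, local))
    return {aid: (lo, hi + 1) for aid, (lo, hi) in hits.items()}


class TestBuildStag:
    @pytest.mark.parametrize(
        "ref,alt,code",
        [("C", "T", "Y"), ("A", "G", "R"), ("A", "C", "M"),
         ("G", "T", "K"), ("A", "T", "W"), ("C", "G", "S")],
    )
    def test_iupac_codes(self, ref, alt, code):
        stag = build_stag(make_locus(ref_base=ref, alt_base=alt))
        assert stag.ambiguity_base == code
        assert stag.sequence[24] == code

    def test_allele_sequences_reconstruct(self):
        locus = make_locus(ref_base="C", alt_base="T")
        stag = build_stag(locus)
        assert stag.allele_sequence(0) == locus.allele_seqs[0]
        assert stag.allele_sequence(1) == locus.allele_seqs[1]

    def test_ambiguous_allele_rejected(self):
        locus = make_locus(ref_base="C", alt_base="N")
        with pytest.raises(ValueError, match="unambiguous"):
            build_stag(locus)

    def test_stag_invariant_checked(self):
        with pytest.raises(ValueError):
            Stag("x", "AAAA", 1, "Y", ("C", "T"))  # sequence lacks the code

    def test_build_stags_sorts_numerically(self):
        loci = [make_locus(a, calls=(0,)) for a in ("10", "2", "1")]
        stags = build_stags(loci)
        assert [s.allele_id for s in stags] == ["1", "2", "10"]
        assert natural_sort_key("2") < natural_sort_key("10")


class TestConcatIndividual:
    def _stags(self):
        loci = [
            make_locus("1", calls=(0,), ref_base="C", alt_base="T"),
            make_locus("2", calls=(0,), ref_base="A", alt_base="G"),
            make_locus("3", calls=(0,), ref_base="G", alt_base="T"),
        ]
        return build_stags(loci)

    def test_offsets_and_total_length(self):
        stags = self._stags()
        seq, registry = concat_individual(
            stags, {"1": CALL_HOM_REF, "2": CALL_HOM_REF, "3": CALL_HOM_REF}
        )
        assert registry.total_length == 207
        assert [e.offset for e in registry.entries] == [0, 69, 138]
        assert len(seq) == 207

    def test_het_call_emits_ambiguity(self):
        stags = self._stags()
        seq, _ = concat_individual(
            stags, {"1": CALL_HET, "2": CALL_HOM_REF, "3": CALL_HOM_REF}
        )
        assert seq[24] == "Y"

    def test_hom_calls_emit_allele_base(self):
        stags = self._stags()
        seq, _ = concat_individual(
            stags, {"1": CALL_HOM_ALT, "2": CALL_HOM_REF, "3": CALL_HOM_REF}
        )
        assert seq[24] == "T"

    def test_missing_call_emits_n_run(self):
        stags = self._stags()
        seq, _ = concat_individual(
            stags, {"1": CALL_HOM_REF, "2": CALL_MISSING, "3": CALL_HOM_REF}
        )
        assert set(seq[69:138]) == {"N"}
        assert "N" not in seq[:69] and "N" not in seq[138:]

    def test_unknown_allele_id_rejected(self):
        stags = self._stags()
        with pytest.raises(ValueError, match="unknown"):
            concat_individual(stags, {"99": CALL_HOM_REF})

    def test_registry_slicing_recovers_stags(self):
        stags = self._stags()
        seq, registry = concat_individual(
            stags, {s.allele_id: CALL_HET for s in stags}
        )
        for stag, e in zip(stags, registry.entries):
            assert seq[e.offset : e.offset + e.length] == stag.sequence


class TestConsensus:
    def _registry(self, lengths):
        return ConcatRegistry.from_lengths(
            (str(i + 1), n) for i, n in enumerate(lengths)
        )

    def test_majority_column(self):
        reg = self._registry([1])
        genome = build_consensus(["A"] * 50 + ["G"] * 40, reg)
        assert genome.consensus == "A"

    def test_tie_breaks_alphabetically(self):
        reg = self._registry([1])
        genome = build_consensus(["G"] * 45 + ["A"] * 45, reg)
        assert genome.consensus == "A"

    def test_all_missing_column_is_n(self):
        reg = self._registry([2])
        genome = build_consensus(["AN", "CN", "AN"], reg)
        assert genome.consensus == "AN"

    def test_idempotent_on_copies(self, rng):
        seq = "".join("ACGTY"[i] for i in rng.integers(0, 5, 120))
        reg = self._registry([60, 60])
        genome = build_consensus([seq] * 7, reg)
        assert genome.consensus == seq

    def test_majority_wins_regardless_of_rest(self, rng):
        """A symbol held by a strict majority is always the consensus."""
        n, length = 11, 40
        reg = self._registry([length])
        majority = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        rows = [majority] * 6
        for _ in range(5):
            rows.append("".join("ACGTN"[i] for i in rng.integers(0, 5, length)))
        genome = build_consensus(rows, reg)
        assert genome.consensus == majority

    def test_length_mismatch_rejected(self):
        reg = self._registry([3])
        with pytest.raises(ValueError, match="length"):
            build_consensus(["ACG", "AC"], reg)


class TestGcContent:
    def test_pure_gc(self):
        assert gc_content("GCGC") == 1.0

    def test_half_gc(self):
        assert gc_content("ATGC") == 0.5

    def test_ambiguity_excluded(self):
        assert gc_content("ATGCYYNN") == 0.5

    def test_no_unambiguous_bases_rejected(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")


class TestMapToStags:
    def test_junction_spanning_query(self):
        reg = ConcatRegistry.from_lengths([("1", 69), ("2", 69)])
        mapped = map_to_stags(reg, (64, 75))
        assert mapped.spans_junction
        assert mapped.overlaps == [("1", 64, 69), ("2", 0, 6)]

    def test_identity_on_own_interval(self):
        reg = ConcatRegistry.from_lengths([("1", 69), ("2", 69)])
        mapped = map_to_stags(reg, (0, 69))
        assert not mapped.spans_junction
        assert mapped.overlaps == [("1", 0, 69)]

    def test_out_of_bounds_rejected(self):
        reg = ConcatRegistry.from_lengths([("1", 69), ("2", 69), ("3", 69)])
        with pytest.raises(ValueError):
            map_to_stags(reg, (207, 210))
        with pytest.raises(ValueError):
            map_to_stags(reg, (5, 5))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_agrees_with_per_base_oracle(self, data):
        lengths = data.draw(
            st.lists(st.integers(30, 69), min_size=1, max_size=100)
        )
        reg = ConcatRegistry.from_lengths(
            (str(i + 1), n) for i, n in enumerate(lengths)
        )
        total = reg.total_length
        start = data.draw(st.integers(0, total - 1))
        end = data.draw(st.integers(start + 1, total))
        mapped = map_to_stags(reg, (start, end))
        oracle = brute_force_ownership(reg, (start, end))
        assert {o.allele_id: (o.local_start, o.local_end) for o in mapped.overlaps} == oracle
        assert mapped.spans_junction == (len(oracle) > 1)


def test_registry_invariants():
    from stagpipe.stag_assembly import RegistryEntry

    with pytest.raises(ValueError, match="contiguity"):
        ConcatRegistry(
            entries=[RegistryEntry("1", 0, 69), RegistryEntry("2", 70, 69)]
        )
    reg = ConcatRegistry.from_lengths([("1", 10), ("2", 20)])
    assert reg.total_length == 30
    assert reg.junctions == [10]


def test_registry_tsv_round_trip(tmp_path):
    reg = ConcatRegistry.from_lengths([("a", 10), ("b", 35), ("c", 69)])
    p = tmp_path / "reg.tsv"
    reg.to_tsv(p)
    back = ConcatRegistry.from_tsv(p)
    assert back.entries == reg.entries
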