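"""GC content, sliding windows, chunk profiles, localization and lengths."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lnckaryotype import sequence_profile as sp
from lnckaryotype.model import LocalizationRecord


class TestGCFraction:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("ACGTN", 0.5), ("acgt", 0.5)],
    )
    def test_values(self, seq, expected):
        assert sp.gc_fraction(seq) == pytest.approx(expected)

    def test_all_ambiguous_signaled(self):
        with pytest.raises(sp.EmptySequenceError):
            sp.gc_fraction("NNNN")

    def test_strand_skew_is_distinct_statistic(self):
        assert sp.strand_skew("GGC") == pytest.approx(1 / 3)
        assert sp.gc_fraction("GGC") == pytest.approx(1.0)


class TestSlidingGC:
    def test_hand_enumerated_windows(self):
        out = sp.sliding_gc("GGGGGAAAAA", window=5)
        assert out.tolist() == pytest.approx([1.0, 0.8, 0.6, 0.4, 0.2, 0.0])

    def test_homopolymer_is_zero(self):
        assert (sp.sliding_gc("A" * 30) == 0).all()

    def test_window_equals_length_boundary(self):
        seq = "GATCGATCGA"
        out = sp.sliding_gc(seq, window=10)
        assert len(out) == 1 and out[0] == pytest.approx(sp.gc_fraction(seq))

    def test_shorter_than_window_gives_whole_sequence_value(self):
        out = sp.sliding_gc("GC", window=10)
        assert out.tolist() == [1.0]

    @given(st.text(alphabet="ACGT", min_size=12, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_window_mean_close_to_overall_gc(self, seq):
        """Boundary effect bound: |mean of windows - overall GC| <= w/L."""
        w = 10
        windows = sp.sliding_gc(seq, window=w)
        assert abs(float(np.mean(windows)) - sp.gc_fraction(seq)) <= w / len(seq)


class TestChunkProfile:
    def test_one_window_per_chunk_identity(self):
        series = np.linspace(0, 1, 20)
        prof = sp.chunk_profile(series)
        assert prof["gc_mean"].to_numpy() == pytest.approx(series)
        assert (prof["n_windows"] == 1).all()

    def test_constant_series_any_length(self):
        for m in (1, 3, 20, 40, 97):
            prof = sp.chunk_profile(np.full(m, 0.5))
            filled = prof[prof["n_windows"] > 0]
            assert filled["gc_mean"].to_numpy() == pytest.approx(np.full(len(filled), 0.5))

    def test_sparse_series_floor_mapping(self):
        prof = sp.chunk_profile(np.arange(6, dtype=float))
        filled = prof[prof["n_windows"] > 0]["chunk"].tolist()
        # floor(i*20/6) for i=0..5 -> chunks {0,3,6,10,13,16} (1-based +1)
        assert filled == [1, 4, 7, 11, 14, 17]
        assert prof["n_windows"].sum() == 6


class TestGroupProfile:
    def test_identical_members_equal_member_profile(self):
        seqs = {"a": "GCGCATATGCGCATAT" * 4, "b": "GCGCATATGCGCATAT" * 4}
        groups = {"a": "g", "b": "g"}
        prof = sp.group_profile(seqs, groups)
        single = sp.transcript_profile(seqs["a"])
        assert prof["gc_mean"].to_numpy() == pytest.approx(single["gc_mean"].to_numpy())

    def test_group_of_one(self):
        seqs = {"a": "GGGGGGGGGGAAAAAAAAAA"}
        prof = sp.group_profile(seqs, {"a": "solo"})
        assert prof["group"].unique().tolist() == ["solo"]

    def test_excluded_groups_pooled(self):
        seqs = {k: "ACGT" * 30 for k in "abcd"}
        groups = {"a": "novel", "b": "name_assigned", "c": "antisense", "d": "antisense"}
        prof = sp.group_profile(
            seqs, groups, exclude_groups=("novel", "name_assigned"), pool_excluded_as="Others"
        )
        assert set(prof["group"]) == {"Others", "antisense"}

    def test_gradient_bundle_declines_5prime_to_3prime(self, sim_bundle):
        """The generator's 5'->3' GC gradient is recovered: chunk 1 mean
        exceeds chunk 20 mean and the fitted slope matches the configured
        gradient within 20%."""
        gc5, gc3 = sim_bundle.config.gc_gradient_lnc
        lnc_tx = {
            t.transcript_id
            for t in sim_bundle.transcripts
            if t.gene_id.startswith("ENSGS") and t.mature_length >= 400
        }
        seqs = {k: v for k, v in sim_bundle.sequences.items() if k in lnc_tx}
        prof = sp.group_profile(seqs, {k: "lncRNA" for k in seqs})
        first = prof[prof["chunk"] == 1]["gc_mean"].iloc[0]
        last = prof[prof["chunk"] == 20]["gc_mean"].iloc[0]
        assert first > last
        slope = sp.profile_slope(prof[prof["group"] == "lncRNA"])
        assert slope < 0
        assert slope == pytest.approx(gc3 - gc5, rel=0.2)


class TestLocalization:
    @pytest.mark.parametrize(
        "compartment,expected",
        [("Nuclear speckle", "nuclear"), ("Mitochondrion", "cytoplasmic"), ("nucleus", "nuclear")],
    )
    def test_term_lists(self, compartment, expected):
        out = sp.classify_localization([LocalizationRecord("X", compartment)])
        assert out["X"] == expected

    def test_conflict_and_unknown_are_other(self):
        recs = [
            LocalizationRecord("A", "Nucleus"),
            LocalizationRecord("A", "Cytosol"),
            LocalizationRecord("B", "Exosome"),
        ]
        out = sp.classify_localization(recs)
        assert out == {"A": "other", "B": "other"}


class TestAnova:
    def test_equal_groups_give_zero_f(self):
        res = sp.compare_gc_by_group({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res["F"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_f(self):
        # between SS = 54, within SS = 4 on df (1, 4) -> F = 54
        res = sp.compare_gc_by_group({"a": [1, 2, 3], "b": [7, 8, 9]})
        assert res["F"] == pytest.approx(54.0)

    def test_pairwise_adjustment_present_with_three_groups(self):
        res = sp.compare_gc_by_group({"a": [1, 2], "b": [1, 2], "c": [5, 6]})
        assert "pairwise" in res and len(res["pairwise"]) == 3
        for pair in res["pairwise"]:
            assert pair["p_adj"] >= pair["p_raw"] - 1e-12


class TestLengthSummary:
    def test_basic_statistics(self):
        out = sp.length_summary([1, 2, 3])
        assert out["mean"] == pytest.approx(2) and out["median"] == pytest.approx(2)

    def test_single_value(self):
        out = sp.length_summary([7], detect_modes=True)
        assert out["mean"] == out["median"] == 7 and out["modes"] == []

    def test_three_separated_modes_detected(self):
        rng = np.random.default_rng(3)
        sample = np.concatenate(
            [rng.normal(600, 30, 1000), rng.normal(1500, 50, 1000), rng.normal(3000, 80, 1000)]
        )
        out = sp.length_summary(sample, detect_modes=True)
        modes = np.array(out["modes"])
        for center in (600, 1500, 3000):
            assert (np.abs(modes - center) < 120).any()
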