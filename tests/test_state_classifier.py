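import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aavqc.alignfeatures import SupplementaryAlignment
from aavqc.state_classifier import (
    ClassifierConfig,
    DnaStateClassifier,
    classify_reads,
    classify_state,
    contaminant_base_fractions,
    is_full_length,
    itr_at_symmetry_axis,
    summarize,
)
from aavqc.synthetic_data import SimConfig, make_genome, simulate_reads
from conftest import make_read


def features(clip, n_supp, axis):
    return pd.DataFrame(
        {"clip_fraction": [clip], "n_supp": [n_supp], "itr_at_axis": [axis]}
    )


class TestRuleEngine:
    @pytest.mark.parametrize(
        "clip,n_supp,axis,expected",
        [
            (0.05, 0, False, "duplex"),
            (0.099, 3, True, "duplex"),      # duplex rule fires first
            (0.50, 1, True, "fillup"),
            (0.50, 1, False, "snapback"),
            (0.40, 1, True, "fillup"),       # band edges inclusive
            (0.60, 1, False, "snapback"),
            (0.80, 4, False, "multimer"),
            (0.75, 4, False, "multimer"),    # at-least thresholds
            (0.80, 3, False, "other"),       # too few supplementaries
            (0.65, 2, False, "other"),       # clip gap between bands
            (0.50, 2, True, "other"),        # fold band needs exactly 1 SA
            (0.30, 1, True, "other"),
        ],
    )
    def test_label_assignment(self, clip, n_supp, axis, expected):
        clf = DnaStateClassifier()
        assert clf.predict(features(clip, n_supp, axis))[0] == expected

    def test_labels_exhaustive_and_exclusive_on_grid(self):
        """Every (clip, n_supp, axis) combination yields exactly one of
        the five labels; rule regions are disjoint at the defaults."""
        clf = DnaStateClassifier()
        clips = np.round(np.arange(0, 1.0001, 0.025), 4)
        grid = pd.DataFrame(
            [
                {"clip_fraction": c, "n_supp": s, "itr_at_axis": a}
                for c in clips
                for s in range(0, 7)
                for a in (False, True)
            ]
        )
        labels = clf.predict(grid)
        assert set(labels) == {"duplex", "fillup", "snapback", "multimer", "other"}
        # disjointness: duplex/multimer/fold bands cannot co-fire at the defaults
        duplex = grid.clip_fraction < 0.10
        fold = (grid.clip_fraction >= 0.40) & (grid.clip_fraction <= 0.60) & (grid.n_supp == 1)
        multi = (grid.clip_fraction >= 0.75) & (grid.n_supp >= 4)
        assert not (duplex & fold).any() and not (fold & multi).any() and not (duplex & multi).any()
        assert (labels[duplex] == "duplex").all()
        assert (labels[multi] == "multimer").all()

    def test_tightening_duplex_threshold_shrinks_duplex_set(self):
        grid = pd.DataFrame(
            {
                "clip_fraction": np.linspace(0, 0.2, 41),
                "n_supp": 0,
                "itr_at_axis": False,
            }
        )
        loose = set(np.where(DnaStateClassifier(duplex_max_clip=0.10).predict(grid) == "duplex")[0])
        tight = set(np.where(DnaStateClassifier(duplex_max_clip=0.05).predict(grid) == "duplex")[0])
        assert tight <= loose

    def test_inconsistent_thresholds_rejected(self):
        with pytest.raises(ValueError):
            DnaStateClassifier(duplex_max_clip=0.5, fillup_clip_low=0.4).predict(
                features(0.5, 1, True)
            )
        with pytest.raises(ValueError):
            ClassifierConfig(duplex_max_clip=0.5, fillup_clip_low=0.4)

    def test_sklearn_contract(self):
        clf = DnaStateClassifier()
        X = features(0.5, 1, True)
        assert clf.fit(X).classes_.tolist() == [
            "duplex", "fillup", "snapback", "multimer", "other"
        ]
        params = clf.get_params()
        assert params["duplex_max_clip"] == 0.10
        clf2 = DnaStateClassifier().set_params(**params)
        assert clf2.predict(X).tolist() == clf.predict(X).tolist()


class TestSymmetryAxis:
    def test_fillup_folded_at_itr(self, vector_only_model):
        # fragment [0, 3342) folded at the 3' ITR: both inner ends at 3342
        n = 3342
        read = make_read(
            read_length=2 * n, ref_start=0, ref_end=n, clip_right=n,
            supp_entries=(SupplementaryAlignment("vec", 0, "-", f"{n}M{n}S"),),
        )
        assert itr_at_symmetry_axis(read, vector_only_model)

    def test_snapback_folded_mid_genome(self, vector_only_model):
        n = 1500  # fold point at 1500, far from ITRs [0,145) and [3197,3342)
        read = make_read(
            read_length=2 * n, ref_start=0, ref_end=n, clip_right=n,
            supp_entries=(SupplementaryAlignment("vec", 0, "-", f"{n}M{n}S"),),
        )
        assert not itr_at_symmetry_axis(read, vector_only_model)

    def test_no_supplementary_means_no_axis(self, vector_only_model):
        read = make_read(read_length=3342, ref_start=0, ref_end=3342)
        assert not itr_at_symmetry_axis(read, vector_only_model)

    def test_supplementary_on_other_reference_ignored(self, vector_only_model):
        read = make_read(
            read_length=2000, ref_start=0, ref_end=1000, clip_right=1000,
            supp_entries=(SupplementaryAlignment("hum", 0, "-", "1000M1000S"),),
        )
        assert not itr_at_symmetry_axis(read, vector_only_model)


class TestFullLength:
    def test_canonical_fillup_is_full_length(self, vector_only_model):
        read = make_read(
            read_length=6684, ref_start=0, ref_end=3342, clip_right=3342,
            supp_entries=(SupplementaryAlignment("vec", 0, "-", "3342M3342S"),),
        )
        assert is_full_length(read, vector_only_model)

    def test_shifted_start_fails(self, vector_only_model):
        read = make_read(
            read_length=6684, ref_start=400, ref_end=3342, clip_right=3342,
            supp_entries=(SupplementaryAlignment("vec", 400, "-", "2942M3742S"),),
        )
        assert not is_full_length(read, vector_only_model)

    @pytest.mark.parametrize(
        "read_length,expected",
        [(6533, False), (6534, True), (6684, True), (6834, True), (6835, False)],
    )
    def test_length_window_boundaries(self, vector_only_model, read_length, expected):
        """2L +- 150 with L=3342: window [6534, 6834], closed ends."""
        read = make_read(
            read_length=read_length, ref_start=0, ref_end=3342,
            clip_right=read_length - 3342,
            supp_entries=(SupplementaryAlignment("vec", 0, "-", "3342M3342S"),),
        )
        assert is_full_length(read, vector_only_model) is expected

    @pytest.mark.parametrize("start,expected", [(51, False), (50, True), (0, True)])
    @pytest.mark.parametrize("end_offset,expected_end", [(0, True), (50, True), (51, False)])
    def test_end_tolerance_grid(self, vector_only_model, start, expected, end_offset, expected_end):
        """Both ends must be within 50 bp of the genome boundaries."""
        end = 3342 - end_offset
        read = make_read(
            read_length=6684, ref_start=start, ref_end=end,
            clip_right=6684 - (end - start),
            supp_entries=(SupplementaryAlignment("vec", start, "-", f"{end - start}M0S"),),
        )
        assert is_full_length(read, vector_only_model) is (expected and expected_end)

    def test_plain_duplex_fails_doubling_rule(self, vector_only_model):
        # a genome-length duplex covers the genome but is only L long
        read = make_read(read_length=3342, ref_start=0, ref_end=3342)
        assert not is_full_length(read, vector_only_model)


class TestClassifyState:
    def test_non_vector_read_rejected(self, vector_only_model):
        read = make_read(ref_name="hum")
        with pytest.raises(ValueError, match="non-vector"):
            classify_state(read, vector_only_model)

    def test_call_carries_features(self, vector_only_model):
        read = make_read(
            read_length=6684, ref_start=0, ref_end=3342, clip_right=3342,
            supp_entries=(SupplementaryAlignment("vec", 0, "-", "3342M3342S"),),
        )
        call = classify_state(read, vector_only_model)
        assert call.label == "fillup"
        assert call.clip_fraction == pytest.approx(0.5)
        assert call.n_supp == 1
        assert call.itr_at_axis is True
        assert call.full_length is True


class TestSummaries:
    def test_full_length_percentage(self, vector_only_model):
        reads = [
            make_read(
                read_id=f"fl{i}", read_length=6684, ref_start=0, ref_end=3342,
                clip_right=3342,
                supp_entries=(SupplementaryAlignment("vec", 0, "-", "3342M3342S"),),
            )
            for i in range(4)
        ] + [make_read(read_id=f"dx{i}") for i in range(6)]
        calls = classify_reads(reads, vector_only_model)
        summary = summarize(calls)
        assert summary["full_length_pct"] == pytest.approx(40.0)
        assert summary["n_reads"] == 10

    def test_all_duplex_run_has_zero_full_length(self, vector_only_model):
        """Genome-length duplexes never satisfy the doubled-length rule."""
        reads = [make_read(read_id=f"d{i}") for i in range(10)]
        summary = summarize(classify_reads(reads, vector_only_model))
        assert summary["full_length_pct"] == 0.0
        assert summary["state_composition_pct"]["duplex"] == pytest.approx(100.0)

    def test_empty_calls_error(self):
        with pytest.raises(ValueError, match="no vector reads"):
            summarize(pd.DataFrame())

    def test_histogram_counts_total_reads(self, vector_only_model):
        reads = [make_read(read_id=f"d{i}", read_length=3342 + i) for i in range(5)]
        # widen span bookkeeping: clip the extra bases
        reads = [
            make_read(read_id=f"d{i}", read_length=3342 + i, clip_right=i)
            for i in range(5)
        ]
        hist = summarize(classify_reads(reads, vector_only_model))["length_histogram"]
        assert hist["count"].sum() == 5

    def test_permutation_invariance(self, model, sim_config):
        result = simulate_reads(model, sim_config)
        reads = result.aligned_reads()
        vec_reads = [r for r in reads if model.category_of(r.ref_name) == "vector"]
        a = summarize(classify_reads(vec_reads, model))["full_length_pct"]
        b = summarize(classify_reads(list(reversed(vec_reads)), model))["full_length_pct"]
        assert a == b
        assert 0 <= a <= 100


class TestContaminantFractions:
    def test_all_vector(self, vector_only_model):
        fr = contaminant_base_fractions([make_read() for _ in range(3)], vector_only_model)
        assert fr["vector"] == pytest.approx(100.0)
        assert fr.sum() == pytest.approx(100.0)

    def test_ninety_ten_split(self, vector_only_model):
        reads = [
            make_read(read_id="v", read_length=900, ref_end=900),
            make_read(read_id="h", read_length=100, ref_end=100, ref_name="hum"),
        ]
        fr = contaminant_base_fractions(reads, vector_only_model)
        assert fr["vector"] == pytest.approx(90.0)
        assert fr["human"] == pytest.approx(10.0)

    def test_zero_bases_error(self, vector_only_model):
        with pytest.raises(ValueError, match="zero aligned bases"):
            contaminant_base_fractions([], vector_only_model)

    def test_recovers_planted_fractions_exactly(self, model, sim_config):
        result = simulate_reads(model, sim_config)
        fr = contaminant_base_fractions(result.aligned_reads(), model)
        truth = result.truth.groupby("category")["aligned_bases"].sum()
        expected = 100.0 * truth / truth.sum()
        for cat in expected.index:
            assert fr[cat] == pytest.approx(expected[cat])
        assert fr.sum() == pytest.approx(100.0, abs=1e-9)
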