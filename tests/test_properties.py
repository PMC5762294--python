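"""Property computation, ECDFs and the from-scratch two-sample K-S test."""

import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from circbench.properties import (
    ECDF,
    PropertyRecord,
    compare_properties,
    junction_ratio,
    ks_two_sample,
    splice_distance,
    split_groups,
)
from circbench.seq_io import CircCandidate, PredictionSet
from circbench.truth_eval import LabeledCandidate


def brute_force_ks_d(x, y):
    """Independent oracle: sup |F_x - F_y| over pooled points by counting."""
    best = 0.0
    for v in set(x) | set(y):
        fx = sum(1 for a in x if a <= v) / len(x)
        fy = sum(1 for b in y if b <= v) / len(y)
        best = max(best, abs(fx - fy))
    return best


def _true_cand(key, n=5, m=50):
    e = (m - n) / (m + n)
    return LabeledCandidate(key[0], key[1], key[2], ".", n, m, e, e > 0)


class TestScalarProperties:
    @pytest.mark.parametrize("n, N, expected", [(5, 20, 0.25), (7, 7, 1.0), (0, 9, 0.0)])
    def test_junction_ratio_values(self, n, N, expected):
        assert junction_ratio(n, N) == pytest.approx(expected)

    def test_junction_ratio_errors(self):
        with pytest.raises(ValueError):
            junction_ratio(1, 0)
        with pytest.raises(ValueError):
            junction_ratio(5, 3)

    @given(n=st.integers(0, 50), N=st.integers(1, 50), c=st.integers(1, 9))
    def test_junction_ratio_scale_invariant(self, n, N, c):
        if n > N:
            return
        assert junction_ratio(c * n, c * N) == pytest.approx(junction_ratio(n, N))

    @pytest.mark.parametrize(
        "start, end, expected", [(100, 100, 1), (100, 200, 101), (1, 10, 10)]
    )
    def test_splice_distance_inclusive(self, start, end, expected):
        assert splice_distance(CircCandidate("c", start, end)) == expected

    def test_splice_distance_after_bedlike_normalization(self, tmp_path):
        from circbench.seq_io import parse_prediction_table

        path = tmp_path / "p.tsv"
        path.write_text("chr1\t99\t200\t+\t5\n")
        (cand,) = parse_prediction_table(path, "bedlike")
        assert splice_distance(cand) == 101


class TestSplitGroups:
    def _preds(self, keys):
        ps = PredictionSet()
        for k in keys:
            ps.add(CircCandidate(k[0], k[1], k[2], ".", 5))
        return ps

    def test_identical_predictions_leave_s2_empty(self):
        keys = [("c", i, i + 10) for i in range(5)]
        true_circs = [_true_cand(k) for k in keys]
        s1, s2 = split_groups(true_circs, self._preds(keys))
        assert s1 == set(keys) and s2 == set()

    def test_empty_predictions_leave_s1_empty(self):
        keys = [("c", i, i + 10) for i in range(5)]
        s1, s2 = split_groups([_true_cand(k) for k in keys], self._preds([]))
        assert s1 == set() and s2 == set(keys)

    @given(
        n_true=st.integers(0, 12),
        present_mask=st.lists(st.booleans(), min_size=12, max_size=12),
    )
    def test_always_a_partition(self, n_true, present_mask):
        keys = [("c", i, i + 10) for i in range(n_true)]
        present = [k for k, keep in zip(keys, present_mask) if keep]
        s1, s2 = split_groups([_true_cand(k) for k in keys], self._preds(present))
        assert s1 | s2 == set(keys)
        assert s1 & s2 == set()


class TestECDF:
    def test_step_values(self):
        f = ECDF([1, 2, 3])
        assert f(1) == pytest.approx(1 / 3)
        assert f(2) == pytest.approx(2 / 3)
        assert f(3) == 1.0
        assert f(0.5) == 0.0

    def test_ties_accumulate(self):
        f = ECDF([2, 2])
        assert f(2) == 1.0
        assert f(1.9) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ECDF([])


class TestKSTwoSample:
    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 2, 5], [1, 2, 2, 5])
        assert res.D == 0.0 and res.p_value == 1.0
        assert res.shift_direction == "none"

    def test_fully_separated_samples(self):
        res = ks_two_sample([1, 2], [10, 20])
        assert res.D == 1.0
        assert res.shift_direction == "left"

    def test_hand_computed_overlap(self):
        res = ks_two_sample([1, 2, 3], [2, 3, 4])
        assert res.D == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    @given(
        x=st.lists(st.integers(0, 4), min_size=1, max_size=8),
        y=st.lists(st.integers(0, 4), min_size=1, max_size=8),
    )
    def test_d_matches_brute_force_oracle(self, x, y):
        assert ks_two_sample(x, y).D == pytest.approx(brute_force_ks_d(x, y))

    def test_d_matches_scipy_on_exhaustive_small_multisets(self):
        # every pair of multisets over {0,1,2} with sizes 1..4
        values = [0, 1, 2]
        multisets = [
            list(c)
            for n in range(1, 5)
            for c in itertools.combinations_with_replacement(values, n)
        ]
        for x in multisets:
            for y in multisets:
                ours = ks_two_sample(x, y).D
                ref = scipy.stats.ks_2samp(x, y).statistic
                assert ours == pytest.approx(ref)

    def test_p_value_close_to_scipy_asymptotic_at_moderate_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=80)
        y = rng.normal(0.4, size=90)
        ours = ks_two_sample(x, y)
        ref = scipy.stats.ks_2samp(x, y, method="asymp")
        # Different finite-sample corrections: agree loosely, same conclusion.
        assert ours.p_value == pytest.approx(ref.pvalue, rel=0.5, abs=0.02)

    def test_type_one_error_calibrated_smoke(self):
        # Small version of the calibration check (full run in acceptance).
        rng = np.random.default_rng(1234)
        rejections = sum(
            ks_two_sample(rng.normal(size=100), rng.normal(size=100)).p_value < 0.05
            for _ in range(300)
        )
        assert 0.02 <= rejections / 300 <= 0.09

    def test_shift_direction_uses_medians(self):
        res = ks_two_sample([10, 11, 12], [1, 2, 30])
        assert res.shift_direction == "right"


class TestCompareProperties:
    def _records(self, reads_s1, reads_s2):
        recs = []
        for i, r in enumerate(reads_s1):
            recs.append(PropertyRecord("c", i, i + 100, 101, 0.5, 0.2, r, "S1"))
        for i, r in enumerate(reads_s2):
            recs.append(PropertyRecord("c", 1000 + i, 1100 + i, 101, 0.5, 0.2, r, "S2"))
        return recs

    def test_identical_groups_give_zero_d_everywhere(self):
        recs = self._records([2, 5, 9, 9], [2, 5, 9, 9])
        table = compare_properties(recs)
        assert (table["D"] == 0.0).all()
        assert (table["p_value"] == 1.0).all()

    def test_planted_right_shift_in_reads_detected(self):
        rng = np.random.default_rng(5)
        reads_s1 = rng.poisson(30, size=40) + 2
        reads_s2 = rng.poisson(3, size=40) + 2
        table = compare_properties(self._records(reads_s1, reads_s2)).set_index("property")
        assert table.loc["reads", "p_value"] < 1e-6
        assert table.loc["reads", "shift_direction"] == "right"
        # distance identical by construction: no signal
        assert table.loc["distance", "D"] == 0.0

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="skip"):
            compare_properties(self._records([1, 2], []))

    def test_explicit_key_sets_override_groups(self):
        recs = self._records([2, 3], [9, 10])
        s1 = {r.key for r in recs if r.group == "S2"}  # deliberately swapped
        s2 = {r.key for r in recs if r.group == "S1"}
        table = compare_properties(recs, s1, s2).set_index("property")
        assert table.loc["reads", "shift_direction"] == "right"

    def test_null_type_one_error_near_alpha(self):
        # S1/S2 drawn from the same distribution: p should reject ~alpha.
        rng = np.random.default_rng(77)
        alpha = 0.01
        n_rep = 400
        rejections = 0
        for _ in range(n_rep):
            x = rng.normal(size=60)
            y = rng.normal(size=60)
            if ks_two_sample(x, y).p_value < alpha:
                rejections += 1
        assert rejections / n_rep < 0.04  # ~1% expected, generous MC head-room

    def test_cdf_plot_writes_file(self, tmp_path):
        recs = self._records([2, 5, 9], [1, 2, 3])
        from circbench.properties import plot_property_cdfs

        out = tmp_path / "cdf.png"
        plot_property_cdfs(recs, out)
        assert out.stat().st_size > 0
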