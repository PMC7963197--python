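"""Cross-correlation r_max/lag, weight-vector similarity, group pair indexes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from synergycoach.similarity import (pairwise_group_index, vector_similarity,
                                     xcorr_rmax_lag)


def brute_force_xcorr(x, y, max_lag):
    """Exhaustive-lag oracle for the centered, 'coeff'-normalized scan."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    best = None
    for k in range(-max_lag, max_lag + 1):
        if k >= 0:
            v = float(np.dot(xc[:x.size - k], yc[k:])) / denom
        else:
            v = float(np.dot(xc[-k:], yc[:y.size + k])) / denom
        if best is None or v > best[0] + 1e-12 or \
                (abs(v - best[0]) <= 1e-12 and (abs(k), k) < (abs(best[1]), best[1])):
            best = (v, k)
    return best


def _bump(center, n=200, width=8.0):
    t = np.arange(n)
    return np.exp(-0.5 * ((t - center) / width) ** 2)


class TestXcorr:
    def test_identity(self):
        x = _bump(100)
        r, lag = xcorr_rmax_lag(x, x)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert lag == 0.0

    def test_known_shift(self):
        x = _bump(80)
        y = np.roll(x, 10)   # bump away from edges: roll == true delay
        r, lag = xcorr_rmax_lag(x, y)
        assert lag == pytest.approx(+5.0)   # 10 of 200 points
        # centering makes the truncated linear overlap slightly sub-unity
        assert r > 0.98
        r2, lag2 = xcorr_rmax_lag(y, x)
        assert lag2 == pytest.approx(-5.0)
        assert r2 == pytest.approx(r, abs=1e-12)

    def test_anticorrelated_matches_oracle(self):
        x = _bump(100)
        y = -x
        r, lag = xcorr_rmax_lag(x, y)
        vb, kb = brute_force_xcorr(x, y, 100)
        assert r == pytest.approx(vb, abs=1e-12)
        assert lag == pytest.approx(kb / 2.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.integers(0, 10 ** 6))
    def test_matches_brute_force_on_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(60)
        y = rng.standard_normal(60)
        r, lag_pct = xcorr_rmax_lag(x, y, max_lag=20, cycle_points=60)
        vb, kb = brute_force_xcorr(x, y, 20)
        assert r == pytest.approx(vb, abs=1e-10)
        assert lag_pct == pytest.approx(kb * 100.0 / 60, abs=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hst.integers(0, 10 ** 6))
    def test_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(80)
        y = rng.standard_normal(80)
        r1, l1 = xcorr_rmax_lag(x, y, max_lag=30, cycle_points=80)
        r2, l2 = xcorr_rmax_lag(y, x, max_lag=30, cycle_points=80)
        assert r1 == pytest.approx(r2, abs=1e-10)
        assert l1 == pytest.approx(-l2, abs=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            xcorr_rmax_lag(np.ones(50), np.arange(50.0))


class TestVectorSimilarity:
    def test_identity_and_affine_invariance(self):
        w = np.random.default_rng(0).random(16)
        assert vector_similarity(w, w) == pytest.approx(1.0)
        assert vector_similarity(w, 3.2 * w + 0.7) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hst.integers(0, 10 ** 6))
    def test_matches_covariance_formula(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(16), rng.random(16)
        ac, bc = a - a.mean(), b - b.mean()
        expected = (ac @ bc) / np.sqrt((ac ** 2).sum() * (bc ** 2).sum())
        assert vector_similarity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            vector_similarity(np.ones(16), np.random.default_rng(0).random(16))


class TestPairwiseGroupIndex:
    @staticmethod
    def _cohort(n_a, n_b, seed=0, n_pts=200):
        rng = np.random.default_rng(seed)
        sig, grp = {}, {}
        for i in range(n_a):
            sig[f"U{i}"] = rng.random((1, n_pts)) + _bump(100, n_pts)
            grp[f"U{i}"] = "UNE"
        for i in range(n_b):
            sig[f"E{i}"] = rng.random((1, n_pts)) + _bump(100, n_pts)
            grp[f"E{i}"] = "EXP"
        return sig, grp

    def test_study_pair_counts(self):
        sig, grp = self._cohort(10, 7)
        idx = {g.group_pair: g.n_pairs
               for g in pairwise_group_index(sig, grp, group_order=("UNE", "EXP"))}
        assert idx == {"within-UNE": 45, "within-EXP": 21, "between": 70}

    def test_minimal_groups(self):
        sig, grp = self._cohort(2, 2)
        idx = {g.group_pair: g.n_pairs
               for g in pairwise_group_index(sig, grp, group_order=("UNE", "EXP"))}
        assert idx == {"within-UNE": 1, "within-EXP": 1, "between": 4}

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(hst.integers(2, 20), hst.integers(2, 20))
    def test_pair_count_closed_forms(self, n_a, n_b):
        sig, grp = self._cohort(n_a, n_b, n_pts=24)
        idx = {g.group_pair: g.n_pairs
               for g in pairwise_group_index(sig, grp, max_lag=6,
                                             group_order=("UNE", "EXP"))}
        assert idx["within-UNE"] == n_a * (n_a - 1) // 2
        assert idx["within-EXP"] == n_b * (n_b - 1) // 2
        assert idx["between"] == n_a * n_b
        assert sum(idx.values()) == (n_a + n_b) * (n_a + n_b - 1) // 2

    def test_identical_signals_give_unit_similarity(self):
        shared = _bump(70) + 0.1
        sig = {s: shared[None, :] for s in ["a", "b", "c", "d", "e"]}
        grp = {"a": "UNE", "b": "UNE", "c": "UNE", "d": "EXP", "e": "EXP"}
        for g in pairwise_group_index(sig, grp, group_order=("UNE", "EXP")):
            assert g.mean_rmax == pytest.approx(1.0, abs=1e-12)
            assert g.mean_lag == 0.0
            assert g.sd_lag == 0.0 or np.isnan(g.sd_lag)

    def test_imposed_delay_sign_convention(self):
        """EXP delayed relative to UNE gives positive between-group lag."""
        base = _bump(80)
        sig = {"u0": base[None, :], "u1": base[None, :],
               "e0": np.roll(base, 6)[None, :], "e1": np.roll(base, 6)[None, :]}
        grp = {"u0": "UNE", "u1": "UNE", "e0": "EXP", "e1": "EXP"}
        idx = {g.group_pair: g for g in
               pairwise_group_index(sig, grp, group_order=("UNE", "EXP"))}
        assert idx["between"].mean_lag == pytest.approx(+3.0)
        assert idx["within-UNE"].mean_lag == 0.0

    def test_single_subject_group_rejected(self):
        sig, grp = self._cohort(1, 3)
        with pytest.raises(ValueError):
            pairwise_group_index(sig, grp, group_order=("UNE", "EXP"))
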