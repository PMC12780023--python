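"""Circular-shift surrogates, p-value aggregation, FDR masking, C_All."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from corticoflow.datatypes import Condition
from corticoflow.significance import (
    aggregate_two_level,
    bh_fdr,
    build_condition_connectivity,
    circular_shift,
    draw_offsets,
    pair_pvalue,
    stouffer,
    trial_pvalue_matrix,
)


class TestCircularShift:
    def test_offset_one(self):
        np.testing.assert_array_equal(circular_shift(np.array([1, 2, 3, 4]), 1), [4, 1, 2, 3])

    def test_full_length_rotation_disallowed(self):
        with pytest.raises(ValueError):
            circular_shift(np.arange(5), 5)
        with pytest.raises(ValueError):
            circular_shift(np.arange(5), 0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=2, max_value=50), st.integers(min_value=0, max_value=10_000))
    def test_value_multiset_preserved(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        off = int(rng.integers(1, n))
        np.testing.assert_array_equal(np.sort(circular_shift(x, off)), np.sort(x))

    def test_offsets_respect_minimum_rotation(self):
        rng = np.random.default_rng(0)
        offs = draw_offsets(rng, length=100, T=6, n_iter=500)
        assert offs.min() >= 7 and offs.max() <= 93

    def test_autocorrelation_preserved_up_to_edges(self):
        # rotating an AR series leaves its lag-1 autocorrelation nearly intact
        rng = np.random.default_rng(1)
        x = np.empty(2000)
        x[0] = rng.standard_normal()
        for t in range(1, 2000):
            x[t] = 0.7 * x[t - 1] + rng.standard_normal()

        def rho1(v):
            vc = v - v.mean()
            return (vc[:-1] @ vc[1:]) / (vc @ vc)

        shifted = circular_shift(x, 731)
        assert abs(rho1(shifted) - rho1(x)) < 0.01


class TestPairPvalue:
    def test_observed_above_all_surrogates(self):
        assert pair_pvalue(1.0, np.zeros(100)) == pytest.approx(1 / 101)

    def test_observed_below_all(self):
        assert pair_pvalue(-1.0, np.zeros(100)) == 1.0

    def test_observed_at_median(self):
        sur = np.linspace(0, 1, 101)
        assert pair_pvalue(0.5, sur) == pytest.approx(0.5, abs=0.01)

    def test_empty_ensemble_error(self):
        with pytest.raises(ValueError):
            pair_pvalue(0.5, np.array([np.nan]))

    def test_null_pvalues_uniform_on_grid(self):
        # exchangeable observed/surrogate values: p lands uniformly on the
        # achievable grid k/(n+1); chi-square goodness of fit
        rng = np.random.default_rng(2)
        n_iter = 19
        ps = np.array(
            [pair_pvalue(rng.standard_normal(), rng.standard_normal(n_iter)) for _ in range(2000)]
        )
        grid = np.arange(1, n_iter + 2) / (n_iter + 1)
        counts = np.array([np.sum(np.isclose(ps, g)) for g in grid])
        assert counts.sum() == 2000
        chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
        assert sps.chi2.sf(chi2, df=n_iter) > 0.001


class TestStouffer:
    def test_half_half_fixed_point(self):
        assert stouffer([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_two_at_005(self):
        # z = 1.6449 each, Z = 2.3264
        assert stouffer([0.05, 0.05]) == pytest.approx(0.0100, abs=1e-4)

    def test_single_p_identity(self):
        assert stouffer([0.2]) == pytest.approx(0.2, abs=1e-9)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            stouffer([])


class TestAggregateTwoLevel:
    def _stack(self, p, participants=2, trials=3, n=3):
        arr = np.full((trials, n, n), p)
        for t in range(trials):
            np.fill_diagonal(arr[t], np.nan)
        return {f"s{i}": arr.copy() for i in range(participants)}

    def test_all_half_fixed_point(self):
        gp = aggregate_two_level(self._stack(0.5))
        off = gp[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-12)

    def test_28_participants_closed_form(self):
        # within-participant p = 0.2 each -> group 1 - Phi(sqrt(28) * Phi^-1(0.8))
        stacks = {f"s{i:02d}": np.full((1, 2, 2), 0.2) for i in range(28)}
        for arr in stacks.values():
            arr[0, 0, 0] = np.nan
            arr[0, 1, 1] = np.nan
        gp = aggregate_two_level(stacks)
        expected = sps.norm.sf(np.sqrt(28) * sps.norm.isf(0.2))
        assert gp[0, 1] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(4.3e-6, rel=0.05)

    def test_participant_order_irrelevant(self):
        rng = np.random.default_rng(3)
        stacks = {f"s{i}": rng.uniform(0.01, 0.99, (4, 3, 3)) for i in range(5)}
        gp1 = aggregate_two_level(stacks)
        gp2 = aggregate_two_level(dict(reversed(list(stacks.items()))))
        np.testing.assert_allclose(gp1, gp2, atol=1e-14)

    def test_pair_missing_everywhere_yields_nan(self):
        stacks = self._stack(0.3)
        for arr in stacks.values():
            arr[:, 0, 1] = np.nan
        gp = aggregate_two_level(stacks)
        assert np.isnan(gp[0, 1])
        assert np.isfinite(gp[1, 0])


class TestBhFdr:
    def test_hand_example_rejects_exactly_three(self):
        p = np.full((5, 5), np.nan)
        vals = [0.001, 0.01, 0.02, 0.5]
        slots = [(0, 1), (1, 2), (2, 3), (3, 4)]
        for (i, j), v in zip(slots, vals):
            p[i, j] = v
        mask = bh_fdr(p, q=0.05)
        assert mask.sum() == 3
        assert mask[0, 1] and mask[1, 2] and mask[2, 3] and not mask[3, 4]

    def test_all_ones_empty_mask(self):
        p = np.ones((4, 4))
        assert bh_fdr(p, 0.05).sum() == 0

    def test_matches_brute_force_step_up_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            m = int(rng.integers(2, 40))
            pv = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            # brute force: largest k with p_(k) <= k q / m
            q = 0.05
            order = np.argsort(pv)
            ks = np.nonzero(pv[order] <= (np.arange(1, m + 1) * q / m))[0]
            expected = np.zeros(m, dtype=bool)
            if ks.size:
                expected[order[: ks.max() + 1]] = True
            # embed into a matrix family
            n = m + 1
            mat = np.full((n, n), np.nan)
            ti, si = np.nonzero(~np.eye(n, dtype=bool))
            mat[ti[:m], si[:m]] = pv
            mask = bh_fdr(mat, q)
            np.testing.assert_array_equal(mask[ti[:m], si[:m]], expected)


class TestConditionConnectivity:
    def test_all_false_mask_zero_matrix(self):
        f = {"s0": np.random.default_rng(0).random((2, 3, 3))}
        conn = build_condition_connectivity(f, np.zeros((3, 3), dtype=bool))
        np.testing.assert_array_equal(conn.c_all, 0.0)

    def test_single_trial_all_true_identity(self):
        mat = np.random.default_rng(1).random((3, 3))
        conn = build_condition_connectivity({"s0": mat[None]}, np.ones((3, 3), dtype=bool))
        np.testing.assert_allclose(conn.c_all, mat, atol=1e-14)

    def test_trial_pvalue_matrix_shapes(self):
        rng = np.random.default_rng(5)
        trial = rng.standard_normal((3, 120))
        f, p = trial_pvalue_matrix(trial, T=2, n_iter=10, rng=rng)
        assert f.shape == (3, 3) and p.shape == (3, 3)
        off = ~np.eye(3, dtype=bool)
        assert np.all(np.isfinite(p[off]))
        assert np.all((p[off] > 0) & (p[off] <= 1))
        assert np.all(np.isnan(np.diag(p)))

    def test_stage_is_deterministic_given_rng_state(self):
        trial = np.random.default_rng(6).standard_normal((3, 100))
        f1, p1 = trial_pvalue_matrix(trial, 2, 8, np.random.default_rng(99))
        f2, p2 = trial_pvalue_matrix(trial, 2, 8, np.random.default_rng(99))
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(p1, p2)
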