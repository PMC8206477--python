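"""Ridge partial correlation, Fisher z, permutation test, summaries."""

import itertools

import numpy as np
import pytest

from brainnets.io_core import InputError, NumericError
from brainnets.netmats import (
    NetMat, edge_group_summaries, fisher_z, partial_corr_ridge,
    permutation_group_test, select_edges,
)


class TestPartialCorr:
    def test_three_variable_closed_form(self):
        rng = np.random.default_rng(0)
        T = 500
        x1 = rng.standard_normal(T)
        x2 = rng.standard_normal(T)
        x3 = x1 + x2 + 0.5 * rng.standard_normal(T)
        tcs = np.column_stack([x1, x2, x3])
        net = partial_corr_ridge(tcs, rho=0.0)
        r = np.corrcoef(tcs.T)
        # textbook r_{12.3} on the same sample
        expected = (r[0, 1] - r[0, 2] * r[1, 2]) / np.sqrt(
            (1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2))
        assert net.pc[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_equals_normalized_precision_at_rho_zero(self):
        rng = np.random.default_rng(1)
        for K in (3, 6):
            L = rng.standard_normal((K, K))
            tcs = rng.standard_normal((400, K)) @ L
            net = partial_corr_ridge(tcs, rho=0.0)
            X = (tcs - tcs.mean(0)) / tcs.std(0)
            prec = np.linalg.inv(X.T @ X / 400)
            d = np.sqrt(np.diag(prec))
            expected = -prec / np.outer(d, d)
            np.fill_diagonal(expected, 0.0)
            np.testing.assert_allclose(net.pc, (expected + expected.T) / 2,
                                       atol=1e-10)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(2)
        net = partial_corr_ridge(rng.standard_normal((10000, 4)), rho=0.1)
        off = net.pc[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_shrinkage_monotone_in_rho(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(300)
        tcs = np.column_stack([z + 0.5 * rng.standard_normal(300)
                               for _ in range(3)])
        mags = [np.abs(partial_corr_ridge(tcs, rho=r).pc[0, 1])
                for r in (0.1, 1.0, 10.0)]
        assert mags[0] > mags[1] > mags[2]

    def test_singular_at_rho_zero_advises_ridge(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(100)
        tcs = np.column_stack([x, x, rng.standard_normal(100)])
        with pytest.raises(NumericError, match="rho"):
            partial_corr_ridge(tcs, rho=0.0)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(InputError):
            partial_corr_ridge(np.random.default_rng(0).standard_normal((3, 4)))


class TestFisherZ:
    def _net(self, r):
        pc = np.array([[0.0, r], [r, 0.0]])
        return NetMat(pc=pc, rho=0.1)

    def test_values_and_round_trip(self):
        assert fisher_z(self._net(0.0))[0, 1] == 0.0
        z = fisher_z(self._net(0.5))
        assert z[0, 1] == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert z[0, 1] == pytest.approx(0.5493, abs=1e-4)
        np.testing.assert_allclose(np.tanh(z[0, 1]), 0.5, atol=1e-12)
        assert z[0, 0] == 0.0

    def test_unit_correlation_overflows(self):
        with pytest.raises(NumericError):
            fisher_z(self._net(1.0))


def _z_cohort(rng, n_case, n_ctrl, K=4, shift=None):
    """Symmetric z-matrices with iid N(0,1) upper triangles."""
    mats, labels = [], []
    for g, n in ((1, n_case), (0, n_ctrl)):
        for _ in range(n):
            z = np.zeros((K, K))
            iu = np.triu_indices(K, 1)
            vals = rng.standard_normal(len(iu[0]))
            if g == 1 and shift is not None:
                vals[0] += shift
            z[iu] = vals
            mats.append(z + z.T)
            labels.append(g)
    return mats, np.array(labels)


class TestPermutationTest:
    def test_minimum_p_is_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(5)
        mats, labels = _z_cohort(rng, 10, 10, shift=50.0)
        comp = permutation_group_test(mats, labels, n_perm=200, seed=0)
        floor = 1.0 / 201
        assert comp.p_values.min() >= floor - 1e-12
        # a sampled permutation can tie the observed split only by
        # reproducing it exactly, so the planted edge sits at (or a hair
        # above) the attainable floor
        assert comp.p_values.min() <= 2 * floor + 1e-12

    def test_relabeling_groups_preserves_p(self):
        rng = np.random.default_rng(6)
        mats, labels = _z_cohort(rng, 8, 12, shift=1.0)
        a = permutation_group_test(mats, labels, n_perm=500, seed=3)
        b = permutation_group_test(mats, 1 - labels, n_perm=500, seed=3)
        np.testing.assert_allclose(a.p_values, b.p_values, atol=1e-12)
        np.testing.assert_allclose(a.observed, -b.observed, atol=1e-12)

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(7)
        mats, labels = _z_cohort(rng, 4, 4, K=3, shift=1.5)
        Z = np.stack([m[np.triu_indices(3, 1)] for m in mats])
        obs = Z[labels == 1].mean(0) - Z[labels == 0].mean(0)
        # exhaustive unordered assignments of 4 case slots among 8
        count = np.zeros(Z.shape[1])
        combos = list(itertools.combinations(range(8), 4))
        for c in combos:
            mask = np.zeros(8, dtype=bool)
            mask[list(c)] = True
            stat = Z[mask].mean(0) - Z[~mask].mean(0)
            count += np.abs(stat) >= np.abs(obs) - 1e-15
        exact = count / len(combos)
        comp = permutation_group_test(mats, labels, n_perm=10000, seed=1)
        np.testing.assert_allclose(comp.p_values, exact, atol=0.02)

    def test_tiny_groups_rejected(self):
        rng = np.random.default_rng(8)
        mats, labels = _z_cohort(rng, 1, 5)
        with pytest.raises(InputError):
            permutation_group_test(mats, labels, n_perm=10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        mats, labels = _z_cohort(rng, 6, 6)
        a = permutation_group_test(mats, labels, n_perm=300, seed=7)
        b = permutation_group_test(mats, labels, n_perm=300, seed=7)
        np.testing.assert_array_equal(a.p_values, b.p_values)


class TestEdgeSelection:
    def test_threshold_and_sign_annotation(self):
        rng = np.random.default_rng(10)
        mats, labels = _z_cohort(rng, 12, 12, shift=3.0)
        comp = permutation_group_test(mats, labels, n_perm=999, seed=0)
        sel = select_edges(comp, alpha=0.05)
        assert (0, 1) in list(zip(sel.i, sel.j))
        planted = sel[(sel.i == 0) & (sel.j == 1)]
        assert planted.direction.iloc[0] == "case > control"

    def test_all_p_one_selects_nothing(self):
        comp_frame_edges = [(0, 1), (0, 2)]
        from brainnets.netmats import EdgeComparison
        comp = EdgeComparison(edges=comp_frame_edges,
                              observed=np.zeros(2),
                              p_values=np.ones(2), n_perm=10, alpha=0.05)
        assert len(select_edges(comp)) == 0


class TestSummaries:
    def test_five_number_summary(self):
        K = 3
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        mats = []
        for v in vals + vals:
            z = np.zeros((K, K))
            z[0, 1] = z[1, 0] = v
            mats.append(z)
        labels = np.array([1] * 5 + [0] * 5)
        frame = edge_group_summaries(mats, labels, [(0, 1)])
        case = frame[frame.group == "case"].iloc[0]
        assert case["median"] == 3.0 and case.q1 == 2.0 and case.q3 == 4.0

    def test_constant_values_no_outliers(self):
        K = 2
        mats = [np.array([[0.0, 1.0], [1.0, 0.0]])] * 6
        labels = np.array([1, 1, 1, 0, 0, 0])
        frame = edge_group_summaries(mats, labels, [(0, 1)])
        assert all(len(o) == 0 for o in frame.outliers)

    def test_far_value_listed_as_outlier(self):
        K = 2
        vals = [1.0, 1.1, 1.2, 1.3, 5.0]
        mats = []
        for v in vals + [0.0] * 3:
            z = np.zeros((K, K))
            z[0, 1] = z[1, 0] = v
            mats.append(z)
        labels = np.array([1] * 5 + [0] * 3)
        frame = edge_group_summaries(mats, labels, [(0, 1)])
        case = frame[frame.group == "case"].iloc[0]
        assert 5.0 in case.outliers

    def test_empty_edges_rejected(self):
        with pytest.raises(InputError):
            edge_group_summaries([np.zeros((2, 2))] * 4, np.array([1, 1, 0, 0]),
                                 [])
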