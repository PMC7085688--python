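"""Elastic-net path, candidate subsets, and the grouping diagnostic."""

import numpy as np
import pytest

from epsvm import (
    CandidateSubsets,
    ENetConfig,
    SimulationSpec,
    enet_path,
    simulate_dataset,
    subset_grouping_score,
)
from epsvm.enet_select import ENetError, _working_data


def ista_enet(X, y, lam, alpha, n_steps=200_000, lr=None):
    """Independent proximal-gradient (ISTA) solver for
    ||y - X b||^2 + lam * (alpha |b|_1 + (1 - alpha) ||b||^2)."""
    n, p = X.shape
    if lr is None:
        lr = 1.0 / (2 * np.linalg.eigvalsh(X.T @ X).max() + 2 * lam * (1 - alpha))
    b = np.zeros(p)
    for _ in range(n_steps):
        grad = -2 * X.T @ (y - X @ b) + 2 * lam * (1 - alpha) * b
        z = b - lr * grad
        b_new = np.sign(z) * np.maximum(np.abs(z) - lr * lam * alpha, 0.0)
        if np.max(np.abs(b_new - b)) < 1e-12:
            return b_new
        b = b_new
    return b


def correlated_toy(seed=0, n=40):
    """Two strongly correlated informative columns plus one noise column."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=n)
    x1 = base + 0.1 * rng.normal(size=n)
    x2 = base + 0.1 * rng.normal(size=n)
    x3 = rng.normal(size=n)
    y = np.where(base > 0, 1.0, -1.0)
    return np.column_stack([x1, x2, x3]), y


class TestConfig:
    def test_alpha_open_interval_enforced(self):
        with pytest.raises(ENetError):
            ENetConfig(alpha=1.0)
        with pytest.raises(ENetError):
            ENetConfig(alpha=0.0)
        ENetConfig(alpha=1.0, allow_boundary=True)

    def test_ridge_limit_needs_lambda_grid(self):
        with pytest.raises(ENetError):
            ENetConfig(alpha=0.0, allow_boundary=True)


class TestPath:
    def test_lambda_above_max_gives_no_subset(self):
        X, y = correlated_toy()
        Xw, yw = _working_data(X, y, True)
        lam_max = 2.0 * np.max(np.abs(Xw.T @ yw)) / 0.5
        cands = enet_path(X, y, ENetConfig(alpha=0.5, lambdas=[2 * lam_max, lam_max / 50]))
        # the all-zero solution at 2*lam_max is dropped; only smaller lambda remains
        assert len(cands) == 1
        assert cands.lambdas[0] == pytest.approx(lam_max / 50)

    def test_matches_independent_ista_solver(self):
        X, y = correlated_toy()
        alpha = 0.5
        Xw, yw = _working_data(X, y, True)
        lam_max = 2.0 * np.max(np.abs(Xw.T @ yw)) / alpha
        for lam in (lam_max * 0.5, lam_max * 0.1, lam_max * 0.02):
            cands = enet_path(
                X, y, ENetConfig(alpha=alpha, lambdas=[lam], tol=1e-12)
            )
            b_oracle = ista_enet(Xw, yw, lam, alpha)
            support_oracle = set(np.flatnonzero(np.abs(b_oracle) > 1e-8).tolist())
            if not support_oracle:
                assert cands.fallback
                continue
            assert set(cands.subsets[0].tolist()) == support_oracle
            np.testing.assert_allclose(
                cands.coefficients[:, 0], b_oracle, atol=1e-5
            )

    def test_correlated_pair_enters_before_noise(self):
        X, y = correlated_toy()
        cands = enet_path(X, y, ENetConfig(alpha=0.5))
        first = set(cands.subsets[0].tolist())
        assert first == {0, 1}  # the correlated pair enters together first
        # the noise column only appears later on the path
        first_noise = next(
            (k for k, s in enumerate(cands.subsets) if 2 in set(s.tolist())),
            len(cands),
        )
        assert first_noise > 0

    def test_ridge_override_matches_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 6))
        y = np.sign(rng.normal(size=30))
        lam = 3.7
        cfg = ENetConfig(alpha=0.0, allow_boundary=True, lambdas=[lam],
                         standardize=False)
        cands = enet_path(X, y, cfg)
        Xw, yw = _working_data(X, y, False)
        b_closed = np.linalg.solve(Xw.T @ Xw + lam * np.eye(6), Xw.T @ yw)
        np.testing.assert_allclose(cands.coefficients[:, 0], b_closed, atol=1e-8)
        assert cands.subsets[0].size == 6  # ridge keeps everything

    def test_lasso_override_support_bounded_by_n(self):
        rng = np.random.default_rng(2)
        n, p = 20, 50
        X = rng.normal(size=(n, p))
        y = np.sign(rng.normal(size=n))
        cands = enet_path(X, y, ENetConfig(alpha=1.0, allow_boundary=True))
        assert max(s.size for s in cands.subsets) <= n

    def test_support_growth_and_dedup(self):
        X, y = correlated_toy()
        cands = enet_path(X, y, ENetConfig(alpha=0.5))
        assert cands.subsets[0].size <= cands.subsets[-1].size
        keys = {tuple(s.tolist()) for s in cands.subsets}
        assert len(keys) == len(cands.subsets)
        assert all(s.size > 0 for s in cands.subsets)
        assert (np.diff(cands.lambdas) < 0).all()

    def test_returned_solution_beats_zero_and_perturbations(self):
        X, y = correlated_toy(seed=3)
        alpha = 0.5
        cfg = ENetConfig(alpha=alpha)
        cands = enet_path(X, y, cfg)
        Xw, yw = _working_data(X, y, True)

        def obj(b, lam):
            return (
                np.sum((yw - Xw @ b) ** 2)
                + lam * (alpha * np.abs(b).sum() + (1 - alpha) * np.sum(b**2))
            )

        rng = np.random.default_rng(0)
        for k in (0, len(cands) // 2, len(cands) - 1):
            b = cands.coefficients[:, k]
            lam = cands.lambdas[k]
            best = obj(b, lam)
            assert best <= obj(np.zeros_like(b), lam) + 1e-9
            for _ in range(100):
                assert best <= obj(b + rng.normal(0, 0.01, b.size), lam) + 1e-9

    def test_standardization_makes_supports_scale_invariant(self):
        X, y = correlated_toy(seed=4)
        X2 = X.copy()
        X2[:, 0] *= 1000.0
        a = enet_path(X, y, ENetConfig(alpha=0.5))
        b = enet_path(X2, y, ENetConfig(alpha=0.5))
        assert [s.tolist() for s in a.subsets] == [s.tolist() for s in b.subsets]

    def test_all_empty_path_falls_back_to_full_feature_set(self):
        X, y = correlated_toy()
        Xw, yw = _working_data(X, y, True)
        lam_max = 2.0 * np.max(np.abs(Xw.T @ yw)) / 0.5
        with pytest.warns(UserWarning, match="full feature set"):
            cands = enet_path(
                X, y, ENetConfig(alpha=0.5, lambdas=[2 * lam_max, 4 * lam_max])
            )
        assert cands.fallback
        assert len(cands) == 1
        assert cands.subsets[0].tolist() == [0, 1, 2]

    def test_both_classes_required(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ENetError):
            enet_path(X, np.ones(10), ENetConfig())


class TestGroupingScore:
    def test_always_and_never_paired_extremes(self):
        always = CandidateSubsets(
            subsets=[np.array([0, 1]), np.array([0, 1, 4, 5])],
            lambdas=np.array([2.0, 1.0]),
        )
        never = CandidateSubsets(
            subsets=[np.array([0, 4]), np.array([0, 2])],
            lambdas=np.array([2.0, 1.0]),
        )
        pairs = [(0, 1), (4, 5)]
        assert subset_grouping_score(always, pairs) == 1.0
        assert subset_grouping_score(never, pairs) == 0.0

    def test_enet_groups_correlated_duplicates_better_than_lasso(self):
        # class-1 subproblem of the 3-class simulation: feature j and
        # j+60 share the same signal draw; grouping should favor the
        # elastic net over the LASSO limit
        enet_scores, lasso_scores = [], []
        for seed in range(20):
            ds = simulate_dataset(SimulationSpec(index=1, seed=seed))
            ybin = np.where(ds.y == 1, 1, -1)
            pairs = [(j, j + 60) for j in range(60)]
            e = enet_path(ds.X, ybin, ENetConfig(alpha=0.5))
            l = enet_path(ds.X, ybin, ENetConfig(alpha=1.0, allow_boundary=True))
            enet_scores.append(subset_grouping_score(e, pairs))
            lasso_scores.append(subset_grouping_score(l, pairs))
        assert np.mean(enet_scores) > np.mean(lasso_scores)
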