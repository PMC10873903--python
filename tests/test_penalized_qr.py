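import numpy as np
import pytest
from scipy import stats

from quantmed.data_model import MediationDataset, standardize_mediators
from quantmed.penalized_qr import (
    McpParams,
    fit_path,
    fit_penalized,
    lambda_path,
    mcp_penalty,
    mcp_scalar_update,
    select_lambda,
)
from quantmed.quantile_core import fit_quantile


@pytest.mark.parametrize(
    "t, lam, delta, expected",
    [
        (0.0, 1.0, 3.0, 0.0),
        (5.0, 1.0, 3.0, 1.5),       # saturation lam^2 delta / 2
        (1.0, 1.0, 3.0, 1.0 - 1 / 6),
        (-1.0, 1.0, 3.0, 1.0 - 1 / 6),  # even function
        (3.0, 1.0, 3.0, 1.5),       # boundary |t| = delta*lam
        (0.5, 2.0, 2.5, 2.0 * (0.5 - 0.25 / (2 * 2.5 * 2.0))),
    ],
)
def test_mcp_penalty_closed_form(t, lam, delta, expected):
    assert mcp_penalty(t, McpParams(lam=lam, delta=delta)) == pytest.approx(expected)


def test_mcp_penalty_continuous_at_kink():
    p = McpParams(lam=0.7, delta=2.3)
    edge = p.delta * p.lam
    assert mcp_penalty(edge - 1e-9, p) == pytest.approx(mcp_penalty(edge + 1e-9, p), abs=1e-8)


class TestScalarUpdate:
    def test_zero_maps_to_zero(self):
        assert mcp_scalar_update(0.0, 1.0, McpParams(lam=1.0)) == 0.0

    def test_identity_beyond_flat_region(self):
        p = McpParams(lam=1.0, delta=3.0)
        for z in (3.0, -3.5, 10.0):
            assert mcp_scalar_update(z, 1.0, p) == pytest.approx(z)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            mcp_scalar_update(1.0, 0.3, McpParams(lam=1.0, delta=3.0))  # delta*w <= 1

    def test_matches_grid_search_oracle(self):
        """Proximal rule vs brute-force minimization on random triples."""
        rng = np.random.default_rng(11)
        grid = np.arange(-4.0, 4.0, 1e-4)
        for _ in range(300):
            z = float(rng.uniform(-3, 3))
            lam = float(rng.uniform(0.05, 1.5))
            delta = float(rng.uniform(1.5, 5.0))
            w = float(rng.uniform(1.05 / delta + 0.05, 3.0))
            p = McpParams(lam=lam, delta=delta)
            vals = w * (z - grid) ** 2 / 2 + mcp_penalty(grid, p)
            oracle = grid[np.argmin(vals)]
            ours = mcp_scalar_update(z, w, p)
            assert abs(ours - oracle) < 1e-3  # grid resolution 1e-4

    def test_spec_point_against_fine_grid(self):
        p = McpParams(lam=1.0, delta=3.0)
        grid = np.arange(-3.0, 3.0, 1e-5)
        vals = (1.5 - grid) ** 2 / 2 + mcp_penalty(grid, p)
        assert mcp_scalar_update(1.5, 1.0, p) == pytest.approx(grid[np.argmin(vals)], abs=1e-4)


def penalized_instance(rng, n=120, p=8):
    x = rng.normal(0, 2, n)
    z = rng.normal(0, 2, (n, 2))
    m = np.outer(x, np.r_[0.8, -0.6, np.zeros(p - 2)]) + rng.normal(size=(n, p))
    y = 0.5 * x + 1.5 * m[:, 0] - 1.0 * m[:, 1] + 0.5 * z.sum(axis=1) + rng.normal(size=n)
    ds = MediationDataset(exposure=x, mediators=m, covariates=z, outcome=y)
    std, _ = standardize_mediators(ds)
    return std


class TestFitPenalized:
    def test_huge_lambda_empties_the_model(self, rng):
        std = penalized_instance(rng)
        fit = fit_penalized(std, np.arange(std.p), 0.5, McpParams(lam=50.0))
        assert fit.active_set.size == 0
        np.testing.assert_array_equal(fit.mediator_coefficients, 0.0)

    def test_vanishing_lambda_recovers_unpenalized_fit(self, rng):
        std = penalized_instance(rng, n=150, p=4)
        fit = fit_penalized(std, np.arange(4), 0.5, McpParams(lam=1e-6))
        n = std.n
        design = np.column_stack([np.ones(n), std.exposure, std.mediators, std.covariates])
        h = fit.theta  # layout check below
        free = fit_quantile(design, std.outcome, 0.5, se=None,
                            bandwidth=None, min_bandwidth=None)
        # compare on the smoothed scale: refit with the same fixed bandwidth
        from quantmed.quantile_core import default_bandwidth
        hb = default_bandwidth(n, design.shape[1])
        free_smoothed = fit_quantile(design, std.outcome, 0.5, se=None,
                                     bandwidth=hb, min_bandwidth=hb)
        np.testing.assert_allclose(fit.theta, free_smoothed.coefficients, atol=1e-4)

    def test_objective_beats_zero_solution(self, rng):
        """In the solver's smoothed metric, the returned fit is at least as
        good as its zero-mediator-coefficient starting point."""
        from quantmed.penalized_qr import (
            _design,
            _null_mediator_theta,
            _screened_pilot_scale,
            _smooth_loss_mean,
            mcp_penalty,
        )
        from quantmed.quantile_core import default_bandwidth

        std = penalized_instance(rng)
        retained = np.arange(std.p)
        lam = 0.2
        fit = fit_penalized(std, retained, 0.5, McpParams(lam=lam))
        A = _design(std, retained)
        y = std.outcome
        h = default_bandwidth(std.n, A.shape[1]) * _screened_pilot_scale(A, y)

        def smoothed_obj(theta):
            pen = float(np.sum(mcp_penalty(theta[2 : 2 + std.p], fit.params)))
            return _smooth_loss_mean(y - A @ theta, 0.5, h) + pen

        null = _null_mediator_theta(std, retained, 0.5)
        assert smoothed_obj(fit.theta) <= smoothed_obj(null) + 1e-10

    def test_deterministic(self, rng):
        std = penalized_instance(rng)
        f1 = fit_penalized(std, np.arange(std.p), 0.5, McpParams(lam=0.3))
        f2 = fit_penalized(std, np.arange(std.p), 0.5, McpParams(lam=0.3))
        np.testing.assert_array_equal(f1.theta, f2.theta)


class TestLambdaPath:
    def test_two_point_grid_hits_endpoints(self, rng):
        std = penalized_instance(rng)
        grid = lambda_path(std, np.arange(std.p), 0.5, n_lambda=2)
        assert grid.size == 2
        assert grid[1] == pytest.approx(0.01 * grid[0])

    def test_grid_strictly_decreasing(self, rng):
        std = penalized_instance(rng)
        grid = lambda_path(std, np.arange(std.p), 0.5, n_lambda=10)
        assert np.all(np.diff(grid) < 0)

    def test_largest_lambda_gives_empty_set(self, rng):
        std = penalized_instance(rng)
        grid = lambda_path(std, np.arange(std.p), 0.5, n_lambda=5)
        fit = fit_penalized(std, np.arange(std.p), 0.5, McpParams(lam=float(grid[0])))
        assert fit.active_set.size == 0

    def test_rejects_single_point_grid(self, rng):
        std = penalized_instance(rng)
        with pytest.raises(ValueError):
            lambda_path(std, np.arange(std.p), 0.5, n_lambda=1)


class TestSelectLambda:
    def test_single_fit_returned(self, rng):
        std = penalized_instance(rng)
        fit = fit_penalized(std, np.arange(std.p), 0.5, McpParams(lam=0.5))
        assert select_lambda([fit]) is fit

    def test_tie_goes_to_sparser_first_listed(self, rng):
        std = penalized_instance(rng)
        f1 = fit_penalized(std, np.arange(std.p), 0.5, McpParams(lam=0.5))
        f2 = fit_penalized(std, np.arange(std.p), 0.5, McpParams(lam=0.5))
        assert select_lambda([f1, f2]) is f1  # equal criteria -> first (larger lam)

    def test_path_selection_finds_true_support(self, rng):
        std = penalized_instance(rng, n=200, p=10)
        best, fits = fit_path(std, np.arange(10), 0.5)
        assert {0, 1} <= set(best.active_set.tolist())
        assert best.active_set.size <= 6

    def test_weak_monotone_sparsity_along_path(self, rng):
        std = penalized_instance(rng, n=150, p=10)
        _, fits = fit_path(std, np.arange(10), 0.5, n_lambda=12)
        sizes = np.array([f.active_set.size for f in fits], dtype=float)
        lams = np.array([f.params.lam for f in fits])
        rho = stats.spearmanr(lams, sizes).statistic
        assert rho < 0 or np.all(sizes == sizes[0])
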