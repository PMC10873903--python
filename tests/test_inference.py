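import numpy as np
import pytest

from quantmed.data_model import MediationDataset, standardize_mediators
from quantmed.inference import (
    controlled_effects,
    js_statistic,
    ols_mediator_model,
    refit_submodel,
    run_mediation,
    select_mediators,
)
from quantmed.quantile_core import fit_quantile

from conftest import lp_quantile_regression


class TestOlsMediatorModel:
    def test_noiseless_slope(self, rng):
        n = 40
        x = rng.normal(size=n)
        m = (0.5 * x)[:, None]
        ds = MediationDataset(
            exposure=x, mediators=m, covariates=np.empty((n, 0)), outcome=rng.normal(size=n)
        )
        alpha, se, p = ols_mediator_model(ds, 0)
        assert alpha == pytest.approx(0.5, abs=1e-10)
        assert p < 1e-12

    def test_normal_quantile_pvalue(self):
        # a z-statistic of 1.959964 must give p = 0.05 under the printed
        # two-sided normal rule; engineered by direct construction
        from scipy.special import ndtr

        z = 1.959964
        assert 2 * (1 - ndtr(z)) == pytest.approx(0.05, abs=1e-6)

    def test_matches_statsmodels_ols(self, rng, toy_dataset):
        sm = pytest.importorskip("statsmodels.api")
        alpha, se, p = ols_mediator_model(toy_dataset, 0)
        X = sm.add_constant(
            np.column_stack([toy_dataset.exposure, toy_dataset.covariates])
        )
        fit = sm.OLS(toy_dataset.mediators[:, 0], X).fit()
        assert alpha == pytest.approx(fit.params[1], rel=1e-10)
        assert se == pytest.approx(fit.bse[1], rel=1e-10)

    def test_null_pvalues_uniform(self):
        """Independent X: the alpha p-value is Uniform(0,1) across replicates."""
        from scipy import stats

        rng = np.random.default_rng(3)
        n = 2000
        pvals = []
        for _ in range(200):
            x = rng.normal(size=n)
            m = rng.normal(size=(n, 1))
            ds = MediationDataset(
                exposure=x, mediators=m, covariates=np.empty((n, 0)), outcome=np.zeros(n)
            )
            pvals.append(ols_mediator_model(ds, 0)[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRefitSubmodel:
    def test_full_set_matches_direct_fit(self, toy_dataset):
        std, _ = standardize_mediators(toy_dataset)
        s = np.arange(3)
        refit = refit_submodel(std, s, 0.5)
        n = std.n
        design = np.column_stack(
            [np.ones(n), std.exposure, std.mediators[:, :3], std.covariates]
        )
        direct = fit_quantile(design, std.outcome, 0.5)
        np.testing.assert_allclose(refit.coefficients, direct.coefficients, atol=1e-10)

    def test_empty_set_gives_direct_effect_only_model(self, toy_dataset):
        refit = refit_submodel(toy_dataset, np.array([], dtype=int), 0.5)
        n = toy_dataset.n
        base = np.column_stack([np.ones(n), toy_dataset.exposure, toy_dataset.covariates])
        direct = fit_quantile(base, toy_dataset.outcome, 0.5)
        np.testing.assert_allclose(refit.coefficients, direct.coefficients, atol=1e-10)

    def test_matches_lp_oracle_small_instance(self, rng):
        n = 30
        x = rng.normal(size=n)
        z = np.empty((n, 0))
        m = rng.normal(size=(n, 2))
        y = 0.3 * x + m @ [1.0, -0.5] + rng.normal(size=n)
        ds = MediationDataset(exposure=x, mediators=m, covariates=z, outcome=y)
        refit = refit_submodel(ds, np.array([0, 1]), 0.5)
        design = np.column_stack([np.ones(n), x, m])
        oracle = lp_quantile_regression(design, y, 0.5)
        np.testing.assert_allclose(refit.coefficients, oracle, atol=1e-5)


class TestJsStatistic:
    @pytest.mark.parametrize(
        "pa, pb, d, exp_p, exp_d",
        [
            (0.001, 0.02, 5, 0.02, 0.1),
            (0.5, 0.4, 3, 0.5, 1.0),
            (0.0, 0.0, 7, 0.0, 0.0),
            (0.01, 0.001, 4, 0.01, 0.04),
        ],
    )
    def test_arithmetic(self, pa, pb, d, exp_p, exp_d):
        p_js, d_js = js_statistic(pa, pb, d)
        assert p_js == pytest.approx(exp_p)
        assert d_js == pytest.approx(exp_d)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            js_statistic(0.1, 0.2, 0)
        with pytest.raises(ValueError):
            js_statistic(-0.1, 0.2, 3)

    def test_monotone_in_arguments(self):
        base = js_statistic(0.01, 0.02, 3)[1]
        assert js_statistic(0.015, 0.02, 3)[1] >= base
        assert js_statistic(0.01, 0.03, 3)[1] >= base
        assert js_statistic(0.01, 0.02, 5)[1] >= base


class TestSelection:
    def _mk(self, idx, d_js):
        from quantmed.inference import MediatorTest

        return MediatorTest(
            index=idx, name=f"M{idx}", alpha_hat=1, se_alpha=1, beta_hat=1, se_beta=1,
            p_alpha=0, p_beta=0, p_js=0, d_js=d_js, effect=1.0, selected=d_js < 0.05,
        )

    def test_boundary_is_strict(self):
        tests = [self._mk(0, 0.05), self._mk(1, 0.0499), self._mk(2, 1.0)]
        np.testing.assert_array_equal(select_mediators(tests), [1])

    def test_all_ones_select_nothing(self):
        tests = [self._mk(i, 1.0) for i in range(4)]
        assert select_mediators(tests).size == 0


class TestControlledEffects:
    def _mk(self, effect, selected):
        from quantmed.inference import MediatorTest

        return MediatorTest(
            index=0, name="M", alpha_hat=1, se_alpha=1, beta_hat=1, se_beta=1,
            p_alpha=0, p_beta=0, p_js=0, d_js=0, effect=effect, selected=selected,
        )

    def test_no_shift_no_effect(self):
        cde, cie = controlled_effects(0.7, [self._mk(1.2, True)], 2.0, 2.0)
        assert cde == 0.0 and cie == 0.0

    def test_unit_shift_direct(self):
        cde, cie = controlled_effects(0.5, [], 1.0, 0.0)
        assert cde == pytest.approx(0.5) and cie == 0.0

    def test_true_cie_of_simulated_strong_mediators(self):
        # products of the design's true path coefficients for mediators 1-3
        from quantmed.synthetic_data import default_config, truth_at

        cfg = default_config(300, 9, "I", seed=0)
        truth = truth_at(cfg, 0.5)
        assert float(truth.effects_at_tau[:3].sum()) == pytest.approx(3.1625)
        tests = [self._mk(e, True) for e in truth.effects_at_tau[:3]]
        _, cie = controlled_effects(0.5, tests, 1.0, 0.0)
        assert cie == pytest.approx(3.1625)


class TestPipeline:
    def test_overwhelming_single_path_is_found(self):
        rng = np.random.default_rng(21)
        n, p = 500, 5
        x = rng.normal(size=n)
        m = rng.normal(size=(n, p)) * 0.1
        m[:, 0] = 2.0 * x + 0.1 * rng.normal(size=n)
        y = 2.0 * m[:, 0] + 0.1 * rng.normal(size=n)
        ds = MediationDataset(
            exposure=x, mediators=m, covariates=np.empty((n, 0)), outcome=y
        )
        res = run_mediation(ds, 0.5)
        np.testing.assert_array_equal(res.selected_set, [0])
        # single-mediator oracle: the path product is about alpha*beta = 4
        t = res.tests[[t.index for t in res.tests].index(0)]
        assert t.effect == pytest.approx(4.0, rel=0.1)

    def test_funnel_nesting_and_determinism(self, toy_dataset):
        r1 = run_mediation(toy_dataset, 0.4)
        r2 = run_mediation(toy_dataset, 0.4)
        assert set(r1.selected_set) <= set(r1.survived_set) <= set(
            r1.screening.retained.tolist()
        )
        np.testing.assert_array_equal(r1.selected_set, r2.selected_set)
        np.testing.assert_array_equal(
            r1.refit.coefficients, r2.refit.coefficients
        )
        assert r1.gamma_hat == r2.gamma_hat

    def test_effect_invariant_to_mediator_scaling(self, toy_dataset):
        """alpha_k * beta_k,tau does not change when mediators are rescaled."""
        r1 = run_mediation(toy_dataset, 0.5)
        scaled = MediationDataset(
            exposure=toy_dataset.exposure,
            mediators=toy_dataset.mediators * np.geomspace(0.01, 100, toy_dataset.p),
            covariates=toy_dataset.covariates,
            outcome=toy_dataset.outcome,
        )
        r2 = run_mediation(scaled, 0.5)
        e1 = {t.index: t.effect for t in r1.tests}
        e2 = {t.index: t.effect for t in r2.tests}
        assert set(e1) == set(e2)
        for k in e1:
            assert e1[k] == pytest.approx(e2[k], rel=1e-6, abs=1e-8)

    def test_result_table_schema(self, toy_dataset):
        res = run_mediation(toy_dataset, 0.5)
        frame = res.to_frame()
        expected = {
            "index", "name", "alpha_hat", "se_alpha", "beta_hat", "se_beta",
            "p_alpha", "p_beta", "p_js", "d_js", "effect", "selected",
        }
        assert expected <= set(frame.columns)
        assert len(frame) == res.survived_set.size
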