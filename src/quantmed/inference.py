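"""Step 3 — refitting, joint-significance testing, and effect reporting.

For each mediator surviving the penalized stage, two coefficients form the
mediation path at quantile level tau: the exposure effect on the mediator
(``alpha_k``, from an ordinary least-squares fit of M_k on X and Z) and the
mediator effect on the outcome quantile (``beta_k,tau``, from an
unpenalized quantile refit restricted to the survivors).  The
joint-significance decision statistic

    D_k = min(d_tau * max(P_alpha, P_beta), 1),   d_tau = |S_tau|,

scales the weaker of the two normal-based p-values by the survivor count,
and mediators with ``D_k < 0.05`` form the reported set.  The controlled
direct effect is ``gamma_tau (x - x*)`` and the controlled indirect effect
``sum_k alpha_k beta_k,tau (x - x*)`` over the selected mediators; the
products ``alpha_k beta_k,tau`` are invariant to mediator standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .data_model import (
    MediationDataset,
    QuantileLevel,
    StandardizationRecord,
    standardize_mediators,
)
from .penalized_qr import PenalizedFit, fit_path
from .quantile_core import FitError, QuantileFit, fit_quantile
from .screening import ScreeningResult, screen

__all__ = [
    "MediatorTest",
    "MediationResult",
    "ols_mediator_model",
    "refit_submodel",
    "js_statistic",
    "select_mediators",
    "controlled_effects",
    "run_mediation",
]


@dataclass(frozen=True)
class MediatorTest:
    """Per-mediator path estimates and the joint-significance decision."""

    index: int
    name: str
    alpha_hat: float
    se_alpha: float
    beta_hat: float
    se_beta: float
    p_alpha: float
    p_beta: float
    p_js: float
    d_js: float
    effect: float
    selected: bool
    beta_hat_std: float = np.nan
    se_beta_std: float = np.nan


@dataclass(frozen=True)
class MediationResult:
    """Full pipeline output for one quantile level."""

    tau: QuantileLevel
    gamma_hat: float
    tests: tuple
    selected_set: np.ndarray
    total_cie: float
    screening: ScreeningResult
    penalized: PenalizedFit
    refit: QuantileFit
    standardization: StandardizationRecord
    alpha_level: float = 0.05

    @property
    def survived_set(self) -> np.ndarray:
        return self.penalized.active_set

    def to_frame(self) -> pd.DataFrame:
        """One row per tested mediator (the survivor set S_tau)."""
        return pd.DataFrame(
            [
                {
                    "index": t.index,
                    "name": t.name,
                    "alpha_hat": t.alpha_hat,
                    "se_alpha": t.se_alpha,
                    "beta_hat": t.beta_hat,
                    "se_beta": t.se_beta,
                    "p_alpha": t.p_alpha,
                    "p_beta": t.p_beta,
                    "p_js": t.p_js,
                    "d_js": t.d_js,
                    "effect": t.effect,
                    "selected": t.selected,
                    "beta_hat_std": t.beta_hat_std,
                    "se_beta_std": t.se_beta_std,
                }
                for t in self.tests
            ]
        )


def ols_mediator_model(dataset: MediationDataset, k: int):
    """OLS fit of mediator k on [1, X, Z]: returns (alpha_hat, se, p-value).

    The p-value is the two-sided normal one, ``2(1 - Phi(|alpha|/se))``.
    """
    a, s, p = _ols_alpha_batch(dataset, np.asarray([k], dtype=int))
    return float(a[0]), float(s[0]), float(p[0])


def _ols_alpha_batch(dataset: MediationDataset, indices: np.ndarray):
    """Closed-form OLS of each M_k on [1, X, Z], vectorized over k."""
    n = dataset.n
    D = np.column_stack([np.ones(n), dataset.exposure, dataset.covariates])
    kdim = D.shape[1]
    if n <= kdim:
        raise FitError(f"mediator OLS needs n > q + 2; got n={n}, q+2={kdim}")
    G = D.T @ D
    Ginv = np.linalg.inv(G)
    M = dataset.mediators[:, indices]
    coef = Ginv @ (D.T @ M)  # (kdim, |S|)
    resid = M - D @ coef
    dof = n - kdim
    sigma2 = np.einsum("nk,nk->k", resid, resid) / dof
    se = np.sqrt(sigma2 * Ginv[1, 1])
    alpha = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(alpha) / se
    p = 2.0 * (1.0 - ndtr(z))
    return alpha, se, p


def refit_submodel(dataset: MediationDataset, s_tau, tau, **fit_options) -> QuantileFit:
    """Unpenalized quantile refit on [1, X, M_S, Z] (direct-effect-only when
    ``S_tau`` is empty).  Coefficient layout matches the penalized design."""
    s_tau = np.asarray(s_tau, dtype=int)
    n = dataset.n
    design = np.column_stack(
        [np.ones(n), dataset.exposure, dataset.mediators[:, s_tau], dataset.covariates]
    )
    if design.shape[1] >= n:
        raise FitError("refit sub-model is not overdetermined")
    return fit_quantile(design, dataset.outcome, tau, **fit_options)


def js_statistic(p_alpha: float, p_beta: float, d_tau: int):
    """Joint-significance statistic: ``p_js = max(p_a, p_b)``,
    ``d_js = min(d_tau * p_js, 1)``."""
    if d_tau < 1:
        raise ValueError(f"d_tau must be >= 1; got {d_tau}")
    for p in (p_alpha, p_beta):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-values must lie in [0, 1]; got {p}")
    p_js = max(p_alpha, p_beta)
    return p_js, min(d_tau * p_js, 1.0)


def select_mediators(tests, alpha: float = 0.05) -> np.ndarray:
    """Indices with ``d_js`` strictly below ``alpha``, sorted ascending."""
    return np.asarray(sorted(t.index for t in tests if t.d_js < alpha), dtype=int)


def controlled_effects(gamma_hat: float, tests, x: float, x_star: float):
    """Controlled direct and indirect effects for an exposure shift x* -> x.

    CDE = gamma_tau (x - x*); CIE sums alpha_k beta_k,tau over the selected
    mediators.  The products are scale-invariant, so either coefficient
    scale (raw or standardized) yields the same CIE.
    """
    dx = x - x_star
    cie = sum(t.effect for t in tests if t.selected) * dx
    return gamma_hat * dx, cie


def run_mediation(
    dataset: MediationDataset,
    tau,
    *,
    alpha_level: float = 0.05,
    delta: float = 3.0,
    n_lambda: int = 20,
    d: int | None = None,
    screen_options: dict | None = None,
    path_options: dict | None = None,
) -> MediationResult:
    """Run the full three-step selection pipeline at one quantile level.

    standardize -> marginal screening -> MCP path + HBIC -> refit -> joint
    significance.  Deterministic: identical inputs give identical output.
    """
    tau = tau if isinstance(tau, QuantileLevel) else QuantileLevel(float(tau))
    try:
        std_data, record = standardize_mediators(dataset)
    except Exception as exc:
        raise type(exc)(f"[standardize] {exc}") from exc

    try:
        screening = screen(
            std_data, tau, d=d, assume_standardized=True, compute_se=False,
            **(screen_options or {}),
        )
    except Exception as exc:
        raise type(exc)(f"[screen] {exc}") from exc

    try:
        penalized, _path = fit_path(
            std_data, screening.retained, tau, delta=delta, n_lambda=n_lambda,
            **(path_options or {}),
        )
    except Exception as exc:
        raise type(exc)(f"[penalize] {exc}") from exc

    s_tau = penalized.active_set
    try:
        refit = refit_submodel(std_data, s_tau, tau)
    except Exception as exc:
        raise type(exc)(f"[refit] {exc}") from exc

    gamma_hat = float(refit.coefficients[1])
    tests: list[MediatorTest] = []
    if s_tau.size:
        alpha_hat, se_alpha, p_alpha = _ols_alpha_batch(dataset, s_tau)
        d_tau = int(s_tau.size)
        scale = record.scale[s_tau]
        for j, k in enumerate(s_tau):
            beta_std = float(refit.coefficients[2 + j])
            se_std = float(refit.standard_errors[2 + j])
            p_beta = float(2.0 * (1.0 - ndtr(abs(beta_std) / se_std))) if se_std > 0 else 0.0
            p_js, d_js = js_statistic(float(p_alpha[j]), p_beta, d_tau)
            beta_raw = beta_std / scale[j]
            effect = float(alpha_hat[j]) * beta_raw
            tests.append(
                MediatorTest(
                    index=int(k),
                    name=dataset.mediator_names[k],
                    alpha_hat=float(alpha_hat[j]),
                    se_alpha=float(se_alpha[j]),
                    beta_hat=beta_raw,
                    se_beta=se_std / scale[j],
                    p_alpha=float(p_alpha[j]),
                    p_beta=p_beta,
                    p_js=p_js,
                    d_js=d_js,
                    effect=effect,
                    selected=d_js < alpha_level,
                    beta_hat_std=beta_std,
                    se_beta_std=se_std,
                )
            )

    selected = select_mediators(tests, alpha_level)
    total_cie = float(sum(t.effect for t in tests if t.selected))
    return MediationResult(
        tau=tau,
        gamma_hat=gamma_hat,
        tests=tuple(tests),
        selected_set=selected,
        total_cie=total_cie,
        screening=screening,
        penalized=penalized,
        refit=refit,
        standardization=record,
        alpha_level=alpha_level,
    )


def run_summary(result: MediationResult, dataset: MediationDataset) -> dict:
    """Run-level record mirroring the dimension funnel p -> d -> |S| -> |Omega|."""
    return {
        "tau": float(result.tau),
        "n": dataset.n,
        "p": dataset.p,
        "d": int(result.screening.d),
        "n_survived": int(result.survived_set.size),
        "n_selected": int(result.selected_set.size),
        "gamma_hat": result.gamma_hat,
        "total_cie": result.total_cie,
    }
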