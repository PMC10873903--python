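"""Monte-Carlo harness: repeated simulations and the evaluation metrics.

Per repetition the three-step pipeline runs on a fresh dataset; the effect
estimate for mediator k is ``alpha_hat_k * beta_hat_k,tau`` from the Step-3
refit when k survives Step 2 and exactly 0 otherwise.  Across repetitions
the harness reports, per mediator, the bias (mean estimate minus truth) and
the sampling standard error SSE (standard deviation of the estimates), and,
per run, the model size MS = mean |Omega_hat|, the true positive proportion
TPP = mean |Omega_hat intersect Omega_0| / |Omega_0| and the false
discovery proportion FDP = mean |Omega_hat \\ Omega_0| / |Omega_hat| (zero
for empty selections).  Monte-Carlo standard errors accompany each metric.

Repetition seeds derive deterministically from ``(base_seed, cell, rep)``
via ``numpy.random.SeedSequence``, so any single repetition can be re-run
in isolation and parallel execution cannot change the results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import run_mediation
from .synthetic_data import GroundTruth, SimulationConfig, generate, truth_at, with_seed

logger = logging.getLogger("quantmed")

__all__ = [
    "RepetitionResult",
    "SimulationMetrics",
    "repetition_seed",
    "run_repetition",
    "run_cell",
    "aggregate",
    "run_study",
    "single_mediator_scan",
]


@dataclass(frozen=True)
class RepetitionResult:
    """Sparse record of one repetition: estimates over S_tau and the sets."""

    estimates: np.ndarray      # length p; 0 outside S_tau
    selected: np.ndarray       # Omega_hat (absolute indices)
    survived: np.ndarray       # S_tau
    seed: int


@dataclass(frozen=True)
class SimulationMetrics:
    """Aggregated evaluation metrics with Monte-Carlo standard errors."""

    bias: np.ndarray
    sse: np.ndarray
    ms: float
    tpp: float
    fdp: float
    ms_se: float
    tpp_se: float
    fdp_se: float
    n_reps: int
    n_failed: int = 0


def repetition_seed(base_seed: int, cell: int, rep: int) -> int:
    """Stable per-repetition seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(cell), int(rep)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_repetition(config: SimulationConfig, tau: float, rep_seed: int, **pipeline_options) -> RepetitionResult:
    """One simulate-then-analyze repetition."""
    cfg = with_seed(config, rep_seed)
    dataset = generate(cfg)
    result = run_mediation(dataset, tau, **pipeline_options)
    estimates = np.zeros(cfg.p)
    for t in result.tests:
        estimates[t.index] = t.effect
    return RepetitionResult(
        estimates=estimates,
        selected=result.selected_set,
        survived=result.survived_set,
        seed=rep_seed,
    )


def aggregate(reps, truth: GroundTruth) -> SimulationMetrics:
    """Bias/SSE per mediator and MS/TPP/FDP selection summaries."""
    reps = list(reps)
    if not reps:
        raise ValueError("aggregate needs at least one successful repetition")
    est = np.stack([r.estimates for r in reps])
    n_reps = len(reps)
    active = set(truth.active_set.tolist())
    n_active = max(len(active), 1)
    ms_arr = np.array([r.selected.size for r in reps], dtype=float)
    tpp_arr = np.array(
        [len(active.intersection(r.selected.tolist())) / n_active for r in reps]
    )
    fdp_arr = np.array(
        [
            (len(set(r.selected.tolist()) - active) / r.selected.size) if r.selected.size else 0.0
            for r in reps
        ]
    )
    sd = lambda a: float(a.std(ddof=1)) if n_reps > 1 else 0.0
    return SimulationMetrics(
        bias=est.mean(axis=0) - truth.effects_at_tau,
        sse=est.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(est.shape[1]),
        ms=float(ms_arr.mean()),
        tpp=float(tpp_arr.mean()),
        fdp=float(fdp_arr.mean()),
        ms_se=sd(ms_arr) / np.sqrt(n_reps),
        tpp_se=sd(tpp_arr) / np.sqrt(n_reps),
        fdp_se=sd(fdp_arr) / np.sqrt(n_reps),
        n_reps=n_reps,
    )


def run_cell(
    config: SimulationConfig,
    tau: float,
    n_reps: int,
    base_seed: int,
    cell: int = 0,
    keep_reps: bool = False,
    **pipeline_options,
):
    """All repetitions of one (config, tau) cell; failures logged, skipped."""
    reps = []
    n_failed = 0
    for r in range(n_reps):
        seed = repetition_seed(base_seed, cell, r)
        try:
            reps.append(run_repetition(config, tau, seed, **pipeline_options))
        except Exception as exc:  # noqa: BLE001 - recorded, never silent
            n_failed += 1
            logger.warning("repetition %d (seed %d) failed: %s", r, seed, exc)
    metrics = aggregate(reps, truth_at(config, tau))
    metrics = SimulationMetrics(**{**metrics.__dict__, "n_failed": n_failed})
    return (metrics, reps) if keep_reps else metrics


def run_study(
    cells,
    n_reps: int,
    base_seed: int,
    *,
    n_report: int = 6,
    **pipeline_options,
) -> pd.DataFrame:
    """Run a grid of simulation cells and tabulate the metrics.

    ``cells`` is an iterable of ``(config, tau)``; the output has one row
    per cell with MS/TPP/FDP (plus Monte-Carlo SEs) and the bias/SSE of the
    first ``n_report`` mediation effects.
    """
    rows = []
    for c, (config, tau) in enumerate(cells):
        metrics = run_cell(config, tau, n_reps, base_seed, cell=c, **pipeline_options)
        row = {
            "cell": c,
            "case": config.case,
            "n": config.n,
            "p": config.p,
            "tau": tau,
            "reps": metrics.n_reps,
            "failed": metrics.n_failed,
            "MS": metrics.ms,
            "TPP": metrics.tpp,
            "FDP": metrics.fdp,
            "MS_mcse": metrics.ms_se,
            "TPP_mcse": metrics.tpp_se,
            "FDP_mcse": metrics.fdp_se,
        }
        for k in range(min(n_report, config.p)):
            row[f"bias_{k + 1}"] = metrics.bias[k]
            row[f"sse_{k + 1}"] = metrics.sse[k]
        rows.append(row)
    return pd.DataFrame(rows)


def single_mediator_scan(dataset, tau, variant: str = "ols", alpha_level: float = 0.05):
    """One-mediator-at-a-time comparator with Bonferroni correction.

    For each k the mediator model is fit on [1, X, Z] (``variant="ols"``
    least squares; ``variant="median"`` a median regression) and the
    outcome model is the marginal quantile regression on [1, X, M_k, Z].
    The joint-significance p-value max(P_alpha, P_beta) is Bonferroni
    multiplied by p and mediators below ``alpha_level`` are selected.
    Returns ``(effects, selected, p_adjusted)``.

    This is a reduced-fidelity stand-in for the published one-mediator
    methods, implementing their shared marginal structure rather than
    either method's full internals.
    """
    from scipy.special import ndtr

    from .data_model import standardize_mediators
    from .inference import _ols_alpha_batch
    from .quantile_core import fit_quantile
    from .screening import marginal_effects

    if variant not in ("ols", "median"):
        raise ValueError(f"unknown variant {variant!r}")
    p = dataset.p
    std_data, record = standardize_mediators(dataset)
    beta_std, se_std = marginal_effects(std_data, tau)
    beta_raw = beta_std / record.scale
    if variant == "ols":
        alpha_hat, se_alpha, p_alpha = _ols_alpha_batch(dataset, np.arange(p))
    else:
        n = dataset.n
        D = np.column_stack([np.ones(n), dataset.exposure, dataset.covariates])
        alpha_hat = np.empty(p)
        se_alpha = np.empty(p)
        for k in range(p):
            f = fit_quantile(D, dataset.mediators[:, k], 0.5, check_rank=False)
            alpha_hat[k] = f.coefficients[1]
            se_alpha[k] = f.standard_errors[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            p_alpha = 2.0 * (1.0 - ndtr(np.abs(alpha_hat) / se_alpha))
    with np.errstate(divide="ignore", invalid="ignore"):
        p_beta = 2.0 * (1.0 - ndtr(np.abs(beta_std) / se_std))
    p_js = np.maximum(p_alpha, p_beta)
    p_adj = np.minimum(p_js * p, 1.0)
    effects = alpha_hat * beta_raw
    selected = np.flatnonzero(p_adj < alpha_level)
    return effects, selected, p_adj
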