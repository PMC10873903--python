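"""Step 1 — marginal quantile screening of high-dimensional mediators.

Each candidate mediator enters its own small quantile model

    Q_tau(Y | X, M_k, Z) = c + gamma X + beta_k M_k + eta'Z,

and the ``d = 2*floor(n / log n)`` mediators with the largest marginal
|beta_k| (on the standardized mediator scale, so magnitudes are comparable)
are retained.  Marginal quantile screening of this form retains all truly
active mediators with probability tending to one while shrinking the
problem from p to d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import MediationDataset, QuantileLevel, standardize_mediators
from .quantile_core import fit_marginal_batch

__all__ = ["ScreeningResult", "screening_dimension", "marginal_effects", "screen"]


@dataclass(frozen=True)
class ScreeningResult:
    """Marginal coefficients and the retained index set I_tau."""

    tau: QuantileLevel
    marginal_coefficients: np.ndarray
    marginal_se: np.ndarray | None
    retained: np.ndarray  # sorted absolute mediator indices, |retained| = min(d, p)
    d: int


def screening_dimension(n: int) -> int:
    """Screening set size ``d = 2 * floor(n / ln n)``."""
    if n < 3:
        raise ValueError(f"screening dimension needs n >= 3; got {n}")
    return 2 * int(np.floor(n / np.log(n)))


def marginal_effects(
    dataset: MediationDataset,
    tau,
    *,
    compute_se: bool = True,
    **solver_options,
):
    """Marginal mediator coefficients beta_k from p single-mediator fits.

    The dataset's mediators are expected to be standardized already.
    Returns ``(coefficients, standard_errors)``; the k-th entries come from
    the quantile regression of the outcome on [1, X, M_k, Z].
    """
    n = dataset.n
    base = np.column_stack([np.ones(n), dataset.exposure, dataset.covariates])
    theta, ses = fit_marginal_batch(
        base,
        dataset.mediators,
        dataset.outcome,
        tau,
        compute_se=compute_se,
        **solver_options,
    )
    return theta[:, -1], (ses[:, -1] if ses is not None else None)


def screen(
    dataset: MediationDataset,
    tau,
    *,
    d: int | None = None,
    assume_standardized: bool = False,
    compute_se: bool = True,
    **solver_options,
) -> ScreeningResult:
    """Retain the min(d, p) mediators with the largest marginal |beta_k|.

    ``d`` defaults to ``2*floor(n/log n)``, additionally capped at ``p`` and
    at ``n - q - 3`` so that the subsequent joint fit over the retained
    mediators stays overdetermined.  Ties at the retention boundary are
    broken toward the lower column index, making the output deterministic.
    """
    tau = tau if isinstance(tau, QuantileLevel) else QuantileLevel(float(tau))
    if not assume_standardized:
        dataset, _ = standardize_mediators(dataset)
    d_formula = d if d is not None else screening_dimension(dataset.n)
    d_eff = max(1, min(d_formula, dataset.p, dataset.n - dataset.q - 3))
    beta, ses = marginal_effects(dataset, tau, compute_se=compute_se, **solver_options)
    # stable sort on (-|beta|, index): equal magnitudes keep ascending index
    order = np.argsort(-np.abs(beta), kind="stable")
    retained = np.sort(order[:d_eff])
    return ScreeningResult(
        tau=tau,
        marginal_coefficients=beta,
        marginal_se=ses,
        retained=retained,
        d=d_eff,
    )
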