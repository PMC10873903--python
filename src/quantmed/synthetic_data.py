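"""Simulation designs for evaluating high-dimensional quantile mediation.

Mediators follow linear models ``M_k = alpha_k X + zeta_k' Z + e_k`` with
jointly Gaussian errors under an AR-type covariance ``Sigma_ij =
rho^|i-j|`` (rho = 0.25, unit variances).  Two outcome designs are
generated:

* Case I  (additive error):        ``Y = gamma X + beta'M + eta'Z + eps``
* Case II (heteroscedastic error): ``Y = gamma X + beta'M + eta'Z +
  eps (theta X + phi'M)``

with ``eps ~ N(0, 1)``.  Under Case I every conditional quantile shares the
slopes ``beta``; under Case II the mediator-to-outcome slope at level tau
becomes ``beta_k + Q_tau(eps) phi_k``, so the active mediation pathways vary
across the outcome distribution.  The default coefficient vectors place
seven nonzero exposure->mediator paths and seven nonzero mediator->outcome
entries so that exactly five mediators (1-5) carry nonzero products, the
others exercising the two one-sided null configurations.

All randomness flows from the config seed; generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.signal import lfilter

from .data_model import MediationDataset

__all__ = ["SimulationConfig", "GroundTruth", "default_config", "generate", "truth_at"]

_ALPHA_HEAD = (0.85, 1.2, 1.0, 0.15, -0.25, 0.65, -0.50)
_BETA_HEAD = (0.85, 1.2, 1.0, 0.25, -0.15, 0.0, 0.0, 0.75, -0.5)
_PHI_HEAD = (0.1, 0.1, 0.1)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one simulated dataset."""

    n: int
    p: int
    case: str  # "I" or "II"
    alpha_true: np.ndarray
    beta_true: np.ndarray
    phi_true: np.ndarray
    gamma: float = 0.5
    theta: float = 0.1
    zeta: tuple = (0.3, 0.3)
    eta: tuple = (0.5, 0.5)
    rho: float = 0.25
    exposure_sd: float = 2.0
    covariate_sd: float = 2.0
    binary_exposure: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.case not in ("I", "II"):
            raise ValueError(f"case must be 'I' or 'II'; got {self.case!r}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1); got {self.rho}")
        for name in ("alpha_true", "beta_true", "phi_true"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (self.p,):
                raise ValueError(f"{name} must have length p={self.p}; got {v.shape}")


@dataclass(frozen=True)
class GroundTruth:
    """Quantile-specific true mediation effects and the active set."""

    tau: float
    effects_at_tau: np.ndarray  # alpha_k * beta_k,tau
    active_set: np.ndarray      # indices with nonzero product


def default_config(n: int, p: int = 3000, case: str = "I", seed: int = 0, **overrides) -> SimulationConfig:
    """Default study conditions: the stated truth vectors padded with zeros.

    alpha = (0.85, 1.2, 1, 0.15, -0.25, 0.65, -0.50, 0, ...),
    beta  = (0.85, 1.2, 1, 0.25, -0.15, 0, 0, 0.75, -0.5, 0, ...),
    phi   = (0.1, 0.1, 0.1, 0, ...); gamma=0.5, theta=0.1,
    zeta_k=(0.3, 0.3), eta=(0.5, 0.5); X, Z1, Z2 ~ N(0, 4) (variance 4).
    """
    if n < 50:
        raise ValueError(f"n must be >= 50; got {n}")
    if p < 9:
        raise ValueError(f"p must be >= 9 to hold the truth vectors; got {p}")
    alpha = np.zeros(p)
    alpha[: len(_ALPHA_HEAD)] = _ALPHA_HEAD
    beta = np.zeros(p)
    beta[: len(_BETA_HEAD)] = _BETA_HEAD
    phi = np.zeros(p)
    phi[: len(_PHI_HEAD)] = _PHI_HEAD
    return SimulationConfig(
        n=n, p=p, case=case, alpha_true=alpha, beta_true=beta, phi_true=phi,
        seed=seed, **overrides,
    )


def generate(config: SimulationConfig) -> MediationDataset:
    """Draw one dataset under the configured design.

    Draw order (fixed for reproducibility): exposure, covariates, mediator
    errors, outcome error.  Mediator errors use a stationary AR(1)
    recursion with coefficient ``rho`` and innovation sd ``sqrt(1-rho^2)``,
    which has exactly the target covariance ``rho^|i-j|`` with unit
    marginal variances.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n, config.p
    if config.binary_exposure:
        x = rng.binomial(1, 0.5, size=n).astype(float)
    else:
        x = rng.normal(0.0, config.exposure_sd, size=n)
    z = rng.normal(0.0, config.covariate_sd, size=(n, 2))
    innov = rng.standard_normal((n, p))
    innov[:, 1:] *= np.sqrt(1.0 - config.rho**2)
    e = lfilter([1.0], [1.0, -config.rho], innov, axis=1)
    eps = rng.standard_normal(n)

    zeta = np.asarray(config.zeta, dtype=float)
    m = np.outer(x, config.alpha_true) + (z @ zeta)[:, None] + e
    eta = np.asarray(config.eta, dtype=float)
    y = config.gamma * x + m @ config.beta_true + z @ eta
    if config.case == "I":
        y = y + eps
    else:
        y = y + eps * (config.theta * x + m @ config.phi_true)

    names = tuple(f"M{k + 1}" for k in range(p))
    return MediationDataset(
        exposure=x, mediators=m, covariates=z, outcome=y,
        mediator_names=names, covariate_names=("Z1", "Z2"),
    )


def truth_at(config: SimulationConfig, tau: float) -> GroundTruth:
    """True quantile-level mediation effects ``alpha_k * beta_k,tau``.

    Case I: ``beta_k,tau = beta_k`` for every tau.  Case II: the
    conditional-quantile slope is ``beta_k + Q_tau(eps) phi_k`` with
    ``Q_tau`` the standard normal quantile.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must lie in (0, 1); got {tau}")
    beta_tau = config.beta_true.copy()
    if config.case == "II":
        beta_tau = beta_tau + stats.norm.ppf(tau) * config.phi_true
    effects = config.alpha_true * beta_tau
    return GroundTruth(
        tau=float(tau),
        effects_at_tau=effects,
        active_set=np.flatnonzero(effects != 0.0),
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Same design, different random draw."""
    return replace(config, seed=int(seed))
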