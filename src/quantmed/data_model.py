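"""Core containers and validation shared by all pipeline stages.

The data model mirrors the structural quantile mediation setup: an exposure
``X``, a (possibly very wide) mediator matrix ``M`` with ``p`` columns, an
optional covariate matrix ``Z`` with ``q`` columns, and an outcome ``Y``,
all observed on the same ``n`` subjects.  Mediators are standardized before
screening so that marginal regression coefficients are rank-comparable;
the :class:`StandardizationRecord` retains the affine transform so that
coefficients can be mapped back to the raw mediator scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("quantmed")

__all__ = [
    "MediationDataset",
    "StandardizationRecord",
    "QuantileLevel",
    "ValidationError",
    "validate_dataset",
    "standardize_mediators",
]


class ValidationError(ValueError):
    """Raised when an input table or dataset violates the data contract."""


@dataclass(frozen=True)
class QuantileLevel:
    """A quantile level tau constrained to the open interval (0, 1)."""

    tau: float

    def __post_init__(self) -> None:
        if not (0.0 < float(self.tau) < 1.0):
            raise ValidationError(f"tau must lie in (0, 1); got {self.tau}")

    def __float__(self) -> float:
        return float(self.tau)


@dataclass(frozen=True)
class StandardizationRecord:
    """Per-mediator centering/scaling used to standardize the mediator matrix.

    ``center``/``scale`` are aligned with the mediator columns.  A coefficient
    ``b`` estimated on the standardized scale corresponds to ``b / scale`` on
    the raw scale (the intercept absorbs the centering shift).
    """

    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.scale)) or np.any(self.scale <= 0):
            raise ValidationError("standardization scales must be finite and > 0")

    def transform(self, mediators: np.ndarray) -> np.ndarray:
        return (mediators - self.center) / self.scale

    def inverse_transform(self, mediators_std: np.ndarray) -> np.ndarray:
        return mediators_std * self.scale + self.center

    def coef_to_raw(self, coef_std: np.ndarray | float, index=None):
        """Map mediator-slope coefficients from standardized to raw scale."""
        scale = self.scale if index is None else self.scale[index]
        return np.asarray(coef_std) / scale


@dataclass(frozen=True)
class MediationDataset:
    """Validated exposure / mediators / covariates / outcome container.

    Invariants: all arrays share the row count ``n >= 1``, contain no missing
    values, ``p >= 1``, ``q >= 0``, and mediator names are unique.
    """

    exposure: np.ndarray
    mediators: np.ndarray
    covariates: np.ndarray
    outcome: np.ndarray
    mediator_names: tuple = ()
    covariate_names: tuple = ()
    n_dropped: int = 0

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.exposure, dtype=float))
        y = np.atleast_1d(np.asarray(self.outcome, dtype=float))
        m = np.asarray(self.mediators, dtype=float)
        if m.ndim == 1:
            m = m[:, None]
        z = np.asarray(self.covariates, dtype=float)
        if z.size == 0:
            z = np.empty((x.shape[0], 0))
        elif z.ndim == 1:
            z = z[:, None]
        object.__setattr__(self, "exposure", x)
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "mediators", m)
        object.__setattr__(self, "covariates", z)

        n = x.shape[0]
        if n < 1:
            raise ValidationError("dataset has zero usable rows")
        if not (y.shape[0] == m.shape[0] == z.shape[0] == n):
            raise ValidationError(
                f"row mismatch: exposure {n}, outcome {y.shape[0]}, "
                f"mediators {m.shape[0]}, covariates {z.shape[0]}"
            )
        if m.shape[1] < 1:
            raise ValidationError("at least one mediator column is required")
        for name, arr in (("exposure", x), ("outcome", y), ("mediators", m), ("covariates", z)):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite values in {name} after validation")

        med_names = tuple(self.mediator_names) or tuple(f"M{k + 1}" for k in range(m.shape[1]))
        cov_names = tuple(self.covariate_names) or tuple(f"Z{j + 1}" for j in range(z.shape[1]))
        if len(med_names) != m.shape[1]:
            raise ValidationError("mediator_names length does not match mediator count")
        if len(cov_names) != z.shape[1]:
            raise ValidationError("covariate_names length does not match covariate count")
        if len(set(med_names)) != len(med_names):
            raise ValidationError("mediator names must be unique")
        object.__setattr__(self, "mediator_names", med_names)
        object.__setattr__(self, "covariate_names", cov_names)

    @property
    def n(self) -> int:
        return self.exposure.shape[0]

    @property
    def p(self) -> int:
        return self.mediators.shape[1]

    @property
    def q(self) -> int:
        return self.covariates.shape[1]

    def with_mediators(self, mediators: np.ndarray, names=None) -> "MediationDataset":
        return replace(
            self,
            mediators=mediators,
            mediator_names=tuple(names) if names is not None else self.mediator_names,
        )


def validate_dataset(
    table: pd.DataFrame,
    exposure: str,
    outcome: str,
    mediators,
    covariates=(),
) -> MediationDataset:
    """Build a :class:`MediationDataset` from a tabular frame and column roles.

    Exactly one exposure and one outcome column must be named; mediator and
    covariate sets must be disjoint from each other and from the scalar roles.
    Rows with any missing value among the used columns are dropped (listwise
    deletion) and the drop count is logged and recorded on the dataset.
    """
    mediators = list(mediators)
    covariates = list(covariates)
    roles: list[str] = [exposure, outcome, *mediators, *covariates]
    if len(set(roles)) != len(roles):
        seen: set[str] = set()
        dups = sorted({c for c in roles if c in seen or seen.add(c)})
        raise ValidationError(f"column roles overlap: {dups}")
    missing = [c for c in roles if c not in table.columns]
    if missing:
        raise ValidationError(f"columns not found in table: {missing}")
    if not mediators:
        raise ValidationError("at least one mediator column is required")

    sub = table.loc[:, roles]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & sub.notna()
    if bad.to_numpy().any():
        col = bad.any(axis=0)
        raise ValidationError(
            f"non-numeric cells in columns: {list(col.index[col])}"
        )
    keep = ~numeric.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("validate_dataset: dropped %d row(s) with missing values", n_dropped)
    numeric = numeric.loc[keep]
    if numeric.shape[0] == 0:
        raise ValidationError("zero usable rows after dropping missing values")

    return MediationDataset(
        exposure=numeric[exposure].to_numpy(float),
        mediators=numeric[mediators].to_numpy(float),
        covariates=numeric[covariates].to_numpy(float) if covariates else np.empty((numeric.shape[0], 0)),
        outcome=numeric[outcome].to_numpy(float),
        mediator_names=tuple(mediators),
        covariate_names=tuple(covariates),
        n_dropped=n_dropped,
    )


def standardize_mediators(dataset: MediationDataset):
    """Center and scale each mediator column to mean 0, sample sd 1 (ddof=1).

    Returns the transformed dataset and a :class:`StandardizationRecord`.
    Exposure, covariates and outcome are left on their raw scales: the
    standardization exists only to make mediator coefficients comparable for
    screening and penalization, and the direct-effect coefficient stays
    interpretable per raw exposure unit.
    """
    m = dataset.mediators
    center = m.mean(axis=0)
    ddof = 1 if dataset.n > 1 else 0
    scale = m.std(axis=0, ddof=ddof)
    zero = ~(scale > 0) | ~np.isfinite(scale)
    if np.any(zero):
        names = [dataset.mediator_names[k] for k in np.flatnonzero(zero)]
        raise ValidationError(f"zero-variance mediator column(s): {names}")
    record = StandardizationRecord(center=center, scale=scale)
    return dataset.with_mediators((m - center) / scale), record
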