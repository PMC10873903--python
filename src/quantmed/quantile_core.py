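"""Unpenalized quantile regression: check-loss fitting and standard errors.

The solver minimizes a convolution-smoothed check loss (Gaussian kernel),
which is twice differentiable and amenable to damped Newton iterations.
Starting from the bandwidth ``h0 = max(0.05, ((k + log n)/n)^(2/5))`` scaled
by a robust residual spread, the bandwidth is annealed geometrically towards
zero, so the returned coefficients coincide with the exact check-loss
minimizer (the linear-programming solution) to high accuracy while retaining
the speed and determinism of a smooth solver.  Scaling every bandwidth by the
residual spread of an affine-equivariant pilot fit (OLS) makes the whole
procedure equivariant: ``fit(a*y + X@d)`` returns ``a*coef + d``.

Standard errors use the kernel (Powell) sandwich estimator with a
Hall–Sheather-type bandwidth for the density factor; a pair bootstrap is
available as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .data_model import QuantileLevel

__all__ = [
    "QuantileFit",
    "FitError",
    "check_loss",
    "default_bandwidth",
    "fit_quantile",
    "quantile_covariance",
    "bootstrap_se",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


class FitError(RuntimeError):
    """Raised on rank deficiency, non-convergence, or degenerate bandwidths."""


@dataclass(frozen=True)
class QuantileFit:
    """Result of one quantile regression.

    ``objective`` is the mean check loss at the returned coefficients (the
    quantity the solver minimizes in its exact, unsmoothed form).
    """

    tau: QuantileLevel
    coefficients: np.ndarray
    standard_errors: np.ndarray | None
    objective: float
    n_obs: int
    n_iter: int = 0
    bandwidth: float = 0.0


def check_loss(residual, tau):
    """Check (pinball) loss ``rho_tau(v) = v * (tau - 1{v < 0})``, vectorized."""
    v = np.asarray(residual, dtype=float)
    tau = float(tau)
    return v * (tau - (v < 0.0))


def default_bandwidth(n: int, n_coef: int) -> float:
    """Smoothing bandwidth ``max(0.05, ((k + log n)/n)^(2/5))`` (unit scale)."""
    return max(0.05, ((n_coef + np.log(n)) / n) ** 0.4)


def _phi(u):
    return np.exp(-0.5 * u * u) / _SQRT2PI


def _smooth_loss(r, tau, h):
    # Gaussian-smoothed check loss: rho_tau convolved with N(0, h^2).
    u = r / h
    return h * _phi(u) + r * (ndtr(u) - 1.0 + tau)


def _smooth_grad(r, tau, h):
    # d/dr of the smoothed loss: Phi(r/h) - (1 - tau).
    return ndtr(r / h) - 1.0 + tau


def _robust_scale(r: np.ndarray) -> float:
    """MAD-based spread with std fallback; 0.0 only for exactly constant r."""
    r = np.asarray(r, dtype=float)
    mad = np.median(np.abs(r - np.median(r)))
    s = mad / 0.6744897501960817
    if s <= 0:
        s = float(np.std(r))
    return float(s)


def _pilot_scale(design: np.ndarray, y: np.ndarray) -> float:
    """Residual spread of an OLS pilot fit (affine-equivariant)."""
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return _robust_scale(y - design @ coef)


def fit_quantile(
    design: np.ndarray,
    response: np.ndarray,
    tau,
    *,
    bandwidth: float | None = None,
    min_bandwidth: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    se: str | None = "sandwich",
    check_rank: bool = True,
) -> QuantileFit:
    """Fit a linear model for the conditional ``tau``-quantile of ``response``.

    Parameters
    ----------
    design
        ``n x k`` design matrix; the caller supplies the intercept column.
    bandwidth, min_bandwidth
        Initial and terminal smoothing bandwidths on the *standardized*
        residual scale; defaults are the ``((k + log n)/n)^(2/5)`` rule and
        ``1e-7`` respectively.  Both are multiplied internally by a robust
        residual spread, making the fit affine-equivariant.
    se
        ``"sandwich"`` (default), ``None`` to skip standard errors.
    """
    tau = tau if isinstance(tau, QuantileLevel) else QuantileLevel(float(tau))
    t = float(tau)
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    n, k = X.shape
    if n <= k:
        raise FitError(f"need n > #coefficients; got n={n}, k={k}")
    if check_rank and np.linalg.matrix_rank(X) < k:
        raise FitError("design matrix is rank deficient")

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    scale = _robust_scale(y - X @ coef)
    yspread = max(1.0, float(np.median(np.abs(y))))
    if scale <= 0:
        scale = 1e-8 * yspread
    h0 = (bandwidth if bandwidth is not None else default_bandwidth(n, k)) * scale
    h_min = (min_bandwidth if min_bandwidth is not None else 1e-7) * scale
    floor = 1e-10 * yspread
    h0 = max(h0, floor)
    h_min = min(max(h_min, floor), h0)

    # Continuation: solve loosely at each intermediate bandwidth (the iterate
    # only warm-starts the next stage), tightly at the terminal one.  Newton
    # on the nearly kinked loss stalls below ~1e-2 of the residual spread, so
    # higher accuracy is reached by an IRLS majorize-minimize polish followed
    # by a vertex polish (the exact optimum interpolates k observations).
    total_iter = 0
    h = h0
    h_newton = max(h_min, 1e-2 * scale)
    will_polish = h_min < h_newton * (1 - 1e-12)
    while h > h_newton * (1 + 1e-12):
        stage_tol = max(tol, 0.1 * h / scale)
        coef, it = _newton(X, y, t, h, coef, min(50, max_iter), stage_tol)
        total_iter += it
        h = max(h / 8.0, h_newton)
    budget = max(max_iter - total_iter, 50)
    coef, it = _newton(X, y, t, h, coef, budget, tol)
    total_iter += it
    if it >= budget and not will_polish:
        raise FitError(f"quantile fit did not converge within {max_iter} iterations")
    if will_polish:
        coef, it = _irls_polish(X, y, t, coef, eps0=1e-2 * scale, eps_min=max(h_min, 1e-9 * scale))
        total_iter += it
        polished = _vertex_polish(X, y, t, coef)
        if polished is not None:
            coef = polished

    resid = y - X @ coef
    objective = float(np.mean(check_loss(resid, t)))
    ses = None
    if se == "sandwich":
        ses = quantile_covariance(coef, X, y, t)
    elif se in ("kernel", "nid"):
        ses = quantile_covariance(coef, X, y, t, method=se)
    return QuantileFit(
        tau=tau,
        coefficients=coef,
        standard_errors=ses,
        objective=objective,
        n_obs=n,
        n_iter=total_iter,
        bandwidth=h,
    )


def _newton(X, y, tau, h, coef, max_iter, tol):
    """Damped (step-halved) Newton on the smoothed loss at fixed bandwidth."""
    n, k = X.shape
    r = y - X @ coef
    obj = float(np.mean(_smooth_loss(r, tau, h)))
    for it in range(1, max(max_iter, 1) + 1):
        g = -X.T @ _smooth_grad(r, tau, h) / n
        w = _phi(r / h) / h
        H = (X.T * w) @ X / n
        ridge = 1e-10 * (np.trace(H) / k + 1.0)
        step = np.linalg.solve(H + ridge * np.eye(k), -g)
        new = coef + step
        r_new = y - X @ new
        obj_new = float(np.mean(_smooth_loss(r_new, tau, h)))
        halvings = 0
        while obj_new > obj + 1e-14 and halvings < 30:
            step *= 0.5
            new = coef + step
            r_new = y - X @ new
            obj_new = float(np.mean(_smooth_loss(r_new, tau, h)))
            halvings += 1
        delta = float(np.max(np.abs(step)))
        coef, r, obj = new, r_new, obj_new
        if delta < tol * max(1.0, float(np.max(np.abs(coef)))):
            return coef, it
    return coef, max(max_iter, 1)


def _irls_polish(X, y, tau, coef, *, eps0, eps_min, iters_per_stage=8):
    """Iteratively reweighted least squares on the eps-perturbed check loss.

    The check loss ``c_i |r_i|`` (``c_i = tau`` or ``1 - tau`` by residual
    sign) is majorized by ``c_i r_i^2 / (2 max(|r_i|, eps))``; annealing
    ``eps`` drives the iterate to the exact minimizer.  Returns the iterate
    with the lowest exact check loss seen.
    """
    n, k = X.shape
    best = coef
    best_obj = float(np.mean(check_loss(y - X @ coef, tau)))
    eps = eps0
    it = 0
    while True:
        for _ in range(iters_per_stage):
            it += 1
            r = y - X @ coef
            c = np.where(r >= 0, tau, 1.0 - tau)
            w = c / np.maximum(np.abs(r), eps)
            A = (X.T * w) @ X
            ridge = 1e-12 * (np.trace(A) / k + 1.0)
            try:
                coef = np.linalg.solve(A + ridge * np.eye(k), (X.T * w) @ y)
            except np.linalg.LinAlgError:
                return best, it
            obj = float(np.mean(check_loss(y - X @ coef, tau)))
            if obj < best_obj:
                best, best_obj = coef, obj
        if eps <= eps_min * (1 + 1e-12):
            return best, it
        eps = max(eps / 10.0, eps_min)


def _vertex_polish(X, y, tau, coef, max_steps: int = 400):
    """Exact finisher: simplex-type descent over interpolating vertices.

    The check-loss optimum interpolates k observations.  Starting from the
    vertex spanned by the k smallest-|residual| rows of the warm iterate,
    each step examines the 2k edge directions (relaxing one interpolated row
    up or down), and follows a descending edge to the next residual-crossing
    breakpoint chosen by the weighted-median rule.  Finite and exact up to
    floating point; returns None if no well-conditioned starting vertex is
    found near the iterate.
    """
    n, k = X.shape
    r = y - X @ coef
    order = np.argsort(np.abs(r))
    active = None
    for start in range(min(6, n - k + 1)):
        idx = np.sort(order[start : start + k])
        Xa = X[idx]
        if np.linalg.matrix_rank(Xa) == k:
            active = idx.copy()
            break
    if active is None:
        return None
    theta = np.linalg.solve(X[active], y[active])
    obj = float(np.sum(check_loss(y - X @ theta, tau)))
    obj_warm = float(np.sum(check_loss(r, tau)))

    for _ in range(max_steps):
        Xa = X[active]
        try:
            V = X @ np.linalg.inv(Xa)  # column j: x_i' d_j with X_A d_j = e_j
        except np.linalg.LinAlgError:
            break
        r = y - X @ theta
        r[active] = 0.0
        psi = np.where(r > 0, tau, tau - 1.0)  # d rho/d r off the kink
        # Unnormalized directional derivative of sum-check-loss along +/- d_j:
        #   D(j, s) = -s * sum_{i not in A} psi_i v_ij + rho'(0; -s), v_ij = x_i' d_j.
        base = -(psi @ V) + psi[active] * V[active, np.arange(k)]
        best_dir, best_D = None, -1e-10 * (1.0 + abs(obj))
        for j in range(k):
            for s in (1.0, -1.0):
                Dj = s * base[j] + (tau * (-s) if -s > 0 else (tau - 1.0) * (-s))
                if Dj < best_D:
                    best_D, best_dir = Dj, (j, s)
        if best_dir is None:
            break
        j, s = best_dir
        v = s * V[:, j]
        with np.errstate(divide="ignore", invalid="ignore"):
            tcross = r / v
        tcross[active] = np.nan
        mask = np.isfinite(tcross) & (tcross > 1e-13)
        if not mask.any():
            break
        idxs = np.flatnonzero(mask)
        order_t = np.argsort(tcross[idxs])
        slope = best_D
        enter = idxs[order_t[-1]]
        for ii in order_t:  # weighted-median stopping rule along the edge
            slope += abs(v[idxs[ii]])
            if slope >= -1e-12:
                enter = idxs[ii]
                break
        new_active = np.sort(np.append(np.delete(active, j), enter))
        try:
            theta_new = np.linalg.solve(X[new_active], y[new_active])
        except np.linalg.LinAlgError:
            break
        obj_new = float(np.sum(check_loss(y - X @ theta_new, tau)))
        if obj_new >= obj - 1e-14 * (1.0 + abs(obj)):
            break
        active, theta, obj = new_active, theta_new, obj_new
    if obj > obj_warm + 1e-12 * (1.0 + abs(obj_warm)):
        return None  # descent never reached the warm iterate's level
    return theta


def _hall_sheather(n: int, tau: float, alpha: float = 0.05) -> float:
    """Hall–Sheather bandwidth on the probability scale."""
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    q = stats.norm.ppf(tau)
    num = 1.5 * stats.norm.pdf(q) ** 2
    den = 2.0 * q**2 + 1.0
    return float(n ** (-1.0 / 3.0) * z ** (2.0 / 3.0) * (num / den) ** (1.0 / 3.0))


def quantile_covariance(coef, design, response, tau, method: str = "kernel") -> np.ndarray:
    """Sandwich standard errors for a quantile fit.

    ``method="kernel"`` (default): Powell's Gaussian-kernel Hessian with
    the Hall–Sheather-rate bandwidth ``spread * (qnorm(tau+hs) -
    qnorm(tau-hs))``.  ``method="nid"``: per-observation densities from
    the Hall–Sheather difference quotient ``2 hs / x_i'(b(tau+hs) -
    b(tau-hs))``, requiring two auxiliary fits.  The meat is
    ``tau (1 - tau) X'X / n`` in both cases.  Scale-equivariant:
    multiplying the response by ``c`` multiplies the standard errors by
    ``c``.
    """
    t = float(tau)
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y)) and np.all(np.isfinite(coef))):
        raise FitError("non-finite inputs to quantile_covariance")
    n, k = X.shape
    r = y - X @ np.asarray(coef, dtype=float)

    hs = _hall_sheather(n, t)
    if method == "nid":
        lo = max(t - hs, 1e-3)
        hi = min(t + hs, 1.0 - 1e-3)
        if not lo < hi:
            raise FitError(f"degenerate Hall-Sheather band [{lo}, {hi}]")
        b_hi = fit_quantile(X, y, hi, se=None, check_rank=False).coefficients
        b_lo = fit_quantile(X, y, lo, se=None, check_rank=False).coefficients
        dyhat = X @ (b_hi - b_lo)
        eps = np.finfo(float).eps ** (2 / 3) * (1.0 + float(np.median(np.abs(y))))
        f = np.maximum(0.0, (hi - lo) / (dyhat + eps))
        H = (X.T * f) @ X / n
    elif method == "kernel":
        lo = max(t - hs, 1e-3)
        hi = min(t + hs, 1.0 - 1e-3)
        spread = _robust_scale(r)
        if spread <= 0:
            spread = max(float(np.std(r)), 1e-12)
        b = spread * (stats.norm.ppf(hi) - stats.norm.ppf(lo))
        if not np.isfinite(b) or b <= 0:
            raise FitError(f"degenerate density bandwidth {b!r}")
        w = _phi(r / b) / b
        H = (X.T * w) @ X / n
    else:
        raise ValueError(f"unknown SE method {method!r}")
    J = t * (1.0 - t) * (X.T @ X) / n
    Hinv = np.linalg.inv(H + 1e-12 * np.eye(k) * (np.trace(H) / k + 1.0))
    cov = Hinv @ J @ Hinv / n
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def bootstrap_se(
    design, response, tau, *, n_boot: int = 500, seed: int = 0, **fit_kwargs
) -> np.ndarray:
    """Pair-bootstrap standard errors (fallback to the sandwich estimator)."""
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    fit_kwargs.setdefault("se", None)
    fit_kwargs.setdefault("check_rank", False)
    coefs = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        coefs[b] = fit_quantile(X[idx], y[idx], tau, **fit_kwargs).coefficients
    return coefs.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# Batched marginal fits: one shared base design, one varying column.
# Used by the screening stage, where p single-mediator models
#   Q_tau(Y | X, M_k, Z) = c + gamma X + beta_k M_k + eta'Z
# share the columns [1, X, Z] and differ only in M_k.  The solver is the
# same annealed Newton as fit_quantile, vectorized across the p problems.
# ---------------------------------------------------------------------------


def fit_marginal_batch(
    base: np.ndarray,
    columns: np.ndarray,
    response: np.ndarray,
    tau,
    *,
    bandwidth: float | None = None,
    min_bandwidth: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    compute_se: bool = True,
):
    """Fit ``p`` quantile regressions ``y ~ [base | columns[:, k]]`` at once.

    Returns ``(coefs, ses)`` with shapes ``(p, kb+1)``; the varying column's
    coefficient is the last entry of each row.  ``ses`` is None when
    ``compute_se`` is False.  Matches :func:`fit_quantile` applied column by
    column given the same bandwidth schedule and tolerances.  Unlike single
    fits, the default here performs *no* bandwidth annealing: the marginal
    models feed a magnitude ranking, for which the plain smoothed fit at the
    ``((k + log n)/n)^(2/5)`` bandwidth is the intended estimator, and
    annealing ``p`` fits to near-exactness would dominate the run time.
    Pass ``min_bandwidth`` explicitly to anneal.
    """
    t = float(tau if not isinstance(tau, QuantileLevel) else tau.tau)
    B = np.asarray(base, dtype=float)
    M = np.asarray(columns, dtype=float)
    y = np.asarray(response, dtype=float)
    n, kb = B.shape
    p = M.shape[1]
    k = kb + 1
    if n <= k:
        raise FitError(f"need n > #coefficients; got n={n}, k={k}")

    # Batched OLS pilot: assemble p normal-equation systems of size k.
    G_bb = B.T @ B                     # (kb, kb)
    G_bm = B.T @ M                     # (kb, p)
    G_mm = np.einsum("np,np->p", M, M)  # (p,)
    b_by = B.T @ y                     # (kb,)
    b_my = M.T @ y                     # (p,)
    A = np.empty((p, k, k))
    A[:, :kb, :kb] = G_bb
    A[:, :kb, kb] = G_bm.T
    A[:, kb, :kb] = G_bm.T
    A[:, kb, kb] = G_mm
    rhs = np.empty((p, k))
    rhs[:, :kb] = b_by
    rhs[:, kb] = b_my
    ridge0 = 1e-10 * (np.trace(G_bb) / kb + 1.0)
    theta = np.linalg.solve(A + ridge0 * np.eye(k), rhs[..., None])[..., 0]  # (p, k)

    def residuals(th):
        return y[:, None] - B @ th[:, :kb].T - M * th[:, kb]

    R = residuals(theta)
    med = np.median(R, axis=0)
    scale = np.median(np.abs(R - med), axis=0) / 0.6744897501960817
    fallback = R.std(axis=0)
    scale = np.where(scale > 0, scale, fallback)
    yspread = max(1.0, float(np.median(np.abs(y))))
    scale = np.maximum(scale, 1e-8 * yspread)

    h0u = bandwidth if bandwidth is not None else default_bandwidth(n, k)
    hmu = min_bandwidth if min_bandwidth is not None else h0u
    floor = 1e-10 * yspread
    h0 = np.maximum(h0u * scale, floor)
    h_min = np.minimum(np.maximum(hmu * scale, floor), h0)

    # Precompute the kb*(kb+1)/2 base outer-product columns for the Hessian.
    iu, ju = np.triu_indices(kb)
    P = B[:, iu] * B[:, ju]  # (n, n_pairs)

    def smooth_obj(R, h):
        U = R / h
        return (h * _phi(U) + R * (ndtr(U) - 1.0 + t)).mean(axis=0)

    def newton_stage(active, h, stage_tol, iter_budget):
        """Damped Newton at fixed per-column bandwidths on the active subset.

        Columns are dropped from the working set as they converge, so late
        iterations only touch the few stragglers.
        """
        nonlocal total_iter
        idx = active.copy()
        while idx.size and total_iter < iter_budget:
            total_iter += 1
            Ma = M[:, idx]
            tha = theta[idx]
            ha = h[idx]
            Ra = y[:, None] - B @ tha[:, :kb].T - Ma * tha[:, kb]
            Ua = Ra / ha
            Ga = ndtr(Ua) - 1.0 + t
            Wa = _phi(Ua) / ha
            obj_a = (ha * _phi(Ua) + Ra * Ga).mean(axis=0)
            grad = np.empty((idx.size, k))
            grad[:, :kb] = -(B.T @ Ga).T / n
            grad[:, kb] = -np.einsum("np,np->p", Ma, Ga) / n
            Hbb_flat = (P.T @ Wa).T / n
            T = Wa * Ma
            Hbm = (B.T @ T).T / n
            Hmm = np.einsum("np,np->p", T, Ma) / n
            Hmat = np.empty((idx.size, k, k))
            Hmat[:, iu, ju] = Hbb_flat
            Hmat[:, ju, iu] = Hbb_flat
            Hmat[:, :kb, kb] = Hbm
            Hmat[:, kb, :kb] = Hbm
            Hmat[:, kb, kb] = Hmm
            tr = np.einsum("pii->p", Hmat)
            Hmat[:, np.arange(k), np.arange(k)] += (1e-10 * (tr / k + 1.0))[:, None]
            step = np.linalg.solve(Hmat, -grad[..., None])[..., 0]
            new = tha + step
            Rn = y[:, None] - B @ new[:, :kb].T - M[:, idx] * new[:, kb]
            obj_new = smooth_obj_cols(Rn, ha)
            for _ in range(30):
                worse = obj_new > obj_a + 1e-14
                if not worse.any():
                    break
                step[worse] *= 0.5
                new = tha + step
                Rn = y[:, None] - B @ new[:, :kb].T - M[:, idx] * new[:, kb]
                obj_new = smooth_obj_cols(Rn, ha)
            theta[idx] = new
            delta = np.max(np.abs(step), axis=1)
            done = delta < stage_tol * np.maximum(1.0, np.max(np.abs(new), axis=1))
            idx = idx[~done]
        return idx

    def smooth_obj_cols(R, h):
        U = R / h
        return (h * _phi(U) + R * (ndtr(U) - 1.0 + t)).mean(axis=0)

    total_iter = 0
    h = h0.copy()
    all_cols = np.arange(p)
    # Continuation: a loose solve at each intermediate bandwidth warm-starts
    # the next; only the terminal bandwidth is solved to full tolerance.
    while np.any(h > h_min * (1 + 1e-12)):
        stage_tol = np.median(h / scale) * 0.1
        newton_stage(all_cols, h, max(stage_tol, tol), max_iter)
        if total_iter >= max_iter:
            raise FitError(f"batched marginal fits not converged in {max_iter} iterations")
        h = np.maximum(h / 8.0, h_min)
    left = newton_stage(all_cols, h, tol, max_iter)
    if left.size:
        raise FitError(
            f"batched marginal fits: {left.size} column(s) not converged "
            f"in {max_iter} iterations"
        )
    R = residuals(theta)

    ses = None
    if compute_se:
        # Powell kernel sandwich, Hall-Sheather-rate bandwidth (matches the
        # default quantile_covariance method)
        hs = _hall_sheather(n, t)
        lo = max(t - hs, 1e-3)
        hi = min(t + hs, 1.0 - 1e-3)
        med = np.median(R, axis=0)
        spread = np.median(np.abs(R - med), axis=0) / 0.6744897501960817
        spread = np.where(spread > 0, spread, np.maximum(R.std(axis=0), 1e-12))
        b = spread * (stats.norm.ppf(hi) - stats.norm.ppf(lo))
        W = _phi(R / b) / b
        Hbb_flat = (P.T @ W).T / n
        T = W * M
        Hbm = (B.T @ T).T / n
        Hmm = np.einsum("np,np->p", T, M) / n
        Hmat = np.empty((p, k, k))
        Hmat[:, iu, ju] = Hbb_flat
        Hmat[:, ju, iu] = Hbb_flat
        Hmat[:, :kb, kb] = Hbm
        Hmat[:, kb, :kb] = Hbm
        Hmat[:, kb, kb] = Hmm
        tr = np.einsum("pii->p", Hmat)
        Hmat[:, np.arange(k), np.arange(k)] += (1e-12 * (tr / k + 1.0))[:, None]
        Jmat = np.empty((p, k, k))
        Jbb = t * (1.0 - t) * (B.T @ B) / n
        Jmat[:, :kb, :kb] = Jbb
        Jbm = t * (1.0 - t) * (B.T @ M).T / n
        Jmat[:, :kb, kb] = Jbm
        Jmat[:, kb, :kb] = Jbm
        Jmat[:, kb, kb] = t * (1.0 - t) * G_mm / n
        Hinv = np.linalg.inv(Hmat)
        cov = Hinv @ Jmat @ np.transpose(Hinv, (0, 2, 1)) / n
        diag = np.einsum("pii->pi", cov)
        ses = np.sqrt(np.clip(diag, 0.0, None))
    return theta, ses
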