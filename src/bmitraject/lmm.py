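"""Linear mixed models with random intercept+slope and spatial-power errors.

The model for individual *i* with observation times :math:`t_{i1..n_i}`:

.. math::

    y_i = X_i \\beta + Z_i b_i + e_i, \\qquad
    b_i \\sim N(0, G), \\quad e_i \\sim N(0, \\sigma^2 R_i)

where :math:`Z_i = [1, t_i]` (random intercept and slope),
:math:`R_i[j,k] = \\rho^{|t_{ij} - t_{ik}|}` is the continuous-time
spatial-power correlation (the continuous analogue of AR(1)), and the
marginal covariance is :math:`V_i = Z_i G Z_i' + \\sigma^2 R_i`.

Estimation maximises the restricted (REML) log-likelihood over an
unconstrained reparameterisation — log-Cholesky for :math:`G/\\sigma^2`, a
logistic transform for :math:`\\rho \\in [0, 1)` — with :math:`\\beta`
profiled out by generalised least squares and :math:`\\sigma^2` profiled in
closed form.  Everything is computed per individual (block-diagonal,
batched over individuals); the full-cohort covariance matrix is never
materialised.  The power form :math:`\\rho^d` with real gaps *d* requires
:math:`\\rho \\ge 0`, so negative serial correlation is outside the model
family.

Individual annual trajectories are formed from the covariate-free (or
exposure-offset-only) fit as the fixed time slope plus the individual's
BLUP slope deviation, :math:`\\hat\\beta_{time} + \\hat b_{i,1}`.
Outlier handling follows the fitted model: observations with internally
studentised marginal residual beyond a threshold (default |t| > 3) are
removed and the model refitted exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "LmmData", "LmmFit", "ConvergenceError",
    "from_dataframe", "marginal_loglik", "fit",
    "studentized_residuals", "fit_with_outlier_pass", "trajectories",
]

_LOG2PI = math.log(2.0 * math.pi)
_PENALTY = 1e10
_DUPLICATE_PERTURB = 1.0 / 365.25  # one day, keeps R_i positive definite


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the best parameters seen so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class LmmData:
    """A longitudinal design: grouped rows of (id, time, response, X)."""

    ids: np.ndarray
    time: np.ndarray
    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    interaction_cols: list[str] = field(default_factory=list)
    dropped_columns: list[str] = field(default_factory=list)
    n_perturbed_times: int = 0

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_groups(self) -> int:
        return np.unique(self.ids).size

    def subset(self, keep: np.ndarray) -> "LmmData":
        return LmmData(
            ids=self.ids[keep], time=self.time[keep], y=self.y[keep],
            X=self.X[keep], columns=list(self.columns),
            interaction_cols=list(self.interaction_cols),
            dropped_columns=list(self.dropped_columns),
        )


def from_dataframe(
    df: pd.DataFrame,
    response: str = "bmi",
    time: str = "time",
    group: str = "id",
    fixed_cols: Optional[Sequence[str]] = None,
    interaction_cols: Sequence[str] = (),
) -> LmmData:
    """Assemble an :class:`LmmData` from stacked observation rows.

    ``fixed_cols`` are additional numeric design columns beyond the implicit
    intercept and time.  Collinear columns are pruned (QR with pivoting) and
    recorded; intercept and time are never pruned.  Duplicate times within an
    individual are perturbed by one day so R_i stays positive definite.
    """
    ids = df[group].to_numpy()
    t = df[time].to_numpy(dtype=float).copy()
    y = df[response].to_numpy(dtype=float)
    if not np.isfinite(t).all() or not np.isfinite(y).all():
        raise ValueError("times and responses must be finite")

    n_perturbed = 0
    for _, idx in pd.Series(np.arange(len(ids)), index=ids).groupby(level=0, sort=False):
        rows = idx.to_numpy()
        ti = t[rows]
        srt = np.argsort(ti, kind="stable")
        for a in range(1, len(srt)):
            if ti[srt[a]] <= ti[srt[a - 1]]:
                ti[srt[a]] = ti[srt[a - 1]] + _DUPLICATE_PERTURB
                n_perturbed += 1
        t[rows] = ti

    cols = ["intercept", "time"] + list(fixed_cols or [])
    X = np.column_stack(
        [np.ones_like(t), t] + [df[c].to_numpy(dtype=float) for c in (fixed_cols or [])])

    # prune collinear columns (never intercept/time)
    dropped: list[str] = []
    if X.shape[1] > 2:
        keep = _independent_columns(X)
        for j in range(2):
            keep[j] = True
        if not keep.all():
            dropped = [c for c, k in zip(cols, keep) if not k]
            X = X[:, keep]
            cols = [c for c, k in zip(cols, keep) if k]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"fixed-effect design is rank deficient (columns {cols})")

    inter = [c for c in interaction_cols if c in cols]
    return LmmData(ids=ids, time=t, y=y, X=X, columns=cols,
                   interaction_cols=inter, dropped_columns=dropped,
                   n_perturbed_times=n_perturbed)


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Greedy left-to-right selection of a full-rank column subset."""
    keep = np.ones(X.shape[1], dtype=bool)
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return keep
    chosen: list[int] = []
    for j in range(X.shape[1]):
        cand = chosen + [j]
        if np.linalg.matrix_rank(X[:, cand]) == len(cand):
            chosen.append(j)
    keep[:] = False
    keep[chosen] = True
    return keep


# --- packing ---------------------------------------------------------------


class _Packed:
    """Per-individual arrays padded to the largest group size."""

    def __init__(self, data: LmmData):
        uid, inv = np.unique(data.ids, return_inverse=True)
        counts = np.bincount(inv, minlength=uid.size)
        n, m = uid.size, int(counts.max())
        p = data.X.shape[1]
        order = np.argsort(inv, kind="stable")
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        g = inv[order]
        pos = np.arange(data.n_obs) - starts[g]

        self.uid, self.n, self.m, self.p = uid, n, m, p
        self.counts = counts
        self.order, self.g, self.pos = order, g, pos
        self.T = np.zeros((n, m))
        self.Y = np.zeros((n, m))
        self.Xp = np.zeros((n, m, p))
        self.mask = np.zeros((n, m), dtype=bool)
        self.T[g, pos] = data.time[order]
        self.Y[g, pos] = data.y[order]
        self.Xp[g, pos, :] = data.X[order]
        self.mask[g, pos] = True
        self.D = np.abs(self.T[:, :, None] - self.T[:, None, :])
        self.Z = np.stack([self.mask.astype(float), self.T * self.mask], axis=-1)
        self.N = int(data.n_obs)

    def unpack(self, packed_values: np.ndarray) -> np.ndarray:
        """Map an (n, m) per-group array back to original row order."""
        flat = np.empty(self.N)
        flat[self.order] = packed_values[self.g, self.pos]
        return flat


def _masked_cov(packed: _Packed, M: np.ndarray) -> np.ndarray:
    """Zero padded rows/cols of a batched covariance and set their diagonal to 1."""
    mo = packed.mask[:, :, None] & packed.mask[:, None, :]
    M = np.where(mo, M, 0.0)
    idx = np.arange(packed.m)
    diag = M[:, idx, idx]
    M[:, idx, idx] = np.where(packed.mask, diag, 1.0)
    return M


def _corr(packed: _Packed, rho: float) -> np.ndarray:
    if rho == 0.0:
        return np.broadcast_to(np.eye(packed.m), (packed.n, packed.m, packed.m)).copy()
    return rho ** packed.D


def _scaled_cov(packed: _Packed, Gt: np.ndarray, rho: float) -> np.ndarray:
    """W_i = Z_i (G/sigma2) Z_i' + R_i, padded entries set to identity."""
    W = np.einsum("nmi,ij,nkj->nmk", packed.Z, Gt, packed.Z, optimize=True)
    W = W + _corr(packed, rho)
    return _masked_cov(packed, W)


def _gls_pieces(packed: _Packed, W: np.ndarray):
    """Cholesky log-determinant plus GLS cross-products for a batched W."""
    L = np.linalg.cholesky(W)  # raises LinAlgError if any block not PD
    logdetW = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
    rhs = np.concatenate([packed.Y[:, :, None], packed.Xp], axis=2)
    A = np.linalg.solve(W, rhs)
    Ay, AX = A[:, :, 0], A[:, :, 1:]
    XtWiX = np.einsum("nmp,nmq->pq", packed.Xp, AX, optimize=True)
    XtWiy = np.einsum("nmp,nm->p", packed.Xp, Ay, optimize=True)
    ytWiy = float(np.einsum("nm,nm->", packed.Y, Ay, optimize=True))
    return logdetW, XtWiX, XtWiy, ytWiy


def _theta_to_Gt(theta: np.ndarray) -> np.ndarray:
    a, b, c = np.clip(theta[0], -14, 14), np.clip(theta[1], -14, 14), np.clip(theta[2], -1e3, 1e3)
    L = np.array([[math.exp(a), 0.0], [c, math.exp(b)]])
    return L @ L.T


def _profiled_nll(theta, packed: _Packed, reml: bool,
                  random_effects: bool, estimate_rho: bool) -> float:
    k = 0
    if random_effects:
        Gt = _theta_to_Gt(theta[:3])
        k = 3
    else:
        Gt = np.zeros((2, 2))
    rho = float(expit(theta[k])) if estimate_rho else 0.0
    W = _scaled_cov(packed, Gt, rho)
    try:
        logdetW, XtWiX, XtWiy, ytWiy = _gls_pieces(packed, W)
    except np.linalg.LinAlgError:
        return _PENALTY
    try:
        cF = np.linalg.cholesky(XtWiX)
    except np.linalg.LinAlgError:
        return _PENALTY
    beta = _chol_solve(cF, XtWiy)
    quad = ytWiy - float(beta @ XtWiy)
    if not np.isfinite(quad) or quad <= 0:
        return _PENALTY
    dof = packed.N - packed.p if reml else packed.N
    sigma2 = quad / dof
    nll = 0.5 * (logdetW + dof * math.log(sigma2) + dof * (1.0 + _LOG2PI))
    if reml:
        nll += float(np.log(np.diag(cF)).sum())  # 0.5 * logdet(X'W^-1 X)
    return float(nll)


def _chol_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular
    return solve_triangular(L.T, solve_triangular(L, b, lower=True), lower=False)


# --- public likelihood (explicit parameters) -------------------------------


def marginal_loglik(data: LmmData, beta, G, sigma2: float, rho: float,
                    reml: bool = True) -> float:
    """Gaussian (restricted) log-likelihood at explicit parameter values.

    Computed per individual from V_i = Z_i G Z_i' + sigma2 R_i; the REML
    variant adds the -0.5 logdet(X'V^-1X) adjustment and uses N - p degrees
    of freedom in the normalising constant.  The quadratic form uses the
    supplied ``beta``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    G = np.asarray(G, dtype=float)
    beta = np.asarray(beta, dtype=float)
    packed = _Packed(data)
    V = np.einsum("nmi,ij,nkj->nmk", packed.Z, G, packed.Z, optimize=True)
    V = V + sigma2 * _corr(packed, rho)
    V = _masked_cov(packed, V)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        bad = _first_non_pd(V)
        raise np.linalg.LinAlgError(
            f"marginal covariance not positive definite for individual {packed.uid[bad]}")
    logdetV = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
    r = (packed.Y - packed.Xp @ beta) * packed.mask
    Vi_r = np.linalg.solve(V, r[:, :, None])[:, :, 0]
    quad = float((r * Vi_r).sum())
    N, p = packed.N, packed.p
    ll = -0.5 * (logdetV + quad + (N - p if reml else N) * _LOG2PI)
    if reml:
        AX = np.linalg.solve(V, packed.Xp)
        XtViX = np.einsum("nmp,nmq->pq", packed.Xp, AX, optimize=True)
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        ll -= 0.5 * logdetX
    return float(ll)


def _first_non_pd(V: np.ndarray) -> int:
    for i in range(V.shape[0]):
        try:
            np.linalg.cholesky(V[i])
        except np.linalg.LinAlgError:
            return i
    return 0


# --- fitting ---------------------------------------------------------------


@dataclass
class LmmFit:
    beta: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    G: np.ndarray
    sigma2: float
    rho: float
    blups: pd.DataFrame            # id, intercept_dev, slope_dev
    loglik: float
    reml: bool
    converged: bool
    n_obs_used: int
    n_groups: int
    covariance: str
    data: LmmData
    n_outliers_removed: int = 0
    dropped_groups: list = field(default_factory=list)
    n_iter: int = 0
    kept_mask: Optional[np.ndarray] = None  # vs the design passed to the outlier pass

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.pvalues,
        })


_DEFAULT_STARTS = (
    np.array([1.0, -0.7, 0.0, -0.85]),
    np.array([0.0, -2.0, 0.0, 0.4]),
)


def fit(
    data: LmmData,
    covariance: str = "sp_pow",
    reml: bool = True,
    random_effects: bool = True,
    max_iter: int = 500,
    tol: float = 1e-10,
    starts: Optional[Sequence[np.ndarray]] = None,
) -> LmmFit:
    """REML (or ML) fit of the random intercept+slope model.

    ``covariance`` is ``"sp_pow"`` (estimate rho) or ``"independent"``
    (rho fixed at 0); ``random_effects=False`` drops G entirely, reducing
    the model to (generalised) least squares.
    """
    if covariance not in ("sp_pow", "independent"):
        raise ValueError(f"unknown covariance structure {covariance!r}")
    estimate_rho = covariance == "sp_pow"
    packed = _Packed(data)
    if packed.n < 2 and random_effects:
        raise ValueError("need at least 2 individuals to estimate random effects")

    n_theta = (3 if random_effects else 0) + (1 if estimate_rho else 0)
    if n_theta == 0:
        theta_hat = np.empty(0)
        res_nit, success = 0, True
    else:
        start_list = [s[:4] for s in (starts or _DEFAULT_STARTS)]
        start_list = [_slice_start(s, random_effects, estimate_rho) for s in start_list]
        best = None
        success = False
        res_nit = 0
        for x0 in start_list:
            res = optimize.minimize(
                _profiled_nll, x0,
                args=(packed, reml, random_effects, estimate_rho),
                method="L-BFGS-B",
                options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success and res.fun < _PENALTY / 2:
                best = res if res.fun <= best.fun else best
                success = True
                break
        if best is None or not np.isfinite(best.fun) or best.fun >= _PENALTY / 2:
            raise ConvergenceError(
                "REML optimisation failed to find an admissible parameter point",
                best=None if best is None else best.x)
        theta_hat = best.x
        res_nit = int(best.nit)
        if not success:
            # L-BFGS-B can report ABNORMAL on near-degenerate surfaces (e.g.
            # vanishing noise); polish with a derivative-free pass before giving up
            polish = optimize.minimize(
                _profiled_nll, best.x,
                args=(packed, reml, random_effects, estimate_rho),
                method="Nelder-Mead",
                options={"maxiter": 400 * len(best.x), "fatol": 1e-10, "xatol": 1e-8})
            if polish.fun <= best.fun + 1e-8 and polish.fun < _PENALTY / 2:
                theta_hat = polish.x
                success = True
            else:
                raise ConvergenceError(
                    f"REML optimisation did not converge: {best.message}",
                    best=theta_hat)

    k = 0
    if random_effects:
        Gt = _theta_to_Gt(theta_hat[:3])
        k = 3
    else:
        Gt = np.zeros((2, 2))
    rho = float(expit(theta_hat[k])) if estimate_rho else 0.0

    W = _scaled_cov(packed, Gt, rho)
    logdetW, XtWiX, XtWiy, ytWiy = _gls_pieces(packed, W)
    cF = np.linalg.cholesky(XtWiX)
    beta = _chol_solve(cF, XtWiy)
    quad = ytWiy - float(beta @ XtWiy)
    dof = packed.N - packed.p if reml else packed.N
    sigma2 = quad / dof
    G = sigma2 * Gt
    cov_beta = sigma2 * np.linalg.inv(XtWiX)
    se = np.sqrt(np.diag(cov_beta))
    z = norm.ppf(0.975)
    pvals = 2.0 * norm.sf(np.abs(beta) / se)

    # BLUPs: b_i = (G/sigma2) Z_i' W_i^-1 (y_i - X_i beta)
    r = (packed.Y - packed.Xp @ beta) * packed.mask
    Wi_r = np.linalg.solve(W, r[:, :, None])[:, :, 0]
    Ztr = np.einsum("nmi,nm->ni", packed.Z, Wi_r, optimize=True)
    b = Ztr @ Gt.T
    blups = pd.DataFrame({
        "id": packed.uid, "intercept_dev": b[:, 0], "slope_dev": b[:, 1]})

    nll = _profiled_nll(theta_hat, packed, reml, random_effects, estimate_rho) \
        if n_theta else _profiled_nll(np.zeros(1), packed, reml, False, False)
    idx = pd.Index(data.columns)
    return LmmFit(
        beta=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        ci_low=pd.Series(beta - z * se, index=idx),
        ci_high=pd.Series(beta + z * se, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        G=G, sigma2=float(sigma2), rho=rho,
        blups=blups, loglik=float(-nll), reml=reml,
        converged=bool(success), n_obs_used=packed.N, n_groups=packed.n,
        covariance=covariance, data=data, n_iter=res_nit,
    )


def _slice_start(s: np.ndarray, random_effects: bool, estimate_rho: bool) -> np.ndarray:
    parts = []
    if random_effects:
        parts.append(s[:3])
    if estimate_rho:
        parts.append(s[3:4])
    return np.concatenate(parts) if parts else np.empty(0)


def studentized_residuals(fit_result: LmmFit, data: Optional[LmmData] = None) -> np.ndarray:
    """Internally studentised marginal residuals.

    The marginal residual y - X beta divided by the square root of the
    fitted marginal variance diag(V_i), in the original row order of the
    design.  In the homoscedastic independent special case (G = 0, rho = 0)
    this reduces to the classical residual / sigma.
    """
    data = data or fit_result.data
    packed = _Packed(data)
    beta = fit_result.beta.to_numpy()
    Gt = fit_result.G / fit_result.sigma2 if fit_result.sigma2 > 0 else np.zeros((2, 2))
    t = packed.T
    var_scaled = (Gt[0, 0] + 2.0 * Gt[0, 1] * t + Gt[1, 1] * t * t + 1.0)
    sd = np.sqrt(fit_result.sigma2 * var_scaled)
    r = packed.Y - packed.Xp @ beta
    return packed.unpack(r / sd)


def fit_with_outlier_pass(
    data: LmmData,
    threshold: float = 3.0,
    **fit_kwargs,
) -> LmmFit:
    """Fit, remove observations with |studentised residual| > threshold, refit once.

    Individuals left with no observations are dropped and recorded.  An
    infinite threshold (or a pass that flags nothing) leaves the initial fit
    untouched.
    """
    first = fit(data, **fit_kwargs)
    first.kept_mask = np.ones(data.n_obs, dtype=bool)
    if not math.isfinite(threshold):
        return first
    resid = studentized_residuals(first, data)
    keep = np.abs(resid) <= threshold
    n_out = int((~keep).sum())
    if n_out == 0:
        return first
    kept_ids = set(np.unique(data.ids[keep]))
    dropped_groups = [g for g in np.unique(data.ids) if g not in kept_ids]
    cleaned = data.subset(keep)
    second = fit(cleaned, **fit_kwargs)
    second.n_outliers_removed = n_out
    second.dropped_groups = dropped_groups
    second.kept_mask = keep
    return second


def trajectories(fit_result: LmmFit) -> pd.DataFrame:
    """Per-individual annual rate: fixed time slope + BLUP slope deviation.

    Only meaningful for the base specification (fixed effects limited to
    intercept, time and time-constant exposure offsets): with covariate-time
    interactions the population slope is covariate-dependent and a single
    fixed slope does not exist, so such fits are refused.
    """
    if fit_result.data.interaction_cols:
        raise ValueError(
            "trajectories are defined for the base model only; this fit includes "
            f"covariate-time interaction columns {fit_result.data.interaction_cols}. "
            "Fit the covariate-free (or exposure-offset) base model instead.")
    rate = fit_result.beta["time"] + fit_result.blups["slope_dev"].to_numpy()
    return pd.DataFrame({"id": fit_result.blups["id"], "rate": rate})
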