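"""Composite Minimax Concave Penalty (cMCP) estimator for bi-level selection.

The model is a stacked linear regression whose coefficients are grouped
(here: by protein, each group holding that protein's effect bundle).  The
penalty applies an outer MCP to the sum of inner MCPs of the member
magnitudes:

    P_lambda(beta) = sum_g f_out( sum_{j in g} f(|beta_j|; lambda, gamma_in) )

with ``f(t; lambda, gamma) = lambda*t - t^2/(2*gamma)`` for ``t <= gamma*lambda``
and ``gamma*lambda^2/2`` beyond.  The outer MCP has unit slope at zero and a
group-size-scaled concavity ``gtilde_g = gamma_out * K_g * lambda^2 / 2`` so
that it plateaus exactly when every member's inner penalty saturates.  This
parameterization keeps the penalty's derivative at zero equal to ``lambda``
(so the path starts at the familiar ``lambda_max = max |x_j' r| / n``) and
makes the whole objective homogeneous of degree two under
``(beta, lambda) -> (c*beta, c*lambda)``, i.e. rescaling the response by c
rescales the solution by c.

Because both the inner penalty and the tangent-majorized outer penalty admit
closed-form univariate minimizers (firm thresholding), the objective is
minimized by cyclic local coordinate descent with warm starts along a
decreasing lambda grid.  Only a stationary point is guaranteed — the penalty
is nonconvex — and small-problem tests compare solutions against brute-force
lattice minimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignMatrix
from .errors import ConvergenceError, ValidationError

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


# --------------------------------------------------------------------------
# penalty primitives
# --------------------------------------------------------------------------

def _check_gamma(gamma: float) -> None:
    if not gamma > 1:
        raise ValidationError(f"MCP concavity gamma must exceed 1, got {gamma}")


def mcp(theta, lam, gamma: float = 3.0):
    """MCP penalty value at |coefficient| ``theta`` (vectorized).

    ``lam*theta - theta^2/(2*gamma)`` inside the concave region
    ``theta <= gamma*lam``; constant plateau ``gamma*lam^2/2`` beyond.
    """
    _check_gamma(gamma)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValidationError("mcp expects theta >= 0 (use the magnitude)")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    inside = lam * theta - theta**2 / (2.0 * gamma)
    out = np.where(theta <= gamma * lam, inside, gamma * lam**2 / 2.0)
    return out if out.ndim else float(out)


def mcp_deriv(theta, lam, gamma: float = 3.0):
    """d/dtheta of the MCP at theta >= 0: ``lam - theta/gamma`` then 0."""
    _check_gamma(gamma)
    theta = np.asarray(theta, dtype=float)
    out = np.where(theta <= gamma * lam, lam - theta / gamma, 0.0)
    return out if out.ndim else float(out)


def firm_threshold(z, lam, gamma: float = 3.0):
    """Univariate MCP minimizer: argmin_b 0.5*(z-b)^2 + MCP(|b|; lam, gamma).

    Soft thresholding inflated by 1/(1 - 1/gamma) inside the concave region,
    identity beyond ``|z| > gamma*lam``.  Odd in ``z``.
    """
    _check_gamma(gamma)
    z = np.asarray(z, dtype=float)
    soft = np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)
    out = np.where(np.abs(z) <= gamma * lam, soft / (1.0 - 1.0 / gamma), z)
    return out if out.ndim else float(out)


def _outer_gamma(lam: float, gamma_outer: float, group_size: int) -> float:
    """Concavity of the outer MCP for a group with ``group_size`` members."""
    return gamma_outer * group_size * lam**2 / 2.0


def cmcp_penalty(beta, group_index, penalized, lam, gamma_inner=3.0, gamma_outer=3.0):
    """Composite penalty value for a coefficient vector."""
    _check_gamma(gamma_inner)
    _check_gamma(gamma_outer)
    if lam == 0:
        return 0.0
    beta = np.asarray(beta, dtype=float)
    group_index = np.asarray(group_index)
    penalized = np.asarray(penalized, dtype=bool)
    total = 0.0
    for g in np.unique(group_index):
        mem = (group_index == g) & penalized
        k = int(mem.sum())
        if k == 0:
            continue
        s = float(np.sum(mcp(np.abs(beta[mem]), lam, gamma_inner)))
        gt = _outer_gamma(lam, gamma_outer, k)
        total += s - s**2 / (2.0 * gt) if s <= gt else gt / 2.0
    return total


def cmcp_objective(beta, X, y, group_index, penalized, lam,
                   gamma_inner=3.0, gamma_outer=3.0):
    """(1/2n)||y - X beta||^2 plus the composite penalty."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != beta.shape[0] or X.shape[0] != y.shape[0]:
        raise ValidationError(
            f"dimension mismatch: X {X.shape}, y {y.shape}, beta {beta.shape}"
        )
    r = y - X @ beta
    rss_term = 0.5 * float(r @ r) / X.shape[0]
    return rss_term + cmcp_penalty(beta, group_index, penalized, lam,
                                   gamma_inner, gamma_outer)


# --------------------------------------------------------------------------
# parameters / results
# --------------------------------------------------------------------------

@dataclass
class PenaltyParams:
    """Tuning knobs for the path fit.

    ``lambda_grid`` overrides the automatic grid (must be strictly
    decreasing and positive); otherwise ``n_lambda`` log-spaced values from
    lambda_max down to ``lambda_min_ratio * lambda_max`` are used.
    """

    lambda_grid: np.ndarray | None = None
    n_lambda: int = 100
    lambda_min_ratio: float = 0.001
    gamma_inner: float = 3.0
    gamma_outer: float = 3.0
    tol: float = 1e-8
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        _check_gamma(self.gamma_inner)
        _check_gamma(self.gamma_outer)
        if not self.tol > 0:
            raise ValidationError("tol must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.ndim != 1 or len(grid) == 0:
                raise ValidationError("lambda_grid must be a 1-d sequence")
            if np.any(grid <= 0) or np.any(np.diff(grid) >= 0):
                raise ValidationError("lambda_grid must be strictly decreasing and > 0")
            self.lambda_grid = grid
        if not (0 < self.lambda_min_ratio < 1):
            raise ValidationError("lambda_min_ratio must lie in (0, 1)")
        if self.n_lambda < 1:
            raise ValidationError("n_lambda must be >= 1")


@dataclass
class CoefPath:
    lambdas: np.ndarray
    coefs: np.ndarray            # (n_lambda, p) on the original scale
    coefs_std: np.ndarray        # (n_lambda, p) on the solver scale
    rss: np.ndarray              # residual sum of squares per lambda
    objective: np.ndarray        # final objective per lambda (solver scale)
    n_iter: np.ndarray
    converged: np.ndarray
    objective_logs: list[np.ndarray]   # per-sweep objective per lambda
    group_index: np.ndarray
    penalized: np.ndarray
    n_obs: int
    params: PenaltyParams

    def support(self, i: int) -> np.ndarray:
        """Indices of nonzero penalized coefficients at grid point i."""
        return np.nonzero((self.coefs_std[i] != 0) & self.penalized)[0]


@dataclass
class SelectedModel:
    lam: float
    index: int
    coef: np.ndarray             # original scale
    coef_std: np.ndarray
    selected_members: np.ndarray  # penalized column indices with nonzero coef
    selected_groups: np.ndarray   # group ids containing a selected member
    criterion: str
    criterion_value: float
    criterion_path: np.ndarray = field(repr=False, default=None)


# --------------------------------------------------------------------------
# coordinate-descent kernel
# --------------------------------------------------------------------------

@njit(cache=False)
def _cd_kernel(G, cvec, yty_n, beta, Gb, svals, group_of, penalized, gsize,
               lam, gamma_in, gamma_out, tol, max_iter, obj_log):  # pragma: no cover
    p = beta.shape[0]
    n_groups = svals.shape[0]
    converged = False
    sweeps = 0
    for it in range(max_iter):
        max_change = 0.0
        for j in range(p):
            bj = beta[j]
            gjj = G[j, j]
            u = cvec[j] - Gb[j] + gjj * bj
            if penalized[j] == 0 or lam <= 0.0:
                b = u / gjj
            else:
                g = group_of[j]
                gt = gamma_out * gsize[g] * lam * lam / 2.0
                w = 1.0 - svals[g] / gt
                if w < 0.0:
                    w = 0.0
                denom = gjj - w / gamma_in
                if w == 0.0 or denom <= 1e-12:
                    b = u / gjj
                else:
                    mag = abs(u) - w * lam
                    if mag < 0.0:
                        mag = 0.0
                    b = mag / denom
                    if u < 0.0:
                        b = -b
                    if abs(b) > gamma_in * lam:
                        b = u / gjj
            d = b - bj
            if d != 0.0:
                for k in range(p):
                    Gb[k] += G[k, j] * d
                if penalized[j] == 1 and lam > 0.0:
                    g = group_of[j]
                    # update the group's inner-penalty sum incrementally
                    old_t = abs(bj)
                    new_t = abs(b)
                    if old_t <= gamma_in * lam:
                        old_pen = lam * old_t - old_t * old_t / (2.0 * gamma_in)
                    else:
                        old_pen = gamma_in * lam * lam / 2.0
                    if new_t <= gamma_in * lam:
                        new_pen = lam * new_t - new_t * new_t / (2.0 * gamma_in)
                    else:
                        new_pen = gamma_in * lam * lam / 2.0
                    svals[g] += new_pen - old_pen
                beta[j] = b
                if abs(d) > max_change:
                    max_change = abs(d)
        # objective after this sweep
        quad = 0.0
        lin = 0.0
        for k in range(p):
            quad += beta[k] * Gb[k]
            lin += beta[k] * cvec[k]
        obj = 0.5 * (yty_n - 2.0 * lin + quad)
        if lam > 0.0:
            for g in range(n_groups):
                if gsize[g] > 0:
                    gt = gamma_out * gsize[g] * lam * lam / 2.0
                    s = svals[g]
                    if s <= gt:
                        obj += s - s * s / (2.0 * gt)
                    else:
                        obj += gt / 2.0
        obj_log[it] = obj
        sweeps = it + 1
        if max_change < tol:
            converged = True
            break
    return sweeps, converged


def _inner_sums(beta, group_of, penalized, gsize, lam, gamma_in):
    n_groups = len(gsize)
    s = np.zeros(n_groups)
    if lam <= 0:
        return s
    for j in range(len(beta)):
        if penalized[j]:
            s[group_of[j]] += mcp(abs(beta[j]), lam, gamma_in)
    return s


# --------------------------------------------------------------------------
# path fitting
# --------------------------------------------------------------------------

def _as_problem(design, y, group_index, penalized):
    if isinstance(design, DesignMatrix):
        return design.X, design.y, design.group_index, design.penalized, design
    X = np.asarray(design, dtype=float)
    if y is None or group_index is None or penalized is None:
        raise ValidationError(
            "raw-array fitting requires y, group_index and penalized masks"
        )
    return (X, np.asarray(y, dtype=float), np.asarray(group_index),
            np.asarray(penalized, dtype=bool), None)


def fit_cmcp_path(design, y=None, params: PenaltyParams | None = None, *,
                  group_index=None, penalized=None) -> CoefPath:
    """Fit the cMCP solution path by warm-started local coordinate descent.

    ``design`` is either a :class:`~mitopanel.design.DesignMatrix` (whose
    standardization record is used to report coefficients on the original
    scale) or an already-standardized numpy array (with ``y``,
    ``group_index`` and ``penalized`` supplied; coefficients are then
    reported as-is).
    """
    params = params or PenaltyParams()
    X, yv, gidx, pen, dm = _as_problem(design, y, group_index, penalized)
    n, p = X.shape
    gidx = gidx.astype(np.int64)

    n_groups = int(gidx.max()) + 1 if p else 0
    gsize = np.zeros(n_groups, dtype=np.int64)
    for j in range(p):
        if pen[j]:
            gsize[gidx[j]] += 1

    G = X.T @ X / n
    cvec = X.T @ yv / n
    yty_n = float(yv @ yv) / n

    unpen_cols = np.nonzero(~pen)[0]
    beta = np.zeros(p)
    if len(unpen_cols):
        Xu = X[:, unpen_cols]
        if np.linalg.matrix_rank(Xu) < len(unpen_cols):
            raise np.linalg.LinAlgError("singular unpenalized design block")
        beta[unpen_cols], *_ = np.linalg.lstsq(Xu, yv, rcond=None)

    if params.lambda_grid is not None:
        lambdas = params.lambda_grid
    else:
        resid_corr = cvec - G @ beta
        lam_max = float(np.max(np.abs(resid_corr[pen]))) if pen.any() else 1.0
        lam_max = max(lam_max, 1e-12)
        lambdas = np.geomspace(lam_max, lam_max * params.lambda_min_ratio,
                               params.n_lambda)

    n_lam = len(lambdas)
    coefs_std = np.zeros((n_lam, p))
    objective = np.zeros(n_lam)
    rss = np.zeros(n_lam)
    n_iter = np.zeros(n_lam, dtype=int)
    converged = np.zeros(n_lam, dtype=bool)
    logs: list[np.ndarray] = []

    pen_i8 = pen.astype(np.int8)
    obj_log = np.empty(params.max_iter)
    Gb = G @ beta
    for i, lam in enumerate(lambdas):
        svals = _inner_sums(beta, gidx, pen, gsize, lam, params.gamma_inner)
        sweeps, ok = _cd_kernel(G, cvec, yty_n, beta, Gb, svals, gidx, pen_i8,
                                gsize, float(lam), params.gamma_inner,
                                params.gamma_outer, params.tol,
                                params.max_iter, obj_log)
        coefs_std[i] = beta
        n_iter[i] = sweeps
        converged[i] = ok
        objective[i] = obj_log[sweeps - 1] if sweeps else np.nan
        rss[i] = n * (yty_n - 2.0 * float(beta @ cvec) + float(beta @ (G @ beta)))
        logs.append(obj_log[:sweeps].copy())
        # refresh Gb to curb incremental drift between warm starts
        Gb = G @ beta

    if dm is not None:
        coefs = np.vstack([dm.destandardize(b) for b in coefs_std])
    else:
        coefs = coefs_std.copy()
    return CoefPath(lambdas=np.asarray(lambdas, dtype=float), coefs=coefs,
                    coefs_std=coefs_std, rss=np.maximum(rss, 0.0),
                    objective=objective, n_iter=n_iter, converged=converged,
                    objective_logs=logs, group_index=gidx, penalized=pen,
                    n_obs=n, params=params)


def select_model(path: CoefPath, criterion: str = "bic") -> SelectedModel:
    """Pick the path point minimizing BIC (default) or AIC.

    BIC = n log(RSS/n) + df log(n) with df = number of nonzero coefficients;
    ties break toward the larger lambda (the sparser model).  Grid points
    that failed to converge are excluded.
    """
    criterion = criterion.lower()
    if criterion not in ("bic", "aic"):
        raise ValidationError(f"unknown selection criterion {criterion!r}")
    if not path.converged.any():
        raise ConvergenceError("no converged path point to select from")
    n = path.n_obs
    df = (path.coefs_std != 0).sum(axis=1)
    with np.errstate(divide="ignore"):
        ll = n * np.log(np.maximum(path.rss, 1e-300) / n)
    mult = np.log(n) if criterion == "bic" else 2.0
    crit = ll + mult * df
    crit = np.where(path.converged, crit, np.inf)
    best = int(np.argmin(crit))  # first minimum = largest lambda on ties
    coef_std = path.coefs_std[best]
    members = np.nonzero((coef_std != 0) & path.penalized)[0]
    groups = np.unique(path.group_index[members])
    return SelectedModel(lam=float(path.lambdas[best]), index=best,
                         coef=path.coefs[best].copy(), coef_std=coef_std.copy(),
                         selected_members=members, selected_groups=groups,
                         criterion=criterion, criterion_value=float(crit[best]),
                         criterion_path=crit)


def kkt_check(model: SelectedModel, design, y=None, params: PenaltyParams | None = None,
              *, group_index=None, penalized=None) -> float:
    """Maximum coordinate-wise stationarity violation at the solution.

    For nonzero penalized coefficients the gradient of the smooth part must
    cancel the penalty's local derivative; for zero coefficients the
    gradient magnitude must not exceed the threshold at zero; unpenalized
    coordinates must have zero gradient.
    """
    params = params or PenaltyParams()
    X, yv, gidx, pen, _ = _as_problem(design, y, group_index, penalized)
    n = X.shape[0]
    beta = model.coef_std
    grad = X.T @ (X @ beta - yv) / n

    n_groups = int(gidx.max()) + 1
    gsize = np.zeros(n_groups, dtype=int)
    for j in range(len(beta)):
        if pen[j]:
            gsize[gidx[j]] += 1
    svals = _inner_sums(beta, gidx, pen, gsize, model.lam, params.gamma_inner)

    worst = 0.0
    for j in range(len(beta)):
        if not pen[j]:
            viol = abs(grad[j])
        else:
            g = gidx[j]
            if model.lam <= 0:
                w = 0.0
            else:
                gt = _outer_gamma(model.lam, params.gamma_outer, gsize[g])
                w = max(0.0, 1.0 - svals[g] / gt)
            if beta[j] != 0:
                dpen = w * mcp_deriv(abs(beta[j]), model.lam, params.gamma_inner)
                viol = abs(grad[j] + np.sign(beta[j]) * dpen)
            else:
                viol = max(0.0, abs(grad[j]) - w * model.lam)
        worst = max(worst, float(viol))
    return worst
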