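"""SCAD-penalized additive-hazards regression with cross-validated lambda.

The second selection stage minimises the penalized least-squares-type loss

    Q(beta) = beta' V beta / 2 - b' beta + sum_{j penalized} p_lambda(|beta_j|)

over the screened design, where ``p_lambda`` is the smoothly clipped absolute
deviation (SCAD) penalty of Fan & Li with derivative

    p'_lambda(|b|) = lambda                      for |b| <= lambda
                   = (a*lambda - |b|)_+ / (a-1)  for |b| >  lambda,   a > 2.

SCAD behaves like the lasso near zero (sparsity) but its penalty flattens for
large coefficients, so selected effects are nearly unbiased. The exposure and
adjustment covariates are never penalized — they stay in the model throughout
and only mediator coefficients carry the penalty.

Minimisation is cyclic coordinate descent: each coordinate update solves a
univariate penalized quadratic in closed form (the partial residual
``z_j = b_j - sum_{l != j} V_jl beta_l`` against the curvature ``V_jj``), so
the objective never increases across sweeps. The sweep order is the design's
column order and the path is warm-started from lambda_max downwards with a
zero start — SCAD is non-convex, and fixing these choices makes the local
solution reproducible. ``lambda`` is chosen by K-fold cross-validation of the
held-out version of the same loss (the natural analogue of cross-validated
partial likelihood, which does not exist for this model).

Two solvers are provided. The default, *stepwise SCAD*, is the one-step
local linear approximation: at each lambda the SCAD penalty is linearised
around an initial solution (the univariate estimates ``b_j / V_jj``), giving
a weighted lasso with per-column penalty ``p'_lambda(|beta_init,j|)`` that is
solved exactly by coordinate descent. Strong columns get a near-zero weight
(nearly unbiased), weak columns the full lasso shrinkage — the behaviour of
the ``sscad`` penalty in the R ``ahaz`` package. The alternative ``exact``
solver iterates the exact three-branch SCAD thresholding to a stationary
point of the non-convex objective; it is markedly more aggressive in
screened designs where many columns proxy the exposure, because selected
coefficients jump to their unshrunken values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .data import DesignBundle, ROLE_MEDIATOR, SurvivalDataset, as_survival_y
from .hazard import HazardStatistics, hazard_statistics
from .screening import ScreenResult

__all__ = [
    "ScadConfig",
    "ScadFit",
    "scad_penalty",
    "scad_derivative",
    "penalized_fit",
    "penalized_objective",
    "lambda_max",
    "default_lambda_grid",
    "univariate_estimates",
    "cross_validate",
    "ScadAdditiveHazardsCV",
]

logger = logging.getLogger("medhaz")


@dataclass(frozen=True)
class ScadConfig:
    """Tuning knobs of the penalized stage.

    ``a`` is the SCAD concavity parameter (must exceed 2; 3.7 is the
    literature standard). ``lambda_grid=None`` builds a 50-point log-spaced
    grid from lambda_max (the smallest lambda zeroing every penalized
    coefficient) down to ``lambda_min_ratio * lambda_max``. ``solver``
    selects the stepwise (LLA, default) or exact SCAD algorithm; ``nsteps``
    is the number of re-linearisation steps of the stepwise solver.
    """

    a: float = 3.7
    lambda_grid: np.ndarray | None = None
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    n_folds: int = 5
    max_iter: int = 500
    tol: float = 1e-7
    penalty_kind: str = "scad"
    solver: str = "stepwise"
    nsteps: int = 1
    penalize_all: bool = False

    def __post_init__(self):
        if self.a <= 2:
            raise ValueError("SCAD requires a > 2")
        if self.penalty_kind not in ("scad", "lasso"):
            raise ValueError("penalty_kind must be 'scad' or 'lasso'")
        if self.solver not in ("stepwise", "exact"):
            raise ValueError("solver must be 'stepwise' or 'exact'")
        if self.nsteps < 1:
            raise ValueError("nsteps must be >= 1")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.ndim != 1 or grid.size == 0:
                raise ValueError("lambda_grid must be a non-empty 1-d array")
            if np.any(grid <= 0):
                raise ValueError("lambda_grid must be strictly positive")
            if grid.size > 1 and np.any(np.diff(grid) >= 0):
                raise ValueError("lambda_grid must be strictly descending")
            object.__setattr__(self, "lambda_grid", grid)


@dataclass
class ScadFit:
    """Result of the cross-validated penalized fit on the screened design."""

    coefficients: np.ndarray
    selected: np.ndarray  # original mediator indices with nonzero coefficient
    lambda_star: float
    cv_curve: pd.DataFrame  # columns: lambda, cv_loss, n_selected
    design: DesignBundle
    screen: ScreenResult | None = None
    converged: bool = True


# --------------------------------------------------------------------------
# penalty primitives
# --------------------------------------------------------------------------

def scad_penalty(beta_abs, lam: float, a: float = 3.7):
    """SCAD penalty primitive p_lambda(|beta|) (vectorised)."""
    _check_pen_params(lam, a)
    babs = np.abs(np.asarray(beta_abs, dtype=float))
    quad = (2 * a * lam * babs - babs**2 - lam**2) / (2 * (a - 1.0))
    out = np.where(
        babs <= lam, lam * babs, np.where(babs <= a * lam, quad, lam**2 * (a + 1.0) / 2.0)
    )
    return out if out.ndim else float(out)


def scad_derivative(beta_abs, lam: float, a: float = 3.7):
    """SCAD penalty derivative, continuous in |beta|.

    lam on [0, lam]; (a*lam - |beta|)_+ / (a - 1) beyond; 0 past a*lam.
    """
    _check_pen_params(lam, a)
    babs = np.asarray(beta_abs, dtype=float)
    if np.any(babs < 0):
        raise ValueError("beta_abs must be nonnegative")
    out = np.where(
        babs <= lam, lam, np.clip(a * lam - babs, 0.0, None) / (a - 1.0)
    )
    return out if out.ndim else float(out)


def _check_pen_params(lam: float, a: float) -> None:
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if a <= 2:
        raise ValueError("SCAD requires a > 2")


# --------------------------------------------------------------------------
# coordinate descent (numba kernels)
# --------------------------------------------------------------------------

@njit(cache=True)
def _scad_pen_scalar(babs, lam, a):
    if babs <= lam:
        return lam * babs
    if babs <= a * lam:
        return (2.0 * a * lam * babs - babs * babs - lam * lam) / (2.0 * (a - 1.0))
    return lam * lam * (a + 1.0) / 2.0


@njit(cache=True)
def _scad_univariate(z, v, lam, a):
    """Exact minimiser of v*b^2/2 - z*b + p_lambda(|b|) over b.

    Evaluates the stationary point of each of the three penalty branches
    (clipped into its region) plus the region boundaries and picks the
    candidate with the lowest objective; ties prefer the smaller |b|. This
    remains correct even when (a-1)*V_jj <= 1 and the middle branch is
    locally concave.
    """
    s = 1.0 if z >= 0.0 else -1.0
    az = abs(z)
    cand = np.empty(5)
    b1 = (az - lam) / v
    if b1 < 0.0:
        b1 = 0.0
    elif b1 > lam:
        b1 = lam
    cand[0] = b1
    den = (a - 1.0) * v - 1.0
    if den != 0.0:
        b2 = ((a - 1.0) * az - a * lam) / den
    else:
        b2 = lam
    if b2 < lam:
        b2 = lam
    elif b2 > a * lam:
        b2 = a * lam
    cand[1] = b2
    b3 = az / v
    if b3 < a * lam:
        b3 = a * lam
    cand[2] = b3
    cand[3] = 0.0
    cand[4] = lam
    best = 0.0
    fbest = np.inf
    for i in range(5):
        bi = s * cand[i]
        f = 0.5 * v * bi * bi - z * bi + _scad_pen_scalar(abs(bi), lam, a)
        if f < fbest or (f == fbest and abs(bi) < abs(best)):
            fbest = f
            best = bi
    return best


@njit(cache=True)
def _cd_weighted_lasso(V, b, beta, lamvec, max_iter, tol):
    """Coordinate descent for a per-column-weighted lasso (convex)."""
    m = b.shape[0]
    for it in range(max_iter):
        maxch = 0.0
        for j in range(m):
            vjj = V[j, j]
            bj = beta[j]
            if vjj <= 0.0:
                if lamvec[j] > 0.0:
                    beta[j] = 0.0
                continue
            z = b[j] - np.dot(V[j], beta) + vjj * bj
            lj = lamvec[j]
            if lj > 0.0:
                az = abs(z) - lj
                nb = (az if az > 0.0 else 0.0) / vjj
                if z < 0.0:
                    nb = -nb
            else:
                nb = z / vjj
            ch = abs(nb - bj)
            if ch > maxch:
                maxch = ch
            beta[j] = nb
        if maxch < tol:
            return True
    return False


@njit(cache=True)
def _cd_sweeps(V, b, beta, pen_mask, lam, a, lasso, max_iter, tol):
    m = b.shape[0]
    for it in range(max_iter):
        maxch = 0.0
        for j in range(m):
            vjj = V[j, j]
            bj = beta[j]
            if vjj <= 0.0:
                if pen_mask[j]:
                    beta[j] = 0.0
                continue
            z = b[j] - np.dot(V[j], beta) + vjj * bj
            if pen_mask[j]:
                if lasso:
                    az = abs(z) - lam
                    nb = (az if az > 0.0 else 0.0) / vjj
                    if z < 0.0:
                        nb = -nb
                else:
                    nb = _scad_univariate(z, vjj, lam, a)
            else:
                nb = z / vjj
            ch = abs(nb - bj)
            if ch > maxch:
                maxch = ch
            beta[j] = nb
        if maxch < tol:
            return True
    return False


def penalized_objective(
    stats: HazardStatistics,
    beta: np.ndarray,
    penalized_mask: np.ndarray,
    lam: float,
    config: ScadConfig | None = None,
) -> float:
    """Penalized loss Q(beta) = beta'V beta/2 - b'beta + sum p_lambda."""
    cfg = config or ScadConfig()
    loss = 0.5 * beta @ stats.V @ beta - stats.b @ beta
    pen_beta = np.abs(beta[np.asarray(penalized_mask, dtype=bool)])
    if cfg.penalty_kind == "lasso":
        pen = lam * pen_beta.sum()
    else:
        pen = float(np.sum(scad_penalty(pen_beta, lam, cfg.a)))
    return float(loss + pen)


def penalized_fit(
    stats: HazardStatistics,
    penalized_mask: np.ndarray,
    lam: float,
    config: ScadConfig | None = None,
    warm_start: np.ndarray | None = None,
    debug: bool = False,
) -> tuple[np.ndarray, bool]:
    """Cyclic coordinate descent at a single lambda.

    Returns ``(coefficients, converged)``; non-convergence at ``max_iter``
    sweeps emits a warning rather than an error. Penalized columns with zero
    curvature (``V_jj = 0``) are pinned at 0. With ``debug=True`` the
    objective is checked to be non-increasing after every sweep.
    """
    cfg = config or ScadConfig()
    _check_pen_params(lam, cfg.a)
    mask = np.ascontiguousarray(np.asarray(penalized_mask, dtype=bool))
    b = np.ascontiguousarray(stats.b, dtype=float)
    V = np.ascontiguousarray(stats.V, dtype=float)
    if mask.shape != b.shape:
        raise ValueError("penalized_mask must align with the design")
    beta = (
        np.zeros_like(b)
        if warm_start is None
        else np.array(warm_start, dtype=float, copy=True)
    )
    lasso = cfg.penalty_kind == "lasso"
    if debug:
        prev = penalized_objective(stats, beta, mask, lam, cfg)
        converged = False
        for _ in range(cfg.max_iter):
            done = _cd_sweeps(V, b, beta, mask, lam, cfg.a, lasso, 1, cfg.tol)
            cur = penalized_objective(stats, beta, mask, lam, cfg)
            if cur > prev + 1e-10 * (1.0 + abs(prev)):
                raise AssertionError("penalized objective increased across a sweep")
            prev = cur
            if done:
                converged = True
                break
    else:
        converged = _cd_sweeps(V, b, beta, mask, lam, cfg.a, lasso, cfg.max_iter, cfg.tol)
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {cfg.max_iter} sweeps at "
            f"lambda={lam:.4g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return beta, converged


def _partial_residuals_at_zero(stats: HazardStatistics, mask: np.ndarray) -> np.ndarray:
    """|z_j| for penalized columns with the unpenalized block at its own fit."""
    free = ~mask
    if free.any():
        fit_free = np.linalg.solve(stats.V[np.ix_(free, free)], stats.b[free])
        z = stats.b[mask] - stats.V[np.ix_(mask, free)] @ fit_free
    else:
        z = stats.b[mask]
    return np.abs(z)


def univariate_estimates(stats: HazardStatistics) -> np.ndarray:
    """Per-column marginal estimates ``b_j / V_jj`` (the stepwise-SCAD init)."""
    d = np.diag(stats.V)
    return np.where(d > 0, stats.b / np.where(d > 0, d, 1.0), 0.0)


def lambda_max(
    stats: HazardStatistics,
    penalized_mask: np.ndarray,
    config: ScadConfig | None = None,
) -> float:
    """Smallest lambda at which all penalized coefficients are zero.

    For the lasso and exact-SCAD solvers, zero is a coordinate-wise solution
    for penalized column j iff |z_j| <= lambda (penalty derivative lambda at
    0+), so lambda_max = max_j |z_j|. For the stepwise solver the threshold
    is the linearised weight p'_lambda(|init_j|), giving per-column
    ``lambda_j = |z_j|`` when ``|init_j| <= |z_j|`` and
    ``((a-1)|z_j| + |init_j|) / a`` otherwise.
    """
    cfg = config or ScadConfig()
    mask = np.asarray(penalized_mask, dtype=bool)
    z = _partial_residuals_at_zero(stats, mask)
    if z.size == 0:
        return 1.0
    if cfg.penalty_kind == "scad" and cfg.solver == "stepwise":
        t = np.abs(univariate_estimates(stats))[mask]
        lam_j = np.where(t <= z, z, ((cfg.a - 1.0) * z + t) / cfg.a)
        lmax = float(lam_j.max(initial=0.0))
    else:
        lmax = float(z.max(initial=0.0))
    return lmax if lmax > 0 else 1.0


def default_lambda_grid(lmax: float, n_lambdas: int, min_ratio: float) -> np.ndarray:
    # tiny inflation so the first grid point really zeroes everything despite
    # floating-point roundoff in the partial residuals
    return np.geomspace(lmax * (1 + 1e-6), lmax * min_ratio, n_lambdas)


def _coefficient_path(V, b, mask, grid, cfg: ScadConfig, init=None):
    """Warm-started path over a descending lambda grid (zero start).

    ``init`` carries the linearisation point for the stepwise solver; when
    omitted it is the univariate estimates of the supplied statistics.
    """
    V = np.ascontiguousarray(V, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    mask = np.ascontiguousarray(mask, dtype=bool)
    lasso = cfg.penalty_kind == "lasso"
    stepwise = cfg.penalty_kind == "scad" and cfg.solver == "stepwise"
    if stepwise and init is None:
        d = np.diag(V)
        init = np.where(d > 0, b / np.where(d > 0, d, 1.0), 0.0)
    beta = np.zeros_like(b)
    path = np.empty((grid.size, b.size))
    all_converged = True
    for i, lam in enumerate(grid):
        lam = float(lam)
        if lasso:
            lamvec = np.where(mask, lam, 0.0)
            conv = _cd_weighted_lasso(V, b, beta, lamvec, cfg.max_iter, cfg.tol)
        elif stepwise:
            ref = np.abs(init)
            conv = True
            for _ in range(cfg.nsteps):
                lamvec = np.where(mask, scad_derivative(np.where(mask, ref, 0.0), lam, cfg.a), 0.0)
                conv = _cd_weighted_lasso(V, b, beta, lamvec, cfg.max_iter, cfg.tol) and conv
                ref = np.abs(beta)  # re-linearise for any further steps
        else:
            conv = _cd_sweeps(V, b, beta, mask, lam, cfg.a, lasso, cfg.max_iter, cfg.tol)
        all_converged &= bool(conv)
        path[i] = beta
    return path, all_converged


def _make_folds(status: np.ndarray, n_folds: int, seed: int):
    """Seeded status-stratified partition; every fold must contain events."""
    n = status.shape[0]
    if n < 2 * n_folds:
        raise ValueError("need at least 2 subjects per fold")
    for attempt in range(10):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(seed + attempt) % 2**31
        )
        folds = list(skf.split(np.zeros(n), status))
        ok = all(
            status[tr].sum() >= 1 and status[te].sum() >= 1 for tr, te in folds
        )
        if ok:
            return folds
    raise ValueError("could not build a fold partition with events in every fold")


def _cross_validate_core(
    Q: np.ndarray,
    time: np.ndarray,
    status: np.ndarray,
    mask: np.ndarray,
    cfg: ScadConfig,
    seed: int,
    folds=None,
):
    stats = hazard_statistics(Q, time, status)
    if cfg.lambda_grid is not None:
        grid = cfg.lambda_grid
    else:
        grid = default_lambda_grid(
            lambda_max(stats, mask, cfg), cfg.n_lambdas, cfg.lambda_min_ratio
        )
    if folds is None:
        folds = _make_folds(np.asarray(status), cfg.n_folds, seed)
    cv_loss = np.zeros(grid.size)
    conv_ok = True
    for train, test in folds:
        st_tr = hazard_statistics(Q[train], time[train], status[train])
        st_te = hazard_statistics(Q[test], time[test], status[test])
        path, conv = _coefficient_path(st_tr.V, st_tr.b, mask, grid, cfg)
        conv_ok &= conv
        # held-out loss of the quadratic pseudo-likelihood per lambda
        cv_loss += 0.5 * np.einsum("ij,jk,ik->i", path, st_te.V, path) - path @ st_te.b
    best = int(np.argmin(cv_loss))  # ties resolve to the largest lambda
    full_path, conv_full = _coefficient_path(stats.V, stats.b, mask, grid, cfg)
    n_selected = np.count_nonzero(full_path[:, mask], axis=1)
    curve = pd.DataFrame(
        {"lambda": grid, "cv_loss": cv_loss, "n_selected": n_selected}
    )
    return full_path[best], float(grid[best]), curve, conv_ok and conv_full, stats


def cross_validate(
    data: SurvivalDataset,
    s1: ScreenResult,
    config: ScadConfig | None = None,
    seed: int = 0,
    folds=None,
) -> ScadFit:
    """K-fold cross-validated SCAD fit over the screened mediator set.

    Folds are a seeded random partition stratified by event status (redrawn
    up to 10 times if a fold lacks events); per fold, the warm-started
    descending-lambda path is fitted on the training statistics and scored by
    the held-out loss ``beta'V_test beta/2 - b_test'beta`` summed over folds.
    The final coefficients come from refitting the whole data at the winning
    lambda, and the selected set S2 is the mediators with nonzero coefficient.
    """
    cfg = config or ScadConfig()
    design = data.design(s1.selected_indices)
    mask = (
        np.ones(design.m, dtype=bool)
        if cfg.penalize_all
        else design.column_roles == ROLE_MEDIATOR
    )
    coef, lam_star, curve, converged, _ = _cross_validate_core(
        design.Q, data.time, data.status, mask, cfg, seed, folds=folds
    )
    med_cols = design.mediator_columns
    nz = med_cols[np.abs(coef[med_cols]) > 0]
    selected = np.sort(design.mediator_indices[nz])
    if not converged:
        logger.warning("SCAD path had non-converged points (max_iter=%d)", cfg.max_iter)
    return ScadFit(
        coefficients=coef,
        selected=selected,
        lambda_star=lam_star,
        cv_curve=curve,
        design=design,
        screen=s1,
        converged=converged,
    )


class ScadAdditiveHazardsCV(BaseEstimator):
    """sklearn-style SCAD-penalized additive-hazards model with CV lambda.

    ``fit(X, y, penalize=None)`` takes a generic design matrix and survival
    ``y`` (``(time, status)`` pair, 2-column array, or structured array);
    ``penalize`` is a boolean mask of columns carrying the penalty (default:
    all columns).

    Attributes
    ----------
    coef_ : ndarray
    lambda_ : float
    cv_curve_ : DataFrame with columns (lambda, cv_loss, n_selected)
    selected_ : ndarray of penalized-column indices with nonzero coefficient
    """

    def __init__(
        self,
        a: float = 3.7,
        n_lambdas: int = 50,
        lambda_min_ratio: float = 1e-3,
        cv: int = 5,
        max_iter: int = 500,
        tol: float = 1e-7,
        penalty: str = "scad",
        solver: str = "stepwise",
        random_state: int = 0,
    ):
        self.a = a
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.max_iter = max_iter
        self.tol = tol
        self.penalty = penalty
        self.solver = solver
        self.random_state = random_state

    def fit(self, X, y, penalize=None):
        X = np.asarray(X, dtype=float)
        time, status = as_survival_y(y)
        mask = (
            np.ones(X.shape[1], dtype=bool)
            if penalize is None
            else np.asarray(penalize, dtype=bool)
        )
        cfg = ScadConfig(
            a=self.a,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            n_folds=self.cv,
            max_iter=self.max_iter,
            tol=self.tol,
            penalty_kind=self.penalty,
            solver=self.solver,
        )
        coef, lam, curve, converged, _ = _cross_validate_core(
            X, time, np.asarray(status), mask, cfg, int(self.random_state)
        )
        self.coef_ = coef
        self.lambda_ = lam
        self.cv_curve_ = curve
        self.selected_ = np.flatnonzero(mask & (np.abs(coef) > 0))
        self.converged_ = converged
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_
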