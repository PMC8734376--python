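"""Lin–Ying least-squares estimation of the additive hazards model.

The semiparametric additive hazards model writes the conditional hazard of
subject ``i`` as ``lambda_i(t) = lambda_0(t) + P' Q_i`` where ``Q_i`` collects
the regressors (exposure, covariates, mediators) and ``lambda_0`` is an
unspecified baseline. With counting process ``N_i(t) = I(T_i <= t, delta_i=1)``
and at-risk indicator ``Y_i(t) = I(T_i >= t)``, the Lin–Ying pseudo-score is
linear in ``P``::

    U(P) = b - V P,
    b = (1/n) sum_i \\int (Q_i - Qbar(t)) dN_i(t),
    V = (1/n) sum_i \\int Y_i(t) (Q_i - Qbar(t))^{x2} dt,

with ``Qbar(t)`` the at-risk average of the regressors. Both integrals reduce
to finite sums over the ordered distinct observed times because the integrands
are piecewise constant between them; :func:`hazard_statistics` evaluates these
sums exactly (no time grid). The estimator solves ``V P = b``, equivalently
minimises the least-squares-type loss ``L(P) = P'VP/2 - b'P``, and its
covariance is the sandwich ``V^{-1} D V^{-1} / n`` where ``D`` is the average
outer product of the per-subject score increments at event times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .data import DesignBundle, SurvivalDataset, as_survival_y

__all__ = [
    "HazardStatistics",
    "HazardFit",
    "hazard_statistics",
    "compute_statistics",
    "solve_statistics",
    "fit_unpenalized",
    "marginal_mediator_fit",
    "marginal_hazard_all",
    "LinYingAdditiveHazards",
]

logger = logging.getLogger("medhaz")

#: Maximum tolerated condition number of V before a fit is refused.
COND_LIMIT = 1e12


@dataclass(frozen=True)
class HazardStatistics:
    """Sufficient statistics ``(b, V, D)`` of the Lin–Ying score.

    ``b`` and ``V`` define the score ``U(P) = b - V P``; ``D`` is the average
    squared centred score increment at event times, used for the sandwich
    covariance. All three are per-subject averages, so pooling two copies of
    the same cohort leaves them unchanged.
    """

    b: np.ndarray
    V: np.ndarray
    D: np.ndarray
    n: int


@dataclass(frozen=True)
class HazardFit:
    """An unpenalized additive-hazards fit with sandwich standard errors."""

    estimates: np.ndarray
    covariance: np.ndarray
    std_errors: np.ndarray
    statistics: HazardStatistics
    design: DesignBundle | None = None

    @property
    def gamma(self) -> float:
        """Exposure coefficient (direct-effect rate difference)."""
        return float(self.estimates[self.design.exposure_column])

    @property
    def gamma_se(self) -> float:
        return float(self.std_errors[self.design.exposure_column])

    def mediator_estimates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (original mediator indices, beta-hat, beta SE) by role tag."""
        cols = self.design.mediator_columns
        return (
            self.design.mediator_indices[cols],
            self.estimates[cols],
            self.std_errors[cols],
        )


def _risk_set_tables(time: np.ndarray, status: np.ndarray, *mats: np.ndarray):
    """Sort by time and build suffix-sum tables over distinct times.

    Returns ``(t, d, u, n_at_risk, w, tidx, sorted_mats, suffix_tables)``
    where for each input matrix ``A`` the suffix table row ``j`` holds
    ``sum_{i: T_i >= u_j} A_i`` and ``w_j = (u_j - u_{j-1}) / n_at_risk_j``.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = status[order].astype(bool)
    u, start = np.unique(t, return_index=True)
    n = t.shape[0]
    n_at_risk = n - start
    delta = np.diff(u, prepend=0.0)
    w = delta / n_at_risk
    tidx = np.searchsorted(u, t)
    sorted_mats = []
    suffix_tables = []
    for A in mats:
        As = A[order]
        suffix = np.cumsum(As[::-1], axis=0)[::-1]
        sorted_mats.append(As)
        suffix_tables.append(suffix[start])
    return t, d, u, n_at_risk, w, tidx, sorted_mats, suffix_tables


def hazard_statistics(Q: np.ndarray, time: np.ndarray, status: np.ndarray) -> HazardStatistics:
    """Compute ``(b, V, D)`` for an arbitrary regressor matrix.

    The time integrals are evaluated exactly as finite sums over the ordered
    distinct observed times (the integrand is piecewise constant in between),
    over ``[0, max observed time]``. Tied subjects all belong to the risk set
    at their shared time. The result is invariant to subject ordering.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2:
        raise ValueError("Q must be a 2-d regressor matrix")
    n, m = Q.shape
    if n < 2:
        raise ValueError("at least two subjects are required")
    if not np.all(np.isfinite(Q)):
        raise ValueError("regressor matrix contains NaN or infinite values")
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("time must be finite and strictly positive")
    if int(status.sum()) < 1:
        raise ValueError("no observed failures: at least one event is required")

    t, d, _, n_at_risk, w, tidx, (Qs,), (C,) = _risk_set_tables(time, status, Q)

    # V = (1/n) [ sum_i T_i Q_i Q_i' - sum_j (delta_j / n_j) S1_j S1_j' ]
    # because subject i is at risk on [0, T_i] and S1_j / n_j = Qbar(u_j).
    V = (Qs.T * t) @ Qs - (C.T * w) @ C
    V /= n
    V = 0.5 * (V + V.T)

    Qbar_at = C[tidx] / n_at_risk[tidx][:, None]
    E = Qs[d] - Qbar_at[d]
    b = E.sum(axis=0) / n
    D = (E.T @ E) / n
    D = 0.5 * (D + D.T)
    return HazardStatistics(b=b, V=V, D=D, n=n)


def compute_statistics(data: SurvivalDataset, regressors: DesignBundle) -> HazardStatistics:
    """Dataset-level wrapper: statistics for a design built from ``data``."""
    if regressors.Q.shape[0] != data.n:
        raise ValueError("design does not align with dataset")
    return hazard_statistics(regressors.Q, data.time, data.status)


def _diagnose_singular(V: np.ndarray, names) -> str:
    _, _, vt = np.linalg.svd(V)
    null = np.abs(vt[-1])
    offenders = np.flatnonzero(null > 0.1 * null.max())
    labels = [names[j] if names else str(j) for j in offenders]
    return ", ".join(labels)


def solve_statistics(
    stats: HazardStatistics,
    design: DesignBundle | None = None,
    cond_limit: float = COND_LIMIT,
) -> HazardFit:
    """Solve ``V P = b`` and attach the sandwich covariance.

    Refuses ill-conditioned ``V`` (condition number above ``cond_limit``),
    naming the columns implicated by the smallest singular vector; no
    pseudo-inverse fallback, because silent rank deficiency would corrupt the
    downstream Sobel standard errors.
    """
    V, b = stats.V, stats.b
    names = design.names if design is not None else None
    sv = np.linalg.svd(V, compute_uv=False)
    if sv[-1] <= 0 or sv[0] > cond_limit * sv[-1]:
        raise np.linalg.LinAlgError(
            "V is singular or ill-conditioned "
            f"(cond ~ {np.inf if sv[-1] <= 0 else sv[0] / sv[-1]:.3g}); "
            f"offending columns: {_diagnose_singular(V, names)}"
        )
    est = np.linalg.solve(V, b)
    grad = V @ est - b
    tol = 1e-8 * (1.0 + np.abs(b).max(initial=0.0))
    if np.abs(grad).max(initial=0.0) > tol:
        raise RuntimeError("linear solve failed the score-equation check")
    Vinv = np.linalg.inv(V)
    cov = Vinv @ stats.D @ Vinv / stats.n
    cov = 0.5 * (cov + cov.T)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return HazardFit(estimates=est, covariance=cov, std_errors=se, statistics=stats, design=design)


def fit_unpenalized(data: SurvivalDataset, regressors: DesignBundle) -> HazardFit:
    """Unpenalized Lin–Ying fit of the additive hazards model."""
    stats = compute_statistics(data, regressors)
    return solve_statistics(stats, design=regressors)


def marginal_mediator_fit(data: SurvivalDataset, k: int) -> HazardFit:
    """Additive-hazards fit on the three-block design ``(X, Z, M_k)``.

    The per-mediator building block of the naive baseline and of the
    outcome-side screening statistic.
    """
    if not 0 <= int(k) < data.n_mediators:
        raise IndexError(f"mediator index {k} out of range [0, {data.n_mediators})")
    return fit_unpenalized(data, data.design([int(k)]))


def marginal_hazard_all(data: SurvivalDataset) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised marginal fits ``(X, Z, M_k)`` for every mediator ``k``.

    Exploits the block structure: the ``(X, Z)`` sub-blocks of ``b``, ``V``
    and ``D`` are shared across mediators, and the mediator cross terms are
    suffix-sum computations of cost O(n p). Returns ``(beta_hat, beta_se)``
    of length ``p`` with sandwich standard errors, matching a loop of
    :func:`marginal_mediator_fit` to solver precision.
    """
    if data.n_events < 1:
        raise ValueError("no observed failures: at least one event is required")
    n = data.n
    B = np.column_stack([data.exposure[:, None], data.covariates])
    M = data.mediators
    p = M.shape[1]
    qb = B.shape[1]

    t, d, _, n_at_risk, w, tidx, (Bs, Ms), (CB, CM) = _risk_set_tables(
        data.time, data.status, B, M
    )

    V_BB = ((Bs.T * t) @ Bs - (CB.T * w) @ CB) / n
    V_BM = ((Bs.T * t) @ Ms - (CB.T * w) @ CM) / n
    V_MM = (np.einsum("i,ij,ij->j", t, Ms, Ms) - np.einsum("j,jk,jk->k", w, CM, CM)) / n

    nr = n_at_risk[tidx][:, None]
    EB = Bs[d] - (CB[tidx] / nr)[d]
    EM = Ms[d] - (CM[tidx] / nr)[d]
    b_B = EB.sum(axis=0) / n
    b_M = EM.sum(axis=0) / n
    D_BB = (EB.T @ EB) / n
    D_BM = (EB.T @ EM) / n
    D_MM = np.einsum("ij,ij->j", EM, EM) / n

    mb = qb + 1
    Vk = np.empty((p, mb, mb))
    Vk[:, :qb, :qb] = V_BB
    Vk[:, :qb, qb] = V_BM.T
    Vk[:, qb, :qb] = V_BM.T
    Vk[:, qb, qb] = V_MM
    Dk = np.empty_like(Vk)
    Dk[:, :qb, :qb] = D_BB
    Dk[:, :qb, qb] = D_BM.T
    Dk[:, qb, :qb] = D_BM.T
    Dk[:, qb, qb] = D_MM
    bk = np.empty((p, mb))
    bk[:, :qb] = b_B
    bk[:, qb] = b_M

    est = np.linalg.solve(Vk, bk[..., None])[..., 0]
    Vinv = np.linalg.inv(Vk)
    cov = Vinv @ Dk @ Vinv / n
    beta_hat = est[:, qb]
    beta_se = np.sqrt(np.clip(cov[:, qb, qb], 0.0, None))
    return beta_hat, beta_se


class LinYingAdditiveHazards(BaseEstimator):
    """sklearn-style unpenalized additive-hazards regressor.

    Parameters
    ----------
    cond_limit : float
        Condition-number guard on the ``V`` matrix.

    Attributes
    ----------
    coef_ : ndarray of shape (m,)
        Estimated rate differences per regressor column.
    covariance_ : ndarray of shape (m, m)
        Lin–Ying sandwich covariance of ``coef_``.
    std_errors_ : ndarray of shape (m,)
    statistics_ : HazardStatistics

    Examples
    --------
    >>> est = LinYingAdditiveHazards().fit(Q, (time, status))
    >>> est.coef_
    """

    def __init__(self, cond_limit: float = COND_LIMIT):
        self.cond_limit = cond_limit

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        time, status = as_survival_y(y)
        stats = hazard_statistics(X, time, status)
        fit = solve_statistics(stats, cond_limit=self.cond_limit)
        self.coef_ = fit.estimates
        self.covariance_ = fit.covariance
        self.std_errors_ = fit.std_errors
        self.statistics_ = stats
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Linear hazard increment ``P' Q`` per subject."""
        return np.asarray(X, dtype=float) @ self.coef_
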