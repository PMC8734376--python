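"""Indirect-effect testing and effect decomposition.

For each candidate mediator ``M_k`` the mediation pathway has two legs:

* the exposure leg ``M_k = c_k + alpha_k X + vartheta' Z + e_k`` (ordinary
  least squares), and
* the outcome leg, the mediator's coefficient ``beta_k`` in the additive
  hazards model fitted jointly on ``(X, Z, M_S2)``.

The per-mediator indirect effect is the product ``alpha_k * beta_k``, tested
with the Sobel normal approximation

    SE(ab) = sqrt(a^2 se_b^2 + b^2 se_a^2),
    p = 2 * (1 - Phi(|ab| / SE)),

with Benjamini–Hochberg (independent hypotheses) or Benjamini–Yekutieli
(arbitrary dependence) step-up adjustment across the tested set. Because
hazards are additive, the counterfactual hazard difference when the exposure
moves from x to x* decomposes exactly as

    TE = gamma (x*-x) + (sum_k alpha_k beta_k)(x*-x) = DE + IE.

The full procedure (screen -> SCAD -> Sobel/BH) and two reference baselines
(the naive per-mediator analysis without selection, and the joint-significance
test variant) live here as well.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .data import SurvivalDataset, as_survival_y
from .hazard import HazardFit, fit_unpenalized, marginal_hazard_all
from .scad import ScadConfig, ScadFit, cross_validate
from .screening import ScreenResult, screen, subset_size

__all__ = [
    "AlphaFit",
    "MediationRecord",
    "EffectDecomposition",
    "ProcedureConfig",
    "ProcedureResult",
    "fit_alpha",
    "fit_alpha_all",
    "sobel_test",
    "adjust_pvalues",
    "refit_and_test",
    "decompose",
    "run_procedure",
    "naive_method",
    "joint_significance_test",
    "records_to_frame",
    "SurvivalMediation",
]

logger = logging.getLogger("medhaz")

WALD_Z = 1.96  # 95% Wald interval multiplier


@dataclass(frozen=True)
class AlphaFit:
    """OLS fit of one mediator on (1, X, Z)."""

    alpha_hat: float
    alpha_se: float
    intercept: float
    covariate_effects: np.ndarray
    degenerate: bool = False  # zero residual variance (exact linear mediator)


@dataclass(frozen=True)
class MediationRecord:
    """Per-mediator inference from the post-selection refit."""

    mediator: str
    index: int
    alpha_hat: float
    alpha_se: float
    beta_hat: float
    beta_se: float
    ie_hat: float
    sobel_se: float
    p_raw: float
    p_bh: float
    p_by: float
    ci_low: float
    ci_high: float
    significant: bool


@dataclass(frozen=True)
class EffectDecomposition:
    """TE = DE + IE for an exposure contrast x -> x*."""

    te: float
    de: float
    ie_total: float
    exposure_contrast: float
    de_ci: tuple[float, float] | None = None
    te_ci: tuple[float, float] | None = None
    te_marginal: float | None = None  # gamma from the mediator-free fit


def records_to_frame(records) -> pd.DataFrame:
    """Tidy table of mediation records (one row per mediator)."""
    cols = [
        "mediator",
        "index",
        "ie_hat",
        "ci_low",
        "ci_high",
        "p_raw",
        "p_bh",
        "p_by",
        "sobel_se",
        "beta_hat",
        "beta_se",
        "alpha_hat",
        "alpha_se",
        "significant",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


# --------------------------------------------------------------------------
# alpha leg (OLS)
# --------------------------------------------------------------------------

def _alpha_design(data: SurvivalDataset) -> np.ndarray:
    return np.column_stack(
        [np.ones(data.n), data.exposure[:, None], data.covariates]
    )


def fit_alpha(data: SurvivalDataset, k: int) -> AlphaFit:
    """OLS of mediator ``k`` on ``(1, X, Z)`` with classical standard errors."""
    if not 0 <= int(k) < data.n_mediators:
        raise IndexError(f"mediator index {k} out of range")
    if np.ptp(data.exposure) == 0:
        raise ValueError("exposure is constant; alpha-path model undefined")
    A = _alpha_design(data)
    ncol = A.shape[1]
    G = A.T @ A
    sv = np.linalg.svd(G, compute_uv=False)
    if sv[-1] <= 0 or sv[0] > 1e12 * sv[-1]:
        raise np.linalg.LinAlgError("collinear (X, Z) design in the alpha-path model")
    y = data.mediators[:, int(k)]
    coef = np.linalg.solve(G, A.T @ y)
    resid = y - A @ coef
    dof = data.n - ncol
    if dof <= 0:
        raise ValueError("not enough subjects for the alpha-path model")
    rss = float(resid @ resid)
    sigma2 = rss / dof
    Ginv = np.linalg.inv(G)
    se = float(np.sqrt(max(sigma2 * Ginv[1, 1], 0.0)))
    degenerate = sigma2 <= 1e-12 * max(float(y @ y) / data.n, 1.0)
    if degenerate:
        logger.warning("mediator %d is an exact linear function of (X, Z)", k)
    return AlphaFit(
        alpha_hat=float(coef[1]),
        alpha_se=se,
        intercept=float(coef[0]),
        covariate_effects=coef[2:],
        degenerate=degenerate,
    )


def fit_alpha_all(data: SurvivalDataset) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised alpha-leg OLS for every mediator: (alpha_hat, alpha_se)."""
    if np.ptp(data.exposure) == 0:
        raise ValueError("exposure is constant; alpha-path model undefined")
    A = _alpha_design(data)
    ncol = A.shape[1]
    G = A.T @ A
    Ginv = np.linalg.inv(G)
    coef = Ginv @ (A.T @ data.mediators)  # (ncol, p)
    resid = data.mediators - A @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    dof = data.n - ncol
    if dof <= 0:
        raise ValueError("not enough subjects for the alpha-path model")
    sigma2 = rss / dof
    se = np.sqrt(np.clip(sigma2 * Ginv[1, 1], 0.0, None))
    return coef[1].copy(), se


# --------------------------------------------------------------------------
# Sobel test and multiplicity adjustment
# --------------------------------------------------------------------------

def sobel_test(alpha_hat, alpha_se, beta_hat, beta_se):
    """Sobel product test of H0: alpha*beta = 0.

    Returns ``(ie_hat, sobel_se, p_raw)`` with
    ``sobel_se = sqrt(alpha^2 se_beta^2 + beta^2 se_alpha^2)`` and a two-sided
    normal p-value. A degenerate zero SE is only tolerated at the null point
    (ie_hat = 0, where p = 1). Scalar in, scalar out; arrays broadcast.
    """
    a = np.asarray(alpha_hat, dtype=float)
    sa = np.asarray(alpha_se, dtype=float)
    b = np.asarray(beta_hat, dtype=float)
    sb = np.asarray(beta_se, dtype=float)
    if np.any(sa < 0) or np.any(sb < 0):
        raise ValueError("standard errors must be nonnegative")
    ie = a * b
    se = np.sqrt(a * a * sb * sb + b * b * sa * sa)
    if np.any((se == 0) & (ie != 0)):
        raise ValueError("degenerate Sobel variance with nonzero indirect effect")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.abs(ie) / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * sps.norm.sf(z)
    p = np.where(se == 0, 1.0, p)
    if ie.ndim == 0:
        return float(ie), float(se), float(p)
    return ie, se, p


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """BH or BY step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "by": "fdr_by"}.get(method.lower())
    if key is None:
        raise ValueError("method must be 'bh' or 'by'")
    return multipletests(p, method=key)[1]


def joint_significance_test(alpha_p, beta_p):
    """Joint-significance p-value: max of the two per-leg p-values."""
    pa = np.asarray(alpha_p, dtype=float)
    pb = np.asarray(beta_p, dtype=float)
    if np.any((pa < 0) | (pa > 1)) or np.any((pb < 0) | (pb > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.maximum(pa, pb)
    return float(out) if out.ndim == 0 else out


def _z_pvalue(est, se):
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.abs(est) / np.where(se > 0, se, 1.0), np.inf)
    z = np.where((se == 0) & (est == 0), 0.0, z)
    return 2.0 * sps.norm.sf(z)


# --------------------------------------------------------------------------
# post-selection refit + testing
# --------------------------------------------------------------------------

def refit_and_test(
    data: SurvivalDataset,
    s2,
    adjust: str = "bh",
    alpha_level: float = 0.05,
    test: str = "sobel",
) -> tuple[list[MediationRecord], HazardFit | None]:
    """Sobel-test the SCAD-selected mediators after an unpenalized refit.

    One joint additive-hazards refit on ``(X, Z, M_S2)`` supplies every
    ``beta_k`` and its sandwich SE (penalized estimates are biased and carry
    no tractable SE, so the refit is the inferential fit); the alpha leg is
    per-mediator OLS. Both BH- and BY-adjusted p-values are recorded;
    ``significant`` flags the chosen adjustment against ``alpha_level``.
    ``test="joint"`` swaps the Sobel p-value for the joint-significance
    max-p (baseline comparison); Sobel SEs and CIs are still reported.

    Returns ``(records, joint_fit)``; an empty selection short-circuits to
    ``([], None)``.
    """
    s2 = np.sort(np.asarray(s2, dtype=np.intp).ravel())
    if s2.size == 0:
        logger.info("empty selected set: nothing to test")
        return [], None
    if s2.size >= data.n_events:
        raise ValueError(
            f"{s2.size} selected mediators but only {data.n_events} events; "
            "increase the penalty (larger lambda) before the refit"
        )
    design = data.design(s2)
    joint = fit_unpenalized(data, design)
    med_idx, beta_hat, beta_se = joint.mediator_estimates()

    rows = []
    for pos, k in enumerate(med_idx):
        af = fit_alpha(data, int(k))
        ie, se, p_sobel = sobel_test(af.alpha_hat, af.alpha_se, beta_hat[pos], beta_se[pos])
        if test == "joint":
            p_raw = joint_significance_test(
                _z_pvalue(af.alpha_hat, af.alpha_se),
                _z_pvalue(beta_hat[pos], beta_se[pos]),
            )
        else:
            p_raw = p_sobel
        rows.append(
            dict(
                mediator=data.mediator_names[int(k)],
                index=int(k),
                alpha_hat=af.alpha_hat,
                alpha_se=af.alpha_se,
                beta_hat=float(beta_hat[pos]),
                beta_se=float(beta_se[pos]),
                ie_hat=ie,
                sobel_se=se,
                p_raw=float(p_raw),
                ci_low=ie - WALD_Z * se,
                ci_high=ie + WALD_Z * se,
            )
        )
    p_raws = np.array([r["p_raw"] for r in rows])
    p_bh = adjust_pvalues(p_raws, "bh")
    p_by = adjust_pvalues(p_raws, "by")
    p_sig = p_bh if adjust.lower() == "bh" else p_by
    records = [
        MediationRecord(
            **row, p_bh=float(p_bh[i]), p_by=float(p_by[i]), significant=bool(p_sig[i] < alpha_level)
        )
        for i, row in enumerate(rows)
    ]
    return records, joint


def decompose(
    gamma_hat: float,
    records,
    x: float = 0.0,
    x_star: float = 1.0,
    gamma_se: float | None = None,
    te_marginal: float | None = None,
    te_marginal_se: float | None = None,
) -> EffectDecomposition:
    """Exact additive decomposition TE = DE + IE for contrast x -> x*.

    ``DE = gamma (x*-x)``, ``IE = sum_k alpha_k beta_k (x*-x)``; their sum is
    the model-based total effect. ``te_marginal`` optionally carries the
    exposure coefficient of the mediator-free fit — a finite-sample
    diagnostic for the same quantity estimated without the mediators.
    """
    contrast = float(x_star) - float(x)
    if contrast == 0:
        warnings.warn("x_star equals x: all effects are zero", UserWarning, stacklevel=2)
    de = float(gamma_hat) * contrast
    ie_total = float(sum(r.ie_hat for r in records)) * contrast
    de_ci = None
    if gamma_se is not None:
        half = WALD_Z * float(gamma_se) * abs(contrast)
        de_ci = (de - half, de + half)
    te_ci = None
    te_m = None
    if te_marginal is not None:
        te_m = float(te_marginal) * contrast
        if te_marginal_se is not None:
            half = WALD_Z * float(te_marginal_se) * abs(contrast)
            te_ci = (te_m - half, te_m + half)
    return EffectDecomposition(
        te=de + ie_total,
        de=de,
        ie_total=ie_total,
        exposure_contrast=contrast,
        de_ci=de_ci,
        te_ci=te_ci,
        te_marginal=te_m,
    )


# --------------------------------------------------------------------------
# full procedure
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProcedureConfig:
    """Everything the end-to-end procedure needs besides the data."""

    screen_stat: str = "exposure_correlation"
    d: int | None = None
    scad: ScadConfig = field(default_factory=ScadConfig)
    adjust: str = "bh"
    alpha_level: float = 0.05
    contrast: tuple[float, float] = (0.0, 1.0)
    test: str = "sobel"
    seed: int = 0


@dataclass
class ProcedureResult:
    """All intermediates of one end-to-end run."""

    screen: ScreenResult
    scad: ScadFit
    records: list[MediationRecord]
    decomposition: EffectDecomposition
    joint_fit: HazardFit | None
    marginal_fit: HazardFit
    config: ProcedureConfig

    @property
    def significant(self) -> list[str]:
        return [r.mediator for r in self.records if r.significant]

    def records_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def run_procedure(data: SurvivalDataset, config: ProcedureConfig | None = None) -> ProcedureResult:
    """Screen -> SCAD with CV -> refit + Sobel/BH -> decomposition.

    Deterministic given (data, config): all randomness (the CV folds) is
    driven by ``config.seed``. Stage failures propagate with the stage named.
    """
    cfg = config or ProcedureConfig()
    try:
        d = cfg.d if cfg.d is not None else subset_size(data.n)
        s1 = screen(data, statistic=cfg.screen_stat, d=d)
    except Exception as exc:
        raise type(exc)(f"screening stage: {exc}") from exc
    try:
        scad_fit = cross_validate(data, s1, config=cfg.scad, seed=cfg.seed)
    except Exception as exc:
        raise type(exc)(f"penalized-selection stage: {exc}") from exc
    try:
        records, joint = refit_and_test(
            data, scad_fit.selected, adjust=cfg.adjust, alpha_level=cfg.alpha_level, test=cfg.test
        )
    except Exception as exc:
        raise type(exc)(f"mediation-testing stage: {exc}") from exc
    marginal = fit_unpenalized(data, data.design([]))  # mediator-free total effect
    if joint is not None:
        gamma, gamma_se = joint.gamma, joint.gamma_se
    else:
        gamma, gamma_se = marginal.gamma, marginal.gamma_se
    x, x_star = cfg.contrast
    decomp = decompose(
        gamma,
        records,
        x=x,
        x_star=x_star,
        gamma_se=gamma_se,
        te_marginal=marginal.gamma,
        te_marginal_se=marginal.gamma_se,
    )
    logger.info(
        "procedure: screened %d -> selected %d -> significant %d",
        s1.selected_indices.size,
        scad_fit.selected.size,
        len([r for r in records if r.significant]),
    )
    return ProcedureResult(
        screen=s1,
        scad=scad_fit,
        records=records,
        decomposition=decomp,
        joint_fit=joint,
        marginal_fit=marginal,
        config=cfg,
    )


# --------------------------------------------------------------------------
# baselines
# --------------------------------------------------------------------------

def naive_method(data: SurvivalDataset, alpha_level: float = 0.05) -> pd.DataFrame:
    """Per-mediator marginal analysis with multiplicity over all p mediators.

    No variable selection: every mediator gets a marginal additive-hazards
    fit ``(X, Z, M_k)`` for the beta leg, the OLS alpha leg, a Sobel test,
    and BH/BY adjustment across all ``p`` hypotheses. Returns a tidy
    DataFrame (one row per mediator) with ``significant_bh``/``significant_by``
    flags at ``alpha_level``.
    """
    beta_hat, beta_se = marginal_hazard_all(data)
    alpha_hat, alpha_se = fit_alpha_all(data)
    ie, se, p_raw = sobel_test(alpha_hat, alpha_se, beta_hat, beta_se)
    p_bh = adjust_pvalues(p_raw, "bh")
    p_by = adjust_pvalues(p_raw, "by")
    return pd.DataFrame(
        {
            "mediator": data.mediator_names,
            "index": np.arange(data.n_mediators),
            "ie_hat": ie,
            "ci_low": ie - WALD_Z * se,
            "ci_high": ie + WALD_Z * se,
            "p_raw": p_raw,
            "p_bh": p_bh,
            "p_by": p_by,
            "sobel_se": se,
            "beta_hat": beta_hat,
            "beta_se": beta_se,
            "alpha_hat": alpha_hat,
            "alpha_se": alpha_se,
            "significant_bh": p_bh < alpha_level,
            "significant_by": p_by < alpha_level,
        }
    )


# --------------------------------------------------------------------------
# sklearn facade
# --------------------------------------------------------------------------

class SurvivalMediation(BaseEstimator):
    """sklearn-style front end for the full high-dimensional mediation procedure.

    ``fit(M, y, exposure=x, covariates=Z)`` runs screening, cross-validated
    SCAD selection and Sobel/FDR testing on mediator matrix ``M`` with
    survival outcome ``y`` (``(time, status)`` pair, 2-column array, or
    structured array).

    Attributes
    ----------
    screen_result_ : ScreenResult
    scad_fit_ : ScadFit
    records_ : list of MediationRecord
    results_ : DataFrame (one row per tested mediator)
    decomposition_ : EffectDecomposition
    selected_ : ndarray — SCAD-selected mediator indices (S2)
    significant_ : list of str — mediators passing the adjusted test
    """

    def __init__(
        self,
        screen_stat: str = "exposure_correlation",
        d: int | None = None,
        a: float = 3.7,
        n_lambdas: int = 50,
        lambda_min_ratio: float = 1e-3,
        cv: int = 5,
        penalty: str = "scad",
        solver: str = "stepwise",
        adjust: str = "bh",
        alpha_level: float = 0.05,
        contrast: tuple[float, float] = (0.0, 1.0),
        test: str = "sobel",
        random_state: int = 0,
    ):
        self.screen_stat = screen_stat
        self.d = d
        self.a = a
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.penalty = penalty
        self.solver = solver
        self.adjust = adjust
        self.alpha_level = alpha_level
        self.contrast = contrast
        self.test = test
        self.random_state = random_state

    def _config(self) -> ProcedureConfig:
        return ProcedureConfig(
            screen_stat=self.screen_stat,
            d=self.d,
            scad=ScadConfig(
                a=self.a,
                n_lambdas=self.n_lambdas,
                lambda_min_ratio=self.lambda_min_ratio,
                n_folds=self.cv,
                penalty_kind=self.penalty,
                solver=self.solver,
            ),
            adjust=self.adjust,
            alpha_level=self.alpha_level,
            contrast=tuple(self.contrast),
            test=self.test,
            seed=int(self.random_state),
        )

    def fit(self, X, y, exposure=None, covariates=None, mediator_names=None):
        if exposure is None:
            raise ValueError("the exposure vector is required (fit param `exposure`)")
        time, status = as_survival_y(y)
        data = SurvivalDataset(
            time=time,
            status=status,
            exposure=np.asarray(exposure, dtype=float),
            covariates=covariates,
            mediators=np.asarray(X, dtype=float),
            mediator_names=mediator_names,
        )
        res = run_procedure(data, self._config())
        self.result_ = res
        self.screen_result_ = res.screen
        self.scad_fit_ = res.scad
        self.records_ = res.records
        self.results_ = res.records_frame()
        self.decomposition_ = res.decomposition
        self.selected_ = res.scad.selected
        self.significant_ = res.significant
        self.n_features_in_ = data.n_mediators
        return self
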