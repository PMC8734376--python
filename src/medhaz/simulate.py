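"""Synthetic cohorts with high-dimensional mediators and an additive hazard.

The generator produces the study conditions used throughout the test suite
and benchmark studies:

* exposure ``X ~ Bernoulli(0.6)``; covariates ``Z1 ~ Bernoulli(0.3)``,
  ``Z2 ~ Uniform(0, 1)``;
* mediators ``M_k = c_k + alpha_k X + 0.4 Z1 + 0.4 Z2 + e_k`` with
  ``c_k ~ Uniform(0, 0.5)`` drawn per mediator and ``e_k ~ N(0, 1)``
  (optionally equicorrelated across mediators at correlation ``rho``);
* hazard ``lambda(t) = 5 t + gamma X + 0.4 Z1 + 0.4 Z2 + sum_k beta_k M_k``
  with ``gamma = 1``;
* default effect vectors ``alpha = (1, 1, 1, 1, 0.5, 0.5, 0, ...)`` and
  ``beta = (1, 1, 1, 1, 0, 0, 0.5, 0.5, 0, ...)`` — the true mediators
  (``alpha_k beta_k != 0``) are the first four;
* censoring ``C ~ Uniform(0, c)`` with ``c`` calibrated by Monte-Carlo
  bisection to hit a target censoring proportion.

Event times invert the cumulative hazard against a unit exponential draw:
``Lambda(t) = 2.5 t^2 + eta t`` with ``eta`` the linear predictor, so
``D = (-eta + sqrt(eta^2 + 10 E)) / 5``. When ``eta < 0`` the additive hazard
is negative near t = 0; the inversion is accepted whenever the cumulative
hazard at the solution is nonnegative (always true for this quadratic) and
the subject is redrawn otherwise, with the redraw rate logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import SurvivalDataset
from .mediation import ProcedureConfig, naive_method, run_procedure

__all__ = [
    "SimScenario",
    "SelectionScore",
    "EstimationScore",
    "StudyResult",
    "generate",
    "calibrate_censoring",
    "score_selection",
    "run_study",
]

logger = logging.getLogger("medhaz")

_CAL_SPAWN = 0xCA11B  # namespace tag for the calibration RNG stream


def _default_alpha(p: int) -> np.ndarray:
    a = np.zeros(p)
    a[0 : min(4, p)] = 1.0
    a[4 : min(6, p)] = 0.5
    return a


def _default_beta(p: int) -> np.ndarray:
    b = np.zeros(p)
    b[0 : min(4, p)] = 1.0
    b[6 : min(8, p)] = 0.5
    return b


@dataclass(frozen=True)
class SimScenario:
    """One simulation condition.

    ``alpha_true``/``beta_true`` default to the standard sparse patterns
    above; ``censor_upper`` may be pre-set to skip calibration (e.g. when
    running many replicates of the same condition).
    """

    n: int = 500
    p: int = 10_000
    alpha_true: np.ndarray | None = None
    beta_true: np.ndarray | None = None
    gamma_true: float = 1.0
    theta_true: tuple[float, float] = (0.4, 0.4)
    vartheta_true: tuple[float, float] = (0.4, 0.4)
    baseline_slope: float = 5.0
    exposure_prob: float = 0.6
    intercept_range: tuple[float, float] = (0.0, 0.5)
    target_censoring: float = 0.15
    censor_upper: float | None = None
    mediator_correlation: float = 0.0
    seed: int = 0

    def alphas(self) -> np.ndarray:
        a = _default_alpha(self.p) if self.alpha_true is None else np.asarray(self.alpha_true, float)
        if a.shape != (self.p,):
            raise ValueError("alpha_true must have length p")
        return a

    def betas(self) -> np.ndarray:
        b = _default_beta(self.p) if self.beta_true is None else np.asarray(self.beta_true, float)
        if b.shape != (self.p,):
            raise ValueError("beta_true must have length p")
        return b

    def truth(self) -> np.ndarray:
        """Indices of true mediators: alpha_k * beta_k != 0."""
        t = np.flatnonzero(self.alphas() * self.betas() != 0)
        return t


@dataclass(frozen=True)
class SelectionScore:
    """TPR / FP count / FDP of one selected set against the truth."""

    tpr: float
    fp: float
    fdp: float


@dataclass(frozen=True)
class EstimationScore:
    """Replicate-averaged indirect-effect estimation metrics for one mediator."""

    est_mean: float
    coverage: float
    emp_se: float
    est_se_mean: float
    n_selected: int


def _rng_for(scenario: SimScenario, stream: int | None = None) -> np.random.Generator:
    entropy = [int(scenario.seed)] if stream is None else [int(scenario.seed), int(stream)]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _invert_hazard(eta: np.ndarray, E: np.ndarray, slope: float) -> np.ndarray:
    # positive root of (slope/2) D^2 + eta D = E
    return (-eta + np.sqrt(eta * eta + 2.0 * slope * E)) / slope


def _draw_mediator_errors(rng, n, p, rho):
    e = rng.standard_normal((n, p))
    if rho > 0:
        shared = rng.standard_normal((n, 1))
        e = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * e
    return e


def generate(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> tuple[SurvivalDataset, np.ndarray]:
    """Draw one cohort; returns ``(dataset, true mediator indices)``.

    All randomness comes from ``rng`` (default: a generator seeded from
    ``scenario.seed``), so a fixed scenario and seed reproduce the dataset
    bit for bit. If ``scenario.censor_upper`` is unset, the censoring bound
    is calibrated first from an independent, fixed calibration stream.
    """
    if rng is None:
        rng = _rng_for(scenario)
    n, p = scenario.n, scenario.p
    alpha = scenario.alphas()
    beta = scenario.betas()
    slope = scenario.baseline_slope

    X = (rng.random(n) < scenario.exposure_prob).astype(float)
    Z = np.column_stack([(rng.random(n) < 0.3).astype(float), rng.random(n)])
    lo, hi = scenario.intercept_range
    c_k = rng.uniform(lo, hi, p)
    e = _draw_mediator_errors(rng, n, p, scenario.mediator_correlation)
    zshift = Z @ np.asarray(scenario.vartheta_true, float)
    M = c_k[None, :] + np.outer(X, alpha) + zshift[:, None] + e

    nz = np.flatnonzero(beta)
    eta = scenario.gamma_true * X + Z @ np.asarray(scenario.theta_true, float)
    if nz.size:
        eta = eta + M[:, nz] @ beta[nz]
    E = rng.exponential(1.0, n)
    D = _invert_hazard(eta, E, slope)

    # redraw subjects whose cumulative hazard at the solution is negative
    # (cannot occur for this quadratic inversion, but guard and count anyway)
    n_redraw = 0
    for _ in range(100):
        lam_cum = 0.5 * slope * D * D + eta * D
        bad = (lam_cum < -1e-12) | (D <= 0)
        nbad = int(bad.sum())
        if nbad == 0:
            break
        n_redraw += nbad
        e_new = _draw_mediator_errors(rng, nbad, p, scenario.mediator_correlation)
        M[bad] = c_k[None, :] + np.outer(X[bad], alpha) + zshift[bad, None] + e_new
        eta_bad = scenario.gamma_true * X[bad] + Z[bad] @ np.asarray(scenario.theta_true, float)
        if nz.size:
            eta_bad = eta_bad + M[np.ix_(bad, nz)] @ beta[nz]
        eta[bad] = eta_bad
        E[bad] = rng.exponential(1.0, nbad)
        D[bad] = _invert_hazard(eta[bad], E[bad], slope)
    if n_redraw:
        logger.info("generate: redrew %d subject(s) with negative cumulative hazard", n_redraw)
        if n_redraw > 0.01 * n:
            warnings.warn(
                f"{n_redraw} redraws (> 1% of subjects): the hazard is frequently negative",
                RuntimeWarning,
                stacklevel=2,
            )

    c = scenario.censor_upper
    if c is None:
        c = calibrate_censoring(scenario, scenario.target_censoring)
    C = np.full(n, np.inf) if np.isinf(c) else rng.uniform(0.0, c, n)
    T = np.minimum(D, C)
    delta = (D <= C).astype(int)
    data = SurvivalDataset(
        time=T,
        status=delta,
        exposure=X,
        covariates=Z,
        mediators=M,
        mediator_names=[f"M{k + 1}" for k in range(p)],
    )
    return data, scenario.truth()


def _event_time_sample(scenario: SimScenario, n_mc: int, rng: np.random.Generator) -> np.ndarray:
    """Uncensored event times for calibration, generating only the mediator
    columns that enter the hazard (the zero-beta columns cannot affect D).

    The mediator intercepts are drawn fresh for every Monte-Carlo subject so
    the sample follows the *marginal* event-time distribution across
    replicates (each replicate redraws its own intercepts)."""
    alpha = scenario.alphas()
    beta = scenario.betas()
    nz = np.flatnonzero(beta)
    X = (rng.random(n_mc) < scenario.exposure_prob).astype(float)
    Z = np.column_stack([(rng.random(n_mc) < 0.3).astype(float), rng.random(n_mc)])
    lo, hi = scenario.intercept_range
    c_k = rng.uniform(lo, hi, (n_mc, nz.size))
    e = _draw_mediator_errors(rng, n_mc, nz.size, scenario.mediator_correlation)
    zshift = Z @ np.asarray(scenario.vartheta_true, float)
    Mnz = c_k + np.outer(X, alpha[nz]) + zshift[:, None] + e
    eta = scenario.gamma_true * X + Z @ np.asarray(scenario.theta_true, float) + Mnz @ beta[nz]
    E = rng.exponential(1.0, n_mc)
    return _invert_hazard(eta, E, scenario.baseline_slope)


def calibrate_censoring(
    scenario: SimScenario,
    target: float | None = None,
    n_mc: int = 20_000,
    tol: float = 0.005,
) -> float:
    """Censoring bound ``c`` achieving the target censoring proportion.

    With ``C ~ U(0, c)``, the censoring probability given the event-time
    distribution is ``E[min(D, c)] / c`` — estimated on a fixed Monte-Carlo
    sample of ``n_mc`` event times drawn from a dedicated calibration stream
    (reproducible for a fixed scenario seed) and solved for ``c`` by Brent's
    method on an expanding bracket.
    """
    if target is None:
        target = scenario.target_censoring
    if not 0.05 < target < 0.95:
        raise ValueError("target censoring must lie in (0.05, 0.95)")
    rng = _rng_for(scenario, _CAL_SPAWN)
    D = _event_time_sample(scenario, n_mc, rng)

    def rate(c: float) -> float:
        return float(np.minimum(D, c).mean() / c)

    lo = max(float(np.min(D)) * 0.5, 1e-9)  # rate -> 1 as c -> 0
    hi = max(float(np.quantile(D, 0.99)), lo * 2)
    for _ in range(200):
        if rate(hi) < target:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the censoring bound from above")
    for _ in range(200):
        if rate(lo) > target:
            break
        lo *= 0.5
    else:
        raise RuntimeError("could not bracket the censoring bound from below")
    c = float(brentq(lambda x: rate(x) - target, lo, hi, xtol=1e-10, rtol=1e-12))
    achieved = rate(c)
    if abs(achieved - target) > tol:
        raise RuntimeError(
            f"censoring calibration landed at {achieved:.4f}, target {target:.4f}"
        )
    return c


def score_selection(selected, truth, p: int) -> SelectionScore:
    """TPR, FP count, and FDP of one selected set (FDP = 0 when empty)."""
    truth = np.asarray(truth, dtype=np.intp).ravel()
    if truth.size == 0:
        raise ValueError("empty truth set: scenario misconfigured")
    selected = np.asarray(selected, dtype=np.intp).ravel()
    if selected.size and (selected.min() < 0 or selected.max() >= p):
        raise ValueError("selected indices out of range")
    tp = np.intersect1d(selected, truth).size
    fp = selected.size - tp
    fdp = fp / selected.size if selected.size else 0.0
    return SelectionScore(tpr=tp / truth.size, fp=float(fp), fdp=float(fdp))


@dataclass
class StudyResult:
    """Replicate-averaged metrics for one scenario/method combination.

    ``selection`` has one row per adjustment (bh, by) with replicate-mean
    tpr / fp / fdp; ``estimation`` (proposed/joint methods only) reports
    per-mediator indirect-effect metrics over the replicates in which that
    mediator entered the SCAD-selected set.
    """

    selection: pd.DataFrame
    estimation: pd.DataFrame | None
    n_replicates: int
    method: str
    scenario: SimScenario
    censor_upper: float
    mean_censoring: float
    failures: list = field(default_factory=list)


def _replicate_proposed(data, truth, scenario, config, rep_seed, level, test):
    cfg = replace(config, seed=rep_seed, test=test)
    res = run_procedure(data, cfg)
    recs = res.records
    sig = {
        "bh": np.array([r.index for r in recs if r.p_bh < level], dtype=np.intp),
        "by": np.array([r.index for r in recs if r.p_by < level], dtype=np.intp),
    }
    alphabeta = scenario.alphas() * scenario.betas()
    est_rows = {}
    for r in recs:
        if r.index < 8:
            true_ie = alphabeta[r.index]
            est_rows[r.index] = (
                r.ie_hat,
                r.sobel_se,
                bool(r.ci_low <= true_ie <= r.ci_high),
            )
    return sig, est_rows


def _replicate_naive(data, level):
    df = naive_method(data, alpha_level=level)
    return {
        "bh": df.loc[df["significant_bh"], "index"].to_numpy(dtype=np.intp),
        "by": df.loc[df["significant_by"], "index"].to_numpy(dtype=np.intp),
    }


def _one_replicate(scenario, rep, method, config, level):
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), int(rep)]))
    data, truth = generate(scenario, rng=rng)
    rep_seed = int(np.random.SeedSequence([int(scenario.seed), int(rep), 1]).generate_state(1)[0] % 2**31)
    out = {"censoring": 1.0 - data.status.mean(), "truth": truth}
    if method == "naive":
        out["sig"] = _replicate_naive(data, level)
        out["est"] = None
    else:
        test = "joint" if method == "joint" else "sobel"
        sig, est = _replicate_proposed(data, truth, scenario, config, rep_seed, level, test)
        out["sig"] = sig
        out["est"] = est
    return out


def run_study(
    scenario: SimScenario,
    n_replicates: int,
    method: str = "proposed",
    config: ProcedureConfig | None = None,
    alpha_level: float = 0.05,
    n_jobs: int = 1,
) -> StudyResult:
    """Replicated simulation study of one scenario.

    Per-replicate seeds derive deterministically from ``scenario.seed`` and
    the replicate index, so results do not depend on worker count or
    replicate order. Replicate failures are recorded and excluded; more than
    5% failures aborts the study.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if method not in ("proposed", "naive", "joint"):
        raise ValueError("method must be proposed|naive|joint")
    cfg = config or ProcedureConfig()
    c = scenario.censor_upper
    if c is None:
        c = calibrate_censoring(scenario, scenario.target_censoring)
    scen = replace(scenario, censor_upper=c)

    def job(rep):
        try:
            return rep, _one_replicate(scen, rep, method, cfg, alpha_level), None
        except Exception as exc:  # pragma: no cover - failure bookkeeping
            return rep, None, f"replicate {rep}: {exc}"

    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(job)(r) for r in range(n_replicates))
    else:
        results = [job(r) for r in range(n_replicates)]
    results.sort(key=lambda t: t[0])

    failures = [msg for _, _, msg in results if msg is not None]
    if failures:
        logger.warning("%d replicate failure(s): %s", len(failures), failures[:3])
        if len(failures) > 0.05 * n_replicates:
            raise RuntimeError(f"too many replicate failures ({len(failures)}/{n_replicates})")
    reps = [out for _, out, msg in results if msg is None]

    truth = scen.truth()
    sel_rows = []
    for adj in ("bh", "by"):
        scores = [score_selection(out["sig"][adj], truth, scen.p) for out in reps]
        sel_rows.append(
            {
                "adjust": adj,
                "tpr": float(np.mean([s.tpr for s in scores])),
                "fp": float(np.mean([s.fp for s in scores])),
                "fdp": float(np.mean([s.fdp for s in scores])),
            }
        )
    selection = pd.DataFrame(sel_rows).set_index("adjust")

    estimation = None
    if method != "naive":
        alphabeta = scen.alphas() * scen.betas()
        rows = []
        for k in range(min(8, scen.p)):
            vals = [out["est"][k] for out in reps if out["est"] and k in out["est"]]
            if vals:
                ies = np.array([v[0] for v in vals])
                ses = np.array([v[1] for v in vals])
                cover = np.array([v[2] for v in vals])
                score = EstimationScore(
                    est_mean=float(ies.mean()),
                    coverage=float(cover.mean()),
                    emp_se=float(ies.std(ddof=1)) if ies.size > 1 else np.nan,
                    est_se_mean=float(ses.mean()),
                    n_selected=int(ies.size),
                )
            else:
                score = EstimationScore(np.nan, np.nan, np.nan, np.nan, 0)
            rows.append(
                {
                    "mediator": f"M{k + 1}",
                    "true_ie": alphabeta[k],
                    "est": score.est_mean,
                    "cp": score.coverage,
                    "emp_se": score.emp_se,
                    "est_se": score.est_se_mean,
                    "n_selected": score.n_selected,
                }
            )
        estimation = pd.DataFrame(rows).set_index("mediator")

    return StudyResult(
        selection=selection,
        estimation=estimation,
        n_replicates=len(reps),
        method=method,
        scenario=scen,
        censor_upper=float(c),
        mean_censoring=float(np.mean([out["censoring"] for out in reps])),
        failures=failures,
    )
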