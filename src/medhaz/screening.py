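"""Sure independence screening (SIS) of mediators.

With ``p >> n`` mediators the penalized fit cannot be applied directly, so the
first stage ranks mediators by a cheap marginal utility and keeps the top
``d = [2n / log n]`` (round half up) — double the classical ``[n / log n]``
because a mediator must relate to *both* the exposure and the outcome, and a
larger screened set protects against losing true mediators at this stage.

The default utility is the raw Pearson correlation between the exposure and
each mediator (the exposure side of the mediation pathway). An outcome-side
alternative — the standardized marginal additive-hazards coefficient of each
mediator — is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .data import SurvivalDataset
from .hazard import marginal_hazard_all

__all__ = ["ScreenResult", "subset_size", "screening_scores", "screen", "MediatorScreener"]

logger = logging.getLogger("medhaz")

STAT_XCORR = "exposure_correlation"
STAT_HAZARD = "marginal_hazard"
_STAT_ALIASES = {
    "exposure_correlation": STAT_XCORR,
    "xcorr": STAT_XCORR,
    "marginal_hazard": STAT_HAZARD,
    "hazard": STAT_HAZARD,
}


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the screening stage.

    ``selected_indices`` holds the ``min(d, p)`` mediators with largest
    absolute score, sorted by descending ``|score|`` with ties broken by
    ascending index (deterministic across platforms). Because the ranking is
    fixed, the screened set at size ``d`` is a prefix of the set at any larger
    size.
    """

    selected_indices: np.ndarray
    scores: np.ndarray
    d: int
    statistic_kind: str

    def to_frame(self, mediator_names=None):
        import pandas as pd

        p = self.scores.shape[0]
        names = mediator_names if mediator_names is not None else [f"M{k+1}" for k in range(p)]
        return pd.DataFrame(
            {
                "mediator": names,
                "score": self.scores,
                "selected": np.isin(np.arange(p), self.selected_indices),
            }
        )


def subset_size(n: int) -> int:
    """Screened-subset size ``d = [2n / log n]``, rounded half up, floored at 1.

    Round-half-up is the integer convention that maps a cohort of 833
    subjects to d = 248.
    """
    n = int(n)
    if n < 3:
        raise ValueError("subset_size requires n >= 3")
    return max(int(math.floor(2.0 * n / math.log(n) + 0.5)), 1)


def screening_scores(data: SurvivalDataset, statistic: str = STAT_XCORR) -> np.ndarray:
    """Per-mediator screening utility.

    ``exposure_correlation``: raw Pearson correlation between X and each
    mediator column (invariant to affine transforms of X). ``marginal_hazard``:
    z-statistic of the mediator coefficient in the marginal additive-hazards
    fit ``(X, Z, M_k)``. Zero-variance mediator columns score 0 (with a logged
    warning) rather than NaN.
    """
    kind = _STAT_ALIASES.get(statistic)
    if kind is None:
        raise ValueError(f"unknown screening statistic {statistic!r}")
    if data.n_mediators < 1:
        raise ValueError("screening requires at least one mediator")
    if kind == STAT_XCORR:
        x = data.exposure
        xc = x - x.mean()
        sx = math.sqrt(float(xc @ xc))
        if sx == 0:
            raise ValueError("exposure is constant; correlation screening undefined")
        M = data.mediators
        Mc = M - M.mean(axis=0)
        sm = np.sqrt(np.einsum("ij,ij->j", Mc, Mc))
        degenerate = sm <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = (xc @ Mc) / (sx * sm)
        if degenerate.any():
            logger.warning(
                "%d zero-variance mediator column(s) scored 0 in screening",
                int(degenerate.sum()),
            )
            scores[degenerate] = 0.0
        return scores
    beta, se = marginal_hazard_all(data)
    degenerate = ~(se > 0)
    if degenerate.any():
        logger.warning(
            "%d mediator(s) with degenerate marginal SE scored 0 in screening",
            int(degenerate.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(degenerate, 0.0, beta / np.where(degenerate, 1.0, se))
    return scores


def screen(data: SurvivalDataset, statistic: str = STAT_XCORR, d: int | None = None) -> ScreenResult:
    """Rank mediators and keep the top ``d`` by absolute score."""
    if d is None:
        d = subset_size(data.n)
    d = int(d)
    if d < 1:
        raise ValueError("d must be >= 1")
    scores = screening_scores(data, statistic)
    p = scores.shape[0]
    order = np.lexsort((np.arange(p), -np.abs(scores)))
    selected = order[: min(d, p)]
    return ScreenResult(
        selected_indices=selected,
        scores=scores,
        d=d,
        statistic_kind=_STAT_ALIASES[statistic],
    )


class MediatorScreener(SelectorMixin, BaseEstimator):
    """sklearn feature selector applying SIS to a mediator matrix.

    For the default exposure-correlation statistic, ``fit(M, exposure)``
    suffices. For the outcome-side statistic, pass the survival outcome and
    adjustment covariates via ``fit(M, exposure, survival=(time, status),
    covariates=Z)``.

    Attributes
    ----------
    scores_ : ndarray of shape (p,)
    result_ : ScreenResult
    """

    def __init__(self, statistic: str = STAT_XCORR, d: int | None = None):
        self.statistic = statistic
        self.d = d

    def fit(self, X, y=None, survival=None, covariates=None):
        M = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("the exposure vector must be passed as y")
        exposure = np.asarray(y, dtype=float)
        kind = _STAT_ALIASES.get(self.statistic)
        if kind == STAT_HAZARD:
            if survival is None:
                raise ValueError("marginal_hazard screening needs survival=(time, status)")
            time, status = survival
        else:
            # correlation screening never looks at the outcome; a placeholder
            # survival structure keeps SurvivalDataset validation happy.
            time = np.ones(M.shape[0])
            status = np.ones(M.shape[0], dtype=int)
        data = SurvivalDataset(
            time=np.asarray(time, dtype=float),
            status=status,
            exposure=exposure,
            covariates=covariates,
            mediators=M,
        )
        self.result_ = screen(data, statistic=self.statistic, d=self.d)
        self.scores_ = self.result_.scores
        self.n_features_in_ = M.shape[1]
        return self

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.result_.selected_indices] = True
        return mask
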