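"""Containers for right-censored survival data with high-dimensional mediators.

The package analyses per-subject records ``(T_i, delta_i, X_i, Z_i, M_i)``:

* ``T_i = min(D_i, C_i)`` — observed follow-up time, the earlier of the event
  time ``D_i`` and the censoring time ``C_i``;
* ``delta_i = I(D_i <= C_i)`` — event indicator (1 = event observed);
* ``X_i`` — scalar exposure (binary or continuous);
* ``Z_i`` — a small vector of adjustment covariates;
* ``M_i`` — a mediator vector whose dimension ``p`` may vastly exceed ``n``
  (e.g. DNA-methylation beta values).

:class:`SurvivalDataset` validates and stores these arrays;
:class:`DesignBundle` assembles the regressor matrix ``Q_i = (X_i, Z_i, M_S,i)``
for a chosen mediator subset ``S`` together with per-column role tags, which is
what the additive-hazards machinery consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ROLE_EXPOSURE",
    "ROLE_COVARIATE",
    "ROLE_MEDIATOR",
    "DesignBundle",
    "SurvivalDataset",
    "as_survival_y",
]

ROLE_EXPOSURE = "exposure"
ROLE_COVARIATE = "covariate"
ROLE_MEDIATOR = "mediator"


@dataclass(frozen=True)
class DesignBundle:
    """A regressor matrix plus per-column metadata.

    Attributes
    ----------
    Q : ndarray of shape (n, m)
        Per-subject regressor rows ``Q_i = (X_i, Z_i, M_S,i)``.
    column_roles : ndarray of str, shape (m,)
        One of ``"exposure"``, ``"covariate"``, ``"mediator"`` per column,
        consistent with construction order.
    mediator_indices : ndarray of int, shape (m,)
        Original mediator index for mediator columns, ``-1`` elsewhere.
    names : list of str
        Human-readable column names.
    """

    Q: np.ndarray
    column_roles: np.ndarray
    mediator_indices: np.ndarray
    names: list[str] = field(default_factory=list)

    @property
    def m(self) -> int:
        return self.Q.shape[1]

    @property
    def exposure_column(self) -> int:
        cols = np.flatnonzero(self.column_roles == ROLE_EXPOSURE)
        if cols.size != 1:
            raise ValueError("design does not contain exactly one exposure column")
        return int(cols[0])

    @property
    def covariate_columns(self) -> np.ndarray:
        return np.flatnonzero(self.column_roles == ROLE_COVARIATE)

    @property
    def mediator_columns(self) -> np.ndarray:
        return np.flatnonzero(self.column_roles == ROLE_MEDIATOR)


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or infinite values")
    return arr


@dataclass
class SurvivalDataset:
    """Aligned survival data for one cohort.

    All arrays share the leading dimension ``n``. ``time`` must be strictly
    positive and ``status`` binary; mediator names must be unique. A dataset
    with zero events can be constructed (e.g. after heavy filtering) but every
    model fit requires at least one observed failure and will refuse it.
    """

    time: np.ndarray
    status: np.ndarray
    exposure: np.ndarray
    covariates: np.ndarray | None = None
    mediators: np.ndarray | None = None
    mediator_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time", 1)
        n = self.time.shape[0]
        if np.any(self.time <= 0):
            raise ValueError("time must be strictly positive for all subjects")
        status = np.asarray(self.status)
        if status.shape != (n,):
            raise ValueError("status must align with time")
        if not np.isin(status, (0, 1)).all():
            raise ValueError("status must contain only 0/1 values")
        self.status = status.astype(np.int64)
        self.exposure = _as_float_array(self.exposure, "exposure", 1)
        if self.exposure.shape != (n,):
            raise ValueError("exposure must align with time")
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        self.covariates = _as_float_array(self.covariates, "covariates", 2)
        if self.covariates.shape[0] != n:
            raise ValueError("covariates must align with time")
        if self.mediators is None:
            self.mediators = np.empty((n, 0))
        self.mediators = _as_float_array(self.mediators, "mediators", 2)
        if self.mediators.shape[0] != n:
            raise ValueError("mediators must align with time")
        p = self.mediators.shape[1]
        if self.mediator_names is None:
            self.mediator_names = [f"M{k + 1}" for k in range(p)]
        self.mediator_names = [str(s) for s in self.mediator_names]
        if len(self.mediator_names) != p:
            raise ValueError("mediator_names must have one entry per mediator column")
        if len(set(self.mediator_names)) != p:
            raise ValueError("mediator_names must be unique")

    # -- basic shape accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_mediators(self) -> int:
        return self.mediators.shape[1]

    # -- derived structures ----------------------------------------------------
    def design(self, mediator_indices=None) -> DesignBundle:
        """Build ``Q_i = (X_i, Z_i, M_S,i)`` for mediator subset ``S``.

        ``mediator_indices=None`` selects *all* mediators; an empty sequence
        yields the mediator-free design used for the total-effect fit.
        Column order is exposure, covariates, then mediators in the order
        given — role tags follow the same order.
        """
        if mediator_indices is None:
            mediator_indices = np.arange(self.n_mediators)
        sel = np.asarray(mediator_indices, dtype=np.intp).ravel()
        if sel.size and (sel.min() < 0 or sel.max() >= self.n_mediators):
            raise IndexError("mediator index out of range")
        Q = np.column_stack(
            [self.exposure[:, None], self.covariates, self.mediators[:, sel]]
        )
        roles = np.array(
            [ROLE_EXPOSURE]
            + [ROLE_COVARIATE] * self.n_covariates
            + [ROLE_MEDIATOR] * sel.size
        )
        med_idx = np.concatenate(
            [np.full(1 + self.n_covariates, -1, dtype=np.intp), sel]
        )
        names = (
            ["exposure"]
            + [f"Z{j + 1}" for j in range(self.n_covariates)]
            + [self.mediator_names[k] for k in sel]
        )
        return DesignBundle(Q=Q, column_roles=roles, mediator_indices=med_idx, names=names)

    def subset(self, rows) -> "SurvivalDataset":
        """Row-subset (used by cross-validation folds)."""
        rows = np.asarray(rows)
        return replace(
            self,
            time=self.time[rows],
            status=self.status[rows],
            exposure=self.exposure[rows],
            covariates=self.covariates[rows],
            mediators=self.mediators[rows],
            mediator_names=list(self.mediator_names),
        )


def as_survival_y(y):
    """Coerce ``y`` into ``(time, status)`` arrays.

    Accepts a structured array with a time field (``time``/``T``) and an
    event field (``status``/``event``/``delta``), a two-column array
    ``[time, status]``, or a ``(time, status)`` pair. This mirrors the
    survival-``y`` conventions of scikit-survival so the estimators compose
    with sklearn tooling.
    """
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return np.asarray(y[0], dtype=float), np.asarray(y[1])
    arr = np.asarray(y)
    if arr.dtype.names:
        names = {n.lower(): n for n in arr.dtype.names}
        tkey = next((names[k] for k in ("time", "t", "futime") if k in names), None)
        skey = next(
            (names[k] for k in ("status", "event", "delta", "d") if k in names), None
        )
        if tkey is None or skey is None:
            raise ValueError(
                "structured survival y needs a time field and an event field; "
                f"got fields {arr.dtype.names}"
            )
        return arr[tkey].astype(float), arr[skey].astype(np.int64)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0], arr[:, 1].astype(np.int64)
    raise ValueError("y must be (time, status), a 2-column array, or structured")
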