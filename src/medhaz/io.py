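"""Delimited-text readers/writers and run manifests.

Datasets are rectangular delimited text (CSV or TSV, sniffed) with a header:
one row per subject, columns for time, status, exposure, optional covariates,
and mediators identified either by a shared name prefix (the natural fit for
methylation arrays, where probes start with ``cg``) or an explicit list.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SurvivalDataset

__all__ = ["ColumnMapping", "read_dataset", "write_dataset", "run_manifest"]

logger = logging.getLogger("medhaz")


@dataclass(frozen=True)
class ColumnMapping:
    """Where to find each model variable in the file's columns."""

    time: str = "time"
    status: str = "status"
    exposure: str = "exposure"
    covariates: tuple[str, ...] = ()
    mediator_prefix: str | None = None
    mediator_columns: tuple[str, ...] | None = None


def _resolve_mediators(df: pd.DataFrame, mapping: ColumnMapping, core: set[str]) -> list[str]:
    if mapping.mediator_columns is not None:
        med = list(mapping.mediator_columns)
        missing = [c for c in med if c not in df.columns]
        if missing:
            raise ValueError(f"mediator columns not in file: {missing[:5]}")
    elif mapping.mediator_prefix is not None:
        med = [c for c in df.columns if c.startswith(mapping.mediator_prefix) and c not in core]
    else:
        med = [c for c in df.columns if c not in core]
    if not med:
        raise ValueError("no mediator columns identified; check prefix/list")
    overlap = core.intersection(med)
    if overlap:
        raise ValueError(f"mediator columns overlap core columns: {sorted(overlap)}")
    return med


def read_dataset(path, mapping: ColumnMapping | None = None) -> SurvivalDataset:
    """Read a delimited-text dataset into a :class:`SurvivalDataset`.

    Rows missing time/status/exposure are dropped (count logged); missing
    mediator cells are mean-imputed per column (count logged). Non-numeric
    mediator cells and status values outside {0, 1} are errors.
    """
    mapping = mapping or ColumnMapping()
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    for name, col in (("time", mapping.time), ("status", mapping.status), ("exposure", mapping.exposure)):
        if col not in df.columns:
            raise ValueError(
                f"{name} column {col!r} not found; available: {list(df.columns)[:10]}..."
            )
    missing_cov = [c for c in mapping.covariates if c not in df.columns]
    if missing_cov:
        raise ValueError(f"covariate columns not in file: {missing_cov}")
    core = {mapping.time, mapping.status, mapping.exposure, *mapping.covariates}
    med_cols = _resolve_mediators(df, mapping, core)

    keep = df[[mapping.time, mapping.status, mapping.exposure]].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d row(s) with missing time/status/exposure", dropped)
    df = df.loc[keep].reset_index(drop=True)

    status = pd.to_numeric(df[mapping.status], errors="coerce")
    if status.isna().any() or not status.isin([0, 1]).all():
        bad = df[mapping.status][~status.isin([0, 1])].head(3).tolist()
        raise ValueError(f"status values outside {{0, 1}}: {bad}")

    M = df[med_cols].copy()
    numeric = M.apply(pd.to_numeric, errors="coerce")
    bad_cells = numeric.isna() & M.notna()
    if bad_cells.any().any():
        col = bad_cells.any(axis=0).idxmax()
        row = int(bad_cells[col].idxmax())
        raise ValueError(
            f"non-numeric mediator value {M.at[row, col]!r} at row {row}, column {col!r}"
        )
    n_missing = int(numeric.isna().sum().sum())
    if n_missing:
        logger.warning("mean-imputed %d missing mediator cell(s)", n_missing)
        numeric = numeric.fillna(numeric.mean())

    return SurvivalDataset(
        time=df[mapping.time].to_numpy(dtype=float),
        status=status.to_numpy(dtype=np.int64),
        exposure=pd.to_numeric(df[mapping.exposure]).to_numpy(dtype=float),
        covariates=df[list(mapping.covariates)].to_numpy(dtype=float)
        if mapping.covariates
        else None,
        mediators=numeric.to_numpy(dtype=float),
        mediator_names=med_cols,
    )


def write_dataset(data: SurvivalDataset, path, mapping: ColumnMapping | None = None) -> None:
    """Write a dataset as TSV with the standard column layout."""
    mapping = mapping or ColumnMapping()
    cov_names = list(mapping.covariates) or [f"Z{j + 1}" for j in range(data.n_covariates)]
    out = pd.DataFrame(
        {
            mapping.time: data.time,
            mapping.status: data.status,
            mapping.exposure: data.exposure,
        }
    )
    for j, name in enumerate(cov_names):
        out[name] = data.covariates[:, j]
    med = pd.DataFrame(data.mediators, columns=data.mediator_names)
    out = pd.concat([out, med], axis=1)
    out.to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_manifest(config, seed) -> dict:
    """Reproducibility manifest: package/library versions, config, its hash."""
    import importlib.metadata

    cfg = _jsonable(config)
    payload = json.dumps(cfg, sort_keys=True, default=str)
    return {
        "medhaz_version": importlib.metadata.version("medhaz"),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": int(seed) if seed is not None else None,
        "config": cfg,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
    }
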