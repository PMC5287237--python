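"""Reading, validation, preprocessing and resampling of growth-curve tables.

Plate-reader growth data are handled in a long format: one record per
(time, well) with the optical density (OD) reading and categorical
covariates (replicate/well id, strain background, stress condition and
optionally batch/study).  :class:`GrowthTable` wraps a pandas DataFrame
with this layout and records whether the OD column has already been
log2-transformed and baseline-normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ParseError, SchemaError, ValidationError

#: canonical column names; files may use anything and map onto these
CANONICAL_COLUMNS = ("time", "od", "replicate", "strain", "condition", "batch")

#: categorical columns that, together with ``replicate``, identify one curve
CURVE_KEY_CANDIDATES = ("replicate", "strain", "condition", "batch")


@dataclass
class GrowthTable:
    """Long-format growth observations.

    Parameters
    ----------
    data
        DataFrame with at least ``time`` and ``od`` columns; ``replicate``,
        ``strain``, ``condition`` and ``batch`` are recognized categorical
        covariates, and any further columns are carried along untouched.
    is_log
        True once ``od`` holds log2-transformed, baseline-normalized values.
    """

    data: pd.DataFrame
    is_log: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        df = self.data
        for col in ("time", "od"):
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} is missing")
            if not np.issubdtype(df[col].dtype, np.number):
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                row = int(bad[0]) if len(bad) else -1
                raise ParseError(f"column {col!r} is not numeric (first bad row: {row})")
        if (df["time"] < 0).any():
            raise ValidationError("negative time values present")
        if df["od"].isna().any():
            raise ValidationError("missing od values present")
        key = self.curve_key()
        if key:
            dup = df.duplicated(subset=key + ["time"])
        else:
            dup = df.duplicated(subset=["time"])
        if dup.any():
            row = df[dup].iloc[0]
            pair = tuple(row[k] for k in key) + (row["time"],)
            raise ValidationError(
                f"duplicate (replicate, time) pair {pair!r}: time values must be "
                "unique within each growth curve"
            )

    def curve_key(self) -> list[str]:
        """Columns that jointly identify a single growth curve."""
        return [c for c in CURVE_KEY_CANDIDATES if c in self.data.columns]

    # -- conveniences ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def od(self) -> np.ndarray:
        return self.data["od"].to_numpy(dtype=float)

    def groupby_curve(self):
        key = self.curve_key()
        if not key:
            return [((), self.data)]
        return self.data.groupby(key, sort=True, observed=True)

    def with_data(self, df: pd.DataFrame, *, is_log: bool | None = None) -> "GrowthTable":
        return GrowthTable(df.reset_index(drop=True), self.is_log if is_log is None else is_log)


def load_growth_table(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str = ",",
    is_log: bool = False,
) -> GrowthTable:
    """Load a delimited long-format table into a :class:`GrowthTable`.

    ``column_map`` maps canonical names (``time``, ``od``, ``replicate``, ...)
    onto the column names used in the file; canonical names already present
    pass through.  Unknown columns are preserved as extra covariates.
    """
    df = pd.read_csv(path, sep=sep)
    column_map = dict(column_map or {})
    for canonical, actual in column_map.items():
        if actual not in df.columns:
            raise SchemaError(f"mapped column {actual!r} (for {canonical!r}) not in file")
    df = df.rename(columns={v: k for k, v in column_map.items()})
    for col in ("time", "od"):
        if col not in df.columns:
            raise SchemaError(f"no column mapped to {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = int(df.index[coerced.isna()][0])
            raise ParseError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = coerced
    return GrowthTable(df, is_log=is_log)


def save_growth_table(table: GrowthTable, path, *, sep: str = ",") -> None:
    """Write the table back to delimited text (column order preserved)."""
    table.data.to_csv(path, sep=sep, index=False)


def log_and_baseline_normalize(
    table: GrowthTable, n_head: int = 10, degree: int = 5
) -> GrowthTable:
    """log2-transform OD and anchor each (strain, condition) group at zero.

    The OD column is replaced by log2(od).  Within each (strain, condition)
    group — pooling every replicate — a polynomial of the given degree is
    least-squares fit to all raw points at the first ``n_head`` distinct time
    points, its value at time 0 is taken as the starting log2-OD of the
    group, and that value is subtracted from every observation in the group.
    All groups therefore start at (approximately) zero.
    """
    if table.is_log:
        df = table.data.copy()
        logod = df["od"].to_numpy(dtype=float)
    else:
        od = table.od
        if (od <= 0).any():
            raise DomainError("od must be strictly positive for log2 transform")
        df = table.data.copy()
        logod = np.log2(od)
    df["od"] = logod

    group_cols = [c for c in ("strain", "condition", "batch") if c in df.columns]
    groups = df.groupby(group_cols, sort=False, observed=True).indices if group_cols else {
        (): np.arange(len(df))
    }
    out = df["od"].to_numpy(dtype=float).copy()
    for _, idx in groups.items():
        t = df["time"].to_numpy(dtype=float)[idx]
        y = out[idx]
        head_times = np.unique(t)[:n_head]
        if len(head_times) < degree + 1:
            raise ValidationError(
                f"need at least degree+1={degree + 1} distinct head time points, "
                f"got {len(head_times)}"
            )
        mask = np.isin(t, head_times)
        # numpy Polynomial.fit uses a scaled domain for conditioning
        poly = np.polynomial.Polynomial.fit(t[mask], y[mask], deg=degree)
        out[idx] = y - poly(0.0)
    df["od"] = out
    return GrowthTable(df, is_log=True)


def subsample_timepoints(
    table: GrowthTable, interval: float, *, tol: float = 1e-6
) -> GrowthTable:
    """Keep only records whose time is a multiple of ``interval`` hours."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    t = table.times
    frac = np.abs(t / interval - np.round(t / interval)) * interval
    mask = frac < tol
    if not mask.any():
        raise ValidationError(
            f"no time points lie on a {interval}-h grid; try a smaller interval"
        )
    return table.with_data(table.data.loc[mask])


def train_test_split(
    table: GrowthTable, train_frac: float = 0.8, seed: int = 0
) -> tuple[GrowthTable, GrowthTable]:
    """Random record-level split within each growth curve.

    Each curve's records are partitioned without replacement so that about
    ``train_frac`` of them land in the training set.  The two outputs
    partition the input exactly and the split is reproducible given ``seed``.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    df = table.data
    key = table.curve_key()
    train_mask = np.zeros(len(df), dtype=bool)
    if key:
        groups = df.groupby(key, sort=True, observed=True).indices
        items = sorted(groups.items(), key=lambda kv: str(kv[0]))
    else:
        items = [((), np.arange(len(df)))]
    for _, idx in items:
        idx = np.asarray(idx)
        n_train = int(round(train_frac * len(idx)))
        chosen = rng.permutation(len(idx))[:n_train]
        train_mask[idx[chosen]] = True
    return (
        table.with_data(df.loc[train_mask]),
        table.with_data(df.loc[~train_mask]),
    )
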