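"""Subject-level survival data container and delimited-text I/O.

The package-wide event coding is fixed: ``event == 1`` means the failure was
observed, ``event == 0`` means the observation was right-censored.  Files
using other column names are adapted through a column map at read time, so
the internal convention never varies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = ["SurvivalSample", "read_sample", "write_table", "read_table"]


@dataclass
class SurvivalSample:
    """Observed right-censored survival data ``(Y, event, X[, Z])``.

    Parameters
    ----------
    time : array of positive floats
        Observed time: the minimum of the failure and censoring times.
    event : array of {0, 1}
        1 if the failure was observed, 0 if censored.
    exposure : array of floats
        Treatment / exposure variable; binary 0/1 or continuous.
    covariates : DataFrame, optional
        Additional measured covariates, one row per subject.
    """

    time: np.ndarray
    event: np.ndarray
    exposure: np.ndarray
    covariates: pd.DataFrame | None = None
    ingest_report: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.exposure = np.asarray(self.exposure, dtype=float)
        n = self.time.shape[0]
        if self.event.shape[0] != n or self.exposure.shape[0] != n:
            raise ValidationError("time, event and exposure must have equal length")
        for name, arr in (("time", self.time), ("event", self.event), ("exposure", self.exposure)):
            if np.any(pd.isna(arr)):
                raise ValidationError(f"missing values in '{name}'")
        if np.any(self.time <= 0):
            row = int(np.flatnonzero(self.time <= 0)[0])
            raise ValidationError(f"non-positive time at row {row}")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicator must be 0 (censored) or 1 (event)")
        self.event = self.event.astype(int)
        if self.event.sum() == 0:
            raise ValidationError("no events: at least one subject must have event == 1")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates).reset_index(drop=True)
            if len(self.covariates) != n:
                raise ValidationError("covariates must have one row per subject")
            if self.covariates.columns.duplicated().any():
                raise ValidationError("duplicate covariate column names")
            if self.covariates.isna().any().any():
                raise ValidationError("missing values in covariates")

    @property
    def n(self) -> int:
        return int(self.time.shape[0])

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event, "exposure": self.exposure})
        if self.covariates is not None:
            df = pd.concat([df, self.covariates], axis=1)
        return df


def read_sample(path, column_map: dict | None = None, delimiter: str | None = None) -> SurvivalSample:
    """Read a delimited text file (CSV/TSV with header) into a :class:`SurvivalSample`.

    ``column_map`` maps the internal names ``time``, ``event``, ``exposure``
    and optionally ``covariates`` (a list of column names) onto the file's
    columns.  Rows with missing values in any mapped column are rejected; the
    retained/rejected counts are reported in ``sample.ingest_report`` and
    always sum to the number of input rows.
    """
    column_map = dict(column_map or {})
    time_col = column_map.get("time", "time")
    event_col = column_map.get("event", "event")
    exp_col = column_map.get("exposure", "exposure")
    cov_cols = list(column_map.get("covariates", []))

    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    for col in [time_col, event_col, exp_col, *cov_cols]:
        if col not in df.columns:
            raise ConfigurationError(f"column '{col}' not found in {path} (has: {list(df.columns)})")

    used = df[[time_col, event_col, exp_col, *cov_cols]]
    keep = ~used.isna().any(axis=1)
    n_rejected = int((~keep).sum())
    kept = used[keep]
    if len(kept) == 0:
        raise ValidationError("all rows rejected: every row has a missing mapped field")

    bad_time = kept.index[kept[time_col] <= 0]
    if len(bad_time):
        raise ValidationError(f"non-positive time at input row {int(bad_time[0])}")

    sample = SurvivalSample(
        time=kept[time_col].to_numpy(float),
        event=kept[event_col].to_numpy(),
        exposure=kept[exp_col].to_numpy(float),
        covariates=kept[cov_cols] if cov_cols else None,
    )
    sample.ingest_report = {"n_input": int(len(df)), "n_retained": int(len(kept)), "n_rejected": n_rejected}
    return sample


def write_table(table: pd.DataFrame, path) -> None:
    """Write a rectangular result table as CSV (header + rows, 10 significant digits)."""
    table = pd.DataFrame(table)
    if table.empty:
        raise ValidationError("refusing to write an empty table")
    if table.columns.duplicated().any():
        raise ValidationError("duplicate column names in result table")
    table.to_csv(path, index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path)
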