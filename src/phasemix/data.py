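"""Longitudinal data containers and long-format table I/O.

A cohort is a collection of patient series: per patient, strictly increasing
visit times (days) and one biomarker value per visit.  Long-format delimited
text (one row per observation) is the single on-disk dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import InvalidSeriesError, ParseError

__all__ = ["PatientSeries", "Cohort", "read_long_table", "write_long_table",
           "cohort_to_frame"]


@dataclass(frozen=True)
class PatientSeries:
    """One subject's visit times (days) and biomarker values.

    Invariants (checked at construction): at least two visits, strictly
    increasing finite times, finite values, equal lengths.
    """

    patient_id: object
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise InvalidSeriesError(
                f"patient {self.patient_id!r}: times and values must be "
                f"1-d and equally long"
            )
        if len(times) < 2:
            raise InvalidSeriesError(
                f"patient {self.patient_id!r}: at least 2 observations required"
            )
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
            raise InvalidSeriesError(
                f"patient {self.patient_id!r}: non-finite time or value"
            )
        if np.any(np.diff(times) <= 0):
            raise InvalidSeriesError(
                f"patient {self.patient_id!r}: times must be strictly increasing"
            )

    @property
    def n_obs(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of :class:`PatientSeries`."""

    patients: tuple
    t_max: float = field(init=False)

    def __init__(self, patients: Iterable[PatientSeries]):
        patients = tuple(patients)
        if len(patients) < 1:
            raise InvalidSeriesError("cohort must contain at least one patient")
        object.__setattr__(self, "patients", patients)
        object.__setattr__(
            self, "t_max", float(max(p.times[-1] for p in patients))
        )

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientSeries]:
        return iter(self.patients)

    def __getitem__(self, i) -> PatientSeries:
        return self.patients[i]

    @property
    def n_obs_total(self) -> int:
        return sum(p.n_obs for p in self.patients)


_DEFAULT_COLUMNS = {"patient_id": "patient_id", "time": "time", "value": "value"}


def read_long_table(path, column_map: Mapping[str, str] | None = None,
                    logger=None) -> Cohort:
    """Read a delimited long-format table (one row per observation).

    The delimiter (comma or tab) is sniffed from the header line.
    ``column_map`` remaps the logical names ``patient_id``, ``time``,
    ``value`` to the file's column names.  Rows are grouped by patient and
    sorted by time; patients with fewer than two usable visits are dropped
    with a warning.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")

    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")
    return cohort_from_frame(df, patient_col=cols["patient_id"],
                             time_col=cols["time"], value_col=cols["value"],
                             logger=logger, source=str(path))


def cohort_from_frame(df: pd.DataFrame, patient_col="patient_id",
                      time_col="time", value_col="value",
                      logger=None, source="<frame>") -> Cohort:
    """Build a :class:`Cohort` from a long-format DataFrame."""
    for col in (time_col, value_col):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"{source}: non-numeric {col!r} in rows {list(bad[:10])}"
            )
        df = df.assign(**{col: coerced})
    df = df.dropna(subset=[time_col, value_col])

    dup = df.duplicated(subset=[patient_col, time_col], keep=False)
    if dup.any():
        rows = list(df.index[dup][:10])
        raise ParseError(
            f"{source}: duplicate (patient, time) rows at index {rows}"
        )

    series = []
    for pid, grp in df.groupby(patient_col, sort=False):
        grp = grp.sort_values(time_col)
        if len(grp) < 2:
            if logger is not None:
                logger.warning(
                    "patient %r has fewer than 2 observations; dropped", pid
                )
            continue
        series.append(PatientSeries(pid, grp[time_col].to_numpy(),
                                    grp[value_col].to_numpy()))
    if not series:
        raise ParseError(f"{source}: no patient with >= 2 observations")
    return Cohort(series)


def write_long_table(cohort: Cohort, path) -> None:
    """Write a cohort as long-format CSV; floats are written with enough
    digits (%.17g) to round-trip bit-exactly."""
    cohort_to_frame(cohort).to_csv(path, index=False, float_format="%.17g")


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-format DataFrame (patient_id, time, value) for a cohort."""
    return pd.DataFrame({
        "patient_id": np.concatenate(
            [np.repeat(p.patient_id, p.n_obs) for p in cohort]),
        "time": np.concatenate([p.times for p in cohort]),
        "value": np.concatenate([p.values for p in cohort]),
    })
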