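"""Readers, writers and validated containers for the pipeline's tables.

Canonical on-disk dialect is TSV (tab-delimited, "." decimal, UTF-8, header
row required); CSV is accepted via ``sep=","``. Missing values are never
imputed — any NaN in a numeric table is a hard error, because the gradient
pipeline assumes complete matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ParcellationMetadata, ValidationError

__all__ = [
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "CohortTable",
    "read_parcellation",
    "write_parcellation",
    "read_time_series",
    "write_time_series",
    "read_matrix",
    "write_matrix",
    "read_cohort",
    "write_cohort",
    "read_gradient_table",
    "write_gradient_table",
]

_SYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """Parcel time series for one subject: ``values`` is T x P."""

    values: np.ndarray = field(repr=False)
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValidationError("time series must be a 2-D timepoints x parcels array")
        if v.shape[0] < 3:
            raise ValidationError(f"need >= 3 timepoints, got {v.shape[0]}")
        if not np.isfinite(v).all():
            t, p = np.argwhere(~np.isfinite(v))[0]
            raise ValidationError(
                f"non-finite value at timepoint {t + 1}, parcel {p + 1} "
                f"(subject {self.subject_id})"
            )
        object.__setattr__(self, "values", v)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Square symmetric parcel x parcel matrix of r or Fisher-z values."""

    values: np.ndarray = field(repr=False)
    value_kind: str = "pearson_r"  # {"pearson_r", "fisher_z"}
    subject_id: str = "group_average"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"connectivity matrix must be square, got {v.shape}")
        if not np.isfinite(v).all():
            raise ValidationError("connectivity matrix contains non-finite values")
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValidationError(f"matrix asymmetric: max |m - m.T| = {asym:.3g}")
        if self.value_kind not in ("pearson_r", "fisher_z"):
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if self.value_kind == "pearson_r" and off.size and np.abs(off).max() > 1 + 1e-12:
            raise ValidationError("pearson_r entries must lie in [-1, 1] off-diagonal")
        object.__setattr__(self, "values", v)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


_COHORT_COLUMNS = ["subject_id", "group", "cesd", "hamd", "age", "sex", "education"]


@dataclass(frozen=True)
class CohortTable:
    """Per-subject group labels, clinical scores and demographics."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = set(_COHORT_COLUMNS) - set(t.columns)
        if missing:
            raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
        dup = t.loc[t["subject_id"].duplicated(), "subject_id"].tolist()
        if dup:
            raise ValidationError(f"duplicate subject_ids: {sorted(set(dup))}")
        groups = sorted(set(t["group"]))
        if len(groups) != 2:
            raise ValidationError(f"group must have exactly 2 levels, got {groups}")
        cesd = t["cesd"].to_numpy()
        if ((cesd < 0) | (cesd > 60)).any():
            bad = t.loc[(t["cesd"] < 0) | (t["cesd"] > 60), "subject_id"].tolist()
            raise ValidationError(f"CESD outside [0, 60] for subjects {bad}")
        if (t["hamd"].to_numpy() < 0).any():
            raise ValidationError("HAMD scores must be >= 0")
        bad_sex = set(t["sex"]) - {"M", "F"}
        if bad_sex:
            raise ValidationError(f"sex must be M or F, got {sorted(bad_sex)}")
        t.reset_index(drop=True, inplace=True)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.table["group"]))

    def subjects_in(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "subject_id"].tolist()


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def read_parcellation(path: str | Path, sep: str = "\t") -> ParcellationMetadata:
    """Read a parcellation metadata TSV into a validated container."""
    return ParcellationMetadata(_read_table(path, sep))


def write_parcellation(meta: ParcellationMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def read_time_series(
    path: str | Path,
    metadata: ParcellationMetadata | None = None,
    subject_id: str | None = None,
    sep: str = "\t",
) -> TimeSeriesMatrix:
    """Read a timepoints x parcels TSV, validating against the atlas.

    Columns must be in parcel_id order. Empty cells are rejected with the
    offending row/column named.
    """
    df = _read_table(path, sep)
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValidationError(
            f"empty/missing cell at data row {r + 1}, column {df.columns[c]!r} in {path}"
        )
    if metadata is not None and df.shape[1] != metadata.n_parcels:
        raise ValidationError(
            f"column count mismatch: expected {metadata.n_parcels} parcels, "
            f"found {df.shape[1]} in {path}"
        )
    sid = subject_id if subject_id is not None else Path(path).stem
    return TimeSeriesMatrix(df.to_numpy(dtype=float), subject_id=sid)


def write_time_series(ts: TimeSeriesMatrix, path: str | Path) -> None:
    cols = [f"parcel_{i + 1}" for i in range(ts.n_parcels)]
    pd.DataFrame(ts.values, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_matrix(
    path: str | Path,
    value_kind: str = "fisher_z",
    subject_id: str | None = None,
    sep: str = "\t",
) -> ConnectivityMatrix:
    """Read a square connectivity matrix (header row of parcel ids)."""
    df = _read_table(path, sep)
    v = df.to_numpy(dtype=float)
    if v.shape[0] != v.shape[1]:
        raise ValidationError(f"matrix in {path} is not square: {v.shape}")
    sid = subject_id if subject_id is not None else Path(path).stem
    return ConnectivityMatrix(v, value_kind=value_kind, subject_id=sid)


def write_matrix(m: ConnectivityMatrix, path: str | Path) -> None:
    cols = [f"parcel_{i + 1}" for i in range(m.n_parcels)]
    pd.DataFrame(m.values, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_cohort(path: str | Path, sep: str = "\t") -> CohortTable:
    df = _read_table(path, sep)
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


def write_gradient_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format gradient score table.

    Expected columns: subject_id, parcel_id (1-based), component_index
    (1-based), gradient_score.
    """
    required = {"subject_id", "parcel_id", "component_index", "gradient_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"gradient table missing columns: {sorted(missing)}")
    if df.duplicated(["subject_id", "parcel_id", "component_index"]).any():
        raise ValidationError("duplicate (subject, parcel, component) rows")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gradient_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = _read_table(path, sep)
    if df.duplicated(["subject_id", "parcel_id", "component_index"]).any():
        raise ValidationError("duplicate (subject, parcel, component) rows")
    if (df["component_index"] < 1).any():
        raise ValidationError("component_index must be >= 1")
    return df
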