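"""Subject-level functional connectivity: Pearson r, Fisher z, group average.

Pipeline order is fixed: per-subject Pearson correlation of parcel time
series, Fisher z-transform, then arithmetic averaging of the z matrices
within group. The Fisher-z diagonal is set to 0 (arctanh(1) is undefined and
self-affinity carries no information for the downstream kernel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import ValidationError
from .io import ConnectivityMatrix, TimeSeriesMatrix

__all__ = ["pearson_fc", "fisher_z", "group_average", "GroupAverageMatrix"]


@dataclass(frozen=True)
class GroupAverageMatrix:
    """Entrywise mean of a stack of subject Fisher-z matrices."""

    matrix: ConnectivityMatrix
    n_subjects_averaged: int
    group: str = "all"

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values


def pearson_fc(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation matrix of the parcel time series.

    The diagonal is recorded as 1 but is excluded from the Fisher transform
    and from sparsification ranking downstream.
    """
    v = ts.values
    sd = v.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValidationError(
            f"zero-variance time series for parcel(s) {[int(i) + 1 for i in zero]} "
            f"(subject {ts.subject_id})"
        )
    r = np.corrcoef(v, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # symmetrize away rounding noise
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, value_kind="pearson_r", subject_id=ts.subject_id)


def fisher_z(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher z-transform (arctanh) of the off-diagonal correlations."""
    if m.value_kind != "pearson_r":
        raise ValidationError(f"fisher_z expects pearson_r input, got {m.value_kind}")
    r = m.values.copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    at_unit = np.argwhere((np.abs(r) >= 1.0) & off)
    if len(at_unit):
        i, j = at_unit[0]
        raise ValidationError(
            f"|r| = 1 off-diagonal between parcels {i + 1} and {j + 1}: "
            "Fisher z is infinite"
        )
    z = np.arctanh(r, where=off, out=np.zeros_like(r))
    return ConnectivityMatrix(z, value_kind="fisher_z", subject_id=m.subject_id)


def group_average(
    ms: list[ConnectivityMatrix], group: str = "all"
) -> GroupAverageMatrix:
    """Arithmetic entrywise mean of subject matrices (same value kind)."""
    if not ms:
        raise ValidationError("group_average needs at least one matrix")
    shapes = {m.values.shape for m in ms}
    if len(shapes) > 1:
        raise ValidationError(f"shape mismatch across matrices: {sorted(shapes)}")
    kinds = {m.value_kind for m in ms}
    if len(kinds) > 1:
        raise ValidationError(f"mixed value kinds: {sorted(kinds)}")
    mean = np.mean([m.values for m in ms], axis=0)
    avg = ConnectivityMatrix(mean, value_kind=ms[0].value_kind, subject_id="group_average")
    return GroupAverageMatrix(avg, n_subjects_averaged=len(ms), group=group)
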