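"""Procrustes alignment of gradient sets to a shared reference template.

Eigenvector sign and rotational ambiguity make raw gradient scores
incomparable across subjects; each subject's P x k gradient matrix is
therefore rotated (orthogonal Procrustes, reflections permitted) onto a
common reference. No scaling and no centering are applied: gradient
magnitudes carry the lambda/(1-lambda) diffusion weighting whose
group-level contraction is the quantity of interest, and scaling would
erase it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .atlas import ValidationError
from .gradients import GradientSet

__all__ = [
    "ReferenceTemplate",
    "AlignedGradientSet",
    "build_reference",
    "procrustes_align",
    "align_cohort",
]


@dataclass(frozen=True)
class ReferenceTemplate:
    """P x k reference gradient matrix with recorded provenance.

    ``provenance`` is one of {"synthetic", "pooled-controls",
    "external-file"}; the pipeline default derives the template from the
    pooled control group-average gradients.
    """

    components: np.ndarray = field(repr=False)
    provenance: str = "pooled-controls"

    def __post_init__(self) -> None:
        c = np.asarray(self.components, dtype=float)
        if c.ndim != 2:
            raise ValidationError("reference components must be a P x k matrix")
        norms = np.linalg.norm(c, axis=0)
        if np.any(norms == 0):
            bad = [int(i) + 1 for i in np.flatnonzero(norms == 0)]
            raise ValidationError(f"degenerate (zero-norm) reference column(s) {bad}")
        object.__setattr__(self, "components", c)


@dataclass(frozen=True)
class AlignedGradientSet:
    """Gradient scores after rotation onto the reference."""

    components: np.ndarray = field(repr=False)
    rotation: np.ndarray = field(repr=False)
    disparity: float
    eigenvalues: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if np.abs(r.T @ r - np.eye(r.shape[1])).max() > 1e-10:
            raise ValidationError("rotation is not orthogonal within 1e-10")
        if self.disparity < 0:
            raise ValidationError("disparity must be >= 0")


def build_reference(
    source: GradientSet | np.ndarray,
    provenance: str | None = None,
    n_parcels: int | None = None,
) -> ReferenceTemplate:
    """Build an alignment reference from gradients or a loaded matrix."""
    if isinstance(source, GradientSet):
        comps = source.components
        prov = provenance or "pooled-controls"
    else:
        comps = np.asarray(source, dtype=float)
        prov = provenance or "external-file"
    if n_parcels is not None and comps.shape[0] != n_parcels:
        raise ValidationError(
            f"reference has {comps.shape[0]} parcels, atlas expects {n_parcels}"
        )
    return ReferenceTemplate(comps, provenance=prov)


def procrustes_align(
    source: GradientSet | np.ndarray, ref: ReferenceTemplate
) -> AlignedGradientSet:
    """Orthogonal Procrustes: R = argmin_{R orthogonal} ||source R - ref||_F.

    Reflections are permitted (they absorb eigenvector sign flips). The
    disparity is the residual ||source R - ref||_F^2.
    """
    if isinstance(source, GradientSet):
        comps = source.components
        lam = source.eigenvalues
        sid = source.subject_id
    else:
        comps = np.asarray(source, dtype=float)
        lam = np.full(comps.shape[1], np.nan)
        sid = "unknown"
    if comps.shape != ref.components.shape:
        raise ValidationError(
            f"shape mismatch: source {comps.shape} vs reference {ref.components.shape}"
        )
    rotation, _ = scipy.linalg.orthogonal_procrustes(comps, ref.components)
    aligned = comps @ rotation
    disparity = float(np.sum((aligned - ref.components) ** 2))
    return AlignedGradientSet(
        components=aligned,
        rotation=rotation,
        disparity=disparity,
        eigenvalues=lam,
        subject_id=sid,
    )


def align_cohort(
    subject_sets: list[GradientSet], ref: ReferenceTemplate
) -> tuple[list[AlignedGradientSet], pd.DataFrame]:
    """Align every subject independently to the same reference.

    Returns the aligned sets and a per-subject disparity report.
    """
    aligned = [procrustes_align(gs, ref) for gs in subject_sets]
    report = pd.DataFrame(
        {
            "subject_id": [a.subject_id for a in aligned],
            "disparity": [a.disparity for a in aligned],
        }
    )
    return aligned, report
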