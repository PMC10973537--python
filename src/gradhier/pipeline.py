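"""End-to-end cohort pipeline: time series -> aligned network gradient scores.

Per subject: Pearson FC -> Fisher z -> sparsified cosine-affinity diffusion
embedding -> Procrustes alignment to a common reference. The reference
defaults to the gradients of the control group's averaged Fisher-z matrix
(a stand-in for an external normative template, recorded in provenance).
Group-level gradient sets are computed from each group's averaged matrix
and aligned to the same reference so group contrasts live in one frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alignment import (
    AlignedGradientSet,
    ReferenceTemplate,
    align_cohort,
    build_reference,
    procrustes_align,
)
from .atlas import ParcellationMetadata
from .connectivity import fisher_z, group_average, pearson_fc
from .gradients import GradientParams, GradientSet, compute_gradients
from .hierarchy import cohort_network_scores
from .io import ConnectivityMatrix
from .simulate import SimulatedCohort

__all__ = ["PipelineResult", "subject_fisher_matrices", "run_cohort_pipeline"]


@dataclass(frozen=True)
class PipelineResult:
    """Everything downstream statistics need, in one bundle."""

    reference: ReferenceTemplate
    group_gradients: dict[str, AlignedGradientSet]  # aligned group-average sets
    group_gradients_raw: dict[str, GradientSet] = field(repr=False)
    aligned_subjects: list[AlignedGradientSet] = field(repr=False)
    disparities: pd.DataFrame = field(repr=False)
    network_scores: pd.DataFrame = field(repr=False)  # long format, all components
    subject_groups: dict[str, str] = field(repr=False)

    def principal_scores(self) -> pd.DataFrame:
        """Wide per-subject principal-gradient network means.

        Columns: subject_id, group, then one column per network.
        """
        principal = self.network_scores[self.network_scores["component_index"] == 1]
        wide = principal.pivot(
            index="subject_id", columns="network_name", values="mean_score"
        ).reset_index()
        wide.columns.name = None
        wide.insert(1, "group", wide["subject_id"].map(self.subject_groups))
        return wide


def subject_fisher_matrices(sim: SimulatedCohort) -> list[ConnectivityMatrix]:
    """Per-subject Fisher-z matrices from whichever form the cohort carries."""
    if sim.timeseries is not None:
        return [fisher_z(pearson_fc(ts)) for ts in sim.timeseries]
    if sim.connectivity is not None:
        return [fisher_z(m) for m in sim.connectivity]
    raise ValueError("cohort carries neither time series nor connectivity")


def run_cohort_pipeline(
    sim: SimulatedCohort,
    params: GradientParams = GradientParams(),
    reference: ReferenceTemplate | None = None,
) -> PipelineResult:
    """Run the full gradient pipeline on a simulated (or assembled) cohort."""
    metadata: ParcellationMetadata = sim.metadata
    z_mats = subject_fisher_matrices(sim)
    subject_ids = [m.subject_id for m in z_mats]
    groups = dict(
        zip(sim.cohort.table["subject_id"], sim.cohort.table["group"], strict=True)
    )

    # group-averaged matrices and their gradient sets
    raw_group: dict[str, GradientSet] = {}
    for grp in sim.cohort.groups:
        members = [m for m, sid in zip(z_mats, subject_ids) if groups[sid] == grp]
        avg = group_average(members, group=grp)
        gm = ConnectivityMatrix(avg.values, value_kind="fisher_z", subject_id=f"avg-{grp}")
        raw_group[grp] = compute_gradients(gm, params, metadata=metadata)

    if reference is None:
        control_key = "control" if "control" in raw_group else sim.cohort.groups[0]
        reference = build_reference(raw_group[control_key], provenance="pooled-controls")

    group_aligned = {
        grp: procrustes_align(gs, reference) for grp, gs in raw_group.items()
    }

    subject_sets = [
        compute_gradients(m, params, metadata=metadata) for m in z_mats
    ]
    aligned, disparities = align_cohort(subject_sets, reference)
    net_scores = cohort_network_scores(aligned, metadata)

    return PipelineResult(
        reference=reference,
        group_gradients=group_aligned,
        group_gradients_raw=raw_group,
        aligned_subjects=aligned,
        disparities=disparities,
        network_scores=net_scores,
        subject_groups=groups,
    )
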