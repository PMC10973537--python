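"""Network-level hierarchy summaries of aligned gradients.

Collapses aligned per-subject gradient scores into the report-level
quantities: per-network mean scores, global score histograms, range /
extremity ("contraction") metrics contrasting groups, and per-parcel
subdivision tables for a single network (by default the DMN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import AlignedGradientSet
from .atlas import ParcellationMetadata, ValidationError, normalize_network_name

__all__ = [
    "network_scores",
    "cohort_network_scores",
    "gradient_histogram",
    "contraction_metrics",
    "HierarchySummary",
    "subdivision_scores",
]


def network_scores(
    aligned: AlignedGradientSet, metadata: ParcellationMetadata
) -> pd.DataFrame:
    """Unweighted per-network mean of each component's parcel scores.

    Returns long-format rows (subject_id, network_name, component_index,
    mean_score) — one row per network per component.
    """
    comps = aligned.components
    if comps.shape[0] != metadata.n_parcels:
        raise ValidationError(
            f"gradients cover {comps.shape[0]} parcels, atlas has {metadata.n_parcels}"
        )
    rows = []
    for network in metadata.networks:
        idx = metadata.parcels_in(network)
        means = comps[idx].mean(axis=0)
        for k, m in enumerate(means, start=1):
            rows.append(
                {
                    "subject_id": aligned.subject_id,
                    "network_name": network,
                    "component_index": k,
                    "mean_score": float(m),
                }
            )
    return pd.DataFrame(rows)


def cohort_network_scores(
    aligned_sets: list[AlignedGradientSet], metadata: ParcellationMetadata
) -> pd.DataFrame:
    """Stacked network_scores over a cohort of aligned subjects."""
    return pd.concat(
        [network_scores(a, metadata) for a in aligned_sets], ignore_index=True
    )


def gradient_histogram(
    groups: dict[str, np.ndarray], bins: int = 50
) -> pd.DataFrame:
    """Histograms of parcel scores with bin edges shared across groups.

    ``groups`` maps a group label to that group's parcel scores (any
    shape; flattened). Equal-width bins span the pooled range so counts
    are comparable across groups.
    """
    if bins < 2:
        raise ValidationError("bins must be >= 2")
    pooled = np.concatenate([np.ravel(v) for v in groups.values()])
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:  # all-equal degenerate case: one informative bin
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    frames = []
    for label, values in groups.items():
        counts, _ = np.histogram(np.ravel(values), bins=edges)
        frames.append(
            pd.DataFrame(
                {
                    "group": label,
                    "bin_left": edges[:-1],
                    "bin_right": edges[1:],
                    "count": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class HierarchySummary:
    """Spread/extremity summary of one group's parcel scores."""

    group: str
    score_range: float  # max - min over parcels
    score_sd: float
    top_decile_mean: float
    bottom_decile_mean: float


def _summarize(scores: np.ndarray, group: str, decile: float) -> HierarchySummary:
    s = np.sort(np.ravel(scores))
    n_tail = max(1, int(round(decile * s.size)))
    return HierarchySummary(
        group=group,
        score_range=float(s[-1] - s[0]),
        score_sd=float(s.std()),
        top_decile_mean=float(s[-n_tail:].mean()),
        bottom_decile_mean=float(s[:n_tail].mean()),
    )


def contraction_metrics(
    control_scores: np.ndarray,
    case_scores: np.ndarray,
    decile: float = 0.1,
) -> pd.DataFrame:
    """Range / SD / extremity means per group, with case - control deltas.

    A contracted hierarchy shows a negative range delta: the case group's
    score extremes pull toward the middle. ``decile`` sets the tail
    fraction used for the extremity means (default top/bottom 10% of
    parcels).
    """
    if not 0.0 < decile <= 0.5:
        raise ValidationError("decile must be in (0, 0.5]")
    ctl = _summarize(control_scores, "control", decile)
    cas = _summarize(case_scores, "case", decile)
    rows = []
    for metric in ("score_range", "score_sd", "top_decile_mean", "bottom_decile_mean"):
        c, k = getattr(ctl, metric), getattr(cas, metric)
        rows.append(
            {"metric": metric, "control": c, "case": k, "delta_case_minus_control": k - c}
        )
    return pd.DataFrame(rows)


def subdivision_scores(
    aligned_sets: list[AlignedGradientSet],
    metadata: ParcellationMetadata,
    network: str = "Default",
    component_index: int = 1,
) -> pd.DataFrame:
    """Per-parcel per-subject scores restricted to one network.

    Long-format table (subject_id, parcel_id, parcel_label, gradient_score)
    ready for per-parcel group tests; defaults to the DMN's subdivisions on
    the principal gradient.
    """
    name = normalize_network_name(network)
    idx = metadata.parcels_in(name)  # raises if the network is empty
    labels = metadata.table["parcel_label"].to_numpy()[idx]
    rows = []
    for a in aligned_sets:
        scores = a.components[idx, component_index - 1]
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": a.subject_id,
                    "parcel_id": idx + 1,
                    "parcel_label": labels,
                    "gradient_score": scores,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
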