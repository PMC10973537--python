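"""Parcellation metadata: parcel -> functional-network assignment.

The pipeline operates on a fixed cortical parcellation (by default 200
parcels in the Schaefer-200 style) in which every parcel belongs to exactly
one of the seven canonical resting-state networks of the Yeo decomposition.
Parcel ids are 1-based in files and converted to 0-based indices at the I/O
boundary; all in-memory code is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven canonical functional networks, ordered roughly along the
#: unimodal -> transmodal cortical hierarchy.
CANONICAL_NETWORKS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Frontoparietal",
    "Default",
)

_NETWORK_LOOKUP = {name.lower(): name for name in CANONICAL_NETWORKS}
# common aliases seen in atlas label files
_NETWORK_LOOKUP.update(
    {
        "vis": "Visual",
        "sommot": "Somatomotor",
        "dorsattn": "DorsalAttention",
        "salventattn": "VentralAttention",
        "ventattn": "VentralAttention",
        "cont": "Frontoparietal",
        "control": "Frontoparietal",
        "dmn": "Default",
    }
)


class ValidationError(ValueError):
    """A structured validation failure in one of the pipeline's tables."""


def normalize_network_name(name: str) -> str:
    """Map a network label to its canonical spelling (case-insensitive)."""
    key = str(name).strip().lower()
    if key not in _NETWORK_LOOKUP:
        raise ValidationError(
            f"unknown network name {name!r}; allowed: {', '.join(CANONICAL_NETWORKS)}"
        )
    return _NETWORK_LOOKUP[key]


@dataclass(frozen=True)
class ParcellationMetadata:
    """Validated parcel -> network assignment for a P-parcel atlas.

    ``table`` holds one row per parcel with columns ``parcel_id`` (1-based,
    contiguous), ``parcel_label``, ``network_name`` (canonical) and
    ``hemisphere`` ({L, R}).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"parcel_id", "parcel_label", "network_name", "hemisphere"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"parcellation table missing columns: {sorted(missing)}")
        ids = t["parcel_id"].to_numpy()
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate parcel_id values: {sorted(set(dup))}")
        expected = np.arange(1, len(t) + 1)
        if not np.array_equal(np.sort(ids), expected):
            missing_ids = sorted(set(expected) - set(ids))
            raise ValidationError(
                f"parcel_ids must be 1..{len(t)} with no gaps; missing {missing_ids}"
            )
        bad_hemi = set(t["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise ValidationError(f"hemisphere must be L or R, got {sorted(bad_hemi)}")
        # canonicalize in place (frozen dataclass: mutate the frame, not the field)
        t["network_name"] = [normalize_network_name(n) for n in t["network_name"]]
        t.sort_values("parcel_id", inplace=True, ignore_index=True)

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        """Canonical names of the networks present, in hierarchy order."""
        present = set(self.table["network_name"])
        return [n for n in CANONICAL_NETWORKS if n in present]

    def network_of(self) -> np.ndarray:
        """Network name per parcel, 0-based parcel order (length P)."""
        return self.table["network_name"].to_numpy()

    def parcels_in(self, network: str) -> np.ndarray:
        """0-based indices of the parcels belonging to ``network``."""
        name = normalize_network_name(network)
        idx = np.flatnonzero(self.table["network_name"].to_numpy() == name)
        if idx.size == 0:
            raise ValidationError(f"network {name!r} has no parcels in this atlas")
        return idx

    def network_sizes(self) -> dict[str, int]:
        counts = self.table["network_name"].value_counts()
        return {n: int(counts[n]) for n in self.networks}


# Per-hemisphere parcel counts for the default synthetic 200-parcel atlas.
# Chosen to resemble the Schaefer-200/Yeo-7 proportions (Default largest,
# Limbic smallest); this is a synthetic stand-in, not the published atlas.
_DEFAULT_COUNTS = {
    "Visual": 15,
    "Somatomotor": 15,
    "DorsalAttention": 12,
    "VentralAttention": 12,
    "Limbic": 7,
    "Frontoparietal": 15,
    "Default": 24,
}


def default_parcellation(n_parcels: int = 200) -> ParcellationMetadata:
    """Synthetic Yeo-7 style parcellation with ``n_parcels`` parcels.

    Parcels are split evenly between hemispheres and assigned to the seven
    networks in proportions resembling the 200-parcel functional atlas.
    ``n_parcels`` must be even and >= 14 so every network is non-empty in
    both hemispheres.
    """
    if n_parcels % 2 != 0 or n_parcels < 14:
        raise ValueError("n_parcels must be even and >= 14")
    per_hemi = n_parcels // 2
    total = sum(_DEFAULT_COUNTS.values())
    # largest-remainder apportionment of per-hemisphere counts
    quotas = {n: c * per_hemi / total for n, c in _DEFAULT_COUNTS.items()}
    counts = {n: max(1, int(q)) for n, q in quotas.items()}
    while sum(counts.values()) < per_hemi:
        rem = {n: quotas[n] - counts[n] for n in counts}
        counts[max(rem, key=rem.get)] += 1
    while sum(counts.values()) > per_hemi:
        rem = {n: quotas[n] - counts[n] for n in counts if counts[n] > 1}
        counts[min(rem, key=rem.get)] -= 1

    rows = []
    pid = 1
    for hemi in ("L", "R"):
        for network in CANONICAL_NETWORKS:
            for k in range(counts[network]):
                rows.append(
                    {
                        "parcel_id": pid,
                        "parcel_label": f"7Networks_{hemi}H_{network}_{k + 1}",
                        "network_name": network,
                        "hemisphere": hemi,
                    }
                )
                pid += 1
    return ParcellationMetadata(pd.DataFrame(rows))
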