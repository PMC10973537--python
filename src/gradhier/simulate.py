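"""Synthetic two-group cohorts with a planted cortical hierarchy axis.

No raw data accompany the study design this pipeline targets, so every
downstream stage is exercised on cohorts with known ground truth. The
generative model:

1. Each parcel receives a latent hierarchy score g_i = center(network(i)) +
   jitter, with network centers ordered from sensorimotor (low) to the
   default-mode network (high) — the unimodal -> transmodal principal
   gradient.
2. The case group's axis is contracted toward its mean by a factor
   kappa <= 1 (optionally per network, to plant a DMN-dominant effect),
   emulating the shrinkage of the hierarchy's extremes seen in
   subthreshold depression. Each subject additionally draws an individual
   contraction around the group value, so planted DMN levels vary across
   subjects within a group.
3. Parcel covariance decays exponentially with latent distance,
   Sigma_ij = exp(-|g_i - g_j| / l) + w * [same network], which makes the
   diffusion embedding of the resulting FC provably order parcels along g.
4. Subject time series are i.i.d. multivariate Gaussian rows from Sigma
   (plus white measurement noise); clinical scores are a negative linear
   function of the subject's planted DMN score plus noise, clipped and
   rounded to the scales' integer ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import (
    CANONICAL_NETWORKS,
    ParcellationMetadata,
    ValidationError,
    default_parcellation,
    normalize_network_name,
)
from .io import CohortTable, ConnectivityMatrix, TimeSeriesMatrix

__all__ = [
    "HierarchySpec",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "build_latent_axis",
    "build_covariance",
    "simulate_subject_timeseries",
    "simulate_clinical_scores",
    "simulate_cohort",
]

#: Default latent centers: Somatomotor is the minimum, Default the maximum,
#: spanning the unimodal -> transmodal continuum.
DEFAULT_NETWORK_CENTERS = {
    "Somatomotor": -1.0,
    "Visual": -2.0 / 3.0,
    "DorsalAttention": -1.0 / 3.0,
    "VentralAttention": 0.0,
    "Limbic": 1.0 / 3.0,
    "Frontoparietal": 2.0 / 3.0,
    "Default": 1.0,
}


@dataclass(frozen=True)
class HierarchySpec:
    """Parameters of the planted hierarchy and its covariance model.

    network_centers : latent center per network (dimensionless).
    within_network_spread : SD of the per-parcel jitter around its center.
    length_scale : exponential decay length l of the latent-distance kernel.
    within_network_boost : additive affinity w for same-network pairs.
    noise_sd : SD of white measurement noise added to each time point.
    """

    network_centers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_CENTERS)
    )
    within_network_spread: float = 0.18
    length_scale: float = 0.75
    within_network_boost: float = 0.05
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        centers = {normalize_network_name(k): float(v) for k, v in self.network_centers.items()}
        object.__setattr__(self, "network_centers", centers)
        vals = list(centers.values())
        if max(vals) - min(vals) <= 0:
            raise ValidationError("network centers must span a nonzero range")
        if self.within_network_spread <= 0:
            raise ValidationError("within_network_spread must be > 0")
        if self.length_scale <= 0:
            raise ValidationError("length_scale must be > 0")
        if self.within_network_boost < 0 or self.noise_sd < 0:
            raise ValidationError("within_network_boost and noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort design: sizes, contraction and clinical coupling.

    contraction_kappa : case-group shrink factor kappa in (0, 1]; 1 means no
        group difference. ``network_kappa`` overrides kappa for named
        networks (e.g. {"Default": 0.6} plants a DMN-dominant contraction).
    kappa_subject_sd : SD of the per-subject contraction jitter (both
        groups); gives subjects distinct planted DMN levels.
    clinical_beta0/clinical_slope/clinical_noise_sd : CESD linear model
        cesd = beta0 - slope * dmn_score + noise; HAMD is the same
        predictor rescaled by ``hamd_scale``. Defaults reproduce the
        target design's group medians (control CESD ~ 6 / HAMD ~ 3, case
        CESD ~ 19 / HAMD ~ 9) in expectation.
    """

    n_parcels: int = 200
    n_per_group: int = 43
    n_timepoints: int = 175
    contraction_kappa: float = 1.0
    network_kappa: dict[str, float] | None = None
    kappa_subject_sd: float = 0.15
    clinical_beta0: float = 38.0
    clinical_slope: float = 32.0
    clinical_noise_sd: float = 3.0
    hamd_scale: float = 0.47
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_parcels, self.n_per_group, self.n_timepoints) <= 0:
            raise ValidationError("all counts must be positive")
        if not 0.0 < self.contraction_kappa <= 1.0:
            raise ValidationError("contraction_kappa must be in (0, 1]")
        if self.clinical_slope < 0:
            raise ValidationError("clinical_slope must be >= 0")
        if self.network_kappa is not None:
            nk = {normalize_network_name(k): float(v) for k, v in self.network_kappa.items()}
            if any(not 0.0 < v <= 1.0 for v in nk.values()):
                raise ValidationError("network_kappa values must be in (0, 1]")
            object.__setattr__(self, "network_kappa", nk)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for validating recovery downstream."""

    latent_axis: dict[str, np.ndarray]  # group -> per-parcel axis (group level)
    true_network_means: dict[str, dict[str, float]]  # group -> network -> mean
    subject_dmn_score: pd.DataFrame  # subject_id, group, dmn_score, kappa
    clinical_coupling_sign: int  # -1 if slope > 0 (higher DMN -> lower CESD)
    seed: int = 0


@dataclass(frozen=True)
class SimulatedCohort:
    metadata: ParcellationMetadata
    cohort: CohortTable
    timeseries: list[TimeSeriesMatrix] | None
    connectivity: list[ConnectivityMatrix] | None
    ground_truth: GroundTruth
    config: SimulationConfig
    spec: HierarchySpec


def build_latent_axis(
    metadata: ParcellationMetadata,
    spec: HierarchySpec,
    rng: np.random.Generator,
    kappa: float = 1.0,
    network_kappa: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-parcel latent hierarchy scores, optionally contracted.

    g_i = center(network(i)) + jitter; then every parcel is pulled toward
    the pre-contraction mean, g_i <- mean(g) + kappa_i * (g_i - mean(g)),
    with kappa_i taken from ``network_kappa`` for that parcel's network if
    given, else the global ``kappa``.
    """
    networks = metadata.network_of()
    unknown = set(networks) - set(spec.network_centers)
    if unknown:
        raise ValidationError(f"no latent center for network(s) {sorted(unknown)}")
    centers = np.array([spec.network_centers[n] for n in networks])
    g = centers + rng.normal(0.0, spec.within_network_spread, size=len(centers))
    kap = np.full(len(g), kappa)
    if network_kappa:
        for name, value in network_kappa.items():
            kap[networks == normalize_network_name(name)] = value
    return g.mean() + kap * (g - g.mean())


def build_covariance(
    g: np.ndarray, metadata: ParcellationMetadata, spec: HierarchySpec
) -> np.ndarray:
    """Exponential latent-distance covariance with a same-network boost.

    Sigma_ij = exp(-|g_i - g_j| / l) + w * [network(i) = network(j)] off the
    diagonal; the diagonal is 1 + w, and a diagonal jitter is added if the
    smallest eigenvalue falls below 1e-8 so the matrix is safely positive
    definite for the Cholesky factorization.
    """
    g = np.asarray(g, dtype=float)
    if not np.isfinite(g).all():
        raise ValidationError("latent axis must be finite")
    networks = metadata.network_of()
    same = networks[:, None] == networks[None, :]
    cov = np.exp(-np.abs(g[:, None] - g[None, :]) / spec.length_scale)
    cov = cov + spec.within_network_boost * same
    np.fill_diagonal(cov, 1.0 + spec.within_network_boost)
    min_eig = float(np.linalg.eigvalsh(cov)[0])
    if min_eig < 1e-8:
        cov = cov + (1e-8 - min_eig) * np.eye(len(g))
    return cov


def simulate_subject_timeseries(
    cov: np.ndarray,
    n_timepoints: int,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    subject_id: str = "sim",
) -> TimeSeriesMatrix:
    """Draw i.i.d. zero-mean Gaussian rows with covariance ``cov``.

    Sampling goes through the Cholesky square root; a non-positive-definite
    covariance raises with a pointer to diagonal jitter.
    """
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "covariance is not positive definite; add diagonal jitter "
            "(build_covariance does this automatically)"
        ) from exc
    z = rng.standard_normal((n_timepoints, cov.shape[0]))
    values = z @ chol.T
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return TimeSeriesMatrix(values, subject_id=subject_id)


def simulate_clinical_scores(
    dmn_score: np.ndarray,
    beta0: float,
    beta1: float,
    noise_sd: float,
    rng: np.random.Generator,
    hamd_scale: float = 0.47,
) -> tuple[np.ndarray, np.ndarray]:
    """CESD and HAMD scores negatively coupled to the DMN gradient score.

    cesd = round(clip(beta0 - beta1 * dmn + eps, 0, 60)); hamd applies the
    same linear predictor scaled by ``hamd_scale`` (noise scales too),
    clipped at 0 below and the 17-item maximum (52) above.
    """
    if beta1 < 0:
        raise ValidationError("beta1 must be >= 0")
    dmn = np.asarray(dmn_score, dtype=float)
    predictor = beta0 - beta1 * dmn
    cesd = predictor + rng.normal(0.0, noise_sd, size=dmn.shape)
    hamd = hamd_scale * predictor + rng.normal(0.0, hamd_scale * noise_sd, size=dmn.shape)
    cesd = np.clip(np.rint(cesd), 0, 60).astype(int)
    hamd = np.clip(np.rint(hamd), 0, 52).astype(int)
    return cesd, hamd


def _group_axes(
    metadata: ParcellationMetadata,
    spec: HierarchySpec,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Group-level latent axes: control uncontracted, case contracted."""
    # one shared jitter draw so the two groups differ only by contraction
    state = rng.bit_generator.state
    control = build_latent_axis(metadata, spec, rng, kappa=1.0)
    rng.bit_generator.state = state
    case = build_latent_axis(
        metadata,
        spec,
        rng,
        kappa=config.contraction_kappa,
        network_kappa=config.network_kappa,
    )
    return {"control": control, "case": case}


def simulate_cohort(
    config: SimulationConfig,
    spec: HierarchySpec = HierarchySpec(),
    metadata: ParcellationMetadata | None = None,
    output: str = "timeseries",
) -> SimulatedCohort:
    """Simulate a full two-group cohort with recorded ground truth.

    ``output`` selects "timeseries" (default) or "connectivity" (the
    per-subject Pearson FC of the simulated series, saving callers the
    correlation step). One master seed expands into independent per-subject
    substreams, so cohorts are reproducible and subjects independent.
    """
    if output not in ("timeseries", "connectivity"):
        raise ValidationError("output must be 'timeseries' or 'connectivity'")
    if metadata is None:
        metadata = default_parcellation(config.n_parcels)
    if metadata.n_parcels != config.n_parcels:
        raise ValidationError(
            f"metadata has {metadata.n_parcels} parcels, config expects {config.n_parcels}"
        )

    master = np.random.SeedSequence(config.seed)
    axis_seq, clinical_seq, *subject_seqs = master.spawn(2 + 2 * config.n_per_group)
    axis_rng = np.random.default_rng(axis_seq)
    axes = _group_axes(metadata, spec, config, axis_rng)

    dmn_idx = metadata.parcels_in("Default")
    mean_axis = axes["control"].mean()
    networks = metadata.network_of()

    timeseries: list[TimeSeriesMatrix] = []
    rows = []
    sub_i = 0
    for group in ("control", "case"):
        g_group = axes[group]
        for k in range(config.n_per_group):
            sid = f"{group}-{k + 1:03d}"
            rng = np.random.default_rng(subject_seqs[sub_i])
            sub_i += 1
            # per-subject contraction jitter about the group axis
            kappa_s = 1.0 + rng.normal(0.0, config.kappa_subject_sd)
            kappa_s = float(np.clip(kappa_s, 0.5, 1.4))
            g_s = mean_axis + kappa_s * (g_group - mean_axis)
            cov = build_covariance(g_s, metadata, spec)
            ts = simulate_subject_timeseries(
                cov, config.n_timepoints, rng, noise_sd=spec.noise_sd, subject_id=sid
            )
            timeseries.append(ts)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "dmn_score": float(g_s[dmn_idx].mean()),
                    "kappa": kappa_s,
                }
            )

    subject_truth = pd.DataFrame(rows)
    clin_rng = np.random.default_rng(clinical_seq)
    cesd, hamd = simulate_clinical_scores(
        subject_truth["dmn_score"].to_numpy(),
        config.clinical_beta0,
        config.clinical_slope,
        config.clinical_noise_sd,
        clin_rng,
        hamd_scale=config.hamd_scale,
    )
    # matched sex composition in both groups, ~16:27 M:F as in the design
    n_male = max(1, round(config.n_per_group * 16 / 43))
    sexes = np.where(np.arange(config.n_per_group) < n_male, "M", "F")
    cohort = CohortTable(
        pd.DataFrame(
            {
                "subject_id": subject_truth["subject_id"],
                "group": subject_truth["group"],
                "cesd": cesd,
                "hamd": hamd,
                "age": np.tile(19 + (np.arange(config.n_per_group) % 5), 2),
                "sex": np.tile(sexes, 2),
                "education": np.tile(13 + (np.arange(config.n_per_group) % 3), 2),
            }
        )
    )

    true_means = {
        grp: {
            n: float(axes[grp][networks == n].mean()) for n in metadata.networks
        }
        for grp in ("control", "case")
    }
    truth = GroundTruth(
        latent_axis=axes,
        true_network_means=true_means,
        subject_dmn_score=subject_truth,
        clinical_coupling_sign=-1 if config.clinical_slope > 0 else 0,
        seed=config.seed,
    )

    connectivity = None
    if output == "connectivity":
        from .connectivity import pearson_fc

        connectivity = [pearson_fc(ts) for ts in timeseries]
        timeseries = None

    return SimulatedCohort(
        metadata=metadata,
        cohort=cohort,
        timeseries=timeseries,
        connectivity=connectivity,
        ground_truth=truth,
        config=config,
        spec=spec,
    )
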