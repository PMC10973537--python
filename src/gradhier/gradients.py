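"""Diffusion-map connectome gradients.

The central computation: each row of a (Fisher-z) connectivity matrix is
sparsified to its top 10% of connections, a cosine-similarity affinity is
built between the sparsified connectivity profiles, and the affinity graph
is embedded by a diffusion map — the eigendecomposition of the
anisotropically normalized random-walk operator. Each retained eigenvector
assigns every parcel a "gradient score" placing it along one axis of
connectivity variation; the principal gradient (largest non-trivial
eigenvalue) spans the sensorimotor-to-default-mode cortical hierarchy.

Normalization (anisotropy alpha = 0.5, the Coifman–Lafon convention):

    d_i = sum_j A_ij
    W_ij = A_ij / (d_i^alpha * d_j^alpha)
    M    = D_w^{-1} W          (row-stochastic; D_w from W's row sums)

M is similar to the symmetric S = D_w^{-1/2} W D_w^{-1/2}, so its spectrum
is real and the eigenproblem is solved on S. The trivial eigenvalue 1
(constant eigenvector) is dropped. With diffusion_time = 0 the k-th
component is the k-th right eigenvector scaled by lambda_k / (1 - lambda_k)
(the multi-scale "automatic time" weighting); for t > 0 the scaling is
lambda_k^t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from .atlas import ParcellationMetadata, ValidationError
from .io import ConnectivityMatrix

__all__ = [
    "GradientParams",
    "GradientSet",
    "sparsify_rows",
    "cosine_affinity",
    "diffusion_embedding",
    "compute_gradients",
    "eigenvalue_spectrum",
]


@dataclass(frozen=True)
class GradientParams:
    """Tunable parameters of the gradient extraction.

    sparsity : fraction of off-diagonal entries zeroed per row (default 0.9,
        i.e. the top 10% of connections by value are kept).
    n_components : number of non-trivial components retained (default 10).
    alpha : diffusion anisotropy exponent in [0, 1]; 0.5 normalizes away
        sampling-density effects and is the reference-toolbox default.
    diffusion_time : 0 selects the automatic lambda/(1-lambda) multi-scale
        weighting; t > 0 uses lambda^t.
    """

    sparsity: float = 0.9
    n_components: int = 10
    alpha: float = 0.5
    diffusion_time: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sparsity < 1.0:
            raise ValidationError(f"sparsity must be in [0, 1), got {self.sparsity}")
        if self.n_components < 2:
            raise ValidationError("n_components must be >= 2")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.diffusion_time < 0:
            raise ValidationError("diffusion_time must be >= 0")


@dataclass(frozen=True)
class GradientSet:
    """P x k gradient scores with the associated eigenvalue spectrum.

    ``eigenvalues`` are the non-trivial random-walk eigenvalues, sorted
    descending, strictly inside (0, 1) for a connected affinity graph.
    ``variance_explained`` holds the normalized squared eigenvalues over
    the retained components.
    """

    components: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray
    subject_id: str = "group_average"

    def __post_init__(self) -> None:
        c = np.asarray(self.components, dtype=float)
        lam = np.asarray(self.eigenvalues, dtype=float)
        if c.ndim != 2 or c.shape[1] != lam.shape[0]:
            raise ValidationError("components must be P x k matching eigenvalues")
        if np.any(np.diff(lam) > 1e-12):
            raise ValidationError("eigenvalues must be sorted descending")
        object.__setattr__(self, "components", c)
        object.__setattr__(self, "eigenvalues", lam)

    @property
    def n_parcels(self) -> int:
        return self.components.shape[0]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def variance_explained(self) -> np.ndarray:
        lam2 = self.eigenvalues**2
        return lam2 / lam2.sum()

    def to_long_table(self) -> pd.DataFrame:
        """Long-format (subject_id, parcel_id, component_index, gradient_score)."""
        p, k = self.components.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_id, p * k),
                "parcel_id": np.repeat(np.arange(1, p + 1), k),
                "component_index": np.tile(np.arange(1, k + 1), p),
                "gradient_score": self.components.ravel(),
            }
        )


def sparsify_rows(z: ConnectivityMatrix | np.ndarray, sparsity: float = 0.9) -> np.ndarray:
    """Keep the top (1 - sparsity) fraction of each row's off-diagonal entries.

    Ranking is by signed value (not magnitude); the number kept per row is
    ceil((1 - sparsity) * (P - 1)). Ties at the cutoff keep the lower parcel
    index. The result is generally asymmetric; symmetry is restored by the
    cosine kernel.
    """
    if not 0.0 <= sparsity < 1.0:
        raise ValidationError(f"sparsity must be in [0, 1), got {sparsity}")
    v = z.values if isinstance(z, ConnectivityMatrix) else np.asarray(z, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValidationError("sparsify_rows expects a square matrix")
    p = v.shape[0]
    n_keep = ceil((1.0 - sparsity) * (p - 1))
    ranked = v.copy()
    np.fill_diagonal(ranked, -np.inf)  # diagonal never competes
    # stable argsort of -row: among ties, lower index ranks first
    order = np.argsort(-ranked, axis=1, kind="stable")
    keep = np.zeros_like(v, dtype=bool)
    rows = np.repeat(np.arange(p), n_keep)
    keep[rows, order[:, :n_keep].ravel()] = True
    out = np.where(keep, v, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def cosine_affinity(s: np.ndarray) -> np.ndarray:
    """Cosine similarity between row vectors of the sparsified matrix.

    Negative similarities are clipped to 0 (the diffusion operator requires
    a nonnegative affinity); the diagonal is set to 0.
    """
    s = np.asarray(s, dtype=float)
    norms = np.linalg.norm(s, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        raise ValidationError(
            f"disconnected parcel after sparsification: all-zero row(s) "
            f"{[int(i) + 1 for i in dead]}"
        )
    a = (s @ s.T) / np.outer(norms, norms)
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(a, 0.0)
    return a


def _fix_signs(
    components: np.ndarray, metadata: ParcellationMetadata | None
) -> np.ndarray:
    """Deterministic per-component sign convention.

    With an atlas: orient each component so its mean over Default-network
    parcels is >= its mean over Somatomotor parcels (principal-gradient
    convention: sensorimotor low, DMN high). If that difference is zero, or
    without an atlas, make the largest-magnitude entry positive (ties: the
    lowest such parcel index).
    """
    out = components.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        sign = 0.0
        if metadata is not None:
            diff = col[metadata.parcels_in("Default")].mean() - col[
                metadata.parcels_in("Somatomotor")
            ].mean()
            if diff != 0.0:
                sign = np.sign(diff)
        if sign == 0.0:
            i = int(np.argmax(np.abs(col)))
            sign = np.sign(col[i]) if col[i] != 0 else 1.0
        out[:, k] = sign * col
    return out


def diffusion_embedding(
    affinity: np.ndarray,
    params: GradientParams = GradientParams(),
    metadata: ParcellationMetadata | None = None,
    subject_id: str = "group_average",
) -> GradientSet:
    """Diffusion-map embedding of a symmetric nonnegative affinity matrix.

    Solves the eigenproblem on the symmetric conjugate of the random-walk
    operator (guaranteeing a real spectrum), drops the trivial unit
    eigenvalue, and returns the top ``n_components`` gradient scores under
    the deterministic sign convention.
    """
    a = np.asarray(affinity, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("affinity must be square")
    if np.abs(a - a.T).max() > 1e-10:
        raise ValidationError("affinity must be symmetric")
    if a.min() < 0:
        raise ValidationError("affinity must be nonnegative")
    p = a.shape[0]
    if params.n_components >= p:
        raise ValidationError(f"n_components must be < P = {p}")
    n_comp, _ = connected_components(a > 0, directed=False)
    if n_comp > 1:
        raise ValidationError(
            f"affinity graph has {n_comp} connected components; "
            "lower the sparsity so every parcel stays connected"
        )

    d = a.sum(axis=1)
    w = a / np.outer(d**params.alpha, d**params.alpha)
    dw = w.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dw)
    s = w * np.outer(inv_sqrt, inv_sqrt)
    s = (s + s.T) / 2.0  # guard rounding asymmetry for eigh

    k = params.n_components
    lam, vec = scipy.linalg.eigh(s, subset_by_index=[p - 1 - k, p - 1])
    lam, vec = lam[::-1], vec[:, ::-1]  # descending
    if not np.isclose(lam[0], 1.0, atol=1e-8):
        raise ValidationError(
            f"leading eigenvalue {lam[0]:.12f} != 1; operator not stochastic"
        )
    lam, vec = lam[1:], vec[:, 1:]  # drop the trivial component
    psi = vec * inv_sqrt[:, None]  # right eigenvectors of the walk operator
    psi /= np.linalg.norm(psi, axis=0)  # unit norm before diffusion scaling
    if params.diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**params.diffusion_time
    components = _fix_signs(psi * scale, metadata)
    return GradientSet(components, lam, subject_id=subject_id)


def compute_gradients(
    z: ConnectivityMatrix,
    params: GradientParams = GradientParams(),
    metadata: ParcellationMetadata | None = None,
) -> GradientSet:
    """Full gradient extraction: sparsify -> cosine affinity -> embedding."""
    sparse = sparsify_rows(z, params.sparsity)
    affinity = cosine_affinity(sparse)
    return diffusion_embedding(
        affinity, params, metadata=metadata, subject_id=z.subject_id
    )


def eigenvalue_spectrum(gs: GradientSet, k: int = 13) -> pd.DataFrame:
    """First-k eigenvalues with variance fractions, as a plot-ready table.

    If fewer than ``k`` components were retained, all available components
    are returned.
    """
    n = min(k, gs.n_components)
    lam = gs.eigenvalues[:n]
    return pd.DataFrame(
        {
            "component_index": np.arange(1, n + 1),
            "eigenvalue": lam,
            "variance_explained": gs.variance_explained[:n],
        }
    )
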