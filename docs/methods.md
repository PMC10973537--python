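# Methods

## Pipeline model and assumptions

The package treats a resting-state functional connectome as a weighted
graph over P cortical parcels (default P = 200, partitioned into the seven
canonical Yeo networks) and summarizes it by connectivity **gradients**:
eigenvectors of a diffusion operator built on inter-parcel affinity. The
modeling assumptions, stage by stage:

- **Connectivity.** Subject FC is the Pearson correlation of parcel time
  series, Fisher z-transformed (variance-stabilizing; off-diagonal only —
  the diagonal is set to 0 because `arctanh(1)` diverges and self-affinity
  is uninformative for the kernel). Group matrices average subject
  z-matrices entrywise; averaging happens after the z-transform, never
  before.
- **Sparsification** keeps, per row, the top `ceil((1−s)(P−1))` off-diagonal
  entries **by signed value** (s = 0.9 by default → 20 per row at P = 200).
  Ranking by value rather than magnitude means strong negative correlations
  are discarded, matching common gradient-toolbox behavior. Ties at the
  cutoff keep the lower parcel index, making the operation deterministic.
  The output is row-wise (asymmetric); symmetry is restored by the kernel.
- **Affinity** is the cosine similarity between sparsified connectivity
  profiles. Negative cosines are clipped to 0 (the diffusion operator
  requires nonnegative weights); the diagonal is zeroed. An all-zero row
  (a parcel disconnected by sparsification) is a hard error, as is a
  disconnected affinity graph — the advice in both cases is to lower the
  sparsity.
- **Diffusion map.** With α = 0.5 (density-normalizing anisotropy) the
  operator `W = D^{-α} A D^{-α}` is row-normalized to a stochastic matrix
  and eigendecomposed through its symmetric conjugate
  `S = D_w^{-1/2} W D_w^{-1/2}`, which guarantees a real spectrum and is
  solved with a partial symmetric eigendecomposition. The trivial
  eigenvalue 1 is dropped; component k is the k-th right eigenvector
  (unit-normalized) scaled by `λ_k/(1−λ_k)` when `diffusion_time = 0`
  (multi-scale automatic weighting) or `λ_k^t` otherwise. Variance
  explained is reported as normalized squared eigenvalues over the
  retained components, alongside the raw eigenvalues.
- **Sign convention.** Eigenvector signs are arbitrary, so each component
  is oriented to put the Default-network mean at or above the Somatomotor
  mean (the field's principal-gradient convention); when that difference is
  exactly zero — or no atlas is supplied — the largest-magnitude entry is
  made positive. Repeated runs are bit-identical.
- **Alignment.** Orthogonal Procrustes (`R = argmin ‖G·R − ref‖_F`,
  reflections permitted) with **no scaling and no centering**: the
  `λ/(1−λ)` magnitudes carry the group contrast of interest and scaling
  would erase it. Subjects are each aligned to a common reference — by
  default the pooled-control group-average gradients, a stand-in for an
  external normative template (provenance is recorded). Subject-level
  gradient extraction followed by alignment is the reading under which
  per-subject network statistics are computable at all.
- **Statistics.** Continuous two-group comparisons run a Shapiro–Wilk gate
  (α = 0.05 per group; "normal" only if both pass — the gate test itself is
  a package choice) into either the classical equal-variance t-test
  (reported mean ± SD) or the Mann–Whitney U with tie-corrected normal
  approximation (reported as Z, median (Q1 ∼ Q3), quartiles by inclusive
  linear interpolation). 2×2 tables use Pearson chi-square without
  continuity correction (Yates available by flag). All tests are
  two-sided. Clinical correlations are Pearson r computed within the case
  group. Family-level outputs always carry both raw and
  Benjamini–Hochberg-adjusted p-values so the uncorrected-vs-corrected
  choice is explicit rather than silent.

## Synthetic cohort generator

The generator emulates a matched two-group clinical design: two groups of
43 subjects, 175 timepoints per subject (a 180-volume scan with the first
5 volumes discarded), ~16:27 male:female in each group, integer CESD
(0–60) and HAMD (≥ 0) scores.

- **Latent axis.** Parcel i gets `g_i = center(network(i)) + jitter`, with
  centers evenly spaced on [−1, 1] from Somatomotor (−1) to Default (+1)
  and jitter SD `within_network_spread = 0.18`. Even spacing keeps adjacent
  networks' latent ranges interleaved, as real gradient distributions are;
  it also keeps the sparsified affinity graph reliably connected
  (verified at 0 disconnections in 36,000 simulated subjects).
- **Contraction.** The case group's axis is pulled toward its mean,
  `g ← mean(g) + κ(g − mean(g))`, either globally (`contraction_kappa`) or
  per network (`network_kappa`, e.g. `{"Default": 0.6}` for a DMN-dominant
  effect; both regimes exist because power analyses need both). Each
  subject additionally draws an individual contraction factor
  `κ_s ~ N(κ, 0.15)` clipped to [0.5, 1.4]. This per-subject jitter is a
  deliberate extension of a strictly group-level axis: without it all
  subjects in a group share one planted DMN level, within-group clinical
  coupling would have no true variance to correlate with, and group
  comparisons would see only measurement noise.
- **Covariance and time series.**
  `Σ_ij = exp(−|g_i − g_j|/ℓ) + w·[same network]` with ℓ = 0.75 and
  w = 0.05, diagonal 1 + w plus a jitter if the minimum eigenvalue falls
  below 1e-8. Rows of the subject time series are i.i.d. zero-mean
  Gaussians with covariance Σ (Cholesky sampling) plus white measurement
  noise (SD 0.3). The exponential-decay model is chosen because the
  diffusion embedding of the resulting FC provably orders parcels along g,
  giving an analyzable ground truth.
- **Clinical scores.** `CESD = round(clip(β0 − β1·dmn_s + ε, 0, 60))` with
  `dmn_s` the subject's planted DMN latent mean; HAMD applies the same
  predictor scaled by 0.47. Defaults β0 = 38, β1 = 32, noise SD 3 solve
  the two-median system so that group medians land near CESD 6/19 and
  HAMD 3/9 (control/case), the canonical values for this design, with
  realistic interquartile ranges.
- **Seeding.** One master seed expands through `numpy.random.SeedSequence`
  into independent substreams (axis, clinical noise, one per subject), so
  cohorts are byte-reproducible and subjects independent.

What the generator does **not** model: hemodynamics, autocorrelated BOLD
noise, head motion, scanner drift, spatial smoothness within parcels,
negative FC structure, site effects. Passing recovery tests therefore
shows the pipeline is correct and well-calibrated under a faithful planted
hierarchy — not that effect sizes on real data will match.

## Numerical choices

- Eigenproblem via `scipy.linalg.eigh` on the symmetric conjugate with a
  partial spectrum (top k+1); the leading eigenvalue must equal 1 to 1e-8
  or the operator is rejected as non-stochastic.
- Matrix symmetry tolerated to 1e-8 on read, enforced exactly afterwards;
  writer/reader round-trips are verified at 1e-12.
- NaNs are never imputed anywhere; they are hard, named errors.
- Degenerate inputs: constant samples route the normality gate to the
  nonparametric branch; all-tied Mann–Whitney returns Z = 0, p = 1;
  single-bin histograms get a widened dummy range.

## Problem sizes for replicated experiments

Replicated validation runs use sizes chosen to keep a full study of
replicates at desk scale: planted-axis recovery and the
contraction/coupling replicates run at the full design (P = 200,
43/group, 175 timepoints; 100 replicates); null calibration runs 500
replicates at P = 60, 20/group, 120 timepoints with sparsity scaled to
keep 24 retained connections per row, preserving graph density and
connectivity at the reduced parcel count. Measured behavior: axis
recovery |ρ| ≈ 0.9997; DMN-contraction detection ≈ 99/100; within-case
negative DMN–CESD sign in roughly 95 of 100 replicates (seed-dependent);
null rejection ≈ 0.04–0.07 at α = 0.05.

## Known limitations

- The alignment reference defaults to pooled-control gradients; against an
  external normative template, absolute scores would differ (alignment is
  not scale-free across templates since no scaling is applied).
- The `λ/(1−λ)` weighting amplifies sampling noise in λ₁ when the graph is
  strongly clustered (λ₁ near 1), which is the dominant source of
  between-subject score variance in the simulation; network-score
  contrasts remain well calibrated, but subject-level score reliability is
  sensitive to scan length.
- Small parcellations (P ≲ 100) at sparsity 0.9 can yield disconnected
  affinity graphs; the embedding refuses them by design rather than
  silently embedding a component.
- Only the first two gradients are written by the analysis scripts;
  components beyond ~3 in the synthetic model are noise-dominated.
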