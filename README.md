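# gradhier

Functional-connectome **gradient hierarchy** analysis for two-group
resting-state fMRI designs, exercised end-to-end on synthetic cohorts with
planted ground truth.

The scientific question this package addresses: does a clinical group (for
example, people with subthreshold depressive symptoms) show an altered
cortical hierarchy — a contraction of the principal connectivity gradient's
extremes, a lowered default-mode-network (DMN) gradient score, and a
coupling between DMN scores and symptom severity? It is written for
researchers who have parcel-level time series (200-parcel, Yeo-7-network
atlas convention) plus a cohort table, and for methodologists who want the
whole chain validated against a generative model with known structure.

## The method

For each subject with parcel time series `X` (T × P):

1. **Connectivity** — Pearson correlation `r_ij` between parcel time
   series; Fisher transform `z_ij = arctanh(r_ij)`; group matrices are
   entrywise means of subject z-matrices.
2. **Sparsification** — per row, keep the top 10 % of off-diagonal values
   (sparsity 0.9; `ceil(0.1·(P−1)) = 20` survivors per row at P = 200).
3. **Affinity** — cosine similarity between sparsified connectivity
   profiles, negatives clipped to zero.
4. **Diffusion-map embedding** — with degrees `d_i = Σ_j A_ij` and
   anisotropy α = 0.5, form `W_ij = A_ij / (d_i^α d_j^α)`, row-normalize to
   a random-walk operator, and eigendecompose via its symmetric conjugate.
   Dropping the trivial unit eigenvalue, gradient k scores each parcel by
   the k-th right eigenvector scaled by `λ_k / (1 − λ_k)`. The principal
   gradient (largest λ) runs from sensorimotor cortex to the DMN.
5. **Alignment** — orthogonal Procrustes rotation (reflections allowed, no
   scaling or centering) of every subject's P × k gradient matrix onto a
   common reference, by default the pooled-control group-average gradients.
6. **Hierarchy statistics** — per-network mean gradient scores (Yeo-7),
   shared-bin histograms, range/extremity contraction metrics,
   normality-gated two-sample tests (Shapiro–Wilk gate: equal-variance
   t-test vs tie-corrected Mann–Whitney U), chi-square for 2×2 tables, and
   within-case Pearson correlations with CESD/HAMD symptom scales, with
   optional Benjamini–Hochberg adjustment.

Because raw clinical fMRI for such designs is typically unavailable, the
`gradhier.simulate` module generates matched two-group cohorts in which a
known unimodal→transmodal latent axis `g` is planted: parcel covariance
decays exponentially with latent distance, the case group's axis is
contracted toward its mean by a factor κ (optionally only in the DMN), and
clinical scores are negative linear functions of each subject's planted DMN
level. Every downstream claim is then testable against ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on the flagship
synthetic cohort (43 + 43 subjects, 200 parcels, DMN contraction κ = 0.6)
and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_group_gradients.py
python analysis/03_subject_gradients.py
python analysis/04_network_stats.py
python analysis/05_clinical_correlations.py
python analysis/06_replicate_calibration.py
```

`02_group_gradients.py` prints, among other things:

```
contraction metrics (principal gradient):
            metric  control    case  delta_case_minus_control
       score_range   22.243  20.661                    -1.582
          score_sd    8.146   7.727                    -0.419
   top_decile_mean   10.757   9.583                    -1.174
bottom_decile_mean  -11.356 -10.928                     0.428
```

— the case group's principal gradient spans a narrower range, its top
extreme (DMN end) is pulled down and its bottom extreme (sensorimotor end)
pulled up: the planted hierarchy contraction, recovered. `04_network_stats.py`
then shows the network-level pattern (sensory networks' scores higher,
DMN significantly lower in the case group; matched demographics at p = 1),
and `05_clinical_correlations.py` reports the within-case clinical coupling:

```
within-case DMN network score vs clinical scales:
clinical_scale  pearson_r  p_value
          cesd    -0.4014   0.0076
          hamd    -0.5288   0.0003
```

lower DMN gradient scores go with more severe depressive symptoms, matching
the planted negative coupling.

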