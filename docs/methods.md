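# Methods

## Problem and data model

The package analyzes a registered lesion cohort: for each subject a fuzzy
lesion mask on a common template grid, with voxel values in [0, 1]
interpreted as the probability that the voxel is tumor after an
interpolating warp of a binary segmentation.  All statistics are computed
in voxel space on one `TemplateSpace` (grid shape, voxel size, brain
mask); the NIfTI affine is carried through I/O but never enters any
computation, so orientation conventions cannot change results.  The t
pathway analyzes the fuzzy probabilities as-is; only the relative-risk
pathway binarizes them (threshold 0.03 by default, with
`probability >= threshold` counting tumor-positive — the boundary rule is
stated because it is otherwise ambiguous).

## Severity grading and grouping

Per-test severity bands on standardized z-scores: severe `z < −2`,
mild/moderate `−2 ≤ z ≤ 0`, normal `z > 0`.  The boundary values −2 and 0
are assigned to the less impaired band, conservative toward the control
group: only unambiguously severe deficits define "affected".  A domain's
severity is the worst of its tests (subjective grades, where norms are
unavailable, enter the same worst-of ordering normal < mild_moderate <
severe); the affected group for a domain is exactly the severe subjects,
everyone else is control.  A subject-domain with no administered test is
absent from the assessment table, and `build_groups` refuses to form
groups unless every cohort subject is assessed, so the affected/control
lists always partition the cohort.

## Voxel statistics

* `t_map`: pooled-variance two-sample Student t,
  `t = (mean_control − mean_affected)/SE`, negative when the affected
  group carries more tumor; left tail is the alternative.  Pooled rather
  than Welch because it is the classical two-sample default and the
  permutation reference distribution makes the choice non-critical; Welch
  is available via `welch=True`.  Voxels with pooled variance below 1e−12
  (numerically zero) are invalid and excluded everywhere downstream.
* `rr_map`: relative risk as the ratio of group *proportions*
  `(a/n_a)/(c/n_c)`, not raw counts — raw counts are incomparable when
  group sizes differ (e.g. 78 vs 22).  `c = 0` with `a > 0` yields +inf
  (valid, maximally extreme); `a = c = 0` yields an invalid voxel.

## Permutation inference

Group labels are exchangeable under the voxelwise null, so nulls are
built by relabeling subjects with group sizes preserved.  If
`C(n, n_a) ≤ exhaustive_limit` (default 20 000) the complete enumeration
is used (the identity labeling is then one of the enumerated
assignments and p = count/total); otherwise `n_permutations` uniform
draws with the `(1 + #extreme)/(K + 1)` correction, so Monte-Carlo p is
never 0 and the test is exactly valid.  Ties count toward the extreme
tail (`≤` left / `≥` right, +inf ties +inf) — conservative.

Three modes:

* **min_stat** — per relabeling, the minimum of the voxelwise t values
  (the left-tail analogue of the maxT null): strong FWE control.
* **perm_percentile (Perm95)** — per relabeling, the 5th percentile of
  the voxelwise t values (`percentile_q=5`, linear interpolation between
  order statistics; nearest-rank via `percentile_method="lower"`).  Both
  summaries are recorded from a *shared* permutation stream, which makes
  the conservativeness ordering `p_minstat ≥ p_perm95` exact, free of
  Monte-Carlo noise.
* **per_voxel** — uncorrected per-voxel permutation p (used with RR),
  with Benjamini–Hochberg step-up q-values (via statsmodels) on top.
  Each p map retains the strict/tie counts behind it;
  `randomized_uniform_pvalues` turns them into the randomized-PIT
  transform `p* = (strict + U·(ties+1))/(K+1)`, which is exactly
  Uniform(0,1) under the null and is what calibration diagnostics
  consume (the conservative p itself is discrete and stochastically
  super-uniform, so a raw KS test on it measures the correction, not
  calibration).

A parametric reference map (Student t CDF, `n_a + n_c − 2` df, left
tail) is produced alongside for comparison.  Significance masks use
strict `p < α`; both α = 0.05 and α = 0.2 are always produced — the
looser threshold is the exploratory, "clinically significant" surface
that feeds the heatmaps.

## Parcel coverage

`coverage = 100 · |sig ∩ parcel| / |parcel|` per parcel and domain;
zero-coverage parcels are retained and voxels outside every parcel go to
a residual row, so summed counts conserve the significant-voxel total
exactly.  Ranking is by coverage desc, parcel size desc, label asc (a
deterministic total order; the tie-break is a package choice).  Heatmap
matrices take the union of each domain's top-N parcels (default top 40
for cortical atlases, all parcels for small subcortical ones), ordered
by maximum coverage across domains, with 0 for absent cells.

## Synthetic cohort generator

The generator emulates the *data contract* of a registered glioma
cohort, not tumor biology: one spherical lesion per subject (radius
uniform in 3–7 voxels at the default 32³ grid), Gaussian-smoothed
(σ = 1.5 voxels) to fuzzy [0, 1] values, clipped to an ellipsoid brain
mask (semi-axes 0.45 of the grid).  A spherical effect region (default:
mask center, radius ≈ grid/6) is the ground-truth "eloquent" area:
designated-affected subjects draw their lesion center inside it with
probability `effect_strength`, controls uniformly in the mask.  Scores
for 5 domains × 2 tests are `z = noise − deficit_shift · overlap` with
`overlap` the subject's mean lesion probability in the domain's region
(all domains share the central region by default, emulating multidomain
involvement) and `noise ~ N(0, 0.5)`.

Default study conditions, chosen once: `n_subjects=100` (cohort scale),
`n_affected=50` (domain affection rates in glioma cohorts span roughly a
quarter to three quarters; a balanced split is the neutral middle),
`deficit_shift=15` (overlap ≳ 0.15 of the region drives z below −2, so
lesion involvement, not noise, determines severity),
`score_noise_sd=0.5`.  `effect_strength=0` yields an exact global null —
labels independent of lesions — under which the permutation
exchangeability assumption holds by construction.

What the generator does *not* emulate: anatomy-aware lesion shapes,
multifocal disease, mass effect and registration distortion, correlated
test batteries, subjective-grading noise.  Passing calibration tests
therefore demonstrates correctness of the statistical machinery under
exchangeability, not robustness to those real-data complications.

Ground truth (labels, centers, effect mask) is kept in a separate object
that is never written into the pipeline's input artifacts, so recovery
metrics cannot leak into the analysis.

## Reproducibility and numerics

One base seed drives everything through derived `SeedSequence` streams
(cohort draw, score noise, per-domain permutations, calibration
batteries), so stages are independently rerunnable and a pipeline rerun
is byte-identical (gzip members are written with a zeroed timestamp).
Permutation statistics are evaluated in vectorized batches of 256
relabelings; group sums use the one-pass formulation with sums-of-squares
clipped at zero, which agrees with the textbook two-pass formula to
better than 1e−12 on probability-scale data.  Lesion volumes are
validated to [−1e−6, 1+1e−6] and clipped; anything further out is
rejected.

## Problem sizes in the shipped experiments

The calibration battery uses 200 simulated null cohorts of 40 subjects
on a 16³ grid with 200 relabelings each, and the recovery experiment one
cohort of 100 subjects on a 24³ grid with 1000 relabelings — sizes at
which the full stack runs in seconds while Monte-Carlo error on an FWE
rate at α = 0.05 stays near ±0.015.  Lesion radii are scaled with the
grid (2–4 voxels at 16³) to keep the lesion-to-brain volume ratio of the
default configuration.

## Known limitations

* Spatially extended lesions make every voxel within a lesion-radius
  "halo" of a true effect region genuinely group-different; voxelwise
  recovery of the *center prior* region therefore has a specificity
  ceiling well below 1 whenever power is high.  This is a property of
  lesion-symptom mapping itself, not of the inference machinery: the
  planted sphere is always recovered and its parcel ranks first, but the
  detected set extends over the dilated signal support.
* With very strong effects and K permutations, FWE p-values saturate at
  their floor 1/(K+1) over many voxels, so thresholded masks cannot
  separate strong from overwhelming evidence; raise K if that gradation
  matters.
* No covariate adjustment (lesion volume, age) and no spatial modelling:
  per-voxel tests ignore spatial correlation, exactly as the mapped
  procedures do; cluster-extent or TFCE-style inference is out of scope.
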