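# Methods

## Voxel model and geometry

All grids live in DICOM patient coordinates (LPS) and are axis-aligned;
a volume is a 3-D array indexed (x, y, z) with per-axis spacing in mm
and the origin at the *center* of voxel (0,0,0). Volumes are
sample-at-center: a structure's volume is (voxel count) × (voxel
volume), with no partial-volume weighting. Contours are rasterized with
the even-odd rule on voxel centers, so inner polygons cut holes; a
center lying exactly on a polygon edge is counted inside (deterministic
tie-break, tolerance 1e-9 of the coordinate scale). Dose grids are
resampled to the CT grid by trilinear interpolation
(`scipy.ndimage.map_coordinates`, order 1), which reproduces affine
fields exactly at interior points and never exceeds the source range.
CT voxels outside the dose grid's physical extent receive 0 Gy but stay
in every denominator — lung outside the dose matrix is unirradiated
lung — and the uncovered fraction is recorded on the resampled volume.

## Segmentation and DVH parameters

Emphysema on free-breathing CT is thresholded at **−856 HU** inside the
planning lung contour: LAV = lung voxels with HU < −856, HAV = lung
voxels with HU ≥ −856 (the boundary value is high attenuation). No
smoothing or connected-component filtering is applied. The −950 HU
convention belongs to inspiratory breath-hold CT and is deliberately
not a mode of this pipeline, though the threshold is a parameter.

Parameters are computed by direct voxel evaluation — no histogram
binning enters any reported value (binned curves exist only for
export, default 0.1 Gy):

- `MLD` = mean dose over the lung mask; `MHALD` = mean dose over HAV.
- `Vx` = 100 · volume(lung ∧ dose ≥ x) / TLV, inclusive at x.
- `HAVx%` = 100 · volume(HAV ∧ dose ≥ x) / TLV — note the **whole-lung
  denominator**, which makes HAVx% ≤ Vx and keeps both families on one
  scale.
- x grid: {2, 5, 10, 20, 30} Gy, configurable.

When HAV is empty, MHALD and HAVx% are undefined and reported as NaN,
never as zeros — silent zeros would bias every downstream cohort
statistic. Useful identities, enforced by tests: Vx and HAVx% are
non-increasing in x; TLV = LAV + HAV; MLD = (HAV·MHALD +
LAV·mean-LAV-dose)/TLV.

## Cohort statistics

Analyses are univariate throughout, matching how dose constraints are
used clinically; no multiplicity correction is applied and no adjusted
models are fit. Per parameter:

- **Logistic regression** of outcome (RP grade ≥ 2) on the parameter,
  Newton/IRLS with log-likelihood tolerance 1e-8, ≤ 100 iterations
  (statsmodels backend); Wald p-values. Quasi-complete separation
  (monotone class split, or |β₁|·sd(x) > 15) sets a flag and emits a
  warning; under a singular Hessian the fit falls back to BFGS so
  estimates are still reported.
- **AUC** via the Mann-Whitney formulation on midranks (ties count ½),
  identical to the trapezoidal ROC area.
- **Optimal threshold**: "highest sensitivity and specificity" is
  formalized as the Youden criterion, maximizing sens + spec over the
  *distinct observed values* with the risk-increasing orientation
  (positive iff value ≥ t); ties take the smallest t. Parameters are
  never auto-flipped. Interpolated cut-points are deliberately not
  used: observed-value thresholds are reproducible from the data table
  alone.
- **Between-cohort comparison**: per-parameter |threshold_A −
  threshold_B|, reported with each HAV parameter paired to its
  conventional counterpart (MHALD↔MLD, HAVx%↔Vx).
- **Baseline tables**: Fisher's exact test (2×2 by hypergeometric tail
  sum; r×2 by Freeman–Halton enumeration, r ≤ 5, written in-house as no
  installed Python package provides it) and the Wilcoxon rank-sum test
  (exact when min(n) ≤ 10 without ties, else normal approximation with
  tie and continuity corrections).

## Synthetic phantoms

The generator emulates only the features the method actually consumes:

- **Anatomy**: one ellipsoidal lung (semi-axes 85×70×55 mm) in soft
  tissue. Tissue HU are Gaussian — background 0±30, normal lung
  −750±40, emphysema −920±20 — so the −856 HU threshold separates
  tissue classes with small, quantifiable tail crossings (≈0.4% of
  normal lung falls below, ≈0.1% of emphysema above). No airways,
  vessels, tumors, or imaging artifacts.
- **Emphysema**: spherical blobs (radius 8–20 mm) added until a target
  LAV fraction is covered; the realized fraction at −856 HU is verified
  within ±0.05 or generation fails with the achieved value. Placement
  is uniform, optionally apically biased, or biased toward the beam
  axis (`blob_beam_affinity`): lung tumors — the beam target — and
  centrilobular emphysema co-localize in heavy smokers, so in a
  lung-cancer-like cohort irradiated lung is enriched in emphysema.
- **Dose**: separable beam model along the anterior-posterior axis —
  lateral Gaussian (σ ≈ 26–38 mm) × linear depth falloff
  (0.0035/mm), peak ~54–66 Gy — optionally combined (pointwise max)
  with a broader mid-dose shoulder and a sub-5-Gy scattered-dose floor,
  the signature of multi-field/IMRT-style plans. The dose is produced
  on a 2× coarser grid than the CT so every cohort exercises the real
  resampling path. Default grid 64×64×32 at 4 mm (≈43,000 lung
  voxels); the replicate experiments use 48×48×24 at 5.33 mm — the
  same physical extent — so one cohort pair takes about a second.
- **Outcomes**: Bernoulli(expit(β₀ + β₁·HAV20%)) with β₀ = −5, β₁ =
  0.25 — a 4-percentage-point logistic scale crossing p = 0.5 at
  HAV20% = 20, giving ~35–40% prevalence in both default cohorts.
  Events get CTCAE grade 2, non-events grade 0; higher grades are off
  by default since only the grade ≥ 2 dichotomy is analyzed. Effect
  sizes are free parameters of the simulation, chosen for realistic
  prevalence, not to match any reported coefficient.

## The two-cohort scenario

The default scenario encodes the contrast the method exists for. Both
cohorts share the outcome model on HAV20% (risk lives in
non-emphysematous lung). They differ in:

- **Emphysema burden**: LAV fraction 0.25±0.06 (lung-cancer-like)
  vs 0.05±0.03 (esophageal-cancer-like).
- **Beam geometry**: the lung-like cohort's beam overlaps its
  emphysema (affinity 0.65); the esophageal-like cohort has a central,
  narrower (×0.64), slightly cooler (×0.88) primary beam plus the
  mid-dose shoulder and scatter floor.

The B-side geometry was chosen so the two cohorts' *high-attenuation*
dose profiles (MHALD, HAV5–HAV30%) and hence event rates line up, while
the whole-lung parameters diverge because cohort A's conventional
parameters count heavily irradiated emphysema. A design point worth
recording: with Youden thresholds, each parameter's optimal cut sits
near the value where its conditional risk equals the cohort prevalence
— close to the cohort mean for unimodal data. Threshold *transfer*
between cohorts therefore requires matched HAV distributions, and an
MLD/MHALD contrast requires emphysema that is preferentially
irradiated; a generator with emphysema placed away from the beam
produces the opposite pattern. What passing the replicate experiment
shows is that the pipeline detects the transfer pattern when the
generating mechanism contains it — not that real cohorts contain it;
that evidence can only come from patient data.

## Determinism and numerics

Every stochastic object is reproducible from (config, seed); cohort
generation derives per-patient seeds from one `numpy` Generator.
Statistics paths are fully deterministic, so re-running the report
writer on the same inputs is byte-identical. CSV output is rounded to
4 decimals; JSON keeps full precision. Exact-test enumeration compares
log-probabilities with a 1e-9 tolerance to absorb floating-point ties.

## Known limitations

- Phantoms are geometric sketches: no respiratory motion (the
  free-breathing setting enters only through the −856 HU convention),
  no heterogeneity corrections, no realistic beam arrangements.
- The lung contour is an input everywhere; automatic lung segmentation
  and airway/tumor exclusion are out of scope (an exclusion structure
  can be subtracted when given).
- Youden thresholds on observed values are step functions of the data;
  with n ≈ 60 their sampling variability is a few units, which is why
  cohort comparisons are evaluated over replicates rather than single
  draws.
- Only axis-aligned geometries are supported; oblique direction
  cosines are rejected rather than silently mishandled.
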