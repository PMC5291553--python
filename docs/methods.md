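# Methods

## Signal model and units

The forward model is the Le Bihan biexponential
`S(b) = S0·[f·exp(−b·D*) + (1−f)·exp(−b·D)]`. Internally everything is
kept in mm²/s and fractions; the reporting scales (×10⁻³ mm²/s, percent)
are applied only when writing cohort CSVs or printed summaries, which
avoids unit mistakes inside the optimizer. The model is symmetric under
swapping `(D, 1−f) ↔ (D*, f)`; the constraint `D* ≥ D`, enforced at fit
time, picks one branch and makes the parameters identifiable.

The default acquisition is a 12-b breast protocol,
b = 0, 10, 20, 30, 50, 70, 100, 150, 200, 400, 800, 1000 s/mm² with
per-b averaging counts (NEX) 1, 3, 3, 3, 3, 2, 2, 2, 2, 3, 5, 6. b
values serialize to the FSL bval dialect; NEX goes in a YAML sidecar
because the bval format has no slot for it.

## Segmented fitting

Stage 1 fits `ln S` vs `b` by unweighted ordinary least squares over
`b > 200 s/mm²` (strictly exclusive, so {400, 800, 1000} by default).
The cut rests on the perfusion pool being fully decayed there —
`exp(−400·D*) ≈ 0` — which holds for D* above roughly 15×10⁻³ mm²/s;
for slower D* a segmented fitter is intrinsically biased, which is why
the round-trip property test restricts D* to ≥ 15×10⁻³ (the clinically
observed range is ~14–40×10⁻³). `D = −slope`, clamped positive;
`f = 1 − exp(intercept)/S(0)`, clamped to [0, 1]. Non-positive signals
(possible after magnitude averaging) are excluded point-wise; fewer than
two usable points is an error at the decay level and an unconverged,
all-missing voxel at the map level.

Stage 2 minimizes the sum of squared residuals of the full biexponential
over all b values, freeing `(D*, f, S0)` with `D` fixed from stage 1.
Initialization is `(10×10⁻³ mm²/s, stage-1 f, measured S(0))`; bounds
`f ∈ [0, 0.6]`, `D* ∈ [D, 0.5 mm²/s]`. The solver is SciPy's trust
region reflective (`least_squares(method="trf")`) — the same damped
Gauss–Newton family as Levenberg–Marquardt, chosen because the box
constraints require a bounded solver; tolerances 1e−10, iteration cap
1500 function evaluations. Refining `f` in stage 2 makes noiseless round
trips exact while `D` stays stage-1-determined; on noiseless decays the
refined and intercept-only `f` agree, so the choice is free at the
precision we report.

If stage-1 `f < 0.01` the perfusion term carries no curvature and `D*`
would be arbitrary; the fit skips stage 2, reports `D*` as NaN and
`converged=False`. This prevents the wild `D*` excursions that make the
parameter notoriously unstable. Fitting is fully deterministic: the same
decay gives bit-identical results.

## Digital phantoms

`generate_phantom` builds an ellipsoidal lesion (default radii 10×8×4
voxels on a 64×64×16 grid, 2.5 mm in-plane, 6 mm slice spacing = 5 mm
section + 1 mm gap) whose voxels draw (D, D*, f) independently and
uniformly from configurable ranges (defaults D ∈ [0.8, 1.5]×10⁻³,
D* ∈ [10, 45]×10⁻³ mm²/s, f ∈ [0.10, 0.40], spanning tumor values before
and during therapy), inside a monoexponential background (f = 0,
D = 1.8×10⁻³ mm²/s, fibroglandular-like). Noise is Rician and applied
per b value: each of the NEX excitations draws
`sqrt((S+g₁)² + g₂²)`, g ~ N(0, σ²), and the stored image is the mean of
the NEX magnitudes — magnitude averaging, as clinical scanners do, which
introduces the realistic low-SNR noise floor. SNR is defined as lesion
S0/σ at b = 0 and is a configuration knob (no published value exists for
the protocol being emulated). Everything is seeded and bit-reproducible.

What the phantom does *not* emulate: EPI distortion, fat suppression,
coil profiles, motion, partial volume at lesion edges, spatial noise
correlation. Passing recovery tests on it demonstrates the estimator's
statistical behavior under magnitude noise, not robustness to scanner
artifacts.

At SNR 50 with the default scheme, error propagation through the
unweighted log-linear stage gives a per-voxel D standard deviation of
about 7%, i.e. a median absolute relative error of ≈5% — the parameter
recovery benchmark in the acceptance suite sits exactly at that
boundary, and its D bound is expected to be marginal by construction
(f recovers to ~3% median, D* to ~8% at high f; D* degrades sharply as
f falls, mirroring its clinical instability).

## ROI measures and Δ-parameters

ROI means average D and f over fitted voxels and D* over identifiable
voxels only. Triplicate measurement is emulated by three seeded re-draws
of the ROI with random boundary-voxel toggling (manual re-measurements
differ at the boundary, so averaging three identical means would be
vacuous); `n_repeats=1` disables it. Maximum transverse diameter is the
largest in-slice pairwise distance between voxel centers (convex-hull
accelerated, 0 mm for a single voxel by convention); volume is voxel
count × in-plane area × slice spacing.

The change convention is `Δx = x_pre − x_mid` everywhere, so a parameter
that *rises* under therapy has a *negative* Δ (a strongly responding
tumor has ΔD ≈ −0.4×10⁻³ mm²/s); Δf is in percentage points and
shrinkage is `100·(pre − mid)/pre`. Cutoff classification places ties on
the positive side.

## Synthetic cohorts

`simulate_cohort` draws a 9 pCR + 19 non-pCR cohort (the split is
reconstructed from published exact binomial CIs — 9/9 → 66.4% lower
bound, 14/19 → 48.8% — and sums to the 28 patients with both scans).
Per patient and parameter, pre and mid values come from correlated
standard normals (ρ = 0.72 on the Gaussian scale) pushed through the
configured marginals (normal, or lognormal for the skewed, highly
dispersed D* and for sizes), then clamped to physical ranges. The
timepoint means are the published group summaries where printed
(f_pre 32.4% vs 24.4%; ΔD −0.45 vs −0.07×10⁻³ mm²/s; Δf 17.3 vs 5.3
points) and plausible values elsewhere; the SDs are not published and
are package assumptions (D 0.2×10⁻³, f 8 points, D* dispersion ~55%),
with ρ = 0.72 chosen so the implied change SDs are ≈0.15×10⁻³ for D and
≈6 points for f. Under these defaults the ΔD separation corresponds to
an analytic AUC ≈ 0.96 and the ΔD* separation to ≈ 0.55. An optional
attrition flag drops 8/36 of the mid rows. All defaults are
config-overridable; pipeline results on default cohorts are
direction-level statements about the generator, not numeric
reproductions of any study.

## Statistics

* **Routing**: Lilliefors-corrected Kolmogorov–Smirnov per group at
  α = 0.05 (the correction is what SPSS-era workflows apply when mean
  and SD are estimated); both normal → pooled-variance Student t,
  otherwise Mann-Whitney. Constant or n < 4 samples route nonparametric
  with a warning.
* **Mann-Whitney**: midranks; exact two-sided p by full enumeration of
  group assignments (`p = P(|U−μ_U| ≥ |u−μ_U|)`) while
  `C(n1+n2, n1) ≤ 20 000`, tie-corrected normal approximation beyond.
  Exactness under ties is why this is hand-rolled rather than delegated.
* **AUC**: Mann-Whitney pair counting with ties at one half, auto-
  oriented to ≥ 0.5 (orientation recorded and logged); CI from the
  Hanley–McNeil standard error with a normal interval truncated to
  [0, 1].
* **Youden cutoff**: exhaustive scan over midpoints between adjacent
  distinct scores plus the two corner thresholds (everything/nothing
  positive); ties broken by higher sensitivity, then smaller |cutoff|.
* **Diagnostic metrics**: exact Clopper–Pearson 95% intervals
  (beta-quantile form); zero denominators yield flagged NaNs.
* **AUC difference**: Hanley–McNeil z with
  `SE² = [A(1−A) + (n₊−1)(Q1−A²) + (n₋−1)(Q2−A²)]/(n₊n₋)`,
  `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`. The between-marker correlation `r`
  is an explicit argument; for pipeline use it is estimated as the mean
  of the within-class Pearson correlations of the two score vectors — a
  practical approximation to the original lookup table (which maps the
  within-class correlation and mean AUC to `r`, and stays close to, and
  slightly below, that average over most of its range), adopted because
  the table itself is not reproducible here without fabrication.
* **Spearman**: midrank ρ with the t-approximation p, ≥ 4 pairs.
* **Multiplicity**: none — single two-sided tests at α = 0.05, flagged
  as such in the report metadata, matching common practice in small
  exploratory imaging cohorts.

`run_full_analysis` composes these into a JSON-serializable report
(group comparisons for D, D*, f, diameter and volume at pre/mid/Δ; ROC
work-ups; pairwise Δ-marker AUC comparisons; Spearman correlations of D
and f with diameter and volume shrinkage) and is deterministic given the
input table. Cohorts without mid-treatment rows run in pre-only mode.

## Problem sizes

Desk-scale defaults throughout: phantom grids of 10⁴–10⁵ voxels fit in
seconds (≈3 ms per voxel fit), the recovery benchmark uses ~500 lesion
voxels, cohort simulations use the 28-patient default or 10⁴ patients
for law-of-large-numbers calibration checks, and the exact
Mann-Whitney enumeration is capped at 20 000 assignments.

## Known limitations

* The segmented fitter assumes `exp(−400·D*) ≈ 0`; tumors with genuinely
  slow pseudo-diffusion violate it and bias D upward.
* D* estimates are unstable at low f by the physics of the model, not as
  an implementation artifact; the unidentifiability floor trades silent
  garbage for explicit missingness.
* The AUC-difference test uses an approximation for `r` (above) and the
  normal Hanley–McNeil interval, not DeLong or bootstrap methods.
* Synthetic cohorts draw parameters per patient independently across
  parameters (no D–f correlation structure), so joint-marker analyses on
  them are optimistic.
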