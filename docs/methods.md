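# Methods

## Functional representation

Each waveform is an ordered set of (time ms, amplitude µV) samples on a
strictly increasing grid.  Curves are interpolated piecewise linearly
(polygonal basis); no smoothing basis is offered, because every downstream
statistic is defined on the observed values and a smoother would change
them.  Evaluation outside a curve's sampled domain is always an error —
callers must window query grids to the intersection of domains rather than
rely on extrapolation.

## Landmarks

The a-wave minimum is the minimal-amplitude **sample** in a closed search
window (default 5–25 ms); the b-wave maximum is the maximal-amplitude
sample strictly after it (default window up to 60 ms).  Ties break to the
earliest time, matching the first-trough/first-peak clinical convention
and making detection deterministic.  Landmarks are exact samples — no
sub-sample (parabolic) refinement — so the registration endpoints are
exact grid points and the registered endpoints are exactly (0,0) and
(1,1) in floating point.  A waveform whose detected "b-wave" does not
exceed its "a-wave" (for example a flat trace) is flagged degenerate,
kept in the landmark table, and excluded from registration with a logged
warning.

The AL-b segment is the closed slice of samples between the two landmarks;
by construction its first/last samples equal the landmarks and the
landmark amplitudes are the segment extrema.

## Registration

Two-landmark affine registration maps each segment onto the unit square:
`u = (t−t_a)/(t_b−t_a)`, `w = (v−v_a)/(v_b−v_a)`.  This is deliberately
the simplest form of curve registration — no monotone time-warping beyond
the two landmarks — and is exactly invariant under positive affine
transforms of either raw axis, which is the property that removes
inter-individual amplitude and latency variability.  Registered curves
are resampled by the same polygonal interpolation onto a common uniform
grid `u_j = j/(m−1)`; the default `m = 101` (step 0.01) makes registered
time 0.6 an exact column.  Comparing on a common registered grid (rather
than at each curve's own warped sample positions) is a convention of this
package.

## Pointwise summaries and bands

All statistics are computed independently at each grid point across
waveforms (rows):

* **mean** — t-interval `x̄ ± t₁₋α/₂,ₙ₋₁·s/√n` (default α = 0.05);
  standard for small n and exact under Gaussian sampling.
* **median, SD, MAD** — seeded percentile bootstrap over rows (default
  1000 replicates).  The percentile band is clipped, where necessary, to
  contain the full-sample point estimate, so the band invariant
  `ci_low ≤ estimate ≤ ci_high` holds even at very small n; SD/MAD bands
  are additionally floored at 0.
* **MAD variant** — "MAD" is ambiguous in common usage; the default here
  is the conventional robust choice, the *median* absolute deviation
  about the median, unscaled.  `mad_kind` selects
  `mean_about_mean`/`mean_about_median`, and `mad_scale` can apply the
  Gaussian consistency factor 1.4826.
* **boxplots** — Tukey rule: quartiles by linear interpolation of order
  statistics (classical hinges available), whiskers at the most extreme
  data within 1.5·IQR of the quartiles, everything beyond flagged as an
  outlier with its waveform id.

Waveforms from a participant's two eyes are treated as independent rows
by default.  For sensitivity analysis, `BootstrapSpec(cluster_ids=...)`
resamples participants (clusters) instead of rows.

The bands are pointwise: no simultaneous (family-wise) coverage is
claimed, and the overlap scan applies no multiplicity correction across
grid points.  Interval endpoints of the scan should therefore be read as
descriptive localisation, not as a formal global test.

## Group comparison by band overlap

At each grid point the two groups' intervals either overlap or not; the
signed gap between the nearer CI boundaries is positive exactly when they
are disjoint.  Bands that merely touch at a boundary count as overlapping
(deterministic convention for the boundary case).  Maximal runs of
non-overlapping points are collapsed into significant intervals (unions
of grid cells; no interpolation of significance between grid points).
`best_separation_point` returns the grid point with the widest gap (ties
to the earliest), or the point of least overlap with a non-positive gap
when nothing is significant.

Non-overlap of two 95% intervals is a *conservative* test: under a
Gaussian null with equal means the per-point rejection rate is far below
5% (empirically under 1% at n = 25 per group; see
`scripts/acceptance.py`).  The rule is implemented as stated, and its
conservativeness is documented rather than corrected.

## Synthetic cohorts

The generator emulates a two-group photopic flash-ERG study: per group a
noise-free template

```
v(t) = −A_a·G(t; μ_a, σ_a) + A_b·G(t; μ_b, σ_b) + Σ_k O_k·G(t; μ_k, σ_k)
```

with Gaussian bumps `G` on a 0–60 ms grid (dt = 0.5 ms).  Defaults:
a-wave 10 µV at 15 ms (σ 3 ms), b-wave 25 µV at 30 ms (σ 6 ms), two
oscillatory potentials 2.5 and 3 µV at 16 and 22 ms (σ 1.2 ms).  The
amplitudes are plausible for photopic skin-electrode recordings and are
configuration, not claims about any particular dataset.  Per participant
(25 per group, 2 waveforms each) a lognormal amplitude multiplier
(CV 0.15, mean 1) and a Gaussian latency shift (sd 1 ms) are applied to
the whole template and shared across both eyes, so cluster bootstraps
have real structure to find; per waveform, white noise smoothed by a
5-sample moving average and rescaled to sd 0.5 µV is added (averaged
clinical waveforms are relatively clean, being means of tens of sweeps).
All draws flow from one `numpy.random.default_rng(seed)` (PCG64) stream:
same seed, bit-identical cohort, any platform.

**Case-group effect (the "figure-3-like" preset, also the default):**
b-wave amplitude ×0.6, b-wave latency +0.5 ms, second OP ×0.8.  The
direction of the registered contrast follows from the registration
algebra: writing `D = −v_a` for the trough depth, the registered mid-rise
amplitude is roughly `(A_b·g(u) + D)/(A_b + D)`, which *increases* as
`A_b` falls (the trough offset weighs more against a smaller span), while
a latency delay *decreases* it (≈ −0.027 per ms at u = 0.6).  With the
preset values the case template sits ≈ +0.03 registered units above
control at u = 0.6, while its raw b-wave maximum remains lower and later
— reproducing the qualitative dissociation between raw and registered
group comparisons that motivates registration.  The +0.5 ms delay is one
grid step, so the delayed template's argmax falls on a strictly later
grid point.

What the generator does **not** emulate: biophysical phototransduction
kinetics, luminance-response series, recording artifacts (blinks, drift),
asymmetric or multi-peaked b-waves, age/sex structure, or unequal group
sizes.  Passing tests therefore demonstrate the statistical machinery on
Gaussian-bump morphology with idealised noise, not performance on any
clinical recording.

## Numerical and validation choices

* Closed intervals throughout: display windows (default 9.55–34.9 ms),
  landmark search windows, and AL-b slices all include their endpoints.
* Missing cells in input CSVs are rejected, never imputed; pointwise
  statistics assume complete curves.  CSV floats are parsed with numpy's
  round-trip-exact converter so write→read→write is byte-identical.
* Registered matrices have exactly-0 and exactly-1 endpoint columns;
  degenerate zero-variance columns are handled (t-interval collapses to a
  point; bootstrap quantiles are constant).
* In validation of the simulator's "delayed b-wave" property, the mean
  curve's peak time is measured with three-point parabolic (sub-grid)
  interpolation, because a 0.5 ms shift cannot be resolved by a bare
  argmax on a 0.5 ms grid when the averaged curve is nearly flat at its
  peak.  Landmark *detection* itself remains pure argmax by design.
* Monte-Carlo problem sizes used in the statistical checks — 500
  replicates for band coverage (n = 30 curves), 1000 replicates for the
  null non-overlap rate (n = 25 per group), 12 replicates per effect size
  for the power-monotonicity check — were chosen to keep Monte-Carlo
  error comfortably inside the asserted tolerances while the whole suite
  runs in seconds.

## Known limitations

* Pointwise inference only: no functional ANOVA, permutation global
  tests, simultaneous bands, or FDR across grid points.
* Two-landmark affine registration cannot align internal features (the
  OPs) that occur at different *relative* positions on the limb; full
  monotone warping is out of scope.
* Shape measures beyond location/scale (e.g. pointwise kurtosis) are not
  provided.
* The CI-overlap rule's effective level depends on the estimator and n;
  it is reported as implemented, not calibrated to exactly 5%.
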