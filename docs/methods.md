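# Methods

## The measurement problem

A cat with its head fixed on a trolley is carried slowly toward a large
stationary sinusoidal grating while a V1 neuron's spikes are recorded under
free gaze.  A grating of physical period *p* (mm) viewed at distance *d*
(mm) has retinal spatial frequency

    sf(d) = d / (p · 57.3)   cycles/degree,

so the approach sweeps a fixed physical stimulus through a continuum of
retinal spatial frequencies.  A neuron tuned to a retinal spatial frequency
*f* must respond maximally at distance d* = f · p · 57.3: halving the period
(the 2F grating) halves the distance of the response maximum.  A neuron
tuned to the *absolute distance* of the screen responds at the same place
for any grating.  The shift statistic

    Shift = (M1 − M2) / M2 · 100%

(M1, M2 = maximum distances for the 1F and 2F gratings) therefore predicts
100% for frequency tuning and 0% for absolute-distance tuning, and the
pipeline's job is to decide, per neuron, which regime the data support.

Two protocols are implemented: *distant space*, 2.8 → 0.2 m at 10 mm/s
(260 s approach, periods 38/19 mm), and *near space*, 1.03 → 0.11 m at
1.7 mm/s (≈541 s, periods 12/6 mm).  Each trial is 60 s dwell, approach,
30 s dwell; gratings alternate, at least six trials per grating.  During
approach the projection of an off-axis point drifts over the retina at
V1 = V2·E·D1/D2² (mm/s; V2 trolley speed, E eccentricity on the screen,
D1 = 13 mm eye diameter, D2 distance), i.e. it accelerates as 1/D2²; the
slow trolley speeds keep this drift below disruptive values over most of
the track.  The degrees-per-radian constant is 57.3 and the deg/s per mm/s
conversion is 57.3/13 ≈ 4.41; both follow from the small-angle pinhole
model and reproduce the protocol's printed cycles-per-degree values.

## Analysis pipeline

1. **Spike density.**  Each trial's spike train becomes a rate curve using a
   sliding boxcar window of 20 s stepped every 0.01 s (window count divided
   by the covered duration; edge windows truncated at the trial span).
   Window centers are restricted to the approach phase and mapped to
   distance through the trolley trace, so all trials of a protocol share
   one distance grid.  The window is deliberately long — it spans 200 mm
   (distant) / 34 mm (near) of track — to integrate over gaze-driven rate
   fluctuations rather than chase short bursts.
2. **Maximum and its significance.**  Trials of one grating are averaged
   pointwise (mean ± SEM) and the global maximum of the mean curve located
   (ties broken toward the farthest distance, the earlier and less
   drift-contaminated observation).  Significance is a bootstrap test with
   1000 resamples at the 95% level: trials are resampled with replacement
   and each resampled curve is given an independent random circular shift
   along the track before averaging; the null distribution is the maximum
   of these surrogate mean curves.  Rotation preserves the rate level and
   the autocorrelation imposed by the 20 s window while destroying
   across-trial alignment of any distance-locked response, so the test is
   calibrated for the *maximum* statistic: a plain percentile band for the
   mean rate level would be exceeded by the max of a flat noisy curve
   almost surely, whereas the rotation null keeps the false-positive rate
   at or below the nominal 5% (verified on flat Poisson simulations).
   Inside the bootstrap the curve is decimated to a 1 s grid; the curve
   varies on the 20 s window scale, so the maximum is insensitive to this.
3. **Shift classification.**  Only neurons with both maxima significant
   proceed (joint chance level 0.05² = 0.0025).  Boundary rules first:
   both maxima within one window span of the track end → *constant maximum
   at the minimal distance* (rate rising monotonically toward the screen);
   1F maximum at the far boundary → excluded, because its true maximum may
   lie beyond the track (and, if the 2F maximum additionally sits closer
   than half the start distance, the cell is an *outlier* whose implied 1F
   maximum is off-track).  Otherwise each trial's own density argmax enters
   the all-pairs shift distribution (6 × 6 = 36 values) and the cell is
   labelled **shifting** if the mean pairwise shift exceeds 70% and a
   one-sided exact sign test (binomial tail, ties dropped) rejects at
   α = 0.05 that the median pairwise shift is at or below 70%, or
   **constant** if the mean is below 30% with the mirror-image test below
   the 30% boundary; anything else is *unclassified*.  The sign test for
   the shifting class is run in the direction that demonstrates the median
   *above* the 70% boundary, mirroring the constant-class construction.
   No multiple-testing correction is applied across neurons; the report
   prints the expected false-discovery count n × 0.0025 instead.
4. **Population structure.**  Mean pairwise shifts of all neurons reaching
   the shift stage are pooled; a Lilliefors test documents that the pooled
   set is non-normal while the two clusters obtained by splitting at 50%
   are individually normal (mean ± SD reported per cluster).  Positions of
   constant maxima are tested for normality and clustered with a 1-D
   Gaussian mixture whose component count (1–4) is chosen by BIC.

Statistical primitives are delegated where a standard implementation
exists: Lilliefors via statsmodels, the Gaussian mixture via scikit-learn,
binomial tails via scipy.  The shift statistic, pairwise distribution,
classification rules, density estimator and bootstrap are implemented here
and cross-checked in the tests against independent oracles (explicit
double loops, closed-form binomial sums, finite-difference projections,
Monte-Carlo calibrations).

## Synthetic data: what it emulates and what it does not

No recordings are distributed with the analysis, so a generator produces
ground-truth populations.  Archetypes: `sf_tuned` (log-Gaussian tuning in
octaves around an optimal retinal SF), `distance_tuned` (Gaussian on the
physical distance axis, grating-independent), `monotonic_near`/
`monotonic_far` (logistic profiles with no interior peak), and
`nonresponsive`.  Spikes are drawn from an inhomogeneous Poisson process by
thinning, with intensity = tuning curve along the trajectory × a slowly
varying log-normal gain (Ornstein–Uhlenbeck on log rate, correlation time
5 s, unit mean).  The gain is the free-gaze surrogate: the analysis only
ever sees the effect of uncontrolled gaze on 20 s window rates, so a slow
multiplicative gain models exactly that effect without simulating eye
position.  The gain is clipped at 1 + 6·CV so the thinning ceiling
(baseline + peak) × (1 + 6·CV) is never exceeded.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| baseline rate | 4 Hz | low ongoing V1 firing; with the 20 Hz peak this gives the peak/baseline = 5 ratio used in the recovery experiments |
| peak rate | 20 Hz | strong localized response, realistic for driven V1 cells |
| optimal SF (population draw) | log-uniform over the admissible range | optima between 0.25–2 c/deg with the admissible interval keeping every grating's predicted maximum ≥ 2.5 window spans inside the track — mirroring the experimental selection, since off-track maxima are precisely the excluded monotonic/outlier categories |
| SF bandwidth σ | 0.5 octaves | FWHM ≈ 1.2 octaves, the typical cat V1 tuning width; broader values blur the distance-domain peak so much that per-trial maxima scatter across the 70% decision boundary |
| distance-tuning σ | 300 mm | broad, strongly overlapping depth tuning (distant space) |
| distance optima (population draw) | uniform, 35% of start distance → 2.5 window spans below start | constant maxima are empirically found in the upper part of the track; optima near the track end also make percent-shift noise blow up as 1/distance |
| gain CV | 0.10 | calibrated once so that the emergent per-neuron shift scatter keeps the two shift clusters separable at the ≥ 90% level specified for the default SNR; the resulting cluster SDs (≈ 4% and ≈ 12%) are *below* the empirical 13.3%/30.3%, which include between-animal and recording variability the generator does not model |
| OU correlation time | 5 s | slow gaze-related fluctuation, shorter than the smoothing window |

Consequently, passing the recovery tests shows the pipeline separates the
two tuning regimes under gaze-like gain noise and Poisson variability; it
does **not** show robustness to everything real recordings contain —
non-Poisson spiking, drift responses at short distances, electrode drift,
arousal changes, or eye-movement artifacts correlated with track position.
An optional drift-response component is deliberately omitted (off) in v1.

## Ratio-code decoder

Constant-maximum cells are broadly tuned and overlap, so single-cell rates
are ambiguous (symmetric around the peak) and stimulus-dependent.  The
ratio of two cells' rates is invariant to any common gain (illumination,
spatial frequency) — the trichromacy trick applied to depth.  The decoder
matches observed rates o to tabulated curves r_i(d) by minimizing

    J(d) = Σ_{i<j} [ (log o_i − log o_j) − (log r_i(d) − log r_j(d)) ]²

over a distance grid, with ε = 0.1 Hz added inside every log.  The argmin
is restricted to the population's support (grid points where the largest
predicted rate is ≥ 5% of its grid-wide maximum): outside it the ε floor
dominates and predicted ratios degenerate toward 1 regardless of distance,
which would let far-tail distances spuriously match any equal-rate
observation.  A flat objective over the support (identical curves) returns
no estimate.  Monte-Carlo experiments with additive rate noise confirm the
flank-precision property: decoding error is smaller between the peaks,
where all curves have steep gradients, than at the peaks themselves, across
tuning widths of 300–900 mm.  The Gaussian curve shape and the decoder
itself are demonstrative design choices; no claim of biological decoding
plausibility is made.

## Numerical and degenerate-input conventions

- Density computed on the time axis (the window is defined in seconds) and
  mapped to distance afterwards; all trials of a protocol share one grid.
- Empty spike train → all-zero curve (valid); all-zero curve → undefined
  maximum, never significant.  Flat or multi-peaked curves break ties
  toward the farthest distance and are flagged degenerate.
- Excluded trials (e.g. sleep-spindle contamination) are dropped before any
  computation; a neuron left with fewer than six trials per grating is
  reported as `insufficient_trials`, not silently dropped.
- Boundary tolerance defaults to one window span on the distance axis
  (200 mm distant / 34 mm near): a maximum cannot be localized more finely
  than the window.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; same seed → byte-identical outputs.
- Three-grating recordings classify on 1F vs 2F; the 2F-vs-3F shift
  (expected 50% for frequency tuning) is reported as a consistency check.

## Problem sizes

The population recovery experiments run 50 + 50 neurons × 6 trials ×
2 gratings per seed over five seeds, with the full 0.01 s density grid and
1000 bootstrap resamples per grating — about 45 s on one core.  Bootstrap
calibration uses 200 simulated flat neurons; decoder Monte-Carlo uses
200–1000 draws per test distance.  These sizes were chosen to make the
binomial slack on each claimed proportion small relative to its margin.

## Known limitations

- The bootstrap null (trial resampling + circular rotation) is one
  defensible construction; the original toolbox band construction is not
  fully specified anywhere, and only the 95% level is certain.
- Whether the 30%/70% thresholds apply to the mean shift or to the fraction
  of pairwise shifts is ambiguous in the source description; the mean is
  used and the pair fractions are reported alongside.
- The per-trial argmax is a crude location estimator at low rates; trials
  with no spikes are dropped from the pairwise distribution.
- Near-space cells with maxima beyond the track (monotonic-far profiles)
  are excluded rather than extrapolated; no attempt is made to recover
  their true optima.
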