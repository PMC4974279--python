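# approachscan

Spike-train analysis for the *slow physical approach* paradigm: an observer
(a head-fixed cat on a trolley) is carried toward a large stationary
sinusoidal grating while single V1 neurons are recorded under free gaze.
Because a grating of physical period *p* viewed at distance *d* has retinal
spatial frequency `sf(d) = d / (p · 57.3)` cycles/degree, the approach
sweeps one physical stimulus through a continuum of retinal spatial
frequencies — and lets two fundamentally different tuning regimes be told
apart:

- a **spatial-frequency-tuned** cell peaks where its preferred retinal
  frequency is attained, at `d* = f · p · 57.3`; halving the period halves
  the distance of the maximum (a *shifting maximum*);
- an **absolute-distance-tuned** cell peaks at the same physical distance
  whatever the grating (a *constant maximum*).

With M1 and M2 the maximum distances for the low- and high-frequency
grating, the shift statistic

    Shift = (M1 − M2) / M2 · 100 %

predicts 100% for frequency tuning and 0% for depth tuning.  The package
implements the full decision pipeline — sliding-window spike densities
(20 s window, 0.01 s step), bootstrap significance of response maxima at
the 95% level, the all-pairs shift distribution over per-trial maxima
(6 trials per grating → 36 shifts), exact sign-test classification against
the 30%/70% boundaries, and population-level normality/cluster analyses —
plus a synthetic-data generator (inhomogeneous Poisson spiking with slow
gaze-like gain noise) that provides ground truth for every stage, and a
demonstrative ratio-code decoder that reads absolute distance from the
rate *ratios* of overlapping constant-maximum cells, invariant to common
gain the way trichromatic color vision is invariant to illumination.

Intended users: electrophysiologists and computational-neuroscience
students working on depth/distance coding, spike-density statistics or
naturalistic stimulation paradigms.

## Worked example

Simulate a small mixed population (3 frequency-tuned + 3 distance-tuned
neurons, distant-space protocol: 2.8 → 0.2 m at 1 cm/s, gratings 38/19 mm),
analyze it, and summarize:

```bash
approachscan simulate --protocol distant --n-sf 3 --n-distance 3 --seed 7 -o demo/data
approachscan analyze demo/data --seed 7 -o demo/results
approachscan report demo/results/population.json
```

which prints:

```
neurons studied:            6
significant both gratings:  6
  constant                  3
  ...
  shifting                  3
  unclassified              0
expected false discoveries: 0.015
constant_cluster: n=3 mean=0.1% SD=2.1%
shifting_cluster: n=3 mean=101.8% SD=8.9%
```

All six neurons pass the double significance test (the chance probability
of both maxima being significant is 0.05² = 0.0025, hence the expected
false-discovery count 6 × 0.0025 = 0.015).  The three distance-tuned cells
land in a cluster of mean shift 0.1% — their maxima stay put when the
grating period halves — and the three frequency-tuned cells in a cluster
at 101.8%, the geometric prediction of a maximum moving half way to the
screen.  Per-neuron detail is in `demo/results/classification.csv`; e.g.
the first frequency-tuned cell has M1 = 1895 mm, M2 = 853 mm and a
sign-test p of 1.6 × 10⁻⁴ against the 70% boundary.

The ratio-code demonstration:

```bash
approachscan ratio-demo --seed 1
```

```
true distance 2000 mm -> decoded 2000 mm
rates x3 (illumination change) -> decoded 2000 mm
Monte-Carlo RMSE: flank 37 mm, peak 81 mm (flank better: True)
```

Tripling both cells' rates (an illumination or spatial-frequency change)
leaves the decoded distance untouched, and decoding is about twice as
precise on the tuning-curve flanks, where both curves have steep
gradients, as at the peaks.

The same functionality is available as a library
(`approachscan.simulate_recording`, `classify_neuron`, `run_population`,
`decode_distance`, …); see `docs/methods.md` for the statistical model,
parameter defaults and their rationale.

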