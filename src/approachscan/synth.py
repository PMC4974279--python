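"""Synthetic spike-train generator for the approach paradigm.

Simulates single neurons of defined archetypes recorded while the animal is
carried toward a stationary grating, so every downstream stage (density
estimation, bootstrap significance, shift classification, population
summaries) is testable without recorded data.

Archetypes
----------
``sf_tuned``
    Classical spatial-frequency-selective cell: log-Gaussian tuning (in
    octaves) around an optimal retinal spatial frequency.  Because retinal SF
    grows with viewing distance, its response peaks at distance
    ``optimal_sf * period * degrees_per_radian`` — halving the grating period
    halves the peak distance (a shifting maximum).
``distance_tuned``
    Absolute-depth cell: Gaussian tuning on the physical distance axis,
    independent of the grating (a constant maximum).
``monotonic_near`` / ``monotonic_far``
    Logistic rate profiles rising toward the screen or toward the far end of
    the track, with no interior peak.
``nonresponsive``
    Ongoing activity only.

Spiking is an inhomogeneous Poisson process (thinning) whose intensity is
the archetype tuning curve evaluated along the trajectory, multiplied by a
slowly varying log-normal gain (an Ornstein-Uhlenbeck process on log rate)
standing in for free-gaze variability: the analysis only ever sees the
effect of uncontrolled gaze on window rates, so the gain models exactly
that effect.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .geometry import EyeModel, GratingSpec, spatial_frequency
from .protocol import Protocol, Trajectory, build_trajectory, distance_at

__all__ = [
    "NeuronModel",
    "Trial",
    "NeuronRecording",
    "rate_function",
    "simulate_recording",
    "sample_population_models",
    "admissible_sf_range",
    "default_gratings",
    "write_recording",
    "read_recording",
]

ARCHETYPES = (
    "sf_tuned",
    "distance_tuned",
    "monotonic_near",
    "monotonic_far",
    "nonresponsive",
)

#: plausible optimal-SF range for central cat V1 (cycles/degree)
SF_PLAUSIBLE_CPD = (0.25, 2.0)


@dataclass(frozen=True)
class NeuronModel:
    """Ground-truth tuning model of one synthetic neuron.

    ``rate_jitter_cv`` is the coefficient of variation of the multiplicative
    slow gain (free-gaze surrogate); ``jitter_tau_s`` its correlation time.
    """

    archetype: str = "sf_tuned"
    baseline_rate_hz: float = 4.0
    peak_rate_hz: float = 20.0
    optimal_sf_cpd: float = 0.7
    sf_bandwidth_oct: float = 0.5
    optimal_distance_mm: float = 2200.0
    distance_sigma_mm: float = 300.0
    half_distance_mm: float = 500.0
    logistic_scale_mm: float = 150.0
    rate_jitter_cv: float = 0.10
    jitter_tau_s: float = 5.0
    sf_plausible_cpd: tuple[float, float] = SF_PLAUSIBLE_CPD

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.baseline_rate_hz < 0 or self.peak_rate_hz < 0:
            raise ValueError("rates must be non-negative")
        if self.sf_bandwidth_oct <= 0 or self.distance_sigma_mm <= 0:
            raise ValueError("bandwidth and sigma must be positive")
        if self.rate_jitter_cv < 0:
            raise ValueError("rate_jitter_cv must be non-negative")
        lo, hi = self.sf_plausible_cpd
        if self.archetype == "sf_tuned" and not (lo <= self.optimal_sf_cpd <= hi):
            raise ValueError(
                f"optimal_sf_cpd {self.optimal_sf_cpd} outside plausible "
                f"range {self.sf_plausible_cpd}"
            )


@dataclass
class Trial:
    """One approach cycle: grating, trajectory and sorted spike times."""

    grating: GratingSpec
    trajectory: Trajectory
    spike_times_s: np.ndarray
    trial_index: int = 0
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if np.any(np.diff(self.spike_times_s) < 0):
            raise ValueError("spike times must be sorted")
        if len(self.spike_times_s) and (
            self.spike_times_s[0] < 0
            or self.spike_times_s[-1] > self.trajectory.end_time_s + 1e-9
        ):
            raise ValueError("spike times outside trajectory span")
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded trials must carry a reason")


@dataclass
class NeuronRecording:
    """A neuron's full test set: alternating trials of 2 (or 3) gratings."""

    neuron_id: str
    trials: list[Trial]
    metadata: dict = field(default_factory=dict)

    def trials_for(self, label: str, include_excluded: bool = False) -> list[Trial]:
        return [
            t
            for t in self.trials
            if t.grating.label == label and (include_excluded or not t.excluded)
        ]

    @property
    def grating_labels(self) -> list[str]:
        seen: list[str] = []
        for t in self.trials:
            if t.grating.label not in seen:
                seen.append(t.grating.label)
        return sorted(seen)


def default_gratings(protocol: Protocol, n: int = 2) -> list[GratingSpec]:
    """The grating pairs used with each protocol (periods in mm).

    Distant space: 38 mm (1F) and 19 mm (2F); near space: 12 mm and 6 mm.
    ``n=3`` adds the 3F grating at one third of the 1F period.
    """
    p1 = 38.0 if protocol.start_distance_mm > 2000 else 12.0
    labels = ["1F", "2F", "3F"][:n]
    return [GratingSpec(p1 / (i + 1), label) for i, label in enumerate(labels)]


def rate_function(
    model: NeuronModel,
    grating: GratingSpec,
    distance_mm,
    eye: EyeModel = EyeModel(),
):
    """Noise-free firing rate (Hz) of the model at the given distance(s).

    sf_tuned:        baseline + peak * exp(-(log2(sf(d)/opt))^2 / (2 bw^2))
    distance_tuned:  baseline + peak * exp(-(d - opt)^2 / (2 sigma^2)), any grating
    monotonic_near:  baseline + peak * logistic rising toward the screen
    monotonic_far:   baseline + peak * logistic rising away from the screen
    nonresponsive:   baseline
    """
    d = np.asarray(distance_mm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance_mm must be positive")
    base, peak = model.baseline_rate_hz, model.peak_rate_hz
    if model.archetype == "sf_tuned":
        sf = spatial_frequency(grating, d, eye)
        z = np.log2(np.asarray(sf) / model.optimal_sf_cpd)
        rate = base + peak * np.exp(-(z**2) / (2 * model.sf_bandwidth_oct**2))
    elif model.archetype == "distance_tuned":
        z = (d - model.optimal_distance_mm) / model.distance_sigma_mm
        rate = base + peak * np.exp(-(z**2) / 2)
    elif model.archetype in ("monotonic_near", "monotonic_far"):
        sign = 1.0 if model.archetype == "monotonic_near" else -1.0
        rate = base + peak / (
            1.0 + np.exp(sign * (d - model.half_distance_mm) / model.logistic_scale_mm)
        )
    else:  # nonresponsive
        rate = base * np.ones_like(d)
    rate = np.maximum(rate, 0.0)
    return rate if rate.ndim else float(rate)


def _ou_log_gain(rng: np.random.Generator, times: np.ndarray, cv: float, tau_s: float) -> np.ndarray:
    """Unit-mean log-normal gain from a stationary OU process on log rate.

    sigma^2 = log(1 + cv^2) gives the requested CV; the mean-log offset
    -sigma^2/2 makes E[gain] = 1.  The gain is clipped at 1 + 6 cv so the
    thinning ceiling (baseline + peak) * (1 + 6 cv) is never exceeded.
    """
    if cv == 0:
        return np.ones_like(times)
    from scipy.signal import lfilter, lfiltic

    sigma = math.sqrt(math.log1p(cv * cv))
    a = math.exp(-(times[1] - times[0]) / tau_s) if len(times) > 1 else 0.0
    x0 = rng.normal(0.0, sigma)
    noise = rng.normal(0.0, sigma * math.sqrt(1 - a * a), size=len(times) - 1)
    # AR(1) recursion x_k = a x_{k-1} + noise_k via an IIR filter
    zi = lfiltic([1.0], [1.0, -a], [x0])
    tail, _ = lfilter([1.0], [1.0, -a], noise, zi=zi)
    x = np.concatenate([[x0], tail])
    gain = np.exp(x - sigma * sigma / 2)
    return np.minimum(gain, 1.0 + 6.0 * cv)


def _simulate_trial_spikes(
    rng: np.random.Generator,
    model: NeuronModel,
    grating: GratingSpec,
    traj: Trajectory,
    eye: EyeModel,
) -> np.ndarray:
    """Inhomogeneous Poisson spikes by thinning a homogeneous process."""
    T = traj.end_time_s
    cap = 1.0 + 6.0 * model.rate_jitter_cv
    lam_max = (model.baseline_rate_hz + model.peak_rate_hz) * cap
    if lam_max == 0:
        return np.empty(0)
    gain = _ou_log_gain(
        rng, traj.times_s, model.rate_jitter_cv, model.jitter_tau_s
    )
    n_cand = rng.poisson(lam_max * T)
    t_cand = np.sort(rng.uniform(0.0, T, size=n_cand))
    d_cand = distance_at(traj, t_cand)
    lam = rate_function(model, grating, d_cand, eye) * np.interp(
        t_cand, traj.times_s, gain
    )
    keep = rng.uniform(0.0, 1.0, size=n_cand) < lam / lam_max
    return t_cand[keep]


def simulate_recording(
    model: NeuronModel,
    protocol: Protocol,
    gratings: list[GratingSpec] | None = None,
    n_trials_per_grating: int = 6,
    seed: int | np.random.SeedSequence = 0,
    neuron_id: str = "synthetic",
    eye: EyeModel = EyeModel(),
) -> NeuronRecording:
    """Simulate a full recording: alternating 1F/2F(/3F) approach trials.

    Gratings alternate within each repetition block, as in the experimental
    protocol.  Same seed -> identical output (reproducibility contract).
    """
    if n_trials_per_grating < 1:
        raise ValueError("n_trials_per_grating must be >= 1")
    if gratings is None:
        gratings = default_gratings(protocol)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    traj = build_trajectory(protocol)
    n_total = n_trials_per_grating * len(gratings)
    children = ss.spawn(n_total)
    trials = []
    idx = 0
    for rep in range(n_trials_per_grating):
        for g in gratings:
            rng = np.random.default_rng(children[idx])
            spikes = _simulate_trial_spikes(rng, model, g, traj, eye)
            trials.append(
                Trial(grating=g, trajectory=traj, spike_times_s=spikes, trial_index=idx)
            )
            idx += 1
    meta = {
        "protocol": protocol.name or "custom",
        "archetype": model.archetype,
        "model": asdict(model),
        "n_trials_per_grating": n_trials_per_grating,
    }
    return NeuronRecording(neuron_id=neuron_id, trials=trials, metadata=meta)


def admissible_sf_range(
    protocol: Protocol,
    gratings: list[GratingSpec],
    margin_mm: float | None = None,
    eye: EyeModel = EyeModel(),
    window_s: float = 20.0,
) -> tuple[float, float]:
    """Optimal-SF interval whose predicted maxima lie inside the track.

    A frequency-tuned cell with optimum f peaks at f * period * deg_per_rad
    for each grating; the interval keeps every grating's predicted maximum at
    least ``margin_mm`` (default 2.5 smoothing-window spans, comfortably more
    than the trial-to-trial scatter of observed maxima) away from both track
    ends, intersected with the plausible V1 range.  Mirrors the experimental
    selection: only cells whose maxima fall on the track enter the shift
    analysis.
    """
    if margin_mm is None:
        margin_mm = 2.5 * window_s * protocol.speed_mm_s
    lo, hi = SF_PLAUSIBLE_CPD
    for g in gratings:
        span = g.period_mm * eye.degrees_per_radian
        lo = max(lo, (protocol.end_distance_mm + margin_mm) / span)
        hi = min(hi, (protocol.start_distance_mm - margin_mm) / span)
    if not lo < hi:
        raise ValueError("no admissible optimal-SF range for this protocol")
    return lo, hi


def sample_population_models(
    n_sf_tuned: int,
    n_distance_tuned: int,
    protocol: Protocol,
    seed: int | np.random.SeedSequence = 0,
    n_other: int = 0,
    gratings: list[GratingSpec] | None = None,
    base_model: NeuronModel = NeuronModel(),
) -> list[NeuronModel]:
    """Draw ground-truth models for a mixed synthetic population.

    sf_tuned optima are log-uniform over :func:`admissible_sf_range`;
    distance_tuned optima uniform over the upper track interior (from 35% of
    the start distance — where constant maxima are empirically found — up to
    2.5 window spans below the start).  ``n_other`` adds nonresponsive cells.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss)
    if gratings is None:
        gratings = default_gratings(protocol)
    f_lo, f_hi = admissible_sf_range(protocol, gratings)
    models: list[NeuronModel] = []
    for _ in range(n_sf_tuned):
        f = math.exp(rng.uniform(math.log(f_lo), math.log(f_hi)))
        models.append(replace(base_model, archetype="sf_tuned", optimal_sf_cpd=f))
    margin = 2.5 * 20.0 * protocol.speed_mm_s
    d_lo = max(protocol.end_distance_mm + margin, 0.35 * protocol.start_distance_mm)
    d_hi = protocol.start_distance_mm - margin
    for _ in range(n_distance_tuned):
        d = rng.uniform(d_lo, d_hi)
        models.append(
            replace(base_model, archetype="distance_tuned", optimal_distance_mm=d)
        )
    for _ in range(n_other):
        models.append(replace(base_model, archetype="nonresponsive"))
    return models


# ---------------------------------------------------------------------------
# directory layout: recording.json + per-trial spike/trajectory CSVs

def write_recording(rec: NeuronRecording, directory: str) -> None:
    """Write a recording as recording.json plus per-trial CSV files."""
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "neuron_id": rec.neuron_id,
        "metadata": rec.metadata,
        "trials": [],
    }
    for i, t in enumerate(rec.trials):
        spikes_file = f"trial_{i:03d}_spikes.csv"
        traj_file = f"trial_{i:03d}_trajectory.csv"
        manifest["trials"].append(
            {
                "spikes": spikes_file,
                "trajectory": traj_file,
                "grating_period_mm": t.grating.period_mm,
                "grating_label": t.grating.label,
                "grating_orientation_deg": t.grating.orientation_deg,
                "trial_index": t.trial_index,
                "excluded": t.excluded,
                "exclusion_reason": t.exclusion_reason,
            }
        )
        np.savetxt(
            os.path.join(directory, spikes_file),
            t.spike_times_s,
            fmt="%.17g",
            header="spike_time_s",
            comments="",
        )
        t.trajectory.to_csv(os.path.join(directory, traj_file))
    with open(os.path.join(directory, "recording.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_recording(directory: str) -> NeuronRecording:
    """Round-trip reader for :func:`write_recording` output."""
    with open(os.path.join(directory, "recording.json")) as fh:
        manifest = json.load(fh)
    trials = []
    traj_cache: dict[str, Trajectory] = {}
    for entry in manifest["trials"]:
        tf = entry["trajectory"]
        if tf not in traj_cache:
            traj_cache[tf] = Trajectory.from_csv(os.path.join(directory, tf))
        spikes = np.loadtxt(
            os.path.join(directory, entry["spikes"]), skiprows=1, ndmin=1
        )
        trials.append(
            Trial(
                grating=GratingSpec(
                    entry["grating_period_mm"],
                    entry["grating_label"],
                    entry["grating_orientation_deg"],
                ),
                trajectory=traj_cache[tf],
                spike_times_s=spikes,
                trial_index=entry["trial_index"],
                excluded=entry["excluded"],
                exclusion_reason=entry["exclusion_reason"],
            )
        )
    return NeuronRecording(
        neuron_id=manifest["neuron_id"],
        trials=trials,
        metadata=manifest["metadata"],
    )
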