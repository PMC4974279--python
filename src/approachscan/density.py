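"""Spike-density curves along the approach track and their maxima.

The spike train of each trial is converted to a firing-rate curve with a
long sliding boxcar window (default 20 s, stepped every 0.01 s).  The window
has to be long enough to pick up distance-related changes of activity rather
than accidental short bursts under free gaze; on the distance axis it spans
``window_s * trolley speed`` (200 mm nominal in distant space, 34 mm in near
space).  Window centers are restricted to the approach phase — the stimulus
distance is constant during the dwells — and each center time is mapped to a
distance through the trajectory, so curves from all trials of one protocol
share an identical distance grid and their maxima are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import Trajectory, distance_at

__all__ = [
    "AnalysisConfig",
    "DensityCurve",
    "MaximumEstimate",
    "spike_density",
    "average_density",
    "find_maximum",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the analysis pipeline.

    window_s / step_s        sliding-window length and step (s)
    bootstrap_n              trial resamples for maximum significance
    conf_level               confidence level of the bootstrap test
    constant_threshold_pct   mean shift below this -> candidate constant cell
    shifting_threshold_pct   mean shift above this -> candidate shifting cell
    alpha                    sign-test level
    boundary_tolerance_mm    margin for "maximum at the track boundary";
                             None -> one window span (window_s * speed)
    bootstrap_grid_s         spacing of the decimated grid used inside the
                             bootstrap (the curve is smooth at the window
                             scale, so the max is insensitive to this)
    min_trials_per_grating   minimum non-excluded trials required
    min_pairs_sign_test      minimum pair count for the sign test
    """

    window_s: float = 20.0
    step_s: float = 0.01
    bootstrap_n: int = 1000
    conf_level: float = 0.95
    constant_threshold_pct: float = 30.0
    shifting_threshold_pct: float = 70.0
    alpha: float = 0.05
    boundary_tolerance_mm: float | None = None
    bootstrap_grid_s: float = 1.0
    min_trials_per_grating: int = 6
    min_pairs_sign_test: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.window_s:
            raise ValueError("require 0 < step_s <= window_s")
        if not 0 < self.conf_level < 1:
            raise ValueError("conf_level must be in (0, 1)")
        if not self.constant_threshold_pct < self.shifting_threshold_pct:
            raise ValueError("constant threshold must be below shifting threshold")
        if self.bootstrap_n < 1:
            raise ValueError("bootstrap_n must be positive")

    def boundary_tolerance(self, speed_mm_s: float) -> float:
        """Boundary margin: one smoothing-window span on the distance axis."""
        if self.boundary_tolerance_mm is not None:
            return self.boundary_tolerance_mm
        return self.window_s * speed_mm_s


@dataclass
class DensityCurve:
    """Firing rate over distance for one trial or a trial average."""

    distances_mm: np.ndarray
    rate_hz: np.ndarray
    times_s: np.ndarray  # window-center times, shared grid
    n_trials: int = 1
    sem_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        self.rate_hz = np.asarray(self.rate_hz, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if np.any(self.rate_hz < 0):
            raise ValueError("rates must be non-negative")

    def same_grid(self, other: "DensityCurve") -> bool:
        return len(self.times_s) == len(other.times_s) and np.allclose(
            self.times_s, other.times_s
        )

    def to_csv(self, path_or_buf) -> None:
        df = pd.DataFrame(
            {"distance_mm": self.distances_mm, "rate_hz": self.rate_hz}
        )
        if self.sem_hz is not None:
            df["sem_hz"] = self.sem_hz
        df.to_csv(path_or_buf, index=False, float_format="%.17g")


@dataclass
class MaximumEstimate:
    """Location and height of the response maximum of a density curve."""

    distance_mm: float
    rate_hz: float
    significant: bool = False
    threshold_hz: float = float("nan")  # upper bootstrap band the max must exceed
    degenerate: bool = False  # flat curve / tie between equal maxima

    @property
    def defined(self) -> bool:
        return np.isfinite(self.distance_mm)


def spike_density(trial, cfg: AnalysisConfig = AnalysisConfig()) -> DensityCurve:
    """Sliding-window spike density of one trial, on the approach grid.

    For every window center t within the approach phase, the rate is the
    spike count in ``[t - w/2, t + w/2]`` intersected with the trial span,
    divided by the covered duration (edge windows are truncated, not
    zero-padded).  Centers are then mapped to distances via the trajectory.
    """
    if trial.excluded:
        raise ValueError(
            f"trial {trial.trial_index} is excluded ({trial.exclusion_reason})"
        )
    traj: Trajectory = trial.trajectory
    t0, t1 = traj.approach_window_s
    n_steps = int(np.floor((t1 - t0) / cfg.step_s + 1e-9))
    centers = t0 + np.arange(n_steps + 1) * cfg.step_s
    half = cfg.window_s / 2.0
    spikes = trial.spike_times_s
    hi = np.searchsorted(spikes, centers + half, side="right")
    lo = np.searchsorted(spikes, centers - half, side="left")
    covered = np.minimum(traj.end_time_s, centers + half) - np.maximum(
        0.0, centers - half
    )
    rate = (hi - lo) / covered
    distances = np.asarray(distance_at(traj, centers))
    return DensityCurve(distances, rate, centers, n_trials=1)


def average_density(curves: list[DensityCurve]) -> DensityCurve:
    """Pointwise mean (and SEM across trials) of same-grid density curves."""
    if not curves:
        raise ValueError("need at least one curve")
    first = curves[0]
    for c in curves[1:]:
        if not first.same_grid(c):
            raise ValueError("density curves are not on a common grid")
    rates = np.stack([c.rate_hz for c in curves])
    mean = rates.mean(axis=0)
    n = len(curves)
    sem = rates.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return DensityCurve(
        first.distances_mm.copy(), mean, first.times_s.copy(), n_trials=n, sem_hz=sem
    )


def find_maximum(
    curve: DensityCurve, cfg: AnalysisConfig = AnalysisConfig()
) -> MaximumEstimate:
    """Global maximum of the curve over the approach grid.

    Ties (within floating tolerance of the max) are broken toward the
    farthest distance — the earlier, less drift-contaminated observation.
    An all-zero curve yields a NaN-location, non-significant estimate.
    """
    if len(curve.rate_hz) == 0:
        raise ValueError("empty density curve")
    peak = float(curve.rate_hz.max())
    if peak == 0.0:
        return MaximumEstimate(float("nan"), 0.0, significant=False, degenerate=True)
    at_max = np.flatnonzero(curve.rate_hz >= peak * (1 - 1e-12))
    idx = at_max[np.argmax(curve.distances_mm[at_max])]
    degenerate = bool(
        len(at_max) > 1
        and np.ptp(curve.distances_mm[at_max]) > 10 * np.ptp(curve.distances_mm) / max(len(curve.rate_hz) - 1, 1)
    )
    return MaximumEstimate(
        float(curve.distances_mm[idx]), peak, degenerate=degenerate
    )
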