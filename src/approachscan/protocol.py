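"""Trial trajectories: dwell at the start, constant-speed approach, dwell at the end.

Two stereotyped protocols are used.  In the distant-space protocol the trolley
carries the animal from 2.8 m to 0.2 m from the screen at 1 cm/s (a ~4.3 min
approach); in the near-space protocol from 1.03 m to 0.11 m at 1.7 mm/s
(~9 min).  A trial starts with ~60 s standing at the far position and ends
with ~30 s standing at the near position; the quick return to the start is
not part of the record.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Protocol",
    "Trajectory",
    "DISTANT",
    "NEAR",
    "build_trajectory",
    "distance_at",
]

PHASE_DWELL_FAR = "dwell_far"
PHASE_APPROACH = "approach"
PHASE_DWELL_NEAR = "dwell_near"


@dataclass(frozen=True)
class Protocol:
    """Parameters of one approach protocol.

    All distances are eye-to-screen distances in mm; ``speed_mm_s`` is the
    trolley speed V2 during the approach phase.
    """

    start_distance_mm: float
    end_distance_mm: float
    speed_mm_s: float
    dwell_start_s: float = 60.0
    dwell_end_s: float = 30.0
    sample_dt_s: float = 0.1
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start_distance_mm > self.end_distance_mm > 0:
            raise ValueError(
                "require start_distance_mm > end_distance_mm > 0, got "
                f"{self.start_distance_mm} / {self.end_distance_mm}"
            )
        if not self.speed_mm_s > 0:
            raise ValueError("speed_mm_s must be positive")
        if self.dwell_start_s < 0 or self.dwell_end_s < 0:
            raise ValueError("dwell times must be non-negative")
        if not self.sample_dt_s > 0:
            raise ValueError("sample_dt_s must be positive")

    @property
    def approach_duration_s(self) -> float:
        return (self.start_distance_mm - self.end_distance_mm) / self.speed_mm_s

    @property
    def total_duration_s(self) -> float:
        return self.dwell_start_s + self.approach_duration_s + self.dwell_end_s


#: Distant-space protocol: 2.8 -> 0.2 m at 1 cm/s.
DISTANT = Protocol(2800.0, 200.0, 10.0, name="distant")
#: Near-space protocol: 1.03 -> 0.11 m at 1.7 mm/s.
NEAR = Protocol(1030.0, 110.0, 1.7, name="near")


@dataclass
class Trajectory:
    """Sampled time -> distance-from-screen trace of one trial."""

    times_s: np.ndarray
    distances_mm: np.ndarray
    phase: np.ndarray  # per-sample tag: dwell_far / approach / dwell_near
    protocol: Protocol | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (
            len(self.times_s) == len(self.distances_mm) == len(self.phase)
        ):
            raise ValueError("times, distances and phase must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if np.any(np.diff(self.distances_mm) > 1e-9):
            raise ValueError("distances_mm must be non-increasing over time")

    @property
    def end_time_s(self) -> float:
        return float(self.times_s[-1])

    @property
    def approach_window_s(self) -> tuple[float, float]:
        """Start and end time of the approach phase."""
        mask = self.phase == PHASE_APPROACH
        if not mask.any():
            raise ValueError("trajectory has no approach phase")
        t = self.times_s[mask]
        return float(t[0]), float(t[-1])

    def to_csv(self, path_or_buf) -> None:
        pd.DataFrame(
            {
                "time_s": self.times_s,
                "distance_mm": self.distances_mm,
                "phase": self.phase,
            }
        ).to_csv(path_or_buf, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path_or_buf) -> "Trajectory":
        df = pd.read_csv(path_or_buf, float_precision="round_trip")
        return cls(
            times_s=df["time_s"].to_numpy(),
            distances_mm=df["distance_mm"].to_numpy(),
            phase=df["phase"].to_numpy(),
        )

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def build_trajectory(p: Protocol) -> Trajectory:
    """Sample the piecewise-linear trace of one trial.

    Constant at the start distance for ``dwell_start_s``, linear descent at
    ``speed_mm_s``, constant at the end distance for ``dwell_end_s``.  The
    approach lasts ``(start - end) / speed`` seconds.
    """
    t_approach_start = p.dwell_start_s
    t_approach_end = p.dwell_start_s + p.approach_duration_s
    t_end = p.total_duration_s

    n = int(round(t_end / p.sample_dt_s)) + 1
    times = np.arange(n) * p.sample_dt_s
    # guarantee phase-boundary samples are present
    extra = np.array([t_approach_start, t_approach_end, t_end])
    times = np.unique(np.concatenate([times, extra]))
    times = times[times <= t_end + 1e-12]

    distances = np.empty_like(times)
    phase = np.empty(len(times), dtype=object)
    far = times <= t_approach_start
    near = times >= t_approach_end
    mid = ~(far | near)
    distances[far] = p.start_distance_mm
    distances[near] = p.end_distance_mm
    distances[mid] = p.start_distance_mm - p.speed_mm_s * (
        times[mid] - t_approach_start
    )
    phase[far] = PHASE_DWELL_FAR
    phase[mid] = PHASE_APPROACH
    phase[near] = PHASE_DWELL_NEAR
    # boundary samples belong to the approach (distance changes from there)
    phase[np.isclose(times, t_approach_start)] = PHASE_APPROACH
    phase[np.isclose(times, t_approach_end)] = PHASE_APPROACH
    return Trajectory(times, distances, phase, protocol=p)


def distance_at(traj: Trajectory, t_s) -> np.ndarray | float:
    """Distance from the screen at time(s) ``t_s``, by linear interpolation.

    Exact at sample points.  Times outside ``[times[0], times[-1]]`` raise.
    """
    t = np.asarray(t_s, dtype=float)
    if np.any(t < traj.times_s[0] - 1e-9) or np.any(t > traj.times_s[-1] + 1e-9):
        raise ValueError("time outside trajectory range")
    d = np.interp(t, traj.times_s, traj.distances_mm)
    return d if d.ndim else float(d)
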