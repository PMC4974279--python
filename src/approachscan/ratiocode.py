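"""Ratio-based population code for absolute viewing distance.

Broadly tuned distance cells with overlapping tuning curves cannot signal
distance individually: rates are ambiguous around the peak and depend on the
stimulus (spatial frequency, illumination).  But the *ratio* of two cells'
rates is invariant to any gain applied to both — the same trick trichromatic
color vision uses with three overlapping cone sensitivities — and, between
the peaks, varies steeply with distance.  This module implements a
demonstrative decoder: given observed rates of a population of tabulated
tuning curves, it finds the distance whose curve-predicted rate ratios best
match the observed ones in a least-squares sense on the log-ratio scale.
The decoder design (sum of squared log-ratio residuals over all cell pairs,
with a small-rate floor before taking logs) is this module's own
contribution; precision is highest on the tuning-curve flanks, where all
curves have steep gradients, and poorest near the peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CodingCurve",
    "DecodeResult",
    "gaussian_curve",
    "response_ratio",
    "decode_distance",
    "flank_vs_peak_rmse",
    "curves_to_csv",
    "curves_from_csv",
]


@dataclass
class CodingCurve:
    """Tabulated rate-vs-distance tuning curve of one cell.

    ``gain`` is a multiplicative factor standing for stimulus spatial
    frequency or illumination level; effective rate = gain * tuning.
    """

    distances_mm: np.ndarray
    rate_hz: np.ndarray
    gain: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        self.rate_hz = np.asarray(self.rate_hz, dtype=float)
        if np.any(self.rate_hz < 0):
            raise ValueError("rates must be non-negative")
        if self.gain < 0:
            raise ValueError("gain must be non-negative")

    def rate_at(self, distance_mm) -> np.ndarray | float:
        r = self.gain * np.interp(
            np.asarray(distance_mm, dtype=float), self.distances_mm, self.rate_hz
        )
        return r if np.ndim(r) else float(r)

    def with_gain(self, gain: float) -> "CodingCurve":
        return CodingCurve(self.distances_mm, self.rate_hz, gain, self.name)


def gaussian_curve(
    grid_mm: np.ndarray,
    mu_mm: float,
    sigma_mm: float,
    peak_hz: float = 30.0,
    baseline_hz: float = 0.0,
    name: str = "",
) -> CodingCurve:
    """Gaussian-on-distance tuning curve (the stand-in functional form)."""
    grid_mm = np.asarray(grid_mm, dtype=float)
    rate = baseline_hz + peak_hz * np.exp(-((grid_mm - mu_mm) ** 2) / (2 * sigma_mm**2))
    return CodingCurve(grid_mm, rate, name=name)


def response_ratio(
    cell_a: CodingCurve, cell_b: CodingCurve, distance_mm
) -> np.ndarray | float:
    """Rate ratio a/b at the given distance(s).

    Exactly invariant under a common multiplicative gain applied to both
    cells.  A zero denominator yields NaN (flagged by the caller).
    """
    d = np.asarray(distance_mm, dtype=float)
    ra = np.interp(d, cell_a.distances_mm, cell_a.rate_hz)
    rb = np.interp(d, cell_b.distances_mm, cell_b.rate_hz)
    # common gain cancels analytically, so equal gains are exactly invariant
    gain_ratio = cell_a.gain / cell_b.gain if cell_b.gain > 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rb > 0, gain_ratio * ra / np.where(rb > 0, rb, 1.0), np.nan)
    return ratio if ratio.ndim else float(ratio)


@dataclass
class DecodeResult:
    """Decoded distance and the decoding objective along the grid."""

    distance_mm: float | None
    flat: bool
    grid_mm: np.ndarray
    objective: np.ndarray
    reason: str = ""


def _log_rates(rates: np.ndarray, eps_hz: float) -> np.ndarray:
    return np.log(np.asarray(rates, dtype=float) + eps_hz)


def decode_distance(
    population: list[CodingCurve],
    observed_rates,
    grid_mm: np.ndarray | None = None,
    eps_hz: float = 0.1,
    flat_rtol: float = 1e-9,
    support_frac: float = 0.05,
) -> DecodeResult:
    """Decode distance from observed rates by matching rate ratios.

    Objective at each grid distance d:

        J(d) = sum_{i<j} [ (log o_i - log o_j) - (log r_i(d) - log r_j(d)) ]^2

    with ``eps_hz`` added inside every log to stabilize small rates.  The
    estimate is the grid argmin, restricted to the population's support:
    grid points where the largest predicted rate falls below ``support_frac``
    of its grid-wide maximum are excluded, because there the ``eps_hz`` floor
    dominates every log and the predicted ratios degenerate toward 1
    regardless of distance.  When the objective is (near-)constant over the
    support — e.g. identical curves, for which ratios carry no distance
    information — no estimate is returned and ``flat`` is set.
    """
    if len(population) < 2:
        raise ValueError("decoding requires at least 2 cells")
    obs = np.asarray(observed_rates, dtype=float)
    if obs.shape != (len(population),):
        raise ValueError("observed_rates must have one rate per cell")
    if np.any(obs < 0):
        raise ValueError("observed rates must be non-negative")
    if grid_mm is None:
        grid_mm = population[0].distances_mm
    grid_mm = np.asarray(grid_mm, dtype=float)

    rates = np.stack([np.asarray(c.rate_at(grid_mm), dtype=float) for c in population])
    L = _log_rates(rates, eps_hz)
    lo = _log_rates(obs, eps_hz)
    # sum over pairs of squared differences of c_i = lo_i - L_i(d):
    # sum_{i<j} (c_i - c_j)^2 = n sum c_i^2 - (sum c_i)^2
    c = lo[:, None] - L
    n = len(population)
    obj = n * np.sum(c**2, axis=0) - np.sum(c, axis=0) ** 2

    envelope = rates.max(axis=0)
    support = envelope >= support_frac * envelope.max()
    if not support.any():
        support = np.ones_like(support)
    obj_s = obj[support]
    spread = float(obj_s.max() - obj_s.min())
    if spread <= flat_rtol * max(1.0, float(np.abs(obj_s).max())):
        return DecodeResult(
            None, True, grid_mm, obj, reason="objective is flat: ratios carry no distance information"
        )
    i = int(np.flatnonzero(support)[np.argmin(obj_s)])
    return DecodeResult(float(grid_mm[i]), False, grid_mm, obj)


def flank_vs_peak_rmse(
    sigma_mm: float = 600.0,
    mu_mm: tuple[float, float] = (1500.0, 2500.0),
    peak_hz: float = 30.0,
    noise_frac: float = 0.05,
    n_draws: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    grid_mm: np.ndarray | None = None,
    eps_hz: float = 0.1,
) -> dict:
    """Monte-Carlo precision of the decoder at peaks versus the flank.

    Two Gaussian tuning curves; observed rates are the true rates plus
    additive Gaussian noise with SD ``noise_frac * peak_hz`` (clipped at 0).
    Decoding error is measured at each curve's peak and at the inter-peak
    midpoint, where both curves have steep gradients (the flank).  Returns
    RMSEs; the ratio code is expected to be more precise on the flank.
    """
    if grid_mm is None:
        grid_mm = np.arange(200.0, 2801.0, 10.0)
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    pop = [gaussian_curve(grid_mm, mu, sigma_mm, peak_hz) for mu in mu_mm]
    flank_d = 0.5 * (mu_mm[0] + mu_mm[1])

    def rmse_at(d_true: float) -> float:
        true_rates = np.array([c.rate_at(d_true) for c in pop])
        errs = []
        for _ in range(n_draws):
            obs = np.maximum(
                true_rates + rng.normal(0.0, noise_frac * peak_hz, size=len(pop)),
                0.0,
            )
            res = decode_distance(pop, obs, grid_mm, eps_hz=eps_hz)
            if res.distance_mm is not None:
                errs.append(res.distance_mm - d_true)
        return float(np.sqrt(np.mean(np.square(errs))))

    peak_rmse = float(np.mean([rmse_at(mu) for mu in mu_mm]))
    flank_rmse = rmse_at(flank_d)
    return {
        "sigma_mm": sigma_mm,
        "peak_rmse_mm": peak_rmse,
        "flank_rmse_mm": flank_rmse,
        "flank_better": flank_rmse < peak_rmse,
    }


def curves_to_csv(curves: list[CodingCurve], path_or_buf) -> None:
    """Write a population as CSV: distance_mm plus one rate column per cell."""
    grid = curves[0].distances_mm
    for c in curves[1:]:
        if not np.allclose(c.distances_mm, grid):
            raise ValueError("curves must share a distance grid")
    data = {"distance_mm": grid}
    for i, c in enumerate(curves):
        data[c.name or f"cell_{i}"] = c.gain * c.rate_hz
    pd.DataFrame(data).to_csv(path_or_buf, index=False, float_format="%.17g")


def curves_from_csv(path_or_buf) -> list[CodingCurve]:
    df = pd.read_csv(path_or_buf, float_precision="round_trip")
    grid = df["distance_mm"].to_numpy()
    return [
        CodingCurve(grid, df[col].to_numpy(), name=col)
        for col in df.columns
        if col != "distance_mm"
    ]
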