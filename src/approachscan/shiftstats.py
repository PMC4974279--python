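"""Shift statistics: bootstrap significance of maxima, the shift statistic,
its all-pairs distribution, sign-test classification and population tests.

The central quantity is the shift of the response maximum when the grating's
spatial frequency is doubled,

    Shift = (M1 - M2) / M2 * 100%

where M1 and M2 are the distances from the screen of the response maxima for
the low- (1F) and high-frequency (2F) grating.  A cell tuned to retinal
spatial frequency predicts Shift = 100% (the maximum moves half way to the
screen); a cell tuned to absolute distance predicts Shift = 0%.  Per-trial
maxima for the two gratings are combined over all trial pairs (6 trials per
grating -> 36 shifts), and a cell is labelled *shifting* when its mean shift
exceeds 70% with an exact sign test confirming the pairwise differences sit
above the 70% boundary, or *constant* when the mean shift is below 30% with
the sign test confirming the differences sit below the 30% boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .density import AnalysisConfig, DensityCurve, MaximumEstimate, average_density, find_maximum

__all__ = [
    "ShiftResult",
    "PopulationSummary",
    "bootstrap_max_significance",
    "shift_statistic",
    "pairwise_shift_distribution",
    "sign_test_exact",
    "classify_shift",
    "normality_and_clusters",
    "joint_chance_level",
]


def joint_chance_level(alpha: float = 0.05) -> float:
    """Chance probability that both gratings' maxima are significant.

    Trial outcomes for the two gratings are independent, so the joint
    false-positive probability is alpha * alpha (0.05^2 = 0.0025).
    """
    return alpha * alpha


def bootstrap_max_significance(
    trial_curves: list[DensityCurve],
    cfg: AnalysisConfig = AnalysisConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> MaximumEstimate:
    """Test the maximum of the trial-averaged density curve by bootstrap.

    Null construction: resample the trials with replacement ``bootstrap_n``
    times and give each resampled trial an independent random circular shift
    along the track before averaging; the maximum of each such mean curve
    forms the null distribution of "a maximum this high arising from the
    cell's rate level and autocorrelation without any distance-locked
    structure".  The observed maximum is significant iff it exceeds the
    ``conf_level`` percentile of that distribution.  Rotation preserves the
    mean rate and the within-trial correlation of the sliding windows but
    destroys across-trial alignment of any genuine response, which controls
    the multiplicity of the max statistic (a plain confidence band for the
    mean rate level would be exceeded by the maximum of a flat noisy curve
    almost surely).  Deterministic given the seed.
    """
    if len(trial_curves) < 2:
        raise ValueError("bootstrap significance requires at least 2 trials")
    first = trial_curves[0]
    for c in trial_curves[1:]:
        if not first.same_grid(c):
            raise ValueError("trial curves are not on a common grid")
    R = np.stack([c.rate_hz for c in trial_curves])
    n, m = R.shape
    df = max(1, int(round(cfg.bootstrap_grid_s / cfg.step_s)))
    Rd = np.ascontiguousarray(R[:, ::df])
    md = Rd.shape[1]
    obs_max = float(Rd.mean(axis=0).max())

    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    B = cfg.bootstrap_n
    idx = rng.integers(0, n, size=(B, n))
    shifts = rng.integers(0, md, size=(B, n))
    cols = (shifts[:, :, None] + np.arange(md)[None, None, :]) % md
    null_max = np.take_along_axis(Rd[idx], cols, axis=2).mean(axis=1).max(axis=1)
    threshold = float(np.quantile(null_max, cfg.conf_level))

    mean_curve = average_density(trial_curves)
    est = find_maximum(mean_curve, cfg)
    est.significant = bool(obs_max > threshold) and est.defined
    est.threshold_hz = threshold
    return est


def shift_statistic(m1_mm: float, m2_mm: float) -> float:
    """Shift (%) of the response maximum between the 1F and 2F gratings."""
    if not m2_mm > 0:
        raise ValueError(f"m2_mm must be positive, got {m2_mm}")
    return (m1_mm - m2_mm) / m2_mm * 100.0


def pairwise_shift_distribution(
    m1_per_trial, m2_per_trial
) -> np.ndarray:
    """All trial-combination shifts: Cartesian product of per-trial maxima.

    Trial outcomes are independent (long trials), so every M1_i, M2_j pair
    yields a valid shift; 6 trials per grating give 36 values.
    """
    m1 = np.asarray(m1_per_trial, dtype=float)
    m2 = np.asarray(m2_per_trial, dtype=float)
    if m1.size == 0 or m2.size == 0:
        raise ValueError("per-trial maxima lists must be non-empty")
    if np.any(m2 <= 0):
        raise ValueError("all m2 values must be positive")
    return ((m1[:, None] - m2[None, :]) / m2[None, :] * 100.0).ravel()


def sign_test_exact(x, mu0: float = 0.0, alternative: str = "greater") -> float:
    """One-sided exact sign test: binomial tail with ties dropped.

    ``greater``: p = P(Bin(n, 1/2) >= k) where k counts values above mu0
    among the n values different from mu0; ``less`` is the mirror image.
    """
    x = np.asarray(x, dtype=float)
    pos = int(np.sum(x > mu0))
    neg = int(np.sum(x < mu0))
    n = pos + neg
    if n == 0:
        return 1.0
    if alternative == "greater":
        return float(stats.binom.sf(pos - 1, n, 0.5))
    if alternative == "less":
        return float(stats.binom.cdf(pos, n, 0.5))
    raise ValueError("alternative must be 'greater' or 'less'")


@dataclass
class ShiftResult:
    """Shift statistic of one neuron and its classification."""

    m1_mm: float
    m2_mm: float
    shift_pct: float
    pairwise_shifts_pct: np.ndarray
    n_pairs: int
    class_label: str = "unclassified"
    p_sign: float = float("nan")
    mean_pairwise_shift_pct: float = float("nan")
    frac_pairs_above_shifting: float = float("nan")
    frac_pairs_below_constant: float = float("nan")

    @classmethod
    def from_trial_maxima(
        cls, m1_per_trial, m2_per_trial, m1_mm: float, m2_mm: float
    ) -> "ShiftResult":
        pw = pairwise_shift_distribution(m1_per_trial, m2_per_trial)
        return cls(
            m1_mm=m1_mm,
            m2_mm=m2_mm,
            shift_pct=shift_statistic(m1_mm, m2_mm),
            pairwise_shifts_pct=pw,
            n_pairs=len(pw),
            mean_pairwise_shift_pct=float(np.mean(pw)),
        )


def classify_shift(sr: ShiftResult, cfg: AnalysisConfig = AnalysisConfig()) -> str:
    """Label a neuron constant / shifting / unclassified and fill ``sr``.

    With per-pair difference d = M1_i - M2_j and full-shift reference
    r = M2_j (the frequency-tuned geometry predicts M1 = 2 M2), the sign of
    d - 0.7 r is the sign of (pairwise shift - 70%), and of d - 0.3 r the
    sign of (pairwise shift - 30%).  *Shifting*: mean pairwise shift above
    the 70% threshold and a one-sided exact sign test rejecting, at
    ``cfg.alpha``, that the median pairwise shift lies at or below 70%.
    *Constant*: mean below 30% and the mirror-image test rejecting that the
    median lies at or above 30%.  Anything else is unclassified.
    """
    pw = sr.pairwise_shifts_pct
    sr.frac_pairs_above_shifting = float(
        np.mean(pw > cfg.shifting_threshold_pct)
    )
    sr.frac_pairs_below_constant = float(np.mean(pw < cfg.constant_threshold_pct))
    if sr.n_pairs < cfg.min_pairs_sign_test:
        warnings.warn(
            f"only {sr.n_pairs} pairs (< {cfg.min_pairs_sign_test}); "
            "sign test not attempted",
            stacklevel=2,
        )
        sr.class_label = "unclassified"
        return sr.class_label
    mean_shift = sr.mean_pairwise_shift_pct
    if mean_shift > cfg.shifting_threshold_pct:
        p = sign_test_exact(pw, cfg.shifting_threshold_pct, "greater")
        sr.p_sign = p
        sr.class_label = "shifting" if p < cfg.alpha else "unclassified"
    elif mean_shift < cfg.constant_threshold_pct:
        p = sign_test_exact(pw, cfg.constant_threshold_pct, "less")
        sr.p_sign = p
        sr.class_label = "constant" if p < cfg.alpha else "unclassified"
    else:
        sr.class_label = "unclassified"
    return sr.class_label


def _lilliefors(x: np.ndarray) -> tuple[float, float] | None:
    if len(x) < 5 or np.ptp(x) == 0:
        return None
    from statsmodels.stats.diagnostic import lilliefors as _llf

    stat, p = _llf(np.asarray(x, dtype=float), dist="norm", pvalmethod="table")
    return float(stat), float(p)


@dataclass
class PopulationSummary:
    """Population-level shift distribution, normality tests and clusters."""

    shifts_pct: np.ndarray = field(default_factory=lambda: np.empty(0))
    pooled_lilliefors: tuple[float, float] | None = None
    constant_cluster: dict = field(default_factory=dict)
    shifting_cluster: dict = field(default_factory=dict)
    constant_positions_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    positions_lilliefors: tuple[float, float] | None = None
    position_clusters: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _cluster_stats(values: np.ndarray) -> dict:
    out: dict = {"n": int(len(values))}
    if len(values):
        out["mean_pct"] = float(np.mean(values))
        out["sd_pct"] = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        llf = _lilliefors(values)
        out["lilliefors_stat"], out["lilliefors_p"] = llf if llf else (None, None)
    return out


def normality_and_clusters(
    shifts_pct,
    constant_positions_mm=None,
    split_pct: float = 50.0,
    max_components: int = 4,
) -> PopulationSummary:
    """Normality and cluster structure of the population shift distribution.

    Lilliefors test on the pooled shifts (bimodality shows up as a strong
    rejection); the set is then split at ``split_pct`` and each cluster is
    tested individually and summarized by mean and SD.  Constant-maximum
    positions, when given, are tested for normality and clustered with a 1-D
    Gaussian mixture whose component count (1..``max_components``) is chosen
    by BIC.  Tests are skipped (with a notice) when fewer than 5 values are
    available.
    """
    shifts = np.asarray(shifts_pct, dtype=float)
    summary = PopulationSummary(shifts_pct=shifts)
    if len(shifts) < 5:
        summary.notes.append(
            f"only {len(shifts)} shift values; normality tests skipped"
        )
        return summary
    summary.pooled_lilliefors = _lilliefors(shifts)
    lower = shifts[shifts < split_pct]
    upper = shifts[shifts >= split_pct]
    summary.constant_cluster = _cluster_stats(lower)
    summary.shifting_cluster = _cluster_stats(upper)

    if constant_positions_mm is not None:
        pos = np.asarray(constant_positions_mm, dtype=float)
        summary.constant_positions_mm = pos
        if len(pos) < 5:
            summary.notes.append(
                f"only {len(pos)} constant-maximum positions; clustering skipped"
            )
            return summary
        summary.positions_lilliefors = _lilliefors(pos)
        summary.position_clusters = _gmm_clusters(pos, max_components)
    return summary


def _gmm_clusters(pos: np.ndarray, max_components: int) -> dict:
    from sklearn.mixture import GaussianMixture

    X = pos.reshape(-1, 1)
    best = None
    bics = {}
    for k in range(1, min(max_components, len(pos)) + 1):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=0)
        gm.fit(X)
        bics[k] = float(gm.bic(X))
        if best is None or bics[k] < bics[best[0]]:
            best = (k, gm)
    k, gm = best
    order = np.argsort(gm.means_.ravel())
    return {
        "n_components": int(k),
        "bic_by_k": bics,
        "means_mm": gm.means_.ravel()[order].tolist(),
        "sds_mm": np.sqrt(gm.covariances_.ravel()[order]).tolist(),
        "weights": gm.weights_[order].tolist(),
        "assignments": gm.predict(X).tolist(),
    }
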