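"""Per-neuron and population orchestration of the approach analysis.

For each neuron: per-trial spike densities, trial-averaged curves and their
maxima per grating, bootstrap significance of both maxima, boundary rules
for monotonic/outlier response profiles, then the pairwise shift
distribution and the sign-test classification into constant versus shifting
maxima.  At the population level: label counts, the pooled shift
distribution with its normality and cluster structure, and the list of
constant-maximum positions along the track.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import (
    AnalysisConfig,
    DensityCurve,
    MaximumEstimate,
    average_density,
    find_maximum,
    spike_density,
)
from .geometry import check_grating_set
from .shiftstats import (
    PopulationSummary,
    ShiftResult,
    bootstrap_max_significance,
    classify_shift,
    joint_chance_level,
    normality_and_clusters,
    shift_statistic,
)
from .synth import NeuronRecording

__all__ = ["NeuronClassification", "classify_neuron", "run_population", "population_report"]

#: labels of cells excluded before (or instead of) shift classification
EXCLUDED_LABELS = (
    "constant_at_min_distance",
    "monotonic_far_excluded",
    "outlier_excluded",
    "insufficient_trials",
)


@dataclass
class NeuronClassification:
    """Outcome of the full statistical pipeline for one neuron."""

    neuron_id: str
    label: str
    shift: ShiftResult | None = None
    maxima: dict[str, MaximumEstimate] = field(default_factory=dict)
    shift_2f_3f_pct: float | None = None
    truth_archetype: str | None = None
    notes: list[str] = field(default_factory=list)


def _track_limits(traj) -> tuple[float, float, float]:
    """(start_distance, end_distance, approach speed) of a trajectory."""
    start = float(traj.distances_mm.max())
    end = float(traj.distances_mm.min())
    t0, t1 = traj.approach_window_s
    speed = (start - end) / (t1 - t0)
    return start, end, speed


def classify_neuron(
    rec: NeuronRecording,
    cfg: AnalysisConfig = AnalysisConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> NeuronClassification:
    """Run the per-neuron analysis and return its classification.

    Stages: (1) per-trial spike densities (excluded trials dropped first);
    (2) trial-averaged curve and its maximum per grating; (3) bootstrap
    significance of each grating's maximum — any failure makes the cell
    ``nonsignificant``; (4) boundary rules: all maxima within one window
    span of the closest position -> ``constant_at_min_distance`` (rate rises
    monotonically toward the screen); 1F maximum at the far boundary ->
    ``monotonic_far_excluded`` (its true maximum may lie beyond the track,
    so a shifting maximum cannot be excluded), unless the 2F maximum lies
    closer than half the start distance, which makes the implied 1F maximum
    unresolvable -> ``outlier_excluded``; (5) otherwise the all-pairs shift
    distribution and the sign-test classification.  When a 3F grating is
    present and significant, the 2F-vs-3F shift (expected 50% for a
    frequency-tuned cell) is reported as a consistency check only.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    out = NeuronClassification(
        neuron_id=rec.neuron_id,
        label="unclassified",
        truth_archetype=rec.metadata.get("archetype"),
    )
    labels = rec.grating_labels
    if "1F" not in labels or "2F" not in labels:
        raise ValueError(f"recording {rec.neuron_id} lacks a 1F/2F grating pair")
    check_grating_set([rec.trials_for(lab)[0].grating for lab in labels])

    trials_by_label = {lab: rec.trials_for(lab) for lab in labels}
    for lab, trials in trials_by_label.items():
        if len(trials) < cfg.min_trials_per_grating:
            out.label = "insufficient_trials"
            out.notes.append(
                f"{lab}: {len(trials)} non-excluded trials "
                f"(< {cfg.min_trials_per_grating})"
            )
            return out

    curves_by_label = {
        lab: [spike_density(t, cfg) for t in trials]
        for lab, trials in trials_by_label.items()
    }
    seeds = ss.spawn(len(labels))
    for lab, child in zip(labels, seeds):
        out.maxima[lab] = bootstrap_max_significance(curves_by_label[lab], cfg, child)
    if not (out.maxima["1F"].significant and out.maxima["2F"].significant):
        out.label = "nonsignificant"
        return out

    traj = trials_by_label["1F"][0].trajectory
    start_d, end_d, speed = _track_limits(traj)
    tol = cfg.boundary_tolerance(speed)
    m1, m2 = out.maxima["1F"].distance_mm, out.maxima["2F"].distance_mm
    core = [out.maxima[lab] for lab in ("1F", "2F")]
    if all(m.distance_mm <= end_d + tol for m in core):
        out.label = "constant_at_min_distance"
        return out
    if m1 >= start_d - tol:
        if m2 < start_d / 2.0:
            out.label = "outlier_excluded"
            out.notes.append(
                "2F maximum closer than half the start distance while the 1F "
                "maximum sits at the far boundary: implied 1F maximum beyond the track"
            )
        else:
            out.label = "monotonic_far_excluded"
            out.notes.append(
                "1F maximum at the far track boundary; a shifting maximum "
                "beyond the track cannot be excluded"
            )
        return out

    m1_trials = _per_trial_maxima(curves_by_label["1F"], cfg)
    m2_trials = _per_trial_maxima(curves_by_label["2F"], cfg)
    sr = ShiftResult.from_trial_maxima(m1_trials, m2_trials, m1, m2)
    classify_shift(sr, cfg)
    out.shift = sr
    out.label = sr.class_label

    if "3F" in out.maxima and out.maxima["3F"].significant:
        m3 = out.maxima["3F"].distance_mm
        if m3 > 0:
            out.shift_2f_3f_pct = shift_statistic(m2, m3)
    return out


def _per_trial_maxima(curves: list[DensityCurve], cfg: AnalysisConfig) -> list[float]:
    """Each trial's own density argmax; trials with no spikes are dropped."""
    vals = []
    for c in curves:
        est = find_maximum(c, cfg)
        if est.defined:
            vals.append(est.distance_mm)
    if not vals:
        raise ValueError("no trial produced a defined maximum")
    return vals


def run_population(
    recordings: list[NeuronRecording],
    cfg: AnalysisConfig = AnalysisConfig(),
    seed: int | np.random.SeedSequence = 0,
) -> tuple[list[NeuronClassification], PopulationSummary, dict]:
    """Classify every neuron and summarize the population.

    Returns the per-neuron classifications, the shift-distribution summary
    (normality tests, cluster means/SDs, constant-maximum position clusters)
    and a JSON-ready report with label counts.  The shift distribution pools
    the mean pairwise shift of every neuron that reached the shift stage
    (both maxima significant and no boundary exclusion).  Constant-maximum
    positions are the per-grating maxima averaged per constant cell;
    ``constant_at_min_distance`` cells contribute the track end distance.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    classifications = [
        classify_neuron(rec, cfg, child)
        for rec, child in zip(recordings, ss.spawn(len(recordings)))
    ]

    shifts = [
        c.shift.mean_pairwise_shift_pct for c in classifications if c.shift is not None
    ]
    positions: list[float] = []
    for c in classifications:
        if c.label == "constant":
            positions.append(
                float(np.mean([c.maxima[lab].distance_mm for lab in ("1F", "2F")]))
            )
        elif c.label == "constant_at_min_distance":
            end_d = min(m.distance_mm for m in c.maxima.values())
            positions.append(end_d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = normality_and_clusters(shifts, positions)

    report = population_report(classifications, summary, cfg)
    return classifications, summary, report


def population_report(
    classifications: list[NeuronClassification],
    summary: PopulationSummary,
    cfg: AnalysisConfig,
) -> dict:
    """JSON-ready population report (label counts and cluster structure)."""
    counts = {
        lab: sum(c.label == lab for c in classifications)
        for lab in (
            "constant",
            "shifting",
            "unclassified",
            "nonsignificant",
        )
        + EXCLUDED_LABELS
    }
    studied = len(classifications)
    significant_both = (
        counts["constant"] + counts["shifting"] + counts["unclassified"]
    )
    report = {
        "n_studied": studied,
        "n_significant_both": significant_both,
        "counts": counts,
        "joint_chance_level": joint_chance_level(cfg.alpha),
        "expected_false_discoveries": studied * joint_chance_level(cfg.alpha),
        "shifts_sorted_pct": sorted(float(s) for s in summary.shifts_pct),
        "pooled_lilliefors": summary.pooled_lilliefors,
        "constant_cluster": summary.constant_cluster,
        "shifting_cluster": summary.shifting_cluster,
        "constant_positions_mm": sorted(
            float(p) for p in summary.constant_positions_mm
        ),
        "positions_lilliefors": summary.positions_lilliefors,
        "position_clusters": {
            k: v
            for k, v in summary.position_clusters.items()
            if k != "assignments"
        },
        "notes": summary.notes,
    }
    return report


def classifications_to_frame(
    classifications: list[NeuronClassification],
) -> pd.DataFrame:
    """Per-neuron results as a tidy table (one row per neuron)."""
    rows = []
    for c in classifications:
        sr = c.shift
        rows.append(
            {
                "neuron_id": c.neuron_id,
                "label": c.label,
                "truth_archetype": c.truth_archetype,
                "m1_mm": c.maxima.get("1F").distance_mm if "1F" in c.maxima else np.nan,
                "m2_mm": c.maxima.get("2F").distance_mm if "2F" in c.maxima else np.nan,
                "shift_pct": sr.shift_pct if sr else np.nan,
                "mean_pairwise_shift_pct": sr.mean_pairwise_shift_pct if sr else np.nan,
                "n_pairs": sr.n_pairs if sr else 0,
                "p_sign": sr.p_sign if sr else np.nan,
                "shift_2f_3f_pct": c.shift_2f_3f_pct,
                "notes": "; ".join(c.notes),
            }
        )
    return pd.DataFrame(rows)


def write_report_json(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
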