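"""Viewing geometry of a slow physical approach toward a stationary grating.

A sinusoidal grating of fixed physical period projects onto the retina with a
spatial frequency (cycles/degree) that grows linearly with viewing distance:
far away, many cycles fit into one degree of visual angle; up close, few do.
During approach the projection of any off-axis point also drifts across the
retina, faster the closer the eye is to the screen and the more eccentric the
receptive field.  These two closed forms — spatial frequency as a function of
distance, and retinal drift speed as a function of trolley speed, eccentricity
and distance — are the geometric backbone of the whole analysis: a neuron
tuned to a fixed retinal spatial frequency must respond at a distance
proportional to the grating period, so halving the period halves the distance
of its response maximum (a "100% shift"), while a neuron tuned to absolute
distance responds at the same place regardless of the grating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GratingSpec",
    "EyeModel",
    "DriftQuery",
    "DriftSpeed",
    "spatial_frequency",
    "retinal_drift_speed",
    "expected_shift_distance",
    "peak_distance_for_sf",
    "eccentricity_mm_from_deg",
]


@dataclass(frozen=True)
class GratingSpec:
    """Physical sinusoidal grating shown on the screen.

    Parameters
    ----------
    period_mm : float
        Physical period of the grating on the screen, mm.
    label : str
        ``"1F"``, ``"2F"`` or ``"3F"`` — the low-frequency grating and the
        gratings with twice/thrice its spatial frequency (half/one-third the
        physical period).
    orientation_deg : float
        Grating orientation in degrees; informational only.
    """

    period_mm: float
    label: str = "1F"
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.period_mm > 0:
            raise ValueError(f"period_mm must be positive, got {self.period_mm}")
        if self.label not in ("1F", "2F", "3F"):
            raise ValueError(f"label must be one of 1F/2F/3F, got {self.label!r}")


# nominal harmonic ratio of each label to the fundamental
_LABEL_FACTOR = {"1F": 1.0, "2F": 2.0, "3F": 3.0}


def check_grating_set(gratings: list[GratingSpec], rtol: float = 0.01) -> None:
    """Validate that a test set of gratings forms a harmonic series.

    Within one neuron's test set the 2F period must be half the 1F period and
    the 3F period one third of it, to relative tolerance ``rtol``.
    """
    by_label = {g.label: g for g in gratings}
    if "1F" not in by_label:
        raise ValueError("grating set must contain a 1F grating")
    p1 = by_label["1F"].period_mm
    for label, g in by_label.items():
        expected = p1 / _LABEL_FACTOR[label]
        if abs(g.period_mm - expected) > rtol * expected:
            raise ValueError(
                f"{label} period {g.period_mm} mm is not 1F period / "
                f"{_LABEL_FACTOR[label]:.0f} = {expected} mm within {rtol:.0%}"
            )


@dataclass(frozen=True)
class EyeModel:
    """Small-angle pinhole model of the cat eye.

    ``eye_diameter_mm`` is the posterior nodal distance D1 (the radius of the
    eye as an optical system is taken equal to its diameter for the cat), so
    one radian of visual angle — ``degrees_per_radian`` degrees — spans D1 mm
    of retina.
    """

    eye_diameter_mm: float = 13.0
    degrees_per_radian: float = 57.3

    def __post_init__(self) -> None:
        if not self.eye_diameter_mm > 0:
            raise ValueError("eye_diameter_mm must be positive")
        if not self.degrees_per_radian > 0:
            raise ValueError("degrees_per_radian must be positive")


@dataclass(frozen=True)
class DriftQuery:
    """Inputs of the retinal drift-speed formula.

    V2 = ``trolley_speed_mm_s``, E = ``eccentricity_on_screen_mm`` (distance
    of the receptive field from the center of gaze measured on the screen),
    D2 = ``distance_mm`` (eye-to-screen distance).
    """

    trolley_speed_mm_s: float
    eccentricity_on_screen_mm: float
    distance_mm: float

    def __post_init__(self) -> None:
        if not self.distance_mm > 0:
            raise ValueError("distance_mm must be positive")
        if self.trolley_speed_mm_s < 0:
            raise ValueError("trolley_speed_mm_s must be non-negative")
        if self.eccentricity_on_screen_mm < 0:
            raise ValueError("eccentricity_on_screen_mm must be non-negative")


@dataclass(frozen=True)
class DriftSpeed:
    """Retinal drift speed in both conventions."""

    mm_per_s: float
    deg_per_s: float


def spatial_frequency(
    grating: GratingSpec | float,
    distance_mm,
    eye: EyeModel = EyeModel(),
):
    """Retinal spatial frequency (cycles/degree) of a grating viewed at a distance.

    Small-angle form: one degree of visual angle spans
    ``distance_mm / degrees_per_radian`` mm on the screen, so

        sf = distance_mm / (period_mm * degrees_per_radian)

    Strictly decreasing in the period and strictly increasing in distance.

    Parameters
    ----------
    grating : GratingSpec or float
        The grating, or directly its period in mm.
    distance_mm : float or array
        Eye-to-screen distance(s), mm; must be positive.
    """
    period = grating.period_mm if isinstance(grating, GratingSpec) else float(grating)
    if not period > 0:
        raise ValueError(f"grating period must be positive, got {period}")
    distance_mm = np.asarray(distance_mm, dtype=float)
    if np.any(distance_mm <= 0):
        raise ValueError("distance_mm must be positive")
    sf = distance_mm / (period * eye.degrees_per_radian)
    return sf if sf.ndim else float(sf)


def peak_distance_for_sf(
    optimal_sf_cpd: float, period_mm: float, eye: EyeModel = EyeModel()
) -> float:
    """Distance at which a grating attains a given retinal spatial frequency.

    Inverse of :func:`spatial_frequency`: d = sf * period * degrees_per_radian.
    For a purely frequency-tuned cell this is the predicted location of its
    response maximum; it scales linearly with grating period.
    """
    if not optimal_sf_cpd > 0:
        raise ValueError("optimal_sf_cpd must be positive")
    if not period_mm > 0:
        raise ValueError("period_mm must be positive")
    return optimal_sf_cpd * period_mm * eye.degrees_per_radian


def retinal_drift_speed(q: DriftQuery, eye: EyeModel = EyeModel()) -> DriftSpeed:
    """Speed of the retinal drift of a stationary off-axis point during approach.

    V1 = V2 * E * D1 / D2**2 (mm/s on the retina); in degrees/s the same
    drift is V1_mm * degrees_per_radian / D1.  For fixed eccentricity the
    drift accelerates as 1/D2**2 while the trolley approaches the screen.
    """
    mm_per_s = (
        q.trolley_speed_mm_s
        * q.eccentricity_on_screen_mm
        * eye.eye_diameter_mm
        / q.distance_mm**2
    )
    deg_per_s = mm_per_s * eye.degrees_per_radian / eye.eye_diameter_mm
    return DriftSpeed(mm_per_s=mm_per_s, deg_per_s=deg_per_s)


def expected_shift_distance(m1_distance_mm: float) -> float:
    """Predicted 2F maximum position for a purely frequency-tuned cell.

    Doubling the spatial frequency of the grating halves the distance at
    which any fixed retinal spatial frequency is attained, so the maximum is
    expected half way closer to the screen — equivalently a 100% shift.
    """
    if not m1_distance_mm > 0:
        raise ValueError("m1_distance_mm must be positive")
    return m1_distance_mm / 2.0


def eccentricity_mm_from_deg(
    distance_mm: float, eccentricity_deg: float
) -> float:
    """Convert angular receptive-field eccentricity to screen mm at a distance.

    E = D2 * tan(ecc); convenience for building :class:`DriftQuery` inputs.
    """
    if not distance_mm > 0:
        raise ValueError("distance_mm must be positive")
    return distance_mm * float(np.tan(np.deg2rad(eccentricity_deg)))
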