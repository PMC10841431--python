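"""Tangent stiffness and relative fascicle displacement at a force threshold.

The series-compliance manipulation is quantified on force–length curves
restricted to the lengthening phase of a stretch: a second-order polynomial
is fitted by least squares, the displacement where the fitted curve crosses
a fixed force threshold is solved for (first crossing on the rising limb),
and the tangent slope there is the stiffness. The thresholds follow the
stretch type — 0.5 N for ramps, 0.4 N for triangles and sinusoids, whose
lower speeds and amplitudes develop less force.

Relative fascicle displacement (RFD, dL_Fas/dL_MTU) is the local slope of
the fascicle-versus-MTU displacement curve evaluated at the MTU
displacement where force crosses the same threshold; it is the fraction of
imposed stretch actually taken up by the fascicle. For two linear springs
in series, RFD = k_series / (k_fascicle + k_series).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import ConditionedTrial

logger = logging.getLogger(__name__)

#: Force thresholds (N) at which tangents are evaluated, per stretch type.
FORCE_THRESHOLDS = {"ramp_hold": 0.5, "triangle": 0.4, "sinusoid": 0.4}


class ThresholdNotReached(ValueError):
    """The force trace never crosses the requested threshold in range."""


@dataclass
class StiffnessEstimate:
    """Tangent stiffnesses and RFD of one stretch at a force threshold."""

    k_mtu: float             # N/mm, dF/dL_MTU at the threshold
    k_fas: float             # N/mm, dF/dL_Fas at the threshold
    rfd: float               # mm/mm, dL_Fas/dL_MTU at the threshold
    force_threshold: float   # N
    phase_used: str = "lengthening"
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.rfd <= 1.05):
            logger.warning("RFD %.3f outside (0, 1.05]; check fascicle "
                           "calibration", self.rfd)


def _quad_fit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares quadratic fit; returns (coeffs high->low, residual RMS)."""
    coeffs = np.polyfit(x, y, 2)
    resid = y - np.polyval(coeffs, x)
    return coeffs, float(np.sqrt(np.mean(resid ** 2)))


def tangent_slope(
    x: np.ndarray, y: np.ndarray, y_threshold: float,
    return_crossing: bool = False,
):
    """Tangent slope dy/dx of a quadratic fit where y crosses a threshold.

    Fits ``y = a x^2 + b x + c`` over the provided (lengthening-phase)
    samples, solves for the x where the fitted curve equals ``y_threshold``
    — taking the first crossing on the rising limb within the data range —
    and returns ``2 a x0 + b``.

    Raises
    ------
    ThresholdNotReached
        If the fitted curve never attains the threshold within the data
        range (including complex or out-of-range roots).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 samples for a quadratic fit")
    (a, b, c), rms = _quad_fit(x, y)
    lo, hi = float(np.min(x)), float(np.max(x))
    span = hi - lo
    tol = 1e-9 * max(span, 1.0)
    if abs(a) < 1e-12 * max(abs(b), 1.0):
        if b == 0.0:
            raise ThresholdNotReached("threshold not reached: flat fit")
        roots = np.array([(y_threshold - c) / b])
    else:
        disc = b * b - 4.0 * a * (c - y_threshold)
        if disc < 0:
            raise ThresholdNotReached(
                f"threshold not reached: fitted curve never attains "
                f"{y_threshold}")
        sq = np.sqrt(disc)
        roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    in_range = roots[(roots >= lo - tol) & (roots <= hi + tol)]
    if in_range.size == 0:
        raise ThresholdNotReached(
            f"threshold not reached: crossing of {y_threshold} lies outside "
            f"the data range [{lo:.4g}, {hi:.4g}]")
    # rising limb: smallest admissible root = first crossing in time for a
    # monotone lengthening phase
    x0 = float(np.min(in_range))
    slope = 2.0 * a * x0 + b
    if return_crossing:
        return slope, x0, rms
    return slope


def slope_at(x: np.ndarray, y: np.ndarray, x0: float) -> tuple[float, float]:
    """Tangent slope of a quadratic fit evaluated at a given x.

    Returns (slope, residual RMS). Used for RFD, where the evaluation point
    comes from the force-threshold crossing of a different curve.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 samples for a quadratic fit")
    (a, b, _), rms = _quad_fit(x, y)
    return 2.0 * a * x0 + b, rms


def stiffness_and_rfd(
    trial: ConditionedTrial,
    segmentation=None,
    force_threshold: Optional[float] = None,
    stretch_index: int = 0,
) -> StiffnessEstimate:
    """MTU stiffness, fascicle stiffness and RFD for one conditioned trial.

    Fits are restricted to the lengthening phase of one stretch (default
    the first): hysteresis between lengthening and shortening makes a
    single polynomial over the full loop ill-posed. ``k_mtu`` and ``k_fas``
    are tangent slopes of force against MTU and fascicle displacement at
    the threshold; RFD is the slope of fascicle against MTU displacement at
    the MTU displacement where force crosses it.
    """
    from .features import segment_phases  # local import, avoids cycle
    if segmentation is None:
        segmentation = segment_phases(trial)
    if force_threshold is None:
        if trial.protocol is None:
            raise ValueError("force_threshold required when the trial has "
                             "no protocol metadata")
        force_threshold = FORCE_THRESHOLDS[trial.protocol.kind]
    phase = segmentation.stretches[stretch_index]
    m = (trial.time >= phase.onset) & (trial.time <= phase.end_of_lengthening)
    if m.sum() < 3:
        raise ValueError("lengthening phase too short for a quadratic fit")
    L_mtu = trial.mtu_length[m]
    L_fas = trial.fascicle_length[m]
    F = trial.mtu_force[m]

    k_mtu, x0_mtu, rms_mtu = tangent_slope(L_mtu, F, force_threshold,
                                           return_crossing=True)
    k_fas, _, rms_fas = tangent_slope(L_fas, F, force_threshold,
                                      return_crossing=True)
    rfd, rms_rfd = slope_at(L_mtu, L_fas, x0_mtu)
    return StiffnessEstimate(
        k_mtu=k_mtu, k_fas=k_fas, rfd=rfd, force_threshold=force_threshold,
        fit_diagnostics={"rms_mtu": rms_mtu, "rms_fas": rms_fas,
                         "rms_rfd": rms_rfd,
                         "mtu_displacement_at_threshold": x0_mtu},
    )
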