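"""Stretch protocol definitions and servomotor length commands.

Three passive-stretch protocols are used to probe muscle spindle firing:

* ``sinusoid`` — locomotor-like cyclic stretch (2 mm peak-to-peak at 2 Hz);
* ``ramp_hold`` — perturbation-like ramp–hold–release (3 mm at 20 mm/s,
  1 s hold);
* ``triangle`` — repeated symmetric stretches (three 3 mm ramps at
  3.5 mm/s) used to quantify serial history dependence.

A :class:`ProtocolSpec` carries the protocol parameters plus the acquisition
sample rate (17.8 kHz) and the quiet baselines recorded before and after the
motion. :func:`make_command` renders the commanded MTU length trajectory on
the uniform time grid, and :meth:`ProtocolSpec.breakpoints` exposes the exact
phase boundaries (stretch onset, end of lengthening, hold, release) that the
segmentation stage uses for generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

DEFAULT_SAMPLE_RATE = 17_800.0  # Hz

PROTOCOL_KINDS = ("sinusoid", "ramp_hold", "triangle")


@dataclass(frozen=True)
class StretchPhase:
    """Phase boundaries of a single stretch (all in seconds, trial clock)."""

    onset: float
    end_of_lengthening: float
    hold_start: float
    hold_end: float
    release_end: float

    def __post_init__(self) -> None:
        seq = (self.onset, self.end_of_lengthening, self.hold_start,
               self.hold_end, self.release_end)
        if any(b - a < -1e-12 for a, b in zip(seq, seq[1:])):
            raise ValueError(f"stretch phase boundaries out of order: {seq}")

    @property
    def lengthening_duration(self) -> float:
        return self.end_of_lengthening - self.onset


@dataclass(frozen=True)
class ProtocolSpec:
    """Parameters of one stretch protocol.

    Parameters
    ----------
    kind : {"sinusoid", "ramp_hold", "triangle"}
    amplitude : float
        Stretch amplitude in mm (peak-to-peak for sinusoids).
    velocity : float, optional
        Ramp velocity in mm/s (ramp_hold and triangle).
    frequency : float, optional
        Cycle frequency in Hz (sinusoid).
    hold_duration : float
        Hold time at the stretched length in s (ramp_hold).
    repetitions : int
        Number of stretches (triangle) or cycles (sinusoid).
    sample_rate : float
        Acquisition rate in Hz.
    pre_baseline, post_baseline : float
        Quiet time recorded before/after the motion, in s. The pre-stretch
        baseline is what the force signal-to-noise exclusion rule uses.
    """

    kind: str
    amplitude: float
    velocity: Optional[float] = None
    frequency: Optional[float] = None
    hold_duration: float = 0.0
    repetitions: int = 1
    sample_rate: float = DEFAULT_SAMPLE_RATE
    pre_baseline: float = 0.5
    post_baseline: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(
                f"unknown protocol kind {self.kind!r}; expected one of {PROTOCOL_KINDS}")
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be > 0 mm, got {self.amplitude}")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be > 0 Hz, got {self.sample_rate}")
        if self.repetitions < 1:
            raise ValueError(f"repetitions must be >= 1, got {self.repetitions}")
        if self.kind == "sinusoid":
            if self.frequency is None or not self.frequency > 0:
                raise ValueError(
                    f"sinusoid requires frequency > 0 Hz, got {self.frequency}")
        else:
            if self.velocity is None or not self.velocity > 0:
                raise ValueError(
                    f"{self.kind} requires velocity > 0 mm/s, got {self.velocity}")
        if self.kind == "ramp_hold" and self.hold_duration < 0:
            raise ValueError("hold_duration must be >= 0 s")
        if self.pre_baseline < 0 or self.post_baseline < 0:
            raise ValueError("baselines must be >= 0 s")

    # ------------------------------------------------------------------ #

    @property
    def motion_duration(self) -> float:
        """Duration of the commanded motion, excluding baselines (s)."""
        if self.kind == "sinusoid":
            return self.repetitions / self.frequency
        ramp = self.amplitude / self.velocity
        if self.kind == "ramp_hold":
            return 2.0 * ramp + self.hold_duration
        return self.repetitions * 2.0 * ramp  # triangle

    @property
    def total_duration(self) -> float:
        return self.pre_baseline + self.motion_duration + self.post_baseline

    def time_grid(self) -> np.ndarray:
        n = int(round(self.total_duration * self.sample_rate)) + 1
        return np.arange(n) / self.sample_rate

    def breakpoints(self) -> list[StretchPhase]:
        """Exact phase boundaries of each stretch (or sinusoid cycle)."""
        t0 = self.pre_baseline
        phases: list[StretchPhase] = []
        if self.kind == "sinusoid":
            period = 1.0 / self.frequency
            for i in range(self.repetitions):
                on = t0 + i * period
                # lengthening = first half cycle of 1-cos stretch
                phases.append(StretchPhase(on, on + period / 2.0,
                                           on + period / 2.0,
                                           on + period / 2.0, on + period))
            return phases
        ramp = self.amplitude / self.velocity
        if self.kind == "ramp_hold":
            on = t0
            eol = on + ramp
            phases.append(StretchPhase(on, eol, eol, eol + self.hold_duration,
                                       eol + self.hold_duration + ramp))
            return phases
        for i in range(self.repetitions):  # triangle
            on = t0 + i * 2.0 * ramp
            eol = on + ramp
            phases.append(StretchPhase(on, eol, eol, eol, eol + ramp))
        return phases

    def stretch_onsets(self) -> np.ndarray:
        return np.array([p.onset for p in self.breakpoints()])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(**d)


# Study presets ------------------------------------------------------- #

def sinusoid(amplitude: float = 2.0, frequency: float = 2.0,
             repetitions: int = 4, **kw) -> ProtocolSpec:
    """2 mm, 2 Hz sinusoidal stretch (locomotor-like)."""
    return ProtocolSpec("sinusoid", amplitude, frequency=frequency,
                        repetitions=repetitions, **kw)


def ramp_hold(amplitude: float = 3.0, velocity: float = 20.0,
              hold_duration: float = 1.0, **kw) -> ProtocolSpec:
    """3 mm ramp at 20 mm/s with a 1 s hold, then release."""
    return ProtocolSpec("ramp_hold", amplitude, velocity=velocity,
                        hold_duration=hold_duration, **kw)


def triangle(amplitude: float = 3.0, velocity: float = 3.5,
             repetitions: int = 3, **kw) -> ProtocolSpec:
    """Three symmetric 3 mm up–down ramps at 3.5 mm/s."""
    return ProtocolSpec("triangle", amplitude, velocity=velocity,
                        repetitions=repetitions, **kw)


PRESETS = {"sinusoid": sinusoid, "ramp_hold": ramp_hold, "triangle": triangle}


def make_command(protocol: ProtocolSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the commanded MTU length trajectory.

    Returns
    -------
    time, length : ndarray
        Uniform time grid (s) and commanded displacement from rest (mm).
        The trajectory starts at 0, is non-negative throughout (the motor
        only stretches from rest), and ends at 0.
    """
    t = protocol.time_grid()
    y = np.zeros_like(t)
    t0 = protocol.pre_baseline
    a = protocol.amplitude
    if protocol.kind == "sinusoid":
        f = protocol.frequency
        dur = protocol.repetitions / f
        m = (t >= t0) & (t <= t0 + dur)
        # non-negative stretch from rest: 0 -> amplitude -> 0 each cycle
        y[m] = a * (1.0 - np.cos(2.0 * np.pi * f * (t[m] - t0))) / 2.0
        return t, y
    v = protocol.velocity
    ramp = a / v
    if protocol.kind == "ramp_hold":
        rel = (t - t0)
        up = (rel >= 0) & (rel < ramp)
        hold = (rel >= ramp) & (rel < ramp + protocol.hold_duration)
        down = (rel >= ramp + protocol.hold_duration) & \
               (rel < 2 * ramp + protocol.hold_duration)
        y[up] = v * rel[up]
        y[hold] = a
        y[down] = a - v * (rel[down] - ramp - protocol.hold_duration)
        return t, np.clip(y, 0.0, a)
    # triangle
    period = 2.0 * ramp
    for i in range(protocol.repetitions):
        rel = t - (t0 + i * period)
        up = (rel >= 0) & (rel < ramp)
        down = (rel >= ramp) & (rel < period)
        y[up] = v * rel[up]
        y[down] = a - v * (rel[down] - ramp)
    return t, np.clip(y, 0.0, a)
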