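"""Trial containers: the raw and conditioned atoms of the pipeline.

Units are fixed pipeline-wide: mm (displacement from rest), N, s, pps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .protocols import ProtocolSpec

UNITS = {"time": "s", "mtu_length": "mm", "mtu_force": "N",
         "fascicle_length": "mm", "fascicle_voltage": "V",
         "spike_times": "s"}

CONDITIONS = ("CTRL", "SEE")


@dataclass
class TrialRecord:
    """One stretch trial: synchronized time series plus metadata.

    Attributes
    ----------
    time : ndarray
        Uniform time grid in s.
    mtu_length : ndarray
        MTU displacement from rest (L_MTU), mm. In SEE trials the "MTU"
        is the muscle–tendon unit plus the added spring, as one unit.
    mtu_force : ndarray
        MTU force (F_MTU), N.
    spike_times : ndarray
        Sorted afferent spike times, s, within [time[0], time[-1]].
    fascicle_length : ndarray, optional
        Fascicle displacement (L_Fas) from sonomicrometry, mm.
    fascicle_voltage : ndarray, optional
        Raw sonomicrometry voltage, V (calibrate to obtain length).
    condition : {"CTRL", "SEE"}
    discriminable : bool
        Whether action potentials could be discriminated from the cell
        recording; undiscriminable trials are excluded downstream.
    ground_truth : object, optional
        Generator parameters when the trial is synthetic.
    provenance : dict
        Seed, config hash, source notes.
    """

    time: np.ndarray
    mtu_length: np.ndarray
    mtu_force: np.ndarray
    spike_times: np.ndarray
    fascicle_length: Optional[np.ndarray] = None
    fascicle_voltage: Optional[np.ndarray] = None
    animal_id: str = ""
    afferent_id: str = ""
    condition: str = "CTRL"
    protocol: Optional[ProtocolSpec] = None
    trial_id: str = ""
    discriminable: bool = True
    ground_truth: Optional[object] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.mtu_length = np.asarray(self.mtu_length, dtype=float)
        self.mtu_force = np.asarray(self.mtu_force, dtype=float)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.fascicle_length is not None:
            self.fascicle_length = np.asarray(self.fascicle_length, dtype=float)
        if self.fascicle_voltage is not None:
            self.fascicle_voltage = np.asarray(self.fascicle_voltage, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.time.size
        for name in ("mtu_length", "mtu_force", "fascicle_length",
                     "fascicle_voltage"):
            ch = getattr(self, name)
            if ch is not None and ch.size != n:
                raise ValueError(
                    f"channel {name!r} has length {ch.size}, expected {n}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not np.all(np.isfinite(self.mtu_force)):
            raise ValueError("mtu_force contains non-finite values")
        if self.spike_times.size:
            d = np.diff(self.spike_times)
            if np.any(d <= 0):
                bad = self.spike_times[1:][d <= 0][0]
                raise ValueError(
                    f"spike_times must be strictly increasing (offending value {bad})")
            if self.spike_times[0] < self.time[0] or self.spike_times[-1] > self.time[-1]:
                off = (self.spike_times[0] if self.spike_times[0] < self.time[0]
                       else self.spike_times[-1])
                raise ValueError(
                    f"spike time {off} outside record span "
                    f"[{self.time[0]}, {self.time[-1]}]")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    @property
    def n_samples(self) -> int:
        return self.time.size


@dataclass
class ConditionedTrial:
    """A calibrated, decimated, filtered trial with derivative channels.

    Produced by :func:`spindlesee.conditioning.condition_channels`; the
    downsampled grid (≈890 Hz by default) carries smoothed displacement and
    force channels plus Savitzky–Golay velocities and yank (dF/dt).
    """

    time: np.ndarray
    mtu_length: np.ndarray
    mtu_force: np.ndarray
    fascicle_length: np.ndarray
    mtu_velocity: np.ndarray
    fascicle_velocity: np.ndarray
    mtu_yank: np.ndarray
    spike_times: np.ndarray
    source: TrialRecord
    config_hash: str = ""

    # channels usable as regression predictors
    PREDICTORS = ("mtu_displacement", "mtu_velocity", "fascicle_displacement",
                  "fascicle_velocity", "mtu_force")

    def predictor(self, name: str) -> np.ndarray:
        table = {"mtu_displacement": self.mtu_length,
                 "mtu_velocity": self.mtu_velocity,
                 "fascicle_displacement": self.fascicle_length,
                 "fascicle_velocity": self.fascicle_velocity,
                 "mtu_force": self.mtu_force}
        if name not in table:
            raise KeyError(
                f"unknown predictor {name!r}; expected one of {self.PREDICTORS}")
        return table[name]

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    # metadata passthrough
    @property
    def protocol(self) -> Optional[ProtocolSpec]:
        return self.source.protocol

    @property
    def condition(self) -> str:
        return self.source.condition

    @property
    def animal_id(self) -> str:
        return self.source.animal_id

    @property
    def afferent_id(self) -> str:
        return self.source.afferent_id

    @property
    def trial_id(self) -> str:
        return self.source.trial_id
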