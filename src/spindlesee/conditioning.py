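"""Calibration, filtering, differentiation and instantaneous firing rates.

The conditioning chain is fixed in order: decimate by a factor of 20 (with
an anti-alias FIR prefilter, zero-phase) from 17.8 kHz to 890 Hz, low-pass
with a fourth-order zero-phase Butterworth at 100 Hz, then smooth and
differentiate with a second-order Savitzky–Golay filter of window 21
samples (about 24 ms at 890 Hz). Zero-phase filtering is used throughout
because the downstream analysis correlates firing with kinematic channels
sample-by-sample, so phase lag must not be introduced.

Instantaneous firing rate (IFR) is the reciprocal of each inter-spike
interval, assigned to the later spike of the pair (causal convention).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import numpy as np
from scipy import signal

from .records import TrialRecord, ConditionedTrial

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignalConfig:
    """Conditioning parameters (defaults follow the study's processing)."""

    downsample_factor: int = 20
    butter_order: int = 4
    butter_cutoff: float = 100.0       # Hz
    savgol_order: int = 2
    savgol_window: int = 21            # samples, odd
    calibration_factor: float = 1.0    # mm/V, sonomicrometry scale

    def __post_init__(self) -> None:
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ValueError(
                f"savgol_window must be odd and > savgol_order, got "
                f"{self.savgol_window} (order {self.savgol_order})")
        if self.calibration_factor <= 0:
            raise ValueError("calibration_factor must be > 0 mm/V")

    def validate_for_rate(self, sample_rate: float) -> None:
        nyq = sample_rate / self.downsample_factor / 2.0
        if self.butter_cutoff >= nyq:
            raise ValueError(
                f"butter_cutoff {self.butter_cutoff} Hz is not below the "
                f"downsampled Nyquist frequency {nyq} Hz")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class IFRSeries:
    """Per-spike instantaneous firing rates.

    ``ifr[i] = 1 / (spike_times_at[i] - previous spike time)``, anchored at
    the later spike. Length is (number of spikes - 1).
    """

    times: np.ndarray   # s, time of the later spike of each pair
    ifr: np.ndarray     # pps

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.ifr = np.asarray(self.ifr, float)
        if self.times.shape != self.ifr.shape:
            raise ValueError("times and ifr must have the same shape")
        if np.any(self.ifr <= 0):
            raise ValueError("all IFR values must be > 0 pps")

    def __len__(self) -> int:
        return self.times.size

    def in_window(self, t0: float, t1: float) -> "IFRSeries":
        """IFR entries whose anchor spike falls in [t0, t1]."""
        m = (self.times >= t0) & (self.times <= t1)
        return IFRSeries(self.times[m], self.ifr[m])

    def contained(self, t0: float, t1: float) -> "IFRSeries":
        """IFR entries whose full inter-spike interval lies in [t0, t1].

        Used for windowed means: an anchor just after a silent gap carries
        the reciprocal of the whole gap, which would leak a spurious low
        rate into the window.
        """
        prev = self.times - 1.0 / self.ifr
        m = (self.times <= t1) & (prev >= t0 - 1e-12)
        return IFRSeries(self.times[m], self.ifr[m])


def spikes_to_ifr(spike_times: np.ndarray) -> IFRSeries:
    """Instantaneous firing rate from a sorted spike train.

    Fewer than two spikes yields an empty series (not an error); duplicate
    or out-of-order spike times are rejected.
    """
    st = np.asarray(spike_times, float)
    if st.size < 2:
        return IFRSeries(np.empty(0), np.empty(0))
    isi = np.diff(st)
    if np.any(isi <= 0):
        bad = st[1:][isi <= 0][0]
        raise ValueError(
            f"spike times must be strictly increasing (duplicate or reversed "
            f"at {bad})")
    return IFRSeries(st[1:], 1.0 / isi)


def calibrate_sonomicrometry(
    voltage: np.ndarray, calibration_factor: float
) -> np.ndarray:
    """Convert sonomicrometry voltage to fascicle displacement (mm).

    Applies the linear mm/V scale and subtracts the trial's initial value
    so the output is a displacement from rest; no other offset removal.
    """
    if not calibration_factor > 0:
        raise ValueError("calibration_factor must be > 0 mm/V")
    v = np.asarray(voltage, float)
    bad = np.flatnonzero(~np.isfinite(v))
    if bad.size:
        raise ValueError(
            f"non-finite voltage samples at indices {bad[:10].tolist()}"
            + ("..." if bad.size > 10 else ""))
    length = calibration_factor * v
    return length - length[0]


def encode_sonomicrometry(
    fascicle_length: np.ndarray, calibration_factor: float,
    rest_voltage: float = 0.0,
) -> np.ndarray:
    """Inverse of :func:`calibrate_sonomicrometry` (for synthetic trials)."""
    return np.asarray(fascicle_length, float) / calibration_factor + rest_voltage


def smooth_and_differentiate(
    x: np.ndarray, dt: float, cfg: SignalConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Savitzky–Golay smooth and first derivative of a uniform series."""
    smooth = signal.savgol_filter(x, cfg.savgol_window, cfg.savgol_order)
    deriv = signal.savgol_filter(x, cfg.savgol_window, cfg.savgol_order,
                                 deriv=1, delta=dt)
    return smooth, deriv


def condition_channels(
    record: TrialRecord, cfg: SignalConfig = SignalConfig()
) -> ConditionedTrial:
    """Decimate, filter and differentiate a trial's mechanical channels.

    Order of operations is fixed: anti-aliased decimation, zero-phase
    Butterworth low-pass, Savitzky–Golay smoothing + differentiation.
    Outputs include MTU and fascicle velocities (mm/s) and MTU yank (N/s),
    all differentiated with the same Savitzky–Golay operator.
    """
    cfg.validate_for_rate(record.sample_rate)
    q = cfg.downsample_factor
    n_down = record.n_samples // q
    warmup = max(3 * (cfg.butter_order + 1), cfg.savgol_window)
    if n_down <= 2 * warmup:
        raise ValueError(
            f"record too short to condition: {n_down} downsampled samples "
            f"but filters need more than {2 * warmup}")

    if record.fascicle_length is not None:
        fas = record.fascicle_length
    elif record.fascicle_voltage is not None:
        fas = calibrate_sonomicrometry(record.fascicle_voltage,
                                       cfg.calibration_factor)
    else:
        raise ValueError(
            "record has neither fascicle_length nor fascicle_voltage")

    def decimate(x: np.ndarray) -> np.ndarray:
        if q == 1:
            return x.copy()
        return signal.decimate(x, q, ftype="fir", zero_phase=True)

    t_down = record.time[::q]
    dt = float(t_down[1] - t_down[0])
    sos = signal.butter(cfg.butter_order, cfg.butter_cutoff,
                        fs=1.0 / dt, output="sos")

    out: dict[str, np.ndarray] = {}
    deriv: dict[str, np.ndarray] = {}
    for name, raw in (("mtu_length", record.mtu_length),
                      ("mtu_force", record.mtu_force),
                      ("fascicle_length", fas)):
        x = decimate(raw)
        x = signal.sosfiltfilt(sos, x)
        out[name], deriv[name] = smooth_and_differentiate(x, dt, cfg)

    return ConditionedTrial(
        time=t_down,
        mtu_length=out["mtu_length"],
        mtu_force=out["mtu_force"],
        fascicle_length=out["fascicle_length"],
        mtu_velocity=deriv["mtu_length"],
        fascicle_velocity=deriv["fascicle_length"],
        mtu_yank=deriv["mtu_force"],
        spike_times=record.spike_times.copy(),
        source=record,
        config_hash=cfg.hash(),
    )


@dataclass
class Exclusion:
    trial_id: str
    reason: str


def force_snr(record: TrialRecord) -> Optional[float]:
    """Force signal-to-noise ratio of one trial.

    SNR = (peak-to-peak force during the commanded motion) /
    (2 x RMS of the mean-subtracted pre-stretch baseline force). Returns
    ``None`` when the trial has no pre-stretch baseline to estimate noise
    from.
    """
    proto = record.protocol
    if proto is None or proto.pre_baseline <= 0:
        return None
    t = record.time
    base = record.mtu_force[t < proto.pre_baseline]
    if base.size < 2:
        return None
    t_end = proto.pre_baseline + proto.motion_duration
    stretch = record.mtu_force[(t >= proto.pre_baseline) & (t <= t_end)]
    noise_rms = float(np.std(base))
    if noise_rms == 0.0:
        return np.inf
    return float(np.ptp(stretch)) / (2.0 * noise_rms)


def exclude_trials(
    records: Iterable[TrialRecord], snr_threshold: float = 2.0
) -> tuple[list[TrialRecord], list[Exclusion]]:
    """Apply the study's trial-exclusion rules.

    Trials whose action potentials could not be discriminated are dropped,
    as are trials whose force records have SNR below ``snr_threshold``
    (default 2). Every exclusion is logged with its reason. When no
    pre-stretch baseline exists the SNR rule is skipped with a warning.
    """
    kept: list[TrialRecord] = []
    excluded: list[Exclusion] = []
    for rec in records:
        if not rec.discriminable:
            reason = "action potentials not discriminable"
            excluded.append(Exclusion(rec.trial_id, reason))
            logger.info("excluded %s: %s", rec.trial_id, reason)
            continue
        snr = force_snr(rec)
        if snr is None:
            warnings.warn(
                f"trial {rec.trial_id}: no pre-stretch baseline; force SNR "
                "rule skipped", stacklevel=2)
        elif snr < snr_threshold:
            reason = f"force SNR {snr:.3g} < {snr_threshold:g}"
            excluded.append(Exclusion(rec.trial_id, reason))
            logger.info("excluded %s: %s", rec.trial_id, reason)
            continue
        kept.append(rec)
    return kept, excluded
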