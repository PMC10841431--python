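"""Per-stretch firing metrics: burst, dynamic/static responses, history.

Metrics follow the stretch type:

* **sinusoids** — peak and mean IFR after the first cycle (the first cycle
  is excluded to ignore history-dependent firing);
* **ramp–hold–release** — initial burst (IB, 0 when not discernible),
  dynamic response (DR, peak IFR at the end of lengthening), static
  response (SR, firing rate about 0.5 s into the hold), and dynamic index
  (DI = DR − SR);
* **triangles** — mean IFR and spike count for the first and second
  stretches, the burst classification per stretch, and serial history
  dependence as first-minus-second differences.

"Discernible" initial burst is operationalized as a window + ratio rule:
the IFR maximum within the first 25% of lengthening counts as a burst only
when it exceeds 2x the median IFR over the remainder of the lengthening.
Both parameters are configurable and echoed into every output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .conditioning import IFRSeries
from .protocols import StretchPhase
from .records import ConditionedTrial


@dataclass(frozen=True)
class FeatureConfig:
    """Windowing conventions for the firing metrics (times in s)."""

    burst_window_frac: float = 0.25   # fraction of lengthening searched for IB
    burst_factor: float = 2.0         # IB must exceed factor x median IFR
    dr_window: float = 0.020          # DR search window before end of lengthening
    sr_offset: float = 0.5            # SR time into the hold phase
    sr_halfwidth: float = 0.05        # averaging half-window around sr_offset
    sr_fallback: float = 0.15         # widest search for a nearby spike
    mean_mode: str = "spike"          # "spike" (per-spike mean) or "rate"
                                      # (spike count / window duration)

    def __post_init__(self) -> None:
        if not 0 < self.burst_window_frac < 1:
            raise ValueError("burst_window_frac must be in (0, 1)")
        if self.burst_factor <= 0 or self.dr_window <= 0:
            raise ValueError("burst_factor and dr_window must be > 0")
        if self.mean_mode not in ("spike", "rate"):
            raise ValueError("mean_mode must be 'spike' or 'rate'")


@dataclass
class PhaseSegmentation:
    """Per-stretch phase boundaries of one trial."""

    kind: str
    stretches: list[StretchPhase]
    method: str = "command"   # "command" (exact breakpoints) or "detect"

    @property
    def n_stretches(self) -> int:
        return len(self.stretches)


def segment_phases(
    trial: ConditionedTrial,
    method: str = "auto",
    onset_fraction: float = 0.05,
    sustain: float = 0.010,
) -> PhaseSegmentation:
    """Locate stretch phase boundaries for one conditioned trial.

    For generated data the commanded trajectory's exact breakpoints are
    used. For measured data the motion onset is detected as the first
    sample where |MTU velocity| exceeds ``onset_fraction`` of the
    protocol's peak velocity, sustained for ``sustain`` seconds, and the
    protocol's phase template is anchored there.
    """
    proto = trial.protocol
    if proto is None:
        raise ValueError("segmentation requires protocol metadata")
    if method == "auto":
        synthetic = trial.source.provenance.get("source") == "synthetic"
        method = "command" if synthetic else "detect"
    if method == "command":
        return PhaseSegmentation(proto.kind, proto.breakpoints(), "command")
    if method != "detect":
        raise ValueError(f"unknown segmentation method {method!r}")

    if proto.kind == "sinusoid":
        peak_v = proto.amplitude * math.pi * proto.frequency
    else:
        peak_v = proto.velocity
    thr = onset_fraction * peak_v
    # detect on the raw servo channel: the zero-phase conditioning chain
    # smears the motion edge several ms backward
    raw = trial.source
    t_raw = raw.time
    v = np.abs(np.gradient(raw.mtu_length, t_raw))
    dt = float(t_raw[1] - t_raw[0])
    need = max(1, int(round(sustain / dt)))
    above = v > thr
    # first index where the threshold holds for `need` consecutive samples
    run = np.convolve(above.astype(int), np.ones(need, int), mode="valid")
    hits = np.flatnonzero(run == need)
    if hits.size == 0:
        raise ValueError("no motion detected: MTU velocity never exceeds "
                         f"{thr:.4g} mm/s for {sustain * 1e3:.0f} ms")
    onset = float(t_raw[hits[0]])
    shift = onset - proto.pre_baseline
    stretches = [
        StretchPhase(p.onset + shift, p.end_of_lengthening + shift,
                     p.hold_start + shift, p.hold_end + shift,
                     p.release_end + shift)
        for p in proto.breakpoints()
    ]
    return PhaseSegmentation(proto.kind, stretches, "detect")


# --------------------------------------------------------------------- #

@dataclass
class FeatureSet:
    """Firing metrics of one trial (pps unless noted); NaN = undefined."""

    protocol_kind: str
    initial_burst: float = math.nan          # IB; 0 when not discernible
    dynamic_response: float = math.nan       # DR
    static_response: float = math.nan        # SR
    dynamic_index: float = math.nan          # DI = DR - SR, exactly
    peak_ifr: float = math.nan
    mean_ifr: float = math.nan
    spike_count: float = math.nan
    per_stretch: list = field(default_factory=list)   # dicts per stretch
    history_dependence_mean_ifr: float = math.nan     # stretch1 - stretch2
    history_dependence_spike_count: float = math.nan
    flags: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flags"] = list(self.flags)
        return d


def _count_spikes(spike_times: Optional[np.ndarray], ifr: IFRSeries,
                  t0: float, t1: float) -> int:
    if spike_times is not None:
        st = np.asarray(spike_times, float)
        return int(np.sum((st >= t0) & (st <= t1)))
    return len(ifr.in_window(t0, t1))


def _mean_ifr(ifr: IFRSeries, t0: float, t1: float, cfg: FeatureConfig,
              spike_times: Optional[np.ndarray]) -> float:
    if cfg.mean_mode == "rate":
        return _count_spikes(spike_times, ifr, t0, t1) / (t1 - t0)
    w = ifr.contained(t0, t1)   # full-ISI-in-window mean
    if len(w) == 0:
        w = ifr.in_window(t0, t1)
    return float(np.mean(w.ifr)) if len(w) else math.nan


def _burst(ifr: IFRSeries, phase: StretchPhase, cfg: FeatureConfig,
           flags: list) -> float:
    """Window + ratio initial-burst rule; 0 when not discernible."""
    dur = phase.lengthening_duration
    split = phase.onset + cfg.burst_window_frac * dur
    burst = ifr.in_window(phase.onset, split)
    rest = ifr.in_window(split, phase.end_of_lengthening)
    if len(burst) == 0:
        return 0.0
    if len(rest) < 2:
        flags.append("burst rule: too few comparison spikes, IB set to 0")
        return 0.0
    peak = float(np.max(burst.ifr))
    ref = float(np.median(rest.ifr))
    return peak if peak > cfg.burst_factor * ref else 0.0


def sinusoid_features(
    ifr: IFRSeries, seg: PhaseSegmentation,
    cfg: FeatureConfig = FeatureConfig(),
    spike_times: Optional[np.ndarray] = None,
) -> FeatureSet:
    """Peak and mean IFR over cycles 2..end (first cycle excluded)."""
    if seg.n_stretches < 2:
        raise ValueError("sinusoid features need at least 2 cycles")
    fs = FeatureSet("sinusoid", config=asdict(cfg))
    t0 = seg.stretches[1].onset
    t1 = seg.stretches[-1].release_end
    w = ifr.in_window(t0, t1)
    if len(w) == 0:
        fs.flags.append("no spikes after cycle 1: features undefined")
        return fs
    fs.peak_ifr = float(np.max(w.ifr))
    fs.mean_ifr = _mean_ifr(ifr, t0, t1, cfg, spike_times)
    fs.spike_count = _count_spikes(spike_times, ifr, t0, t1)
    return fs


def ramp_features(
    ifr: IFRSeries, seg: PhaseSegmentation,
    cfg: FeatureConfig = FeatureConfig(),
    spike_times: Optional[np.ndarray] = None,
) -> FeatureSet:
    """IB, DR, SR and DI for a ramp–hold–release stretch.

    DR is the maximum IFR within the last ``dr_window`` of lengthening
    (peak firing at the end of lengthening); SR averages the IFR in a
    ±``sr_halfwidth`` window centred ``sr_offset`` into the hold, falling
    back to the nearest spike within ±``sr_fallback`` (flagged) when the
    window is empty.
    """
    phase = seg.stretches[0]
    fs = FeatureSet("ramp_hold", config=asdict(cfg))
    fs.initial_burst = _burst(ifr, phase, cfg, fs.flags)

    dr_w = ifr.in_window(phase.end_of_lengthening - cfg.dr_window,
                         phase.end_of_lengthening)
    if len(dr_w):
        fs.dynamic_response = float(np.max(dr_w.ifr))
    else:
        length_w = ifr.in_window(phase.onset, phase.end_of_lengthening)
        if len(length_w):
            fs.dynamic_response = float(length_w.ifr[-1])
            fs.flags.append("DR fallback: last spike of lengthening")
        else:
            fs.flags.append("DR undefined: no spikes during lengthening")

    sr_t = phase.hold_start + cfg.sr_offset
    sr_w = ifr.in_window(sr_t - cfg.sr_halfwidth, sr_t + cfg.sr_halfwidth)
    if len(sr_w):
        fs.static_response = float(np.mean(sr_w.ifr))
    else:
        near = ifr.in_window(sr_t - cfg.sr_fallback, sr_t + cfg.sr_fallback)
        if len(near):
            i = int(np.argmin(np.abs(near.times - sr_t)))
            fs.static_response = float(near.ifr[i])
            fs.flags.append("SR fallback: nearest spike within +-0.15 s")
        else:
            fs.flags.append("SR undefined: no spikes near 0.5 s into hold")

    fs.dynamic_index = fs.dynamic_response - fs.static_response
    fs.peak_ifr = float(np.max(ifr.ifr)) if len(ifr) else math.nan
    fs.mean_ifr = _mean_ifr(ifr, phase.onset, phase.release_end, cfg,
                            spike_times)
    fs.spike_count = _count_spikes(spike_times, ifr, phase.onset,
                                   phase.release_end)
    return fs


def triangle_features(
    ifr: IFRSeries, seg: PhaseSegmentation,
    cfg: FeatureConfig = FeatureConfig(),
    spike_times: Optional[np.ndarray] = None,
) -> FeatureSet:
    """Per-stretch mean IFR, spike counts, burst, and history dependence.

    History dependence is the first-minus-second stretch difference of
    mean IFR and of spike count over the lengthening phases. The burst
    rule is evaluated on each stretch (the headline ``initial_burst`` is
    the first stretch's value).
    """
    if seg.n_stretches < 2:
        raise ValueError("triangle features need at least 2 stretches")
    fs = FeatureSet("triangle", config=asdict(cfg))
    for i, phase in enumerate(seg.stretches):
        entry = {"stretch": i + 1}
        entry["mean_ifr"] = _mean_ifr(ifr, phase.onset,
                                      phase.end_of_lengthening, cfg,
                                      spike_times)
        entry["spike_count"] = _count_spikes(spike_times, ifr, phase.onset,
                                             phase.end_of_lengthening)
        entry["initial_burst"] = _burst(ifr, phase, cfg, fs.flags)
        if len(ifr.in_window(phase.onset, phase.end_of_lengthening)) == 0:
            entry["mean_ifr"] = math.nan
            fs.flags.append(f"stretch {i + 1}: no spikes, features undefined")
        fs.per_stretch.append(entry)

    s1, s2 = fs.per_stretch[0], fs.per_stretch[1]
    fs.initial_burst = s1["initial_burst"]
    fs.mean_ifr = s1["mean_ifr"]
    fs.spike_count = s1["spike_count"]
    fs.history_dependence_mean_ifr = s1["mean_ifr"] - s2["mean_ifr"]
    fs.history_dependence_spike_count = s1["spike_count"] - s2["spike_count"]
    fs.peak_ifr = float(np.max(ifr.ifr)) if len(ifr) else math.nan
    return fs


def extract_features(
    trial: ConditionedTrial,
    seg: Optional[PhaseSegmentation] = None,
    cfg: FeatureConfig = FeatureConfig(),
) -> FeatureSet:
    """Dispatch to the stretch-type-specific feature extractor."""
    from .conditioning import spikes_to_ifr
    if seg is None:
        seg = segment_phases(trial)
    ifr = spikes_to_ifr(trial.spike_times)
    fn = {"sinusoid": sinusoid_features, "ramp_hold": ramp_features,
          "triangle": triangle_features}[seg.kind]
    return fn(ifr, seg, cfg, spike_times=trial.spike_times)
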