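"""Phase segmentation and per-stretch firing metrics."""

import math

import numpy as np
import pytest

import spindlesee as sp
from spindlesee.features import FeatureConfig


def ifr_from_spikes(spikes):
    return sp.spikes_to_ifr(np.asarray(spikes, float))


def regular_spikes(rate, t0, t1):
    return t0 + np.arange(1, int((t1 - t0) * rate) + 1) / rate


class TestSegmentation:
    def test_ramp_breakpoints_from_command(self, ramp_conditioned):
        seg = sp.segment_phases(ramp_conditioned)
        ph = seg.stretches[0]
        assert seg.method == "command"
        assert ph.onset == pytest.approx(0.5)          # pre-baseline
        assert ph.end_of_lengthening == pytest.approx(0.65)
        assert ph.hold_end == pytest.approx(1.65)      # 1 s hold

    def test_triangle_onsets(self, triangle_conditioned):
        seg = sp.segment_phases(triangle_conditioned)
        period = 2 * 3.0 / 3.5
        for i, ph in enumerate(seg.stretches):
            assert ph.onset == pytest.approx(0.5 + i * period)

    def test_velocity_detection_close_to_truth(self, default_params):
        # measured-style trial: strip the synthetic provenance so the
        # velocity-threshold path runs; onset recovered within 5 ms
        rec = sp.generate_trial(sp.ramp_hold(), default_params, "CTRL",
                                seed=21)
        rec.provenance = {"source": "external"}
        cond = sp.condition_channels(rec)
        seg = sp.segment_phases(cond)
        assert seg.method == "detect"
        assert seg.stretches[0].onset == pytest.approx(0.5, abs=0.005)

    def test_no_motion_raises(self, default_params):
        proto = sp.ramp_hold(pre_baseline=0.2, post_baseline=0.1,
                             hold_duration=0.2, sample_rate=17_800.0)
        t = proto.time_grid()
        rec = sp.TrialRecord(time=t, mtu_length=np.zeros_like(t),
                             mtu_force=np.zeros_like(t),
                             fascicle_length=np.zeros_like(t),
                             spike_times=[], protocol=proto,
                             provenance={"source": "external"})
        with pytest.raises(ValueError, match="no motion"):
            sp.segment_phases(sp.condition_channels(rec))


def sin_segmentation(n_cycles=4, period=0.5, t0=0.0):
    phases = [sp.StretchPhase(t0 + i * period, t0 + (i + 0.5) * period,
                              t0 + (i + 0.5) * period, t0 + (i + 0.5) * period,
                              t0 + (i + 1) * period)
              for i in range(n_cycles)]
    return sp.PhaseSegmentation("sinusoid", phases)


class TestSinusoidFeatures:
    def test_constant_rate(self):
        seg = sin_segmentation()
        spikes = regular_spikes(50.0, 0.0, 2.0)
        fs = sp.sinusoid_features(ifr_from_spikes(spikes), seg)
        assert fs.peak_ifr == pytest.approx(50.0)
        assert fs.mean_ifr == pytest.approx(50.0)

    def test_first_cycle_burst_excluded(self):
        seg = sin_segmentation()
        # 300 pps burst inside cycle 1, 100 pps afterwards
        burst = np.arange(0.1, 0.2, 1 / 300.0)
        later = regular_spikes(100.0, 0.5, 2.0)
        fs = sp.sinusoid_features(ifr_from_spikes(np.r_[burst, later]), seg)
        assert fs.peak_ifr == pytest.approx(100.0, rel=1e-6)

    def test_mean_matches_rate_integral_oracle(self, default_params):
        # with the count/duration convention, mean IFR equals the
        # time-average of the generator rate up to spike quantization
        proto = sp.sinusoid()
        rec = sp.generate_trial(proto, default_params.replace(noise_sd=0.0),
                                "CTRL", seed=7)
        t, cmd = sp.make_command(proto)
        _, F = sp.solve_series_mechanics(t, cmd, default_params, "CTRL")
        rate = sp.spindle_rate(t, F, default_params, proto.stretch_onsets())
        cond = sp.condition_channels(rec)
        seg = sp.segment_phases(cond)
        cfg = FeatureConfig(mean_mode="rate")
        fs = sp.sinusoid_features(sp.spikes_to_ifr(rec.spike_times), seg, cfg,
                                  spike_times=rec.spike_times)
        t0, t1 = seg.stretches[1].onset, seg.stretches[-1].release_end
        m = (t >= t0) & (t <= t1)
        oracle = np.trapezoid(rate[m], t[m]) / (t1 - t0)
        assert fs.mean_ifr == pytest.approx(oracle, abs=2.0 / (t1 - t0))

    def test_no_spikes_after_cycle_one_flagged(self):
        seg = sin_segmentation()
        spikes = np.arange(0.05, 0.45, 0.01)   # all in cycle 1
        fs = sp.sinusoid_features(ifr_from_spikes(spikes), seg)
        assert math.isnan(fs.peak_ifr)
        assert any("undefined" in f for f in fs.flags)


def ramp_segmentation():
    return sp.PhaseSegmentation(
        "ramp_hold", [sp.StretchPhase(0.0, 0.15, 0.15, 1.15, 1.30)])


class TestRampFeatures:
    def test_flat_rate_gives_zero_burst_and_index(self):
        seg = ramp_segmentation()
        spikes = regular_spikes(40.0, -0.2, 1.3)
        fs = sp.ramp_features(ifr_from_spikes(spikes), seg)
        assert fs.initial_burst == 0.0
        assert fs.dynamic_response == pytest.approx(40.0)
        assert fs.static_response == pytest.approx(40.0)
        assert fs.dynamic_index == pytest.approx(0.0)

    def test_dynamic_index_identity(self, default_params):
        # DI = DR - SR exactly, for every trial
        for seed in (1, 5, 9):
            rec = sp.generate_trial(sp.ramp_hold(), default_params, "CTRL",
                                    seed=seed)
            cond = sp.condition_channels(rec)
            fs = sp.extract_features(cond)
            assert fs.dynamic_index == fs.dynamic_response - fs.static_response

    def test_burst_recovered_from_generator(self, ramp_conditioned):
        # yank-driven onset burst: IB equals the burst-window IFR maximum
        seg = sp.segment_phases(ramp_conditioned)
        fs = sp.extract_features(ramp_conditioned, seg)
        ifr = sp.spikes_to_ifr(ramp_conditioned.spike_times)
        ph = seg.stretches[0]
        w = ifr.in_window(ph.onset,
                          ph.onset + 0.25 * ph.lengthening_duration)
        assert fs.initial_burst == pytest.approx(float(np.max(w.ifr)))
        assert fs.initial_burst > 100.0

    def test_burst_absent_when_yank_silenced(self, default_params):
        rec = sp.generate_trial(sp.ramp_hold(),
                                default_params.replace(kY=0.0), "CTRL",
                                seed=3)
        fs = sp.extract_features(sp.condition_channels(rec))
        assert fs.initial_burst == 0.0

    def test_sr_fallback_flagged(self):
        seg = ramp_segmentation()
        # spikes during ramp and early hold, then an isolated pair whose
        # second spike sits outside the +-50 ms SR window but inside the
        # +-150 ms fallback search
        spikes = np.r_[regular_spikes(50.0, -0.1, 0.3), 0.52, 0.53]
        fs = sp.ramp_features(ifr_from_spikes(spikes), seg)
        assert any("fallback" in f for f in fs.flags)
        assert fs.static_response == pytest.approx(100.0)

    def test_features_ignore_spikes_outside_windows(self, ramp_conditioned):
        seg = sp.segment_phases(ramp_conditioned)
        fs0 = sp.extract_features(ramp_conditioned, seg)
        extra = np.array([2.03, 2.04, 2.045])   # after release end
        ifr2 = sp.spikes_to_ifr(np.r_[ramp_conditioned.spike_times, extra])
        fs1 = sp.ramp_features(ifr2, seg)
        for attr in ("initial_burst", "dynamic_response", "static_response",
                     "dynamic_index"):
            assert getattr(fs1, attr) == getattr(fs0, attr)


def triangle_segmentation():
    period = 2 * 3.0 / 3.5
    phases = [sp.StretchPhase(i * period, i * period + period / 2,
                              i * period + period / 2, i * period + period / 2,
                              (i + 1) * period)
              for i in range(3)]
    return sp.PhaseSegmentation("triangle", phases)


class TestTriangleFeatures:
    def test_identical_stretches_zero_history(self):
        seg = triangle_segmentation()
        period = 2 * 3.0 / 3.5
        s1 = regular_spikes(30.0, 0.0, period / 2)
        spikes = np.r_[s1, s1 + period, s1 + 2 * period]
        fs = sp.triangle_features(ifr_from_spikes(spikes), seg,
                                  spike_times=spikes)
        assert fs.history_dependence_mean_ifr == pytest.approx(0.0, abs=1e-9)
        assert fs.history_dependence_spike_count == 0

    def test_spike_count_difference_integer_exact(self):
        seg = triangle_segmentation()
        period = 2 * 3.0 / 3.5
        half = period / 2
        s1 = np.linspace(0.01, half - 0.01, 20)
        s2 = np.linspace(0.01, half - 0.01, 14) + period
        spikes = np.r_[s1, s2]
        fs = sp.triangle_features(ifr_from_spikes(spikes), seg,
                                  spike_times=spikes)
        assert fs.per_stretch[0]["spike_count"] == 20
        assert fs.per_stretch[1]["spike_count"] == 14
        assert fs.history_dependence_spike_count == 6

    def test_history_dependence_monotone_in_slack_gain(self, default_params):
        # stronger second-stretch attenuation -> larger first-minus-second
        # mean-IFR difference; positive at the study's default attenuation
        hds = []
        for slack in (0.2, 0.5, 0.8):
            rec = sp.generate_trial(
                sp.triangle(), default_params.replace(slack_gain=slack),
                "CTRL", seed=13)
            fs = sp.extract_features(sp.condition_channels(rec))
            hds.append(fs.history_dependence_mean_ifr)
        assert hds[0] < hds[1] < hds[2]
        assert hds[2] > 0
        fs_default = sp.extract_features(sp.condition_channels(
            sp.generate_trial(sp.triangle(), default_params, "CTRL",
                              seed=13)))
        assert fs_default.history_dependence_mean_ifr > 0

    def test_burst_first_stretch_only(self, triangle_conditioned):
        fs = sp.extract_features(triangle_conditioned)
        assert fs.per_stretch[0]["initial_burst"] > 0
        assert fs.per_stretch[1]["initial_burst"] == 0.0
        assert fs.initial_burst == fs.per_stretch[0]["initial_burst"]


class TestRecoveryAgainstGroundTruth:
    def test_dr_sr_recovery_and_burst_classification(self, default_params):
        """On 100 seeded trials: DR and SR within 5% of the generator's
        rate, burst present/absent classified >= 95% correctly."""
        rng = np.random.default_rng(99)
        proto = sp.ramp_hold()
        t, cmd = sp.make_command(proto)
        n_dr = n_sr = n_ib = 0
        n_trials = 100
        for i in range(n_trials):
            gain = float(np.exp(rng.normal(0.0, 0.15)))
            with_burst = i % 2 == 0
            # burst-absent trials keep dense static firing (higher force
            # gain) so DR/SR remain measurable without a yank component
            p = default_params.replace(
                kF=(20.0 if with_burst else 80.0) * gain,
                kY=default_params.kY * gain if with_burst else 0.0)
            seed = int(rng.integers(0, 2 ** 31 - 1))
            rec = sp.generate_trial(proto, p, "CTRL", seed=seed)
            cond = sp.condition_channels(rec)
            seg = sp.segment_phases(cond)
            fs = sp.extract_features(cond, seg)
            # ground truth from the (noise-free) rate trace
            _, F = sp.solve_series_mechanics(t, cmd, p, "CTRL")
            rate = sp.spindle_rate(t, F, p, proto.stretch_onsets())
            ph = seg.stretches[0]
            dr_m = (t >= ph.end_of_lengthening - 0.02) & \
                   (t <= ph.end_of_lengthening)
            sr_m = (t >= ph.hold_start + 0.45) & (t <= ph.hold_start + 0.55)
            if abs(fs.dynamic_response - rate[dr_m].max()) \
                    <= 0.05 * rate[dr_m].max():
                n_dr += 1
            if abs(fs.static_response - rate[sr_m].mean()) \
                    <= 0.05 * rate[sr_m].mean():
                n_sr += 1
            if (fs.initial_burst > 0) == with_burst:
                n_ib += 1
        assert n_dr >= 0.95 * n_trials
        assert n_sr >= 0.95 * n_trials
        assert n_ib >= 0.95 * n_trials
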