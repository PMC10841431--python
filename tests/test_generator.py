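"""Series-elastic mechanics solver, rate model and spike generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import spindlesee as sp
from conftest import make_linear_trial


def short_ramp(sample_rate=17_800.0):
    return sp.ramp_hold(pre_baseline=0.1, post_baseline=0.1,
                        hold_duration=0.3, sample_rate=sample_rate)


class TestSeriesMechanics:
    def test_equal_linear_springs_split_half(self, ideal_params):
        # two equal linear springs in series: x_fas = k_s/(k_f+k_s) L = L/2
        t, cmd = sp.make_command(short_ramp())
        x, F = sp.solve_series_mechanics(t, cmd, ideal_params, "CTRL")
        np.testing.assert_allclose(x, 0.5 * cmd, atol=1e-12)
        np.testing.assert_allclose(F, 0.5 * cmd, atol=1e-12)

    def test_rigid_series_limit(self, ideal_params):
        params = ideal_params.replace(k_tendon=1e6)
        t, cmd = sp.make_command(short_ramp())
        x, _ = sp.solve_series_mechanics(t, cmd, params, "CTRL")
        assert np.max(np.abs(x - cmd)) < 1e-3

    def test_see_halves_series_stiffness(self):
        p = sp.GeneratorParams(k_tendon=2.0, k_see=2.0)
        assert p.series_stiffness("SEE") == pytest.approx(1.0)
        assert p.series_stiffness("SEE") < p.series_stiffness("CTRL")

    def test_nonlinear_solution_matches_brute_force_root(self):
        # quasi-static nonlinear spring: compare the per-sample quadratic
        # solution against independent scalar root-finding on the balance
        params = sp.GeneratorParams(k_lin=0.3, k_quad=0.1, c_damp=0.0,
                                    k_tendon=1.5, k_relax=0.0, tau_relax=0.0,
                                    noise_sd=0.0)
        t, cmd = sp.make_command(short_ramp(sample_rate=2000.0))
        x, _ = sp.solve_series_mechanics(t, cmd, params, "SEE")
        k_s = params.series_stiffness("SEE")
        for i in range(0, t.size, 97):
            if cmd[i] == 0.0:
                continue
            oracle = brentq(
                lambda z: params.k_lin * z + params.k_quad * z ** 2
                - k_s * (cmd[i] - z), 0.0, cmd[i])
            assert x[i] == pytest.approx(oracle, abs=1e-10)

    def test_force_balance_residual_all_protocols(self, default_params):
        # fascicle and series-element force agree at every sample
        for preset in (sp.sinusoid, sp.ramp_hold, sp.triangle):
            for cond in ("CTRL", "SEE"):
                rec = sp.generate_trial(preset(), default_params, cond, seed=2)
                res = sp.force_balance_residual(
                    rec.time, rec.mtu_length, rec.fascicle_length,
                    default_params, cond)
                assert np.max(np.abs(res)) < 1e-6

    def test_see_fascicle_displacement_never_exceeds_ctrl(self, default_params):
        # compliance partitions stretch away from the fascicle while the
        # MTU is lengthened or held; viscoelastic recoil after release is
        # excluded (the two conditions relax along different transients)
        proto = short_ramp()
        t, cmd = sp.make_command(proto)
        x_c, _ = sp.solve_series_mechanics(t, cmd, default_params, "CTRL")
        x_s, _ = sp.solve_series_mechanics(t, cmd, default_params, "SEE")
        m = t <= proto.breakpoints()[0].hold_end
        assert np.all(x_s[m] <= x_c[m] + 1e-12)

    def test_strictly_less_for_linear_springs(self, ideal_params):
        t, cmd = sp.make_command(short_ramp())
        x_c, _ = sp.solve_series_mechanics(t, cmd, ideal_params, "CTRL")
        x_s, _ = sp.solve_series_mechanics(t, cmd, ideal_params, "SEE")
        moving = cmd > 0
        assert np.all(x_s[moving] < x_c[moving])

    def test_stiff_see_converges_to_ctrl(self, default_params):
        # as k_see -> inf the SEE condition converges to CTRL on all channels
        proto = short_ramp()
        ctrl = sp.generate_trial(proto, default_params, "CTRL", seed=4)
        sups = []
        for k_see in (1e2, 1e4, 1e6):
            p = default_params.replace(k_see=k_see)
            see = sp.generate_trial(proto, p, "SEE", seed=4)
            sups.append(max(
                np.max(np.abs(see.fascicle_length - ctrl.fascicle_length)),
                np.max(np.abs(see.mtu_force - ctrl.mtu_force))))
        assert sups[0] > sups[1] > sups[2]
        assert sups[2] < 1e-3

    def test_command_not_starting_at_zero_rejected(self, ideal_params):
        t = np.linspace(0, 1, 100)
        with pytest.raises(ValueError, match="start at 0"):
            sp.solve_series_mechanics(t, t + 1.0, ideal_params)


class TestSpindleRate:
    def test_zero_force_gives_baseline(self, ideal_params):
        t = np.linspace(0, 1, 1000)
        p = ideal_params.replace(r0=10.0)
        r = sp.spindle_rate(t, np.zeros_like(t), p)
        np.testing.assert_allclose(r, 10.0)

    def test_constant_yank_closed_form(self):
        # F = 3t during [0,1]: r = r0 + kF*3t + kY*3, peaking at the end
        p = sp.GeneratorParams(kF=2.0, kY=4.0, r0=5.0, noise_sd=0.0)
        t = np.linspace(0, 1, 5000)
        F = 3.0 * t
        r = sp.spindle_rate(t, F, p)
        expected = 5.0 + 2.0 * 3.0 * t + 4.0 * 3.0
        np.testing.assert_allclose(r[5:-5], expected[5:-5], rtol=1e-6)
        assert np.argmax(r) >= t.size - 2

    def test_full_slack_removes_second_stretch_yank(self):
        p = sp.GeneratorParams(slack_gain=1.0, noise_sd=0.0)
        t = np.linspace(0, 2, 8000)
        # two identical force ramps (stretch 1 and stretch 2)
        F = np.where(t < 1.0, t, t - 1.0)
        r = sp.spindle_rate(t, F, p, stretch_onsets=[0.0, 1.0])
        first = (t > 0.05) & (t < 0.95)
        second = (t > 1.05) & (t < 1.95)
        # second stretch: yank term fully removed -> r = r0 + kF*F only
        np.testing.assert_allclose(r[second], p.r0 + p.kF * F[second],
                                   rtol=1e-6)
        assert r[second].mean() < r[first].mean()

    def test_rate_never_negative(self, default_params):
        t = np.linspace(0, 1, 2000)
        F = -np.ones_like(t) * 10.0
        r = sp.spindle_rate(t, F, default_params.replace(r0=0.0))
        assert np.all(r >= 0)


class TestRateToSpikes:
    def test_constant_rate_regular_spikes(self):
        t = np.linspace(0, 1, 17801)
        spikes = sp.rate_to_spikes(t, np.full_like(t, 10.0))
        assert spikes.size == 10
        np.testing.assert_allclose(spikes, 0.1 * np.arange(1, 11), atol=1e-4)

    def test_zero_rate_no_spikes(self):
        t = np.linspace(0, 1, 1000)
        assert sp.rate_to_spikes(t, np.zeros_like(t)).size == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_ifr_tracks_rate_against_fine_grid_oracle(self, seed):
        # 1/ISI at each spike ~ the rate there, vs brute-force integration
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 2, 35601)
        rate = 40.0 + 25.0 * np.sin(2 * np.pi * rng.uniform(0.5, 2.0) * t)
        spikes = sp.rate_to_spikes(t, rate)
        ifr = sp.spikes_to_ifr(spikes)
        # oracle: mean rate over each ISI from dense trapezoid integration
        for st_, en, f in zip(spikes[:-1], spikes[1:], ifr.ifr):
            grid = np.linspace(st_, en, 200)
            mean_rate = np.trapezoid(np.interp(grid, t, rate), grid) / (en - st_)
            assert f == pytest.approx(mean_rate, rel=0.02)

    @given(amp=st.floats(0.0, 30.0), base=st.floats(1.0, 80.0),
           freq=st.floats(0.2, 3.0))
    @settings(max_examples=40, deadline=None)
    def test_spike_count_conserves_rate_integral(self, amp, base, freq):
        t = np.linspace(0, 1.5, 8001)
        rate = np.clip(base + amp * np.sin(2 * np.pi * freq * t), 0, None)
        spikes = sp.rate_to_spikes(t, rate)
        integral = np.trapezoid(rate, t)
        assert abs(spikes.size - integral) <= 1.0

    def test_seeded_reproducibility(self, default_params):
        a = sp.generate_trial(short_ramp(), default_params, "SEE", seed=9)
        b = sp.generate_trial(short_ramp(), default_params, "SEE", seed=9)
        np.testing.assert_array_equal(a.spike_times, b.spike_times)
        np.testing.assert_array_equal(a.mtu_force, b.mtu_force)
        np.testing.assert_array_equal(a.fascicle_length, b.fascicle_length)

    def test_spikes_within_record_and_increasing(self, default_params):
        rec = sp.generate_trial(short_ramp(), default_params, "CTRL", seed=5)
        assert rec.spike_times[0] >= rec.time[0]
        assert rec.spike_times[-1] <= rec.time[-1]
        assert np.all(np.diff(rec.spike_times) > 0)


class TestGeneratorParamsValidation:
    @pytest.mark.parametrize("kw", [
        dict(k_lin=0.0), dict(k_tendon=-1.0), dict(slack_gain=1.5),
        dict(slack_gain=-0.1), dict(noise_sd=-1.0),
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            sp.GeneratorParams(**kw)

    def test_dataset_structure(self, default_params):
        trials = sp.generate_dataset(
            protocols=("ramp_hold",),
            params=default_params.replace(noise_sd=0.0),
            n_animals=2, afferents_per_animal=1, trials_per_condition=1,
            seed=3)
        assert len(trials) == 4  # 2 animals x 1 afferent x 2 conditions x 1
        assert {t.condition for t in trials} == {"CTRL", "SEE"}
        assert len({t.trial_id for t in trials}) == 4
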