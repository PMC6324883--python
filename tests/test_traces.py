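import numpy as np
import pytest

import xlinktrap.simephys as se
import xlinktrap.traces as tr


def _trace(time, current, protocol=None):
    prot = protocol or se.Protocol(
        (se.Episode(float(time[-1] + time[1]), ((0.0, se.Solution()),)),),
        sample_rate=1.0 / (time[1] - time[0]))
    return se.Trace(np.asarray(time, float), np.asarray(current, float), 0,
                    0.0, prot)


class TestMeasureEpisode:
    def test_flat_step_peak(self):
        t = np.arange(0, 0.4, 1e-3)
        i = np.where((t >= 0.1) & (t < 0.3), -100.0, 0.0)
        trace = _trace(t, i)
        assert tr.measure_episode(trace, (0.1, 0.3), (0.0, 0.1)) == \
            pytest.approx(100.0)

    def test_decaying_step_peak_exceeds_steady_state(self):
        t = np.arange(0, 0.4, 1e-3)
        i = np.where((t >= 0.1) & (t < 0.3),
                     -100.0 * np.exp(-(t - 0.1) / 0.05), 0.0)
        trace = _trace(t, i)
        pk = tr.measure_episode(trace, (0.1, 0.3), (0.0, 0.1), "peak")
        ss = tr.measure_episode(trace, (0.1, 0.3), (0.0, 0.1), "steady_state")
        assert pk > ss > 0

    def test_baseline_subtraction(self):
        t = np.arange(0, 0.4, 1e-3)
        i = np.where((t >= 0.1) & (t < 0.3), -120.0, -20.0)
        trace = _trace(t, i)
        assert tr.measure_episode(trace, (0.1, 0.3), (0.0, 0.1)) == \
            pytest.approx(100.0)

    def test_peak_matches_ode_occupancy_maximum(self, gating):
        """Peak read from the trace agrees with the analytic occupancy
        maximum of the underlying gating solution."""
        p = se.Protocol((se.Episode(0.3, ((0.0, se.Solution(dtt=1.0)),
                                          (0.05, se.Solution(glutamate=10.0,
                                                             dtt=1.0)),
                                          (0.25, se.Solution(dtt=1.0)))),),
                        sample_rate=20000)
        trs = se.simulate(gating, se.ModificationModel(), p, "M3M",
                          amplitude_pa=200.0)
        peak = tr.measure_episode(trs[0], (0.05, 0.25), (0.0, 0.05))
        analytic = 200.0 * trs[0].occupancy[:, 1].max()
        assert peak == pytest.approx(analytic, rel=0.01)

    def test_window_outside_episode_rejected(self):
        t = np.arange(0, 0.1, 1e-3)
        trace = _trace(t, np.zeros_like(t))
        with pytest.raises(ValueError):
            tr.measure_episode(trace, (0.5, 0.6))


class TestActiveFraction:
    def test_uses_second_post_pulse(self):
        m = tr.active_fraction([100, 100, 100, 100], [0, 30, 80])
        assert m.active_fraction == pytest.approx(0.30)

    def test_full_response_gives_one(self):
        m = tr.active_fraction([100, 100, 100, 100], [0, 100])
        assert m.active_fraction == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        pre = rng.uniform(50, 150, 4)
        post = rng.uniform(0, 150, 5)
        base = tr.active_fraction(pre, post).active_fraction
        scaled = tr.active_fraction(pre * 3.7, post * 3.7).active_fraction
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_requires_four_pre_and_two_post(self):
        with pytest.raises(ValueError):
            tr.active_fraction([1, 1, 1], [0, 1])
        with pytest.raises(ValueError):
            tr.active_fraction([1, 1, 1, 1], [0])
        with pytest.raises(ZeroDivisionError):
            tr.active_fraction([0, 0, 0, 0], [0, 1])


class TestFitExponential:
    def test_noiseless_single_recovery(self):
        x = np.linspace(0, 12, 80)
        y = 0.2 + 0.8 * np.exp(-x / 3.3)
        fit = tr.fit_exponential(x, y, 1)
        assert fit.taus[0] == pytest.approx(3.3, rel=1e-6)
        assert fit.offset == pytest.approx(0.2, rel=1e-5)

    def test_noiseless_double_recovery(self):
        x = np.linspace(0, 15, 200)
        y = 0.5 * np.exp(-x / 0.5) + 0.5 * np.exp(-x / 3.0)
        fit = tr.fit_exponential(x, y, 2)
        assert sorted(fit.taus) == pytest.approx([0.5, 3.0], rel=1e-5)
        assert fit.weighted_tau == pytest.approx(1.75, rel=1e-5)

    def test_weighted_tau_formula(self):
        fit = tr.ExpFit(np.array([0.5, 0.5]), np.array([0.5, 3.0]), 0.0, 0.0)
        assert fit.weighted_tau == pytest.approx(1.75)

    def test_noisy_recovery_within_ten_percent(self):
        """Median fitted tau over 50 noise seeds stays within 10% of the
        generating value at SNR 20."""
        x = np.linspace(0, 10, 100)
        clean = np.exp(-x / 2.0)
        taus = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = clean + rng.normal(0, 1 / 20.0, size=x.size)
            taus.append(tr.fit_exponential(x, y, 1).taus[0])
        assert abs(np.median(taus) / 2.0 - 1) < 0.10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tr.fit_exponential(np.arange(5.0), np.arange(5.0), 1)

    def test_model_selection_prefers_single_for_single(self):
        x = np.linspace(0, 10, 120)
        y = np.exp(-x / 2.0)
        fit = tr.choose_exponential(x, y)
        assert len(fit.taus) == 1


class TestRecoveryEnvelope:
    def test_simulated_reversal_tau_recovered(self, gating):
        """Post-trap peaks of a population reversing at k_rev = 1/30 s^-1
        recover with a fitted tau near 30 s."""
        p = se.build_protocol("recovery_series", n_pulses=90, sample_rate=2000)
        mod = se.ModificationModel(trap_efficacy=0.0)
        initial = np.array([0.2, 0, 0, 0.8, 0, 0])  # 80% trapped at start
        trs = se.simulate(gating, mod, p, "M1M", initial=initial)
        peaks, times = [], []
        for i, t in enumerate(trs):
            peaks.append(tr.measure_episode(t, p.response_window(i),
                                            p.baseline_window(i)))
            times.append(t.start_time)
        fit = tr.recovery_envelope(peaks, times)
        assert not fit.flagged
        assert fit.taus[0] == pytest.approx(30.0, rel=0.05)

    def test_all_equal_envelope_flagged_with_unit_recovery(self):
        fit = tr.recovery_envelope([5.0] * 10, list(range(10)),
                                   pre_reference=5.0)
        assert fit.flagged
        assert fit.recovered == pytest.approx(1.0)

    def test_zero_recovery_flagged(self):
        y = 2.0 - 0.01 * np.arange(10.0)
        fit = tr.recovery_envelope(y, np.arange(10.0))
        assert fit.flagged == "no recovery"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tr.recovery_envelope([1, 2, 3], [0, 1, 2])


class TestRatios:
    def _square(self, amplitude):
        t = np.arange(0, 0.4, 1e-3)
        i = np.where((t >= 0.1) & (t < 0.3), -amplitude, 0.0)
        return _trace(t, i)

    def test_identical_traces_give_unit_ka_glu(self):
        a = self._square(100.0)
        assert tr.efficacy_ratio(a, a, (0.1, 0.3), (0.0, 0.1)) == \
            pytest.approx(1.0)

    def test_partial_agonist_ratio(self):
        ka = self._square(46.0)
        glu = self._square(100.0)
        assert tr.efficacy_ratio(ka, glu, (0.1, 0.3), (0.0, 0.1)) == \
            pytest.approx(0.46)

    def test_simulated_kainate_efficacy_recovered(self):
        g = se.GatingModel(kainate_efficacy=0.46)
        p = se.build_protocol("ka_glu", sample_rate=10000, ctz=100.0)
        trs = se.simulate(g, se.ModificationModel(), p, "M3M")
        ratio = tr.efficacy_ratio(trs[0], trs[1], p.response_window(0),
                                  p.baseline_window(0))
        assert ratio == pytest.approx(0.46, rel=0.02)

    def test_square_response_is_hundred_percent(self):
        a = self._square(100.0)
        assert tr.ss_peak_ratio(a, (0.1, 0.3), (0.0, 0.1)) == \
            pytest.approx(100.0)

    def test_configured_equilibrium_desensitization_recovered(self):
        """A population equilibrating at 26.6% active occupancy shows a
        steady-state/peak ratio of ~26.6%."""
        g = se.GatingModel.with_equilibrium_desensitization(0.266,
                                                           k_act=1e5)
        p = se.build_protocol("trap_1min", conc=0.0, n_post=1,
                              trap_s=1.0, sample_rate=20000)
        trs = se.simulate(g, se.ModificationModel(), p, "M3M")
        ratio = tr.ss_peak_ratio(trs[0], p.response_window(0),
                                 p.baseline_window(0))
        assert ratio == pytest.approx(26.6, rel=0.02)

    def test_peak_window_inside_decay_reduces_ratio(self):
        t = np.arange(0, 0.4, 1e-3)
        i = np.where((t >= 0.1) & (t < 0.3),
                     -100.0 * np.exp(-(t - 0.1) / 0.05), 0.0)
        trace = _trace(t, i)
        assert tr.ss_peak_ratio(trace, (0.1, 0.3), (0.0, 0.1)) < 100.0


def test_end_to_end_recovers_trapped_fraction(gating):
    """simulate -> measure recovers the simulator's trapped fraction
    (zero-efficacy linker) within 3%."""
    p = se.build_protocol("trap_1min", conc=1e-6, sample_rate=5000)
    mod = se.ModificationModel(accessibility=0.20066, trap_efficacy=0.0)
    trs = se.simulate(gating, mod, p, "M3M")
    pre = [tr.measure_episode(trs[i], p.response_window(i),
                              p.baseline_window(i)) for i in range(4)]
    post = [tr.measure_episode(trs[i], p.response_window(i),
                               p.baseline_window(i)) for i in range(5, 15)]
    measured = tr.active_fraction(pre, post).active_fraction
    truth = 1.0 - trs[4].occupancy[-1, 3:].sum()
    assert measured == pytest.approx(truth, abs=0.03)
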