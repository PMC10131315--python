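"""Voltage-clamp analysis: fits, round trips and error handling."""

import numpy as np
import pandas as pd
import pytest

from cardioclamp import patchclamp as pc
from cardioclamp import synthdata as sd


def _boltzmann(v, vhalf, k):
    return 1.0 / (1.0 + np.exp((vhalf - v) / k))


class TestBoltzmann:
    def test_noiseless_conductance_recovers_gating(self, wt_model):
        """A noiseless I-V family inverts to the generating activation curve."""
        fam = sd.simulate_iv_family(wt_model)
        iv = pc.measure_peak_currents(fam)
        gv = pc.conductance_curve(iv, e_rev=wt_model.e_rev)
        keep = ~gv["excluded"]
        fit = pc.fit_boltzmann(gv.loc[keep, "voltage_mV"],
                               gv.loc[keep, "g_norm"], "activation")
        assert fit.vhalf == pytest.approx(-31.0, abs=1e-6)
        assert fit.k == pytest.approx(6.0, abs=1e-6)

    def test_inactivation_orientation(self, wt_model):
        df = sd.simulate_inactivation_curve(wt_model)
        fit = pc.fit_boltzmann(df["voltage_mV"], df["availability"],
                               "inactivation")
        assert fit.vhalf == pytest.approx(-71.5, abs=1e-6)
        assert fit.k == pytest.approx(9.9, abs=1e-6)
        assert fit.k > 0

    def test_midpoint_identity(self):
        v = np.arange(-60, 10, 5.0)
        fit = pc.fit_boltzmann(v, _boltzmann(v, -31.0, 6.0), "activation")
        assert fit.predict(np.array([fit.vhalf]))[0] == pytest.approx(fit.a / 2)

    @pytest.mark.parametrize("scale", [0.1, 3.0, 250.0])
    def test_scale_invariance(self, scale):
        """V1/2 and k are invariant to uniform scaling of the response."""
        v = np.arange(-60, 10, 5.0)
        y = _boltzmann(v, -31.0, 6.0)
        fit = pc.fit_boltzmann(v, scale * y, "activation")
        assert fit.vhalf == pytest.approx(-31.0, abs=1e-6)
        assert fit.k == pytest.approx(6.0, abs=1e-6)
        assert fit.a == pytest.approx(scale, rel=1e-6)

    def test_too_few_points_rejected(self):
        v = np.array([-40.0, -30.0, -20.0, -10.0])
        with pytest.raises(ValueError, match="at least 5"):
            pc.fit_boltzmann(v, _boltzmann(v, -31, 6), "activation")

    def test_median_vhalf_error_below_reported_se(self, wt_model, rng):
        """Across 100 noisy replicates the median |V1/2 error| stays below
        the between-cell SE typical of such datasets (2 mV)."""
        errs = []
        for _ in range(100):
            df = sd.simulate_inactivation_curve(wt_model, noise_sd=0.02,
                                                seed=int(rng.integers(2 ** 31)))
            fit = pc.fit_boltzmann(df["voltage_mV"], df["availability"],
                                   "inactivation")
            errs.append(abs(fit.vhalf - wt_model.vhalf_inact))
        assert np.median(errs) < 2.0


class TestPeakCurrents:
    def test_zero_driving_force_zero_peak(self, wt_model):
        fam = sd.simulate_iv_family(wt_model)
        iv = pc.measure_peak_currents(fam)
        at_rev = np.flatnonzero(iv.voltages == wt_model.e_rev)
        assert iv.peak_pA[at_rev] == pytest.approx(0.0, abs=1e-9)

    def test_boltzmann_midpoint_peak_value(self, wt_model):
        """At V = V1/2 the gate is half open, so the peak is half-maximal
        conductance times the driving force."""
        fam = sd.simulate_iv_family(
            wt_model, protocol=sd.StepProtocol(-31.0, -31.0, 5.0),
            capacitance_pF=20.0)
        iv = pc.measure_peak_currents(fam)
        expected = 0.5 * wt_model.gmax * (-31.0 - wt_model.e_rev) * 20.0
        assert iv.peak_pA[0] == pytest.approx(expected, rel=1e-9)

    def test_zero_sweeps_zero_density(self):
        sweeps = [pc.Sweep(v, np.zeros(200)) for v in (-40.0, -20.0, 0.0)]
        fam = pc.SweepFamily(sweeps, sample_rate=20_000, capacitance_pF=15.0)
        iv = pc.measure_peak_currents(fam)
        assert np.all(iv.peak_density == 0.0)

    def test_density_requires_capacitance(self, wt_model):
        fam = sd.simulate_iv_family(wt_model)
        fam.capacitance_pF = None
        iv = pc.measure_peak_currents(fam)
        assert iv.peak_density is None

    def test_window_outside_sweep_rejected(self, wt_model):
        fam = sd.simulate_iv_family(wt_model, sweep_ms=50.0)
        with pytest.raises(ValueError, match="window"):
            pc.measure_peak_currents(fam, window_ms=(10.0, 500.0))


class TestConductance:
    def test_chord_conductance_arithmetic(self):
        iv = pc.IVCurve(voltages=np.array([-40.0, -20.0, 0.0]),
                        peak_pA=np.array([-20.0, -26.0, -10.0]),
                        peak_density=np.array([-20.0, -26.0, -10.0]))
        gv = pc.conductance_curve(iv, e_rev=40.0)
        assert gv.loc[1, "g"] == pytest.approx(-26.0 / -60.0, rel=1e-12)

    def test_reversal_band_excluded(self, wt_model):
        fam = sd.simulate_iv_family(wt_model)
        iv = pc.measure_peak_currents(fam)
        gv = pc.conductance_curve(iv, e_rev=wt_model.e_rev)
        assert gv.loc[gv["voltage_mV"] == wt_model.e_rev, "excluded"].all()
        assert gv.loc[gv["excluded"], "g"].isna().all()

    def test_matches_activation_gate_pointwise(self, wt_model):
        fam = sd.simulate_iv_family(wt_model)
        iv = pc.measure_peak_currents(fam)
        gv = pc.conductance_curve(iv, e_rev=wt_model.e_rev)
        keep = ~gv["excluded"]
        act = wt_model.act_inf(gv.loc[keep, "voltage_mV"].to_numpy())
        expected = act / act.max()
        assert np.allclose(gv.loc[keep, "g_norm"], expected, atol=1e-9)

    def test_all_excluded_is_degenerate(self):
        iv = pc.IVCurve(voltages=np.array([39.0, 40.0, 41.0]),
                        peak_pA=np.zeros(3), peak_density=np.zeros(3))
        with pytest.raises(ValueError, match="degenerate"):
            pc.conductance_curve(iv, e_rev=40.0)


class TestDecayKinetics:
    def test_exact_biexponential_recovery(self):
        t = np.arange(0, 60, 0.05)
        i = -420.0 * (0.8 * np.exp(-t / 2.0) + 0.2 * np.exp(-t / 20.0))
        fit = pc.fit_inactivation_decay(t, i)
        assert not fit.monoexponential
        assert fit.tau_fast == pytest.approx(2.0, rel=1e-6)
        assert fit.tau_slow == pytest.approx(20.0, rel=1e-6)
        assert fit.a_fast == pytest.approx(0.8, rel=1e-6)

    def test_tau_ordering_enforced(self):
        t = np.arange(0, 60, 0.05)
        i = -100.0 * (0.3 * np.exp(-t / 25.0) + 0.7 * np.exp(-t / 1.5))
        fit = pc.fit_inactivation_decay(t, i)
        assert fit.tau_fast < fit.tau_slow

    def test_monoexponential_fallback_flagged(self):
        t = np.arange(0, 60, 0.05)
        i = -100.0 * np.exp(-t / 5.0)
        fit = pc.fit_inactivation_decay(t, i)
        assert fit.monoexponential
        assert fit.tau_fast == pytest.approx(5.0, rel=1e-4)

    def test_short_window_rejected(self):
        t = np.arange(0, 0.5, 0.05)
        with pytest.raises(ValueError, match="20 samples"):
            pc.fit_inactivation_decay(t, -np.exp(-t))


class TestRecovery:
    def test_direct_model_evaluation(self):
        """P2/P1 at t = tau_fast with equal fractions has the closed form
        1 - 0.5 e^-1 - 0.5 exp(-tau_f/tau_s)."""
        model = sd.GatingModel(recovery_tau_fast=74.8, recovery_tau_slow=700.3,
                               recovery_a_fast=0.5, recovery_a_slow=0.5)
        expected = 1.0 - 0.5 * np.exp(-1.0) - 0.5 * np.exp(-74.8 / 700.3)
        assert model.recovery_fraction(74.8) == pytest.approx(expected, rel=1e-12)

    def test_noiseless_roundtrip(self, wt_model):
        df = sd.simulate_recovery_protocol(wt_model)
        curve = pc.analyze_recovery(df)
        assert curve.fit.tau_fast == pytest.approx(74.8, rel=1e-6)
        assert curve.fit.tau_slow == pytest.approx(700.3, rel=1e-6)

    def test_full_recovery_at_long_intervals(self, wt_model):
        df = sd.simulate_recovery_protocol(
            wt_model, intervals_ms=(100, 500, 1000, 2000, 4000, 8000))
        assert df["p2"].iloc[-1] / df["p1"].iloc[-1] == pytest.approx(1.0, abs=1e-3)

    def test_amplitude_and_ordering_invariants(self, wt_model, rng):
        for _ in range(20):
            df = sd.simulate_recovery_protocol(wt_model, noise_sd=0.02,
                                               seed=int(rng.integers(2 ** 31)))
            fit = pc.analyze_recovery(df).fit
            assert fit.tau_fast < fit.tau_slow
            assert 0.0 <= fit.a_fast + fit.a_slow <= 1.05

    def test_too_few_intervals_refused(self, wt_model):
        df = sd.simulate_recovery_protocol(wt_model,
                                           intervals_ms=(5, 50, 200, 600, 1000))
        with pytest.raises(ValueError, match="6 intervals"):
            pc.analyze_recovery(df)

    def test_zero_p1_rejected(self):
        pts = pd.DataFrame({"interval_ms": np.arange(1.0, 10.0),
                            "p1": np.zeros(9), "p2": np.ones(9)})
        with pytest.raises(ValueError, match="P1"):
            pc.analyze_recovery(pts)

    def test_asymptomatic_line_recovers_faster(self, wt_model):
        wt = pc.analyze_recovery(sd.simulate_recovery_protocol(wt_model)).fit
        asym = pc.analyze_recovery(
            sd.simulate_recovery_protocol(sd.asymptomatic_gating_model())).fit
        assert asym.tau_fast < wt.tau_fast


class TestSlowEntry:
    def test_no_entry_at_zero_duration(self, wt_model):
        assert wt_model.slow_entry_fraction(0.0) == pytest.approx(1.0)

    def test_noiseless_roundtrip(self, wt_model):
        df = sd.simulate_slow_entry_protocol(wt_model)
        fit = pc.analyze_slow_inactivation_entry(df)
        assert fit.tau_fast == pytest.approx(wt_model.slowentry_tau_fast, rel=1e-4)
        assert fit.tau_slow == pytest.approx(wt_model.slowentry_tau_slow, rel=1e-4)

    def test_fitted_curve_monotone_nonincreasing(self, wt_model):
        df = sd.simulate_slow_entry_protocol(wt_model)
        fit = pc.analyze_slow_inactivation_entry(df)
        t = np.linspace(1.0, 2000.0, 200)
        y = (1.0 - fit.a_fast * (1 - np.exp(-t / fit.tau_fast))
             - fit.a_slow * (1 - np.exp(-t / fit.tau_slow)))
        assert np.all(np.diff(y) <= 1e-12)


class TestCapacitance:
    def test_charge_over_voltage_arithmetic(self):
        # rectangular 50 pA x 5 ms pulse: Q = 250 fC = 0.25 pC; dV = 5 mV
        t = np.arange(0, 20.0, 0.01)
        i = np.where((t >= 5.0) & (t < 10.0), 50.0, 0.0)
        c = pc.measure_capacitance(t, i, dv_mV=5.0)
        assert c == pytest.approx(50.0, rel=1e-3)

    def test_zero_transient_zero_capacitance(self):
        t = np.arange(0, 20.0, 0.01)
        assert pc.measure_capacitance(t, np.zeros_like(t), dv_mV=5.0) == 0.0

    def test_rc_transient_roundtrip(self):
        t, i = sd.simulate_capacitive_transient(capacitance_pF=20.0, dv_mV=-5.0)
        assert pc.measure_capacitance(t, i, dv_mV=-5.0) == pytest.approx(20.0, abs=0.5)

    def test_zero_step_rejected(self):
        t = np.arange(0, 10.0, 0.01)
        with pytest.raises(ValueError):
            pc.measure_capacitance(t, np.ones_like(t), dv_mV=0.0)


class TestIKr:
    def test_known_amplitudes_recovered(self):
        fam = sd.simulate_ikr_family(step_amplitudes_pA=(60, 120, 180, 240),
                                     tail_amplitudes_pA=(30, 60, 90, 120))
        out = pc.measure_ikr(fam, test_end_ms=1000.0,
                             tail_window_ms=(1005.0, 1400.0))
        assert np.allclose(out["peak_pA"], (60, 120, 180, 240), rtol=0.01)
        assert np.allclose(out["tail_pA"], (30, 60, 90, 120), rtol=0.01)

    def test_zero_trace(self):
        sweeps = [pc.Sweep(v, np.zeros(15_001)) for v in (-20.0, 0.0)]
        fam = pc.SweepFamily(sweeps, sample_rate=10_000, holding_mV=-40.0)
        out = pc.measure_ikr(fam, test_end_ms=1000.0,
                             tail_window_ms=(1000.0, 1400.0))
        assert (out["peak_pA"] == 0).all() and (out["tail_pA"] == 0).all()

    def test_tail_on_window_start_flagged(self):
        n = 15_001
        t = np.arange(n) / 10_000 * 1e3
        trace = np.where(t >= 1100.0, 80.0 * np.exp(-(t - 1100.0) / 50.0), 0.0)
        fam = pc.SweepFamily([pc.Sweep(0.0, trace)], sample_rate=10_000)
        out = pc.measure_ikr(fam, test_end_ms=1000.0,
                             tail_window_ms=(1200.0, 1400.0))
        assert out.loc[0, "tail_at_window_start"]

    def test_bad_windows_rejected(self):
        sweeps = [pc.Sweep(0.0, np.zeros(1001))]
        fam = pc.SweepFamily(sweeps, sample_rate=10_000)
        with pytest.raises(pc.ProtocolError):
            pc.measure_ikr(fam, test_end_ms=50.0, tail_window_ms=(10.0, 40.0))


class TestSweepFamily:
    def test_duplicate_voltages_rejected(self):
        sweeps = [pc.Sweep(-20.0, np.zeros(10)), pc.Sweep(-20.0, np.zeros(10))]
        with pytest.raises(pc.ProtocolError):
            pc.SweepFamily(sweeps, sample_rate=20_000)

    def test_mismatched_lengths_rejected(self):
        sweeps = [pc.Sweep(-20.0, np.zeros(10)), pc.Sweep(0.0, np.zeros(11))]
        with pytest.raises(pc.ProtocolError):
            pc.SweepFamily(sweeps, sample_rate=20_000)

    def test_average_iv_mean_and_sem(self, wt_model, rng):
        curves = []
        for _ in range(5):
            fam = sd.simulate_iv_family(wt_model, noise_sd=0.2,
                                        seed=int(rng.integers(2 ** 31)))
            curves.append(pc.measure_peak_currents(fam, smooth_window_ms=0.25))
        avg = pc.average_iv(curves)
        assert (avg["n"] == 5).all()
        at_minus20 = avg.loc[avg["voltage_mV"] == -20.0, "mean"].iloc[0]
        assert at_minus20 == pytest.approx(wt_model.peak_density(-20.0), abs=1.0)
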