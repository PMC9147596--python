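"""Fast sodium-current kinetics: peaks, conductance, Boltzmann fits, window,
inactivation tau and biexponential recovery."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rettephys.core_io import (FitError, InsufficientDataError, Trace,
                               UnitError)
from rettephys.ina_fast import (BoltzmannFit, analyse_iv, availability_curve,
                                availability_sigmoid, boltzmann, conductance,
                                estimate_erev, fit_activation,
                                fit_availability, fit_inactivation_tau,
                                fit_recovery, IvPoint, peak_iv,
                                recovery_ratios, window_current)
from rettephys.synthetic_data import (NaChannelParams,
                                      RECOVERY_INTERVALS_MS, gen_ina_family)


class TestPeakIv:
    def test_matches_closed_form_peak_of_generated_waveform(self, wt_params):
        # with a 0.3 ms exponential rise, the continuous-time peak of
        # (1 - e^{-t/r}) e^{-t/tau} has the closed form (tau/(r+tau)) *
        # ((r+tau)/r)^{-r/tau}; the sampled peak must sit within 1% of it
        p = NaChannelParams(f_late=0.0)
        r = 0.3
        fam = gen_ina_family(p, "IV_ACTIVATION", rise_tau_ms=r)
        for pt in peak_iv(fam):
            tau = float(p.tau_inact(pt.vm))
            cmax = (tau / (r + tau)) * ((r + tau) / r) ** (-r / tau)
            expected = p.gmax * float(p.a_inf(pt.vm)) * (pt.vm - p.erev) * cmax
            if abs(expected) > 1e-3:
                assert pt.peak_density == pytest.approx(expected, rel=0.01)

    def test_zero_current_sweep_gives_zero_peak(self):
        from rettephys.core_io import SweepFamily
        tr = Trace(np.zeros(1000), 0.1, units="pA/pF")
        fam = SweepFamily({-40.0: tr}, "IV_ACTIVATION",
                          meta={"step_start_ms": 20.0, "step_dur_ms": 50.0})
        assert peak_iv(fam)[0].peak_density == 0.0

    def test_most_negative_peak_near_minus_40(self, wt_params):
        fam = gen_ina_family(wt_params, "IV_ACTIVATION")
        iv = peak_iv(fam)
        best = min(iv, key=lambda p: p.peak_density)
        assert best.vm in (-40.0, -30.0)

    def test_unnormalised_sweeps_rejected(self, small_family):
        with pytest.raises(UnitError):
            peak_iv(small_family)


class TestReversalPotential:
    def test_exact_line_intercept(self):
        iv = [IvPoint(-40.0, -35.0), IvPoint(-30.0, -30.0),
              IvPoint(-20.0, -20.0), IvPoint(-10.0, -10.0)]
        assert estimate_erev(iv) == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_family_within_2mv_of_truth(self, wt_params):
        fam = gen_ina_family(wt_params, "IV_ACTIVATION")
        assert abs(estimate_erev(peak_iv(fam)) - wt_params.erev) < 2.0

    def test_two_ascending_points_insufficient(self):
        iv = [IvPoint(-40.0, -35.0), IvPoint(-30.0, -20.0), IvPoint(-20.0, -10.0)]
        with pytest.raises(InsufficientDataError):
            estimate_erev(iv)


class TestConductance:
    def test_hand_calculation(self):
        (vm, g), = conductance([IvPoint(-40.0, -5.0)], erev=30.0)
        assert g == pytest.approx(-5.0 / -70.0)

    def test_zero_current_zero_conductance(self):
        (_, g), = conductance([IvPoint(-40.0, 0.0)], erev=0.0)
        assert g == 0.0

    def test_points_near_erev_excluded_with_warning(self):
        iv = [IvPoint(0.5, -1.0), IvPoint(-40.0, -35.0)]
        with pytest.warns(UserWarning, match="E_rev"):
            out = conductance(iv, erev=0.0)
        assert len(out) == 1

    def test_gmax_found_on_plateau_of_synthetic_iv(self, wt_params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = analyse_iv(gen_ina_family(wt_params, "IV_ACTIVATION"),
                             erev=wt_params.erev)
        v_at_gmax = max(res.gv, key=lambda p: p[1])[0]
        assert v_at_gmax >= -30.0  # plateau, not the steep limb
        assert res.gmax == pytest.approx(wt_params.gmax, rel=0.02)


class TestBoltzmannFits:
    def test_activation_recovers_printed_wt_parameters(self):
        # noiseless conductance curve with v50 = -47.4, k = 3.6 on the
        # protocol grid refits to 3 decimals
        v = np.arange(-80.0, -19.9, 10.0)
        gv = list(zip(v, boltzmann(v, -47.4, 3.6)))
        fit = fit_activation(gv)
        assert fit.v_half == pytest.approx(-47.4, abs=5e-4)
        assert fit.k == pytest.approx(3.6, abs=5e-4)

    def test_midpoint_evaluates_to_half(self):
        assert boltzmann(-47.4, -47.4, 3.6) == pytest.approx(0.5)
        assert availability_sigmoid(-79.6, -79.6, 5.1) == pytest.approx(0.5)

    def test_availability_recovers_printed_mutant_parameters(self):
        v = np.arange(-150.0, -49.9, 10.0)
        pts = list(zip(v, availability_sigmoid(v, -79.6, 5.1)))
        fit = fit_availability(pts)
        assert fit.v_half == pytest.approx(-79.6, abs=5e-4)
        assert fit.k == pytest.approx(5.1, abs=5e-4)

    def test_availability_saturates_at_negative_potentials(self):
        assert availability_sigmoid(-1000.0, -79.6, 5.1) == pytest.approx(1.0)

    def test_activation_mean_recovery_under_noise(self):
        rng = np.random.default_rng(3)
        v = np.arange(-80.0, -19.9, 10.0)
        fitted = []
        for _ in range(200):
            y = boltzmann(v, -47.4, 3.6) + rng.normal(0, 0.02, v.size)
            fitted.append(fit_activation(list(zip(v, y))).v_half)
        assert abs(np.mean(fitted) + 47.4) < 0.5

    @given(v_half=st.floats(-60, -35), k=st.floats(2, 9))
    @settings(max_examples=40, deadline=None)
    def test_noiseless_round_trip_is_exact_for_any_gating(self, v_half, k):
        v = np.arange(-90.0, -10.0, 5.0)
        act = fit_activation(list(zip(v, boltzmann(v, v_half, k))),
                             v_range=(-90.0, -10.0))
        assert act.residual_sse < 1e-10
        assert act.v_half == pytest.approx(v_half, abs=1e-4)
        ih, ik = v_half - 35.0, k + 1.0
        vi = np.arange(-150.0, -40.0, 10.0)
        avail = fit_availability(list(zip(vi, availability_sigmoid(vi, ih, ik))),
                                 v_range=(-150.0, -40.0))
        assert avail.residual_sse < 1e-10
        assert avail.v_half == pytest.approx(ih, abs=1e-4)


class TestInactivationTau:
    def test_recovers_printed_wt_tau(self):
        # noiseless monoexponential decay, tau 2.6 ms, 20 ms window at 10 kHz
        t = np.arange(0.0, 20.0, 0.1)
        tr = Trace(np.concatenate([np.zeros(100), -30.0 * np.exp(-t / 2.6)]),
                   0.1, units="pA/pF")
        fit = fit_inactivation_tau(tr, step_start=10.0, step_dur=20.0)
        assert fit.tau == pytest.approx(2.6, abs=5e-4)

    def test_constant_after_peak_is_degenerate(self):
        samples = np.concatenate([np.zeros(100), np.full(500, -30.0)])
        tr = Trace(samples, 0.1, units="pA/pF")
        with pytest.raises(FitError):
            fit_inactivation_tau(tr, step_start=10.0, step_dur=50.0)

    def test_downsampling_changes_tau_below_1pct(self):
        t1 = np.arange(0.0, 20.0, 0.1)
        t2 = np.arange(0.0, 20.0, 0.2)
        f1 = fit_inactivation_tau(
            Trace(np.concatenate([np.zeros(100), -30 * np.exp(-t1 / 2.6)]),
                  0.1, units="pA/pF"), 10.0, 20.0)
        f2 = fit_inactivation_tau(
            Trace(np.concatenate([np.zeros(50), -30 * np.exp(-t2 / 2.6)]),
                  0.2, units="pA/pF"), 10.0, 20.0)
        assert f2.tau == pytest.approx(f1.tau, rel=0.01)

    def test_family_sweep_recovers_voltage_dependent_tau(self, wt_params):
        fam = gen_ina_family(wt_params, "IV_ACTIVATION")
        fit = fit_inactivation_tau(fam.sweeps[-40.0], 20.0, 250.0)
        assert fit.tau == pytest.approx(2.6, abs=5e-3)


class TestWindowCurrent:
    @pytest.fixture
    def fits(self):
        act = BoltzmannFit(-47.4, 3.6, 1.0, 0.0, "activation")
        inact = BoltzmannFit(-83.1, 6.5, 1.0, 0.0, "availability")
        return act, inact

    def test_closed_tails(self, fits):
        w = window_current(*fits, gmax=1.0, erev=0.0)
        assert w.values[0] == pytest.approx(0.0, abs=1e-6)
        assert w.values[-1] == pytest.approx(0.0, abs=1e-4)

    def test_peak_between_the_two_midpoints(self, fits):
        w = window_current(*fits, gmax=1.0, erev=0.0)
        assert -83.1 < w.peak_v < -47.4

    def test_gmax_linearity(self, fits):
        w1 = window_current(*fits, gmax=1.0, erev=0.0)
        w2 = window_current(*fits, gmax=2.0, erev=0.0)
        np.testing.assert_allclose(w2.values, 2.0 * w1.values)

    def test_peak_matches_dense_grid_brute_force(self, fits):
        act, inact = fits
        w = window_current(act, inact, gmax=1.0, erev=0.0)
        dense = np.arange(-120.0, 20.0, 0.01)
        prod = (boltzmann(dense, act.v_half, act.k)
                * availability_sigmoid(dense, inact.v_half, inact.k)
                * (dense - 0.0))
        brute = dense[int(np.argmax(-prod))]
        assert abs(w.peak_v - brute) <= 2.0  # within one grid step


class TestRecovery:
    @staticmethod
    def ratios(tau_f=11.0, tau_s=362.0, a_f=0.85):
        t = np.array(RECOVERY_INTERVALS_MS)
        r = 1 - (a_f * np.exp(-t / tau_f) + (1 - a_f) * np.exp(-t / tau_s))
        return list(zip(t, r))

    def test_recovers_printed_wt_parameters(self):
        fit = fit_recovery(self.ratios())
        assert fit.tau_fast == pytest.approx(11.0, abs=5e-4)
        assert fit.tau_slow == pytest.approx(362.0, abs=0.05)
        assert fit.a_fast == pytest.approx(0.85, abs=1e-4)
        assert fit.tau_fast < fit.tau_slow

    def test_full_recovery_at_long_intervals(self):
        _, r_last = self.ratios()[-1]
        assert r_last == pytest.approx(1.0, abs=2e-4)

    def test_single_exponential_data_matches_reduced_model(self):
        t = np.array(RECOVERY_INTERVALS_MS)
        r = 1 - np.exp(-t / 9.0)  # a_slow = 0
        fit = fit_recovery(list(zip(t, r)))
        # oracle: log-linear regression on 1 - r over the resolvable range
        sel = r < 0.999
        slope = np.polyfit(t[sel], np.log(1 - r[sel]), 1)[0]
        assert fit.tau_fast == pytest.approx(-1.0 / slope, rel=0.01)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_recovery(self.ratios()[:5])

    def test_family_round_trip(self, wt_params):
        fam = gen_ina_family(wt_params, "RECOVERY")
        fit = fit_recovery(recovery_ratios(fam))
        assert fit.tau_fast == pytest.approx(11.0, abs=1e-3)
        assert fit.a_fast == pytest.approx(0.85, abs=1e-3)


class TestFamilyRoundTrips:
    def test_iv_family_recovers_activation_parameters(self, wt_params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = analyse_iv(gen_ina_family(wt_params, "IV_ACTIVATION"),
                             erev=wt_params.erev)
        assert res.activation.v_half == pytest.approx(-47.4, abs=5e-4)
        assert res.activation.k == pytest.approx(3.6, abs=5e-4)

    def test_availability_family_recovers_inactivation_parameters(self, rtt_params):
        fam = gen_ina_family(rtt_params, "AVAILABILITY")
        fit = fit_availability(availability_curve(fam))
        assert fit.v_half == pytest.approx(-79.6, abs=5e-4)
        assert fit.k == pytest.approx(5.1, abs=5e-4)
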