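"""Capacitance, 9-AC subtraction, IV extraction, Boltzmann fits, Nernst."""

import numpy as np
import pytest

from myorescue import datasets
from myorescue.ephys import (
    BoltzmannIVParams,
    SolutionSpec,
    boltzmann_iv,
    capacitance_from_transient,
    extract_iv,
    fit_boltzmann_iv,
    fit_rel_po,
    nernst_potential,
    rel_po,
    subtract_blocker,
    total_ion_concentration,
)
from myorescue.simulate import simulate_iv_recording, simulate_tail_currents


class TestCapacitance:
    def test_rectangular_pulse_charge_over_voltage(self):
        t = np.linspace(0, 0.01, 1001)
        i = np.where(t <= 0.001, 1000.0, 0.0)  # 1000 pA for 1 ms -> Q = 1 pC
        c = capacitance_from_transient(t, i, dv_mv=10.0)
        assert c == pytest.approx(100.0, rel=0.01)

    def test_exponential_transient_recovers_known_capacitance(self):
        rec = simulate_iv_recording(
            datasets.iv_params_for_genotype("WT"), capacitance_pf=1234.0, noise_sd_pa_pf=0.0
        )
        c = capacitance_from_transient(rec.cap_time_s, rec.cap_current_pa, rec.cap_dv_mv)
        assert c == pytest.approx(1234.0, rel=0.01)

    def test_zero_trace_gives_zero(self):
        t = np.linspace(0, 0.01, 100)
        assert capacitance_from_transient(t, np.zeros_like(t)) == 0.0


class TestSubtraction:
    def test_identical_traces_cancel(self):
        x = np.sin(np.linspace(0, 1, 50))
        assert np.all(subtract_blocker(x, x) == 0.0)

    def test_zero_post_returns_pre(self):
        x = np.sin(np.linspace(0, 1, 50))
        np.testing.assert_array_equal(subtract_blocker(x, np.zeros_like(x)), x)

    def test_recovers_blocker_sensitive_component(self):
        rng = np.random.default_rng(0)
        leak = rng.normal(0, 1, 200).cumsum()
        clc1 = -40.0 * np.exp(-np.linspace(0, 1, 200) / 0.2)
        np.testing.assert_allclose(subtract_blocker(leak + clc1, leak), clc1, atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_blocker(np.zeros(10), np.zeros(11))


class TestExtractIV:
    def test_noiseless_extraction_matches_closed_form(self):
        p = datasets.iv_params_for_genotype("WT")
        rec = simulate_iv_recording(p, noise_sd_pa_pf=0.0, capacitance_pf=2000.0)
        iv = extract_iv(rec, 2000.0)
        expected = boltzmann_iv(rec.voltages_mv, p.imax, p.io, p.v_half, p.kv)
        # ~1 ms of deactivation before the measurement window: within 1%
        np.testing.assert_allclose(iv["inst_cd_pa_pf"], expected, rtol=0.01)

    def test_peak_inward_at_minus_140(self):
        p = datasets.iv_params_for_genotype("WT")  # Imax < 0 at hyperpolarized end
        rec = simulate_iv_recording(p, noise_sd_pa_pf=0.0)
        iv = extract_iv(rec, 2000.0)
        assert iv["inst_cd_pa_pf"].idxmin() == iv["vm_mv"].idxmin()

    def test_noisy_extraction_within_3_se(self):
        p = datasets.iv_params_for_genotype("WT")
        rec = simulate_iv_recording(p, noise_sd_pa_pf=1.0, seed=4, sample_rate_hz=5000)
        iv = extract_iv(rec, 2000.0)
        truth = boltzmann_iv(rec.voltages_mv, p.imax, p.io, p.v_half, p.kv)
        # smoothed extremum over the window: SE bounded by per-sample SD
        assert np.all(np.abs(iv["inst_cd_pa_pf"] - truth) < 3.0)

    def test_window_outside_trace_rejected(self):
        rec = simulate_iv_recording(datasets.iv_params_for_genotype("WT"))
        with pytest.raises(ValueError):
            extract_iv(rec, 2000.0, inst_window_s=(0.001, 2.0))

    def test_steady_state_below_instantaneous_magnitude(self):
        p = datasets.iv_params_for_genotype("WT")
        rec = simulate_iv_recording(p, noise_sd_pa_pf=0.0)
        iv = extract_iv(rec, 2000.0)
        hyper = iv[iv["vm_mv"] < -90]  # deactivation at hyperpolarized steps
        assert np.all(np.abs(hyper["ss_cd_pa_pf"]) < np.abs(hyper["inst_cd_pa_pf"]))


class TestBoltzmannFits:
    def test_exact_point_recovery(self):
        v = np.arange(-140.0, 61.0, 10.0)
        y = boltzmann_iv(v, -50.0, 0.0, -80.0, 20.0)
        fit = fit_boltzmann_iv(v, y)
        assert fit.converged
        for got, want in [(fit.imax, -50.0), (fit.io, 0.0), (fit.v_half, -80.0), (fit.kv, 20.0)]:
            assert got == pytest.approx(want, rel=1e-6, abs=1e-6)

    def test_midpoint_is_half_sum(self):
        fit = BoltzmannIVParams(imax=-50.0, io=-10.0, v_half=-70.0, kv=12.0)
        assert fit.predict(-70.0) == pytest.approx((-50.0 + -10.0) / 2)

    def test_negative_kv_branch_recovered_canonically(self):
        p = datasets.iv_params_for_genotype("Mbnl1KO_dE7a")
        v = np.arange(-140.0, 61.0, 10.0)
        fit = fit_boltzmann_iv(v, boltzmann_iv(v, p.imax, p.io, p.v_half, p.kv))
        assert fit.kv == pytest.approx(p.kv, rel=1e-4)
        assert fit.imax == pytest.approx(p.imax, rel=1e-4)

    def test_monotone_prediction(self):
        v = np.arange(-140.0, 61.0, 10.0)
        fit = fit_boltzmann_iv(v, boltzmann_iv(v, -50.0, 5.0, -80.0, 20.0))
        pred = fit.predict(np.linspace(-140, 60, 500))
        assert np.all(np.diff(pred) >= -1e-12) or np.all(np.diff(pred) <= 1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann_iv([-140, -100, -60, -20], [-40, -30, -10, -1])

    def test_rel_po_noiseless_recovery_and_bounds(self):
        tails = simulate_tail_currents(0.1, -75.0, 18.0, -900.0, noise_sd_pa=0.0)
        fit = fit_rel_po(tails["vm_mv"], tails["tail_pa"])
        assert fit.converged
        assert fit.p_min == pytest.approx(0.1, abs=1e-6)
        assert fit.v_half == pytest.approx(-75.0, rel=1e-4)
        pred = fit.predict(np.linspace(-140, 60, 200))
        assert np.all(pred >= fit.p_min - 1e-9) and np.all(pred <= 1.0 + 1e-9)

    def test_rel_po_normalizes_to_max_tail(self):
        tails = simulate_tail_currents(0.2, -80.0, 20.0, -500.0, noise_sd_pa=0.0)
        fit = fit_rel_po(tails["vm_mv"], tails["tail_pa"])
        assert fit.imax_tail == pytest.approx(tails["tail_pa"].abs().max() * np.sign(tails["tail_pa"].iloc[0]))


class TestNernst:
    def test_equal_concentrations_zero(self):
        s = SolutionSpec(internal_mm={"KCl": 100.0}, external_mm={"KCl": 100.0})
        assert nernst_potential(s) == pytest.approx(0.0)

    def test_tenfold_gradient_at_295k(self):
        s = SolutionSpec(internal_mm={"KCl": 10.0}, external_mm={"KCl": 100.0},
                         temperature_k=295.0)
        # RT/F ln10 at 295 K ~ 58.5 mV; chloride (z=-1) makes it negative
        assert nernst_potential(s) == pytest.approx(-58.5, abs=0.2)

    def test_recording_solutions_near_minus_53(self):
        assert nernst_potential(datasets.RECORDING_SOLUTIONS) == pytest.approx(-53.0, abs=1.0)

    def test_chloride_tally_counts_stoichiometry(self):
        assert total_ion_concentration({"CsCl": 10.0, "MgCl2": 5.0, "Cs2-EGTA": 10.0}) == 20.0
        assert total_ion_concentration(
            {"TEA-Cl": 145.0, "CaCl2": 10.0, "CdCl2": 0.25, "HEPES": 10.0}
        ) == pytest.approx(165.5)

    def test_missing_ion_rejected(self):
        s = SolutionSpec(internal_mm={"K-gluconate": 100.0}, external_mm={"KCl": 100.0})
        with pytest.raises(ValueError):
            nernst_potential(s)


class TestNoisyRecovery:
    def test_v_half_and_kv_recovery_under_noise(self):
        """Median parameter error across seeded noisy step families."""
        p = datasets.iv_params_for_genotype("WT")
        noise = 0.05 * abs(p.imax)
        errs_v, errs_k = [], []
        for ss in np.random.SeedSequence(99).spawn(30):
            rng = np.random.default_rng(ss)
            rec = simulate_iv_recording(p, noise_sd_pa_pf=noise, seed=rng, sample_rate_hz=5000)
            c = capacitance_from_transient(rec.cap_time_s, rec.cap_current_pa, rec.cap_dv_mv)
            iv = extract_iv(rec, c)
            fit = fit_boltzmann_iv(iv["vm_mv"], iv["inst_cd_pa_pf"])
            errs_v.append(abs(fit.v_half - p.v_half))
            errs_k.append(abs(fit.kv - p.kv) / abs(p.kv))
        assert np.median(errs_v) < 2.0
        assert np.median(errs_k) < 0.10
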