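"""Synthetic-data generators: determinism, planted truth, statistical law."""

import numpy as np
import pandas as pd
import pytest

from myorescue.bedio import read_bed12, write_bed12
from myorescue.ephys import boltzmann_iv
from myorescue.simulate import (
    isoform_blocks,
    simulate_de_table,
    simulate_dpsi_table,
    simulate_emg,
    simulate_force_trace,
    simulate_iv_recording,
    simulate_long_reads,
    simulate_tail_currents,
)
from myorescue.splicemodel import default_model, steady_state_isoform_freqs
from myorescue import datasets


class TestLongReads:
    def test_forced_exclusion_yields_no_e7a_blocks(self, gene):
        m = default_model({"I2": 0.1, "E7a": 0.0, "I6": 0.1, "E8a": 0.05})
        _, truth = simulate_long_reads(m, gene, 1000, seed=0)
        assert not truth["E7a"].any()

    def test_empirical_inclusion_within_binomial_error(self, gene):
        m = default_model({"I2": 0, "E7a": 0.5, "I6": 0, "E8a": 0}, nmd_survival=1.0)
        n = 10_000
        _, truth = simulate_long_reads(m, gene, n, seed=11)
        frac = truth["E7a"].mean()
        sd = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * sd

    def test_canonical_reads_have_gene_exon_blocks(self, gene):
        m = default_model({e: 0.0 for e in ("I2", "E7a", "I6", "E8a")})
        reads, _ = simulate_long_reads(m, gene, 5, seed=0)
        for read in reads:
            assert read.blocks == gene.exons

    def test_retained_intron_merges_flanking_blocks(self, gene):
        blocks = isoform_blocks(gene, ("I2",))
        assert (500, 1100) in blocks  # exon2..exon3 merged across intron 2
        assert len(blocks) == len(gene.exons) - 1

    def test_cassette_exon_adds_block(self, gene):
        blocks = isoform_blocks(gene, ("E7a",))
        assert gene.event_interval("E7a") in blocks
        assert len(blocks) == len(gene.exons) + 1

    def test_unknown_event_is_configuration_error(self, gene):
        from myorescue.splicemodel import SpliceModel

        m = SpliceModel(events=("mystery",), inclusion_prob={"mystery": 0.5},
                        frame_disrupting={"mystery": True})
        with pytest.raises(ValueError):
            simulate_long_reads(m, gene, 10, seed=0)

    def test_deterministic_under_seed(self, gene, ko_model):
        r1, t1 = simulate_long_reads(ko_model, gene, 500, seed=7)
        r2, t2 = simulate_long_reads(ko_model, gene, 500, seed=7)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)

    def test_empirical_law_converges_to_steady_state(self, gene, ko_model):
        """Chi-square of simulated isoform counts vs the closed-form law."""
        from scipy.stats import chisquare

        n = 100_000
        _, truth = simulate_long_reads(ko_model, gene, n, seed=5)
        freqs = steady_state_isoform_freqs(ko_model)
        counts = truth["isoform"].value_counts()
        keys = [k for k, f in freqs.items() if f * n >= 5]
        obs = np.array([counts.get(k, 0) for k in keys], float)
        exp = np.array([freqs[k] * n for k in keys], float)
        # fold everything rarer into one cell so expectations stay >= 5
        obs = np.append(obs, n - obs.sum())
        exp = np.append(exp, n - exp.sum())
        stat, p = chisquare(obs, exp * (obs.sum() / exp.sum()))
        assert p > 1e-3

    def test_bed12_roundtrip(self, gene, ko_model, tmp_path):
        reads, _ = simulate_long_reads(ko_model, gene, 50, seed=3)
        path = tmp_path / "reads.bed"
        write_bed12(reads, path)
        assert read_bed12(path) == reads


class TestIVSimulation:
    def test_noiseless_instantaneous_matches_closed_form(self):
        p = datasets.iv_params_for_genotype("WT")
        rec = simulate_iv_recording(p, noise_sd_pa_pf=0.0, capacitance_pf=1500.0)
        cd0 = rec.currents_pa[:, 0] / 1500.0
        expected = boltzmann_iv(rec.voltages_mv, p.imax, p.io, p.v_half, p.kv)
        np.testing.assert_allclose(cd0, expected, rtol=1e-9)

    def test_midpoint_current_at_v_half(self):
        p = datasets.iv_params_for_genotype("WT")
        rec = simulate_iv_recording(p, voltages_mv=[p.v_half], noise_sd_pa_pf=0.0)
        assert rec.currents_pa[0, 0] / 2000.0 == pytest.approx((p.imax + p.io) / 2)

    def test_deterministic_under_seed(self):
        p = datasets.iv_params_for_genotype("Mbnl1KO")
        a = simulate_iv_recording(p, noise_sd_pa_pf=1.0, seed=9)
        b = simulate_iv_recording(p, noise_sd_pa_pf=1.0, seed=9)
        np.testing.assert_array_equal(a.currents_pa, b.currents_pa)
        np.testing.assert_array_equal(a.cap_current_pa, b.cap_current_pa)

    def test_tail_currents_follow_po_law(self):
        df = simulate_tail_currents(0.1, -80.0, 20.0, -800.0, noise_sd_pa=0.0)
        po = df["tail_pa"] / -800.0
        assert po.min() >= 0.1 - 1e-12
        assert po.max() <= 1.0 + 1e-12


class TestForceAndEmg:
    def test_no_myotonia_returns_promptly(self):
        tr = simulate_force_trace(myotonia_amp=0.0, relax_tau_s=0.02)
        post = tr.force_mn[tr.time_s > tr.stim_end_s + 0.2]
        assert np.all(np.abs(post) < 1e-4 * tr.force_mn.max())

    def test_peak_scaling_leaves_normalized_shape(self):
        a = simulate_force_trace(peak_mn=100.0, myotonia_amp=0.4)
        b = simulate_force_trace(peak_mn=200.0, myotonia_amp=0.4)
        np.testing.assert_allclose(a.force_mn / 100.0, b.force_mn / 200.0, atol=1e-12)

    def test_emg_deterministic_and_run_length(self):
        t1, truth = simulate_emg(run_duration_s=0.6, seed=2)
        t2, _ = simulate_emg(run_duration_s=0.6, seed=2)
        np.testing.assert_array_equal(t1.voltage_mv, t2.voltage_mv)
        assert truth["run_duration_s"] == 0.6
        # activity present between stimulus end and run end, absent later
        late = np.abs(t1.voltage_mv[t1.time_s > truth["stim_end_s"] + 0.8])
        mid = np.abs(t1.voltage_mv[(t1.time_s > truth["stim_end_s"]) & (t1.time_s < truth["stim_end_s"] + 0.5)])
        assert mid.max() > 10 * late.max()


class TestPlantedTables:
    def test_dpsi_counts_and_determinism(self):
        tab, truth = simulate_dpsi_table(40, 8, 6, 10, 12, seed=1)
        assert len(tab) == 40
        assert truth.value_counts().to_dict() == {
            "unchanged": 12, "mis_spliced_shared": 10, "complete_rescue": 8,
            "partial_rescue": 6, "novel_in_DKO": 4,
        }
        tab2, truth2 = simulate_dpsi_table(40, 8, 6, 10, 12, seed=1)
        pd.testing.assert_frame_equal(tab, tab2)

    def test_dpsi_rejects_overfull_classes(self):
        with pytest.raises(ValueError):
            simulate_dpsi_table(10, 8, 8, 0, 0, seed=0)

    def test_de_table_uniform_attenuation(self):
        tab, _ = simulate_de_table(500, 100, attenuation=0.5, seed=3)
        from myorescue.rescue import attenuation_summary

        s = attenuation_summary(tab)
        assert s["n_dysregulated"] == 100
        assert s["frac_closer"] == 1.0
        assert s["frac_half_attenuated"] == 1.0

    def test_de_table_planted_counts(self):
        tab, _ = simulate_de_table(3000, 1000, n_closer=800, n_half=300, seed=4)
        from myorescue.rescue import attenuation_summary

        s = attenuation_summary(tab)
        assert s["n_closer"] == 800
        assert s["n_half_attenuated"] == 300
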