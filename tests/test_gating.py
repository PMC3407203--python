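"""Simulator physics: equilibrium occupancies, detailed balance of the
drug-binding squares, calibration against the published drug-free
phenotypes, emergent use dependence, and reproducibility."""

import itertools
import math

import numpy as np
import pytest

import navblock as nb
from navblock.gating import (STATES, STATE_CLASS, available_fraction,
                             availability_curve, build_rate_matrix,
                             _steady_state_multi)
from navblock.stateblock import apparent_kd


class TestSteadyState:
    def test_no_ligand_means_no_bound_occupancy(self, wt_model, bpa_aff):
        labels, p = nb.steady_state(wt_model, bpa_aff, 0.0, -100.0)
        assert len(labels) == 10
        assert p[5:].sum() == 0.0
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_occupancies_normalized_over_random_conditions(self, wt_model,
                                                           bpa_aff):
        rng = np.random.default_rng(11)
        for _ in range(200):
            V = float(rng.uniform(-160, 40))
            D = float(rng.uniform(0, 300))
            _, p = nb.steady_state(wt_model, bpa_aff, D, V)
            assert np.all(p >= 0)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_langmuir_resting_occupancy(self, wt_model, bpa_aff):
        """Where inactivation is negligible, bound fraction is the Langmuir
        D/(D+Kr); at -120 mV the 0.3% inactivated occupancy (availability
        midpoint -90.4, slope 5.1) raises it to the exact partition value."""
        _, p = nb.steady_state(wt_model, bpa_aff, 30.0, -150.0)
        assert p[5:].sum() == pytest.approx(30.0 / (30.0 + 58.6), abs=1e-3)

        _, p = nb.steady_state(wt_model, bpa_aff, 30.0, -120.0)
        K_CI = math.exp((-120.0 + 90.4) / 5.1)
        Z = 1 + 30 / 58.6 + K_CI * (1 + 30 / 8.2)
        expect = (30 / 58.6 + K_CI * 30 / 8.2) / Z
        assert p[5:].sum() == pytest.approx(expect, abs=2e-3)

    def test_disconnected_rate_matrix_rejected(self):
        rp = {("C3", "C2"): nb.RateParam(1.0, 20.0, 1)}
        with pytest.raises(ValueError, match="not connected"):
            nb.GatingModel("broken", rp)


class TestDetailedBalance:
    def test_binding_squares_balance_exactly(self, wt_model, bpa_aff, mex_aff):
        """Product of rates clockwise equals counterclockwise around every
        gating-edge/binding 4-cycle, at arbitrary voltage and for both
        ligands simultaneously."""
        ligands = [(30.0, bpa_aff), (150.0, mex_aff)]
        for V in (-140.0, -90.0, -10.0, 30.0):
            Q = build_rate_matrix(wt_model, V, ligands)
            for k in range(len(ligands)):
                off = 5 * (k + 1)
                for (a, b) in wt_model.rate_params:
                    i, j = STATES.index(a), STATES.index(b)
                    cw = Q[i, j] * Q[j, off + j] * Q[off + j, off + i] * Q[off + i, i]
                    ccw = Q[i, off + i] * Q[off + i, off + j] * Q[off + j, j] * Q[j, i]
                    assert cw == pytest.approx(ccw, rel=1e-12)

    def test_koff_is_kon_times_class_kd(self, wt_model, bpa_aff):
        Q = build_rate_matrix(wt_model, -80.0, [(10.0, bpa_aff)])
        for i, s in enumerate(STATES):
            assert Q[i, 5 + i] == pytest.approx(bpa_aff.kon_per_uM_ms * 10.0)
            assert Q[5 + i, i] == pytest.approx(
                bpa_aff.kon_per_uM_ms * bpa_aff.kd_for_class(STATE_CLASS[s]))


class TestEquilibriumBlock:
    def test_block_matches_apparent_kd_over_random_draws(self, wt_model):
        """Equilibrium block at -120 mV equals D/(D+K_app(h)) for random
        (D, Kr, Ki), with h the drug-free inactivated fraction there."""
        rng = np.random.default_rng(5)
        _, p0 = nb.steady_state(wt_model, V_mV=-120.0)
        h = p0[STATES.index("I")]
        a0 = p0[:4].sum()
        for _ in range(50):
            Kr = float(rng.uniform(20, 600))
            Ki = float(rng.uniform(1, Kr))
            D = float(rng.uniform(5, 300))
            aff = nb.StateAffinities("BPA", Kr, Ki)
            aD = available_fraction(wt_model, [(D, aff)], -120.0)
            B = 1.0 - aD / a0
            assert B == pytest.approx(D / (D + apparent_kd(h, Kr, Ki)), abs=1e-3)

    def test_availability_monotone_non_increasing(self, wt_model):
        V = np.arange(-160.0, 1.0, 5.0)
        a = availability_curve(wt_model, V)
        assert np.all(np.diff(a) <= 1e-9)


class TestCalibration:
    def test_wt_availability_matches_published_values(self, ssfi_fit_wt):
        assert ssfi_fit_wt.Vhalf_mV == pytest.approx(-90.4, abs=1.0)
        assert ssfi_fit_wt.k_mV == pytest.approx(5.1, abs=0.5)

    def test_mutant_availability_shifted_depolarized(self, mut_model,
                                                     cfg_nonoise, ssfi_fit_wt):
        prot = nb.make_protocol("ssfi")
        s = nb.simulate_sweepset(mut_model, prot, cfg=cfg_nonoise,
                                 genotype="F1760A")
        av = nb.availability_from_ssfi(s)
        f = nb.fit_boltzmann(av["V_mV"], av["availability"],
                             kind="inactivation")
        assert f.Vhalf_mV == pytest.approx(-79.9, abs=1.0)
        assert f.k_mV == pytest.approx(5.8, abs=0.5)
        assert f.Vhalf_mV - ssfi_fit_wt.Vhalf_mV == pytest.approx(10.5, abs=1.0)

    def test_activation_midpoint(self, iv_free_wt, wt_model):
        pk = nb.peak_currents(iv_free_wt, 1)
        g = nb.conductance_curve(pk, wt_model.Erev_mV)
        f = nb.fit_boltzmann(g["V_mV"], g["G_norm"], kind="activation")
        assert f.Vhalf_mV == pytest.approx(-32.0, abs=2.0)

    def test_decay_tau_at_minus10(self, wt_model, cfg_nonoise):
        prot = nb.VoltageProtocol("decay", -120.0,
                                  ((-120.0, 2.0), (-10.0, 45.0)), (),
                                  1.0, 1, 20.0)
        s = nb.simulate_sweepset(wt_model, prot, cfg=cfg_nonoise)
        f = nb.fit_decay_from_peak(s, 0, 1, window_ms=40.0)
        assert f.tau_ms == pytest.approx(1.1, abs=0.1)

    def test_protocol_availability_consistent_with_equilibrium_oracle(
            self, wt_model, ssfi_fit_wt):
        """The 500 ms prepulse protocol recovers the same midpoint as the
        steady-state occupancy oracle (full equilibration)."""
        V = np.asarray(nb.make_protocol("ssfi").sweep_values_mV)
        eq = availability_curve(wt_model, V)
        f_eq = nb.fit_boltzmann(V, eq, kind="inactivation")
        assert ssfi_fit_wt.Vhalf_mV == pytest.approx(f_eq.Vhalf_mV, abs=0.2)


class TestSimulation:
    def test_peak_current_is_inward_below_reversal(self, iv_free_wt):
        pk = nb.peak_currents(iv_free_wt, 1)
        at_m10 = pk.loc[pk.level_mV == -10.0, "peak_nA"].iloc[0]
        assert at_m10 < -1.0

    def test_seeded_runs_bit_reproducible(self, wt_model, bpa_aff):
        prot = nb.make_protocol("use_train", freq_Hz=30)
        cfg = nb.SimConfig(seed=99)
        cond = nb.DrugCondition("BPA", 30.0)
        a = nb.simulate_sweepset(wt_model, prot, cond, bpa_aff, cfg)
        b = nb.simulate_sweepset(wt_model, prot, cond, bpa_aff, cfg)
        assert np.array_equal(a.sweeps, b.sweeps)

    def test_occupancy_conservation_during_playback(self, wt_model, bpa_aff):
        """Propagators are stochastic matrices: occupancy stays normalized at
        every output step of a drugged sweep."""
        from scipy.linalg import expm
        prot = nb.make_protocol("ssfi", sampling_rate_kHz=2.0)
        dt = 0.5
        for V in (-120.0, -60.0, -10.0):
            Q = build_rate_matrix(wt_model, V, [(30.0, bpa_aff)])
            M = expm(Q * dt)
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert M.min() >= -1e-14

    def test_dt_resolution_guard(self):
        with pytest.raises(ValueError, match="dt_ms too coarse"):
            nb.SimConfig(dt_ms=2.0)

    def test_tonic_block_half_at_kd(self, wt_model, bpa_aff):
        """At D = Kr a 0.2 Hz train blocks half the resting current."""
        prot = nb.make_protocol("tonic_train", sampling_rate_kHz=5.0)
        cfg = nb.SimConfig(noise_sd_nA=0.0, dt_ms=0.2)
        s = nb.simulate_sweepset(wt_model, prot, nb.DrugCondition("BPA", 58.6),
                                 bpa_aff, cfg)
        assert nb.tonic_block_ratio(s).B == pytest.approx(0.5, abs=0.02)


class TestUseDependence:
    def test_drug_free_1hz_stays_available(self, pulse30):
        assert pulse30[(1, "free")] == pytest.approx(1.0, abs=0.05)

    def test_state_dependent_block_monotone_in_frequency(self, pulse30):
        drugged = [pulse30[(f, "drug")] for f in (1, 10, 30, 50)]
        assert all(a > b for a, b in zip(drugged, drugged[1:]))

    def test_state_independent_binding_adds_no_use_dependence(self, pulse30):
        for f in (1, 10, 30, 50):
            assert abs(pulse30[(f, "flat")] - pulse30[(f, "free")]) < 0.01


class TestManifest:
    def test_manifest_lists_generating_truth(self, wt_model, bpa_aff):
        prot = nb.make_protocol("tonic_train")
        cfg = nb.SimConfig(seed=5)
        m = nb.ground_truth_manifest(wt_model, (nb.DrugCondition("BPA", 30.0),),
                                     (bpa_aff,), cfg, prot,
                                     drug_onset_sweep=10)
        assert m["affinities"][0]["Kr_uM"] == 58.6
        assert m["affinities"][0]["Ki_uM"] == 8.2
        assert m["sim"]["seed"] == 5
        assert m["model"]["phenotype"]["inact_vhalf_mV"] == pytest.approx(-90.26)
        import json
        json.dumps(m)  # JSON-serializable
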