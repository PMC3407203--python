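"""Trace measurements: peak extraction, conductance transform, reversal
potential, tonic-block ratio, use-dependence normalization, inactivated
fraction."""

import numpy as np
import pandas as pd
import pytest

import navblock as nb


def make_sweepset(sweeps, dt_ms=0.1, level=-10.0, genotype="WT",
                  condition=nb.DRUG_FREE, onset=None, holding=-120.0,
                  interval_s=5.0):
    """Wrap a raw current matrix in a single-epoch SweepSet."""
    sweeps = np.atleast_2d(np.asarray(sweeps, dtype=float))
    n, m = sweeps.shape
    prot = nb.VoltageProtocol("synthetic", holding,
                              ((level, m * dt_ms),), (), interval_s, n,
                              1.0 / dt_ms)
    return nb.SweepSet(prot, "synth", genotype, condition, sweeps,
                       np.arange(m) * dt_ms, onset)


class TestPeakCurrents:
    def test_zero_sweep_peaks_at_window_start(self):
        s = make_sweepset(np.zeros((1, 100)))
        pk = nb.peak_currents(s, 0)
        assert pk.peak_nA.iloc[0] == 0.0
        assert pk.t_peak_ms.iloc[0] == pytest.approx(0.3, abs=0.11)

    def test_known_waveform_peak_within_one_sample(self, wt_model,
                                                   cfg_nonoise):
        """Peak of a simulated sweep matches gmax*P_O,max*(V-Erev) from the
        generating occupancy within one sample."""
        from scipy.linalg import expm
        from navblock.gating import build_rate_matrix, OPEN_INDEX, \
            _steady_state_multi
        prot = nb.VoltageProtocol("step", -120.0,
                                  ((-120.0, 2.0), (-10.0, 20.0)), (),
                                  1.0, 1, 20.0)
        s = nb.simulate_sweepset(wt_model, prot, cfg=cfg_nonoise)
        # independent occupancy playback at the same step size
        p = _steady_state_multi(wt_model, [], -120.0)
        po = []
        for V, dur in ((-120.0, 2.0), (-10.0, 20.0)):
            M = expm(build_rate_matrix(wt_model, V) * 0.05)
            for _ in range(int(dur / 0.05)):
                po.append(p[OPEN_INDEX] if V == -10.0 else 0.0)
                p = p @ M
        expected = wt_model.gmax_nS * max(po) * (-10.0 - wt_model.Erev_mV) / 1000.0
        pk = nb.peak_currents(s, 1)
        assert pk.peak_nA.iloc[0] == pytest.approx(expected, rel=1e-6)

    def test_noise_only_peak_bounded_by_gaussian_extremes(self):
        """|peak| of a pure-noise sweep rarely exceeds 5 sd."""
        sd = 0.02
        fails = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            s = make_sweepset(rng.normal(0, sd, (1, 2000)))
            if abs(nb.peak_currents(s, 0).peak_nA.iloc[0]) > 5 * sd:
                fails += 1
        assert fails <= 4  # P(exceed) ~ 0.1% per sweep; allow slack

    def test_epoch_shorter_than_blanking_window(self):
        s = make_sweepset(np.zeros((1, 2)))
        with pytest.raises(ValueError, match="blanking"):
            nb.peak_currents(s, 0, blank_ms=0.3)


class TestConductance:
    def test_chord_conductance_arithmetic(self):
        pk = pd.DataFrame({"sweep_index": [1], "level_mV": [-10.0],
                           "peak_nA": [-1.0], "t_peak_ms": [1.0]})
        g = nb.conductance_curve(pk, 70.0)
        assert g.G_uS.iloc[0] == pytest.approx(0.0125)

    def test_level_at_reversal_rejected(self):
        pk = pd.DataFrame({"sweep_index": [1, 2], "level_mV": [69.5, -10.0],
                           "peak_nA": [0.01, -1.0], "t_peak_ms": [1.0, 1.0]})
        with pytest.raises(ValueError, match="reversal"):
            nb.conductance_curve(pk, 70.0)

    def test_pipeline_recovers_generating_activation_midpoint(
            self, iv_free_wt, wt_model):
        """conductance_curve ∘ peak_currents on noise-free I–V data recovers
        the manifest activation midpoint within 1 mV."""
        pk = nb.peak_currents(iv_free_wt, 1)
        g = nb.conductance_curve(pk, wt_model.Erev_mV)
        f = nb.fit_boltzmann(g["V_mV"], g["G_norm"], kind="activation")
        assert f.Vhalf_mV == pytest.approx(
            wt_model.phenotype["act_vhalf_mV"], abs=1.0)


class TestEstimateErev:
    def test_midpoint_interpolation(self):
        pk = pd.DataFrame({"sweep_index": [1, 2], "level_mV": [60.0, 80.0],
                           "peak_nA": [-0.5, 0.5], "t_peak_ms": [1, 1]})
        assert nb.estimate_erev(pk) == pytest.approx(70.0)

    def test_simulator_reversal_recovered(self, wt_model, cfg_nonoise):
        """With a protocol extended past the reversal potential, the zero
        crossing lands within 2 mV of the model's Erev."""
        values = tuple(float(v) for v in range(-40, 101, 10))
        prot = nb.make_protocol("iv_activation", sweep_values_mV=values)
        s = nb.simulate_sweepset(wt_model, prot, cfg=cfg_nonoise)
        pk = nb.peak_currents(s, 1)
        assert nb.estimate_erev(pk) == pytest.approx(wt_model.Erev_mV, abs=2.0)

    def test_monotone_all_negative_errors(self):
        pk = pd.DataFrame({"sweep_index": [1, 2, 3],
                           "level_mV": [-30.0, -20.0, -10.0],
                           "peak_nA": [-1.0, -2.0, -3.0],
                           "t_peak_ms": [1, 1, 1]})
        with pytest.raises(ValueError, match="sign"):
            nb.estimate_erev(pk)


class TestTonicBlock:
    def _train(self, peaks, onset=10):
        dt = 0.1
        n = len(peaks)
        sweeps = np.zeros((n, 100))
        for i, p in enumerate(peaks):
            sweeps[i, 50] = p
        return make_sweepset(sweeps, dt_ms=dt, onset=onset, interval_s=5.0)

    def test_identical_pre_post_gives_zero(self):
        s = self._train([-2.0] * 25)
        assert nb.tonic_block_ratio(s).B == 0.0

    def test_half_post_gives_half_block(self):
        s = self._train([-2.0] * 10 + [-1.0] * 15)
        bm = nb.tonic_block_ratio(s)
        assert bm.B == pytest.approx(0.5)
        assert not bm.clipped

    def test_pulse15_variant(self):
        peaks = [-2.0] * 10 + [-1.5] * 14 + [-1.0]
        s = self._train(peaks)
        assert nb.tonic_block_ratio(s, method="pulse15").B == pytest.approx(0.5)

    def test_noise_overshoot_clipped_and_flagged(self):
        s = self._train([-2.0] * 10 + [-2.01] * 15)
        bm = nb.tonic_block_ratio(s)
        assert bm.B == 0.0
        assert bm.clipped

    def test_missing_onset_or_short_train_rejected(self):
        s = self._train([-2.0] * 25, onset=None)
        with pytest.raises(ValueError, match="drug_onset"):
            nb.tonic_block_ratio(s)
        s = self._train([-2.0] * 20)
        with pytest.raises(ValueError, match="sweeps"):
            nb.tonic_block_ratio(s)

    def test_simulated_bpa_block_near_langmuir(self, wt_model, bpa_aff):
        prot = nb.make_protocol("tonic_train", sampling_rate_kHz=5.0)
        cfg = nb.SimConfig(noise_sd_nA=0.0, dt_ms=0.2)
        s = nb.simulate_sweepset(wt_model, prot, nb.DrugCondition("BPA", 30.0),
                                 bpa_aff, cfg)
        assert nb.tonic_block_ratio(s).B == pytest.approx(
            30.0 / (30.0 + 58.6), abs=0.02)

    def test_drug_free_trains_show_no_block_across_seeds(self, wt_model):
        """|B| < 0.02 on drug-free trains at default recording noise."""
        prot = nb.make_protocol("tonic_train", sampling_rate_kHz=5.0)
        for seed in range(50):
            cfg = nb.SimConfig(dt_ms=0.2, seed=seed)
            s = nb.simulate_sweepset(wt_model, prot, cfg=cfg)
            # drug-free trains carry no onset; measure with a synthetic one
            s.drug_onset_sweep = 10
            bm = nb.tonic_block_ratio(s)
            assert bm.B < 0.02


class TestUseDependenceCurve:
    def test_constant_amplitude_normalizes_to_one(self):
        sweeps = np.zeros((30, 100))
        sweeps[:, 40] = -3.0
        s = make_sweepset(sweeps, interval_s=0.1)
        c = nb.use_dependence_curve(s)
        assert np.allclose(c.normalized, 1.0)
        assert c.pulse_index.iloc[0] == 1

    def test_zero_first_pulse_rejected(self):
        s = make_sweepset(np.zeros((5, 100)), interval_s=0.1)
        with pytest.raises(ValueError, match="first-pulse"):
            nb.use_dependence_curve(s)


class TestInactivatedFraction:
    def test_half_at_midpoint(self):
        f = nb.BoltzmannFit(-90.0, 5.0, 1.0, 0.1, 0.1, 0.0,
                            "inactivation", 17)
        assert nb.inactivated_fraction(f, -90.0) == pytest.approx(0.5)

    def test_published_example_value(self):
        """h at -90 mV from the availability fit (-89.3, 5.6) is 0.4688."""
        f = nb.BoltzmannFit(-89.3, 5.6, 1.0, 0.1, 0.1, 0.0,
                            "inactivation", 17)
        assert nb.inactivated_fraction(f, -90.0) == pytest.approx(0.4688,
                                                                  abs=1e-4)

    def test_limits_and_kind_guard(self):
        f = nb.BoltzmannFit(-90.0, 5.0, 1.0, 0.1, 0.1, 0.0,
                            "inactivation", 17)
        assert nb.inactivated_fraction(f, -1000.0) == pytest.approx(0.0)
        g = nb.BoltzmannFit(-32.0, 6.0, 1.0, 0.1, 0.1, 0.0,
                            "activation", 15)
        with pytest.raises(ValueError, match="inactivation"):
            nb.inactivated_fraction(g, -90.0)
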