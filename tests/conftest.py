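"""Shared fixtures: calibrated models, reference affinities, and a few
session-scoped noise-free simulations that several test modules reuse."""

import numpy as np
import pytest

import navblock as nb
from navblock.gating import calibrate_default_models


@pytest.fixture(scope="session")
def models():
    return calibrate_default_models()


@pytest.fixture(scope="session")
def wt_model(models):
    return models[0]


@pytest.fixture(scope="session")
def mut_model(models):
    return models[1]


@pytest.fixture(scope="session")
def bpa_aff():
    return nb.StateAffinities("BPA", Kr_uM=58.6, Ki_uM=8.2)


@pytest.fixture(scope="session")
def mex_aff():
    return nb.StateAffinities("mexiletine", Kr_uM=606.2, Ki_uM=6.6)


@pytest.fixture(scope="session")
def cfg_nonoise():
    return nb.SimConfig(noise_sd_nA=0.0)


@pytest.fixture(scope="session")
def ssfi_free_wt(wt_model, cfg_nonoise):
    """Noise-free steady-state fast-inactivation run of the calibrated WT."""
    prot = nb.make_protocol("ssfi")
    return nb.simulate_sweepset(wt_model, prot, cfg=cfg_nonoise)


@pytest.fixture(scope="session")
def ssfi_fit_wt(ssfi_free_wt):
    av = nb.availability_from_ssfi(ssfi_free_wt)
    return nb.fit_boltzmann(av["V_mV"], av["availability"], kind="inactivation")


@pytest.fixture(scope="session")
def iv_free_wt(wt_model, cfg_nonoise):
    prot = nb.make_protocol("iv_activation")
    return nb.simulate_sweepset(wt_model, prot, cfg=cfg_nonoise)


@pytest.fixture(scope="session")
def pulse30(wt_model, bpa_aff, cfg_nonoise):
    """30th-pulse normalized current per train frequency for drug-free,
    state-dependent (Ki < Kr) and state-independent (Ki = Kr = Ko) binding."""
    out = {}
    for f in (1, 10, 30, 50):
        prot = nb.make_protocol("use_train", freq_Hz=f)
        for tag, cond, aff in (
                ("free", nb.DRUG_FREE, None),
                ("drug", nb.DrugCondition("BPA", 30.0), bpa_aff),
                ("flat", nb.DrugCondition("BPA", 30.0),
                 nb.StateAffinities("BPA", 58.6, 58.6, 58.6))):
            s = nb.simulate_sweepset(wt_model, prot, cond, aff, cfg_nonoise)
            out[(f, tag)] = float(
                nb.use_dependence_curve(s)["normalized"].iloc[-1])
    return out


def rand_sweepset(rng: np.random.Generator) -> nb.SweepSet:
    """A small randomized SweepSet for round-trip tests."""
    n_sweeps = int(rng.integers(1, 5))
    use_var = rng.random() < 0.5
    epochs = [(-120.0, float(rng.integers(2, 6)))]
    if use_var:
        epochs.append((nb.VAR, float(rng.integers(5, 15))))
        values = tuple(float(v) for v in rng.uniform(-160, 40, n_sweeps))
    else:
        epochs.append((float(rng.uniform(-60, 20)), float(rng.integers(5, 15))))
        values = ()
    prot = nb.VoltageProtocol(
        name=f"rand{rng.integers(1e6)}", holding_mV=-120.0,
        epochs=tuple(epochs), sweep_values_mV=values,
        inter_sweep_interval_s=5.0, n_sweeps=n_sweeps,
        sampling_rate_kHz=float(rng.choice([1.0, 2.0, 5.0])))
    sweeps = rng.normal(0, 1.0, (n_sweeps, prot.n_samples))
    tb = np.arange(prot.n_samples) * prot.dt_ms
    cond = nb.DrugCondition("BPA", float(rng.uniform(0, 100)))
    onset = int(rng.integers(1, n_sweeps + 1)) if rng.random() < 0.3 else None
    return nb.SweepSet(prot, f"cell{rng.integers(100)}", "WT", cond,
                       sweeps, tb, onset)
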