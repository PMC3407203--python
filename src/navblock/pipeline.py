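"""End-to-end demo pipeline: simulate a panel of synthetic recordings, then
run the full analysis (peaks → conductance/availability → fits → Kr/Ki →
shift predictions → shared-vs-separate verdict → statistics) and build a
report.  The command-line interface in :mod:`navblock.cli` is a thin wrapper
over these functions.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from glob import glob

import numpy as np

from . import stats as nbstats
from .fits import fit_boltzmann, fit_hill
from .gating import (GatingModel, SimConfig, StateAffinities,
                     calibrate_default_models, default_affinities,
                     ground_truth_manifest, simulate_sweepset)
from .protocols import (DRUG_FREE, DrugCondition, SweepSet, make_protocol,
                        read_sweepset, write_sweepset)
from .stateblock import (classify_overlap, ki_from_inactivated_block,
                         kr_from_resting_block, predict_shift_combo,
                         predict_shift_single)
from .traces import (availability_from_ssfi, conductance_curve, estimate_erev,
                     fit_decay_from_peak, inactivated_fraction, peak_currents,
                     tonic_block_ratio, use_dependence_curve)

__all__ = ["PipelineConfig", "default_panel", "run_simulation_panel",
           "analyze_directory"]

#: Holding potential used for inactivated-state (Ki) block measurements:
#: chosen so that 30–50% of channels are inactivated (h ≈ 0.5 at the
#: availability midpoint of the wild-type channel).
KI_HOLDING_MV = -90.0

#: Tonic dose panels per compound (µM), spanning the published Kd values.
TONIC_DOSES = {"BPA": (10.0, 30.0, 100.0, 300.0),
               "mexiletine": (100.0, 300.0, 1000.0, 3000.0)}

USE_FREQS = (1.0, 10.0, 30.0, 50.0)


@dataclass(frozen=True)
class PipelineConfig:
    """Flat configuration for the demo pipeline.

    ``n_cells`` replicate synthetic cells (distinct noise seeds) are produced
    per tonic-train condition so the comparison statistics have within-group
    replication.  ``panel`` selects the scope: ``"full"`` (everything the
    analysis consumes), ``"verdict"`` (the subset needed for the binding-site
    verdict) or ``"smoke"`` (a minimal pair of sweep sets).
    """

    seed: int = 0
    output_dir: str = "navblock-out"
    panel: str = "full"
    n_cells: int = 3
    noise_sd_nA: float = 0.02
    sampling_rate_kHz: float = 5.0
    fix_nH: float | None = None
    vehicle_correction: bool = False

    def __post_init__(self) -> None:
        if self.panel not in ("full", "verdict", "smoke"):
            raise ValueError(f"unknown panel {self.panel!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------------------
# Simulation panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimJob:
    name: str
    genotype: str
    protocol_family: str
    protocol_kwargs: dict = field(default_factory=dict)
    conditions: tuple[DrugCondition, ...] = (DRUG_FREE,)
    cell: int = 0


def default_panel(cfg: PipelineConfig) -> list[SimJob]:
    """The simulation jobs the analysis stage consumes."""
    bpa30 = DrugCondition("BPA", 30.0)
    mex150 = DrugCondition("mexiletine", 150.0)
    jobs: list[SimJob] = []

    def add(name, genotype, family, conditions=(DRUG_FREE,), cell=0, **kw):
        jobs.append(SimJob(name=name, genotype=genotype, protocol_family=family,
                           protocol_kwargs=kw, conditions=tuple(conditions),
                           cell=cell))

    if cfg.panel == "smoke":
        add("wt_ssfi_free", "WT", "ssfi")
        add("wt_tonic_bpa30", "WT", "tonic_train", (bpa30,))
        return jobs

    # drug-free characterization + the co-application verdict inputs
    add("wt_iv_free", "WT", "iv_activation")
    add("wt_ssfi_free", "WT", "ssfi")
    add("f1760a_ssfi_free", "F1760A", "ssfi")
    add("wt_ssfi_bpa30", "WT", "ssfi", (bpa30,))
    add("wt_ssfi_mex150", "WT", "ssfi", (mex150,))
    add("wt_ssfi_combo", "WT", "ssfi", (bpa30, mex150))
    # resting (Kr) and inactivated-state (Ki) block, replicated cells
    for cell in range(cfg.n_cells):
        for comp, cond in (("BPA", bpa30), ("mexiletine", mex150)):
            add(f"wt_tonic_{comp}_kr_c{cell}", "WT", "tonic_train",
                (cond,), cell=cell)
            add(f"wt_tonic_{comp}_ki_c{cell}", "WT", "tonic_train",
                (cond,), cell=cell, holding_mV=KI_HOLDING_MV)
    if cfg.panel == "verdict":
        return jobs
    # dose-response panels (Hill Kd) at -120 mV, WT and F1760A
    for genotype in ("WT", "F1760A"):
        for comp, doses in TONIC_DOSES.items():
            for cell in range(cfg.n_cells):
                for d in doses:
                    add(f"{genotype.lower()}_tonic_{comp}_{d:g}uM_c{cell}",
                        genotype, "tonic_train",
                        (DrugCondition(comp, d),), cell=cell)
    # use-dependence trains
    for f in USE_FREQS:
        add(f"wt_use{f:g}_free", "WT", "use_train", freq_Hz=f)
        add(f"wt_use{f:g}_bpa30", "WT", "use_train", (bpa30,), freq_Hz=f)
    return jobs


def run_simulation_panel(cfg: PipelineConfig,
                         out_dir: str | None = None) -> list[str]:
    """Simulate every panel job, writing sweep tables, sidecars and
    ground-truth manifests.  Deterministic for a given seed.  Returns the
    written table paths."""
    out_dir = out_dir or cfg.output_dir
    os.makedirs(out_dir, exist_ok=True)
    wt, mut = calibrate_default_models()
    models = {"WT": wt, "F1760A": mut}
    jobs = default_panel(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(jobs))]
    paths = []
    for job, seed in zip(jobs, child_seeds):
        model = models[job.genotype]
        kw = dict(job.protocol_kwargs)
        kw.setdefault("sampling_rate_kHz", cfg.sampling_rate_kHz)
        protocol = make_protocol(job.protocol_family, **kw)
        affs = tuple(default_affinities(c.compound, job.genotype)
                     for c in job.conditions if c.blocks)
        sim_cfg = SimConfig(noise_sd_nA=cfg.noise_sd_nA, seed=seed,
                            dt_ms=1.0 / protocol.sampling_rate_kHz)
        s = simulate_sweepset(model, protocol, job.conditions, affs, sim_cfg,
                              genotype=job.genotype,
                              cell_id=f"{job.name}")
        base = os.path.join(out_dir, job.name)
        paths.append(write_sweepset(s, base))
        manifest = ground_truth_manifest(
            model, job.conditions, affs, sim_cfg, protocol,
            genotype=job.genotype, drug_onset_sweep=s.drug_onset_sweep)
        with open(base + ".manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------

def _condition_key(s: SweepSet) -> str:
    parts = [f"{c.compound}{c.concentration_uM:g}" for c in s.conditions
             if c.compound != "none"]
    return "+".join(parts) if parts else "free"


def _load_dir(input_dir: str) -> list[SweepSet]:
    sidecars = sorted(glob(os.path.join(input_dir, "*.json")))
    sweepsets = []
    for sc in sidecars:
        if sc.endswith(".manifest.json"):
            continue
        sweepsets.append(read_sweepset(sc[:-5]))
    if not sweepsets:
        raise FileNotFoundError(f"no sweep sets found in {input_dir}")
    return sweepsets


def analyze_directory(input_dir: str, cfg: PipelineConfig | None = None,
                      seed: int | None = None) -> dict:
    """Run the full analysis over a directory of sweep sets and return a
    report document.

    Stages: activation I–V (reversal potential + activation Boltzmann),
    availability fits per condition and genotype with drug-induced shifts,
    tonic block per dose with Hill fits, Kr from resting block and Ki from
    block at a partially inactivated holding potential, shift predictions for
    the co-applied pair under separate-site and shared-site models, the
    binding-site verdict, use-dependence summaries, and comparison
    statistics.
    """
    cfg = cfg or PipelineConfig()
    sweepsets = _load_dir(input_dir)
    results: dict = {}

    by_kind: dict[tuple[str, str, str, float], list[SweepSet]] = {}
    for s in sweepsets:
        fam = s.protocol.name.split("_")[0] if s.protocol.name.startswith("use") \
            else s.protocol.name
        key = (fam, s.genotype, _condition_key(s), s.protocol.holding_mV)
        by_kind.setdefault(key, []).append(s)

    def grab(fam, genotype="WT", cond="free", holding=-120.0):
        return by_kind.get((fam, genotype, cond, holding), [])

    # ---- activation ------------------------------------------------------
    iv = grab("iv_activation")
    if iv:
        pk = peak_currents(iv[0], 1)
        erev = estimate_erev(pk, method="auto")
        g = conductance_curve(pk, erev)
        act = fit_boltzmann(g["V_mV"], g["G_norm"], kind="activation")
        tau = fit_decay_from_peak(iv[0], sweep_index=int(
            np.argmin(np.abs(np.asarray(iv[0].protocol.sweep_values_mV) + 10.0))),
            epoch_index=1)
        results["activation"] = {"Erev_mV": erev, "boltzmann": act.to_dict(),
                                 "decay_at_-10mV": tau.to_dict()}

    # ---- availability (steady-state fast inactivation) -------------------
    ssfi_fits: dict[tuple[str, str], object] = {}
    avail_out = {}
    for (fam, genotype, cond, hold), sets in sorted(by_kind.items()):
        if fam != "ssfi":
            continue
        av = availability_from_ssfi(sets[0])
        f = fit_boltzmann(av["V_mV"], av["availability"], kind="inactivation")
        ssfi_fits[(genotype, cond)] = f
        avail_out[f"{genotype}:{cond}"] = f.to_dict()
    if avail_out:
        results["availability"] = avail_out
    pre = ssfi_fits.get(("WT", "free"))

    shifts = {}
    if pre is not None:
        for (genotype, cond), f in ssfi_fits.items():
            if genotype != "WT" or cond == "free":
                continue
            d = f.Vhalf_mV - pre.Vhalf_mV
            se = float(np.hypot(f.se_Vhalf, pre.se_Vhalf))
            shifts[cond] = {"delta_Vhalf_mV": d, "se_mV": se}
        if shifts:
            results["ssfi_shifts"] = shifts
    mut_free = ssfi_fits.get(("F1760A", "free"))
    if pre is not None and mut_free is not None:
        results["genotype_shift"] = {
            "delta_Vhalf_mV": mut_free.Vhalf_mV - pre.Vhalf_mV}

    # ---- tonic block and Hill fits ---------------------------------------
    tonic: dict[tuple[str, str, float, float], list[float]] = {}
    for s in sweepsets:
        if s.protocol.name != "tonic_train" or s.drug_onset_sweep is None:
            continue
        c = s.conditions[0]
        bm = tonic_block_ratio(s)
        key = (s.genotype, c.compound, c.concentration_uM, s.protocol.holding_mV)
        tonic.setdefault(key, []).append(bm.B)
    if tonic:
        results["tonic_block"] = {
            f"{g}:{comp}:{d:g}uM@{h:g}mV": dict(
                zip(("mean", "sem"), nbstats.mean_sem(bs)))
            for (g, comp, d, h), bs in sorted(tonic.items())}

    hill_out = {}
    for genotype in ("WT", "F1760A"):
        for comp in ("BPA", "mexiletine"):
            pts = sorted((d, float(np.mean(bs)))
                         for (g, c, d, h), bs in tonic.items()
                         if g == genotype and c == comp and h == -120.0)
            if len(pts) >= 4:
                try:
                    hf = fit_hill(np.array(pts), fix_nH=cfg.fix_nH)
                    hill_out[f"{genotype}:{comp}@-120mV"] = hf.to_dict()
                except (ValueError, RuntimeError) as exc:
                    hill_out[f"{genotype}:{comp}@-120mV"] = {"error": str(exc)}
    if hill_out:
        results["hill_fits"] = hill_out

    # ---- Kr / Ki ---------------------------------------------------------
    constants = {}
    for comp, ref_d in (("BPA", 30.0), ("mexiletine", 150.0)):
        kr_b = [np.mean(bs) for (g, c, d, h), bs in tonic.items()
                if g == "WT" and c == comp and h == -120.0 and d == ref_d]
        ki_b = [np.mean(bs) for (g, c, d, h), bs in tonic.items()
                if g == "WT" and c == comp and h == KI_HOLDING_MV and d == ref_d]
        if not (kr_b and ki_b and pre is not None):
            continue
        Kr = kr_from_resting_block(ref_d, float(kr_b[0]))
        h = inactivated_fraction(pre, KI_HOLDING_MV)
        try:
            Ki = ki_from_inactivated_block(ref_d, float(ki_b[0]), h, Kr)
        except ValueError as exc:
            constants[comp] = {"Kr_uM": Kr, "h": h, "error": str(exc)}
            continue
        constants[comp] = {"D_uM": ref_d, "Kr_uM": Kr, "Ki_uM": Ki, "h": h}
    if constants:
        results["state_affinities"] = constants

    # ---- shift predictions and the binding-site verdict ------------------
    if (pre is not None and "BPA" in constants and "mexiletine" in constants
            and "Ki_uM" in constants["BPA"] and "Ki_uM" in constants["mexiletine"]
            and "BPA30+mexiletine150" in shifts):
        k = pre.k_mV
        b, m = constants["BPA"], constants["mexiletine"]
        d1 = (b["D_uM"], b["Kr_uM"], b["Ki_uM"])
        d2 = (m["D_uM"], m["Kr_uM"], m["Ki_uM"])
        obs = shifts["BPA30+mexiletine150"]
        obs_shift = obs["delta_Vhalf_mV"]
        if cfg.vehicle_correction and "ETOH" in shifts:
            obs_shift -= shifts["ETOH"]["delta_Vhalf_mV"]
        p1 = predict_shift_single(*d1, k)
        p2 = predict_shift_single(*d2, k)
        sep = predict_shift_combo(d1, d2, k, "separate")
        sha = predict_shift_combo(d1, d2, k, "shared")
        verdict = classify_overlap(obs_shift, obs["se_mV"], sep, sha)
        results["binding_site"] = {
            "k_mV": k,
            "single_drug_predictions": {
                "BPA": p1.delta_Vhalf_mV, "mexiletine": p2.delta_Vhalf_mV},
            "combo_predictions": {"separate": sep.delta_Vhalf_mV,
                                  "shared": sha.delta_Vhalf_mV},
            "verdict": verdict.to_dict(),
        }

    # ---- use dependence --------------------------------------------------
    ud_out = {}
    for s in sweepsets:
        if not s.protocol.name.startswith("use_train"):
            continue
        curve = use_dependence_curve(s)
        freq = 1.0 / s.protocol.inter_sweep_interval_s
        key = f"{s.genotype}:{_condition_key(s)}@{freq:g}Hz"
        ud_out[key] = {"pulse30": float(curve["normalized"].iloc[-1])}
    if ud_out:
        results["use_dependence"] = ud_out

    # ---- statistics ------------------------------------------------------
    stats_out = {}
    # paired one-sided t: pre vs post peaks across replicate tonic cells
    for comp, ref_d in (("BPA", 30.0), ("mexiletine", 150.0)):
        pre_means, post_means = [], []
        for s in sweepsets:
            c = s.conditions[0]
            if (s.protocol.name == "tonic_train" and s.genotype == "WT"
                    and c.compound == comp and c.concentration_uM == ref_d
                    and s.protocol.holding_mV == -120.0
                    and s.drug_onset_sweep is not None):
                pk = np.abs(peak_currents(s, 1)["peak_nA"].to_numpy())
                o = s.drug_onset_sweep
                pre_means.append(pk[:o].mean())
                post_means.append(pk[o + 5:o + 15].mean())
        if len(pre_means) >= 2:
            try:
                tr = nbstats.paired_t_one_sided(
                    pre_means, post_means, "greater",
                    groups=("pre", f"post {comp} {ref_d:g} uM"))
                stats_out[f"paired_t:{comp}"] = tr.to_dict()
            except ValueError as exc:
                stats_out[f"paired_t:{comp}"] = {"error": str(exc)}
    # ANOVA + LSD across BPA doses (WT, -120 mV) when replicated
    groups, labels = [], []
    for (g, c, d, h), bs in sorted(tonic.items()):
        if g == "WT" and c == "BPA" and h == -120.0 and len(bs) >= 2:
            groups.append(bs)
            labels.append(f"{d:g}uM")
    if len(groups) >= 2:
        stats_out["anova_lsd:BPA_doses"] = [
            t.to_dict() for t in nbstats.anova_fisher_lsd(groups, labels)]
    if stats_out:
        results["statistics"] = stats_out

    return nbstats.build_report(results, seed=seed)
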