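"""Voltage-clamp protocols and episodic sweep sets, with plain-text I/O.

The data model mirrors what an episodic whole-cell acquisition produces: a
:class:`VoltageProtocol` describes the stimulus (holding potential, a short
list of constant-voltage epochs, an optional per-sweep varying level, the
start-to-start inter-sweep interval) and a :class:`SweepSet` carries the
recorded current matrix (one row per sweep, nA) plus condition metadata.

Storage is a tab-separated UTF-8 table (comment lines prefixed ``#``, column 1
time in ms, one current column per sweep, 9 significant digits) with a JSON
sidecar holding the protocol and metadata.  Units throughout: mV, ms, nA, µM.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "VAR",
    "Epoch",
    "VoltageProtocol",
    "DrugCondition",
    "DRUG_FREE",
    "SweepSet",
    "make_protocol",
    "read_sweepset",
    "write_sweepset",
]

#: Sentinel level for the epoch whose voltage varies sweep by sweep.
VAR = "VAR"

GENOTYPES = ("WT", "F1760A")
COMPOUNDS = ("none", "BPA", "mexiletine", "lidocaine", "lamotrigine", "ETOH")


@dataclass(frozen=True)
class Epoch:
    """One constant-voltage segment of a sweep."""

    level_mV: float | str  # a voltage, or the VAR sentinel
    duration_ms: float

    def __post_init__(self) -> None:
        if self.level_mV != VAR:
            object.__setattr__(self, "level_mV", float(self.level_mV))
        if not self.duration_ms > 0:
            raise ValueError(f"epoch duration must be > 0, got {self.duration_ms}")


@dataclass(frozen=True)
class VoltageProtocol:
    """Epoch-structured stimulus description with an optional sweep-varying level."""

    name: str
    holding_mV: float
    epochs: tuple[Epoch, ...]
    sweep_values_mV: tuple[float, ...]
    inter_sweep_interval_s: float
    n_sweeps: int
    sampling_rate_kHz: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(
            e if isinstance(e, Epoch) else Epoch(*e) for e in self.epochs))
        object.__setattr__(self, "sweep_values_mV",
                           tuple(float(v) for v in self.sweep_values_mV))
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if not self.epochs:
            raise ValueError("protocol needs at least one epoch")
        if self.sampling_rate_kHz <= 0:
            raise ValueError("sampling_rate_kHz must be > 0")
        has_var = any(e.level_mV == VAR for e in self.epochs)
        if has_var and len(self.sweep_values_mV) != self.n_sweeps:
            raise ValueError(
                f"VAR epoch requires {self.n_sweeps} sweep values, "
                f"got {len(self.sweep_values_mV)}")
        if self.sweep_duration_ms > self.inter_sweep_interval_s * 1000.0 + 1e-9:
            raise ValueError(
                f"sweep duration {self.sweep_duration_ms} ms exceeds inter-sweep "
                f"interval {self.inter_sweep_interval_s * 1000.0} ms")

    # -- derived geometry ---------------------------------------------------
    @property
    def sweep_duration_ms(self) -> float:
        return float(sum(e.duration_ms for e in self.epochs))

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_rate_kHz

    @property
    def n_samples(self) -> int:
        return int(round(self.sweep_duration_ms * self.sampling_rate_kHz))

    def epoch_n_samples(self, epoch_index: int) -> int:
        return int(round(self.epochs[epoch_index].duration_ms * self.sampling_rate_kHz))

    def epoch_slice(self, epoch_index: int) -> slice:
        """Sample-index slice of an epoch within a sweep."""
        start = 0
        for i in range(epoch_index):
            start += self.epoch_n_samples(i)
        return slice(start, start + self.epoch_n_samples(epoch_index))

    def epoch_onset_ms(self, epoch_index: int) -> float:
        return float(sum(e.duration_ms for e in self.epochs[:epoch_index]))

    def levels_for_sweep(self, sweep_index: int) -> tuple[float, ...]:
        """Epoch voltage levels for one sweep (0-based), VAR resolved."""
        out = []
        for e in self.epochs:
            if e.level_mV == VAR:
                out.append(self.sweep_values_mV[sweep_index])
            else:
                out.append(float(e.level_mV))
        return tuple(out)

    @property
    def var_epoch_index(self) -> int | None:
        for i, e in enumerate(self.epochs):
            if e.level_mV == VAR:
                return i
        return None


@dataclass(frozen=True)
class DrugCondition:
    """A compound at a bath concentration; ``none`` means drug-free."""

    compound: str
    concentration_uM: float = 0.0
    vehicle_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.compound not in COMPOUNDS:
            raise ValueError(f"unknown compound {self.compound!r}")
        if self.concentration_uM < 0:
            raise ValueError("concentration_uM must be >= 0")
        if self.compound == "none" and self.concentration_uM != 0:
            raise ValueError("compound 'none' requires concentration 0")

    @property
    def blocks(self) -> bool:
        """Whether this condition carries a channel-blocking ligand."""
        return self.compound not in ("none", "ETOH") and self.concentration_uM > 0


DRUG_FREE = DrugCondition("none", 0.0)


@dataclass
class SweepSet:
    """Episodic current recordings plus condition metadata.

    ``sweeps`` has one row per sweep (nA); ``time_base`` is the shared sample
    clock in ms.  ``condition`` may be a tuple of :class:`DrugCondition` for
    co-applied compounds.  ``drug_onset_sweep`` is the 1-based sweep count
    after which the drug is present (``None`` = same condition throughout).
    """

    protocol: VoltageProtocol
    cell_id: str
    genotype: str
    condition: DrugCondition | tuple[DrugCondition, ...]
    sweeps: np.ndarray
    time_base: np.ndarray
    drug_onset_sweep: int | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        self.time_base = np.asarray(self.time_base, dtype=float)
        p = self.protocol
        if self.sweeps.shape[0] != p.n_sweeps:
            raise ValueError(
                f"sweep matrix has {self.sweeps.shape[0]} rows for an "
                f"{p.n_sweeps}-sweep protocol")
        if self.sweeps.shape[1] != p.n_samples:
            raise ValueError(
                f"sweep matrix has {self.sweeps.shape[1]} columns, protocol "
                f"implies {p.n_samples}")
        if self.time_base.shape != (p.n_samples,):
            raise ValueError("time_base length does not match sample count")
        d = np.diff(self.time_base)
        if len(d) and (np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6, atol=1e-9)):
            raise ValueError("time_base must be strictly increasing and uniform")

    @property
    def conditions(self) -> tuple[DrugCondition, ...]:
        c = self.condition
        return c if isinstance(c, tuple) else (c,)


# ---------------------------------------------------------------------------
# Protocol factories
# ---------------------------------------------------------------------------

#: Test-pulse length (ms) per use-dependence train frequency (Hz).
USE_TRAIN_PULSE_MS = {1: 40.0, 10: 40.0, 30: 20.0, 50: 10.0}

#: Sweep count after which the drug washes in on a tonic train (convention
#: applied by the simulator / CLI; the protocol itself has no drug fields).
TONIC_DRUG_ONSET_SWEEP = 10

_FAMILY_KEYS = {
    "iv_activation": {"holding_mV", "sweep_values_mV", "inter_sweep_interval_s",
                      "sampling_rate_kHz", "pulse_ms", "pre_ms"},
    "ssfi": {"holding_mV", "sweep_values_mV", "inter_sweep_interval_s",
             "sampling_rate_kHz", "prepulse_ms", "test_mV", "test_ms", "pre_ms"},
    "tonic_train": {"holding_mV", "n_sweeps", "inter_sweep_interval_s",
                    "sampling_rate_kHz", "test_mV", "pulse_ms", "pre_ms"},
    "use_train": {"holding_mV", "freq_Hz", "n_sweeps", "sampling_rate_kHz",
                  "test_mV", "test_ms", "pre_ms"},
}


def make_protocol(family: str, **overrides) -> VoltageProtocol:
    """Build one of the four standard protocol families.

    Families
    --------
    ``iv_activation``
        250 ms steps from −120 mV to −90..+40 mV in 10 mV increments with a
        final +45 mV sweep appended (15 sweeps; the nominal −90..+45 range is
        not divisible by 10, so the top level is appended), every 5 s.
    ``ssfi``
        500 ms conditioning prepulses −160..0 mV in 10 mV steps, each followed
        by a −10 mV test step, every 5 s (steady-state fast inactivation).
    ``tonic_train``
        25 test pulses to −10 mV, 250 ms, every 5 s (0.2 Hz); drug wash-in is
        conventionally applied after pulse 10.
    ``use_train``
        30 test pulses to −10 mV at ``freq_Hz`` ∈ {1, 10, 30, 50}; pulse
        length 40/40/20/10 ms respectively.

    Overrides are restricted to documented keys per family; anything that
    violates a :class:`VoltageProtocol` invariant raises ``ValueError``.
    """
    if family not in _FAMILY_KEYS:
        raise ValueError(f"unknown protocol family {family!r}")
    bad = set(overrides) - _FAMILY_KEYS[family]
    if bad:
        raise ValueError(f"unsupported override(s) for {family}: {sorted(bad)}")

    hold = float(overrides.get("holding_mV", -120.0))
    rate = float(overrides.get("sampling_rate_kHz", 20.0))
    pre = float(overrides.get("pre_ms", 5.0))

    if family == "iv_activation":
        values = overrides.get("sweep_values_mV")
        if values is None:
            values = [float(v) for v in range(-90, 41, 10)] + [45.0]
        pulse = float(overrides.get("pulse_ms", 250.0))
        return VoltageProtocol(
            name="iv_activation", holding_mV=hold,
            epochs=(Epoch(hold, pre), Epoch(VAR, pulse)),
            sweep_values_mV=tuple(values),
            inter_sweep_interval_s=float(overrides.get("inter_sweep_interval_s", 5.0)),
            n_sweeps=len(tuple(values)), sampling_rate_kHz=rate)

    if family == "ssfi":
        values = overrides.get("sweep_values_mV")
        if values is None:
            values = [float(v) for v in range(-160, 1, 10)]
        prep = float(overrides.get("prepulse_ms", 500.0))
        test_mV = float(overrides.get("test_mV", -10.0))
        test_ms = float(overrides.get("test_ms", 40.0))
        return VoltageProtocol(
            name="ssfi", holding_mV=hold,
            epochs=(Epoch(hold, pre), Epoch(VAR, prep), Epoch(test_mV, test_ms)),
            sweep_values_mV=tuple(values),
            inter_sweep_interval_s=float(overrides.get("inter_sweep_interval_s", 5.0)),
            n_sweeps=len(tuple(values)), sampling_rate_kHz=rate)

    if family == "tonic_train":
        pulse = float(overrides.get("pulse_ms", 250.0))
        test_mV = float(overrides.get("test_mV", -10.0))
        return VoltageProtocol(
            name="tonic_train", holding_mV=hold,
            epochs=(Epoch(hold, pre), Epoch(test_mV, pulse)),
            sweep_values_mV=(),
            inter_sweep_interval_s=float(overrides.get("inter_sweep_interval_s", 5.0)),
            n_sweeps=int(overrides.get("n_sweeps", 25)), sampling_rate_kHz=rate)

    # use_train
    freq = float(overrides.get("freq_Hz", 1.0))
    test_ms = overrides.get("test_ms")
    if test_ms is None:
        key = int(round(freq))
        if key not in USE_TRAIN_PULSE_MS or abs(freq - key) > 1e-9:
            raise ValueError(
                f"no default pulse length for {freq} Hz; pass test_ms explicitly")
        test_ms = USE_TRAIN_PULSE_MS[key]
    pre = float(overrides.get("pre_ms", 2.0))
    test_mV = float(overrides.get("test_mV", -10.0))
    return VoltageProtocol(
        name=f"use_train_{freq:g}Hz", holding_mV=hold,
        epochs=(Epoch(hold, pre), Epoch(test_mV, float(test_ms))),
        sweep_values_mV=(),
        inter_sweep_interval_s=1.0 / freq,
        n_sweeps=int(overrides.get("n_sweeps", 30)), sampling_rate_kHz=rate)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FMT = "%.9g"  # fixed text precision; round trips are bit-stable after one pass


def _table_path(path: str) -> str:
    return path if path.endswith(".tsv") else path + ".tsv"


def _sidecar_path(path: str) -> str:
    base = path[:-4] if path.endswith(".tsv") else path
    return base + ".json"


def _condition_to_dict(c: DrugCondition) -> dict:
    return {"compound": c.compound, "concentration_uM": c.concentration_uM,
            "vehicle_fraction": c.vehicle_fraction}


def _condition_from_dict(d: dict) -> DrugCondition:
    return DrugCondition(d["compound"], d["concentration_uM"],
                         d.get("vehicle_fraction", 0.0))


def write_sweepset(s: SweepSet, path: str) -> str:
    """Write a SweepSet as a text table plus JSON sidecar; returns table path."""
    p = s.protocol
    tpath, jpath = _table_path(path), _sidecar_path(path)
    conds = [_condition_to_dict(c) for c in s.conditions]
    meta = {
        "format": "navblock-sweepset",
        "format_version": 1,
        "protocol": {
            "name": p.name,
            "holding_mV": p.holding_mV,
            "epochs": [[e.level_mV, e.duration_ms] for e in p.epochs],
            "sweep_values_mV": list(p.sweep_values_mV),
            "inter_sweep_interval_s": p.inter_sweep_interval_s,
            "n_sweeps": p.n_sweeps,
            "sampling_rate_kHz": p.sampling_rate_kHz,
        },
        "cell_id": s.cell_id,
        "genotype": s.genotype,
        "condition": conds if len(conds) > 1 else conds[0],
        "drug_onset_sweep": s.drug_onset_sweep,
        "n_rows": int(p.n_samples),
        "n_sweep_columns": int(p.n_sweeps),
    }
    with open(jpath, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    cols = [s.time_base] + [s.sweeps[i] for i in range(p.n_sweeps)]
    header = "\t".join(["time_ms"] + [f"sweep_{i + 1:03d}_nA" for i in range(p.n_sweeps)])
    with open(tpath, "w", encoding="utf-8") as fh:
        fh.write("# navblock episodic sweep table\n")
        fh.write(f"# protocol: {p.name}\n")
        fh.write(f"# {header}\n")
        for row in zip(*cols):
            fh.write("\t".join(_FMT % v for v in row))
            fh.write("\n")
    return tpath


def read_sweepset(path: str) -> SweepSet:
    """Read a SweepSet written by :func:`write_sweepset` (lossless round trip)."""
    tpath, jpath = _table_path(path), _sidecar_path(path)
    if not os.path.exists(jpath):
        raise FileNotFoundError(f"missing sidecar descriptor {jpath}")
    with open(jpath, encoding="utf-8") as fh:
        meta = json.load(fh)
    if meta.get("format") != "navblock-sweepset":
        raise ValueError(f"{jpath}: not a navblock sweepset descriptor")
    pm = meta["protocol"]
    protocol = VoltageProtocol(
        name=pm["name"], holding_mV=pm["holding_mV"],
        epochs=tuple(Epoch(lv if lv == VAR else float(lv), du)
                     for lv, du in pm["epochs"]),
        sweep_values_mV=tuple(pm["sweep_values_mV"]),
        inter_sweep_interval_s=pm["inter_sweep_interval_s"],
        n_sweeps=pm["n_sweeps"], sampling_rate_kHz=pm["sampling_rate_kHz"])
    try:
        data = np.loadtxt(tpath, comments="#", delimiter="\t", ndmin=2)
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise ValueError(f"{tpath}: malformed sweep table ({exc})") from exc
    if data.shape[0] != meta["n_rows"]:
        raise ValueError(
            f"{tpath}: {data.shape[0]} rows, descriptor says {meta['n_rows']}")
    if data.shape[1] != meta["n_sweep_columns"] + 1:
        raise ValueError(
            f"{tpath}: {data.shape[1] - 1} sweep columns for a "
            f"{meta['n_sweep_columns']}-sweep protocol")
    cond = meta["condition"]
    condition: DrugCondition | tuple[DrugCondition, ...]
    if isinstance(cond, list):
        condition = tuple(_condition_from_dict(c) for c in cond)
    else:
        condition = _condition_from_dict(cond)
    return SweepSet(
        protocol=protocol, cell_id=meta["cell_id"], genotype=meta["genotype"],
        condition=condition, sweeps=data[:, 1:].T.copy(),
        time_base=data[:, 0].copy(), drug_onset_sweep=meta["drug_onset_sweep"])
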