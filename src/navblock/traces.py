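"""Scalar measurements from episodic sweep sets: peak currents, conductance
transforms, reversal-potential estimation, tonic-block ratios, use-dependence
curves, and the inactivated fraction at a holding potential.

Conventions: inward current is negative; peaks are the extremum of largest
absolute value within an epoch, searched after a short blanking window (to
skip any residual edge artifact); block fractions are computed on absolute
peaks.  All tables are pandas DataFrames exportable as tab-separated text.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fits import BoltzmannFit, ExpFit, fit_exponential
from .protocols import DRUG_FREE, DrugCondition, SweepSet

__all__ = [
    "BlockMeasurement",
    "peak_currents",
    "availability_from_ssfi",
    "conductance_curve",
    "estimate_erev",
    "tonic_block_ratio",
    "use_dependence_curve",
    "inactivated_fraction",
    "fit_decay_from_peak",
]

DEFAULT_BLANK_MS = 0.3


@dataclass(frozen=True)
class BlockMeasurement:
    """Blocked fraction B under one condition (optionally with the
    inactivated fraction h at the holding potential)."""

    condition: DrugCondition | tuple[DrugCondition, ...]
    B: float
    holding_mV: float
    h: float | None = None
    clipped: bool = False  # True when raw B fell outside [0, 1] (noise)
    method: str = "mean_ratio"

    def __post_init__(self) -> None:
        if not 0.0 <= self.B <= 1.0:
            raise ValueError("B must lie in [0, 1]")
        if self.h is not None and not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")


def peak_currents(s: SweepSet, epoch_index: int,
                  blank_ms: float = DEFAULT_BLANK_MS) -> pd.DataFrame:
    """Signed peak current per sweep within one epoch.

    The peak is the sample of largest absolute value after ``blank_ms`` from
    epoch onset; sign is preserved.  Columns: sweep_index (1-based),
    level_mV (the epoch's level for that sweep), peak_nA, t_peak_ms
    (absolute sweep time).
    """
    p = s.protocol
    if not 0 <= epoch_index < len(p.epochs):
        raise IndexError(f"epoch {epoch_index} does not exist")
    sl = p.epoch_slice(epoch_index)
    onset = p.epoch_onset_ms(epoch_index)
    n_blank = int(round(blank_ms * p.sampling_rate_kHz))
    if n_blank >= (sl.stop - sl.start):
        raise ValueError("epoch shorter than the blanking window")
    rows = []
    for i in range(p.n_sweeps):
        seg = s.sweeps[i, sl][n_blank:]
        j = int(np.argmax(np.abs(seg)))
        rows.append({
            "sweep_index": i + 1,
            "level_mV": p.levels_for_sweep(i)[epoch_index],
            "peak_nA": float(seg[j]),
            "t_peak_ms": onset + (n_blank + j) * p.dt_ms,
        })
    return pd.DataFrame(rows)


def availability_from_ssfi(s: SweepSet, test_epoch_index: int = -1,
                           blank_ms: float = DEFAULT_BLANK_MS) -> pd.DataFrame:
    """Normalized test-pulse peak vs conditioning prepulse voltage
    (steady-state availability curve).  Columns: V_mV, availability."""
    p = s.protocol
    idx = test_epoch_index % len(p.epochs)
    pk = peak_currents(s, idx, blank_ms)
    if not p.sweep_values_mV:
        raise ValueError("protocol has no sweep-varying prepulse")
    a = np.abs(pk["peak_nA"].to_numpy())
    if a.max() <= 0:
        raise ValueError("no measurable test current")
    return pd.DataFrame({"V_mV": np.asarray(p.sweep_values_mV, dtype=float),
                         "availability": a / a.max()})


def conductance_curve(p: pd.DataFrame, Erev_mV: float) -> pd.DataFrame:
    """Normalized chord conductance G = I/(V − Erev) from a peak table.

    Raises if any level lies within 1 mV of the reversal potential (the
    transform diverges there).  Columns: V_mV, G_uS, G_norm.
    """
    V = p["level_mV"].to_numpy(dtype=float)
    I = p["peak_nA"].to_numpy(dtype=float)
    if np.any(np.abs(V - Erev_mV) < 1.0):
        raise ValueError("test level within 1 mV of the reversal potential")
    G = I / (V - Erev_mV)  # nA/mV = µS
    G = np.clip(G, 0.0, None)  # sign handling: conductance is non-negative
    gmax = G.max()
    if gmax <= 0:
        raise ValueError("all conductances are zero; cannot normalize")
    return pd.DataFrame({"V_mV": V, "G_uS": G, "G_norm": G / gmax})


def estimate_erev(p: pd.DataFrame, method: str = "interpolate") -> float:
    """Reversal potential from a peak-current table.

    ``interpolate`` (default): linear interpolation of the zero crossing
    between the bracketing levels; raises if the peaks never change sign.
    ``ohmic``: linear extrapolation of the ohmic limb (least-squares line
    through the four most depolarized levels) — useful when the protocol
    stops short of the reversal potential.  ``auto`` tries interpolation
    first and falls back to the ohmic limb.
    """
    q = p.sort_values("level_mV")
    V = q["level_mV"].to_numpy(dtype=float)
    I = q["peak_nA"].to_numpy(dtype=float)
    if method not in ("interpolate", "ohmic", "auto"):
        raise ValueError(f"unknown method {method!r}")
    # only crossings depolarized of the largest inward peak count: near-zero
    # sub-threshold levels can produce spurious noise crossings
    imax = int(np.argmin(I))
    sign_change = imax + np.nonzero((I[imax:-1] < 0) & (I[imax + 1:] >= 0))[0]
    if method in ("interpolate", "auto") and len(sign_change):
        i = int(sign_change[0])
        f = -I[i] / (I[i + 1] - I[i])  # f = 1 when the upper level sits at 0
        return float(V[i] + f * (V[i + 1] - V[i]))
    if method == "interpolate":
        raise ValueError("peak currents do not change sign across the level range")
    if len(V) < 4:
        raise ValueError("need at least 4 levels for ohmic-limb extrapolation")
    m, b = np.polyfit(V[-4:], I[-4:], 1)
    if m <= 0:
        raise ValueError("ohmic limb has non-positive slope; cannot extrapolate")
    return float(-b / m)


def tonic_block_ratio(s: SweepSet, method: str = "mean_ratio",
                      blank_ms: float = DEFAULT_BLANK_MS) -> BlockMeasurement:
    """Tonic block from a 0.2 Hz train with drug wash-in after pulse ``o``.

    ``mean_ratio`` (primary): B = 1 − mean(|peak|, pulses o+6..o+15) /
    mean(|peak|, pulses 1..o) — the post window starts five pulses after
    wash-in so that the bath and binding have equilibrated.
    ``pulse15``: the single-pulse form, B = 1 − |peak at pulse o+15| / pre
    mean.  B outside [0, 1] (possible by chance at low drug effect) is
    clipped and flagged rather than raised.
    """
    o = s.drug_onset_sweep
    if o is None:
        raise ValueError("sweep set has no drug_onset_sweep")
    p = s.protocol
    if p.n_sweeps < o + 15:
        raise ValueError(f"need at least {o + 15} sweeps, protocol has {p.n_sweeps}")
    pk = peak_currents(s, len(p.epochs) - 1, blank_ms)
    a = np.abs(pk["peak_nA"].to_numpy())
    pre = a[:o].mean()
    if pre < 1e-9:
        raise ValueError("pre-drug mean peak is ~0; cannot normalize")
    if method == "mean_ratio":
        post = a[o + 5:o + 15].mean()
    elif method == "pulse15":
        post = a[o + 14]
    else:
        raise ValueError(f"unknown method {method!r}")
    raw = 1.0 - post / pre
    clipped = not (0.0 <= raw <= 1.0)
    return BlockMeasurement(condition=s.condition, B=float(np.clip(raw, 0.0, 1.0)),
                            holding_mV=p.holding_mV, clipped=clipped, method=method)


def use_dependence_curve(s: SweepSet,
                         blank_ms: float = DEFAULT_BLANK_MS) -> pd.DataFrame:
    """Peak currents of a pulse train normalized to the first pulse.

    Columns: pulse_index (1-based), normalized.  The 30th-pulse value is the
    conventional use-dependence summary.
    """
    p = s.protocol
    pk = peak_currents(s, len(p.epochs) - 1, blank_ms)
    a = np.abs(pk["peak_nA"].to_numpy())
    if a[0] < 1e-9:
        raise ValueError("first-pulse peak is ~0; cannot normalize")
    return pd.DataFrame({"pulse_index": np.arange(1, len(a) + 1),
                         "normalized": a / a[0]})


def inactivated_fraction(fit: BoltzmannFit, holding_mV: float) -> float:
    """Fraction of channels inactivated at a holding potential, from an
    availability-curve fit: h = 1 − 1/(1 + exp((V_hold − V_half)/k))."""
    if fit.kind != "inactivation":
        raise ValueError("inactivated_fraction requires an inactivation fit")
    return float(1.0 - 1.0 / (1.0 + np.exp((holding_mV - fit.Vhalf_mV) / fit.k_mV)))


def fit_decay_from_peak(s: SweepSet, sweep_index: int = 0,
                        epoch_index: int | None = None, window_ms: float = 40.0,
                        blank_ms: float = DEFAULT_BLANK_MS) -> ExpFit:
    """Single-exponential fit of the current decay, starting at the peak
    sample of the chosen epoch and extending ``window_ms``."""
    p = s.protocol
    if epoch_index is None:
        epoch_index = len(p.epochs) - 1
    sl = p.epoch_slice(epoch_index)
    n_blank = int(round(blank_ms * p.sampling_rate_kHz))
    seg = s.sweeps[sweep_index, sl][n_blank:]
    j = int(np.argmax(np.abs(seg)))
    n_win = int(round(window_ms * p.sampling_rate_kHz))
    y = seg[j:j + n_win]
    t = np.arange(len(y)) * p.dt_ms
    return fit_exponential(t, y)
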