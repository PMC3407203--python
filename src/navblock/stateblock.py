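"""Modulated-receptor inference: resting/inactivated dissociation constants,
the apparent affinity at partial inactivation, predicted availability-curve
shifts for one drug and for two co-applied drugs under separate-site versus
shared-site (competitive) binding, and a discrimination step.

The equilibrium relations are the standard modulated-receptor results for a
single-site blocker whose affinity differs between resting (Kr) and
fast-inactivated (Ki) channels:

* resting block:        B_rest = D / (D + Kr)   ⇒   Kr = D·(1 − B)/B
* apparent affinity:    1/K_app(h) = h/Ki + (1 − h)/Kr
* availability shift:   ΔV½ = −k·ln[(1 + D/Ki)/(1 + D/Kr)]
* two drugs, separate sites:
      ΔV½ = −k·ln[(1 + D1/Ki1)(1 + D2/Ki2) / ((1 + D1/Kr1)(1 + D2/Kr2))]
* two drugs, one shared/overlapping site (competitive):
      ΔV½ = −k·ln[(1 + D1/Ki1 + D2/Ki2) / (1 + D1/Kr1 + D2/Kr2)]

Signs: shifts are reported signed, negative = hyperpolarizing.  These forms
are validated by their limiting identities (h=0 ⇒ Kr, h=1 ⇒ Ki, D2=0 ⇒
single-drug, Ki=Kr ⇒ zero shift) and by the ordering |shared| < |separate|,
which follows from (1+x1+x2) < (1+x1)(1+x2) for positive x.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "ShiftPrediction",
    "OverlapVerdict",
    "kr_from_resting_block",
    "apparent_kd",
    "ki_from_inactivated_block",
    "predict_shift_single",
    "predict_shift_combo",
    "classify_overlap",
    "load_reference_params",
]


@dataclass(frozen=True)
class ShiftPrediction:
    """A predicted availability-midpoint shift (mV, negative =
    hyperpolarizing) under one binding model."""

    model: str  # "single", "combo_separate" or "combo_shared"
    delta_Vhalf_mV: float
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("single", "combo_separate", "combo_shared"):
            raise ValueError(f"unknown shift model {self.model!r}")


@dataclass(frozen=True)
class OverlapVerdict:
    """Observed combined shift versus the two competing predictions."""

    observed_shift_mV: float
    se_mV: float
    prediction_separate: ShiftPrediction
    prediction_shared: ShiftPrediction
    verdict: str            # "shared", "separate" or "indeterminate"
    margin_mV: float        # |dist(obs, losing model)| − |dist(obs, winner)|
    nearest: str            # model with the smaller |observed − predicted|

    def to_dict(self) -> dict:
        return {
            "observed_shift_mV": self.observed_shift_mV, "se_mV": self.se_mV,
            "pred_separate_mV": self.prediction_separate.delta_Vhalf_mV,
            "pred_shared_mV": self.prediction_shared.delta_Vhalf_mV,
            "verdict": self.verdict, "margin_mV": self.margin_mV,
            "nearest": self.nearest,
        }


# ---------------------------------------------------------------------------
# Dissociation-constant estimators
# ---------------------------------------------------------------------------

def kr_from_resting_block(D_uM: float, Brest: float) -> float:
    """Resting-state dissociation constant from single-site occupancy:
    Kr = D·(1 − B_rest)/B_rest."""
    if not D_uM > 0:
        raise ValueError("D_uM must be > 0")
    if not 0.0 < Brest < 1.0:
        raise ValueError("Brest must lie strictly between 0 and 1")
    return D_uM * (1.0 - Brest) / Brest


def apparent_kd(h: float, Kr_uM: float, Ki_uM: float) -> float:
    """Apparent dissociation constant at inactivated fraction h:
    1/K_app = h/Ki + (1 − h)/Kr."""
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must lie in [0, 1]")
    if not (Kr_uM > 0 and Ki_uM > 0):
        raise ValueError("Kr and Ki must be > 0")
    return 1.0 / (h / Ki_uM + (1.0 - h) / Kr_uM)


def ki_from_inactivated_block(D_uM: float, Bdrug: float, h: float,
                              Kr_uM: float, Bmax: float = 1.0) -> float:
    """Inactivated-state dissociation constant from the block measured at a
    holding potential with inactivated fraction h.

    Inverts B/Bmax = D/(D + K_app(h)) for K_app, then
    Ki = h / (1/K_app − (1 − h)/Kr).  Raises when the inputs imply a
    non-positive Ki (block too small to be consistent with the supplied Kr
    and h).
    """
    if not D_uM > 0:
        raise ValueError("D_uM must be > 0")
    if not 0.0 < Bdrug / Bmax < 1.0:
        raise ValueError("Bdrug/Bmax must lie strictly between 0 and 1")
    if not 0.0 < h <= 1.0:
        raise ValueError("h must lie in (0, 1] to constrain Ki")
    if not Kr_uM > 0:
        raise ValueError("Kr_uM must be > 0")
    b = Bdrug / Bmax
    Kapp = D_uM * (1.0 - b) / b
    inv_ki_term = 1.0 / Kapp - (1.0 - h) / Kr_uM
    if inv_ki_term <= 0:
        raise ValueError(
            "measured block is incompatible with the supplied Kr and h "
            "(implied Ki <= 0)")
    return h / inv_ki_term


# ---------------------------------------------------------------------------
# Shift predictions
# ---------------------------------------------------------------------------

def _occupancy_factor(D: float, Kr: float, Ki: float) -> tuple[float, float]:
    if D < 0:
        raise ValueError("concentration must be >= 0")
    if not (Kr > 0 and Ki > 0):
        raise ValueError("Kr and Ki must be > 0")
    return D / Ki, D / Kr


def predict_shift_single(D_uM: float, Kr_uM: float, Ki_uM: float,
                         k_mV: float) -> ShiftPrediction:
    """Predicted availability-midpoint shift for one drug:
    ΔV½ = −k·ln[(1 + D/Ki)/(1 + D/Kr)]."""
    xi, xr = _occupancy_factor(D_uM, Kr_uM, Ki_uM)
    if not k_mV > 0:
        raise ValueError("k_mV must be > 0")
    dv = -k_mV * math.log((1.0 + xi) / (1.0 + xr))
    return ShiftPrediction(model="single", delta_Vhalf_mV=dv,
                           inputs={"D_uM": D_uM, "Kr_uM": Kr_uM,
                                   "Ki_uM": Ki_uM, "k_mV": k_mV})


def predict_shift_combo(d1, d2, k_mV: float,
                        model: str = "shared") -> ShiftPrediction:
    """Predicted shift for two co-applied drugs.

    ``d1`` and ``d2`` are (D_uM, Kr_uM, Ki_uM) triples.  ``model`` is
    ``"separate"`` (independent sites; stabilization energies add) or
    ``"shared"`` (one common/overlapping site; competitive occupancy).
    With either drug at zero concentration both models reduce exactly to the
    single-drug prediction.
    """
    if model not in ("separate", "shared"):
        raise ValueError(f"unknown combination model {model!r}")
    if not k_mV > 0:
        raise ValueError("k_mV must be > 0")
    D1, Kr1, Ki1 = d1
    D2, Kr2, Ki2 = d2
    x1i, x1r = _occupancy_factor(D1, Kr1, Ki1)
    x2i, x2r = _occupancy_factor(D2, Kr2, Ki2)
    if model == "separate":
        ratio = (1.0 + x1i) * (1.0 + x2i) / ((1.0 + x1r) * (1.0 + x2r))
    else:
        ratio = (1.0 + x1i + x2i) / (1.0 + x1r + x2r)
    dv = -k_mV * math.log(ratio)
    return ShiftPrediction(
        model=f"combo_{model}", delta_Vhalf_mV=dv,
        inputs={"drug1": {"D_uM": D1, "Kr_uM": Kr1, "Ki_uM": Ki1},
                "drug2": {"D_uM": D2, "Kr_uM": Kr2, "Ki_uM": Ki2},
                "k_mV": k_mV})


def classify_overlap(observed_shift_mV: float, se_mV: float,
                     pred_sep: ShiftPrediction,
                     pred_shared: ShiftPrediction) -> OverlapVerdict:
    """Decide which binding model the observed combined shift supports.

    The verdict is the model whose prediction lies within the observed 95%
    interval (±1.96·se) when exactly one does.  When the two predictions are
    closer than 2·se, or when both/neither fall inside the interval, the
    verdict is ``indeterminate`` and only the nearest model is reported.
    """
    if se_mV < 0:
        raise ValueError("se_mV must be >= 0")
    ps, pc = pred_sep.delta_Vhalf_mV, pred_shared.delta_Vhalf_mV
    d_sep = abs(observed_shift_mV - ps)
    d_sha = abs(observed_shift_mV - pc)
    nearest = "shared" if d_sha <= d_sep else "separate"
    margin = abs(d_sep - d_sha)
    half = 1.96 * se_mV
    in_sep = d_sep <= half
    in_sha = d_sha <= half
    if abs(ps - pc) < 2.0 * se_mV or in_sep == in_sha:
        verdict = "indeterminate"
    else:
        verdict = "separate" if in_sep else "shared"
    return OverlapVerdict(
        observed_shift_mV=observed_shift_mV, se_mV=se_mV,
        prediction_separate=pred_sep, prediction_shared=pred_shared,
        verdict=verdict, margin_mV=margin, nearest=nearest)


# ---------------------------------------------------------------------------
# Reference constants
# ---------------------------------------------------------------------------

def load_reference_params() -> dict:
    """Packaged reference constants (published whole-cell patch-clamp values
    for hNav1.5: per-compound Kr/Ki, tonic-block Kd, availability-curve
    parameters) used by the demo pipeline and acceptance checks."""
    with resources.files("navblock.data").joinpath(
            "reference_params.json").open(encoding="utf-8") as fh:
        return json.load(fh)
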