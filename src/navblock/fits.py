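"""Nonlinear least-squares estimators for the three curve families used in
state-dependent block analysis: Boltzmann (activation / availability), Hill
(dose–response with endpoints fixed at 0 and 1), and single exponential
(current decay).  Fitting is Levenberg–Marquardt via lmfit; standard errors
come from the Jacobian covariance scaled by residual variance and are
reported "best fit ± standard error".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from scipy.stats import t as t_dist

__all__ = [
    "BoltzmannFit",
    "HillFit",
    "ExpFit",
    "boltzmann",
    "hill",
    "single_exponential",
    "fit_boltzmann",
    "fit_hill",
    "fit_exponential",
    "hill_confidence_band",
]

_FIT_KWS = {"xtol": 1e-12, "ftol": 1e-12, "gtol": 1e-12}
_MAX_NFEV = 5000  # generous cap; LM converges in far fewer evaluations
_MULTISTART_FACTORS = (1.0, 0.7, 1.4)  # perturbed restarts on non-convergence


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------

def boltzmann(V, Vhalf, k, A=1.0, kind="inactivation"):
    """A / (1 + exp(s·(Vhalf − V)/k)); s = +1 for activation (rising with V),
    −1 for inactivation/availability (falling with V)."""
    s = 1.0 if kind == "activation" else -1.0
    return A / (1.0 + np.exp(s * (Vhalf - np.asarray(V, dtype=float)) / k))


def hill(D, Kd, nH=1.0):
    """D^nH / (D^nH + Kd^nH); block is 0 at D=0 and saturates at 1."""
    D = np.asarray(D, dtype=float)
    with np.errstate(divide="ignore"):
        x = np.where(D > 0, (D / Kd) ** nH, 0.0)
    return x / (1.0 + x)


def single_exponential(t, tau, a, c):
    """a·exp(−t/τ) + c."""
    return a * np.exp(-np.asarray(t, dtype=float) / tau) + c


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoltzmannFit:
    Vhalf_mV: float
    k_mV: float
    amplitude: float
    se_Vhalf: float
    se_k: float
    rss: float
    kind: str
    ndata: int

    def __post_init__(self) -> None:
        if not self.k_mV > 0:
            raise ValueError("k_mV must be > 0")
        if self.kind not in ("activation", "inactivation"):
            raise ValueError(f"unknown Boltzmann kind {self.kind!r}")

    def __call__(self, V):
        return boltzmann(V, self.Vhalf_mV, self.k_mV, self.amplitude, self.kind)

    def to_dict(self) -> dict:
        return {"Vhalf_mV": self.Vhalf_mV, "k_mV": self.k_mV,
                "amplitude": self.amplitude, "se_Vhalf": self.se_Vhalf,
                "se_k": self.se_k, "rss": self.rss, "kind": self.kind,
                "ndata": self.ndata}


@dataclass(frozen=True)
class HillFit:
    Kd_uM: float
    nH: float
    se_Kd: float
    se_nH: float
    rss: float
    ndata: int
    cov: tuple  # covariance over the free parameters, row-major
    free_params: tuple  # names of the free parameters, in cov order

    def __post_init__(self) -> None:
        if not self.Kd_uM > 0:
            raise ValueError("Kd_uM must be > 0")
        if not self.nH > 0:
            raise ValueError("nH must be > 0")

    def __call__(self, D):
        return hill(D, self.Kd_uM, self.nH)

    def to_dict(self) -> dict:
        return {"Kd_uM": self.Kd_uM, "nH": self.nH, "se_Kd": self.se_Kd,
                "se_nH": self.se_nH, "rss": self.rss, "ndata": self.ndata}


@dataclass(frozen=True)
class ExpFit:
    tau_ms: float
    amplitude_nA: float
    offset_nA: float
    se_tau: float
    rss: float
    ndata: int

    def __post_init__(self) -> None:
        if not self.tau_ms > 0:
            raise ValueError("tau_ms must be > 0")

    def __call__(self, t):
        return single_exponential(t, self.tau_ms, self.amplitude_nA, self.offset_nA)

    def to_dict(self) -> dict:
        return {"tau_ms": self.tau_ms, "amplitude_nA": self.amplitude_nA,
                "offset_nA": self.offset_nA, "se_tau": self.se_tau,
                "rss": self.rss, "ndata": self.ndata}


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _xy(xy, x=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept (x, y) arrays, a 2-column array, or a 2-column DataFrame."""
    if x is not None:
        return np.asarray(xy, dtype=float), np.asarray(x, dtype=float)
    if isinstance(xy, pd.DataFrame):
        a = xy.iloc[:, :2].to_numpy(dtype=float)
    else:
        a = np.asarray(xy, dtype=float)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("expected a two-column table or separate x, y arrays")
    return a[:, 0], a[:, 1]


def _run_fit(model: Model, y, params, restart_names, **indep):
    """LM fit with up to three perturbed restarts on non-convergence."""
    last = None
    for f in _MULTISTART_FACTORS:
        p = params.copy()
        for name in restart_names:
            p[name].value = params[name].value * f
        res = model.fit(y, p, method="leastsq", fit_kws=_FIT_KWS,
                        max_nfev=_MAX_NFEV, nan_policy="raise", **indep)
        last = res
        if res.success:
            return res
    raise RuntimeError(f"fit did not converge: {last.message if last else 'no run'}")


def _stderr(res, name) -> float:
    v = res.params[name].stderr
    return float(v) if v is not None else float("nan")


# ---------------------------------------------------------------------------
# Fitters
# ---------------------------------------------------------------------------

def fit_boltzmann(xy, y=None, kind: str = "inactivation", *,
                  fix_amplitude: float | None = None) -> BoltzmannFit:
    """Fit y(V) = A/(1+exp(s·(Vhalf−V)/k)).

    ``xy`` may be a (V, y) table or the V array with ``y`` given separately.
    Requires ≥ 5 points spanning the transition.  The amplitude is free by
    default (normalized data fit close to 1); pass ``fix_amplitude=1.0`` to
    pin it.
    """
    if kind not in ("activation", "inactivation"):
        raise ValueError(f"unknown Boltzmann kind {kind!r}")
    V, yv = _xy(xy, y)
    if len(V) < 5:
        raise ValueError("need at least 5 points for a Boltzmann fit")
    if np.ptp(yv) < 1e-12:
        raise ValueError("degenerate data: y is constant")

    half = (yv.min() + yv.max()) / 2.0
    v0 = float(V[np.argmin(np.abs(yv - half))])
    a0 = float(yv.max()) if fix_amplitude is None else float(fix_amplitude)

    # bind the kind (sign convention) via a closure; lmfit parameters are numeric
    m = Model(lambda V, Vhalf, k, A: boltzmann(V, Vhalf, k, A, kind),
              independent_vars=["V"])
    params = m.make_params(Vhalf=v0, k=6.0, A=a0)
    params["k"].min = 1e-6
    if fix_amplitude is not None:
        params["A"].vary = False
    res = _run_fit(m, yv, params, ["k"], V=V)
    return BoltzmannFit(
        Vhalf_mV=float(res.params["Vhalf"].value), k_mV=float(res.params["k"].value),
        amplitude=float(res.params["A"].value), se_Vhalf=_stderr(res, "Vhalf"),
        se_k=_stderr(res, "k"), rss=float(np.sum(res.residual**2)),
        kind=kind, ndata=len(V))


def fit_hill(dose_block, B=None, *, fix_nH: float | None = None) -> HillFit:
    """Fit B(D) = D^nH/(D^nH + Kd^nH) with endpoints fixed at 0 and 1.

    Requires ≥ 4 doses with at least one B > 0.2 and one B < 0.8 (the data
    must straddle the transition).  The Hill coefficient is free by default;
    pass ``fix_nH=1.0`` to pin it.
    """
    D, Bv = _xy(dose_block, B)
    pos = D > 0
    if pos.sum() < 4:
        raise ValueError("need at least 4 non-zero doses for a Hill fit")
    if np.all(np.abs(Bv) < 1e-12):
        raise ValueError("all-zero block: nothing to fit")
    if not (np.any(Bv > 0.2) and np.any(Bv < 0.8)):
        raise ValueError("doses do not span the transition (need B>0.2 and B<0.8)")

    kd0 = float(D[pos][np.argmin(np.abs(Bv[pos] - 0.5))])
    m = Model(hill, independent_vars=["D"])
    params = m.make_params(Kd=kd0, nH=1.0 if fix_nH is None else fix_nH)
    params["Kd"].min = 1e-9
    params["nH"].min = 1e-3
    if fix_nH is not None:
        params["nH"].vary = False
    res = _run_fit(m, Bv, params, ["Kd"], D=D)

    free = tuple(n for n in ("Kd", "nH") if res.params[n].vary)
    if res.covar is not None:
        cov = tuple(float(v) for v in np.asarray(res.covar).ravel())
    else:
        cov = ()
    return HillFit(
        Kd_uM=float(res.params["Kd"].value), nH=float(res.params["nH"].value),
        se_Kd=_stderr(res, "Kd"),
        se_nH=_stderr(res, "nH") if fix_nH is None else 0.0,
        rss=float(np.sum(res.residual**2)), ndata=len(D),
        cov=cov, free_params=free)


def fit_exponential(t, y=None) -> ExpFit:
    """Fit y(t) = a·exp(−t/τ) + c to a decay segment starting at its peak.

    τ is initialized from a log-linear regression over the first 10 ms.
    Raises on non-decaying segments.
    """
    tv, yv = _xy(t, y)
    tv = tv - tv[0]
    if np.ptp(yv) < 1e-12:
        raise ValueError("degenerate data: constant trace cannot define a decay")
    c0 = float(yv[-1])
    a0 = float(yv[0] - c0)
    if abs(a0) < 1e-12:
        raise ValueError("segment does not decay from its first sample")
    # the caller passes a segment starting at the peak; a deviation extremum
    # later in the trace means there is no decay to fit from sample 0
    dev = np.abs(yv - c0)
    if int(np.argmax(dev)) > max(1, len(yv) // 20):
        raise ValueError("segment does not decay from its first sample "
                         "(extremum lies inside the window)")
    head = tv <= min(10.0, tv[-1])
    z = np.abs(yv[head] - c0)
    ok = z > 1e-12
    if ok.sum() >= 2:
        slope = np.polyfit(tv[head][ok], np.log(z[ok]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else 1.0
    else:
        tau0 = 1.0
    tau0 = float(np.clip(tau0, 1e-3, 1e4))

    m = Model(single_exponential, independent_vars=["t"])
    params = m.make_params(tau=tau0, a=a0, c=c0)
    params["tau"].min = 1e-9
    res = _run_fit(m, yv, params, ["tau"], t=tv)
    return ExpFit(
        tau_ms=float(res.params["tau"].value),
        amplitude_nA=float(res.params["a"].value),
        offset_nA=float(res.params["c"].value),
        se_tau=_stderr(res, "tau"),
        rss=float(np.sum(res.residual**2)), ndata=len(tv))


# ---------------------------------------------------------------------------
# Confidence band
# ---------------------------------------------------------------------------

def hill_confidence_band(fit: HillFit, doses: Sequence[float],
                         level: float = 0.95) -> pd.DataFrame:
    """Pointwise confidence band for a fitted Hill curve by first-order error
    propagation of the parameter covariance; the quantile is Student-t with
    (ndata − n_free) degrees of freedom.
    """
    nfree = len(fit.free_params)
    if not fit.cov or len(fit.cov) != nfree * nfree:
        raise ValueError("singular or missing covariance; cannot build a band")
    C = np.asarray(fit.cov, dtype=float).reshape(nfree, nfree)
    D = np.asarray(doses, dtype=float)
    Kd, n = fit.Kd_uM, fit.nH
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(D > 0, (D / Kd) ** n, 0.0)
        denom = (1.0 + x) ** 2
        dB_dKd = np.where(D > 0, -n * x / Kd / denom, 0.0)
        dB_dn = np.where(D > 0, x * np.log(np.maximum(D, 1e-300) / Kd) / denom, 0.0)
    grads = {"Kd": dB_dKd, "nH": dB_dn}
    G = np.column_stack([grads[p] for p in fit.free_params])
    var = np.einsum("ij,jk,ik->i", G, C, G)
    var = np.clip(var, 0.0, None)
    df = max(fit.ndata - nfree, 1)
    q = t_dist.ppf(0.5 + level / 2.0, df)
    mid = fit(D)
    half = q * np.sqrt(var)
    return pd.DataFrame({"D_uM": D, "B": mid, "lower": mid - half,
                         "upper": mid + half})
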