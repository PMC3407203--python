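"""Comparison statistics for block measurements (paired one-sided t,
one-way ANOVA with Fisher LSD posthoc) and a deterministic report builder.

Fisher LSD p-values are deliberately unadjusted — that is what the LSD
procedure is.  Summary values follow the mean ± SEM convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "paired_t_one_sided",
    "anova_fisher_lsd",
    "mean_sem",
    "build_report",
    "render_markdown",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    test: str
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df,
                "p_value": self.p_value, "test": self.test,
                "groups": list(self.groups)}


def paired_t_one_sided(x: Sequence[float], y: Sequence[float],
                       direction: str = "greater",
                       groups: tuple[str, str] = ("x", "y")) -> TestResult:
    """Classical paired t-test on x − y with a one-sided alternative
    (``greater``: mean(x − y) > 0; ``less``: < 0).  Raises on zero-variance
    differences (the statistic is undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    if direction not in ("greater", "less"):
        raise ValueError(f"unknown direction {direction!r}")
    d = x - y
    if np.ptp(d) < 1e-300 * max(1.0, np.abs(d).max()) or d.std(ddof=1) == 0.0:
        raise ValueError("zero-variance differences: paired t undefined")
    res = sps.ttest_rel(x, y, alternative=direction)
    return TestResult(statistic=float(res.statistic), df=float(len(x) - 1),
                      p_value=float(res.pvalue), test="paired_t_one_sided",
                      groups=groups)


def anova_fisher_lsd(groups: Sequence[Sequence[float]],
                     labels: Sequence[str] | None = None) -> list[TestResult]:
    """One-way ANOVA followed by Fisher LSD pairwise comparisons.

    Returns the omnibus F test first, then one two-sided pairwise t per group
    pair, using the pooled within-group variance (MSW) with N − k degrees of
    freedom and no multiplicity adjustment.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.ndim != 1 or len(a) < 2 for a in arrs):
        raise ValueError("each group needs at least 2 observations")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrs))]
    labels = list(labels)
    N = sum(len(a) for a in arrs)
    k = len(arrs)
    df_w = N - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_w
    if msw <= 0:
        raise ValueError("degenerate groups: zero within-group variance")
    f = sps.f_oneway(*arrs)
    out = [TestResult(statistic=float(f.statistic), df=float(k - 1),
                      p_value=float(f.pvalue), test="anova_oneway_F",
                      groups=tuple(labels))]
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(msw * (1.0 / len(arrs[i]) + 1.0 / len(arrs[j])))
            t = (arrs[i].mean() - arrs[j].mean()) / se
            p = 2.0 * sps.t.sf(abs(t), df_w)
            out.append(TestResult(statistic=float(t), df=float(df_w),
                                  p_value=float(min(p, 1.0)), test="fisher_lsd",
                                  groups=(labels[i], labels[j])))
    return out


def mean_sem(x: Sequence[float]) -> tuple[float, float]:
    """Mean ± SEM summary of a sample."""
    a = np.asarray(x, dtype=float)
    sem = float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0
    return float(a.mean()), sem


# ---------------------------------------------------------------------------
# Report builder
# ---------------------------------------------------------------------------

REPORT_SCHEMA_VERSION = 1


def build_report(results: dict, *, seed: int | None = None) -> dict:
    """Assemble a deterministic report document from pipeline results.

    ``results`` maps stage names to JSON-serializable payloads (fit
    dictionaries, block tables, predictions, verdicts).  The report embeds
    the schema version, package version and seed; serializing it with
    ``json.dumps(..., sort_keys=True)`` is byte-stable for identical inputs.
    """
    if not results:
        raise ValueError("no analysis stage results to report")
    from . import __version__

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package": {"name": "navblock", "version": __version__},
        "seed": seed,
        "results": results,
    }


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=True) + "\n"


def _render(value, indent: int, lines: list[str]) -> None:
    pad = "  " * indent
    if isinstance(value, dict):
        for key in value:
            v = value[key]
            if isinstance(v, (dict, list)):
                lines.append(f"{pad}- **{key}**:")
                _render(v, indent + 1, lines)
            else:
                lines.append(f"{pad}- {key}: {_fmt(v)}")
    elif isinstance(value, list):
        for v in value:
            if isinstance(v, (dict, list)):
                _render(v, indent, lines)
                lines.append("")
            else:
                lines.append(f"{pad}- {_fmt(v)}")
    else:
        lines.append(f"{pad}{_fmt(value)}")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def render_markdown(report: dict) -> str:
    """Human-readable rendering of a report document."""
    lines = [
        "# navblock analysis report",
        "",
        f"schema {report['schema_version']}, "
        f"{report['package']['name']} {report['package']['version']}, "
        f"seed {report.get('seed')}",
        "",
    ]
    for stage, payload in report["results"].items():
        lines.append(f"## {stage}")
        lines.append("")
        _render(payload, 0, lines)
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"
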