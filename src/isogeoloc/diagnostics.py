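"""Residual diagnostics: dispersion and offset tests across data subsets.

Calibration residuals r_i = y_i - (alpha + beta e_i) carry the
non-geographic signal. Three subset comparisons matter in practice:

* H1 — assumed-origin records should show *wider* residual dispersion than
  known-origin records if origin assumptions are unreliable (variance
  comparison, Levene / Brown-Forsythe).
* H2 — laboratory and calibration differences between studies show up as
  *offsets* of the per-study mean residual (one-way ANOVA over study_id).
* H3 — tooth mineralization age affects body-water d18O, so tooth groups
  formed at different ages show offset mean residuals (ANOVA over
  tooth_group).

p-values are reported, never thresholded here; the conventional 0.05
level is annotation only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .calibration import CalibrationFit

__all__ = [
    "ResidualGroupSummary",
    "summarize_residuals",
    "test_equal_variances",
    "test_equal_means",
    "test_normality",
    "diagnostics_report",
]


class DiagnosticsError(ValueError):
    pass


@dataclass
class ResidualGroupSummary:
    group_id: str
    n: int
    mean_residual: float
    sd_residual: float


def _group_arrays(
    residuals: Sequence[float], groups: Sequence[str]
) -> dict[str, np.ndarray]:
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) != len(groups):
        raise DiagnosticsError("residuals and groups must align")
    if len(residuals) == 0:
        raise DiagnosticsError("empty residual set")
    out: dict[str, list[float]] = {}
    for r, g in zip(residuals, groups):
        out.setdefault(str(g), []).append(float(r))
    return {g: np.array(v) for g, v in out.items()}


def summarize_residuals(
    fit: CalibrationFit, grouping: Mapping[str, str]
) -> list[ResidualGroupSummary]:
    """Per-group n, mean and sd of calibration residuals.

    ``grouping`` maps sample_id -> group label and must cover every record
    in the fit. Groups are returned ordered by group_id.
    """
    if not grouping:
        raise DiagnosticsError("empty group map")
    missing = [sid for sid in fit.record_ids if sid not in grouping]
    if missing:
        raise DiagnosticsError(f"records missing from group map: {missing[:5]}")
    labels = [grouping[sid] for sid in fit.record_ids]
    by_group = _group_arrays(fit.residuals, labels)
    return [
        ResidualGroupSummary(
            group_id=g,
            n=len(v),
            mean_residual=float(v.mean()),
            sd_residual=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        )
        for g, v in sorted(by_group.items())
    ]


def test_equal_variances(
    residuals: Sequence[float],
    groups: Sequence[str],
    center: str = "median",
) -> tuple[float, int, int, float]:
    """Levene's test for homogeneity of residual variance across groups.

    Default centering is the group median (Brown-Forsythe variant, robust
    to non-normal residuals); ``center="mean"`` gives classic Levene.
    Returns (W statistic, df1, df2, p).
    """
    if center not in ("median", "mean"):
        raise DiagnosticsError("center must be 'median' or 'mean'")
    by_group = _group_arrays(residuals, groups)
    if len(by_group) < 2:
        raise DiagnosticsError("need >= 2 groups")
    arrays = list(by_group.values())
    if any(len(a) < 2 for a in arrays):
        raise DiagnosticsError("every group needs >= 2 records")
    if all(np.ptp(a) == 0 for a in arrays):
        raise DiagnosticsError("all groups have zero spread; variance test degenerate")
    stat, p = stats.levene(*arrays, center=center)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    return float(stat), k - 1, n - k, float(p)


def test_equal_means(
    residuals: Sequence[float], groups: Sequence[str]
) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA of residual means across groups.

    Returns (F, df1, df2, p) with df = (k-1, n-k). Zero within-group
    variance with unequal means yields F = +inf, p = 0.
    """
    by_group = _group_arrays(residuals, groups)
    if len(by_group) < 2:
        raise DiagnosticsError("need >= 2 groups")
    arrays = list(by_group.values())
    if any(len(a) < 2 for a in arrays):
        raise DiagnosticsError("every group needs >= 2 records")
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    if n <= k + 1:
        raise DiagnosticsError("too few records for ANOVA degrees of freedom")
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    means = [a.mean() for a in arrays]
    if ssw == 0.0:
        if max(means) > min(means):
            return float("inf"), k - 1, n - k, 0.0
        return 0.0, k - 1, n - k, 1.0
    with np.errstate(invalid="ignore"):
        f, p = stats.f_oneway(*arrays)
    return float(f), k - 1, n - k, float(p)


def test_normality(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; supported for 3 <= n <= 5000."""
    v = np.asarray(values, dtype=float)
    if not (3 <= len(v) <= 5000):
        raise DiagnosticsError(f"Shapiro-Wilk supported for 3 <= n <= 5000, got {len(v)}")
    if np.ptp(v) == 0:
        raise DiagnosticsError("constant input; normality test degenerate")
    w, p = stats.shapiro(v)
    return float(w), float(p)


def diagnostics_report(
    fit: CalibrationFit,
    grouping: Mapping[str, str],
    tests: Sequence[str] = ("variance", "means"),
    exclude_groups: Sequence[str] = (),
) -> dict:
    """JSON-ready report: per-group residual summaries plus requested tests.

    ``exclude_groups`` removes heterogeneous groups (e.g. the "Unknown"
    tooth group) from the tests while keeping them in the summaries.
    """
    summaries = summarize_residuals(fit, grouping)
    labels = [grouping[sid] for sid in fit.record_ids]
    keep = [lbl not in set(exclude_groups) for lbl in labels]
    resid = fit.residuals[np.array(keep, dtype=bool)]
    labs = [l for l, k in zip(labels, keep) if k]

    out: dict = {
        "groups": [s.__dict__ for s in summaries],
        "tests": [],
        "significance_level_note": "conventional alpha = 0.05; p-values are not thresholded",
    }
    for t in tests:
        if t == "variance":
            w, df1, df2, p = test_equal_variances(resid, labs)
            out["tests"].append(
                {"test": "levene_brown_forsythe", "statistic": w, "df1": df1, "df2": df2, "p": p}
            )
        elif t == "means":
            f, df1, df2, p = test_equal_means(resid, labs)
            fval = f if math.isfinite(f) else None
            out["tests"].append(
                {"test": "anova_one_way", "statistic": fval, "df1": df1, "df2": df2, "p": p}
            )
        elif t == "normality":
            w, p = test_normality(resid)
            out["tests"].append({"test": "shapiro_wilk", "statistic": w, "p": p})
        else:
            raise DiagnosticsError(f"unknown test {t!r}")
    return out


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2)
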