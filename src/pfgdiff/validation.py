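"""Model-validation rules: the rescaling checks that decide which attenuation
formula may legitimately be fitted to a set of PFG curves.

Gaussian processes with stationary increments attenuate proportionally to
g^2 and, after delta^-2 rescaling, differ between two pulse durations by a
Delta-independent constant. Superstatistical (Brownian yet non-Gaussian)
signals instead depend on the acquisition only through the b value. The
checks quantify those signatures:

* ``g2_collapse_check``   — curves at equal delta, different g, rescaled by
  1/g^2 must collapse;
* ``delta_f_check``       — f(delta1, delta2) = (gamma g)^-2 [delta1^-2 lnS1 -
  delta2^-2 lnS2] must be Delta-independent;
* ``b_collapse_check``    — curves re-indexed by b must collapse;
* ``classify``            — the decision flowchart: Gaussian-stationary pass ->
  derivative trend -> Brownian/anomalous formula; fail -> b collapse ->
  superstatistical formulas; fail -> no formula applies.

The collapse thresholds are engineering defaults (the underlying analysis
discriminates visually); every report echoes the threshold used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .engine import AttenuationCurve
from .fitting import classify_trend, log_derivative, pooled_trend

__all__ = [
    "ValidationReport",
    "g2_collapse_check",
    "delta_f_check",
    "b_collapse_check",
    "classify",
    "COLLAPSE_THRESHOLD",
    "DRIFT_THRESHOLD",
]

COLLAPSE_THRESHOLD = 0.05   # normalized RMS pairwise difference
DRIFT_THRESHOLD = 0.1       # relative drift of f(delta1, delta2) over the window
REL_ERR_MAX = 0.10          # per-point relative signal error admitted to checks


def _usable(c: AttenuationCurve, rel_err_max: float = REL_ERR_MAX) -> AttenuationCurve:
    """Non-flagged points with tolerable noise (no-op for analytic curves)."""
    if c.stderr is None and c.noise_sigma is None:
        return c.good()
    return c.reliable(rel_err_max)


@dataclass
class ValidationReport:
    check: str
    statistic: float
    threshold: float
    verdict: bool                 # True = pass
    details: dict = field(default_factory=dict)
    classification: str | None = None
    recommended_formula: str | None = None

    def __str__(self) -> str:
        out = [f"check: {self.check}",
               f"statistic: {self.statistic:.6g} (threshold {self.threshold:g})",
               f"verdict: {'pass' if self.verdict else 'fail'}"]
        if self.classification is not None:
            out.append(f"classification: {self.classification}")
            out.append(f"recommended formula: {self.recommended_formula}")
        for k, v in self.details.items():
            out.append(f"{k}: {v}")
        return "\n".join(out)


def _common_support(xs: list[np.ndarray]):
    """Union of sample points inside the shared [max(min), min(max)] range."""
    lo = max(float(x[0]) for x in xs)
    hi = min(float(x[-1]) for x in xs)
    if hi <= lo:
        raise ValueError("curves share no common support")
    pooled = np.unique(np.concatenate(xs))
    return pooled[(pooled >= lo) & (pooled <= hi)]


def _pairwise_collapse(xs, ys, grid, ses=None):
    """Normalized RMS of pairwise differences after linear interpolation of
    each curve onto ``grid`` (never extrapolating — grid is inside every
    curve's range).

    When per-point standard errors ``ses`` are supplied (same rescaling as
    ``ys``), the expected Monte-Carlo contribution to the squared difference
    is subtracted before normalizing, so the statistic estimates the *true*
    curve separation rather than separation-plus-noise and stays comparable
    to the analytic-curve thresholds at any ensemble size.
    """
    interp = [np.interp(grid, x, y) for x, y in zip(xs, ys)]
    diff2 = []
    noise2 = []
    if ses is None:
        ses = [None] * len(interp)
    se_interp = [None if s is None else np.interp(grid, x, s)
                 for x, s in zip(xs, ses)]
    for (i, u), (j, v) in combinations(enumerate(interp), 2):
        diff2.append(np.square(u - v))
        si, sj = se_interp[i], se_interp[j]
        if si is not None and sj is not None:
            noise2.append(si * si + sj * sj)
        else:
            noise2.append(np.zeros_like(u))
    rms2_diff = float(np.mean(diff2))
    rms2_noise = float(np.mean(noise2))
    rms_mag = math.sqrt(float(np.mean(np.square(interp))))
    if rms_mag == 0:
        return 0.0
    return math.sqrt(max(rms2_diff - rms2_noise, 0.0)) / rms_mag


def g2_collapse_check(curves: list[AttenuationCurve],
                      threshold: float = COLLAPSE_THRESHOLD) -> ValidationReport:
    """Collapse of g^-2-rescaled log-signals across gradient strengths."""
    if len(curves) < 2:
        raise ValueError("g2_collapse_check needs >= 2 curves")
    deltas = {round(c.delta, 12) for c in curves}
    if len(deltas) != 1:
        raise ValueError("g2_collapse_check requires equal delta across curves")
    if len({round(c.g, 12) for c in curves}) < 2:
        raise ValueError("g2_collapse_check requires >= 2 distinct g values")
    curves = [_usable(c) for c in curves]
    grid = _common_support([c.Delta for c in curves])
    ses = [None if c.stderr is None else (c.stderr / np.abs(c.S)) / c.g ** 2
           for c in curves]
    stat = _pairwise_collapse([c.Delta for c in curves],
                              [c.lnS / c.g ** 2 for c in curves], grid, ses)
    return ValidationReport(
        check="g2_collapse", statistic=stat, threshold=threshold,
        verdict=stat < threshold,
        details={"g_values": sorted(c.g for c in curves),
                 "n_common": int(grid.size)})


def delta_f_check(curves: list[AttenuationCurve],
                  threshold: float = DRIFT_THRESHOLD) -> ValidationReport:
    """Delta-independence of f(delta1, delta2) across two pulse durations."""
    if len(curves) != 2:
        raise ValueError("delta_f_check takes exactly 2 curves")
    c1, c2 = (_usable(c) for c in curves)
    if abs(c1.g - c2.g) > 1e-12 * max(c1.g, 1e-30):
        raise ValueError("delta_f_check requires equal g")
    if abs(c1.gamma - c2.gamma) > 1e-6 * c1.gamma:
        raise ValueError("delta_f_check requires equal gamma")
    grid = _common_support([c1.Delta, c2.Delta])
    y1 = np.interp(grid, c1.Delta, c1.lnS) / c1.delta ** 2
    y2 = np.interp(grid, c2.Delta, c2.lnS) / c2.delta ** 2
    f = (y1 - y2) / (c1.gamma * c1.g) ** 2

    if abs(c1.delta - c2.delta) < 1e-12:
        return ValidationReport(
            check="delta_f_constancy", statistic=0.0, threshold=threshold,
            verdict=True,
            details={"warning": "degenerate: delta1 == delta2, f is identically 0",
                     "n_common": int(grid.size)})

    mean_f = float(np.mean(f))
    res = stats.linregress(grid, f)
    if mean_f == 0.0:
        stat = 0.0
    else:
        stat = abs(res.slope) * (grid[-1] - grid[0]) / abs(mean_f)
    return ValidationReport(
        check="delta_f_constancy", statistic=float(stat), threshold=threshold,
        verdict=stat < threshold,
        details={"mean_f": mean_f, "slope": float(res.slope),
                 "deltas": (c1.delta, c2.delta), "n_common": int(grid.size)})


def b_collapse_check(curves: list[AttenuationCurve],
                     threshold: float = COLLAPSE_THRESHOLD) -> ValidationReport:
    """Collapse of the curves re-indexed by the b value."""
    if len(curves) < 2:
        raise ValueError("b_collapse_check needs >= 2 curves")
    conds = {(round(c.g, 12), round(c.delta, 12)) for c in curves}
    if len(conds) < 2:
        raise ValueError("b_collapse_check requires >= 2 distinct (g, delta) conditions")
    curves = [_usable(c) for c in curves]
    bs = [c.b for c in curves]
    grid = _common_support(bs)
    ses = [None if c.stderr is None else c.stderr / np.abs(c.S) for c in curves]
    stat = _pairwise_collapse(bs, [c.lnS for c in curves], grid, ses)
    return ValidationReport(
        check="b_collapse", statistic=stat, threshold=threshold,
        verdict=stat < threshold,
        details={"conditions": sorted(conds), "n_common": int(grid.size)})


def classify(curves: list[AttenuationCurve],
             collapse_threshold: float = COLLAPSE_THRESHOLD,
             drift_threshold: float = DRIFT_THRESHOLD,
             ci_level: float = 0.95) -> ValidationReport:
    """Run the full validation flowchart on a multi-condition curve set.

    Requires at least two acquisition conditions (two gradient strengths at
    equal pulse duration, and/or two pulse durations at equal gradient).
    """
    if len(curves) < 2:
        raise ValueError(
            "classification needs >= 2 acquisition conditions "
            "(two g values at equal delta, or two delta values at equal g)")

    # group curves for the Gaussian-stationary checks
    sub_reports: list[ValidationReport] = []
    by_delta: dict = {}
    for c in curves:
        by_delta.setdefault(round(c.delta, 12), []).append(c)
    for group in by_delta.values():
        if len({round(c.g, 12) for c in group}) >= 2:
            sub_reports.append(g2_collapse_check(group, collapse_threshold))
    by_g: dict = {}
    for c in curves:
        by_g.setdefault(round(c.g, 12), []).append(c)
    for group in by_g.values():
        seen = {}
        for c in group:
            seen.setdefault(round(c.delta, 12), c)
        ds = sorted(seen)
        for d1, d2 in combinations(ds, 2):
            sub_reports.append(delta_f_check([seen[d1], seen[d2]], drift_threshold))

    if not sub_reports:
        raise ValueError(
            "cannot classify: no usable condition pair (need two g values at "
            "equal delta, or two delta values at equal g)")

    details = {r.check + f"[{i}]": f"{r.statistic:.4g} "
               f"({'pass' if r.verdict else 'fail'})"
               for i, r in enumerate(sub_reports)}
    gaussian_stationary = all(r.verdict for r in sub_reports)
    stat = max(r.statistic for r in sub_reports)

    if gaussian_stationary:
        dcurves = [log_derivative(_usable(c)) for c in curves]
        trend = pooled_trend(dcurves, ci_level=ci_level)
        details["derivative_trends"] = [classify_trend(dc) for dc in dcurves]
        details["pooled_trend"] = trend
        label = {
            "normal": ("gaussian_stationary_normal", "Eq22"),
            "subdiffusive": ("gaussian_stationary_subdiffusive", "Eq24"),
            "superdiffusive": ("gaussian_stationary_superdiffusive", "Eq24"),
            "unclassified": ("unclassified", "none"),
        }[trend]
        return ValidationReport(
            check="flowchart", statistic=stat, threshold=collapse_threshold,
            verdict=True, details=details,
            classification=label[0], recommended_formula=label[1])

    b_rep = b_collapse_check(curves, collapse_threshold)
    details["b_collapse"] = (f"{b_rep.statistic:.4g} "
                             f"({'pass' if b_rep.verdict else 'fail'})")
    if b_rep.verdict:
        return ValidationReport(
            check="flowchart", statistic=b_rep.statistic,
            threshold=collapse_threshold, verdict=True, details=details,
            classification="brownian_non_gaussian",
            recommended_formula="Eq28/29")
    return ValidationReport(
        check="flowchart", statistic=b_rep.statistic,
        threshold=collapse_threshold, verdict=False, details=details,
        classification="unclassified", recommended_formula="none")
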