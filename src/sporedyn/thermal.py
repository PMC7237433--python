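"""Thermal analysis of MSD series: force constants, breakpoints, ratios.

The effective force constant (resilience) follows from the temperature
slope of the mean square displacement,

    <k> = 0.00276 / (d<u2>/dT)        [N/m, <u2> in A^2, T in K],

with the coefficient corresponding to ~2 k_B in these units.  A slope
consistent with zero at one sigma gives a meaningless force constant and
is flagged as such rather than suppressed.

Germination shows up as an abrupt steepening of the low-Q MSD (and a
drop of the summed intensities) above a threshold temperature; it is
localized with a continuous two-segment (hinge) fit whose breakpoint is
searched over the interior data temperatures.  Mutant/wild-type MSD
ratios are averaged over the temperatures shared by both series, with
the across-temperature spread quoted as the uncertainty (a propagated
measurement error is reported alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .constants import FORCE_CONSTANT_COEFF
from .msd import MSDSeries, QWindow

__all__ = ["ForceConstantResult", "BreakpointResult", "RatioResult",
           "fit_force_constant", "detect_breakpoint", "msd_ratio", "build_report"]

logger = logging.getLogger(__name__)


def _weighted_line(x: np.ndarray, y: np.ndarray, sigma: np.ndarray):
    """Weighted LS line fit; returns slope, intercept, their variances, SSE."""
    w = 1.0 / sigma**2
    S, Sx, Sy = w.sum(), (w * x).sum(), (w * y).sum()
    Sxx, Sxy = (w * x * x).sum(), (w * x * y).sum()
    delta = S * Sxx - Sx * Sx
    slope = (S * Sxy - Sx * Sy) / delta
    intercept = (Sxx * Sy - Sx * Sxy) / delta
    sse = float((w * (y - intercept - slope * x) ** 2).sum())
    return slope, intercept, S / delta, Sxx / delta, sse


@dataclass
class ForceConstantResult:
    """Effective force constant over one temperature range and Q window."""

    k: float                 # N/m; NaN when the slope is not positive
    k_error: float           # N/m, first-order propagation
    slope: float             # d<u2>/dT, A^2/K
    slope_error: float
    T_range: tuple
    window: QWindow
    meaningless: bool        # slope consistent with <= 0 at 1 sigma
    n_points: int
    label: str = ""


def fit_force_constant(series: MSDSeries, T_range: tuple | None = None,
                       weighted: bool = True) -> ForceConstantResult:
    """Fit msd vs T over ``T_range`` and convert the slope to <k>.

    k = 0.00276 / slope and k_error = 0.00276 * slope_error / slope^2.
    When the slope is not positive, k is reported as NaN; when the slope
    does not exceed its own one-sigma error the result is flagged
    ``meaningless`` (the sample is evolving or statistics are too poor
    for the resilience to be interpretable).
    """
    if T_range is None:
        T_range = (float(series.T.min()), float(series.T.max()))
    lo, hi = float(T_range[0]), float(T_range[1])
    sel = (series.T >= lo - 1e-9) & (series.T <= hi + 1e-9)
    if np.sum(sel) < 3:
        raise ValueError(f"need >= 3 MSD records in T range [{lo}, {hi}]")
    sigma = series.msd_error[sel] if weighted else np.ones(int(np.sum(sel)))
    slope, _, var_slope, _, _ = _weighted_line(series.T[sel], series.msd[sel], sigma)
    slope_err = float(np.sqrt(var_slope))
    meaningless = slope <= slope_err
    if slope > 0:
        k = FORCE_CONSTANT_COEFF / slope
        k_err = FORCE_CONSTANT_COEFF * slope_err / slope**2
    else:
        k, k_err = float("nan"), float("nan")
        logger.warning("%s/%s: non-positive MSD slope, force constant undefined",
                       series.label, series.window.name)
    return ForceConstantResult(k=k, k_error=k_err, slope=float(slope),
                               slope_error=slope_err, T_range=(lo, hi),
                               window=series.window, meaningless=bool(meaningless),
                               n_points=int(np.sum(sel)), label=series.label)


@dataclass
class BreakpointResult:
    """Continuous two-segment fit of a thermal series."""

    T_b: float | None
    segments: list            # [(T_range, slope, slope_error, k), ...]
    delta_sse: float
    significant: bool
    p_value: float
    sse_single: float
    sse_hinge: float
    label: str = ""


def _hinge_fit(T: np.ndarray, y: np.ndarray, sigma: np.ndarray, T_b: float):
    w = 1.0 / sigma
    X = np.column_stack([np.ones_like(T), T, np.maximum(T - T_b, 0.0)])
    beta, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
    resid = (y - X @ beta) / sigma
    sse = float(resid @ resid)
    XtWX = (X * (w**2)[:, None]).T @ X
    cov = np.linalg.inv(XtWX)
    return beta, cov, sse


def detect_breakpoint(series: MSDSeries | pd.DataFrame, alpha: float = 0.05,
                      min_per_side: int = 3) -> BreakpointResult:
    """Locate a slope change with a continuous piecewise-linear (hinge) fit.

    Candidate breakpoints are the interior data temperatures leaving at
    least ``min_per_side`` points on each side (the breakpoint belongs to
    both segments); the one minimizing the total weighted SSE wins.
    Significance compares the hinge fit to a single line with an F-style
    test (2 extra parameters), Bonferroni-corrected for the number of
    candidates searched.  With no admissible candidate, the single-line
    result is returned with ``significant=False``.

    Accepts an :class:`MSDSeries` or any DataFrame with columns
    ``T``/value/error (e.g. a relative summed-intensity table).
    """
    if isinstance(series, MSDSeries):
        T, y, sigma = series.T, series.msd, series.msd_error
        window, label = series.window, series.label
    else:
        df = series
        value_col = "percent" if "percent" in df.columns else "msd"
        err_col = "error" if "error" in df.columns else "msd_error"
        T = df["T"].to_numpy(float)
        y = df[value_col].to_numpy(float)
        sigma = df[err_col].to_numpy(float)
        sigma = np.where(sigma > 0, sigma, np.max(sigma[sigma > 0], initial=1.0))
        window, label = None, ""
    n = T.size
    if n < 7:
        raise ValueError("breakpoint detection needs at least 7 records")
    slope0, icpt0, var0, _, sse0 = _weighted_line(T, y, sigma)

    candidates = [T[i] for i in range(n) if i + 1 >= min_per_side and n - i >= min_per_side
                  and 0 < i < n - 1]
    if not candidates:
        return BreakpointResult(T_b=None, segments=[_segment(T, slope0, np.sqrt(var0), (T[0], T[-1]))],
                                delta_sse=0.0, significant=False, p_value=1.0,
                                sse_single=sse0, sse_hinge=sse0, label=label)

    best = None
    for T_b in candidates:
        beta, cov, sse = _hinge_fit(T, y, sigma, T_b)
        if best is None or sse < best[0]:
            best = (sse, T_b, beta, cov)
    sse_b, T_b, beta, cov = best
    dof = n - 4  # intercept, slope, hinge coefficient, searched breakpoint
    if dof <= 0 or sse_b <= 0:
        p = 0.0 if sse_b < sse0 else 1.0
    else:
        F = ((sse0 - sse_b) / 2.0) / (sse_b / dof)
        p = float(stats.f.sf(F, 2, dof))
    significant = p < alpha / len(candidates)

    slope_left, slope_right = beta[1], beta[1] + beta[2]
    err_left = float(np.sqrt(cov[1, 1]))
    err_right = float(np.sqrt(cov[1, 1] + cov[2, 2] + 2 * cov[1, 2]))
    segments = [_segment(T, slope_left, err_left, (float(T[0]), float(T_b))),
                _segment(T, slope_right, err_right, (float(T_b), float(T[-1])))]
    return BreakpointResult(T_b=float(T_b), segments=segments,
                            delta_sse=float(sse0 - sse_b), significant=bool(significant),
                            p_value=p, sse_single=sse0, sse_hinge=sse_b, label=label)


def _segment(T, slope, slope_err, T_range):
    k = FORCE_CONSTANT_COEFF / slope if slope > 0 else float("nan")
    return {"T_range": T_range, "slope": float(slope), "slope_error": float(slope_err),
            "k": k}


@dataclass
class RatioResult:
    """Temperature-averaged mutant / wild-type MSD ratio in one window."""

    ratio_mean: float
    ratio_sd: float              # across-temperature spread (quoted +/-)
    ratio_propagated_error: float  # alternative: propagated measurement error
    per_T: pd.DataFrame
    window: QWindow
    T_range: tuple
    pair: tuple = ("mutant", "wildtype")


def msd_ratio(mutant: MSDSeries, wildtype: MSDSeries,
              T_range: tuple | None = None) -> RatioResult:
    """Per-temperature mutant/wild-type MSD ratio, averaged over temperature.

    Only temperatures present in both series (inside ``T_range``) enter.
    Each per-T ratio carries the quadrature of the two relative errors;
    the headline number is the unweighted mean with the across-temperature
    standard deviation as its spread.  Temperatures where the wild-type
    MSD is not positive are dropped with a warning.
    """
    shared, im, iw = np.intersect1d(mutant.T, wildtype.T, return_indices=True)
    if T_range is not None:
        sel = (shared >= T_range[0] - 1e-9) & (shared <= T_range[1] + 1e-9)
        shared, im, iw = shared[sel], im[sel], iw[sel]
    ok = wildtype.msd[iw] > 0
    if np.any(~ok):
        logger.warning("dropping %d temperatures with non-positive wild-type MSD",
                       int(np.sum(~ok)))
    shared, im, iw = shared[ok], im[ok], iw[ok]
    if shared.size < 3:
        raise ValueError("need >= 3 shared temperatures for an MSD ratio")
    ratio = mutant.msd[im] / wildtype.msd[iw]
    rel = np.hypot(mutant.msd_error[im] / np.abs(mutant.msd[im]),
                   wildtype.msd_error[iw] / wildtype.msd[iw])
    ratio_err = np.abs(ratio) * rel
    per_T = pd.DataFrame({"T": shared, "ratio": ratio, "ratio_error": ratio_err})
    mean = float(ratio.mean())
    sd = float(ratio.std(ddof=1))
    propagated = float(np.sqrt(np.sum(ratio_err**2)) / shared.size)
    return RatioResult(ratio_mean=mean, ratio_sd=sd, ratio_propagated_error=propagated,
                       per_T=per_T, window=mutant.window,
                       T_range=(float(shared.min()), float(shared.max())),
                       pair=(mutant.label, wildtype.label))


def build_report(force_constants: list, ratios: list,
                 outdir: str | Path | None = None) -> dict:
    """Assemble tab-separated summary tables of force constants and ratios.

    Returns ``{"force_constants": DataFrame, "ratios": DataFrame | None,
    "summary": str}`` and, when ``outdir`` is given, writes
    ``force_constants.tsv``, ``ratios.tsv`` and ``summary.txt``.
    An empty ratio list omits the ratio table with a notice.
    """
    if not force_constants and not ratios:
        raise ValueError("nothing to report")
    fc_rows = []
    for r in force_constants:
        fc_rows.append({
            "sample": r.label,
            "window": r.window.name,
            "T_range": f"[{r.T_range[0]:g}-{r.T_range[1]:g} K]",
            "k_N_per_m": r.k,
            "k_error": r.k_error,
            "slope_A2_per_K": r.slope,
            "slope_error": r.slope_error,
            "flags": "meaningless" if r.meaningless else "",
        })
    fc_table = pd.DataFrame(fc_rows)
    ratio_table = None
    if ratios:
        ratio_table = pd.DataFrame([{
            "pair": f"{r.pair[0]}/{r.pair[1]}",
            "window": r.window.name,
            "T_range": f"[{r.T_range[0]:g}-{r.T_range[1]:g} K]",
            "ratio": r.ratio_mean,
            "ratio_sd": r.ratio_sd,
            "ratio_propagated_error": r.ratio_propagated_error,
        } for r in ratios])

    lines = ["Effective force constants (N/m):"]
    for row in fc_rows:
        flag = " *" if row["flags"] else ""
        lines.append(f"  {row['sample']:<16} {row['window']:<5} {row['T_range']:<16} "
                     f"k = {row['k_N_per_m']:.3g} +/- {row['k_error']:.2g}{flag}")
    if any(r["flags"] for r in fc_rows):
        lines.append("  * slope within 1 sigma of zero: force constant meaningless")
    if ratio_table is not None:
        lines.append("MSD ratios (mutant / wild-type):")
        for _, row in ratio_table.iterrows():
            lines.append(f"  {row['pair']:<28} {row['window']:<5} "
                         f"{row['ratio']:.2f} +/- {row['ratio_sd']:.2f}")
    else:
        lines.append("No ratio pairs declared; ratio table omitted.")
    summary = "\n".join(lines) + "\n"

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fc_table.to_csv(outdir / "force_constants.tsv", sep="\t", index=False,
                        float_format="%.6g")
        if ratio_table is not None:
            ratio_table.to_csv(outdir / "ratios.tsv", sep="\t", index=False,
                               float_format="%.6g")
        (outdir / "summary.txt").write_text(summary, encoding="utf-8")
    return {"force_constants": fc_table, "ratios": ratio_table, "summary": summary}
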