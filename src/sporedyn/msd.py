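"""Mean-square-displacement extraction via the Gaussian approximation.

Within the Gaussian approximation the elastic incoherent intensity falls
off with momentum transfer as

    I(Q, T) ~ I0(T) * exp(-<u2>(T) * Q^2 / 6),

so ln I is linear in Q^2 with slope -<u2>/6.  Each temperature row is
fitted by weighted least squares of ln I on Q^2 inside a configurable Q
window; the weights are (I / sigma_I)^2, the delta-method variance of
ln I under counting statistics.  The intercept ln I0 is free.

Two windows are used by convention: "low Q" (0.5-1.67 A^-1), sensitive
to large-amplitude/diffusive motions, and "high Q" (1.4-2.02 A^-1),
dominated by local macromolecular motions.  The windows deliberately
overlap.  Window membership is closed-interval; non-positive intensities
are dropped before the log and a temperature record is only emitted when
at least three points survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reduction import ReductionConfig
from .scans import ElasticScan

__all__ = ["QWindow", "LOW_Q", "HIGH_Q", "MSDSeries",
           "fit_msd_at_temperature", "extract_msd_series"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QWindow:
    """Closed Q interval [q_min, q_max] (A^-1) used for the Gaussian fits."""

    q_min: float
    q_max: float
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.q_min < self.q_max:
            raise ValueError("require 0 < q_min < q_max")

    def contains(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return (q >= self.q_min - 1e-12) & (q <= self.q_max + 1e-12)


#: Default windows: low Q probes large-amplitude motions, high Q local ones.
LOW_Q = QWindow(0.5, 1.67, "low")
HIGH_Q = QWindow(1.4, 2.02, "high")


@dataclass
class MSDSeries:
    """Per-temperature <u2> (A^2) extracted in one Q window."""

    window: QWindow
    T: np.ndarray
    msd: np.ndarray
    msd_error: np.ndarray
    intercept: np.ndarray
    n_points: np.ndarray
    chi2_reduced: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if np.any(np.diff(self.T) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(np.asarray(self.msd_error) <= 0):
            raise ValueError("msd_error must be positive")
        if np.any(np.asarray(self.n_points) < 3):
            raise ValueError("each record needs at least 3 fitted points")

    def __len__(self) -> int:
        return self.T.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "T": self.T, "msd": self.msd, "msd_error": self.msd_error,
            "ln_I0": self.intercept, "n_points": self.n_points,
            "chi2_reduced": self.chi2_reduced,
        })

    def to_tsv(self, path) -> None:
        header = (f"# window: {self.window.name} [{self.window.q_min}, {self.window.q_max}]\n"
                  f"# label: {self.label}\n"
                  "# weighting: (I/sigma)^2 on ln I\n")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, sep="\t", index=False)


def fit_msd_at_temperature(q: np.ndarray, intensity: np.ndarray, error: np.ndarray,
                           window: QWindow, weighted: bool = True):
    """Weighted linear fit of ln I on Q^2 in one window; msd = -6 * slope.

    Returns ``(msd, msd_error, intercept, diagnostics)`` where diagnostics
    holds the point count, reduced chi-square and the slope/intercept
    covariance from the analytic normal equations.  Returns ``None`` when
    fewer than three positive-intensity points fall inside the window.
    """
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    error = np.asarray(error, dtype=float)
    sel = window.contains(q) & (intensity > 0) & (error > 0)
    if np.sum(sel) < 3:
        logger.info("window %s: only %d usable points, record skipped",
                    window.name or f"[{window.q_min},{window.q_max}]", int(np.sum(sel)))
        return None
    x = q[sel] ** 2
    y = np.log(intensity[sel])
    w = (intensity[sel] / error[sel]) ** 2 if weighted else np.ones(x.size)

    S = w.sum()
    Sx = (w * x).sum()
    Sy = (w * y).sum()
    Sxx = (w * x * x).sum()
    Sxy = (w * x * y).sum()
    delta = S * Sxx - Sx * Sx
    slope = (S * Sxy - Sx * Sy) / delta
    intercept = (Sxx * Sy - Sx * Sxy) / delta
    var_slope = S / delta
    var_intercept = Sxx / delta
    cov = -Sx / delta
    resid = y - (intercept + slope * x)
    n = x.size
    chi2_red = float((w * resid**2).sum() / (n - 2)) if n > 2 else np.nan
    diagnostics = {
        "n_points": int(n),
        "chi2_reduced": chi2_red,
        "cov": np.array([[var_intercept, cov], [cov, var_slope]]),
    }
    return -6.0 * slope, 6.0 * np.sqrt(var_slope), intercept, diagnostics


def extract_msd_series(scan: ElasticScan, window: QWindow,
                       config: ReductionConfig | None = None,
                       weighted: bool = True) -> MSDSeries:
    """Fit every temperature row of a reduced scan in the given window.

    Q values on the exclusion list (and masked detectors) are never used.
    Temperatures with fewer than three usable points are skipped with a
    logged reason; an entirely empty series is a hard error.
    """
    config = config or ReductionConfig()
    keep = config.usable_q(scan.q, scan.meta)
    rows = []
    for i, T in enumerate(scan.T):
        fit = fit_msd_at_temperature(scan.q[keep], scan.intensity[i, keep],
                                     scan.error[i, keep], window, weighted=weighted)
        if fit is None:
            logger.warning("%s: T=%g K skipped in window %s", scan.label or "scan",
                           T, window.name)
            continue
        msd, msd_err, intercept, diag = fit
        rows.append((T, msd, msd_err, intercept, diag["n_points"], diag["chi2_reduced"]))
    if not rows:
        raise ValueError(f"no usable temperature records in window {window.name!r}")
    arr = list(zip(*rows))
    return MSDSeries(window=window, T=np.array(arr[0]), msd=np.array(arr[1]),
                     msd_error=np.array(arr[2]), intercept=np.array(arr[3]),
                     n_points=np.array(arr[4]), chi2_reduced=np.array(arr[5]),
                     label=scan.label)
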