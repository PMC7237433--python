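"""Container and plain-text I/O for fixed-window elastic scans.

An :class:`ElasticScan` holds the elastic intensity and its one-sigma
counting error on a temperature x momentum-transfer grid, together with
free-form metadata (sample label, geometry, transmission, ...).

Scans are stored on disk as UTF-8 tab-separated text: a header block of
``# key: value`` metadata lines, then one row per (T, Q) pair with
columns ``T  Q  intensity  error``.  Rows are written T-major.  Unknown
metadata keys survive a read/write round trip verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

__all__ = ["ElasticScan", "ScanFormatError", "read_scan", "write_scan"]

VALID_KINDS = ("sample", "vanadium", "empty")


class ScanFormatError(ValueError):
    """Raised when a scan file cannot be parsed."""


@dataclass
class ElasticScan:
    """Elastic intensity matrix on a Q x T grid.

    Parameters
    ----------
    q : ndarray, shape (nq,)
        Strictly increasing momentum-transfer grid, A^-1.
    T : ndarray, shape (nT,)
        Strictly increasing temperature grid, K.
    intensity : ndarray, shape (nT, nq)
        Elastic counts (or corrected intensities).
    error : ndarray, shape (nT, nq)
        One-sigma uncertainties; positive wherever intensity is positive.
    kind : str
        One of ``sample``, ``vanadium``, ``empty``.
    meta : dict
        Free-form metadata (label, geometry, transmission, provenance).
    """

    q: np.ndarray
    T: np.ndarray
    intensity: np.ndarray
    error: np.ndarray
    kind: str = "sample"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.intensity = np.atleast_2d(np.asarray(self.intensity, dtype=float))
        self.error = np.atleast_2d(np.asarray(self.error, dtype=float))
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}, got {self.kind!r}")
        if self.q.ndim != 1 or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be a strictly increasing 1-d grid")
        if self.T.ndim != 1 or np.any(np.diff(self.T) <= 0):
            raise ValueError("T must be a strictly increasing 1-d grid")
        if self.kind == "sample" and self.T.size < 2:
            raise ValueError("sample scans require at least two temperatures")
        shape = (self.T.size, self.q.size)
        if self.intensity.shape != shape or self.error.shape != shape:
            raise ValueError(
                f"intensity/error must have shape {shape}, got "
                f"{self.intensity.shape} / {self.error.shape}"
            )
        if not (np.all(np.isfinite(self.intensity)) and np.all(np.isfinite(self.error))):
            raise ValueError("non-finite intensity or error")

    @property
    def label(self) -> str:
        return str(self.meta.get("label", ""))

    def copy(self, **replacements) -> "ElasticScan":
        out = ElasticScan(
            q=self.q.copy(),
            T=self.T.copy(),
            intensity=self.intensity.copy(),
            error=self.error.copy(),
            kind=self.kind,
            meta=dict(self.meta),
        )
        for k, v in replacements.items():
            setattr(out, k, v)
        return out


def write_scan(scan: ElasticScan, path: str | Path) -> Path:
    """Write a scan to tab-separated text (C locale, UTF-8)."""
    path = Path(path)
    lines = [f"# kind: {scan.kind}"]
    for key, value in scan.meta.items():
        lines.append(f"# {key}: {value}")
    lines.append("# columns: T\tQ\tintensity\terror")
    for i, t in enumerate(scan.T):
        for j, q in enumerate(scan.q):
            lines.append(
                f"{t:.6g}\t{q:.10g}\t{scan.intensity[i, j]:.12g}\t{scan.error[i, j]:.12g}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_scan(path: str | Path) -> ElasticScan:
    """Read a scan written by :func:`write_scan`.

    Raises :class:`ScanFormatError` naming the offending line on malformed
    rows, incomplete grids or non-finite intensities.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    kind = "sample"
    rows: list[tuple[float, float, float, float]] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key, value = key.strip(), value.strip()
                if key == "kind":
                    kind = value
                elif key != "columns":
                    meta[key] = value
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ScanFormatError(f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}")
        try:
            t, q, inten, err = (float(p) for p in parts)
        except ValueError as exc:
            raise ScanFormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        if not (np.isfinite(inten) and np.isfinite(err)):
            raise ScanFormatError(f"{path}:{lineno}: non-finite intensity or error")
        rows.append((t, q, inten, err))
    if not rows:
        raise ScanFormatError(f"{path}: no data rows")
    arr = np.array(rows)
    T = np.unique(arr[:, 0])
    q = np.unique(arr[:, 1])
    if arr.shape[0] != T.size * q.size:
        raise ScanFormatError(
            f"{path}: {arr.shape[0]} data rows do not fill a {T.size}x{q.size} grid"
        )
    intensity = np.full((T.size, q.size), np.nan)
    error = np.full((T.size, q.size), np.nan)
    ti = np.searchsorted(T, arr[:, 0])
    qi = np.searchsorted(q, arr[:, 1])
    intensity[ti, qi] = arr[:, 2]
    error[ti, qi] = arr[:, 3]
    if np.any(np.isnan(intensity)):
        raise ScanFormatError(f"{path}: duplicate or missing (T, Q) rows")
    return ElasticScan(q=q, T=T, intensity=intensity, error=error, kind=kind, meta=meta)
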