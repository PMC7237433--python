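"""Raw elastic-scan reduction: transmission, absorption, empty-cell and vanadium.

The correction chain mirrors standard practice on a thermal backscattering
spectrometer with flat-slab sample cells:

1. a transmission check (samples should transmit >= 90% of the beam so
   that multiple scattering stays negligible),
2. Paalman-Pings absorption coefficients for a slab sample inside a slab
   container, computed by numerical integration over the scattering depth,
3. empty-cell subtraction combining sample and empty scans with those
   coefficients,
4. division by a vanadium scan to cancel detector efficiencies and
   geometry factors,
5. relative summed intensities (thermograms): per-temperature sums over
   all usable detectors, normalized to the lowest temperature and quoted
   in percent.

Geometry convention: the slab normal makes an angle ``tilt`` with the
incident beam (default 45 deg, i.e. the slab plane at 135 deg to the
beam); the container is modelled as two identical windows of thickness
``d_c / 2`` on either side of the sample.  Scattering angles whose exit
ray lies in the slab plane are rejected rather than approximated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .constants import DEFAULT_WAVELENGTH
from .scans import ElasticScan

__all__ = [
    "SlabGeometry",
    "AbsorptionCoefficients",
    "ReductionConfig",
    "transmission",
    "q_to_two_theta",
    "paalman_pings_slab",
    "coefficients_for_scan",
    "subtract_empty_cell",
    "normalize_to_vanadium",
    "relative_summed_intensity",
    "q_to_length",
]

logger = logging.getLogger(__name__)

#: Exit rays making an angle smaller than this (deg) with the slab plane
#: are rejected: path lengths diverge in that transmission-edge geometry.
_EDGE_ANGLE_DEG = 1.0


@dataclass(frozen=True)
class SlabGeometry:
    """Flat-slab sample in a flat container.

    mu_s, mu_c : linear attenuation coefficients (cm^-1)
    d_s, d_c   : sample thickness / total container wall thickness (cm)
    tilt       : angle of the slab normal to the incident beam (deg)
    """

    mu_s: float = 2.0
    mu_c: float = 0.1
    d_s: float = 0.02
    d_c: float = 0.1
    tilt: float = 45.0

    def __post_init__(self) -> None:
        if self.d_s <= 0 or self.d_c <= 0:
            raise ValueError("thicknesses must be positive")
        if self.mu_s < 0 or self.mu_c < 0:
            raise ValueError("attenuation coefficients must be non-negative")
        if abs(self.tilt) >= 90.0:
            raise ValueError("|tilt| must be < 90 deg (slab normal to beam)")


@dataclass
class AbsorptionCoefficients:
    """Per-angle Paalman-Pings attenuation factors for a slab in a container.

    A_ss  : scattering in the sample, attenuated by the sample
    A_ssc : scattering in the sample, attenuated by sample + container
    A_csc : scattering in the container, attenuated by sample + container
    A_cc  : scattering in the container, attenuated by the container
    """

    two_theta: np.ndarray
    A_ss: np.ndarray
    A_ssc: np.ndarray
    A_csc: np.ndarray
    A_cc: np.ndarray

    def __post_init__(self) -> None:
        for name in ("A_ss", "A_ssc", "A_csc", "A_cc"):
            a = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, a)
            if np.any(a <= 0) or np.any(a > 1 + 1e-12):
                raise ValueError(f"{name} out of (0, 1]")
        if np.any(self.A_ssc > self.A_ss + 1e-12) or np.any(self.A_csc > self.A_cc + 1e-12):
            raise ValueError("extra attenuation must not increase a coefficient")


@dataclass
class ReductionConfig:
    """Policy knobs of the reduction/fitting chain.

    q_exclude : Q values (A^-1) dropped before any fitting; the smallest
        instrument Q (0.3 A^-1) carries large-scale motions outside the
        Gaussian analysis and is excluded by default.
    transmission_min : acceptance threshold on the slab transmission.
    mask : Q values of bad detectors, excluded everywhere.
    propagate_vanadium_error : include the vanadium counting error in the
        normalized-scan errors (on by default; switchable for sensitivity).
    """

    q_exclude: frozenset = frozenset({0.3})
    transmission_min: float = 0.90
    mask: frozenset = frozenset()
    propagate_vanadium_error: bool = True

    def __post_init__(self) -> None:
        self.q_exclude = frozenset(float(q) for q in self.q_exclude)
        self.mask = frozenset(float(q) for q in self.mask)
        if not 0.0 < self.transmission_min < 1.0:
            raise ValueError("transmission_min must be in (0, 1)")

    def usable_q(self, q: np.ndarray, meta: dict | None = None) -> np.ndarray:
        """Boolean mask of Q points that survive exclusions and bad detectors."""
        q = np.asarray(q, dtype=float)
        bad = self.q_exclude | self.mask
        if meta and meta.get("masked_q"):
            bad = bad | {float(x) for x in str(meta["masked_q"]).split(",") if x}
        keep = np.ones(q.size, dtype=bool)
        for value in bad:
            keep &= ~np.isclose(q, value, rtol=0, atol=1e-9)
        return keep


def transmission(geometry: SlabGeometry) -> float:
    """Straight-through beam transmission of sample plus container.

    T = exp(-(mu_s d_s + mu_c d_c) / cos(tilt)).
    """
    cos_t = math.cos(math.radians(geometry.tilt))
    return math.exp(-(geometry.mu_s * geometry.d_s + geometry.mu_c * geometry.d_c) / cos_t)


def q_to_two_theta(q: np.ndarray, wavelength: float = DEFAULT_WAVELENGTH) -> np.ndarray:
    """Scattering angle 2-theta (deg) for elastic momentum transfer Q (A^-1)."""
    q = np.asarray(q, dtype=float)
    s = q * wavelength / (4.0 * math.pi)
    if np.any(s > 1.0):
        raise ValueError("Q outside the elastic range for this wavelength")
    return np.degrees(2.0 * np.arcsin(s))


def _layer_paths(t: float, w: float, d_s: float) -> tuple[float, float]:
    """Normal-distance (container, sample) between the front face and depth t."""
    c_front = min(t, w) + max(0.0, t - w - d_s)
    s_front = min(max(t - w, 0.0), d_s)
    return c_front, s_front


def _attenuation_integrand(t: float, mu_s: float, mu_c: float, w: float, d_s: float,
                           cos_in: float, cos_out: float) -> float:
    d_total = 2 * w + d_s
    c_in, s_in = _layer_paths(t, w, d_s)
    # normal distances behind t, per layer
    c_behind = max(0.0, w - t) + min(w, d_total - max(t, w + d_s))
    s_behind = d_s - s_in
    if cos_out > 0:  # exits through the back face
        c_out, s_out = c_behind, s_behind
    else:  # exits back through the front face
        c_out, s_out = c_in, s_in
    path = (mu_c * c_in + mu_s * s_in) / cos_in + (mu_c * c_out + mu_s * s_out) / abs(cos_out)
    return math.exp(-path)


def _average_over(region: Sequence[tuple[float, float]], mu_s: float, mu_c: float,
                  w: float, d_s: float, cos_in: float, cos_out: float) -> float:
    total_len = sum(b - a for a, b in region)
    acc = 0.0
    for a, b in region:
        val, _ = quad(_attenuation_integrand, a, b,
                      args=(mu_s, mu_c, w, d_s, cos_in, cos_out),
                      epsabs=1e-10, epsrel=1e-10)
        acc += val
    return acc / total_len


def paalman_pings_slab(geometry: SlabGeometry,
                       two_theta: Iterable[float]) -> AbsorptionCoefficients:
    """Paalman-Pings coefficients for a slab sample inside a slab container.

    For each scattering angle the four factors are averages of
    ``exp(-mu * path_in - mu' * path_out)`` over the scattering depth,
    computed by adaptive quadrature (absolute error <= 1e-6).  Angles
    whose exit ray lies (nearly) in the slab plane are rejected.
    """
    angles = np.atleast_1d(np.asarray(list(np.atleast_1d(two_theta)), dtype=float))
    if np.any(angles <= 0) or np.any(angles >= 180):
        raise ValueError("scattering angles must lie in (0, 180) deg")
    cos_in = math.cos(math.radians(geometry.tilt))
    w = geometry.d_c / 2.0
    d_s = geometry.d_s
    sample_region = [(w, w + d_s)]
    container_region = [(0.0, w), (w + d_s, 2 * w + d_s)]

    out = {k: np.empty(angles.size) for k in ("A_ss", "A_ssc", "A_csc", "A_cc")}
    for i, tt in enumerate(angles):
        exit_to_normal = tt - geometry.tilt
        if abs(abs(math.remainder(exit_to_normal, 180.0)) - 90.0) < _EDGE_ANGLE_DEG:
            raise ValueError(
                f"scattering angle {tt:.2f} deg: exit ray within {_EDGE_ANGLE_DEG} deg "
                "of the slab plane (transmission-edge geometry unsupported)"
            )
        cos_out = math.cos(math.radians(exit_to_normal))
        args = (w, d_s, cos_in, cos_out)
        out["A_ss"][i] = _average_over(sample_region, geometry.mu_s, 0.0, *args)
        out["A_ssc"][i] = _average_over(sample_region, geometry.mu_s, geometry.mu_c, *args)
        out["A_cc"][i] = _average_over(container_region, 0.0, geometry.mu_c, *args)
        out["A_csc"][i] = _average_over(container_region, geometry.mu_s, geometry.mu_c, *args)
    return AbsorptionCoefficients(two_theta=angles, **out)


def coefficients_for_scan(geometry: SlabGeometry, q: np.ndarray,
                          wavelength: float = DEFAULT_WAVELENGTH) -> AbsorptionCoefficients:
    """Coefficients on a scan's Q grid, mapping Q to 2-theta elastically."""
    return paalman_pings_slab(geometry, q_to_two_theta(q, wavelength))


def subtract_empty_cell(sample: ElasticScan, empty: ElasticScan,
                        coeffs: AbsorptionCoefficients) -> ElasticScan:
    """Absorption-corrected empty-cell subtraction.

    I_corr = I_sample / A_ssc - (A_csc / (A_cc * A_ssc)) * I_empty,
    with counting errors combined in quadrature.  Negative corrected
    intensities are retained (summed intensities stay unbiased) but their
    count is flagged in the metadata; they are only dropped later, at the
    log-transform stage of the MSD fits.
    """
    if sample.q.size != empty.q.size or not np.allclose(sample.q, empty.q):
        raise ValueError("Q grids of sample and empty scans differ")
    if sample.T.size != empty.T.size or not np.allclose(sample.T, empty.T):
        raise ValueError("temperature grids of sample and empty scans differ")
    if coeffs.A_ssc.size != sample.q.size:
        raise ValueError("absorption coefficients not on the scan Q grid")
    a_ssc = coeffs.A_ssc[np.newaxis, :]
    factor = (coeffs.A_csc / (coeffs.A_cc * coeffs.A_ssc))[np.newaxis, :]
    intensity = sample.intensity / a_ssc - factor * empty.intensity
    error = np.hypot(sample.error / a_ssc, factor * empty.error)
    n_negative = int(np.sum(intensity < 0))
    if n_negative:
        logger.warning("%s: %d negative intensities after empty-cell subtraction",
                       sample.label or "scan", n_negative)
    meta = dict(sample.meta)
    meta["corrected"] = "pp_slab"
    meta["n_negative"] = n_negative
    return ElasticScan(q=sample.q, T=sample.T, intensity=intensity, error=error,
                       kind=sample.kind, meta=meta)


def normalize_to_vanadium(scan: ElasticScan, vanadium: ElasticScan,
                          propagate_vanadium_error: bool = True) -> ElasticScan:
    """Divide a scan by the per-Q vanadium response.

    Vanadium is an (almost) purely incoherent, temperature-insensitive
    elastic scatterer: dividing by its scan cancels detector efficiencies
    and geometry factors.  Vanadium rows are averaged over temperature
    first.  When the vanadium metadata states the standard's own mean
    square displacement (key ``vanadium_msd``, A^2), its Debye-Waller
    factor exp(-u_v^2 Q^2 / 6) is divided out so that only efficiencies
    are cancelled and extracted MSDs are not shifted by the standard's.
    Q points where the vanadium signal is not positive are auto-masked
    with a warning (recorded under ``meta['masked_q']``).
    """
    if scan.q.size != vanadium.q.size or not np.allclose(scan.q, vanadium.q):
        raise ValueError("Q grids of scan and vanadium differ")
    v = vanadium.intensity.mean(axis=0)
    u_v = float(vanadium.meta.get("vanadium_msd", 0.0))
    if u_v:
        v = v * np.exp(u_v * scan.q**2 / 6.0)
    v_err = np.sqrt(np.sum(vanadium.error**2, axis=0)) / vanadium.T.size
    if u_v:
        v_err = v_err * np.exp(u_v * scan.q**2 / 6.0)
    good = v > 0
    masked = scan.q[~good]
    if masked.size:
        logger.warning("vanadium non-positive at Q=%s; masking", masked)
    intensity = np.zeros_like(scan.intensity)
    error = np.zeros_like(scan.error)
    intensity[:, good] = scan.intensity[:, good] / v[good]
    if propagate_vanadium_error:
        rel = np.hypot(
            np.divide(scan.error[:, good], scan.intensity[:, good],
                      out=np.zeros_like(scan.error[:, good]),
                      where=scan.intensity[:, good] != 0),
            (v_err[good] / v[good])[np.newaxis, :],
        )
        error[:, good] = np.abs(intensity[:, good]) * rel
        # points with zero intensity keep their scaled counting error
        zero = scan.intensity[:, good] == 0
        error[:, good][zero] = (scan.error[:, good] / v[good][np.newaxis, :])[zero]
    else:
        error[:, good] = scan.error[:, good] / v[good]
    meta = dict(scan.meta)
    meta["vanadium"] = vanadium.label or "vanadium"
    if masked.size:
        prior = str(meta.get("masked_q", "")).strip()
        new = ",".join(f"{x:.10g}" for x in masked)
        meta["masked_q"] = f"{prior},{new}" if prior else new
    return ElasticScan(q=scan.q, T=scan.T, intensity=intensity, error=error,
                       kind=scan.kind, meta=meta)


def relative_summed_intensity(scan: ElasticScan,
                              config: ReductionConfig | None = None) -> pd.DataFrame:
    """Summed intensities vs temperature, relative to the lowest T, in percent.

    Intensities are summed over all usable Q at each temperature, divided
    by the lowest-temperature sum and multiplied by 100.  The reference
    point is exactly 100% with zero error; other points carry the
    quadrature of the two relative counting errors.
    """
    if scan.T.size < 2:
        raise ValueError("need at least two temperatures")
    config = config or ReductionConfig()
    keep = config.usable_q(scan.q, scan.meta)
    if not np.any(keep):
        raise ValueError("no usable Q points after exclusions")
    sums = scan.intensity[:, keep].sum(axis=1)
    errs = np.sqrt(np.sum(scan.error[:, keep] ** 2, axis=1))
    ref, ref_err = sums[0], errs[0]
    if ref <= 0:
        raise ValueError("summed intensity at the lowest temperature is not positive")
    percent = 100.0 * sums / ref
    rel = np.sqrt((errs / np.where(sums != 0, sums, 1.0)) ** 2 + (ref_err / ref) ** 2)
    err_pct = np.abs(percent) * rel
    err_pct[0] = 0.0
    return pd.DataFrame({"T": scan.T, "percent": percent, "error": err_pct})


def q_to_length(q: float) -> float:
    """Real-space length scale 2*pi/Q (A) probed at momentum transfer Q (A^-1)."""
    q = float(q)
    if not math.isfinite(q) or q <= 0:
        raise ValueError("q must be positive and finite")
    return 2.0 * math.pi / q
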