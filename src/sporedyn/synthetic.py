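"""Synthetic elastic-scan generator with known ground truth.

Forward model of a fixed-window elastic temperature scan on a thermal
backscattering instrument (IN13-like: Q within 0.3-4.9 A^-1, scans over
~280-315 K).  The sample dynamics are a two-population mixture of
Gaussian scatterers,

    S(T, Q) = I0 * [ (1-p) * exp(-u_s^2(T) Q^2 / 6)
                     + p  * exp(-u_l^2(T) Q^2 / 6) ] + background,

where the "small" population stands for local macromolecular motions and
the "large" one for large-amplitude/diffusive motions (small solutes,
solvent).  Each population's mean square displacement follows a
piecewise-linear law in temperature; a germination-like transition is an
optional breakpoint in the large-amplitude population only, because at
high Q that population hardly contributes to the elastic signal and the
transition all but vanishes there.

Detector efficiencies are drawn log-normally once per triplet and shared
by sample, vanadium and empty scans, so vanadium division cancels them
exactly.  Slab absorption enters through the same Paalman-Pings
coefficients the reduction uses; observed counts are Poisson draws with
errors max(sqrt(counts), 1).  All randomness derives from the spec seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace
from functools import lru_cache
from pathlib import Path
from typing import NamedTuple

import numpy as np
import yaml

from .constants import Q_MAX, Q_MIN
from .reduction import SlabGeometry, coefficients_for_scan, transmission
from .scans import ElasticScan, write_scan

__all__ = ["MSDLaw", "SampleSpec", "ScanTriplet", "evaluate_msd_law",
           "simulate_scan_triplet", "make_fixture_suite",
           "default_q_grid", "default_T_grid",
           "wildtype_spec", "germinating_spec", "dpaless_spec", "coatless_spec"]

logger = logging.getLogger(__name__)

#: Fixed vanadium mean square displacement (A^2): small and
#: temperature-independent; it only has to cancel efficiencies.
VANADIUM_MSD = 0.05


def default_q_grid(n: int = 24) -> np.ndarray:
    """Uniform Q grid over the instrument range (24 points -> 0.2 A^-1 step)."""
    return np.linspace(Q_MIN, Q_MAX, n)


def default_T_grid(n: int = 8) -> np.ndarray:
    """Temperature grid of a germination-bracketing thermal scan (K)."""
    return np.linspace(280.0, 315.0, n)


@dataclass(frozen=True)
class MSDLaw:
    """Piecewise-linear <u2>(T) law, continuous at the optional breakpoint.

    u0          : <u2> at T_ref (A^2)
    slope       : d<u2>/dT below the breakpoint (A^2/K)
    T_ref       : reference temperature (K)
    breakpoint  : transition temperature T_b (K) or None
    slope_after : d<u2>/dT above T_b (A^2/K)
    T_valid     : temperatures outside this range are rejected
    """

    u0: float
    slope: float = 0.0
    T_ref: float = 280.0
    breakpoint: float | None = None
    slope_after: float = 0.0
    T_valid: tuple = (150.0, 400.0)

    def __post_init__(self) -> None:
        if self.u0 < 0:
            raise ValueError("u0 must be non-negative")

    def __call__(self, T) -> np.ndarray:
        return evaluate_msd_law(self, T)

    def scaled(self, factor: float) -> "MSDLaw":
        """Law whose value is ``factor`` times this one at every T."""
        return replace(self, u0=self.u0 * factor, slope=self.slope * factor,
                       slope_after=self.slope_after * factor)


def evaluate_msd_law(law: MSDLaw, T) -> np.ndarray:
    """Evaluate <u2>(T), clamping negative excursions at zero with a warning."""
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("non-finite temperature")
    if np.any(T < law.T_valid[0]) or np.any(T > law.T_valid[1]):
        raise ValueError(f"temperature outside validity range {law.T_valid}")
    value = law.u0 + law.slope * (T - law.T_ref)
    if law.breakpoint is not None:
        at_break = law.u0 + law.slope * (law.breakpoint - law.T_ref)
        above = T > law.breakpoint
        value = np.where(above, at_break + law.slope_after * (T - law.breakpoint), value)
    if np.any(value < 0):
        logger.warning("MSD law dipped below zero; clamping at 0")
        value = np.maximum(value, 0.0)
    return value if value.ndim else float(value)


@dataclass(frozen=True)
class SampleSpec:
    """Complete ground truth for one simulated sample.

    The two MSD laws, their mixing fraction and the counting/absorption
    parameters fully determine the noiseless scan; ``seed`` fixes the
    efficiency draw and the Poisson noise.
    """

    population_small: MSDLaw
    population_large: MSDLaw
    fraction_large: float = 0.0
    I0: float = 1.0
    flat_background: float = 0.02
    mu_sample: float = 2.0
    mu_container: float = 0.1
    d_sample: float = 0.02
    d_container: float = 0.1
    tilt: float = 45.0
    detector_efficiency_sd: float = 0.10
    counts_scale: float = 5.0e4
    container_scale: float = 0.05
    vanadium_scale: float = 1.0
    scan_time_h: float = 3.5
    seed: int | None = None
    label: str = "sample"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_large <= 1.0:
            raise ValueError("fraction_large must lie in [0, 1]")
        if self.d_sample <= 0 or self.d_container <= 0:
            raise ValueError("thicknesses must be positive")
        if self.counts_scale <= 0:
            raise ValueError("counts_scale must be positive")

    @property
    def geometry(self) -> SlabGeometry:
        return SlabGeometry(mu_s=self.mu_sample, mu_c=self.mu_container,
                            d_s=self.d_sample, d_c=self.d_container, tilt=self.tilt)


class ScanTriplet(NamedTuple):
    sample: ElasticScan
    vanadium: ElasticScan
    empty: ElasticScan
    truth: dict


@lru_cache(maxsize=64)
def _cached_coefficients(geometry: SlabGeometry, q_key: tuple):
    return coefficients_for_scan(geometry, np.array(q_key))


def simulate_scan_triplet(spec: SampleSpec, q_grid=None, T_grid=None,
                          noise: bool = True) -> ScanTriplet:
    """Simulate a (sample, vanadium, empty) scan triplet from ground truth.

    The noiseless sample mean at (T, Q) is

        eff(Q) * [ A_ssc(Q) * (amp * mix(T, Q) + bg) + A_csc(Q) * C(Q) ],

    with ``mix`` the two-population Gaussian mixture, ``C`` the container
    term, efficiencies ``eff`` drawn once from the seed, and amplitudes
    scaled so the pure sample term at Q -> 0 and the lowest temperature
    equals ``counts_scale``.  The empty scan carries only the container
    term (through A_cc); the vanadium scan is a temperature-independent
    elastic scatterer with <u2> = 0.05 A^2 through the same efficiencies.
    With ``noise=True`` counts are Poisson draws and errors
    max(sqrt(counts), 1); with ``noise=False`` the exact means are
    returned.  The full ground truth travels in ``triplet.truth``.
    """
    if spec.seed is None:
        raise ValueError("SampleSpec.seed is required for reproducible simulation")
    q = np.asarray(default_q_grid() if q_grid is None else q_grid, dtype=float)
    T = np.asarray(default_T_grid() if T_grid is None else T_grid, dtype=float)
    rng = np.random.default_rng(spec.seed)

    sd = spec.detector_efficiency_sd
    if sd > 0:
        sigma_ln = np.sqrt(np.log1p(sd**2))
        eff = rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln, size=q.size)
    else:
        eff = np.ones(q.size)

    coeffs = _cached_coefficients(spec.geometry, tuple(np.round(q, 12)))
    u_small = spec.population_small(T)[:, None]
    u_large = spec.population_large(T)[:, None]
    p = spec.fraction_large
    q2 = (q**2)[None, :]
    mix = (1 - p) * np.exp(-u_small * q2 / 6.0) + p * np.exp(-u_large * q2 / 6.0)

    scale = spec.counts_scale / (spec.I0 + spec.flat_background)
    amp, bg = scale * spec.I0, scale * spec.flat_background
    container = spec.container_scale * spec.counts_scale * np.exp(-0.1 * q**2 / 6.0)
    vanadium_mean = (eff * spec.vanadium_scale * spec.counts_scale
                     * np.exp(-VANADIUM_MSD * q**2 / 6.0))[None, :]

    sample_mean = eff[None, :] * (coeffs.A_ssc[None, :] * (amp * mix + bg)
                                  + coeffs.A_csc[None, :] * container[None, :])
    empty_mean = (eff * coeffs.A_cc * container)[None, :] * np.ones((T.size, 1))
    if np.any(sample_mean < 0) or np.any(empty_mean < 0):
        raise RuntimeError("negative mean count in forward model")

    trans = transmission(spec.geometry)

    def _observe(mean: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        counts = rng.poisson(mean).astype(float) if noise else mean
        return counts, np.maximum(np.sqrt(counts), 1.0)

    common = {"label": spec.label, "transmission": f"{trans:.6f}",
              "mu_s": spec.mu_sample, "mu_c": spec.mu_container,
              "d_s": spec.d_sample, "d_c": spec.d_container, "tilt": spec.tilt,
              "scan_time_h": spec.scan_time_h, "seed": spec.seed}
    s_counts, s_err = _observe(sample_mean)
    v_counts, v_err = _observe(vanadium_mean)
    e_counts, e_err = _observe(empty_mean)
    sample = ElasticScan(q=q, T=T, intensity=s_counts, error=s_err, kind="sample",
                         meta={**common, "kind_note": "sample"})
    vanadium = ElasticScan(q=q, T=T[:1], intensity=v_counts, error=v_err,
                           kind="vanadium",
                           meta={**common, "label": f"{spec.label}_vanadium",
                                 "vanadium_msd": VANADIUM_MSD})
    empty = ElasticScan(q=q, T=T, intensity=e_counts, error=e_err, kind="empty",
                        meta={**common, "label": f"{spec.label}_empty"})
    truth = {
        "spec": spec,
        "efficiency": eff,
        "amplitude": amp,
        "background": bg,
        "container": container,
        "coefficients": coeffs,
        "mix_mean": amp * mix + bg,
        "transmission": trans,
    }
    return ScanTriplet(sample=sample, vanadium=vanadium, empty=empty, truth=truth)


# ---------------------------------------------------------------------------
# Standard fixture battery: a wild-type-like dormant spore, a spontaneously
# germinating preparation, a CaDPA-less mutant and a coatless mutant.
# ---------------------------------------------------------------------------

#: Local (high-Q) population of the dormant wild type: slope chosen so a
#: single-population analysis recovers a resilience of 0.21 N/m.
_WT_SMALL = MSDLaw(u0=0.30, slope=0.00276 / 0.21, T_ref=280.0)
#: Large-amplitude (low-Q) population: bigger amplitude, gentler slope.
_WT_LARGE = MSDLaw(u0=3.0, slope=0.003, T_ref=280.0)
_FRACTION_LARGE = 0.35
#: Germination: the large-amplitude population steepens a hundredfold at
#: T_b, doubling its MSD over the last 10 K of the scan -- the "drastic"
#: mobility increase of a spontaneously germinating preparation.
_GERMINATION_TB = 305.0
_GERMINATION_SLOPE_AFTER = 0.3


def wildtype_spec(seed: int = 1, **overrides) -> SampleSpec:
    """Dormant wild-type-like sample: stable two-population dynamics."""
    return SampleSpec(population_small=_WT_SMALL, population_large=_WT_LARGE,
                      fraction_large=_FRACTION_LARGE, seed=seed, label="wildtype",
                      **overrides)


def germinating_spec(seed: int = 2, **overrides) -> SampleSpec:
    """Germinating sample: breakpoint at 305 K in the large population only."""
    large = replace(_WT_LARGE, breakpoint=_GERMINATION_TB,
                    slope_after=_GERMINATION_SLOPE_AFTER)
    return SampleSpec(population_small=_WT_SMALL, population_large=large,
                      fraction_large=_FRACTION_LARGE, seed=seed,
                      label="germinating", **overrides)


def dpaless_spec(seed: int = 3, **overrides) -> SampleSpec:
    """CaDPA-less mutant: large-amplitude MSD 1.8x the wild type at every T."""
    return SampleSpec(population_small=_WT_SMALL,
                      population_large=_WT_LARGE.scaled(1.8),
                      fraction_large=_FRACTION_LARGE, seed=seed, label="dpaless",
                      **overrides)


def coatless_spec(seed: int = 4, **overrides) -> SampleSpec:
    """Coatless mutant: local-motion MSD reduced to 0.6x the wild type."""
    return SampleSpec(population_small=_WT_SMALL.scaled(0.6),
                      population_large=_WT_LARGE,
                      fraction_large=_FRACTION_LARGE, seed=seed, label="coatless",
                      **overrides)


def _law_dict(law: MSDLaw) -> dict:
    d = {"u0": law.u0, "slope": law.slope, "T_ref": law.T_ref}
    if law.breakpoint is not None:
        d["breakpoint"] = law.breakpoint
        d["slope_after"] = law.slope_after
    return d


def make_fixture_suite(outdir: str | Path, seed: int = 1,
                       noise: bool = True, q_grid=None, T_grid=None) -> dict:
    """Write the four-sample fixture battery plus a ground-truth manifest.

    Returns ``{label: {"spec": SampleSpec, "paths": {...}}}``.  Each
    sample gets its own derived seed; the manifest records every
    ground-truth parameter (including the vanadium MSD and the seeds).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    builders = [wildtype_spec, germinating_spec, dpaless_spec, coatless_spec]
    suite: dict = {}
    manifest: dict = {"seed": seed, "vanadium_msd": VANADIUM_MSD, "samples": {}}
    for i, build in enumerate(builders):
        spec = build(seed=(seed * 10007 + i) % (2**31))
        triplet = simulate_scan_triplet(spec, q_grid=q_grid, T_grid=T_grid, noise=noise)
        paths = {}
        for role in ("sample", "vanadium", "empty"):
            path = outdir / f"{spec.label}_{role}.tsv"
            write_scan(getattr(triplet, role), path)
            paths[role] = str(path)
        suite[spec.label] = {"spec": spec, "paths": paths, "triplet": triplet}
        entry = asdict(spec)
        entry["population_small"] = _law_dict(spec.population_small)
        entry["population_large"] = _law_dict(spec.population_large)
        entry["paths"] = paths
        manifest["samples"][spec.label] = entry
    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return suite
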