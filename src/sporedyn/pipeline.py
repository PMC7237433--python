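"""End-to-end pipeline: configuration, orchestration, provenance.

A single YAML configuration drives the whole chain: per-sample scan
triplets (sample/vanadium/empty files), slab geometry, reduction policy,
Q windows, temperature ranges and ratio pairs.  ``run_pipeline`` then
reduces every sample, extracts MSD series per window, fits force
constants (with a breakpoint scan proposing split ranges), computes the
declared mutant/wild-type ratios and writes the report tables.  Every
warning emitted along the way is collected into the :class:`RunRecord`,
and identical configuration + inputs yield byte-identical report tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .msd import HIGH_Q, LOW_Q, QWindow, extract_msd_series
from .reduction import (ReductionConfig, SlabGeometry, coefficients_for_scan,
                        normalize_to_vanadium, relative_summed_intensity,
                        subtract_empty_cell, transmission)
from .scans import read_scan, write_scan
from .thermal import build_report, detect_breakpoint, fit_force_constant, msd_ratio

__all__ = ["PipelineConfig", "RunRecord", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

STAGES = ("reduce", "msd", "analyze", "report")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see :func:`load_config`)."""

    samples: dict                 # label -> {sample, vanadium, empty, T_ranges?}
    geometry: SlabGeometry
    reduction: ReductionConfig
    windows: list
    ratio_pairs: list             # [{mutant, wildtype, window, T_range?}, ...]
    outdir: Path
    seed: int = 0
    breakpoint_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("at least one Q window is required")
        if not self.samples:
            raise ValueError("at least one sample is required")
        names = {w.name for w in self.windows}
        for label, entry in self.samples.items():
            for role in ("sample", "vanadium", "empty"):
                if role not in entry:
                    raise ValueError(f"sample {label!r}: missing {role!r} scan path")
        for pair in self.ratio_pairs:
            for side in ("mutant", "wildtype"):
                if pair[side] not in self.samples:
                    raise ValueError(
                        f"ratio pair references undeclared sample {pair[side]!r}")
            if pair.get("window", "low") not in names:
                raise ValueError(f"ratio pair references unknown window {pair['window']!r}")

    def digest(self) -> str:
        """Whitespace-insensitive digest of the semantic config content."""
        payload = {
            "samples": self.samples,
            "geometry": vars(self.geometry),
            "reduction": {"q_exclude": sorted(self.reduction.q_exclude),
                          "transmission_min": self.reduction.transmission_min,
                          "mask": sorted(self.reduction.mask),
                          "propagate_vanadium_error": self.reduction.propagate_vanadium_error},
            "windows": [{"name": w.name, "q_min": w.q_min, "q_max": w.q_max}
                        for w in self.windows],
            "ratio_pairs": self.ratio_pairs,
            "seed": self.seed,
            "breakpoint_alpha": self.breakpoint_alpha,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    geometry = SlabGeometry(**raw.get("geometry", {}))
    red = raw.get("reduction", {})
    reduction = ReductionConfig(
        q_exclude=frozenset(red.get("q_exclude", [0.3])),
        transmission_min=red.get("transmission_min", 0.90),
        mask=frozenset(red.get("mask", [])),
        propagate_vanadium_error=red.get("propagate_vanadium_error", True),
    )
    windows = [QWindow(w["q_min"], w["q_max"], w.get("name", f"w{i}"))
               for i, w in enumerate(raw.get("windows", []))] or [LOW_Q, HIGH_Q]
    base = path.parent

    def _resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    samples = {}
    for label, entry in (raw.get("samples") or {}).items():
        entry = dict(entry)
        for role in ("sample", "vanadium", "empty"):
            if role in entry:
                entry[role] = _resolve(entry[role])
        samples[label] = entry
    return PipelineConfig(
        samples=samples,
        geometry=geometry,
        reduction=reduction,
        windows=windows,
        ratio_pairs=list(raw.get("ratio_pairs", [])),
        outdir=Path(raw.get("outdir", "sporedyn_out")),
        seed=int(raw.get("seed", 0)),
        breakpoint_alpha=float(raw.get("breakpoint_alpha", 0.05)),
    )


@dataclass
class RunRecord:
    """Provenance of one pipeline run."""

    config_digest: str
    version: str
    started: str
    finished: str = ""
    warnings: list = field(default_factory=list)

    def to_yaml(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(vars(self), fh, sort_keys=False)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.records: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.records.append(f"{record.name}: {record.getMessage()}")


def run_pipeline(config: PipelineConfig, stage: str = "report") -> dict:
    """Run the pipeline up to ``stage`` and return its products.

    Stages: ``reduce`` (corrected+normalized scans and thermograms),
    ``msd`` (adds per-window MSD series), ``analyze`` (adds force
    constants, breakpoints, ratios), ``report`` (adds the report tables
    on disk).  Any hard error aborts with the stage and sample named.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    depth = STAGES.index(stage)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    root = logging.getLogger("sporedyn")
    root.addHandler(collector)
    record = RunRecord(config_digest=config.digest(), version=__version__,
                       started=datetime.now(timezone.utc).isoformat())
    products: dict = {"reduced": {}, "thermograms": {}, "series": {},
                      "breakpoints": {}, "force_constants": [], "ratios": [],
                      "record": record}
    try:
        trans = transmission(config.geometry)
        if trans < config.reduction.transmission_min:
            logger.warning("slab transmission %.3f below the %.2f acceptance threshold",
                           trans, config.reduction.transmission_min)
        for label, entry in config.samples.items():
            try:
                _process_sample(label, entry, config, depth, outdir, products)
            except Exception as exc:
                raise RuntimeError(f"stage for sample {label!r} failed: {exc}") from exc
        if depth >= 2 and config.ratio_pairs:
            windows = {w.name: w for w in config.windows}
            for pair in config.ratio_pairs:
                wname = pair.get("window", "low")
                t_range = tuple(pair["T_range"]) if "T_range" in pair else None
                mutant = products["series"][pair["mutant"]][wname]
                wildtype = products["series"][pair["wildtype"]][wname]
                products["ratios"].append(msd_ratio(mutant, wildtype, t_range))
        if depth >= 3:
            products["report"] = build_report(products["force_constants"],
                                              products["ratios"], outdir)
    finally:
        root.removeHandler(collector)
        record.warnings = collector.records
        record.finished = datetime.now(timezone.utc).isoformat()
        record.to_yaml(outdir / "run_record.yaml")
    return products


def _process_sample(label: str, entry: dict, config: PipelineConfig, depth: int,
                    outdir: Path, products: dict) -> None:
    sample = read_scan(entry["sample"])
    vanadium = read_scan(entry["vanadium"])
    empty = read_scan(entry["empty"])
    sample.meta.setdefault("label", label)
    coeffs = coefficients_for_scan(config.geometry, sample.q)
    corrected = subtract_empty_cell(sample, empty, coeffs)
    reduced = normalize_to_vanadium(
        corrected, vanadium,
        propagate_vanadium_error=config.reduction.propagate_vanadium_error)
    write_scan(reduced, outdir / f"{label}_reduced.tsv")
    thermogram = relative_summed_intensity(corrected, config.reduction)
    thermogram.to_csv(outdir / f"{label}_summed.tsv", sep="\t", index=False,
                      float_format="%.6g")
    products["reduced"][label] = reduced
    products["thermograms"][label] = thermogram
    if depth < 1:
        return
    products["series"][label] = {}
    products["breakpoints"][label] = {}
    for window in config.windows:
        series = extract_msd_series(reduced, window, config.reduction)
        series.to_tsv(outdir / f"{label}_msd_{window.name}.tsv")
        products["series"][label][window.name] = series
        if depth < 2:
            continue
        ranges = [tuple(r) for r in entry.get("T_ranges", [])]
        bp = None
        if len(series) >= 7:
            bp = detect_breakpoint(series, alpha=config.breakpoint_alpha)
            products["breakpoints"][label][window.name] = bp
        if not ranges:
            ranges = [(float(series.T.min()), float(series.T.max()))]
            if bp is not None and bp.significant:
                ranges += [seg["T_range"] for seg in bp.segments]
                logger.warning("%s/%s: breakpoint at %.1f K; reporting split ranges",
                               label, window.name, bp.T_b)
        for t_range in ranges:
            products["force_constants"].append(
                fit_force_constant(series, t_range))
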