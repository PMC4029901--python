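"""End-to-end orchestration: one YAML config drives the full analysis.

calibrate isoscapes -> estimate covariance -> per-group assignment (one
run per isotope subset) -> aggregation maps -> range-consistency
statistics -> manifest.  Hybrid birds are additionally partitioned by
maternal species and re-run through the identical pipeline; no new
computation is involved.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml
from shapely.geometry import shape

from . import __version__
from .assignment import (
    coslat_weights,
    estimate_covariance,
    range_consistency,
    rasterize_range,
    run_group_assignment,
)
from .feathers import FeatherRecord, FeatherTableError, read_feathers
from .grids import RasterError, read_raster, write_raster
from .isoscapes import CalibrationError, CalibrationSpec, calibrate_stack

__all__ = ["PipelineConfig", "ValidationReport", "load_config", "validate", "run", "simulate"]

logger = logging.getLogger("isoassign")


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis settings; paths resolve relative to ``base_dir``."""

    base_dir: Path
    isoscapes: Mapping[str, str]
    feathers: str
    output_dir: str
    calibration: Mapping[str, float]
    ranges: str | None = None
    isotope_subsets: Sequence[Sequence[str]] = (
        ("d2H", "d13C", "d15N"),
        ("d2H", "d13C"),
    )
    level: float = 0.67
    groups: Sequence[str] = ("collared", "pied", "hybrid")
    covariance_mode: str = "pooled"  # pooled | per_group
    area_weighted: bool = False
    ridge: float = 0.0
    seed: int = 0
    simulation: Mapping | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.covariance_mode not in ("pooled", "per_group"):
            raise ValueError(f"unknown covariance mode {self.covariance_mode!r}")

    def path(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "base_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    raw["isotope_subsets"] = [tuple(s) for s in raw.get("isotope_subsets", PipelineConfig.isotope_subsets)]
    return PipelineConfig(base_dir=path.parent.resolve(), **raw)


@dataclass
class ValidationReport:
    ok: bool
    messages: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        status = "OK" if self.ok else "FAILED"
        return "\n".join([f"validation: {status}"] + [f"  - {m}" for m in self.messages])


def _load_inputs(config: PipelineConfig):
    spec = CalibrationSpec.from_mapping(config.calibration)
    raw = {iso: read_raster(config.path(p)) for iso, p in config.isoscapes.items()}
    stack = calibrate_stack(raw, spec)
    records = read_feathers(config.path(config.feathers))
    ranges = {}
    if config.ranges:
        with open(config.path(config.ranges)) as fh:
            gj = json.load(fh)
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        for i, feat in enumerate(feats):
            name = feat.get("properties", {}).get("name", f"range_{i}")
            ranges[name] = shape(feat["geometry"])
    return stack, records, ranges


def validate(config: PipelineConfig) -> ValidationReport:
    """Check grid alignment, feather schema, ranges and covariance estimability."""
    messages: list[str] = []
    try:
        stack, records, ranges = _load_inputs(config)
    except (RasterError, CalibrationError, FeatherTableError, OSError, KeyError, ValueError) as exc:
        return ValidationReport(ok=False, messages=[str(exc)])
    messages.append(
        f"isoscape stack: {len(stack.isotopes)} layers, {stack.template.shape[0]}x"
        f"{stack.template.shape[1]} cells ({stack.template.n_valid} valid)"
    )
    messages.append(f"feather table: {len(records)} records")
    ok = True
    for subset in config.isotope_subsets:
        missing_layers = [iso for iso in subset if iso not in stack]
        if missing_layers:
            messages.append(f"subset {subset}: missing isoscape layer(s) {missing_layers}")
            ok = False
            continue
        complete = [r for r in records if r.is_complete(subset)]
        if len(complete) < len(subset) + 1:
            messages.append(
                f"subset {subset}: only {len(complete)} complete records; "
                f"covariance not estimable"
            )
            ok = False
    known_groups = {r.group for r in records}
    for g in config.groups:
        if g not in known_groups:
            messages.append(f"group {g!r} has no records")
            ok = False
    for name, poly in ranges.items():
        try:
            rasterize_range(poly, stack.template, name=name)
        except Exception as exc:
            messages.append(f"range {name!r}: {exc}")
            ok = False
    if ok:
        messages.append("all checks passed")
    return ValidationReport(ok=ok, messages=messages)


def _partitions(records: Sequence[FeatherRecord], groups: Sequence[str]):
    """The mapped groups: each configured group, plus hybrids split by mother."""
    parts: dict[str, list[FeatherRecord]] = {
        g: [r for r in records if r.group == g] for g in groups
    }
    if "hybrid" in groups:
        hybrids = parts["hybrid"]
        for mother in ("collared", "pied"):
            sub = [r for r in hybrids if r.maternal_species == mother]
            if sub:
                parts[f"hybrid_maternal_{mother}"] = sub
    return parts


@dataclass
class RunResult:
    output_dir: Path
    manifest: dict
    populations: dict  # (group, subset) -> PopulationSurface


def run(config: PipelineConfig) -> RunResult:
    """Execute the full analysis; deterministic given fixed inputs."""
    report = validate(config)
    if not report.ok:
        raise ValueError(f"configuration failed validation:\n{report}")
    stack, records, ranges = _load_inputs(config)
    outdir = config.path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    weights = coslat_weights(stack.template) if config.area_weighted else None

    parts = _partitions(records, config.groups)
    group_stats: list[dict] = []
    consistency_rows: list[dict] = []
    populations = {}
    for subset in config.isotope_subsets:
        subset = tuple(subset)
        tag = "".join(iso.replace("d", "") for iso in subset)
        if config.covariance_mode == "pooled":
            cov_all = estimate_covariance(
                [r for r in records if r.is_complete(subset)], subset, ridge=config.ridge
            )
        for group, members in parts.items():
            t0 = time.perf_counter()
            usable = [r for r in members if r.is_complete(subset)]
            if not usable:
                raise ValueError(f"group {group!r} has no usable records for {subset}")
            cov = (
                cov_all
                if config.covariance_mode == "pooled"
                else estimate_covariance(usable, subset, ridge=config.ridge)
            )
            binaries, pop = run_group_assignment(
                usable, stack, cov, subset, level=config.level, group=group
            )
            if weights is not None:
                from .assignment import aggregate_population, binarize_upper_density, mvnpdf_surface

                binaries = [
                    binarize_upper_density(
                        mvnpdf_surface(r, stack.subset(subset), cov, subset),
                        level=config.level,
                        weights=weights,
                    )
                    for r in usable
                ]
                pop = aggregate_population(binaries, group=group)
            populations[(group, subset)] = pop
            write_raster(pop.count, outdir / f"{group}_{tag}_count.asc")
            write_raster(pop.rescaled, outdir / f"{group}_{tag}_rescaled.asc")
            group_stats.append(
                {
                    "group": group,
                    "isotopes": list(subset),
                    "n": pop.n_individuals,
                    "max_count": pop.max_count,
                    "max_count_proportion": pop.max_count_proportion,
                }
            )
            for name, poly in ranges.items():
                mask = rasterize_range(poly, stack.template, name=name)
                rc = range_consistency(pop, mask)
                consistency_rows.append(
                    {
                        "group": group,
                        "isotopes": "+".join(subset),
                        "range": name,
                        "n": rc.n,
                        "min_proportion": rc.min_proportion,
                        "min_proportion_nonzero": rc.min_proportion_nonzero,
                        "max_proportion": rc.max_proportion,
                    }
                )
            logger.info(
                "group %s x %s: n=%d max_count=%d (%.3f) in %.2fs",
                group,
                "+".join(subset),
                pop.n_individuals,
                pop.max_count,
                pop.max_count_proportion,
                time.perf_counter() - t0,
            )

    if consistency_rows:
        import pandas as pd

        pd.DataFrame(consistency_rows).to_csv(outdir / "range_consistency.csv", index=False)

    props = [g["max_count_proportion"] for g in group_stats]
    manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "level": config.level,
        "isotope_subsets": [list(s) for s in config.isotope_subsets],
        "groups": sorted(parts),
        "group_stats": group_stats,
        "mean_max_count_proportion": sum(props) / len(props),
        "min_max_count_proportion": min(props),
        "max_max_count_proportion": max(props),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(output_dir=outdir, manifest=manifest, populations=populations)


def _config_hash(config: PipelineConfig) -> str:
    payload = {
        k: v
        for k, v in (
            ("isoscapes", dict(config.isoscapes)),
            ("feathers", config.feathers),
            ("ranges", config.ranges),
            ("calibration", dict(config.calibration)),
            ("isotope_subsets", [list(s) for s in config.isotope_subsets]),
            ("level", config.level),
            ("groups", list(config.groups)),
            ("covariance_mode", config.covariance_mode),
            ("area_weighted", config.area_weighted),
            ("ridge", config.ridge),
        )
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def simulate(config_path: str | Path | None, outdir: str | Path, seed: int = 0) -> dict:
    """Write a synthetic input bundle that round-trips through validate/run."""
    from .simulate import SimulationConfig, write_bundle

    sim_kwargs = {}
    if config_path is not None:
        cfg = load_config(config_path)
        sim_kwargs = dict(cfg.simulation or {})
        seed = sim_kwargs.pop("seed", cfg.seed)
    sim = SimulationConfig(seed=seed, **sim_kwargs)
    return write_bundle(sim, outdir)
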