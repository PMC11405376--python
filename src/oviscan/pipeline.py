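"""Region-level orchestration: phantom → segment → folds/fractal → shape.

A :class:`PipelineConfig` describes one region's analysis: how many
cross-section slices to analyze (phantom specs or mask files), fold and
fractal parameters, and where the (V, S, h) triple for the shape factor
comes from (a tube phantom or precomputed values).  The resulting
:class:`RegionReport` pools per-slice fractal results as min–max ranges
plus the median, summarizes folds, and records full provenance (config
hash, seeds) so any report can be regenerated byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import foldmetrics, fractal, phantom, segment, shape3d
from .foldmetrics import FoldSummary
from .imgio import BinaryMask, read_mask_stack, write_mask_stack

__all__ = ["PipelineConfig", "RegionReport", "run_region_analysis", "compare_regions"]


@dataclass
class PipelineConfig:
    """Declarative description of one region analysis."""

    region: str = "UTJ"
    phase: str = "late_follicular"
    n_slices: int = 4
    seed: int = 0
    # either phantom parameters (dict of FoldPhantomSpec overrides) ...
    fold_phantom: dict[str, Any] | None = None
    # ... or per-slice mask paths: list of {"tissue": path, "internal": path}
    slice_masks: list[dict[str, str]] | None = None
    px_size_um: float = phantom.DEFAULT_PX_SIZE_UM
    fold_params: dict[str, Any] = field(default_factory=dict)
    fractal_params: dict[str, Any] = field(default_factory=dict)
    # which mask the fractal statistics describe: the mucosal relief
    # ("folds", default), the whole wall ("tissue") or the lumen ("internal")
    fractal_target: str = "folds"
    # shape source: {"tube": TubePhantomSpec overrides} or
    # {"precomputed": [{"structure": ..., "volume_mm3": ..., "surface_mm2": ...}, ...]}
    shape_source: dict[str, Any] | None = None
    height_mm: float = 4.46
    smoothing_iterations: int = 10
    smoothing_method: str = "taubin"
    output_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RegionReport:
    """Pooled results for one region, with provenance."""

    region: str
    phase: str
    fold_summary: FoldSummary
    fold_measurements: list[foldmetrics.FoldMeasurement]
    fractal_per_slice: list[fractal.FractalResult]
    fd_range: tuple[float, float]
    fd_median: float
    lacunarity_range: tuple[float, float]
    lacunarity_median: float
    shape: dict[str, shape3d.ShapeFactorResult]
    provenance: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "region": self.region,
            "phase": self.phase,
            "fold_summary": self.fold_summary.to_dict(),
            "fold_measurements": [dataclasses.asdict(m) for m in self.fold_measurements],
            "fractal_per_slice": [r.to_dict() for r in self.fractal_per_slice],
            "fd_range": list(self.fd_range),
            "fd_median": self.fd_median,
            "lacunarity_range": list(self.lacunarity_range),
            "lacunarity_median": self.lacunarity_median,
            "shape": {k: v.rounded(6) for k, v in self.shape.items()},
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _slice_masks(config: PipelineConfig, slice_idx: int) -> tuple[BinaryMask, BinaryMask, Any]:
    """Tissue and internal masks for one slice, plus phantom truth if any."""
    if config.slice_masks is not None:
        entry = config.slice_masks[slice_idx]
        sp = (config.px_size_um,) * 3
        tissue = read_mask_stack(entry["tissue"], spacing_um=sp)
        internal = read_mask_stack(entry["internal"], spacing_um=sp)
        return tissue, internal, None
    overrides = dict(config.fold_phantom or {})
    overrides.setdefault("px_size_um", config.px_size_um)
    overrides["seed"] = config.seed * 10_000 + slice_idx
    spec = phantom.FoldPhantomSpec(**overrides)
    tissue, _, truth = phantom.make_fold_cross_section(spec)
    external, internal = segment.split_structures(tissue)
    return tissue, internal, truth


def run_region_analysis(config: PipelineConfig) -> RegionReport:
    """Run the full per-region chain; deterministic under the config seed."""
    measurements: list[foldmetrics.FoldMeasurement] = []
    fr_results: list[fractal.FractalResult] = []
    truths = []
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    for i in range(config.n_slices):
        tissue, internal, truth = _slice_masks(config, i)
        truths.append(truth)
        folds = foldmetrics.detect_folds(tissue, internal, **config.fold_params)
        for fold in folds:
            m = foldmetrics.measure_fold(fold, config.px_size_um)
            m.fold_id = len(measurements)
            measurements.append(m)
        if config.fractal_target == "folds":
            target = foldmetrics.protrusion_mask(tissue)
        elif config.fractal_target == "tissue":
            target = tissue
        elif config.fractal_target == "internal":
            target = internal
        else:
            raise ValueError(f"unknown fractal_target {config.fractal_target!r}")
        fr = fractal.analyze_mask(
            target, seed=config.seed * 10_000 + i, **config.fractal_params
        )
        fr_results.append(fr)
        if out:
            write_mask_stack(tissue, out / f"slice_{i:03d}_tissue.tif")
            write_mask_stack(internal, out / f"slice_{i:03d}_internal.tif")

    summary = foldmetrics.summarize_folds(measurements)
    fds = np.array([r.fd for r in fr_results])
    lams = np.array([r.lacunarity_mean for r in fr_results])

    shape_results: dict[str, shape3d.ShapeFactorResult] = {}
    if config.shape_source:
        if "precomputed" in config.shape_source:
            for entry in config.shape_source["precomputed"]:
                res = shape3d.shape_factor(
                    surface_mm2=entry["surface_mm2"],
                    volume_mm3=entry["volume_mm3"],
                    height_mm=entry.get("height_mm", config.height_mm),
                    structure=entry.get("structure"),
                    region=config.region,
                    phase=config.phase,
                )
                shape_results[entry.get("structure", f"structure_{len(shape_results)}")] = res
        elif "tube" in config.shape_source:
            spec = phantom.TubePhantomSpec(
                **{**config.shape_source["tube"], "seed": config.seed}
            )
            mask3d, _ = phantom.make_tube_volume(spec)
            v = shape3d.measure_volume(mask3d)
            mesh = shape3d.extract_surface(
                mask3d,
                smoothing_iterations=config.smoothing_iterations,
                method=config.smoothing_method,  # type: ignore[arg-type]
            )
            s = shape3d.mesh_area(mesh)
            shape_results["external"] = shape3d.shape_factor(
                s, v, config.height_mm, structure="external",
                region=config.region, phase=config.phase,
            )
        else:
            raise ValueError("shape_source must contain 'precomputed' or 'tube'")

    report = RegionReport(
        region=config.region,
        phase=config.phase,
        fold_summary=summary,
        fold_measurements=measurements,
        fractal_per_slice=fr_results,
        fd_range=(float(fds.min()), float(fds.max())),
        fd_median=float(np.median(fds)),
        lacunarity_range=(float(lams.min()), float(lams.max())),
        lacunarity_median=float(np.median(lams)),
        shape=shape_results,
        provenance={
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_slices": config.n_slices,
            "true_fold_count": sum(
                len(t.true_fold_lengths_um) for t in truths if t is not None
            ),
        },
    )
    if out:
        (out / "region_report.json").write_text(report.to_json())
        foldmetrics.measurements_frame(measurements).to_csv(
            out / "fold_measurements.csv", index=False
        )
    return report


def compare_regions(a: RegionReport, b: RegionReport) -> pd.DataFrame:
    """Signed differences (b − a) of the pooled morphometry metrics.

    Positive difference: b exceeds a.  Rejects reports produced under
    different fractal conventions (the lacunarity values would not be
    commensurable).
    """
    conv_a = {r.convention for r in a.fractal_per_slice}
    conv_b = {r.convention for r in b.fractal_per_slice}
    if conv_a != conv_b:
        raise ValueError(f"mismatched fractal conventions: {conv_a} vs {conv_b}")

    def _metrics(r: RegionReport) -> dict[str, float | None]:
        m = {
            "fold_length_median_um": r.fold_summary.length_median_um,
            "fold_width_median_um": r.fold_summary.width_median_um,
            "fd_median": r.fd_median,
            "lacunarity_median": r.lacunarity_median,
        }
        for name, res in r.shape.items():
            m[f"shape_index_{name}"] = res.shape_index
        return m

    ma, mb = _metrics(a), _metrics(b)
    rows = []
    for key in ma:
        va, vb = ma.get(key), mb.get(key)
        if va is None or vb is None:
            continue
        diff = vb - va
        rows.append(
            {
                "metric": key,
                a.region: va,
                b.region: vb,
                "difference": diff,
                "direction": "higher_in_b" if diff > 0 else ("higher_in_a" if diff < 0 else "equal"),
            }
        )
    return pd.DataFrame(rows)
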