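"""End-to-end pipeline: simulate -> reconstruct -> noise analysis.

A :class:`RunConfig` collects the phantom, grid, acquisition, stopping and
analysis settings (typically from a strict-schema YAML file).  The pipeline
reconstructs once down to the smallest requested stopping value, capturing
image snapshots as the stopping statistic first crosses each larger value,
then reports per-stopping-point ROI noise, autocorrelation curves, WET line
sums and iteration counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .grid import VoxelGrid
from .noise import ROISpec, autocorrelation, roi_stats, wet_line_sum
from .phantoms import PhantomElement, PhantomSpec, make_phantom, water_cylinder
from .simulate import SimulationConfig, simulate_protons
from .solver import StoppingConfig, reconstruct

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

logger = logging.getLogger(__name__)


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {name} section: {sorted(unknown)}")


def parse_grid(section: dict) -> VoxelGrid:
    _check_keys(section, {"shape", "voxel_size", "origin"}, "grid")
    shape = tuple(section["shape"])
    voxel = float(section.get("voxel_size", 1.0))
    if "origin" in section:
        return VoxelGrid(shape=shape, voxel_size=voxel, origin=tuple(section["origin"]))
    return VoxelGrid.centered(shape, voxel)


def parse_phantom(section: dict) -> PhantomSpec:
    if "elements" in section:
        _check_keys(section, {"elements", "background_rsp"}, "phantom")
        elements = tuple(
            PhantomElement(shape=el["shape"], center=tuple(el["center"]),
                           dimensions=tuple(el["dimensions"]), rsp=float(el["rsp"]))
            for el in section["elements"]
        )
        return PhantomSpec(elements=elements,
                           background_rsp=float(section.get("background_rsp", 0.0)))
    _check_keys(section, {"diameter_mm", "height_mm", "rsp"}, "phantom")
    return water_cylinder(diameter_mm=float(section.get("diameter_mm", 180.0)),
                          height_mm=float(section.get("height_mm", 16.0)),
                          rsp=float(section.get("rsp", 1.0)))


def parse_simulation(section: dict, seed: int | None = None) -> SimulationConfig:
    allowed = {f.name for f in dc_fields(SimulationConfig)}
    _check_keys(section, allowed, "simulation")
    kwargs = dict(section)
    if "beam_extent" in kwargs and isinstance(kwargs["beam_extent"], (list, tuple)):
        kwargs["beam_extent"] = tuple(kwargs["beam_extent"])
    if seed is not None:
        kwargs["seed"] = seed
    return SimulationConfig(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for one simulate/reconstruct/analyze run."""

    grid: VoxelGrid
    phantom: PhantomSpec
    simulation: SimulationConfig
    r_stops: tuple[float, ...] = (2.0, 1.0, 0.75, 0.5, 0.2)
    max_iterations: int = 1000
    x0_mode: str = "uniform"
    roi: ROISpec | None = None
    delta_max: int = 5
    wet_line: tuple[int, int, int, int] | None = None  # (i, j, k0, k1) along z
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.r_stops) == 0:
            raise ValueError("stopping section must list at least one r value")
        if any(not r > 0 for r in self.r_stops):
            raise ValueError("all r_stop values must be > 0")


def load_run_config(source) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file path or a config dict."""
    if isinstance(source, (str, Path)):
        cfg = yaml.safe_load(Path(source).read_text())
    else:
        cfg = dict(source)
    _check_keys(cfg, {"seed", "grid", "phantom", "simulation", "stopping",
                      "analysis"}, "run config")
    grid = parse_grid(cfg.get("grid", {"shape": [96, 8, 96], "voxel_size": 2.0}))
    phantom = parse_phantom(cfg.get("phantom", {}))
    sim = parse_simulation(cfg.get("simulation", {}), seed=cfg.get("seed"))

    stopping = dict(cfg.get("stopping", {}))
    _check_keys(stopping, {"r_stop", "max_iterations", "x0_mode"}, "stopping")
    r_raw = stopping.get("r_stop", [2.0, 1.0, 0.75, 0.5, 0.2])
    r_stops = tuple(float(v) for v in (r_raw if isinstance(r_raw, (list, tuple)) else [r_raw]))

    analysis = dict(cfg.get("analysis", {}))
    _check_keys(analysis, {"roi_start", "roi_extent", "delta_max", "wet_line"},
                "analysis")
    roi = None
    if "roi_extent" in analysis:
        extent = tuple(analysis["roi_extent"])
        if "roi_start" in analysis:
            roi = ROISpec(start=tuple(analysis["roi_start"]), extent=extent)
        else:
            roi = ROISpec.centered(grid.shape, extent)
    wet_line = tuple(analysis["wet_line"]) if "wet_line" in analysis else None
    return RunConfig(grid=grid, phantom=phantom, simulation=sim,
                     r_stops=r_stops,
                     max_iterations=int(stopping.get("max_iterations", 1000)),
                     x0_mode=stopping.get("x0_mode", "uniform"),
                     roi=roi, delta_max=int(analysis.get("delta_max", 5)),
                     wet_line=wet_line, raw=cfg)


def _iterations_to(history: list[dict], r_value: float) -> int | None:
    for rec in history:
        if np.isfinite(rec["r"]) and rec["r"] <= r_value:
            return rec["iteration"]
    return None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return a JSON-serializable report.

    One reconstruction runs to the smallest requested stopping value; images
    at the larger values are snapshots taken as r first crosses each of
    them, so every entry of the report comes from the same proton sample.
    """
    stage = "simulate"
    try:
        truth = make_phantom(config.phantom, config.grid)
        protons = simulate_protons(truth, config.simulation)
        logger.info("simulated %d protons over %d angles", len(protons),
                    config.simulation.n_angles)

        stage = "reconstruct"
        r_min = min(config.r_stops)
        others = tuple(r for r in config.r_stops if r != r_min)
        stop = StoppingConfig(r_stop=r_min, max_iterations=config.max_iterations,
                              x0_mode=config.x0_mode)
        result = reconstruct(protons, config.grid, stop, snapshot_r=others)
        volumes = dict(result.snapshots)
        volumes[r_min] = result.volume

        stage = "noise analysis"
        roi = config.roi or ROISpec.centered(
            config.grid.shape,
            tuple(max(2, min(n // 3, 30)) for n in config.grid.shape))
        nx, ny, nz = config.grid.shape
        wet_line = config.wet_line or (nx // 2, ny // 2, 0, nz - 1)
        i, j, k0, k1 = wet_line

        entries = []
        for r_value in sorted(config.r_stops, reverse=True):
            if r_value not in volumes:  # never reached (max_iterations hit)
                continue
            vol = volumes[r_value]
            mean, var = roi_stats(vol, roi)
            ac = autocorrelation(vol, roi, config.delta_max)
            entries.append({
                "r_stop": r_value,
                "iterations": _iterations_to(result.history, r_value),
                "roi_mean_rsp": mean,
                "roi_sigma_rsp": float(np.sqrt(var)),
                "rho": {ax: ac.rho[ax].tolist() for ax in ac.rho},
                "wet_mm": wet_line_sum(vol, (i, j, k0), "z", k1),
            })
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return {
        "config": config.raw,
        "seed": config.simulation.seed,
        "n_protons": len(protons),
        "final_r": result.state.r,
        "total_iterations": result.state.iteration,
        "roi": {"start": list(roi.start), "extent": list(roi.extent)},
        "wet_line": list(wet_line),
        "reconstructions": entries,
    }
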