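"""End-to-end study orchestration and configuration.

A ``RunConfig`` fully describes a study: physiology preset and overrides,
network source (file or generator preset + seed), solver discretization,
the voxel-size sweep, and evaluation options.  ``run_study`` executes
generate -> solve-ref -> fuse -> evaluate and writes scatter tables plus
a JSON results bundle; the resolved config is serialized alongside so
every bundle is reproducible from its own output directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import vasculature as vasc
from .evaluation import (
    BRAIN_HF_THRESHOLDS,
    TUMOR_HF_THRESHOLDS,
    gaussian_error_propagation,
    hf_correlation,
    linear_regression,
    nearest_neighbor_correction,
    sensitivity_scan,
)
from .fusion import grid_translation_ensemble, make_voxel_grid, run_fusion
from .physiology import PhysiologyParams, brain_params, to_canonical_units, tumor_params
from .reference_solver import discretize, solve_reference_field

__all__ = ["RunConfig", "run_study", "load_config", "physiology_from_config"]

#: Voxel sweep defaults: 50-300 µm in 50 µm steps for the tumor domain,
#: 50 and 100 µm for the small brain domain.
TUMOR_VOXEL_SIZES = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0)
BRAIN_VOXEL_SIZES = (50.0, 100.0)


@dataclass
class RunConfig:
    preset: str = "tumor"  # krogh | parallel | tumor | brain
    seed: int = 0
    physiology: dict = field(default_factory=dict)  # field overrides, canonical units
    network_path: str | None = None  # read instead of generating when set
    network_kwargs: dict = field(default_factory=dict)
    lattice_spacing: float = 15.0
    subsegment_length: float = 50.0
    voxel_sizes: tuple | None = None  # None -> preset default
    n_offsets_large: int = 5  # grid translations for voxels >= offset_threshold
    offset_threshold: float = 200.0
    hf_thresholds: tuple | None = None  # None -> preset default
    sensitivity: bool = True
    error_propagation: bool = True
    error_voxel_size: float = 150.0
    out_dir: str = "oxyfuse_out"

    def resolved_voxel_sizes(self) -> tuple:
        if self.voxel_sizes is not None:
            return tuple(self.voxel_sizes)
        return BRAIN_VOXEL_SIZES if self.preset == "brain" else TUMOR_VOXEL_SIZES

    def resolved_hf_thresholds(self) -> tuple:
        if self.hf_thresholds is not None:
            return tuple(self.hf_thresholds)
        return BRAIN_HF_THRESHOLDS if self.preset == "brain" else TUMOR_HF_THRESHOLDS


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**doc)


def physiology_from_config(preset: str, overrides: dict | None = None) -> PhysiologyParams:
    """Preset physiology with optional per-field overrides.

    Overrides may be plain numbers (canonical units) or ``{value, unit}``
    mappings routed through the unit converter.
    """
    kwargs = {}
    for key, val in (overrides or {}).items():
        if isinstance(val, dict):
            kwargs[key] = to_canonical_units(val["value"], val["unit"])
        else:
            kwargs[key] = float(val)
    if preset == "brain":
        return brain_params(**kwargs)
    return tumor_params(**kwargs)


def build_network(config: RunConfig) -> vasc.VesselNetwork:
    if config.network_path:
        return vasc.read_network(config.network_path)
    kw = dict(config.network_kwargs)
    if config.preset == "krogh":
        kw.setdefault("length", 120.0)
        kw.setdefault("radius", 6.0)
        kw.setdefault("flow", 2.0e5)
        return vasc.generate_single_vessel(**kw)
    if config.preset == "parallel":
        kw.setdefault("n_vessels", 16)
        kw.setdefault("spacing", 100.0)
        kw.setdefault("jitter", 10.0)
        return vasc.generate_parallel_array(seed=config.seed, **kw)
    if config.preset == "brain":
        return vasc.brain_network_preset(seed=config.seed, **kw)
    if config.preset == "tumor":
        return vasc.tumor_network_preset(seed=config.seed, **kw)
    raise ValueError(f"unknown preset {config.preset!r}")


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline and write the result bundle.

    Returns the results dictionary (also written as ``results.json``):
    per-voxel-size regression and HF regression, the sensitivity table,
    and the error-propagation CV summary.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(config)))

    params = physiology_from_config(
        "brain" if config.preset == "brain" else "tumor", config.physiology)
    net = build_network(config)
    vasc.write_network(net, out / "network", format="csv-pair")

    lattice, sources = discretize(net, h=config.lattice_spacing,
                                  ds=config.subsegment_length)
    sol = solve_reference_field(net, lattice, sources, params)

    results: dict = {
        "preset": config.preset,
        "seed": config.seed,
        "solver": {
            "iterations": sol.iterations,
            "total_release": sol.total_release,
            "total_consumption": sol.total_consumption,
            "conservation_error": sol.conservation_error,
        },
        "voxel_sizes": {},
    }

    thresholds = config.resolved_hf_thresholds()
    tables = {}
    for L in config.resolved_voxel_sizes():
        n_off = config.n_offsets_large if L >= config.offset_threshold else 1
        table = grid_translation_ensemble(net, lattice, L, params,
                                          n_offsets=n_off, seed=config.seed)
        tables[L] = table
        table.to_csv(out / f"scatter_L{int(L)}.csv", index=False)
        entry: dict = {"n_offsets": n_off}
        sub = table[table["valid"]]
        entry["n_valid"] = int(len(sub))
        if len(sub):
            entry["mean_gpo2"] = float(sub["gpo2"].mean())
            entry["mean_mpo2"] = float(sub["mpo2"].mean())
        if len(sub) >= 3 and np.ptp(sub["gpo2"].to_numpy()) > 0:
            reg = linear_regression(sub)
            entry["regression"] = asdict(reg)
            try:
                hf = hf_correlation(sub["mpo2"].to_numpy(), sub["gpo2"].to_numpy(),
                                    thresholds)
                entry["hf_regression"] = asdict(hf)
            except ValueError as exc:
                entry["hf_regression"] = {"error": str(exc)}
        results["voxel_sizes"][f"{L:g}"] = entry

    # six-neighbor correction at the smallest voxel size, untranslated grid
    L_min = min(config.resolved_voxel_sizes())
    grid = make_voxel_grid(net.domain_box, L_min)
    maps = run_fusion(net, lattice, grid, params)
    corrected, _cvalid = nearest_neighbor_correction(maps.mpo2, maps.valid)
    try:
        before = linear_regression(maps.gpo2[maps.valid], maps.mpo2[maps.valid])
        # same voxel set before/after: filled vessel-free voxels carry
        # neighbor averages, not model output
        after = linear_regression(maps.gpo2[maps.valid], corrected[maps.valid])
        results["nearest_neighbor"] = {
            "voxel_size": L_min,
            "r2_before": before.r_squared,
            "r2_after": after.r_squared,
        }
    except ValueError as exc:  # too few voxels to regress (tiny studies)
        results["nearest_neighbor"] = {"voxel_size": L_min, "skipped": str(exc)}

    if config.sensitivity or config.error_propagation:
        gridE = make_voxel_grid(net.domain_box, config.error_voxel_size)
        mapsE = run_fusion(net, lattice, gridE, params)
        vis = list(mapsE.inputs.values())
        if config.sensitivity:
            table = sensitivity_scan(vis, config.error_voxel_size, params)
            table.rows.to_csv(out / "sensitivity.csv", index=False)
            results["sensitivity"] = {
                name: table.mean_absolute(name)
                for name in table.rows["input"].unique()
            }
        if config.error_propagation:
            results["error_propagation"] = {}
            for target in ("F", "fvv"):
                ep = gaussian_error_propagation(
                    vis, config.error_voxel_size, params, target=target,
                    seed=config.seed)
                results["error_propagation"][target] = {
                    "average_cv_percent": 100.0 * ep.average_cv,
                    "n_replicates": ep.n_replicates,
                }

    results["elapsed_s"] = time.time() - t0
    (out / "results.json").write_text(json.dumps(results, indent=1, default=float))
    return results
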