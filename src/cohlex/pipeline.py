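"""End-to-end workflow: infer rates -> steady state -> lattice -> polymer ->
observables, with a reproducibility manifest.

A :class:`RunConfig` (constructible from YAML) names the topology, the
measurement source, an optional depletion, and the per-stage simulation
configurations; :func:`pipeline_predict` executes the enabled stages in
order, writes columnar outputs into the run directory, and records a
manifest (config hash, seeds, package versions, derived quantities) from
which the run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import kinetics, lattice, observables, polymer
from .inference import solve_rates
from .measurements import load_measurements
from .network import builtin_topologies


@dataclass
class RunConfig:
    """Declarative description of a full model run."""

    topology: str = "five_state"
    measurements: str = "hela_wt"
    depletion: dict = field(default_factory=dict)  # species -> fraction
    seed: int = 0
    outdir: str = "cohlex_run"
    # stage toggles and scaled-down defaults
    run_lattice: bool = False
    lattice_sites: int = 5000
    lattice_extruders: int = 168
    lattice_chains: int = 4
    lattice_steps: int = 4000
    lattice_burn_in: int = 1000
    run_polymer: bool = False
    polymer_monomers: int = 0  # 0 -> one lattice chain
    polymer_steps_per_update: int = 50
    polymer_burn_in_frames: int = 40
    run_microscopy: bool = False
    ps_bins: int = 60

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def pipeline_predict(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the report bundle as a dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(cfg), "stages": {}}
    t_start = time.time()

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as err:  # persist partial outputs, then surface
                _write_manifest(report, out, cfg, failed=name)
                raise StageError(name, err) from err
            report["stages"][name] = {"wall_s": round(time.time() - t0, 3)}

        return wrap

    holder: dict = {}

    @stage("infer")
    def _infer():
        topo = builtin_topologies()[cfg.topology]
        ms = load_measurements(cfg.measurements)
        rates = solve_rates(topo, ms)
        rates.to_frame().to_csv(out / "rates.csv", index=False)
        holder["rates"] = rates
        holder["totals"] = {sp: m.copy_number for sp, m in ms.items()}

    @stage("steady_state")
    def _steady():
        rates, totals = holder["rates"], holder["totals"]
        spec = kinetics.DepletionSpec(dict(cfg.depletion))
        pred = kinetics.predict_depletion(rates, totals, spec)
        ss = pred.steady
        holder["steady"] = ss
        report["derived"] = {
            "bound_fraction": ss.bound_fraction,
            "residence_time_s": ss.residence_time,
            "active_to_loaded_ratio": ss.active_to_loaded_ratio,
            "relative_extrusion_rate": pred.relative_extrusion_rate,
            "occupancies": pred.occupancies,
            "transition_freqs_per_min": pred.transition_freqs_per_min,
            "tau_1d_s": kinetics.lattice_time_mapping(ss.active_to_loaded_ratio),
        }

    if cfg.run_lattice:

        @stage("lattice")
        def _lattice():
            rates = holder["rates"]
            totals = kinetics.DepletionSpec(dict(cfg.depletion)).apply(
                holder["totals"]
            )
            lat_cfg = lattice.LatticeConfig(
                n_sites=cfg.lattice_sites,
                n_extruders=cfg.lattice_extruders,
                rates=rates,
                totals=totals,
                n_chains=cfg.lattice_chains,
                n_steps=cfg.lattice_steps,
                burn_in_steps=cfg.lattice_burn_in,
                seed=cfg.seed,
            )
            res = lattice.run(lat_cfg)
            res.series.to_csv(out / "lattice_series.csv", index=False)
            holder["lattice"] = res
            report["derived"]["loaded_density_per_mb"] = res.mean(
                "loaded_density_per_mb"
            )
            report["derived"]["percolation"] = res.mean("percolation")
            report["derived"]["collided_fraction"] = res.mean("collided_fraction")

    if cfg.run_polymer:

        @stage("polymer")
        def _polymer():
            res = holder["lattice"]
            n_mono = cfg.polymer_monomers or (
                cfg.lattice_sites // cfg.lattice_chains
            )
            pcfg = polymer.PolymerConfig(
                n_monomers=n_mono,
                seed=cfg.seed + 1,
                steps_per_lattice_update=cfg.polymer_steps_per_update,
            )
            sub = _restrict_to_first_chain(res, n_mono)
            frames = polymer.run_polymer(
                pcfg, sub, burn_in_frames=cfg.polymer_burn_in_frames
            )
            holder["frames"] = frames
            curve = observables.contacts_and_ps(frames, n_bins=cfg.ps_bins)
            curve.to_csv(out / "ps_curve.csv")
            holder["ps"] = curve

    if cfg.run_microscopy:

        @stage("microscopy")
        def _microscopy():
            frames = holder["frames"]
            ss = holder["steady"]
            n_ext = cfg.lattice_extruders * (
                (cfg.lattice_sites // cfg.lattice_chains) / cfg.lattice_sites
            )
            unloaded = int(round(n_ext * (1.0 - ss.bound_fraction)))
            report["derived"]["vermicelli_score"] = observables.vermicelli_score(
                frames, unloaded, seed=cfg.seed + 2
            )

    report["wall_s"] = round(time.time() - t_start, 3)
    _write_manifest(report, out, cfg)
    return report


class _ChainView:
    def __init__(self, frames):
        self.frames = frames


def _restrict_to_first_chain(res: "lattice.LatticeRun", n_mono: int):
    """Project lattice frames onto the first chain for polymer driving."""
    frames = []
    for fr in res.frames:
        inside = (
            (fr["state"] != 0) & (fr["left"] >= 0) & (fr["right"] < n_mono)
        )
        frames.append(
            {
                "state": fr["state"][inside],
                "left": fr["left"][inside],
                "right": fr["right"][inside],
            }
        )
    return _ChainView(frames)


def _write_manifest(report, out: Path, cfg: RunConfig, failed=None):
    import scipy

    manifest = {
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "versions": {
            "cohlex": _version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "failed_stage": failed,
        "report": _jsonable(report),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _version():
    from . import __version__

    return __version__


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
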