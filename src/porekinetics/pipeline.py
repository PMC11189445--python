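"""Config-driven orchestration of the analysis stages.

A pipeline config is a YAML document:

.. code-block:: yaml

    seed: 1
    outdir: out
    stages:
      - stage: simulate
        params: {n_ions: 4, duration: 50.0, voltage: -500.0}
      - stage: permeation
        params: {traces: auto, upper: 18.0, lower: -18.0, hysteresis: 2.0}
      - stage: pmf
        params: {traces: auto, z_min: -40.0, z_max: 40.0, bin_width: 2.0}

Stages run in the listed order; ``traces: auto`` consumes the most recent
trace-producing stage. Every output file carries the config hash, the seed,
and the package version, so identical config + seed reproduce byte-identical
outputs. A stage failure leaves completed outputs intact and is recorded in
the manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .gating import fit_boltzmann
from .io import read_ion_traces, read_structure, write_ion_traces
from .model import build_pore_frame
from .permeation import detect_events, estimate_conductance
from .poreprofile import (BONDI_RADII, HOLE_SIMPLE_RADII, assign_radii,
                          compute_profile, gate_metrics)
from .solvation import ion_density_profile, pmf_from_density
from .synthetic import GVCurve, LangevinSpec, simulate_ion_langevin

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

KNOWN_STAGES = {"simulate", "profile", "permeation", "pmf", "gv"}

RADIUS_SETS = {"simple": HOLE_SIMPLE_RADII, "bondi": BONDI_RADII}


class PipelineConfig:
    """Validated pipeline configuration with a stable content hash."""

    def __init__(self, data: dict):
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        stages = data.get("stages")
        if not isinstance(stages, list) or not stages:
            raise ValueError("config needs a non-empty 'stages' list")
        for i, st in enumerate(stages):
            if not isinstance(st, dict) or "stage" not in st:
                raise ValueError(f"stage {i}: each entry needs a 'stage' key")
            if st["stage"] not in KNOWN_STAGES:
                raise ValueError(f"stage {i}: unknown stage {st['stage']!r} "
                                 f"(known: {sorted(KNOWN_STAGES)})")
            params = st.get("params", {})
            if not isinstance(params, dict):
                raise ValueError(f"stage {i}: 'params' must be a mapping")
        self.data = data
        self.seed = int(data.get("seed", 0))
        self.outdir = Path(data.get("outdir", "porekinetics_out"))
        self.stages = stages

    @property
    def hash(self) -> str:
        canonical = json.dumps(self.data, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig(yaml.safe_load(fh))


def _meta(cfg: PipelineConfig) -> dict:
    return {"config_hash": cfg.hash, "seed": cfg.seed, "version": __version__}


def _write_tsv(path: Path, header: list[str], rows, cfg: PipelineConfig):
    with open(path, "w") as fh:
        for k, v in _meta(cfg).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(f"{v:.8g}" if isinstance(v, float) else str(v)
                               for v in row) + "\n")


def _write_json(path: Path, payload: dict, cfg: PipelineConfig):
    payload = {"meta": _meta(cfg), **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def run_pipeline(config: PipelineConfig | dict, base_dir=".") -> dict:
    """Run the configured stages in order and return the output manifest."""
    if isinstance(config, dict):
        config = PipelineConfig(config)
    base = Path(base_dir)
    outdir = base / config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"meta": _meta(config), "outputs": [], "failures": []}
    last_traces = None  # (IonTraceSet-like trace list, duration, voltage)

    for i, st in enumerate(config.stages):
        name = st["stage"]
        p = dict(st.get("params", {}))
        tag = f"{i:02d}_{name}"
        try:
            if name == "simulate":
                p.setdefault("seed", config.seed)
                spec = LangevinSpec(**p)
                trace_set, expected = simulate_ion_langevin(spec)
                path = outdir / f"{tag}_traces.tsv"
                write_ion_traces(trace_set, path, xy=trace_set.meta.get("xy"),
                                 header_comments=[f"{k}: {v}" for k, v
                                                  in _meta(config).items()])
                _write_json(outdir / f"{tag}_summary.json",
                            {"expected_crossings_per_ion": expected,
                             "n_ions": spec.n_ions, "duration_ns": spec.duration,
                             "voltage_mV": spec.voltage}, config)
                last_traces = (list(trace_set), spec.duration, spec.voltage)
                manifest["outputs"] += [str(path), str(outdir / f"{tag}_summary.json")]
            elif name == "profile":
                model = read_structure(base / p["structure"])
                rs = RADIUS_SETS[p.get("radius_set", "simple")]
                model = assign_radii(model, rs)
                frame = build_pore_frame(
                    model, p.get("gate", "resid 394-398 and heavy"),
                    p.get("filter", "resid 358-361 and heavy"))
                prof = compute_profile(
                    model, frame, tuple(p.get("z_range", (-15.0, 35.0))),
                    step=p.get("step", 0.25),
                    anneal={"seed": p.get("seed", config.seed)})
                path = outdir / f"{tag}_profile.tsv"
                _write_tsv(path, ["z", "radius", "cx", "cy", "converged"],
                           [(float(z), float(r), float(c[0]), float(c[1]), int(cv))
                            for z, r, c, cv in zip(prof.z_grid, prof.radius,
                                                   prof.center_xy, prof.converged)],
                           config)
                summary = {"radius_set": rs.name, "step": prof.meta["step"]}
                if "residues" in p:
                    summary["constrictions"] = gate_metrics(
                        prof, model, frame, p["residues"])
                zmin, rmin = prof.min_radius()
                summary["min_radius"] = {"z": zmin, "radius": rmin,
                                         "diameter": 2 * rmin}
                _write_json(outdir / f"{tag}_summary.json", summary, config)
                manifest["outputs"] += [str(path), str(outdir / f"{tag}_summary.json")]
            elif name == "permeation":
                traces, duration, voltage = _resolve_traces(p, base, last_traces)
                events = detect_events(traces, p.get("upper", 18.0),
                                       p.get("lower", -18.0),
                                       p.get("hysteresis", 2.0))
                path = outdir / f"{tag}_events.tsv"
                _write_tsv(path, ["ion_id", "t_enter", "t_exit", "direction"],
                           [(e.ion_id, e.t_enter, e.t_exit, e.direction)
                            for e in events], config)
                est = estimate_conductance(
                    [len(events)], p.get("duration", duration),
                    p.get("voltage", voltage),
                    p.get("spread_convention", "population_sd"))
                _write_json(outdir / f"{tag}_conductance.json",
                            {"events_per_replica": est.events_per_replica,
                             "g_per_replica_pS": est.g_per_replica,
                             "g_mean_pS": est.g_mean, "g_spread_pS": est.g_spread,
                             "spread_convention": est.spread_convention,
                             "duration_ns": est.duration,
                             "voltage_mV": est.voltage}, config)
                manifest["outputs"] += [str(path),
                                        str(outdir / f"{tag}_conductance.json")]
            elif name == "pmf":
                traces, _, _ = _resolve_traces(p, base, last_traces)
                edges = np.arange(p.get("z_min", -40.0),
                                  p.get("z_max", 40.0) + p.get("bin_width", 2.0),
                                  p.get("bin_width", 2.0))
                dens = ion_density_profile(traces, edges,
                                           p.get("radial_cutoff", 12.0))
                prof = pmf_from_density(
                    dens, reference_window=tuple(p.get("reference_window",
                                                       (-40.0, -30.0))))
                path = outdir / f"{tag}_pmf.tsv"
                _write_tsv(path, ["z", "F_kcal_mol"],
                           [(float(z), float(f)) for z, f
                            in zip(prof.z_bins, prof.F)], config)
                manifest["outputs"].append(str(path))
            elif name == "gv":
                import pandas as pd
                df = pd.read_csv(base / p["input"], sep="\t", comment="#")
                curve = GVCurve(voltages=df["voltage_mV"].to_numpy(float),
                                normalized_conductance=df["g_norm"].to_numpy(float))
                fit = fit_boltzmann(curve)
                _write_json(outdir / f"{tag}_fit.json",
                            {"v_half_mV": fit.v_half, "slope_k_mV": fit.slope_k,
                             "residual_sse": fit.residual_sse,
                             "covariance": fit.covariance}, config)
                manifest["outputs"].append(str(outdir / f"{tag}_fit.json"))
        except Exception as exc:  # stage isolation: later stages may still run
            manifest["failures"].append({"stage": name, "index": i,
                                         "error": str(exc)})
    _write_json(outdir / "manifest.json",
                {"outputs": manifest["outputs"],
                 "failures": manifest["failures"]}, config)
    return manifest


def _resolve_traces(params: dict, base: Path, last):
    src = params.get("traces", "auto")
    if src == "auto":
        if last is None:
            raise ValueError("no earlier stage produced traces; "
                             "give an explicit 'traces' path")
        return last
    ts = read_ion_traces(base / src)
    return list(ts), params.get("duration", ts.duration), params.get("voltage", -500.0)
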