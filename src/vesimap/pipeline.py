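"""End-to-end orchestration: simulate/load -> fit -> select -> compare -> report.

Configuration is a YAML mapping with a versioned ``schema_version`` key;
unknown keys are rejected (fail fast). Re-running the same config+seed
reproduces the report bit-exact except for the timestamp field.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError, UndefinedCorrelationError, VesimapError
from .geometry import (GeometryParams, assign_vesicles, count_distribution,
                       pearson_count_radius)
from .io import (read_membrane, read_particle_table, write_particle_table,
                 write_vesicle_table)
from .sphere_stats import estimate_bias, randomness_test, select_vesicles
from .synthetic import SceneConfig, generate_scene

__all__ = ["run_pipeline", "load_config", "SCHEMA_VERSION"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_TOP_KEYS = {"schema_version", "seed", "scene", "inputs", "geometry",
             "selection", "null", "output"}
_SELECTION_KEYS = {"radius_range", "k_values", "rule"}
_NULL_KEYS = {"n_vesicles", "radius_mode", "bias_bins", "ks_mode"}
_INPUT_KEYS = {"particles", "membranes", "dialect", "pixel_size", "euler_sense"}


def load_config(path_or_mapping) -> dict:
    """Load and validate a pipeline config (YAML path or mapping)."""
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_mapping)
    if not isinstance(cfg, dict):
        raise ConfigurationError("pipeline config must be a mapping")
    if cfg.get("schema_version") != SCHEMA_VERSION:
        raise ConfigurationError(
            f"config schema_version must be {SCHEMA_VERSION}, "
            f"got {cfg.get('schema_version')!r}")
    _reject_unknown(cfg, _TOP_KEYS, "top level")
    _reject_unknown(cfg.get("selection", {}), _SELECTION_KEYS, "selection")
    _reject_unknown(cfg.get("null", {}), _NULL_KEYS, "null")
    _reject_unknown(cfg.get("inputs", {}), _INPUT_KEYS, "inputs")
    if ("scene" in cfg) == ("inputs" in cfg):
        raise ConfigurationError("config needs exactly one of 'scene' or 'inputs'")
    return cfg


def _reject_unknown(section, allowed, where) -> None:
    if not isinstance(section, dict):
        raise ConfigurationError(f"{where}: expected a mapping")
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(f"unknown config keys at {where}: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    """Context manager labeling errors with their pipeline stage."""

    def __init__(self, name: str, out_dir: Path | None):
        self.name = name
        self.out_dir = out_dir

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            if self.out_dir is not None:
                (self.out_dir / ".partial").write_text(
                    f"failed at stage {self.name}: {exc}\n")
            raise VesimapError(f"stage {self.name!r} failed: {exc}") from exc
        logger.info("stage %s: done", self.name)
        return False


def run_pipeline(config, out_dir: str | Path) -> dict:
    """Execute the full analysis and return the consolidated report dict.

    Stages: simulate (or load inputs) -> fit vesicles -> copy-number and
    count-radius statistics -> per-k selection, bias estimation, null
    simulation and KS comparison -> report with file manifest.
    """
    cfg = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    partial = out_dir / ".partial"
    if partial.exists():
        partial.unlink()
    seed = int(cfg.get("seed", 0))

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    with _Stage("load", out_dir):
        if "scene" in cfg:
            scene_cfg = SceneConfig(**{**cfg["scene"], "seed": seed})
            particles, membranes, truth = generate_scene(scene_cfg)
            membranes = [membranes] if membranes is not None else None
            report["config"]["scene"] = {
                k: v for k, v in asdict(scene_cfg).items() if k != "bias_table"}
        else:
            inp = cfg["inputs"]
            particles = read_particle_table(
                inp["particles"], dialect=inp.get("dialect"),
                pixel_size=inp.get("pixel_size"),
                euler_sense=inp.get("euler_sense", "reference_to_particle"))
            membranes = ([read_membrane(inp["membranes"])]
                         if inp.get("membranes") else None)
        write_particle_table(particles, out_dir / "particles.csv", dialect="csv")
        report["stages"]["load"] = {"n_particles": len(particles)}

    with _Stage("fit", out_dir):
        params = GeometryParams(**cfg.get("geometry", {}))
        vesicles = assign_vesicles(particles, membranes, params)
        write_vesicle_table(vesicles, out_dir / "vesicles.csv")
        fractions, mean_count = count_distribution(vesicles)
        report["stages"]["fit"] = {"n_vesicles": len(vesicles)}
        report["count_distribution"] = {
            "fractions": {str(k): f for k, f in fractions.items()},
            "mean": mean_count,
        }
        try:
            r, p, n = pearson_count_radius(vesicles)
            report["pearson_count_radius"] = {"r": r, "p_value": p, "n": n}
        except (UndefinedCorrelationError, ValueError) as exc:
            report["pearson_count_radius"] = {"error": str(exc)}

    sel_cfg = cfg.get("selection", {})
    radius_range = tuple(sel_cfg.get("radius_range", (19, 20)))
    k_values = list(sel_cfg.get("k_values", [2, 3]))
    rule = sel_cfg.get("rule", "rounded")
    null_cfg = cfg.get("null", {})
    n_null = int(null_cfg.get("n_vesicles", 2000))

    with _Stage("bias", out_dir):
        bias = estimate_bias(particles, n_bins=int(null_cfg.get("bias_bins", 18)))
        report["bias"] = {
            "bin_edges": bias.bin_edges.tolist(),
            "weights": bias.weights.tolist(),
            "n_source": bias.n_source,
        }

    report["randomness_tests"] = {}
    rng = np.random.default_rng(seed + 1)
    for k in k_values:
        with _Stage(f"randomness_k{k}", out_dir):
            selected = select_vesicles(vesicles, radius_range, k, rule=rule)
            entry: dict = {"n_selected": len(selected),
                           "radius_range": list(radius_range), "rule": rule,
                           "seed": seed}
            if len(selected) < 2:
                entry["skipped"] = "fewer than 2 selected vesicles"
            else:
                ks, exp, null = randomness_test(
                    selected, particles, bias, n_null=n_null, seed=rng,
                    radius_mode=null_cfg.get("radius_mode", "mean"),
                    ks_mode=null_cfg.get("ks_mode", "auto"))
                np.savetxt(out_dir / f"distances_experimental_k{k}.csv",
                           exp.values, header="distance_nm", comments="# ")
                np.savetxt(out_dir / f"distances_null_k{k}.csv",
                           null.values, header="distance_nm", comments="# ")
                entry.update({
                    "D": ks.D, "p_value": ks.p_value, "mode": ks.mode,
                    "n_experimental": ks.n1, "n_null": ks.n2,
                    "mean_experimental_nm": float(exp.values.mean()),
                    "mean_null_nm": float(null.values.mean()),
                })
            report["randomness_tests"][f"k={k}"] = entry

    with _Stage("report", out_dir):
        n_sel = sum(e["n_selected"] for e in report["randomness_tests"].values())
        assert n_sel <= len(vesicles) <= len(particles), \
            "stage-count consistency violated"
        report_path = out_dir / "report.json"
        manifest = {}
        for f in sorted(out_dir.iterdir()):
            if f.is_file() and f.name != "report.json":
                manifest[f.name] = _sha256(f)
        report["file_manifest"] = manifest
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report
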