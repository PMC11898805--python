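"""Config-driven orchestration: simulate -> select -> benchmark.

A run is described by one YAML file with ``seed``, ``out_dir`` (optional,
may be given at call time) and the stage sections ``synthetic``,
``selection``, ``training`` and ``evaluation`` (``model`` is optional).
Each stage's seed is derived deterministically from the run seed unless
the section sets its own, so one integer reproduces the whole run.  All
artifacts land in a single run directory together with a manifest of
SHA-256 hashes and a log of per-stage wall-clock times.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import yaml

from . import __version__
from .evaluation import SplitSpec, run_benchmark, stratified_split
from .models import TrainingConfig, records_xy
from .selection import FitnessSpec, irf_select, make_intervals, vcpa_select
from .synthetic import SyntheticConfig, simulate_dataset

REQUIRED_SECTIONS = ("synthetic", "selection", "training", "evaluation")


def validate_config(config: dict) -> dict:
    """Structural validation; raises naming the missing/invalid section."""
    if not isinstance(config, dict):
        raise ValueError("run config must be a mapping")
    if "seed" not in config:
        raise ValueError("run config missing required section 'seed'")
    for section in REQUIRED_SECTIONS:
        if section not in config:
            raise ValueError(f"run config missing required section '{section}'")
        if not isinstance(config[section], dict):
            raise ValueError(f"section '{section}' must be a mapping")
    ev = config["evaluation"]
    target = ev.get("target", "label")
    if target not in ("label", "polysaccharide", "phenol", "so2"):
        raise ValueError(f"evaluation.target {target!r} is not a known target")
    return config


def load_config(path: str | Path) -> dict:
    return validate_config(yaml.safe_load(Path(path).read_text()))


def _stage_seed(run_seed: int, stage: int) -> int:
    return (run_seed * 1000 + stage) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Execute the full pipeline and return the run directory."""
    config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_seed = int(config["seed"])
    log_lines = [f"hsiq {__version__} run_seed={run_seed}"]

    def _log(stage: str, t0: float) -> None:
        log_lines.append(f"{stage}: {time.perf_counter() - t0:.2f}s")

    # --- synthetic data ----------------------------------------------------
    t0 = time.perf_counter()
    syn = dict(config["synthetic"])
    syn.setdefault("seed", _stage_seed(run_seed, 1))
    for key in ("signature_band", "range_nm"):
        if key in syn:
            syn[key] = tuple(syn[key])
    if "content_ranges" in syn:
        syn["content_ranges"] = {k: tuple(v) for k, v in syn["content_ranges"].items()}
    syn_cfg = SyntheticConfig(**syn)
    dataset = simulate_dataset(syn_cfg)
    dataset.to_csv(out / "dataset.csv")
    syn_cfg.to_yaml(out / "synthetic_config.yaml")
    _log("simulate", t0)

    # --- split and selection (training partition only) ---------------------
    t0 = time.perf_counter()
    ev = config["evaluation"]
    target = ev.get("target", "label")
    split = SplitSpec(
        test_fraction=float(ev.get("test_fraction", 0.3)),
        stratify=bool(ev.get("stratify", True)),
        seed=int(ev.get("split_seed", _stage_seed(run_seed, 2))),
    )
    train_set, _ = stratified_split(dataset, split)
    X_tr, y_tr = records_xy(train_set, target)

    sel = dict(config["selection"])
    fitness = FitnessSpec(
        task="classification" if target == "label" else "regression",
        max_latent=int(sel.get("max_latent", 10)),
        folds=int(sel.get("folds", 5)),
    )
    sel_seed = int(sel.get("seed", _stage_seed(run_seed, 3)))
    intervals = make_intervals(
        X_tr.shape[1], int(sel.get("width", 20)), int(sel.get("step", 10))
    )
    irf = irf_select(
        X_tr, y_tr, intervals, fitness,
        n_iterations=int(sel.get("irf_iterations", 1000)),
        n_keep=int(sel.get("irf_keep", 10)),
        seed=sel_seed,
    )
    irf.to_json(out / "selection_irf.json", dataset.grid.centers)
    vcpa = vcpa_select(
        X_tr, y_tr, fitness,
        n_edf_runs=int(sel.get("vcpa_runs", 50)),
        n_bms=int(sel.get("vcpa_bms", 1000)),
        keep_ratio=float(sel.get("keep_ratio", 0.1)),
        final_pool=int(sel.get("final_pool", 10)),
        seed=sel_seed,
    )
    vcpa.to_json(out / "selection_vcpa.json", dataset.grid.centers)
    _log("select", t0)

    # --- benchmark ---------------------------------------------------------
    t0 = time.perf_counter()
    tr = dict(config["training"])
    tr.setdefault("seed", _stage_seed(run_seed, 4))
    training = TrainingConfig(**tr)
    table = run_benchmark(
        dataset,
        {"iRF": irf, "VCPA": vcpa},
        target=target,
        training=training,
        split=split,
        arch_overrides=config.get("model"),
    )
    table.to_frame().to_csv(out / "benchmark.csv", index=False)
    (out / "benchmark.json").write_text(
        json.dumps(
            {
                "configs": table.configs,
                "cells": {
                    f"{g}/{m}": rep.as_dict() for (g, m), rep in table.cells.items()
                },
            },
            indent=2,
        )
    )
    pred_dir = out / "predictions"
    pred_dir.mkdir(exist_ok=True)
    for (group, model), frame in table.predictions.items():
        frame.to_csv(pred_dir / f"{group}_{model}.csv", index=False)
    _log("benchmark", t0)

    # --- manifest + log ----------------------------------------------------
    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
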