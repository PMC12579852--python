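"""End-to-end pipeline: simulate data, compute metrics, fit, simulate FMR.

``run_pipeline`` chains the stages with one root seed and writes every
intermediate table to an output directory, so a fixed configuration is
byte-reproducible.  Configuration is a plain dict (typically loaded from
YAML); see ``DEFAULT_CONFIG`` for the recognized keys.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import write_table
from .metrics import sequence_table
from .models import (MCMCSettings, StandardizationConstants, build_dataset,
                     coefficient_summary, fit_model)
from .fmr import FMRConfig, run_grid
from .synthetic import TruthParameters, generate_foraging_data, generate_whales

log = logging.getLogger("whaleresp")

DEFAULT_CONFIG = {
    "seed": 0,
    "n_whales": 20,
    "n_sequences_per_whale": 8,
    "designs": ["recovery_breath_count"],
    "mcmc": {"chains": 3, "iterations": 4000, "warmup": 1500},
    "check_convergence": False,
    "fmr_iterations": 2000,
}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: dict, out_dir) -> dict:
    """Run simulate-data -> compute-metrics -> fit-model(s) -> simulate-fmr.

    Returns a dict of artifact paths.  Any stage failure propagates with a
    stage-labeled message.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    log.info("pipeline start: seed=%d config_hash=%s version=%s",
             seed, _config_hash(cfg), __version__)
    artifacts = {}

    stage = "simulate-data"
    try:
        params = TruthParameters(seed=seed)
        whales = generate_whales(cfg["n_whales"], params, seed=seed)
        events, dives, manifest = generate_foraging_data(
            whales, params, cfg["n_sequences_per_whale"], seed=seed + 1)
        for name, df in [("whales", whales), ("breath_events", events),
                         ("dives", dives)]:
            path = out / f"{name}.csv"
            write_table(df, path)
            artifacts[name] = path
        manifest.to_json(out / "truth_manifest.json")
        artifacts["truth_manifest"] = out / "truth_manifest.json"

        stage = "compute-metrics"
        metrics = sequence_table(events, dives)
        write_table(metrics, out / "sequence_metrics.csv")
        artifacts["sequence_metrics"] = out / "sequence_metrics.csv"

        stage = "fit-model"
        mcmc_cfg = cfg["mcmc"]
        constants = StandardizationConstants()
        constants.set("tl", params.tl_mean_m, params.tl_sd_m)
        constants.set("bai", params.bai_mean, params.bai_sd)
        for design in cfg["designs"]:
            data = build_dataset(design, metrics, whales,
                                 constants=StandardizationConstants(
                                     dict(constants.values)))
            fit = fit_model(
                data,
                mcmc=MCMCSettings(chains=mcmc_cfg["chains"],
                                  iterations=mcmc_cfg["iterations"],
                                  warmup=mcmc_cfg["warmup"], seed=seed + 2),
                check=cfg["check_convergence"])
            summary = coefficient_summary(fit)
            path = out / f"coefficients_{design}.csv"
            write_table(summary, path)
            artifacts[f"coefficients_{design}"] = path

        stage = "simulate-fmr"
        fmr_cfg = FMRConfig(iterations=int(cfg["fmr_iterations"]),
                            seed=seed + 3)
        result = run_grid(fmr_cfg)
        write_table(result.combos, out / "fmr_combos.csv")
        write_table(result.comparisons, out / "fmr_comparisons.csv")
        artifacts["fmr_combos"] = out / "fmr_combos.csv"
        artifacts["fmr_comparisons"] = out / "fmr_comparisons.csv"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    log.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return artifacts
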