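"""End-to-end pipeline: wells -> preprocessing -> CV comparison -> map -> risk.

Driven by a nested config dict (normally from YAML); every stage logs its
parameters and counts, artifacts are stamped with the config hash and seed
in a manifest, and two runs with identical config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate, preprocess, risk
from .bpnn import NetworkSpec, TrainConfig
from .grids import (
    ConcentrationGrid, make_grid, read_wells, write_grid_ascii, write_grid_csv,
    write_wells, write_zones,
)
from .models import KrigingModel, NeuralFieldModel
from .synthetic import FieldSpec, generate_wells
from .variogram import VariogramModel

log = logging.getLogger("asriskmap")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "wells_csv": None,              # path; if absent, simulate
    "simulate": {
        "n_wells": 300,
        "variogram": {"kind": "exponential", "nugget": 0.015,
                      "partial_sill": 0.05, "range": 15000.0},
        "log_mean": -0.0506,  # log10(0.89): survey-like median, ~50% non-detects
        "extent": [0.0, 0.0, 30000.0, 20000.0],
        "detection_limit": 0.9,
        "cluster_factor": 0.0,
    },
    "origin": [0.0, 0.0],
    "split_k": 3,
    "methods": ["ok", "bpnn"],
    "variogram_kind": "exponential",
    "network": {"layer_sizes": [2, 10, 10, 1], "mse_goal": 1e-2,
                "max_epochs": 1000, "restarts": 3},
    "grid": {"cell_size": 1000.0, "padding": 1000.0},
    "exposure": {},                 # overrides of the default ExposureParams
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    import yaml

    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides or {})


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the full workflow and write artifacts under ``outdir``.

    Returns the manifest dict (also written as ``manifest.json``).  Stage
    failures raise with the stage name; artifacts produced before the
    failure are left in place.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"config_hash": config_hash(cfg), "seed": seed, "stages": {}}

    def fail(stage, exc):
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- ingest / simulate -------------------------------------------------
    _stage("wells")
    try:
        if cfg["wells_csv"]:
            wells = read_wells(cfg["wells_csv"])
        else:
            sim = cfg["simulate"]
            vm = VariogramModel(
                sim["variogram"]["kind"], sim["variogram"]["nugget"],
                sim["variogram"]["partial_sill"], sim["variogram"]["range"],
            )
            spec = FieldSpec(vm, sim["log_mean"], tuple(sim["extent"]), seed)
            wells = generate_wells(spec, sim["n_wells"], sim["detection_limit"],
                                   sim.get("cluster_factor", 0.0))
        write_wells(wells, outdir / "wells.csv")
        manifest["stages"]["wells"] = {"status": "ok", "n_wells": len(wells),
                                       "n_censored": int(wells["censored"].sum())}
    except Exception as exc:
        fail("wells", exc)

    # --- preprocess --------------------------------------------------------
    _stage("preprocess")
    try:
        wells = preprocess.recenter(wells, tuple(cfg["origin"]))
        split = preprocess.ordered_split(wells, k=int(cfg["split_k"]))
        split.to_csv(outdir / "split.csv")
        logc = preprocess.log_transform(wells["conc_ugL"])
        pval = preprocess.normality_pvalue(logc) if len(wells) >= 20 else float("nan")
        manifest["stages"]["preprocess"] = {
            "status": "ok", "split_sizes": split.value_counts().to_dict(),
            "log_normality_pvalue": pval,
        }
    except Exception as exc:
        fail("preprocess", exc)

    # --- cross-validation --------------------------------------------------
    _stage("crossval")
    methods = tuple(cfg["methods"])
    net_cfg = cfg["network"]
    spec_net = NetworkSpec(tuple(net_cfg["layer_sizes"]))
    tconf = TrainConfig(mse_goal=net_cfg["mse_goal"],
                        max_epochs=net_cfg["max_epochs"], seed=seed)
    try:
        report = evaluate.cross_validate(
            wells, split, cfg["variogram_kind"], spec_net, tconf,
            restarts=net_cfg["restarts"], methods=methods,
        )
        report.to_csv(outdir / "cv_report.csv")
        selected = evaluate.select_method(report)
        manifest["stages"]["crossval"] = {
            "status": "ok", "selected_method": selected,
            "averages": report.averages.round(6).to_dict(),
        }
    except Exception as exc:
        fail("crossval", exc)

    # --- final fit and map -------------------------------------------------
    _stage("map")
    try:
        grid = make_grid(wells, cfg["grid"]["cell_size"], cfg["grid"]["padding"])
        if selected == "OK":
            res = KrigingModel(wells, cfg["variogram_kind"]).fit()
            res.vfit.model.to_json(outdir / "variogram.json")
            cg = res.predict_grid(grid)
        else:
            res = NeuralFieldModel(wells, tuple(net_cfg["layer_sizes"]), tconf).fit(
                restarts=net_cfg["restarts"])
            res.network.to_json(outdir / "network.json")
            cg = res.predict_grid(grid)
        manifest["stages"]["map"] = {
            "status": "ok", "method": selected,
            "ncols": grid.ncols, "nrows": grid.nrows,
            "cells_predicted": int(np.isfinite(cg["conc_ugL"]).sum()),
        }
    except Exception as exc:
        fail("map", exc)

    # --- risk layers -------------------------------------------------------
    _stage("risk")
    try:
        params = risk.ExposureParams(**cfg["exposure"])
        for name, arr in risk.risk_layers(cg["conc_ugL"], params).items():
            cg.add_layer(name, arr)
        write_grid_csv(cg, outdir / "grid.csv")
        for layer in ("conc_ugL", "HQ", "TR"):
            write_grid_ascii(cg, layer, outdir / f"{layer}.asc")
        for layer in ("conc_class", "tr_level", "hq_level", "suitability"):
            write_zones(cg, layer, outdir / f"zones_{layer}.geojson")
        classes, counts = np.unique(
            cg["conc_class"][cg["conc_class"] != 0], return_counts=True)
        manifest["stages"]["risk"] = {
            "status": "ok", "exposure": params.to_dict(),
            "cells_per_conc_class": {int(c): int(n) for c, n in zip(classes, counts)},
        }
    except Exception as exc:
        fail("risk", exc)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %s", outdir)
    return manifest
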