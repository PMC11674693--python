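"""End-to-end orchestration: simulate -> segment -> patches -> features ->
select -> CNN -> classifier battery.

A single master seed fans out deterministically to per-stage seeds (data
generation, split, CNN initialisation, classifier seeding), so one integer
reproduces a whole run while the stages stay independently reseedable.
Artifacts are plain CSV/PNG/JSON files under a work directory; every stage
writes a small manifest recording the configuration hash and seed so stale
mixes of artifacts are detected.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cnn import TabularCNNClassifier
from .evaluate import CLASSIFIER_NAMES, SplitSpec, run_battery, stratified_split
from .features import FEATURE_NAMES, features_for_patches
from .mrmr import MRMRSelector
from .patches import expand_dataset
from .synthetic import StripParams, generate_dataset, null_params

__all__ = ["default_config", "validate_config", "run_all", "PipelineResult"]

STAGES = ("simulate", "preprocess", "patches", "features", "select", "cnn", "evaluate", "all")


def default_config() -> dict[str, Any]:
    """The full default configuration, one block per stage."""
    return {
        "synthetic": {
            "n_per_label": 100,
            "null_signal": False,
            "params": {},  # StripParams overrides
        },
        "preprocess": {"polarity": "dark", "control_half": 0},
        "patches": {"n_patches": 4, "offsets": [-8, 8]},
        "glcm": {"levels": 64, "d_max": 25, "symmetric": False, "range_mode": "per_image"},
        "features": {"strict_printed_formulas": True},
        "mrmr": {"k": 9, "bins": 16, "criterion": "mid"},
        "cnn": {
            "conv_filters": [8, 16, 32],
            "lr": 0.01,
            "max_epochs": 10,
            "batch_size": 32,
            "momentum": 0.9,
            "val_fraction": 0.15,
            "shuffle_each_epoch": True,
        },
        "eval": {
            "classifiers": list(CLASSIFIER_NAMES),
            "fractions": [0.70, 0.15, 0.15],
        },
        "io": {"workdir": None, "log_level": "INFO"},
    }


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Merge a user config over the defaults, rejecting unknown keys."""
    base = default_config()

    def merge(dst: dict, src: dict, path: str) -> None:
        for key, val in src.items():
            if key not in dst:
                raise KeyError(f"unknown config key {path}{key!r}")
            if isinstance(dst[key], dict) and key != "params":
                if not isinstance(val, dict):
                    raise TypeError(f"config key {path}{key!r} must be a mapping")
                merge(dst[key], val, f"{path}{key}.")
            else:
                dst[key] = val

    merge(base, config or {}, "")
    return base


def config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from one master seed."""
    state = np.random.SeedSequence(int(master_seed) & 0x7FFFFFFF).generate_state(4)
    names = ("data", "split", "cnn", "classifier")
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


class PipelineResult:
    """In-memory artifacts of a full run."""

    def __init__(self) -> None:
        self.images = None
        self.patches = None
        self.feature_table: pd.DataFrame | None = None
        self.ranking: pd.DataFrame | None = None
        self.selected: list[str] | None = None
        self.cnn: TabularCNNClassifier | None = None
        self.cnn_features: np.ndarray | None = None
        self.reports = None
        self.summary: pd.DataFrame | None = None
        self.timings: dict[str, float] = {}


def _strip_params(cfg: dict[str, Any]) -> StripParams:
    overrides = dict(cfg["synthetic"]["params"] or {})
    if "test_line_depth_map" in overrides:
        overrides["test_line_depth_map"] = {
            float(k): float(v) for k, v in overrides["test_line_depth_map"].items()
        }
    if cfg["synthetic"]["null_signal"]:
        return null_params(**overrides)
    return StripParams(**overrides)


def run_all(
    config: dict[str, Any] | None = None,
    seed: int = 42,
    workdir: str | Path | None = None,
    log=print,
) -> PipelineResult:
    """Run every stage and return the in-memory result.

    When ``workdir`` is given, CSV artifacts (feature table, MRMR ranking,
    CNN history, summary, confusion matrices) and a run manifest are
    written there; image/patch PNGs are only written by the file-based CLI
    stages to keep in-process runs light.
    """
    cfg = validate_config(config or {})
    seeds = stage_seeds(seed)
    res = PipelineResult()
    t0 = time.perf_counter()

    def tic(stage: str) -> None:
        res.timings[stage] = time.perf_counter() - t0

    params = _strip_params(cfg)
    res.images = generate_dataset(params, cfg["synthetic"]["n_per_label"], seeds["data"])
    log(f"simulate: {len(res.images)} images "
        f"({len(params.labels)} labels x {cfg['synthetic']['n_per_label']})")
    tic("simulate")

    res.patches = expand_dataset(
        res.images,
        n_patches=cfg["patches"]["n_patches"],
        offsets=tuple(cfg["patches"]["offsets"]),
        polarity=cfg["preprocess"]["polarity"],
        control_half=cfg["preprocess"]["control_half"],
    )
    log(f"patches: {len(res.patches)} patches of 128x32")
    tic("patches")

    res.feature_table = features_for_patches(
        res.patches,
        levels=cfg["glcm"]["levels"],
        d_max=cfg["glcm"]["d_max"],
        symmetric=cfg["glcm"]["symmetric"],
        range_mode=cfg["glcm"]["range_mode"],
        strict_printed_formulas=cfg["features"]["strict_printed_formulas"],
    )
    log(f"features: table {res.feature_table.shape[0]} x {len(FEATURE_NAMES)}")
    tic("features")

    # class labels as strings: concentrations are categories, not magnitudes
    y = np.array([f"{v:g}" for v in res.feature_table["label"]])
    X_all = res.feature_table[list(FEATURE_NAMES)].to_numpy()
    split = SplitSpec(fractions=tuple(cfg["eval"]["fractions"]), seed=seeds["split"])
    tr, va, te = stratified_split(y, split)

    # MRMR and the CNN both see only the training split, so the held-out
    # test samples never influence selection or the learned representation.
    selector = MRMRSelector(
        k=cfg["mrmr"]["k"], bins=cfg["mrmr"]["bins"], criterion=cfg["mrmr"]["criterion"]
    )
    selector.fit(res.feature_table.iloc[tr][list(FEATURE_NAMES)], y[tr])
    res.ranking = selector.ranking_table()
    res.selected = res.ranking["feature"].tolist()[: cfg["mrmr"]["k"]]
    log(f"select: top {cfg['mrmr']['k']} = {res.selected}")
    tic("select")

    cnn_cfg = cfg["cnn"]
    res.cnn = TabularCNNClassifier(
        conv_filters=tuple(cnn_cfg["conv_filters"]),
        lr=cnn_cfg["lr"],
        max_epochs=cnn_cfg["max_epochs"],
        batch_size=cnn_cfg["batch_size"],
        momentum=cnn_cfg["momentum"],
        val_fraction=cnn_cfg["val_fraction"],
        shuffle_each_epoch=cnn_cfg["shuffle_each_epoch"],
        random_state=seeds["cnn"],
    )
    res.cnn.fit(X_all[tr], y[tr])
    res.cnn_features = res.cnn.transform(X_all)
    hist = res.cnn.history_[-1]
    log(f"cnn: {len(res.cnn.history_)} epochs, "
        f"final val acc {hist.get('val_acc', float('nan')):.3f}, "
        f"{res.cnn.n_cnn_features_} extracted features")
    tic("cnn")

    sel_idx = [list(FEATURE_NAMES).index(n) for n in res.selected]
    feature_sets = {
        "All": X_all,
        "MRMR": X_all[:, sel_idx],
        "CNN": res.cnn_features,
    }
    res.reports, res.summary = run_battery(
        feature_sets, y, split,
        classifiers=tuple(cfg["eval"]["classifiers"]),
        seed=seeds["classifier"],
    )
    best = res.summary.loc[res.summary["accuracy"].idxmax()]
    log(f"evaluate: {len(res.reports)} reports; best {best['classifier']}/"
        f"{best['feature_set']} accuracy {best['accuracy']:.2f}%")
    tic("evaluate")

    if workdir is not None:
        wd = Path(workdir)
        wd.mkdir(parents=True, exist_ok=True)
        res.feature_table.to_csv(wd / "features.csv", index=False)
        res.ranking.to_csv(wd / "mrmr_ranking.csv", index=False)
        pd.DataFrame(res.cnn.history_).to_csv(wd / "cnn_history.csv", index=False)
        res.summary.to_csv(wd / "summary.csv", index=False)
        for rep in res.reports:
            pd.DataFrame(rep.confusion, index=rep.labels, columns=rep.labels).to_csv(
                wd / f"confusion_{rep.classifier}_{rep.feature_set}.csv"
            )
        manifest = {
            "config_hash": config_hash(cfg),
            "seed": int(seed),
            "stage_seeds": seeds,
            "version": __version__,
            "timings_s": {k: round(v, 2) for k, v in res.timings.items()},
        }
        (wd / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return res
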