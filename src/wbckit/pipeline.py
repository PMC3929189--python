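"""End-to-end pipeline: simulate -> segment -> extract -> train -> report.

The pipeline is deterministic given (config, seed): every stage draws its
randomness from seeds derived from the master seed, and the emitted JSON
report embeds a version stamp (package version, frozen feature order,
format version, seed) so trained models and reports are traceable.
"""

from __future__ import annotations

import json
import logging
import time

import numpy as np

from . import __version__
from .classifiers import (
    CLASS_LABELS, evaluate, hrcnn_classifier, hrcnn_train, mlp_train,
    svm_train,
)
from .discriminating_region import load_region
from .features import FEATURE_NAMES, FEATURE_ORDER_VERSION, extract_features
from .segmentation import evaluate_segmentation, segment_cell
from .synthetic_data import (
    SyntheticSceneSpec, default_scene_region, generate_feature_dataset,
    generate_scene,
)

log = logging.getLogger("wbckit.pipeline")

FORMAT_VERSION = 1

DEFAULT_CONFIG = {
    "seed": 0,
    "region_file": None,            # None -> default synthetic tone region
    "scenes_per_class": 5,
    "scene_size": [120, 120],
    "tone_quantile": 0.7,
    "speckle_fraction": 0.01,
    "granule_density": 0.0,
    "separation": 5.0,
    "n_per_class": 60,
    "train_fraction": 299 / 450,
    "classifiers": ["mlp", "svm", "hrcnn"],
    "morphology": {"dilation_size": 3, "closing_size": 3, "median_size": 7},
}


def version_stamp(seed=None) -> dict:
    """Metadata block embedded in every pipeline output."""
    return {
        "package_version": __version__,
        "format_version": FORMAT_VERSION,
        "feature_order_version": FEATURE_ORDER_VERSION,
        "feature_names": list(FEATURE_NAMES),
        "seed": seed,
    }


def _load_config(config) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    return cfg


def _stratified_split(X, y, train_fraction, rng):
    train_idx, test_idx = [], []
    for c in dict.fromkeys(y.tolist()):
        idx = np.flatnonzero(y == c)
        idx = rng.permutation(idx)
        k = max(1, int(round(train_fraction * idx.size)))
        k = min(k, idx.size - 1) if idx.size > 1 else k
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k:])
    return np.sort(train_idx), np.sort(test_idx)


def run_pipeline(config=None) -> dict:
    """Execute every stage and return the JSON-serializable report.

    Stages, in order: discriminating-region setup (load or default);
    synthetic-scene simulation per class; per-scene segmentation and
    pixel-level scoring against ground truth; 20-feature extraction from
    each segmented cell; classifier training/testing on a separated
    synthetic feature set; report assembly.

    Raises
    ------
    ValueError / OSError
        On an invalid config or a missing referenced file, before any
        processing starts.
    """
    cfg = _load_config(config)
    seed = int(cfg["seed"])
    t0 = time.time()

    if cfg["region_file"] is not None:
        region = load_region(cfg["region_file"])
    else:
        region = default_scene_region()

    rng = np.random.default_rng(seed)
    report = {"version": version_stamp(seed), "config": cfg,
              "segmentation": [], "features": [], "classification": {}}

    # --- simulate + segment + extract -------------------------------------
    morph = cfg["morphology"]
    for k, cls in enumerate(CLASS_LABELS):
        for s in range(int(cfg["scenes_per_class"])):
            scene_seed = seed * 10007 + k * 101 + s
            spec = SyntheticSceneSpec(
                size=tuple(cfg["scene_size"]),
                tone_quantile=cfg["tone_quantile"],
                speckle_fraction=cfg["speckle_fraction"],
                granule_density=cfg["granule_density"],
                seed=scene_seed,
            )
            scene = generate_scene(spec)
            mask, crop = segment_cell(scene.image, region, **morph)
            metrics = evaluate_segmentation(mask, scene.truth)
            entry = {"class": cls, "scene_seed": scene_seed,
                     **metrics.as_dict()}
            report["segmentation"].append(entry)
            if mask.pixels.any():
                fv = extract_features(scene.image, mask)
                report["features"].append(
                    {"class": cls, "scene_seed": scene_seed,
                     "vector": fv.to_array().tolist()})
            log.info("scene %s/%d: sens=%.3f spec=%.3f", cls, s,
                     metrics.sensitivity, metrics.specificity)

    sens = [e["sensitivity"] for e in report["segmentation"]]
    spec_ = [e["specificity"] for e in report["segmentation"]]
    report["segmentation_summary"] = {
        "mean_sensitivity": float(np.mean(sens)),
        "mean_specificity": float(np.mean(spec_)),
        "n_scenes": len(sens),
    }

    # --- classifier training on a separated synthetic feature set ---------
    X, y = generate_feature_dataset(n_per_class=int(cfg["n_per_class"]),
                                    separation=float(cfg["separation"]),
                                    seed=seed + 1)
    tr, te = _stratified_split(X, y, float(cfg["train_fraction"]),
                               np.random.default_rng(seed + 2))
    for kind in cfg["classifiers"]:
        if kind == "mlp":
            clf = mlp_train(X[tr], y[tr], seed=seed)
        elif kind == "svm":
            clf = svm_train(X[tr], y[tr], seed=seed)
        elif kind == "hrcnn":
            clf = hrcnn_classifier(hrcnn_train(X[tr], y[tr]), X[tr], y[tr])
        else:
            raise ValueError(f"unknown classifier kind {kind!r}")
        report["classification"][kind] = {
            "training": evaluate(clf, X[tr], y[tr]),
            "testing": evaluate(clf, X[te], y[te]),
        }
        log.info("%s: train=%.3f test=%.3f", kind,
                 report["classification"][kind]["training"]["overall"],
                 report["classification"][kind]["testing"]["overall"])

    overall = [r["testing"]["overall"]
               for r in report["classification"].values()]
    report["overall_accuracy"] = float(np.mean(overall)) if overall else None
    log.info("pipeline done in %.1fs", time.time() - t0)
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
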