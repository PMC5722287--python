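"""End-to-end pipeline: filter -> segment -> features -> normalize ->
(optional electrode selection) -> classify, driven by a plain-text config.

The configuration is a flat YAML/JSON document; :func:`default_config`
returns the fully-populated default so every pipeline constant is
reviewable. :func:`run_pipeline` executes the stages, writes the
artifacts (report JSON, feature table, weight table) and returns the
per-classifier evaluation reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .entropy import ARSpec, EntropyParams
from .evaluation import (
    CVSpec,
    ClassifierSpec,
    EvaluationReport,
    loo_cross_validate,
)
from .features import NormalizationSpec, extract_feature_matrix
from .io import write_feature_matrix, write_report, write_weights
from .montage import DEFAULT_REGIONS
from .preprocessing import Recording, segment_recordings
from .selection import compute_accuracy_matrix, electrode_weights, standardize_weights
from .synthetic import generate_cohort

log = logging.getLogger("entrofuse")


def default_config() -> dict:
    """The fully-populated default pipeline configuration."""
    return {
        "filter": {"notch_hz": 50.0, "band": [0.15, 45.0]},
        "epoch_length_s": 1.0,
        "feature_mode": "entropy_fusion",  # entropy_fusion | entropy_subset | ar
        "measures": ["PE", "AE", "SE", "FE"],
        "entropy": {"m": 2, "r_factor": 0.2, "n_grad": 2},
        "ar": {"order": 10},
        "normalization": {"new_min": -1.0, "new_max": 1.0, "per_subject": True},
        "classifiers": ["rbf_svm", "feedforward_net", "random_forest", "nearest_neighbor"],
        "classifier_params": {
            "c": 2.0 ** -1,
            "g": 2.0 ** -5,
            "hidden_units": 20,
            "n_trees": 500,
            "mtry": 22,
            "k_neighbors": 5,
            "n_restarts": 1,
        },
        "cv": {"scheme": "leave_one_out", "unit": "epoch", "holdout_fraction": 0.5},
        "electrodes": None,  # list of names, a region key (A-D), or None for all
        "regions": {k: list(v) for k, v in DEFAULT_REGIONS.items()},
        "select_channels": False,  # compute accuracy-weight electrode ranking
        "seed": 0,
        "output_dir": "entrofuse_out",
    }


def load_config(path: str | Path) -> dict:
    """Read a YAML/JSON config and overlay it on the defaults."""
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in user.items():
        if key not in cfg:
            raise KeyError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _resolve_electrodes(cfg: dict, available: Sequence[str]) -> list[str] | None:
    sel = cfg.get("electrodes")
    if sel is None:
        return None
    if isinstance(sel, str):
        regions = cfg.get("regions") or {}
        if sel not in regions:
            raise KeyError(f"electrodes={sel!r} is neither a list nor a known region")
        sel = regions[sel]
    missing = [e for e in sel if e not in available]
    if missing:
        raise ValueError(f"configured electrodes not in montage: {missing}")
    return list(sel)


def run_pipeline(cfg: dict, recordings: Sequence[Recording] | None = None) -> dict:
    """Execute the full pipeline and write artifacts to ``cfg['output_dir']``.

    If no recordings are given, a synthetic cohort is generated from the
    config seed. Returns ``{"reports": {classifier: EvaluationReport},
    "weights": ElectrodeWeights | None, "paths": {...}}``.
    """
    t0 = time.time()
    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg.get("output_dir", "entrofuse_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    if recordings is None:
        from .synthetic import desk_spec

        spec = desk_spec(seed=seed)
        log.info("no recordings supplied; generating desk-scale cohort (seed=%d)", seed)
        recordings = generate_cohort(spec)

    log.info("preprocessing %d recordings", len(recordings))
    epochs = segment_recordings(
        recordings,
        notch_hz=cfg["filter"]["notch_hz"],
        band=tuple(cfg["filter"]["band"]),
        epoch_length_s=cfg["epoch_length_s"],
    )

    log.info("extracting %s features from %d epochs", cfg["feature_mode"], epochs.n_epochs)
    fm = extract_feature_matrix(
        epochs,
        mode=cfg["feature_mode"],
        measures=cfg.get("measures"),
        entropy_params=EntropyParams(**cfg["entropy"]),
        ar_spec=ARSpec(**cfg["ar"]),
    )
    selected = _resolve_electrodes(cfg, fm.channels)
    if selected is not None:
        fm = fm.select_channels(selected)

    norm = NormalizationSpec(**cfg["normalization"])
    cv = CVSpec(seed=seed, **cfg["cv"])

    weights = None
    if cfg.get("select_channels"):
        log.info("computing accuracy-weight electrode ranking")
        acc = compute_accuracy_matrix(
            fm,
            ClassifierSpec(kind="rbf_svm", seed=seed, **_clf_kw(cfg)),
            cv=CVSpec(scheme="holdout", seed=seed),
            normalization=norm,
        )
        weights = standardize_weights(electrode_weights(acc))
        write_weights(weights, outdir / "electrode_weights.tsv")

    reports: dict[str, EvaluationReport] = {}
    for kind in cfg["classifiers"]:
        t1 = time.time()
        spec = ClassifierSpec(kind=kind, seed=seed, **_clf_kw(cfg))
        reports[kind] = loo_cross_validate(fm, spec, normalization=norm, cv=cv)
        log.info("%s evaluated in %.1f s (Acc %.1f%%)", kind, time.time() - t1,
                 reports[kind].acc)

    write_feature_matrix(fm, outdir / "features.tsv")
    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    report_doc = {
        "entrofuse_version": __version__,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "config": json.loads(cfg_text),
        "seed": seed,
        "elapsed_s": round(time.time() - t0, 2),
        "n_epochs": int(fm.n_epochs),
        "n_features": int(fm.n_features),
        "electrodes": list(fm.channels),
        "reports": {k: r.to_dict() for k, r in reports.items()},
    }
    report_path = write_report(report_doc, outdir / "report.json")
    return {
        "reports": reports,
        "weights": weights,
        "paths": {
            "report": report_path,
            "features": outdir / "features.tsv",
            "weights": outdir / "electrode_weights.tsv" if weights is not None else None,
        },
    }


def _clf_kw(cfg: dict) -> dict:
    return dict(cfg.get("classifier_params", {}))
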