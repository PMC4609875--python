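"""End-to-end pipeline: phantoms → LoG/quantize → features → selection → report.

Configuration is a flat YAML file with one block per stage; every block is
validated before any stage runs, and every artifact is stamped with the
config hash and seed so a run is reproducible from its outputs alone.
Intermediate artifacts are files (CSV/JSON), so stages can be re-run and
tested independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, features, phantom, preprocess
from .gsa import GSAConfig
from .model import FeatureSelectionSVM

log = logging.getLogger("tumortex")

KNOWN_KEYS = {
    "seed", "out_dir", "n_per_class", "shape", "lesion_axes",
    "use_log_filter", "log_sigma", "n_levels", "distances",
    "n_agents", "n_iters", "g0", "theta", "p", "variant", "knn_k",
}


@dataclass
class PipelineConfig:
    """Validated stage parameters for a full phantom-to-report run."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    # phantom
    n_per_class: int = 10
    shape: tuple[int, int, int] = (32, 32, 32)
    lesion_axes: tuple[float, float, float] = (10.0, 8.0, 6.0)
    # preprocess
    use_log_filter: bool = True
    log_sigma: float = 1.0
    n_levels: int = 16
    # features
    distances: tuple[int, ...] = (1, 2)
    # selection (published defaults: 100 agents, 500 iterations, G0=100, θ=0.7)
    n_agents: int = 100
    n_iters: int = 500
    g0: float = 100.0
    theta: float = 0.7
    p: float = 0.8
    variant: str = "refined"
    # classification
    knn_k: int = 5
    warnings: list = field(default_factory=list, repr=False)

    def config_hash(self) -> str:
        d = {k: v for k, v in asdict(self).items() if k != "warnings"}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(path_or_dict) -> PipelineConfig:
    """Parse and validate a config file (or dict); aggregate all errors.

    Unknown keys warn (forward compatibility); constraint violations are
    collected and raised together as one ValueError.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict or {})
    warnings = []
    for key in list(raw):
        if key not in KNOWN_KEYS:
            warnings.append(f"unknown config key {key!r} ignored")
            raw.pop(key)
    for key in ("shape", "lesion_axes", "distances"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    cfg.warnings = warnings

    errors = []
    if cfg.log_sigma <= 0:
        errors.append("log_sigma must be > 0")
    if cfg.n_levels < 2:
        errors.append("n_levels must be >= 2")
    if cfg.n_agents < 2:
        errors.append("n_agents must be >= 2")
    if not 0 < cfg.theta < 1:
        errors.append("theta must be in (0, 1)")
    if not 0 < cfg.p <= 1:
        errors.append("p must be in (0, 1]")
    if cfg.n_per_class < 1:
        errors.append("n_per_class must be >= 1")
    if min(cfg.shape) < 8:
        errors.append("shape components must be >= 8")
    if cfg.knn_k % 2 == 0:
        errors.append("knn_k must be odd")
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    for w in warnings:
        log.warning(w)
    return cfg


def extract_cohort_features(cohort, cfg: PipelineConfig):
    """LoG-filter (optional), quantize and extract the 77-vector per subject."""
    vois, labels, ids = [], [], []
    for lv in cohort:
        vol = lv.volume
        if cfg.use_log_filter:
            vol = preprocess.log_filter(
                vol, preprocess.LoGParams(cfg.log_sigma, cfg.log_sigma, cfg.log_sigma)
            )
        vois.append(preprocess.quantize(vol, lv.mask, cfg.n_levels))
        labels.append(lv.label)
        ids.append(lv.subject_id or f"subj{len(ids):03d}")
    return features.extract_table(vois, labels, ids, distances=cfg.distances)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order; returns paths of the written artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    artifacts = {}

    def stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %-10s done in %.2fs", name, time.time() - t0)
        return result

    spec = phantom.PhantomSpec(
        shape=cfg.shape, lesion_axes=cfg.lesion_axes,
        n_subjects_per_class=cfg.n_per_class, seed=cfg.seed,
    )
    cohort = stage("phantom", lambda: phantom.generate_cohort(spec))
    log.info("generated %d phantom subjects", len(cohort))

    table = stage("extract", lambda: extract_cohort_features(cohort, cfg))
    feat_csv = out / "features.csv"
    table.to_csv(feat_csv, index=False)
    artifacts["features"] = str(feat_csv)

    model = FeatureSelectionSVM.from_dataframe(table)
    gsa_cfg = GSAConfig(
        n_agents=cfg.n_agents, n_iters=cfg.n_iters, g0=cfg.g0,
        p=cfg.p, variant=cfg.variant,
    )
    results = stage(
        "select",
        lambda: model.fit(theta=cfg.theta, seed=cfg.seed, config=gsa_cfg),
    )
    mask_json = out / "mask.json"
    mask_json.write_text(json.dumps({
        **stamp,
        "selected": results.selected_features,
        "C": results.settings.C,
        "sigma": results.settings.sigma,
        "fitness": results.selection.fitness,
        "history": results.fitness_history.tolist(),
    }, indent=1))
    artifacts["mask"] = str(mask_json)

    knn_report = stage(
        "knn",
        lambda: classify.knn_baseline(
            model.X[:, results.mask.mask], model.y, k=min(cfg.knn_k, len(model.y) - 1) | 1
        ),
    )
    report_json = out / "report.json"
    report_json.write_text(json.dumps({
        **stamp,
        "svm": results.report.to_dict(),
        "knn": knn_report.to_dict(),
        "summary": results.summary(),
    }, indent=1))
    artifacts["report"] = str(report_json)
    return artifacts
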