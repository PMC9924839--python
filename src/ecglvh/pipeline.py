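"""End-to-end pipeline: simulate -> detect -> features -> criteria -> model.

``run_pipeline`` executes the full study protocol on a synthetic
cohort and writes every stage artifact plus a manifest into a run
directory.  Reruns with an identical configuration and seed are
bit-identical; the manifest records the configuration hash, seeds,
library versions, and a SHA-256 digest of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import sklearn

from . import __version__
from .criteria import evaluate_criteria_cohort
from .detect import DetectorParams, annotations_to_frame, detect_record
from .features import FEATURE_NAMES, median_amplitudes, segment_beats
from .models import (
    BackpropNetLVH,
    BpnConfig,
    DecisionTreeLVH,
    KMeansLVH,
    SplitPlan,
    split_cases,
)
from .persist import save_model
from .synthetic import CohortSpec, synth_cohort

logger = logging.getLogger("ecglvh")

REQUIRED_SECTIONS = ("cohort", "detector", "model", "split")


class ConfigError(ValueError):
    """Raised when a pipeline configuration is invalid."""


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def validate_config(config: dict) -> dict:
    """Check structure before any work is done; returns a normalised copy."""
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    missing = [s for s in REQUIRED_SECTIONS if s not in config]
    if missing:
        raise ConfigError(f"configuration missing section(s): {', '.join(missing)}")
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in config.items()}
    cfg.setdefault("seed", 0)
    cfg.setdefault("reference_lead", "II")
    cfg["model"].setdefault("kind", "bpn")
    if cfg["model"]["kind"] not in ("bpn", "tree", "kmeans"):
        raise ConfigError(f"unknown model kind {cfg['model']['kind']!r}")
    cfg["model"].setdefault("level", "beat")
    if cfg["model"]["level"] not in ("beat", "case"):
        raise ConfigError("model.level must be 'beat' or 'case'")
    # constructor validation of the subsections, before any stage runs
    DetectorParams(**cfg["detector"])
    CohortSpec(**{**cfg["cohort"], "seed": cfg["seed"]})
    SplitPlan(**{**cfg["split"], "seed": cfg["seed"]})
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_model(cfg: dict, train_df: pd.DataFrame, group_col: str | None):
    kind = cfg["model"]["kind"]
    seed = cfg["seed"]
    opts = {k: v for k, v in cfg["model"].items() if k not in ("kind", "level", "cv")}
    if kind == "tree":
        model = DecisionTreeLVH.from_dataframe(train_df, group_col=group_col, seed=seed)
        return model.fit(cv=SplitPlan(**{**cfg["split"], "seed": seed}))
    if kind == "kmeans":
        model = KMeansLVH.from_dataframe(train_df, group_col=group_col, seed=seed)
        return model.fit(k=int(opts.get("k", 2)))
    bpn_cfg = BpnConfig(
        epochs=int(opts.get("epochs", 400)),
        learning_rate=float(opts.get("learning_rate", 0.01)),
        batch_size=int(opts.get("batch_size", 32)),
        seed=seed,
    )
    model = BackpropNetLVH.from_dataframe(train_df, group_col=group_col, config=bpn_cfg)
    cv_plan = SplitPlan(**{**cfg["split"], "seed": seed}) if cfg["model"].get("cv") else None
    return model.fit(cv=cv_plan)


def run_pipeline(config: dict, outdir) -> Path:
    """Run every stage and write artifacts to ``outdir``.

    Stages: synthetic cohort generation, per-lead R/S detection,
    case-median and per-beat feature construction, the seven voltage
    criteria, balanced subject-grouped train/test split, model fit,
    and held-out evaluation.  Any stage error halts the run with the
    stage name and offending subject id.
    """
    cfg = validate_config(config)
    chash = config_hash(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    logger.info("pipeline start: config %s seed %s -> %s", chash, seed, outdir)

    spec = CohortSpec(**{**cfg["cohort"], "seed": seed})
    cases, truth_table = synth_cohort(spec)
    params = DetectorParams(**cfg["detector"])

    ann_frames, case_rows, beat_frames = [], [], []
    for case in cases:
        try:
            annotations = detect_record(case.sequence, params)
            frame = annotations_to_frame(annotations)
            frame.insert(0, "subject_id", case.subject_id)
            ann_frames.append(frame)
            medians = median_amplitudes(annotations)
            case_rows.append(
                {
                    "subject_id": case.subject_id,
                    "sex": case.sex,
                    "lvmi": case.lvmi,
                    "label": case.label,
                    **medians.to_dict(),
                }
            )
            beat_frames.append(
                segment_beats(
                    annotations,
                    reference_lead=cfg["reference_lead"],
                    subject_id=case.subject_id,
                    label=case.label,
                )
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage 'detect/features' failed for subject {case.subject_id}: {exc}"
            ) from exc

    annotations_df = pd.concat(ann_frames, ignore_index=True)
    case_features = pd.DataFrame(case_rows)
    beat_table = pd.concat(beat_frames, ignore_index=True)

    criteria_reports = evaluate_criteria_cohort(
        case_features[list(FEATURE_NAMES)],
        case_features["label"],
        sex=case_features["sex"],
    )

    plan = SplitPlan(**{**cfg["split"], "seed": seed})
    if cfg["model"]["level"] == "beat":
        train_df, test_df = split_cases(beat_table, plan, group_col="subject_id")
        group_col = "subject_id"
    else:
        train_df, test_df = split_cases(case_features, plan)
        group_col = None
    results = _fit_model(cfg, train_df, group_col)
    report = results.evaluate(test_df[list(FEATURE_NAMES)], test_df["label"])

    # ---- write artifacts --------------------------------------------
    artifacts = {}
    annotations_df.to_csv(outdir / "annotations.csv", index=False)
    case_features.to_csv(outdir / "features.csv", index=False)
    beat_table.to_csv(outdir / "beats.csv", index=False)
    truth_table.to_csv(outdir / "truth_features.csv", index=False)
    (outdir / "criteria_reports.json").write_text(
        json.dumps(
            {
                "config_hash": chash,
                "reports": {k: v.as_dict() for k, v in criteria_reports.items()},
            },
            indent=1,
            default=float,
        )
    )
    (outdir / "model_report.json").write_text(
        json.dumps(
            {
                "config_hash": chash,
                "model": cfg["model"]["kind"],
                "level": cfg["model"]["level"],
                "n_train": len(train_df),
                "n_test": len(test_df),
                "report": report.as_dict(),
            },
            indent=1,
            default=float,
        )
    )
    try:
        save_model(results, outdir / "model.json")
    except TypeError:
        pass
    (outdir / "summary.txt").write_text(results.summary() + "\n")

    for name in (
        "annotations.csv",
        "features.csv",
        "beats.csv",
        "truth_features.csv",
        "criteria_reports.json",
        "model_report.json",
        "summary.txt",
    ):
        artifacts[name] = _sha256(outdir / name)
    if (outdir / "model.json").exists():
        artifacts["model.json"] = _sha256(outdir / "model.json")

    manifest = {
        "config_hash": chash,
        "seed": seed,
        "config": cfg,
        "versions": {
            "ecglvh": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("pipeline done: accuracy %.3f", report.accuracy)
    return outdir
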