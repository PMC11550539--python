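"""End-to-end orchestration: simulate -> train -> classify -> evaluate.

``run_pipeline`` executes the stages named in a config dict (or YAML file),
writes TSV/CSV artifacts plus a machine-readable run manifest (seeds,
stage list, file hashes) and returns the paths. Every stage is a thin call
into the library modules, so the pipeline adds bookkeeping, not behavior.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .cascade import CascadeClassifier, MlpSpec, ThresholdPolicy
from .evaluate import evaluate_predictions
from .synthetic import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def default_config(seed: int = 0) -> dict:
    """A small, fully-specified default run: 3 positive classes plus
    mimickers, desk-scale network sizes."""
    positives = [["PAAD", 140], ["iCCA", 140], ["NormalBile", 120]]
    mimickers = [[f"Mimicker{i:02d}", 80] for i in range(10)]
    return {
        "seed": seed,
        "cohort": {
            "n_probes": 6000,
            "classes": positives + mimickers,
            "delta": 0.3,
            "frac_informative": 0.02,
            "noise_sd": 0.05,
            "purity_range": [0.6, 1.0],
            "ffpe_fraction": 0.5,
            "batch_shift": 0.05,
        },
        "holdout_fraction": 0.3,
        "model": {
            "k": 256,
            "anomaly": {"hidden_widths": [128, 128], "learning_rate": 0.0088,
                        "dropout": 0.2, "l1": 0.00067, "epochs": 60, "batch_size": 64},
            "classifier": {"hidden_widths": [128, 64, 32, 16], "learning_rate": 0.00895,
                           "dropout": 0.0, "l1": 0.00441, "epochs": 120, "batch_size": 64},
        },
    }


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def train_eval_split(sample_sheet: pd.DataFrame, holdout_fraction: float, seed: int):
    """Stratified train/holdout split over truth labels."""
    rng = np.random.default_rng(seed)
    holdout = np.zeros(len(sample_sheet), dtype=bool)
    labels = sample_sheet["label"].to_numpy()
    for cls in pd.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_hold = max(1, int(round(holdout_fraction * len(idx))))
        holdout[rng.choice(idx, size=n_hold, replace=False)] = True
    return ~holdout, holdout


def run_pipeline(config: dict | str | Path, outdir) -> dict:
    """Run the configured stages; returns a dict of artifact paths."""
    if not isinstance(config, dict):
        import yaml

        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text())
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    t0 = time.time()
    artifacts: dict[str, str] = {}

    # -- simulate --------------------------------------------------------
    try:
        cohort_cfg = dict(config["cohort"])
        cohort_cfg["classes"] = [tuple(c) for c in cohort_cfg["classes"]]
        if "purity_range" in cohort_cfg:
            cohort_cfg["purity_range"] = tuple(cohort_cfg["purity_range"])
        cohort = simulate_cohort(CohortConfig(seed=seed, **cohort_cfg))
    except Exception as e:  # noqa: BLE001 - stage attribution
        raise StageError("simulate", e) from e
    cohort.sample_sheet.to_csv(out / "sample_sheet.csv")
    artifacts["sample_sheet"] = str(out / "sample_sheet.csv")

    # -- train -----------------------------------------------------------
    try:
        mcfg = config["model"]
        train_mask, hold_mask = train_eval_split(
            cohort.sample_sheet, float(config.get("holdout_fraction", 0.3)), seed + 1
        )
        X = cohort.beta.T  # samples x probes
        y = cohort.sample_sheet["label"].to_numpy()
        material = cohort.sample_sheet["material"].to_numpy()
        model = CascadeClassifier(
            k=int(mcfg["k"]),
            anomaly_spec=MlpSpec(output="sigmoid", **mcfg["anomaly"]),
            classifier_spec=MlpSpec(output="softmax", **mcfg["classifier"]),
            policy=ThresholdPolicy(),
            seed=seed,
        )
        model.fit(X.loc[train_mask], y[train_mask], batch=material[train_mask])
        model.save(out / "model")
        artifacts["model"] = str(out / "model")
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("train", e) from e

    # -- classify --------------------------------------------------------
    try:
        records = model.predict_records(X.loc[hold_mask], batch=material[hold_mask])
        pred_path = out / "predictions.tsv"
        records.to_csv(pred_path, sep="\t", index=False, float_format="%.6f")
        artifacts["predictions"] = str(pred_path)
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", e) from e

    # -- evaluate --------------------------------------------------------
    try:
        truth = y[hold_mask]
        result = evaluate_predictions(records, truth)
        result.confusion.to_csv(out / "confusion.tsv", sep="\t")
        summary = {
            "accuracy": result.accuracy,
            "per_class_sensitivity": result.per_class_sensitivity,
            "anomaly_pass_rate": result.anomaly_pass_rate,
        }
        (out / "evaluation.json").write_text(json.dumps(summary, indent=2))
        artifacts["confusion"] = str(out / "confusion.tsv")
        artifacts["evaluation"] = str(out / "evaluation.json")
    except Exception as e:  # noqa: BLE001
        raise StageError("evaluate", e) from e

    from . import __version__ as pkg_version

    manifest = {
        "version": pkg_version,
        "seed": seed,
        "elapsed_s": round(time.time() - t0, 2),
        "stages": ["simulate", "train", "classify", "evaluate"],
        "artifacts": {k: v for k, v in artifacts.items()},
        "hashes": {
            k: _file_hash(Path(v)) for k, v in artifacts.items() if Path(v).is_file()
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["run_manifest"] = str(out / "run_manifest.json")
    return artifacts
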