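"""Run configuration, artifact writing and the end-to-end pipeline.

``run_pipeline`` wires the stages together: generate (or load) a
dataset, curate it, split, train a model, evaluate, and optionally
produce saliency assessments and an NGED curve. Every artifact lands in
the run's output directory:

* ``checkpoint.npz`` / ``checkpoint.json`` — weights + config + seed
* ``loss_history.csv``   — (epoch, split, loss)
* ``metrics.csv``        — (model, metric, mean, ci_low, ci_high)
* ``roc.csv``            — (fpr, tpr, threshold)
* ``saliency.csv``       — (image_id, model, verdict, reason)
* ``nged.csv``           — (n, nged)
* ``run_log.jsonl``      — config, seeds, versions, stage results

All randomness flows from one root seed.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimator import HybridClassifier
from .metrics import (
    MetricsReport,
    compute_metrics,
    roc_points,
    summarize_folds,
)
from .quantum import build_pqc
from .effective_dimension import nged_curve
from .saliency import classify_trustworthy, gradcam_pp, project_mask
from .synthetic import SyntheticConfig, generate_dataset
from .training import SplitSpec, make_splits

__all__ = ["RunConfig", "run_pipeline", "save_checkpoint", "load_checkpoint"]


@dataclass
class RunConfig:
    """One experiment: model variant + training + split + data settings."""

    head: str = "classical"
    n_qubits: int = 4
    circuit_depth: int = 4
    output_dim: int = 2
    shots: int | None = None
    feature_dim: int = 64
    epochs: int = 20
    freezer_epochs: int = 2
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 8
    augment: bool = True
    split_mode: str = "holdout_70_30"
    k_folds: int = 10
    n_per_class: int = 100
    image_size: int = 320
    noise_sd: float = 0.03
    confounder_prob: float = 0.2
    with_saliency: bool = False
    with_nged: bool = False
    out_dir: str = "run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head not in ("classical", "quantum_expectation", "quantum_sampling"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.head == "classical" and self.shots is not None:
            raise ValueError("shots only apply to quantum heads")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            image_size=self.image_size,
            noise_sd=self.noise_sd,
            confounder_prob=self.confounder_prob,
            seed=self.seed,
        )

    def classifier(self) -> HybridClassifier:
        return HybridClassifier(
            head=self.head,
            n_qubits=self.n_qubits,
            circuit_depth=self.circuit_depth,
            output_dim=self.output_dim,
            shots=self.shots,
            feature_dim=self.feature_dim,
            epochs=self.epochs,
            freezer_epochs=self.freezer_epochs,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            augment=self.augment,
            random_state=self.seed,
        )


def save_checkpoint(clf: HybridClassifier, out_dir: Path, config: RunConfig) -> None:
    weights = dict(clf.network_.params)
    np.savez(out_dir / "checkpoint.npz", **weights)
    with open(out_dir / "checkpoint.json", "w") as fh:
        json.dump(
            {"config": asdict(config), "seed": config.seed, "version": __version__},
            fh,
            indent=2,
        )


def load_checkpoint(out_dir: Path) -> tuple[HybridClassifier, RunConfig]:
    with open(Path(out_dir) / "checkpoint.json") as fh:
        config = RunConfig(**json.load(fh)["config"])
    clf = config.classifier()
    clf.classes_ = np.array([0, 1])
    clf.network_ = clf._build_network()
    from .model import PreprocessSpec

    clf.preprocess_ = PreprocessSpec()
    clf.loss_history_ = []
    with np.load(Path(out_dir) / "checkpoint.npz") as data:
        for key in data.files:
            if key.startswith("extractor."):
                clf.network_.extractor.set_params_array(data[key])
            else:
                clf.network_.head.set_param(key, data[key])
    return clf, config


class _RunLog:
    def __init__(self, path: Path) -> None:
        self._fh = open(path, "a")

    def write(self, stage: str, **payload) -> None:
        rec = {"time": time.time(), "stage": stage, **payload}
        self._fh.write(json.dumps(rec) + "\n")
        self._fh.flush()

    def close(self) -> None:
        self._fh.close()


def _evaluate_fold(
    config: RunConfig, records, labels, train_idx, test_idx, seed: int
) -> tuple[HybridClassifier, MetricsReport, np.ndarray]:
    clf = config.classifier()
    clf.random_state = seed
    clf.fit([records[i].image for i in train_idx], labels[train_idx])
    scores = clf.predict_proba([records[i].image for i in test_idx])[:, 1]
    return clf, compute_metrics(labels[test_idx], scores), scores


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict of artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(out_dir / "run_log.jsonl")
    log.write(
        "start",
        config=asdict(config),
        python=sys.version.split()[0],
        package_version=__version__,
        numpy=np.__version__,
    )
    summary: dict = {"out_dir": str(out_dir)}
    try:
        records, manifest = generate_dataset(config.n_per_class, config.synthetic_config())
        labels = np.array([r.label for r in records])
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        log.write("generate", n_records=len(records))

        split = SplitSpec(mode=config.split_mode, k=config.k_folds, seed=config.seed)
        splits = make_splits(labels, split)
        log.write("split", mode=split.mode, n_splits=len(splits))

        reports, loss_rows, roc_df = [], [], None
        clf = None
        for fold, (tr, te) in enumerate(splits):
            clf, report, scores = _evaluate_fold(config, records, labels, tr, te, config.seed)
            reports.append(report)
            for epoch, loss in enumerate(clf.loss_history_):
                loss_rows.append({"epoch": epoch, "split": fold, "loss": loss})
            if fold == 0:
                roc_df = roc_points(labels[te], scores)
            log.write("train_eval", fold=fold, auc=report.auc, accuracy=report.accuracy)

        pd.DataFrame(loss_rows).to_csv(out_dir / "loss_history.csv", index=False)
        roc_df.to_csv(out_dir / "roc.csv", index=False)
        fold_frame = pd.DataFrame([r.as_dict() for r in reports])
        fold_frame.insert(0, "fold", np.arange(len(reports)))
        fold_frame.to_csv(out_dir / "fold_metrics.csv", index=False)
        if len(reports) >= 2:
            frame = summarize_folds(reports).as_frame()
        else:
            frame = pd.DataFrame(
                {
                    "metric": list(reports[0].as_dict()),
                    "mean": list(reports[0].as_dict().values()),
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
        frame.insert(0, "model", config.head)
        frame.to_csv(out_dir / "metrics.csv", index=False)
        summary["metrics"] = frame
        save_checkpoint(clf, out_dir, config)

        if config.with_saliency:
            tr, te = splits[-1]
            scores = clf.predict_proba([records[i].image for i in te])[:, 1]
            rows = []
            for j, i in enumerate(te):
                if labels[i] != 1 or scores[j] < 0.5:
                    continue
                hm = gradcam_pp(clf.network_, records[i].image, target_class=1)
                verdict = classify_trustworthy(hm, project_mask(records[i].heart_mask))
                rows.append(
                    {
                        "image_id": records[i].patient_id,
                        "model": config.head,
                        "verdict": verdict.verdict,
                        "reason": verdict.reason,
                    }
                )
            sal = pd.DataFrame(rows, columns=["image_id", "model", "verdict", "reason"])
            sal.to_csv(out_dir / "saliency.csv", index=False)
            summary["saliency"] = sal
            log.write("saliency", n=len(sal))

        if config.with_nged:
            spec = build_pqc(config.n_qubits, config.circuit_depth)
            curve = nged_curve(
                spec,
                max(config.output_dim, 2),
                np.logspace(2, 6, 17),
                seed=config.seed,
            )
            curve.as_frame().to_csv(out_dir / "nged.csv", index=False)
            summary["nged"] = curve
            log.write("nged", n_grid=len(curve.sizes))
    except Exception as exc:  # pragma: no cover - error path
        log.write("error", error=f"{type(exc).__name__}: {exc}")
        log.close()
        raise
    log.write("done")
    log.close()
    return summary
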