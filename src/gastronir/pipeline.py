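"""End-to-end orchestration of the two study workflows.

``run_origin_id`` reproduces the origin-discrimination protocol:
replicate averaging, SD + normalization preprocessing, SPXY 3:1 split
with integer class codes as the response, training-set augmentation,
fitting each model in the roster and evaluating on the untouched test
set.  ``run_quantitation`` runs the calibration protocol per component
(GA, HA, PE, PB, PC, PA, GA+HA, total): the SPXY split is recomputed with
that component as the response, regressors are fit on the augmented
training set, and each model is reported with cross-validated training
statistics (Rv2, MRECV, RMSECV) and held-out prediction statistics (Rp2,
MREP, RMSEP).

The test partition never enters augmentation, cross-validation,
hyperparameter selection or training; each run records the sample ids
that reached every training stage so that this hygiene is verifiable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .augmentation import AugmentConfig, augment_matrix
from .cnn import CNNClassifier, CNNRegressor, TrainConfig
from .contents import ALL_COMPONENTS, ContentTable
from .metrics import (
    ClassReport,
    RegReport,
    classification_report,
    cross_validated_report,
    regression_report,
    report_from_confusion as _report_from_confusion,
)
from .models import GridSearchSVM, KNNModel, PLSCalibration, PLSDAClassifier
from .partition import Split, spxy_split
from .preprocessing import PreprocessConfig, apply_pipeline
from .simulate import SyntheticConfig, SyntheticDataset, generate_dataset
from .spectra import SpectrumSet

__all__ = [
    "RunConfig",
    "RunReport",
    "run_origin_id",
    "run_quantitation",
    "CLASSIFIER_ROSTER",
    "REGRESSOR_ROSTER",
]

logger = logging.getLogger("gastronir")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")

CLASSIFIER_ROSTER = ("plsda", "knn", "svm", "cnn")
REGRESSOR_ROSTER = ("plsr", "knn", "svr", "cnn")


@dataclass
class RunConfig:
    """Everything a workflow run needs; defaults follow the study protocol."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    test_fraction: float = 0.25
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    roster: tuple[str, ...] = ("plsda", "knn", "svm", "cnn")
    train: TrainConfig = field(default_factory=TrainConfig)
    components: tuple[str, ...] = ALL_COMPONENTS
    shared_split: bool = False  # quantitation: one split for all components
    cv_folds: int = 5
    # model-selection budgets (kept modest; all selectable per run)
    pls_max_components: int = 20
    knn_k: int | None = 3
    svm_c_grid: tuple[float, ...] = tuple(2.0 ** k for k in range(-2, 9, 2))
    svm_g_grid: tuple[float, ...] = tuple(2.0 ** k for k in range(-8, 3, 2))
    outdir: str | None = None
    seed: int = 0


@dataclass
class RunReport:
    """Results grid plus provenance; JSON round-trippable."""

    task: str  # "origin_id" or "quantitation"
    class_reports: dict[str, ClassReport] | None = None
    reg_reports: dict[str, dict[str, dict[str, RegReport]]] | None = None
    train_history: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    trace: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {"task": self.task, "provenance": self.provenance}
        if self.class_reports is not None:
            out["class_reports"] = {
                m: r.to_dict() for m, r in self.class_reports.items()
            }
        if self.reg_reports is not None:
            out["reg_reports"] = {
                comp: {
                    m: {ctx: r.to_dict() for ctx, r in by_ctx.items()}
                    for m, by_ctx in by_model.items()
                }
                for comp, by_model in self.reg_reports.items()
            }
        # canonicalize to JSON-representable types (tuples -> lists, numpy
        # scalars -> python) so the dict round-trips through a JSON file
        return json.loads(json.dumps(out, default=_jsonable))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, payload: dict) -> "RunReport":
        report = cls(task=payload["task"], provenance=payload.get("provenance", {}))
        if "class_reports" in payload:
            report.class_reports = {}
            for model, rep in payload["class_reports"].items():
                cm = np.asarray(rep["confusion"])
                # per-class table and aggregates are functions of the matrix
                rebuilt = _report_from_confusion(cm, rep["classes"])
                report.class_reports[model] = rebuilt
        if "reg_reports" in payload:
            report.reg_reports = {
                comp: {
                    model: {ctx: RegReport(**r) for ctx, r in by_ctx.items()}
                    for model, by_ctx in by_model.items()
                }
                for comp, by_model in payload["reg_reports"].items()
            }
        return report

    @classmethod
    def from_json(cls, path) -> "RunReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def metrics_frame(self) -> pd.DataFrame:
        """Tabular summary mirroring the published comparison tables."""
        rows = []
        if self.class_reports is not None:
            for model, rep in self.class_reports.items():
                rows.append(
                    {
                        "model": model,
                        "accuracy": rep.accuracy,
                        "precision": rep.precision,
                        "recall": rep.recall,
                        "f1": rep.f1,
                    }
                )
        if self.reg_reports is not None:
            for comp, by_model in self.reg_reports.items():
                for model, by_ctx in by_model.items():
                    cv = by_ctx.get("cv")
                    pred = by_ctx.get("prediction")
                    rows.append(
                        {
                            "component": comp,
                            "model": model,
                            "Rv2": cv.r2 if cv else np.nan,
                            "MRECV": cv.mre if cv else np.nan,
                            "RMSECV": cv.rmse if cv else np.nan,
                            "Rp2": pred.r2 if pred else np.nan,
                            "MREP": pred.mre if pred else np.nan,
                            "RMSEP": pred.rmse if pred else np.nan,
                        }
                    )
        return pd.DataFrame(rows)


def _seeds(cfg: RunConfig, n: int) -> list[int]:
    # sub-seeds for data / augmentation / models, all derived from one seed
    ss = np.random.SeedSequence(cfg.seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _prepare(cfg: RunConfig, data: SyntheticDataset | None, data_seed: int):
    if data is None:
        data = generate_dataset(cfg.synthetic, seed=data_seed)
    averaged = data.averaged()
    pre = apply_pipeline(averaged, cfg.preprocess)
    return data, pre


def _augmented_train(
    cfg: RunConfig, X: np.ndarray, y: np.ndarray, aug_seed: int
):
    if cfg.augment is None:
        return X, y
    aug = AugmentConfig(**{**asdict(cfg.augment), "seed": aug_seed})
    X_aug, parent = augment_matrix(X, aug)
    return X_aug, np.asarray(y)[parent]


def _classifier(name: str, cfg: RunConfig, seed: int):
    if name == "plsda":
        return PLSDAClassifier(
            max_components=cfg.pls_max_components, cv=cfg.cv_folds, random_state=seed
        )
    if name == "knn":
        return KNNModel(k=cfg.knn_k, task="classify", cv=cfg.cv_folds,
                        random_state=seed)
    if name == "svm":
        return GridSearchSVM(
            c_grid=cfg.svm_c_grid, g_grid=cfg.svm_g_grid, folds=cfg.cv_folds,
            task="classify", random_state=seed,
        )
    if name == "cnn":
        t = cfg.train
        return CNNClassifier(
            learning_rate=t.learning_rate, epochs=t.epochs,
            batch_size=t.batch_size, lr_decay=t.lr_decay,
            clipnorm=t.clipnorm, random_state=seed,
        )
    raise ValueError(f"unknown classifier {name!r}")


def _regressor(name: str, cfg: RunConfig, seed: int):
    if name == "plsr":
        return PLSCalibration(
            max_components=cfg.pls_max_components, cv=cfg.cv_folds, random_state=seed
        )
    if name == "knn":
        return KNNModel(k=cfg.knn_k, task="regress", cv=cfg.cv_folds,
                        random_state=seed)
    if name == "svr":
        return GridSearchSVM(
            c_grid=cfg.svm_c_grid, g_grid=cfg.svm_g_grid, folds=cfg.cv_folds,
            task="regress", random_state=seed,
        )
    if name == "cnn":
        t = cfg.train
        return CNNRegressor(
            learning_rate=t.learning_rate, epochs=t.epochs,
            batch_size=t.batch_size, lr_decay=t.lr_decay,
            clipnorm=t.clipnorm, random_state=seed,
        )
    raise ValueError(f"unknown regressor {name!r}")


def run_origin_id(
    cfg: RunConfig, data: SyntheticDataset | None = None
) -> RunReport:
    """Origin-discrimination workflow; returns per-model classification
    reports on the held-out SPXY test set."""
    data_seed, aug_seed, model_seed = _seeds(cfg, 3)
    data, pre = _prepare(cfg, data, data_seed)
    labels = pre.origin_labels
    if labels is None:
        raise ValueError("origin labels are required for origin identification")
    try:
        codes = data.config.class_codes(labels)
        origin_codes = list(data.config.origin_codes)
    except (KeyError, AttributeError):  # externally supplied labels
        origin_codes = sorted(set(labels))
        lookup = {c: i + 1 for i, c in enumerate(origin_codes)}
        codes = np.array([lookup[l] for l in labels], dtype=int)
    split = spxy_split(pre.absorbance, codes.astype(float), cfg.test_fraction)
    tr, te = list(split.train_indices), list(split.test_indices)
    X_train, y_train = pre.absorbance[tr], codes[tr]
    X_test, y_test = pre.absorbance[te], codes[te]
    logger.info("origin-id: %d train / %d test samples", len(tr), len(te))

    report = RunReport(task="origin_id", class_reports={})
    report.trace.append(("split_train", tuple(pre.sample_ids[i] for i in tr)))
    X_aug, y_aug = _augmented_train(cfg, X_train, y_train, aug_seed)
    report.trace.append(
        ("augment", tuple(pre.sample_ids[i] for i in tr))
    )
    logger.info("origin-id: training on %d spectra after augmentation", len(X_aug))
    to_codes = np.asarray(origin_codes)  # report in origin codes, not ints
    for name in cfg.roster:
        model = _classifier(name, cfg, model_seed)
        if name == "cnn":
            model.fit(X_aug, y_aug, X_test, y_test)
            report.train_history[name] = model.history_.to_frame()
            _save_model(cfg, name, model)
        else:
            model.fit(X_aug, y_aug)
        report.trace.append(("fit:" + name, tuple(pre.sample_ids[i] for i in tr)))
        pred = np.asarray(model.predict(X_test), dtype=int)
        rep = classification_report(
            to_codes[y_test - 1], to_codes[pred - 1], labels=origin_codes
        )
        report.class_reports[name] = rep
        logger.info("origin-id %s: test accuracy %.4f", name, rep.accuracy)
    report.provenance = _provenance(cfg, data, split)
    _write_outputs(cfg, report)
    return report


def run_quantitation(
    cfg: RunConfig, data: SyntheticDataset | None = None
) -> RunReport:
    """Component-content calibration workflow (regression grid)."""
    data_seed, aug_seed, model_seed, cv_seed = _seeds(cfg, 4)
    data, pre = _prepare(cfg, data, data_seed)
    contents: ContentTable = data.contents
    report = RunReport(task="quantitation", reg_reports={})
    shared = None
    for comp in cfg.components:
        y = contents.values_for(comp)
        if cfg.shared_split:
            if shared is None:
                shared = spxy_split(pre.absorbance, y, cfg.test_fraction)
            split = shared
        else:
            split = spxy_split(pre.absorbance, y, cfg.test_fraction)
        tr, te = list(split.train_indices), list(split.test_indices)
        X_train, y_train = pre.absorbance[tr], y[tr]
        X_test, y_test = pre.absorbance[te], y[te]
        report.trace.append(
            (f"split_train:{comp}", tuple(pre.sample_ids[i] for i in tr))
        )
        X_aug, y_aug = _augmented_train(cfg, X_train, y_train, aug_seed)
        report.reg_reports[comp] = {}
        for name in cfg.roster:
            model = _regressor(name, cfg, model_seed)
            if name == "cnn":
                model.fit(X_aug, y_aug, X_test, y_test)
                report.train_history[f"{comp}:{name}"] = model.history_.to_frame()
                _save_model(cfg, f"{comp}_{name}", model)
            else:
                model.fit(X_aug, y_aug)
            report.trace.append(
                (f"fit:{comp}:{name}", tuple(pre.sample_ids[i] for i in tr))
            )
            cv_rep = cross_validated_report(
                lambda: _regressor(name, cfg, model_seed),
                X_aug,
                y_aug,
                folds=cfg.cv_folds,
                seed=cv_seed,
            )
            pred_rep = regression_report(y_test, model.predict(X_test))
            report.reg_reports[comp][name] = {"cv": cv_rep, "prediction": pred_rep}
            logger.info(
                "quantitation %s/%s: Rv2 %.4f Rp2 %.4f RMSEP %.4f",
                comp, name, cv_rep.r2, pred_rep.r2, pred_rep.rmse,
            )
    report.provenance = _provenance(cfg, data, None)
    _write_outputs(cfg, report)
    return report


def _provenance(cfg: RunConfig, data: SyntheticDataset, split: Split | None) -> dict:
    import sklearn

    prov = {
        "seed": cfg.seed,
        "test_fraction": cfg.test_fraction,
        "roster": list(cfg.roster),
        "preprocess": asdict(cfg.preprocess),
        "augment": None if cfg.augment is None else asdict(cfg.augment),
        "train": asdict(cfg.train),
        "n_samples": data.config.n_samples,
        "versions": {
            "numpy": np.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    if split is not None:
        prov["train_indices"] = list(split.train_indices)
        prov["test_indices"] = list(split.test_indices)
    return prov


def _save_model(cfg: RunConfig, name: str, model) -> None:
    if cfg.outdir is None:
        return
    outdir = Path(cfg.outdir) / "models"
    outdir.mkdir(parents=True, exist_ok=True)
    model.network_.save(outdir / name)


def _write_outputs(cfg: RunConfig, report: RunReport) -> None:
    if cfg.outdir is None:
        return
    outdir = Path(cfg.outdir)
    (outdir / "metrics").mkdir(parents=True, exist_ok=True)
    report.to_json(outdir / "report.json")
    report.metrics_frame().to_csv(outdir / "metrics" / "summary.csv", index=False)
    if report.class_reports:
        (outdir / "confusion").mkdir(exist_ok=True)
        for model, rep in report.class_reports.items():
            rep.confusion_frame().to_csv(outdir / "confusion" / f"{model}.csv")
    if report.train_history:
        (outdir / "history").mkdir(exist_ok=True)
        for key, frame in report.train_history.items():
            frame.to_csv(
                outdir / "history" / f"{key.replace(':', '_')}.csv", index=False
            )
    logger.info("outputs written to %s", outdir)
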