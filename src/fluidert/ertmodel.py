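"""The 3-class receptivity classifier and its evaluation.

A random forest is trained on the marker panel to distinguish
pre-receptive (PR), receptive (RE) and post-receptive (PO) uterine-fluid
transcriptomes.  Predictions use a probability-threshold call rule: a sample
is assigned the maximum-probability class only when that probability reaches
tau (default 0.6); otherwise the test reports NO_CALL.  On a transfer-day
sample the call is read as a window-of-implantation (WOI) status: RE means
the WOI is where it should be (normal), PR means it has not opened yet
(delayed), PO means it has already passed (advanced).

Cross-validation groups folds by patient so the three stage-timed samples of
one woman never straddle a train/test split; metrics are macro one-vs-rest
averages over the three classes.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier

from .exprio import ExpressionDataset
from .markers import RFConfig

CLASS_ORDER = ("PR", "RE", "PO")
DEFAULT_TAU = 0.6
NO_CALL = "NO_CALL"
WOI_MAP = {"RE": "normal", "PR": "delayed", "PO": "advanced",
           NO_CALL: "indeterminate"}


class ModelError(ValueError):
    """Invalid input to training or prediction."""


@dataclass
class ERTModel:
    """Fitted receptivity classifier plus its call threshold."""

    markers: list[str]
    forest: RandomForestClassifier
    tau: float = DEFAULT_TAU
    rf_config: RFConfig = field(default_factory=RFConfig)
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.markers:
            raise ModelError("marker list is empty")
        if not (1.0 / 3.0 < self.tau <= 1.0):
            raise ModelError("tau must lie in (1/3, 1]")

    def save(self, path) -> None:
        """Persist as JSON metadata + a pickled forest alongside."""
        path = Path(path)
        meta = {
            "markers": self.markers,
            "tau": self.tau,
            "class_order": list(CLASS_ORDER),
            "rf_config": {"n_trees": self.rf_config.n_trees,
                          "max_features": self.rf_config.max_features,
                          "seed": self.rf_config.seed},
            "class_counts": self.class_counts,
            "forest_file": path.stem + ".forest.pkl",
        }
        path.write_text(json.dumps(meta, indent=2))
        with open(path.parent / meta["forest_file"], "wb") as fh:
            pickle.dump(self.forest, fh)

    @classmethod
    def load(cls, path) -> "ERTModel":
        path = Path(path)
        meta = json.loads(path.read_text())
        with open(path.parent / meta["forest_file"], "rb") as fh:
            forest = pickle.load(fh)
        cfg = RFConfig(n_trees=meta["rf_config"]["n_trees"],
                       max_features=meta["rf_config"]["max_features"],
                       seed=meta["rf_config"]["seed"])
        return cls(meta["markers"], forest, meta["tau"], cfg, meta["class_counts"])


def _design_matrix(dataset: ExpressionDataset, markers) -> np.ndarray:
    missing = [g for g in markers if g not in dataset.values.index]
    if missing:
        raise ModelError(f"marker genes absent from matrix: {missing[:5]}")
    return dataset.values.loc[list(markers)].to_numpy(dtype=float).T


def train(dataset: ExpressionDataset, markers, rf_config: RFConfig | None = None,
          tau: float = DEFAULT_TAU) -> ERTModel:
    """Fit the forest on the panel genes versus stage labels."""
    if dataset.scale != "log2":
        raise ModelError(f"training expects log2 scale, got {dataset.scale}")
    rf_config = rf_config or RFConfig()
    X = _design_matrix(dataset, markers)
    y = dataset.stages().to_numpy()
    counts = pd.Series(y).value_counts()
    for s in CLASS_ORDER:
        if counts.get(s, 0) < 2:
            raise ModelError(f"stage {s} has fewer than 2 training samples")
    forest = RandomForestClassifier(n_estimators=rf_config.n_trees,
                                    max_features=rf_config.max_features,
                                    random_state=rf_config.seed)
    forest.fit(X, y)
    return ERTModel(list(markers), forest, tau, rf_config,
                    {s: int(counts.get(s, 0)) for s in CLASS_ORDER})


def predict_with_threshold(model: ERTModel, dataset: ExpressionDataset,
                           failed_samples=()) -> pd.DataFrame:
    """Per-sample class probabilities, thresholded call and WOI status.

    ``failed_samples`` are libraries that failed upstream QC; they appear in
    the report with NaN probabilities and WOI ``detection_failed``.
    Returns a DataFrame indexed by sample id with columns ``p_PR``, ``p_RE``,
    ``p_PO``, ``call`` and ``woi``.
    """
    if dataset.scale != "log2":
        raise ModelError(f"prediction expects log2 scale, got {dataset.scale}")
    X = _design_matrix(dataset, model.markers)
    proba = model.forest.predict_proba(X)
    # reorder forest class columns into the fixed PR/RE/PO order
    cols = {c: i for i, c in enumerate(model.forest.classes_)}
    proba = np.column_stack([proba[:, cols[c]] if c in cols else np.zeros(len(X))
                             for c in CLASS_ORDER])
    maxp = proba.max(axis=1)
    argmax = proba.argmax(axis=1)
    calls = np.where(maxp >= model.tau,
                     np.array(CLASS_ORDER)[argmax], NO_CALL)
    report = pd.DataFrame(proba, index=dataset.values.columns,
                          columns=[f"p_{c}" for c in CLASS_ORDER])
    report["call"] = calls
    report["woi"] = [interpret_woi(c) for c in calls]
    failed = [s for s in failed_samples if s not in report.index]
    if failed:
        extra = pd.DataFrame(np.nan, index=pd.Index(failed, name=report.index.name),
                             columns=report.columns[:3])
        extra["call"] = "DETECTION_FAILED"
        extra["woi"] = "detection_failed"
        report = pd.concat([report, extra])
    report.index.name = "sample_id"
    return report


def interpret_woi(call: str) -> str:
    """Map a stage call on a transfer-day sample to a WOI status.

    RE -> normal; PR -> delayed (not yet receptive at the expected day);
    PO -> advanced (receptivity already passed); NO_CALL -> indeterminate.
    """
    if call == "DETECTION_FAILED":
        return "detection_failed"
    if call not in WOI_MAP:
        raise ModelError(f"unknown call label {call!r}")
    return WOI_MAP[call]


def _macro_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    acc = float((y_true == y_pred).mean())
    sens, spec, ppv, npv = [], [], [], []
    for c in CLASS_ORDER:
        tp = np.sum((y_true == c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        fp = np.sum((y_true != c) & (y_pred == c))
        tn = np.sum((y_true != c) & (y_pred != c))
        sens.append(tp / (tp + fn) if tp + fn else np.nan)
        spec.append(tn / (tn + fp) if tn + fp else np.nan)
        ppv.append(tp / (tp + fp) if tp + fp else np.nan)
        npv.append(tn / (tn + fn) if tn + fn else np.nan)
    return {"accuracy": acc,
            "sensitivity": float(np.nanmean(sens)),
            "specificity": float(np.nanmean(spec)),
            "ppv": float(np.nanmean(ppv)),
            "npv": float(np.nanmean(npv))}


@dataclass
class CVReport:
    """Per-fold and mean cross-validation metrics."""

    folds: pd.DataFrame  # one row per fold
    fold_patients: list[list[str]]
    k: int
    seed: int
    panel_mode: str = "fixed"

    @property
    def mean(self) -> pd.Series:
        return self.folds.mean()

    def to_json(self, path) -> None:
        payload = {"k": self.k, "seed": self.seed,
                   "panel_mode": self.panel_mode,
                   "folds": self.folds.to_dict(orient="records"),
                   "mean": {k: float(v) for k, v in self.mean.items()},
                   "fold_patients": self.fold_patients}
        Path(path).write_text(json.dumps(payload, indent=2))


def cross_validate(dataset: ExpressionDataset, markers, k: int = 10,
                   rf_config: RFConfig | None = None,
                   group_by_patient: bool = True,
                   select_fn=None) -> CVReport:
    """k-fold cross-validation of the classifier on the panel genes.

    Folds partition patients (all stage-timed samples of one patient stay in
    the same fold) unless ``group_by_patient`` is off, in which case samples
    are folded naively.  Reports accuracy and macro one-vs-rest sensitivity,
    specificity, PPV and NPV per fold.

    With the default fixed ``markers`` the panel was selected on the full
    cohort, so fold estimates carry selection leakage (noted in the report).
    Passing ``select_fn(training_subset) -> marker list`` re-selects the
    panel inside every fold for a nested, leakage-free estimate.
    """
    rf_config = rf_config or RFConfig()
    if k < 2:
        raise ModelError("k must be >= 2")
    meta = dataset.sample_meta
    groups = meta["patient_id"] if group_by_patient else pd.Series(
        meta.index, index=meta.index)
    units = list(pd.unique(groups))
    if k > len(units):
        raise ModelError(f"k={k} exceeds the {len(units)} groupable units")
    rng = np.random.default_rng(rf_config.seed)
    order = rng.permutation(len(units))
    fold_of_unit = {units[j]: i % k for i, j in enumerate(order)}
    fold_ids = groups.map(fold_of_unit).to_numpy()

    y = dataset.stages().to_numpy()
    sample_ids = np.array(dataset.sample_ids)
    X_fixed = _design_matrix(dataset, markers) if select_fn is None else None
    rows, fold_patients = [], []
    for f in range(k):
        test = fold_ids == f
        if select_fn is None:
            X_train, X_test = X_fixed[~test], X_fixed[test]
        else:
            train_ds = dataset.subset_samples(sample_ids[~test])
            fold_markers = list(select_fn(train_ds))
            X_train = _design_matrix(train_ds, fold_markers)
            X_test = _design_matrix(dataset.subset_samples(sample_ids[test]),
                                    fold_markers)
        forest = RandomForestClassifier(n_estimators=rf_config.n_trees,
                                        max_features=rf_config.max_features,
                                        random_state=rf_config.seed + f)
        forest.fit(X_train, y[~test])
        pred = forest.predict(X_test)
        rows.append(_macro_metrics(y[test], pred))
        fold_patients.append(sorted(set(groups[test])))
    mode = "nested" if select_fn is not None else "fixed (panel selected on the full cohort; fold estimates carry selection leakage)"
    return CVReport(pd.DataFrame(rows), fold_patients, k, rf_config.seed, mode)


def lda_project(dataset: ExpressionDataset, markers) -> pd.DataFrame:
    """Two-axis linear-discriminant projection of the panel expression.

    Visualisation aid only; the classifier of record is the forest.  The SVD
    solver handles singular within-class scatter (collinear class means
    simply leave the second axis near-zero).  Deterministic up to axis sign.
    """
    X = _design_matrix(dataset, markers)
    y = dataset.stages().to_numpy()
    counts = pd.Series(y).value_counts()
    singletons = [s for s, c in counts.items() if c < 2]
    if singletons:
        raise ModelError(f"classes with a single sample: {singletons}")
    lda = LinearDiscriminantAnalysis(solver="svd", n_components=min(2, len(counts) - 1))
    coords = lda.fit_transform(X, y)
    if coords.shape[1] == 1:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    return pd.DataFrame(coords[:, :2], index=dataset.values.columns,
                        columns=["LD1", "LD2"])
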