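"""End-to-end orchestration: screen -> decompose -> SRKDA -> NN, with CV.

The full classifier chains, inside each training fold only: two-sample
t-test feature screening, dictionary decomposition of the screened
training matrix, spectral-regression KDA on the class-specific training
components (the columns of A), and one-nearest-neighbor prediction of
held-out subjects coded against the fold's dictionaries.  Stratified
k-fold cross-validation reports accuracy, sensitivity, specificity and
rank-based AUC per fold and pooled over all held-out predictions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import decomposition as dc
from . import features as ft
from . import kda

__all__ = [
    "PipelineConfig",
    "FittedPipeline",
    "CVReport",
    "fit",
    "predict",
    "run_cv",
    "compute_metrics",
    "calibrate_decomp_params",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full classification pipeline.

    ``screen_threshold`` is the uncorrected two-sided p-value cutoff of
    the training-only t-test screen (1.0 disables screening);
    ``positive_class`` is the label treated as disease-positive for
    sensitivity/specificity; ``use_decomposition=False`` gives the
    KDA-only ablation (screened raw features go straight to SRKDA).
    """

    screen_threshold: float = 0.05
    decomp: dc.DecompParams = field(default_factory=dc.DecompParams)
    kernel: kda.KernelSpec = field(default_factory=kda.KernelSpec)
    delta: float | None = None
    n_folds: int = 10
    cv_seed: int = 0
    positive_class: int = 1
    use_decomposition: bool = True
    calibrate_gamma: bool = True
    label_corr_threshold: float = 0.3
    test_tol: float = 1e-6
    test_max_iter: int = 2000

    def __post_init__(self) -> None:
        if not (0.0 < self.screen_threshold <= 1.0):
            raise ValueError(f"screen_threshold must be in (0, 1], got {self.screen_threshold}")
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")


@dataclass
class FittedPipeline:
    """Everything a training fold learned, sufficient for prediction."""

    config: PipelineConfig
    screen: ft.ScreenResult
    model: dc.DecompModel | None    # None in the KDA-only ablation
    kda_model: kda.KDAModel
    train_labels: np.ndarray


@dataclass
class CVReport:
    """Per-fold and pooled cross-validation metrics."""

    fold_assignments: np.ndarray            # subject -> test-fold index
    per_fold: list[dict[str, float]]
    pooled: dict[str, float]
    config: PipelineConfig

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["kernel"]["sigma"] = (
            cfg["kernel"]["sigma"] if isinstance(cfg["kernel"]["sigma"], str)
            else float(cfg["kernel"]["sigma"])
        )
        return {
            "fold_assignments": self.fold_assignments.tolist(),
            "per_fold": self.per_fold,
            "pooled": self.pooled,
            "config": cfg,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _stage(name: str):
    """Context that re-raises stage failures with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def calibrate_decomp_params(
    Xs: np.ndarray,
    labels: np.ndarray,
    base: dc.DecompParams | None = None,
    label_corr_threshold: float = 0.3,
) -> dc.DecompParams:
    """Scale gamma so label-correlated variation is protected in A.

    The decomposition objective is label-blind and splits singular
    directions of the low-rank structure by amplitude: directions
    stronger than the crossover ``27 mu^2 gamma / 4`` are cheaper in the
    non-class-specific part.  The absolute crossover must be set per
    dataset; we place it just above the strongest training singular
    direction whose subject scores correlate with the class labels
    (|Pearson r| >= ``label_corr_threshold``), so that discriminative
    structure stays in the class-specific dictionary while stronger,
    label-independent (confound) directions are absorbed.  If no
    direction correlates with the labels, every direction is protected.
    """
    from dataclasses import replace as _replace

    if base is None:
        base = dc.DecompParams()
    _, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    y = labels - labels.mean()
    ynorm = np.linalg.norm(y)
    protect = s[0]
    if ynorm > 0:
        corr = np.abs(Vt @ y) / (np.linalg.norm(Vt, axis=1) * ynorm)
        hits = np.flatnonzero(corr >= label_corr_threshold)
        protect = s[hits].max() if hits.size else s[0]
    gamma = 1.1 * protect / (27.0 / 4.0 * base.mu**2)
    return _replace(base, gamma=float(gamma))


def fit(train: ft.FeatureMatrix, config: PipelineConfig | None = None) -> FittedPipeline:
    """Fit the full pipeline on training subjects only."""
    if config is None:
        config = PipelineConfig()
    if train.n_classes < 2:
        raise ValueError("training data must contain at least 2 classes")
    if np.any(train.class_counts() < 2):
        raise ValueError(f"each class needs >= 2 training subjects, got {train.class_counts()}")

    with _stage("screen"):
        screen = ft.ttest_screen(train, config.screen_threshold)
        if screen.selected.size == 0:
            raise ValueError("screening removed every feature; raise screen_threshold")
        Xs = train.X[screen.selected]

    model: dc.DecompModel | None = None
    if config.use_decomposition:
        with _stage("decompose"):
            params = config.decomp
            if config.calibrate_gamma:
                params = calibrate_decomp_params(
                    Xs, train.labels, config.decomp, config.label_corr_threshold
                )
            model = dc.train_decompose(ft.FeatureMatrix(Xs, train.labels), params)
        components = model.A
    else:
        components = Xs

    with _stage("kda"):
        kmodel = kda.srkda_fit(components, train.labels, config.kernel, config.delta)

    return FittedPipeline(
        config=config, screen=screen, model=model,
        kda_model=kmodel, train_labels=train.labels,
    )


def predict(pipe: FittedPipeline, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and margin scores for test feature columns."""
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    if X_test.shape[1] == 0:
        return np.empty(0, dtype=int), np.empty(0)
    n_expected = pipe.screen.pvalues.shape[0]
    if X_test.shape[0] != n_expected:
        raise ValueError(
            f"test feature length {X_test.shape[0]} does not match training space {n_expected}"
        )
    Xs = X_test[pipe.screen.selected]
    cfg = pipe.config
    if pipe.model is not None:
        comps = np.empty_like(Xs)
        for j in range(Xs.shape[1]):
            code = dc.test_decompose(
                Xs[:, j], pipe.model, tol=cfg.test_tol, max_iter=cfg.test_max_iter
            )
            comps[:, j] = dc.class_component(code, pipe.model)
    else:
        comps = Xs
    embedded = kda.project(pipe.kda_model, comps)
    return kda.nn_classify(pipe.kda_model, embedded, positive_label=cfg.positive_class)


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None,
    positive_class: int,
) -> dict[str, float]:
    """ACC, SEN, SPE and rank-based (Mann-Whitney) AUC.

    SEN is the fraction of positive-class subjects predicted positive,
    SPE the fraction of negative subjects predicted negative; AUC uses
    the continuous scores with ties contributing 1/2.  With one class
    absent from ``y_true`` only ACC is defined; the rest are NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label lengths differ")
    acc = float(np.mean(y_true == y_pred))
    pos = y_true == positive_class
    neg = ~pos
    if not (pos.any() and neg.any()):
        return {"ACC": acc, "SEN": np.nan, "SPE": np.nan, "AUC": np.nan}
    sen = float(np.mean(y_pred[pos] == positive_class))
    spe = float(np.mean(y_pred[neg] != positive_class))
    auc = np.nan
    if scores is not None and np.all(np.isfinite(scores)):
        auc = float(roc_auc_score(pos.astype(int), np.asarray(scores, dtype=float)))
    return {"ACC": acc, "SEN": sen, "SPE": spe, "AUC": auc}


def run_cv(data: ft.FeatureMatrix, config: PipelineConfig | None = None) -> CVReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Every stage (screening, decomposition, KDA) is refitted from scratch
    inside each training fold; held-out subjects are predicted once each.
    """
    if config is None:
        config = PipelineConfig()
    counts = data.class_counts()
    if config.n_folds > counts.min():
        raise ValueError(
            f"n_folds={config.n_folds} exceeds smallest class size {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.cv_seed)
    N = data.n_subjects
    fold_assignments = np.full(N, -1, dtype=int)
    y_pred = np.empty(N, dtype=int)
    scores = np.empty(N, dtype=float)
    per_fold: list[dict[str, float]] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(data.X.T, data.labels)):
        fold_assignments[test_idx] = fold
        pipe = fit(data.subset(train_idx), config)
        pred, sc = predict(pipe, data.X[:, test_idx])
        y_pred[test_idx] = pred
        scores[test_idx] = sc
        per_fold.append(
            compute_metrics(data.labels[test_idx], pred, sc, config.positive_class)
        )
    pooled = compute_metrics(data.labels, y_pred, scores, config.positive_class)
    return CVReport(
        fold_assignments=fold_assignments, per_fold=per_fold,
        pooled=pooled, config=config,
    )
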