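"""Cost-sensitive random-forest prediction of T-cell reactivity.

Reactive peptides are rare among MHC binders (roughly 1:13 in melanoma
screening data), and a missed reactive peptide is far more costly than a
false alarm, so the classifier is trained cost-sensitively: the
misclassification-cost matrix [[0, 0.15], [1, 0]] (rows true class in
order negative, positive; columns predicted) is realized as per-class
observation weights — a positive carries weight 1, a negative 0.15 —
which is the expected-cost-minimizing equivalent for tree ensembles.

Evaluation follows a leave-one-out-on-positives protocol: the negatives
are split into as many disjoint near-equal folds as there are positives;
fold i holds out positive i together with negative fold i, the model is
trained on the complement, and the pooled held-out scores form a single
ROC curve.

Usage follows the fit/results idiom::

    model = ReactivityModel.from_dataset(ds, ModelConfig(n_estimators=300))
    res = model.fit()
    scores = res.predict_scores(new_features)
    ev = loo_evaluate(ds, config)   # EvaluationResult with .auc, .summary()
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve as _sk_roc_curve

from .epitope_features import FEATURE_COLUMNS, LabeledDataset

__all__ = [
    "ModelConfig",
    "ReactivityModel",
    "ReactivityResults",
    "EvaluationResult",
    "loo_evaluate",
    "roc_auc",
    "operating_metrics",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the reactivity forest.

    ``cost_matrix``: 2x2, rows = true class, columns = predicted class,
    class order (negative, positive); off-diagonal entries are the
    penalties for the two error types. The default [[0, 0.15], [1, 0]]
    makes missing a reactive peptide ~6.7x worse than a false positive.
    """

    n_estimators: int = 5000
    min_leaf_size: int = 10
    cost_matrix: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.15), (1.0, 0.0))
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.min_leaf_size < 1:
            raise ValueError("n_estimators and min_leaf_size must be >= 1")
        cm = np.asarray(self.cost_matrix, dtype=float)
        if cm.shape != (2, 2):
            raise ValueError("cost matrix must be 2x2")
        if (cm < 0).any() or cm[0, 0] != 0 or cm[1, 1] != 0:
            raise ValueError("cost matrix needs non-negative costs and a zero diagonal")
        if cm[0, 1] == 0 and cm[1, 0] == 0:
            raise ValueError("cost matrix has no off-diagonal penalty")

    @property
    def class_weights(self) -> dict[int, float]:
        """Observation weights per true class equivalent to the cost matrix:
        weight of class c is the cost of misclassifying a class-c sample."""
        cm = np.asarray(self.cost_matrix, dtype=float)
        return {0: cm[0, 1], 1: cm[1, 0]}


class ReactivityModel:
    """Random-forest model of T-cell reactivity, built from a feature table.

    Parameters
    ----------
    features : DataFrame with the seven feature columns.
    labels : binary array, 1 = reactive.
    config : ModelConfig.
    """

    def __init__(self, features: pd.DataFrame, labels, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        labels = np.asarray(labels, dtype=int)
        if len(features) != len(labels):
            raise ValueError("features/labels length mismatch")
        if len(np.unique(labels)) < 2:
            raise ValueError("training data must contain both classes")
        bad = [c for c in features.columns if not np.isfinite(features[c].to_numpy(float)).all()]
        if bad:
            raise ValueError(f"non-finite values in feature columns: {bad}")
        self.features = features.copy()
        self.labels = labels
        self.feature_names = list(features.columns)

    @classmethod
    def from_dataset(cls, data: LabeledDataset, config: ModelConfig | None = None) -> "ReactivityModel":
        data.require_both_classes()
        return cls(data.features, data.labels, config)

    def fit(self) -> "ReactivityResults":
        cfg = self.config
        est = RandomForestClassifier(
            n_estimators=cfg.n_estimators,
            min_samples_leaf=cfg.min_leaf_size,
            class_weight=cfg.class_weights,
            random_state=cfg.random_seed,
            n_jobs=1,
        )
        est.fit(self.features.to_numpy(float), self.labels)
        return ReactivityResults(model=self, estimator=est)


@dataclass
class ReactivityResults:
    """A fitted reactivity forest.

    ``predict_scores`` returns the weighted fraction of trees voting
    positive — a probability-like score in [0, 1], higher = more likely
    reactive.
    """

    model: ReactivityModel
    estimator: RandomForestClassifier

    def _check_schema(self, features: pd.DataFrame) -> np.ndarray:
        expected = self.model.feature_names
        missing = [c for c in expected if c not in features.columns]
        extra = [c for c in features.columns if c not in expected]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch: missing={missing} extra={extra}; "
                f"model expects columns {expected}"
            )
        return features[expected].to_numpy(float)

    def predict_scores(self, features: pd.DataFrame) -> np.ndarray:
        X = self._check_schema(features)
        pos_col = int(np.where(self.estimator.classes_ == 1)[0][0])
        return self.estimator.predict_proba(X)[:, pos_col]

    @property
    def feature_importances(self) -> pd.Series:
        return pd.Series(
            self.estimator.feature_importances_, index=self.model.feature_names
        ).sort_values(ascending=False)

    def save(self, path: str | Path) -> None:
        joblib.dump({"config": self.model.config, "feature_names": self.model.feature_names,
                     "estimator": self.estimator}, path)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Reactivity random forest",
            "=" * 40,
            f"training samples:   {len(self.model.labels)} "
            f"({int(self.model.labels.sum())} pos / {int((1 - self.model.labels).sum())} neg)",
            f"trees:              {cfg.n_estimators}",
            f"min leaf size:      {cfg.min_leaf_size}",
            f"class weights:      neg={cfg.class_weights[0]}, pos={cfg.class_weights[1]}",
            f"seed:               {cfg.random_seed}",
            "",
            "feature importances:",
        ]
        for name, v in self.feature_importances.items():
            lines.append(f"  {name:<14s} {v:.3f}")
        return "\n".join(lines)


def load_results(path: str | Path) -> ReactivityResults:
    """Load a model persisted by :meth:`ReactivityResults.save`.

    Rebuilds a stub ReactivityModel carrying the schema fingerprint so that
    ``predict_scores`` keeps refusing mismatched columns.
    """
    blob = joblib.load(path)
    stub = ReactivityModel.__new__(ReactivityModel)
    stub.config = blob["config"]
    stub.feature_names = blob["feature_names"]
    stub.features = pd.DataFrame(columns=blob["feature_names"])
    stub.labels = np.array([0, 1])
    return ReactivityResults(model=stub, estimator=blob["estimator"])


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC by threshold sweep and trapezoid AUC.

    The sweep runs over the unique scores (plus an above-max sentinel);
    a sample is predicted positive iff score >= threshold. With ties the
    trapezoid area equals the pair-counting statistic
    P(score+ > score-) + 0.5 P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return points, auc


def operating_metrics(scores, labels) -> dict[str, float]:
    """Screening operating points over the threshold sweep.

    predicted positive iff score >= t, t over unique scores plus sentinels:

    - ``neg_kept_at_half_pos``: FPR at the largest threshold that still
      retains >= 50% of positives ("fraction of negatives kept when losing
      50% of positives");
    - ``pos_kept_at_half_neg``: TPR at the smallest threshold that removes
      >= 50% of negatives;
    - ``max_accuracy`` and ``max_f1`` over all thresholds (positive class),
      plus ``f1_at_max_accuracy``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("operating metrics require both classes")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    best_acc, best_f1, f1_at_best_acc = -1.0, 0.0, 0.0
    neg_kept = None
    pos_kept = None
    # descending thresholds: predicted-positive set grows monotonically
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        tpr = tp / n_pos
        fpr = fp / n_neg
        acc = (tp + (n_neg - fp)) / (n_pos + n_neg)
        f1 = 2 * tp / (2 * tp + fp + (n_pos - tp)) if tp else 0.0
        if acc > best_acc:
            best_acc, f1_at_best_acc = acc, f1
        best_f1 = max(best_f1, f1)
        if neg_kept is None and tpr >= 0.5:
            neg_kept = fpr  # largest t retaining >= half the positives
        if fpr <= 0.5:
            pos_kept = tpr  # smallest t removing >= half the negatives
    return {
        "neg_kept_at_half_pos": float(neg_kept),
        "pos_kept_at_half_neg": float(pos_kept if pos_kept is not None else 0.0),
        "max_accuracy": float(best_acc),
        "max_f1": float(best_f1),
        "f1_at_max_accuracy": float(f1_at_best_acc),
    }


@dataclass
class EvaluationResult:
    """Pooled held-out evaluation of the LOO-on-positives protocol."""

    scores: pd.DataFrame  # columns: id, label, score, fold
    roc: pd.DataFrame  # columns: threshold, fpr, tpr
    auc: float
    metrics: dict[str, float]
    config: ModelConfig
    folds: list[dict]  # per-fold train/test index bookkeeping

    def summary(self) -> str:
        lines = [
            "Leave-one-out-on-positives evaluation",
            "=" * 45,
            f"samples:  {len(self.scores)} "
            f"({int(self.scores['label'].sum())} pos / "
            f"{int((1 - self.scores['label']).sum())} neg), {len(self.folds)} folds",
            f"AUC:      {self.auc:.3f}",
            "",
            "operating metrics (threshold sweep, score >= t => positive):",
        ]
        labels = {
            "neg_kept_at_half_pos": "negatives kept at 50% positive loss",
            "pos_kept_at_half_neg": "positives kept at 50% negative loss",
            "max_accuracy": "max accuracy",
            "max_f1": "max F1",
            "f1_at_max_accuracy": "F1 at max-accuracy threshold",
        }
        for k, label in labels.items():
            lines.append(f"  {label:<38s} {self.metrics[k]:.3f}")
        return "\n".join(lines)

    def write(self, outdir: str | Path, prefix: str = "loo") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scores": outdir / f"{prefix}_scores.csv",
            "roc": outdir / f"{prefix}_roc.csv",
            "metrics": outdir / f"{prefix}_metrics.csv",
        }
        self.scores.to_csv(paths["scores"], index=False)
        self.roc.to_csv(paths["roc"], index=False)
        mrow = {"auc": self.auc, **self.metrics, "seed": self.config.random_seed}
        pd.DataFrame([mrow]).to_csv(paths["metrics"], index=False)
        return paths

    def plot_roc(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(self.roc["fpr"], self.roc["tpr"], label=f"AUC = {self.auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("FPR")
        ax.set_ylabel("TPR")
        ax.legend(loc="lower right")
        return ax


def make_loo_folds(labels: np.ndarray, seed: int) -> list[dict]:
    """Partition for the LOO-on-positives protocol.

    Fold i tests {positive i} plus the i-th of n_pos disjoint near-equal
    negative folds (sizes differ by <= 1; assignment by seeded shuffle);
    training is the complement. Every sample is tested exactly once.
    """
    labels = np.asarray(labels, dtype=int)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if len(pos_idx) < 2:
        raise ValueError(f"LOO-on-positives needs >= 2 positives, got {len(pos_idx)}")
    if len(neg_idx) < len(pos_idx):
        raise ValueError("need at least as many negatives as positives")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(neg_idx)
    neg_folds = np.array_split(shuffled, len(pos_idx))
    all_idx = np.arange(len(labels))
    folds = []
    for i, (p, nf) in enumerate(zip(pos_idx, neg_folds)):
        test = np.concatenate([[p], nf])
        train = np.setdiff1d(all_idx, test)
        folds.append({"fold": i, "test": test, "train": train})
    return folds


def loo_evaluate(data: LabeledDataset, config: ModelConfig | None = None) -> EvaluationResult:
    """Run the LOO-on-positives protocol and pool held-out scores.

    Deterministic given ``config.random_seed`` (used for both the negative
    fold assignment and every per-fold forest).
    """
    config = config or ModelConfig()
    data.require_both_classes()
    folds = make_loo_folds(data.labels, seed=config.random_seed)
    ids = data.features.index.to_numpy()
    recs = []
    for f in folds:
        tr, te = f["train"], f["test"]
        model = ReactivityModel(
            data.features.iloc[tr], data.labels[tr], config=config
        )
        res = model.fit()
        s = res.predict_scores(data.features.iloc[te])
        for idx, sc in zip(te, s):
            recs.append(
                {"id": ids[idx], "label": int(data.labels[idx]), "score": float(sc),
                 "fold": f["fold"]}
            )
    scores = pd.DataFrame(recs)
    roc, auc = roc_auc(scores["score"], scores["label"])
    metrics = operating_metrics(scores["score"], scores["label"])
    return EvaluationResult(
        scores=scores, roc=roc, auc=auc, metrics=metrics, config=config, folds=folds
    )
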