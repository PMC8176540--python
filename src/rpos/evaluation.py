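"""Split-sample evaluation of selected gene sets.

Protocol: for each requested gene count, repeat over runs — draw a
plain random train/test split (no stratification), select genes on the
training part only, fit a classifier on the training samples restricted
to the selected genes, and score error rate, Brier score, and
sensitivity on the test part.  Per-gene-count means and standard
deviations are aggregated over runs.

Classifiers are consumed through a thin adapter (fit / predict /
positive-class probability) over scikit-learn, so the harness itself
contains no learning code.  Splits that leave the training part with a
single class, or the test part without the positive class (which would
make sensitivity undefined), are redrawn from the next derived seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .core import LabeledExpressionData, SelectionConfig
from .selection import select_genes

__all__ = [
    "EvaluationConfig",
    "EvaluationReport",
    "ClassifierAdapter",
    "make_classifier",
    "split_indices",
    "error_rate",
    "brier",
    "sensitivity",
    "run_experiment",
]


@dataclass(frozen=True)
class EvaluationConfig:
    runs: int = 500
    train_fraction: float = 0.70
    gene_counts: tuple = (5, 10, 15, 20, 25, 30)
    classifier: str = "random_forest"
    knn_k: int = 5
    positive_class: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.classifier not in ("random_forest", "knn", "svm"):
            raise ValueError(f"unknown classifier {self.classifier!r}")


@dataclass
class EvaluationReport:
    """Per-run metric records plus per-gene-count aggregates.

    ``records`` is a list of dicts with keys gene_count, run,
    error_rate, brier, sensitivity; ``aggregates`` maps gene_count to
    {metric: {"mean": .., "sd": ..}}.
    """

    records: list = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "records": self.records,
            "aggregates": {
                str(gc): metrics for gc, metrics in self.aggregates.items()
            },
        }


class ClassifierAdapter:
    """Uniform contract over a scikit-learn classifier: binary labels in,
    labels and positive-class probabilities out."""

    def __init__(self, estimator, positive_class: int) -> None:
        self.estimator = estimator
        self.positive_class = positive_class

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierAdapter":
        self.estimator.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X))

    def predict_positive_proba(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        col = list(self.estimator.classes_).index(self.positive_class)
        return np.asarray(proba[:, col])


def make_classifier(cfg: EvaluationConfig, seed: int) -> ClassifierAdapter:
    if cfg.classifier == "random_forest":
        est = RandomForestClassifier(random_state=seed)
    elif cfg.classifier == "knn":
        est = KNeighborsClassifier(n_neighbors=cfg.knn_k)
    else:
        est = SVC(probability=True, random_state=seed)
    return ClassifierAdapter(est, cfg.positive_class)


def split_indices(
    labels, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Plain random split without replacement; train size =
    round(train_fraction * n).  Redrawn until both classes appear in the
    training part."""
    labels = np.asarray(labels)
    n = labels.size
    n_train = int(round(train_fraction * n))
    if not 1 <= n_train <= n - 1:
        raise ValueError("train_fraction leaves an empty train or test part")
    rng = np.random.default_rng(seed)
    while True:
        perm = rng.permutation(n)
        train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        if np.unique(labels[train]).size == 2:
            return train, test


def error_rate(predicted, truth) -> float:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size != truth.size or truth.size == 0:
        raise ValueError("predicted/true label lengths differ or are empty")
    return float(np.mean(predicted != truth))


def brier(prob_positive, truth, positive_class: int = 1) -> float:
    """Binary Brier score: mean of (p_hat - y)^2 with y the 0/1 indicator
    of the positive class."""
    prob = np.asarray(prob_positive, dtype=float)
    truth = np.asarray(truth)
    if prob.size != truth.size or truth.size == 0:
        raise ValueError("probability/label lengths differ or are empty")
    if np.any((prob < 0) | (prob > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = (truth == positive_class).astype(float)
    return float(np.mean((prob - y) ** 2))


def sensitivity(predicted, truth, positive_class: int = 1) -> float:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size != truth.size:
        raise ValueError("predicted/true label lengths differ")
    pos = truth == positive_class
    if not pos.any():
        raise ValueError("no positive-class sample in the truth labels")
    return float(np.mean(predicted[pos] == positive_class))


def _draw_valid_split(labels, train_fraction, seed, positive_class):
    """Split with both classes in train and the positive class in test;
    degenerate draws advance to the next derived seed."""
    labels = np.asarray(labels)
    for attempt in range(1000):
        s = int((seed + attempt) % (2**31))
        train, test = split_indices(labels, train_fraction, s)
        if np.any(labels[test] == positive_class):
            return train, test
    raise RuntimeError("could not draw a usable split in 1000 attempts")


def run_experiment(
    data: LabeledExpressionData,
    sel_cfg: SelectionConfig,
    eval_cfg: EvaluationConfig,
) -> EvaluationReport:
    """Run the full repeated-split protocol and aggregate the metrics.

    Gene selection sees only the training part of each split; the test
    part enters only through the final metric computation.
    """
    report = EvaluationReport()
    id_to_idx = {g: j for j, g in enumerate(data.gene_ids)}
    ss = np.random.SeedSequence(eval_cfg.seed)
    run_seeds = ss.generate_state(eval_cfg.runs * len(eval_cfg.gene_counts)) % (2**31)
    k = 0
    for gc in eval_cfg.gene_counts:
        per_run = {"error_rate": [], "brier": [], "sensitivity": []}
        for run in range(eval_cfg.runs):
            seed = int(run_seeds[k])
            k += 1
            train, test = _draw_valid_split(
                data.labels, eval_cfg.train_fraction, seed, eval_cfg.positive_class
            )
            train_data = data.subset_samples(train)
            sel = select_genes(train_data, sel_cfg.with_n_genes(gc))
            gene_idx = [id_to_idx[g] for g in sel.final]
            Xtr = data.values[np.ix_(gene_idx, train)].T
            Xte = data.values[np.ix_(gene_idx, test)].T
            clf = make_classifier(eval_cfg, seed).fit(Xtr, data.labels[train])
            pred = clf.predict(Xte)
            prob = clf.predict_positive_proba(Xte)
            truth = data.labels[test]
            rec = {
                "gene_count": int(gc),
                "run": run,
                "error_rate": error_rate(pred, truth),
                "brier": brier(prob, truth, eval_cfg.positive_class),
                "sensitivity": sensitivity(pred, truth, eval_cfg.positive_class),
            }
            report.records.append(rec)
            for m in per_run:
                per_run[m].append(rec[m])
        report.aggregates[int(gc)] = {
            m: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1) if len(v) > 1 else 0.0)}
            for m, v in per_run.items()
        }
    return report
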