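"""Macrostate classifiers and random-forest feature importance.

Four classifier families separate macrostates from pairwise-distance
features: a single-hidden-layer neural network (logistic loss with an
L2 penalty, SGD training), a Gini-impurity decision tree, a random
forest, and a stratified dummy baseline. The workhorse for attribution
is the one-vs-one random forest: one distinct forest per unordered
macrostate pair (M(M-1)/2 of them, 28 for eight states), each trained
only on its two states' frames, yielding per-pair normalized Gini
importance vectors whose average is the overall importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import FeatureMatrix


@dataclass
class LabeledFeatures:
    features: FeatureMatrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != self.features.values.shape[0]:
            raise ValueError("one label per frame required")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class ClassifierSpec:
    """Hyperparameters shared across the classifier families.

    ``l2_alpha`` is the L2 regularization weight of the neural-network
    loss; ``n_trees``/``max_depth`` govern the tree ensembles (defaults:
    100 trees, unlimited depth); ``folds`` is the cross-validation fold
    count (default 12).
    """

    kind: str = "ovo_forest"           # ann | tree | forest | ovo_forest | dummy
    n_trees: int = 100
    max_depth: int | None = None
    max_features: float | str | None = "sqrt"
    l2_alpha: float = 1e-4
    hidden_units: int = 64
    folds: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.l2_alpha < 0:
            raise ValueError("l2_alpha must be >= 0")


@dataclass
class ImportanceTable:
    """Per state-pair normalized feature importances and their average."""

    per_pair: dict[tuple[int, int], np.ndarray]
    pair_map: list[tuple[int, int]]
    residue_labels: list[str]

    def __post_init__(self) -> None:
        for key, vec in self.per_pair.items():
            if key[0] >= key[1]:
                raise ValueError("state pairs must be ordered s1 < s2")
            s = float(np.sum(vec))
            if not np.isclose(s, 1.0, atol=1e-8) or np.any(vec < -1e-12):
                raise ValueError(f"importance vector for {key} not a distribution")

    @property
    def state_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.per_pair)

    @property
    def overall(self) -> np.ndarray:
        """Arithmetic mean of the per-pair importance vectors."""
        return np.mean([self.per_pair[p] for p in self.state_pairs], axis=0)

    def feature_name(self, f: int) -> str:
        i, j = self.pair_map[f]
        return f"{self.residue_labels[i]}-{self.residue_labels[j]}"

    def ranked_report(self, top: int = 5, ranks: int = 4) -> pd.DataFrame:
        """Top features by overall importance with their leading state pairs."""
        overall = self.overall
        order = np.argsort(-overall, kind="stable")[:top]
        rows = []
        for f in order:
            row = {
                "feature": int(f),
                "pair": self.feature_name(int(f)),
                "overall_pct": 100.0 * overall[f],
            }
            contrib = sorted(
                ((self.per_pair[p][f], p) for p in self.state_pairs), reverse=True
            )[:ranks]
            for r, (val, (s1, s2)) in enumerate(contrib, start=1):
                row[f"rank{r}"] = f"S{s1 + 1}-S{s2 + 1}: {100.0 * val:.2f}%"
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        data = {"feature": np.arange(len(self.pair_map)),
                "residue_i": [self.residue_labels[i] for i, _ in self.pair_map],
                "residue_j": [self.residue_labels[j] for _, j in self.pair_map],
                "overall": self.overall}
        for s1, s2 in self.state_pairs:
            data[f"S{s1 + 1}-S{s2 + 1}"] = self.per_pair[(s1, s2)]
        pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# classifier construction


def _make_classifier(kind: str, spec: ClassifierSpec):
    from sklearn.dummy import DummyClassifier
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.tree import DecisionTreeClassifier

    if kind == "ann":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        # distances live far from zero; the net needs standardized inputs
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(spec.hidden_units,),
                alpha=spec.l2_alpha,
                solver="sgd",
                learning_rate_init=0.01,
                max_iter=300,
                random_state=spec.seed,
            ),
        )
    if kind == "tree":
        return DecisionTreeClassifier(
            criterion="gini", max_depth=spec.max_depth, random_state=spec.seed
        )
    if kind == "forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            criterion="gini",
            max_depth=spec.max_depth,
            max_features=spec.max_features,
            random_state=spec.seed,
        )
    if kind == "dummy":
        return DummyClassifier(strategy="stratified", random_state=spec.seed)
    raise ValueError(f"unknown classifier kind {kind!r}")


def train_baselines(
    data: LabeledFeatures,
    spec: ClassifierSpec | None = None,
    kinds: Sequence[str] = ("ann", "tree", "forest", "dummy"),
) -> pd.DataFrame:
    """Stratified k-fold accuracies for the baseline classifier families.

    Accuracy is the fraction of correctly classified frames; every
    model sees identical seeded folds, so the comparison against the
    stratified-dummy control is paired.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.model_selection import StratifiedKFold

    spec = spec or ClassifierSpec()
    X, y = data.features.values, data.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < spec.folds:
        raise ValueError("every class needs at least `folds` samples")
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    splits = list(skf.split(X, y))
    rows = []
    for kind in kinds:
        train_acc, val_acc = [], []
        for tr, te in splits:
            clf = _make_classifier(kind, spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X[tr], y[tr])
            train_acc.append(float(np.mean(clf.predict(X[tr]) == y[tr])))
            val_acc.append(float(np.mean(clf.predict(X[te]) == y[te])))
        rows.append({
            "model": kind,
            "train_accuracy": float(np.mean(train_acc)),
            "val_accuracy": float(np.mean(val_acc)),
            "val_accuracy_std": float(np.std(val_acc)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-vs-one random forest


@dataclass
class OneVsOneForest:
    """One random forest per unordered macrostate pair, voting at prediction."""

    classifiers: dict[tuple[int, int], object]
    classes: np.ndarray

    @property
    def n_classifiers(self) -> int:
        return len(self.classifiers)

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros((X.shape[0], self.classes.size), dtype=int)
        pos = {c: i for i, c in enumerate(self.classes)}
        for (s1, s2), clf in self.classifiers.items():
            pred = clf.predict(X)
            for c in (s1, s2):
                votes[pred == c, pos[c]] += 1
        return self.classes[np.argmax(votes, axis=1)]


def train_ovo(
    data: LabeledFeatures, spec: ClassifierSpec | None = None
) -> tuple[OneVsOneForest, ImportanceTable]:
    """Fit one forest per macrostate pair and collect importances.

    Each forest is trained only on the frames of its two states; its
    per-pair importance is the mean Gini impurity decrease across
    trees, normalized to sum 1.
    """
    from sklearn.ensemble import RandomForestClassifier

    spec = spec or ClassifierSpec()
    X, y = data.features.values, data.labels
    classes = data.classes
    if classes.size < 2:
        raise ValueError("need at least two classes")
    classifiers: dict[tuple[int, int], object] = {}
    per_pair: dict[tuple[int, int], np.ndarray] = {}
    for idx, (s1, s2) in enumerate(combinations(classes.tolist(), 2)):
        mask = (y == s1) | (y == s2)
        if np.sum(y == s1) < 2 or np.sum(y == s2) < 2:
            raise ValueError(f"state pair ({s1},{s2}) lacks samples")
        clf = RandomForestClassifier(
            n_estimators=spec.n_trees,
            criterion="gini",
            max_depth=spec.max_depth,
            max_features=spec.max_features,
            random_state=spec.seed + idx,
        ).fit(X[mask], y[mask])
        imp = np.asarray(clf.feature_importances_, dtype=float)
        total = imp.sum()
        if total <= 0:
            raise ValueError(f"no informative splits for state pair ({s1},{s2})")
        classifiers[(s1, s2)] = clf
        per_pair[(s1, s2)] = imp / total
    table = ImportanceTable(
        per_pair=per_pair,
        pair_map=data.features.pair_map,
        residue_labels=data.features.residue_labels,
    )
    return OneVsOneForest(classifiers=classifiers, classes=classes), table


def overall_importance(table: ImportanceTable) -> np.ndarray:
    """Average importance vector over all state pairs (sums to 1)."""
    return table.overall


def cumulative_coverage(overall: np.ndarray, threshold: float = 0.9) -> int:
    """Smallest number of top-ranked features covering ``threshold`` mass.

    Features are sorted by importance descending (ties broken by feature
    index); returns the shortest prefix whose cumulative sum reaches the
    threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    overall = np.asarray(overall, dtype=float)
    if not np.isclose(overall.sum(), 1.0, atol=1e-6):
        raise ValueError("importance vector must sum to 1")
    order = np.argsort(-overall, kind="stable")
    csum = np.cumsum(overall[order])
    return int(np.searchsorted(csum, threshold - 1e-12) + 1)


def hyperparameter_grid(
    data: LabeledFeatures,
    spec: ClassifierSpec,
    kind: str,
    param: str,
    values: Sequence,
) -> pd.DataFrame:
    """Scan one hyperparameter, reporting fold-wise accuracies per value."""
    from dataclasses import replace

    rows = []
    for v in values:
        report = train_baselines(data, replace(spec, **{param: v}), kinds=(kind,))
        rec = report.iloc[0].to_dict()
        rec[param] = v
        rows.append(rec)
    return pd.DataFrame(rows)
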