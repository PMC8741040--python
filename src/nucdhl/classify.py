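"""Pipeline 1, the deep-hybrid head, the max-probability fusion and the
conventional-CNN baseline.

Pipeline 1 takes the standard-scaled morphometric table, removes correlated
dimensions with PCA, and trains three tree ensembles — adaptive boosting,
random forest and a single decision tree — under stratified k-fold
cross-validation. The adaptive-boosting probabilities are pipeline 1's
output. Scaling and PCA are fit inside each fold, so no statistic of a
validation fold leaks into training.

Pipeline 2 (deep hybrid learning) fits a gradient-boosted-tree or
random-forest head on the frozen encoder's flattened features.

The fused verdict per sample is the larger of the two pipeline probabilities;
a tie is attributed to pipeline 2 and logged.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .augmentation import AugmentParams
from .encoder import EncoderConfig, TrainConfig, TrainedEncoder, train_encoder
from .exceptions import ArgumentError, ShapeError, TrainingError
from .types import Decision, ProbPair

logger = logging.getLogger(__name__)

HEAD_ALGORITHMS = ("gradient_boosted_trees", "random_forest")


# ---------------------------------------------------------------------------
# dimensionality reduction

@dataclass
class PCAProjection:
    """A fitted PCA truncated at the first ``n_components`` axes, reusable on
    held-out rows."""

    pca: PCA
    n_components: int
    explained: float

    def transform(self, table) -> np.ndarray:
        values = np.asarray(table, dtype=float)
        return self.pca.transform(values)[:, :self.n_components]

    def inverse_transform(self, reduced: np.ndarray) -> np.ndarray:
        full = np.zeros((len(reduced), self.pca.n_components_))
        full[:, :self.n_components] = reduced
        return self.pca.inverse_transform(full)


def pca_reduce(table, variance_retained: float = 0.95) -> tuple[np.ndarray, PCAProjection]:
    """Project a standard-scaled table onto the smallest number of principal
    components whose cumulative explained variance reaches
    ``variance_retained`` (1.0 keeps every non-degenerate component, i.e. the
    matrix rank)."""
    if not (0.0 < variance_retained <= 1.0):
        raise ArgumentError("variance_retained must lie in (0, 1]")
    values = np.asarray(table, dtype=float)
    if values.ndim != 2 or len(values) < 2:
        raise ArgumentError("pca_reduce needs a 2-D table with >= 2 rows")
    pca = PCA(n_components=None, svd_solver="full").fit(values)
    ratios = pca.explained_variance_ratio_
    nonzero = ratios > 1e-12
    cumulative = np.cumsum(ratios)
    k = int(np.searchsorted(cumulative, variance_retained - 1e-12) + 1)
    k = min(k, int(nonzero.sum()))
    projection = PCAProjection(pca=pca, n_components=k,
                               explained=float(cumulative[k - 1]))
    return projection.transform(values), projection


# ---------------------------------------------------------------------------
# pipeline 1

@dataclass
class Pipeline1Report:
    """Cross-validation report of the three morphometric classifiers plus the
    descriptive outputs (gini feature importance and feature correlations)."""

    cv_accuracy: dict[str, float]
    cv_folds: int
    feature_importance: pd.Series = field(repr=False)
    correlation: pd.DataFrame = field(repr=False)


def _pipeline1_models(variance_retained: float, seed: int) -> dict:
    def make(clf):
        return Pipeline([
            ("scale", StandardScaler()),
            ("pca", PCA(n_components=variance_retained, svd_solver="full")),
            ("clf", clf),
        ])

    return {
        "adaboost": make(AdaBoostClassifier(random_state=seed)),
        "random_forest": make(RandomForestClassifier(random_state=seed)),
        "decision_tree": make(DecisionTreeClassifier(random_state=seed)),
    }


def train_pipeline1(table, labels, folds: int = 5, seed: int = 0,
                    variance_retained: float = 0.95):
    """Train the morphometric branch.

    ``table`` is the raw (unscaled) feature table — scaling and PCA live
    inside each fold's pipeline. Returns ``(fitted adaptive-boosting
    pipeline, Pipeline1Report)``; the fitted pipeline exposes
    ``predict_proba`` whose second column is p(cancer).
    """
    values = np.asarray(table, dtype=float)
    y = np.asarray(labels).astype(int)
    if folds < 2:
        raise ArgumentError("folds must be >= 2")
    if len(np.unique(y)) < 2:
        raise TrainingError("pipeline 1 needs both classes present")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    models = _pipeline1_models(variance_retained, seed)
    cv_accuracy = {
        name: float(np.mean(cross_val_score(model, values, y, cv=cv,
                                            scoring="accuracy")))
        for name, model in models.items()
    }
    ada = models["adaboost"].fit(values, y)

    forest = RandomForestClassifier(random_state=seed).fit(
        StandardScaler().fit_transform(values), y)
    columns = (list(table.columns) if isinstance(table, pd.DataFrame)
               else [f"f{i}" for i in range(values.shape[1])])
    importance = pd.Series(forest.feature_importances_, index=columns,
                           name="gini_importance").sort_values(ascending=False)
    correlation = pd.DataFrame(np.corrcoef(values, rowvar=False),
                               index=columns, columns=columns)
    report = Pipeline1Report(cv_accuracy=cv_accuracy, cv_folds=folds,
                             feature_importance=importance,
                             correlation=correlation)
    return ada, report


# ---------------------------------------------------------------------------
# deep hybrid head

class DHLHead:
    """Probabilistic tree-ensemble classifier on frozen encoder features."""

    def __init__(self, algorithm: str = "gradient_boosted_trees", seed: int = 0):
        if algorithm not in HEAD_ALGORITHMS:
            raise ArgumentError(
                f"algorithm must be one of {HEAD_ALGORITHMS}, got {algorithm!r}")
        self.algorithm = algorithm
        self.seed = seed
        self.n_features: int | None = None
        if algorithm == "gradient_boosted_trees":
            from xgboost import XGBClassifier

            self.model = XGBClassifier(
                n_estimators=200, max_depth=4, learning_rate=0.1,
                tree_method="hist", n_jobs=1, random_state=seed,
                eval_metric="logloss")
        else:
            self.model = RandomForestClassifier(n_estimators=200,
                                                random_state=seed, n_jobs=1)

    def fit(self, features: np.ndarray, labels) -> "DHLHead":
        features = np.asarray(features)
        y = np.asarray(labels).astype(int)
        if len(np.unique(y)) < 2:
            raise TrainingError("DHL head needs both classes present")
        self.n_features = features.shape[1]
        self.model.fit(features, y)
        return self

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """p(cancer) per sample."""
        features = np.asarray(features)
        if self.n_features is not None and features.shape[1] != self.n_features:
            raise ShapeError(
                f"feature length {features.shape[1]} != training length "
                f"{self.n_features}")
        return self.model.predict_proba(features)[:, 1]


def train_dhl_head(features, labels, algorithm: str = "gradient_boosted_trees",
                   seed: int = 0) -> DHLHead:
    """Fit the deep-hybrid head on flattened encoder features."""
    return DHLHead(algorithm=algorithm, seed=seed).fit(features, labels)


# ---------------------------------------------------------------------------
# decision fusion

def fuse(pair: ProbPair, threshold: float = 0.5) -> Decision:
    """Max-probability fusion of the two pipelines.

    ``fused = max(p_ada, p_deep)``; the label is cancer when the fused
    probability reaches the threshold; ``source`` names the winning pipeline
    (ties go to pipeline 2 and are logged).
    """
    if not (0.0 < threshold < 1.0):
        raise ArgumentError("threshold must lie in (0, 1)")
    if pair.p_deep >= pair.p_ada:
        source = "pipeline2"
        if pair.p_deep == pair.p_ada:
            logger.info("fusion tie at p=%.6f for sample %r; attributing to "
                        "pipeline2", pair.p_deep, pair.sample_id)
    else:
        source = "pipeline1"
    fused = max(pair.p_ada, pair.p_deep)
    label = "cancer" if fused >= threshold else "normal"
    return Decision(fused_probability=fused, predicted_label=label, source=source)


def fuse_all(pairs: list[ProbPair], threshold: float = 0.5) -> list[Decision]:
    return [fuse(p, threshold) for p in pairs]


# ---------------------------------------------------------------------------
# conventional end-to-end CNN baseline

def train_dense_baseline(images, labels, tconfig: TrainConfig | None = None,
                         config: EncoderConfig | None = None,
                         val_data=None,
                         augment_params: AugmentParams | None = None
                         ) -> TrainedEncoder:
    """Conventional deep neural network: the same 21-layer topology trained
    end to end with a dense softmax readout, from random initialisation (no
    pretrained weights). Returns the trained model; its
    :meth:`~nucdhl.encoder.TrainedEncoder.predict_proba` is the baseline's
    probability output and its manifest records the absence of pretrained
    weights."""
    return train_encoder((images, labels), val_data, tconfig=tconfig,
                         config=config, augment_params=augment_params)


# ---------------------------------------------------------------------------
# split bookkeeping

def split_hash(indices) -> str:
    """Stable hash of a sorted index set, used to audit that every stage of
    an experiment consumed the same split."""
    data = ",".join(map(str, sorted(map(int, indices)))).encode()
    return hashlib.sha256(data).hexdigest()[:16]


def stratified_split(labels, fractions: dict[str, float], seed: int = 0
                     ) -> dict[str, np.ndarray]:
    """Single stratified split into named partitions (e.g. train/val/test).

    Fractions must sum to 1; each class is partitioned proportionally.
    Returns a name -> index-array mapping.
    """
    labels = np.asarray(labels)
    names = list(fractions)
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ArgumentError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: dict[str, list] = {name: [] for name in names}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        bounds = np.cumsum([fractions[name] for name in names])
        cuts = np.r_[0, np.round(bounds * len(idx)).astype(int)]
        for name, lo, hi in zip(names, cuts[:-1], cuts[1:]):
            parts[name].append(idx[lo:hi])
    return {name: np.sort(np.concatenate(chunks))
            for name, chunks in parts.items()}
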