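"""Projection + clustering classifiers and off-the-shelf comparators.

The core classifier projects the high-dimensional feature vectors with a
linear transformation ``T`` (m features × c components) — supervised (LDA,
maximizing between- to within-class scatter) or unsupervised (PCA, top
covariance eigenvectors) — so the whole dataset transforms as the matrix
product ``N = D·T`` (after centering).  KMeans then finds clusters in the
projected training data; each cluster is labeled with the majority class of
its members ("cluster-to-classes"), and test points inherit the label of the
nearest centroid under Euclidean distance.  The resulting model is nothing
but ``T``, the centroids and the cluster→class map, which is what makes it
attractive for embedded deployment.

Random forest and SVM comparators use the settings reported for the study
(100 trees / Gini / unlimited depth; polynomial kernel of degree 6); all
tie-breaks (cluster majority, nearest centroid) resolve to the lowest index
and are logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

__all__ = [
    "ComponentCountError",
    "EmptyClusterError",
    "ComparatorUnavailableError",
    "PROJECTION_METHODS",
    "COMPARATOR_METHODS",
    "ProjectionModel",
    "ClassifierSpec",
    "default_spec",
    "fit_projection",
    "kmeans_cluster_to_classes",
    "fit_projection_classifier",
    "transform",
    "predict",
    "fit_comparator",
    "feature_relevance",
    "save_model",
    "load_model",
]

logger = logging.getLogger("etongue")

PROJECTION_METHODS = ("LDA_KMEANS", "PCA_KMEANS")
COMPARATOR_METHODS = ("RF", "SVM", "RNN")


class ComponentCountError(ValueError):
    """Requested more projection components than the method permits."""


class EmptyClusterError(RuntimeError):
    """KMeans repeatedly produced an empty cluster."""


class ComparatorUnavailableError(RuntimeError):
    """A comparator method has no available backend."""


@dataclass
class ProjectionModel:
    """A fitted linear projection with optional cluster-to-classes head.

    ``transform(X) = (X - mean) @ T`` maps instances into the c-dimensional
    projected space; ``centroids`` and ``cluster_to_class`` (present after
    the KMeans stage) turn the projection into a classifier.
    """

    method: str                                   # "LDA" or "PCA"
    T: np.ndarray                                 # (m, c)
    mean: np.ndarray                              # (m,)
    explained_fraction: np.ndarray                # (c,)
    classes: list[str] = field(default_factory=list)
    centroids: np.ndarray | None = None           # (n_clusters, c)
    cluster_to_class: dict[int, str] | None = None
    block_lengths: dict[str, int] | None = None   # sensor -> block length

    @property
    def n_components(self) -> int:
        return self.T.shape[1]


def _max_components(method: str, n_features: int, n_samples: int, n_classes: int) -> int:
    bound = min(n_features, n_samples)
    if method == "LDA":
        bound = min(bound, n_classes - 1)
    return bound


def fit_projection(
    X: np.ndarray,
    y: np.ndarray | None,
    method: str = "LDA",
    c: int | None = None,
    block_lengths: dict[str, int] | None = None,
) -> ProjectionModel:
    """Fit the transformation matrix ``T`` (no clustering head yet).

    PCA columns are the top-``c`` covariance eigenvectors by eigenvalue;
    LDA columns solve the generalized eigenproblem maximizing between- to
    within-class scatter (computed with the SVD-based solver, which remains
    well defined when the within-class scatter is singular, as it always is
    here with far more features than training instances).
    """
    X = np.asarray(X, dtype=float)
    d, m = X.shape
    if d < 2:
        raise ValueError("need at least 2 instances to fit a projection")
    method = method.upper()
    if method == "LDA":
        if y is None:
            raise ValueError("LDA requires class labels")
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2 or counts.min() < 2:
            raise ValueError("LDA needs >= 2 classes with >= 2 instances each")
        cmax = _max_components(method, m, d, len(classes))
        c = cmax if c is None else c
        if not 1 <= c <= cmax:
            raise ComponentCountError(
                f"LDA with {len(classes)} classes permits 1..{cmax} components, got {c}"
            )
        lda = LinearDiscriminantAnalysis(solver="svd", n_components=c)
        lda.fit(X, y)
        return ProjectionModel(
            method="LDA",
            T=np.array(lda.scalings_[:, :c]),
            mean=np.array(lda.xbar_),
            explained_fraction=np.array(lda.explained_variance_ratio_[:c]),
            classes=[str(v) for v in classes],
            block_lengths=block_lengths,
        )
    if method == "PCA":
        cmax = _max_components(method, m, d, 0)
        c = min(2, cmax) if c is None else c
        if not 1 <= c <= cmax:
            raise ComponentCountError(
                f"PCA on a {d}x{m} matrix permits 1..{cmax} components, got {c}"
            )
        pca = PCA(n_components=c, svd_solver="full")
        pca.fit(X)
        classes = [] if y is None else [str(v) for v in np.unique(y)]
        return ProjectionModel(
            method="PCA",
            T=np.array(pca.components_.T),
            mean=np.array(pca.mean_),
            explained_fraction=np.array(pca.explained_variance_ratio_),
            classes=classes,
            block_lengths=block_lengths,
        )
    raise ValueError(f"unknown projection method {method!r}")


def transform(model: ProjectionModel, X: np.ndarray) -> np.ndarray:
    """Project instances: ``(X - mean) @ T``."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.T.shape[0]:
        raise ValueError(
            f"expected {model.T.shape[0]} features, got {X.shape[-1]}"
        )
    return (X - model.mean) @ model.T


def kmeans_cluster_to_classes(
    Z: np.ndarray,
    y: np.ndarray,
    n_clusters: int | None = None,
    seed: int = 0,
    max_retries: int = 5,
) -> tuple[np.ndarray, dict[int, str]]:
    """Cluster the projected training data and label clusters by majority.

    Each cluster is assigned the class to which the majority of its members
    belong; ties resolve to the lowest class index (sorted label order) and
    are logged.  An empty cluster triggers a reseeded refit, bounded by
    ``max_retries``.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    n_clusters = len(classes) if n_clusters is None else n_clusters
    if n_clusters < len(classes):
        raise ValueError(
            f"n_clusters={n_clusters} < number of classes ({len(classes)})"
        )
    if Z.shape[0] == 0:
        raise ValueError("empty training data")
    for attempt in range(max_retries + 1):
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed + attempt)
        assignments = km.fit_predict(Z)
        sizes = np.bincount(assignments, minlength=n_clusters)
        if sizes.min() > 0:
            break
        logger.warning(
            "KMeans produced an empty cluster (seed %d); retrying", seed + attempt
        )
    else:
        raise EmptyClusterError(
            f"empty cluster persisted after {max_retries + 1} fits"
        )
    cluster_to_class: dict[int, str] = {}
    for cluster in range(n_clusters):
        members = y[assignments == cluster]
        counts = {cls: int(np.sum(members == cls)) for cls in classes}
        best = max(counts.values())
        winners = [cls for cls in classes if counts[cls] == best]
        if len(winners) > 1:
            logger.info(
                "cluster %d majority tie among %s; resolved to %r (lowest index)",
                cluster, winners, winners[0],
            )
        cluster_to_class[cluster] = str(winners[0])
    return np.array(km.cluster_centers_), cluster_to_class


def fit_projection_classifier(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "LDA",
    c: int | None = None,
    n_clusters: int | None = None,
    seed: int = 0,
    block_lengths: dict[str, int] | None = None,
) -> ProjectionModel:
    """Fit projection + KMeans cluster-to-classes in one call."""
    model = fit_projection(X, y, method=method, c=c, block_lengths=block_lengths)
    Z = transform(model, X)
    model.centroids, model.cluster_to_class = kmeans_cluster_to_classes(
        Z, y, n_clusters=n_clusters, seed=seed
    )
    return model


def predict(X: np.ndarray, model: ProjectionModel) -> np.ndarray:
    """Assign each instance the class of the nearest centroid.

    Instances are projected with ``T`` and assigned under Euclidean
    distance; centroid ties resolve to the lowest cluster index.
    """
    if model.centroids is None or model.cluster_to_class is None:
        raise ValueError("model has no fitted cluster head; run the KMeans stage")
    Z = transform(model, np.atleast_2d(X))
    nearest = np.argmin(cdist(Z, model.centroids), axis=1)  # argmin -> lowest index
    return np.array([model.cluster_to_class[int(i)] for i in nearest])


@dataclass(frozen=True)
class ClassifierSpec:
    """A classification method plus its hyperparameters and seed."""

    method: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


_DEFAULT_HYPERPARAMETERS = {
    "LDA_KMEANS": {"c": None, "n_clusters": None},
    "PCA_KMEANS": {"c": 2, "n_clusters": None},
    # Settings reported for the study; everything unstated is the library default.
    "RF": {"n_estimators": 100, "criterion": "gini", "max_depth": None},
    "SVM": {"kernel": "poly", "degree": 6},
    "RNN": {"dropout": 0.6, "output_activation": "softmax", "validation_split": 0.3},
}


def default_spec(method: str, seed: int = 0) -> ClassifierSpec:
    """The study's default hyperparameters for a method."""
    method = method.upper()
    if method not in _DEFAULT_HYPERPARAMETERS:
        raise ValueError(
            f"unknown method {method!r}; known: "
            f"{sorted(_DEFAULT_HYPERPARAMETERS)}"
        )
    return ClassifierSpec(
        method=method, hyperparameters=dict(_DEFAULT_HYPERPARAMETERS[method]), seed=seed
    )


def fit_comparator(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec):
    """Fit an off-the-shelf comparator (RF or SVM) per its spec.

    The recurrent-network comparator has no backend in this package's
    dependency set and raises :class:`ComparatorUnavailableError`; callers
    treat it as an optional extra and skip it.
    """
    method = spec.method.upper()
    hp = {**_DEFAULT_HYPERPARAMETERS.get(method, {}), **spec.hyperparameters}
    if method == "RF":
        clf = RandomForestClassifier(
            n_estimators=hp["n_estimators"],
            criterion=hp["criterion"],
            max_depth=hp["max_depth"],
            random_state=spec.seed,
        )
    elif method == "SVM":
        clf = SVC(kernel=hp["kernel"], degree=hp["degree"], random_state=spec.seed)
    elif method == "RNN":
        raise ComparatorUnavailableError(
            "no recurrent-network backend is available; the RNN comparator "
            "is an optional extra and is skipped"
        )
    else:
        raise ValueError(f"unknown comparator method {spec.method!r}")
    logger.debug("fitting %s with hyperparameters %s", method, hp)
    return clf.fit(X, y)


def feature_relevance(model: ProjectionModel) -> pd.DataFrame:
    """Per-feature, per-component coefficients of ``T``, sensor-annotated.

    Columns of ``T`` are rescaled to unit norm so coefficient magnitudes are
    comparable across components.  When the model carries per-sensor block
    lengths, each feature is annotated with its source sensor block.
    """
    T = np.array(model.T, dtype=float)
    norms = np.linalg.norm(T, axis=0)
    norms[norms == 0] = 1.0
    T = T / norms
    frame = pd.DataFrame(
        T, columns=[f"component_{j + 1}" for j in range(T.shape[1])]
    )
    frame.insert(0, "feature", np.arange(T.shape[0]))
    if model.block_lengths:
        sensors = np.concatenate([
            np.repeat(sensor, length)
            for sensor, length in model.block_lengths.items()
        ])
        if sensors.size != T.shape[0]:
            raise ValueError("block lengths do not sum to the feature count")
        frame.insert(1, "sensor", sensors)
    return frame


def save_model(model: ProjectionModel, path: str | Path) -> None:
    """Serialize a fitted model to a documented JSON file."""
    payload = {
        "method": model.method,
        "T": model.T.tolist(),
        "mean": model.mean.tolist(),
        "explained_fraction": model.explained_fraction.tolist(),
        "classes": model.classes,
        "centroids": None if model.centroids is None else model.centroids.tolist(),
        "cluster_to_class": model.cluster_to_class,
        "block_lengths": model.block_lengths,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> ProjectionModel:
    """Load a model written by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    return ProjectionModel(
        method=payload["method"],
        T=np.array(payload["T"], dtype=float),
        mean=np.array(payload["mean"], dtype=float),
        explained_fraction=np.array(payload["explained_fraction"], dtype=float),
        classes=list(payload["classes"]),
        centroids=None if payload["centroids"] is None else np.array(payload["centroids"]),
        cluster_to_class=None
        if payload["cluster_to_class"] is None
        else {int(k): v for k, v in payload["cluster_to_class"].items()},
        block_lengths=payload["block_lengths"],
    )
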