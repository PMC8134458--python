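"""Connectome-based prediction of treatment response.

Baseline similarity matrices are flattened to upper-triangle edge
features and fed to a linear support vector machine under stratified
10-fold cross-validation. Per-fold features are standardized using
training-fold statistics only (a scikit-learn Pipeline, so test folds
never touch the scaler fit). Performance is the mean balanced accuracy
over folds; significance comes from re-running the whole CV under label
permutation. The linear kernel makes the weight vector interpretable:
the mean absolute weight of each edge across folds is aggregated per
region (mean over its N-1 incident edges) to rank regions by their
contribution to the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .regions import region_labels

__all__ = [
    "FeatureVector",
    "ClassificationReport",
    "vectorize_connectome",
    "reconstruct_connectome",
    "cross_validated_classification",
    "permutation_significance",
    "nodal_weight_ranking",
]

SYMMETRY_TOL = 1e-9


@dataclass
class FeatureVector:
    """Upper-triangle edge features of one symmetric connectome."""

    values: np.ndarray
    index_map: tuple[tuple[int, int], ...]  # feature -> (region_i, region_j)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.index_map) != self.values.size:
            raise ValueError("index map must be bijective with the feature vector")


@dataclass
class ClassificationReport:
    fold_balanced_accuracies: np.ndarray
    mean_balanced_accuracy: float
    edge_weights: np.ndarray                 # mean |w| per edge feature across folds
    nodal_weights: np.ndarray                # per-region mean over incident edges
    top_regions: tuple[str, ...]             # descending nodal weight, length <= 10
    region_names: tuple[str, ...]
    permutation_p: float = float("nan")
    fold_class_counts: tuple[tuple[int, int], ...] = field(default=())
    seed: int | None = None


def _triu_index_map(n: int) -> tuple[tuple[int, int], ...]:
    iu, ju = np.triu_indices(n, k=1)
    return tuple(zip(iu.tolist(), ju.tolist()))


def vectorize_connectome(matrix) -> FeatureVector:
    """Row-major upper-triangle (diagonal excluded) edge features."""
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("connectome must be a square matrix")
    if np.max(np.abs(values - values.T)) > SYMMETRY_TOL:
        raise ValueError(f"connectome asymmetric beyond tolerance {SYMMETRY_TOL}")
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return FeatureVector(values=values[iu, ju], index_map=_triu_index_map(n))


def reconstruct_connectome(fv: FeatureVector, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_connectome` (diagonal set explicitly)."""
    f = fv.values.size
    n = int(round((1 + np.sqrt(1 + 8 * f)) / 2))
    if n * (n - 1) // 2 != f:
        raise ValueError("feature length is not a valid upper-triangle size")
    out = np.full((n, n), diagonal, dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    out[iu, ju] = fv.values
    out[ju, iu] = fv.values
    return out


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float)
    return np.stack([fv.values for fv in features]).astype(float)


def _n_regions_from_features(n_features: int) -> int:
    n = int(round((1 + np.sqrt(1 + 8 * n_features)) / 2))
    if n * (n - 1) // 2 != n_features:
        raise ValueError("feature count is not N(N-1)/2 for any integer N")
    return n


def cross_validated_classification(
    features,
    labels,
    seed: int = 0,
    n_folds: int = 10,
    C: float = 1.0,
    region_names: tuple[str, ...] | None = None,
) -> ClassificationReport:
    """Stratified k-fold linear-SVM classification of responder status.

    ``features`` is a (subjects x edges) array or a sequence of
    :class:`FeatureVector`; ``labels`` is boolean/binary responder
    status. Deterministic for a fixed ``seed``.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    if y.dtype == object or y.dtype.kind in "US":
        y = np.asarray([str(v).lower() in ("responder", "true", "1") for v in y])
    y = y.astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects, fewer than {n_folds} folds"
        )

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs, weights, fold_counts = [], [], []
    for train, test in skf.split(X, y):
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
        clf.fit(X[train], y[train])
        accs.append(balanced_accuracy_score(y[test], clf.predict(X[test])))
        weights.append(np.abs(clf.named_steps["svc"].coef_.ravel()))
        fold_counts.append((int((y[test] == 0).sum()), int((y[test] == 1).sum())))

    edge_weights = np.mean(weights, axis=0)
    try:
        n_regions = _n_regions_from_features(X.shape[1])
    except ValueError:
        # non-connectome feature matrix: no per-region aggregation possible
        n_regions = 0
    if n_regions:
        names = tuple(region_names) if region_names is not None else region_labels(n_regions)
        nodal = _nodal_mean_weights(edge_weights, n_regions)
        order = _ranked_indices(nodal)
        top = tuple(names[i] for i in order[: min(10, n_regions)])
    else:
        names, nodal, top = (), np.array([]), ()
    return ClassificationReport(
        fold_balanced_accuracies=np.asarray(accs),
        mean_balanced_accuracy=float(np.mean(accs)),
        edge_weights=edge_weights,
        nodal_weights=nodal,
        top_regions=top,
        region_names=names,
        fold_class_counts=tuple(fold_counts),
        seed=seed,
    )


def _nodal_mean_weights(edge_weights: np.ndarray, n_regions: int) -> np.ndarray:
    iu, ju = np.triu_indices(n_regions, k=1)
    nodal = np.zeros(n_regions)
    np.add.at(nodal, iu, edge_weights)
    np.add.at(nodal, ju, edge_weights)
    return nodal / (n_regions - 1)


def _ranked_indices(nodal: np.ndarray) -> np.ndarray:
    # descending weight; ties broken by ascending region index
    return np.lexsort((np.arange(nodal.size), -nodal))


def permutation_significance(
    features,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
    n_folds: int = 10,
    C: float = 1.0,
) -> float:
    """Permutation p-value of the cross-validated balanced accuracy.

    ``p = (1 + #{permuted mean accuracy >= observed}) / (1 + n_perm)``,
    with the full CV re-run on each permuted label vector.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = _as_matrix(features)
    observed = cross_validated_classification(
        X, labels, seed=seed, n_folds=n_folds, C=C
    ).mean_balanced_accuracy
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y.size)
        acc = cross_validated_classification(
            X, y[perm], seed=seed, n_folds=n_folds, C=C
        ).mean_balanced_accuracy
        if acc >= observed - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def nodal_weight_ranking(report: ClassificationReport, top: int = 10):
    """Regions ranked by mean incident-edge weight (descending).

    Returns a DataFrame with region name, nodal mean weight and rank;
    ``report.top_regions`` carries the top-10 shortcut.
    """
    import pandas as pd

    if report.edge_weights.size == 0:
        raise ValueError("report carries no edge weights")
    order = _ranked_indices(report.nodal_weights)
    df = pd.DataFrame(
        {
            "region": [report.region_names[i] for i in order],
            "nodal_weight": report.nodal_weights[order],
            "rank": np.arange(1, order.size + 1),
        }
    )
    return df.head(top) if top is not None else df
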