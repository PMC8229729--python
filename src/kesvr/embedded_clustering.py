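"""Global SVR training, residual construction and k-means partition transfer.

A radial-basis SVR is trained on the target-gene features of a seeded 75%
split, its signed prediction error is computed for every cell line, and
k-means partitions the resulting (AUC, error) tuples.  The partition is then
carried onto the reduced 2-D dataset by cell id, where the local ensemble
operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.svm import SVR

from .data_io import DataError, ExpressionMatrix, GeneSubset, ResponseVector
from .embedding import ReducedDataset


class FitError(RuntimeError):
    """A model could not be fitted on the given data."""


class InfeasibleK(FitError):
    """No k-means restart produced K non-empty clusters."""


@dataclass
class LabeledData:
    """Target-gene feature vectors paired with AUC labels, one row per cell."""

    cell_ids: list[str]
    gene_ids: list[str]
    features: np.ndarray  # (n_cells, n_target_genes)
    labels: np.ndarray    # (n_cells,) AUC

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.features.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise DataError("labeled-data feature shape mismatch")
        if self.labels.shape != (len(self.cell_ids),):
            raise DataError("labeled-data label length mismatch")

    @classmethod
    def from_aligned(
        cls, expr: ExpressionMatrix, resp: ResponseVector, genes: GeneSubset
    ) -> "LabeledData":
        if expr.cell_ids != resp.cell_ids:
            raise DataError("expression and response must be aligned first")
        feats = expr.gene_rows(genes.gene_ids).T
        return cls(list(expr.cell_ids), list(genes.gene_ids), feats, resp.auc.copy())

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class SvrModel:
    """A fitted regressor: RBF SVR on standardized features, or a constant.

    Hyperparameters follow one policy everywhere: kernel width from the
    median pairwise distance of the standardized training features
    (gamma = 1 / (2 m^2)), regularization weight C = 1.0, epsilon tube
    0.1 x the training-label standard deviation.  Clusters too small to
    support an SVR degrade to a constant predictor at the member mean.
    """

    kind: str                       # "svr" | "constant"
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    C: float = 1.0
    gamma: float = 0.0
    epsilon: float = 0.0
    constant: float = 0.0
    _svr: Optional[SVR] = field(default=None, repr=False)

    @property
    def n_features(self) -> int:
        return self.feature_mean.shape[0]

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise DataError(
                f"feature dimension {X.shape[1]} does not match model ({self.n_features})"
            )
        if self.kind == "constant":
            return np.full(X.shape[0], self.constant)
        return self._svr.predict(self._standardize(X))


def median_heuristic_gamma(X_std: np.ndarray) -> float:
    """RBF width from the median pairwise Euclidean distance (standardized)."""
    if X_std.shape[0] < 2:
        return 1.0 / max(X_std.shape[1], 1)
    m = float(np.median(pdist(X_std)))
    if m <= 0:
        return 1.0 / max(X_std.shape[1], 1)
    return 1.0 / (2.0 * m * m)


def fit_svr(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    epsilon_factor: float = 0.1,
    gamma: Optional[float] = None,
) -> SvrModel:
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if features.shape[0] < 2:
        return constant_model(features.shape[1], float(labels.mean()))
    mean = features.mean(axis=0)
    scale = features.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    X_std = (features - mean) / scale
    if gamma is None:
        gamma = median_heuristic_gamma(X_std)
    epsilon = epsilon_factor * float(labels.std())
    svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon)
    svr.fit(X_std, labels)
    return SvrModel("svr", mean, scale, C=C, gamma=gamma, epsilon=epsilon, _svr=svr)


def constant_model(n_features: int, value: float) -> SvrModel:
    return SvrModel(
        "constant", np.zeros(n_features), np.ones(n_features), constant=float(value)
    )


@dataclass
class SplitRecord:
    """Membership of a seeded train/test split, by position and by id."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    train_ids: list[str]
    test_ids: list[str]


def split_indices(n: int, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1) if n > 1 else n
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def train_global_svr(
    q: LabeledData, train_fraction: float = 0.75, seed: int = 0
) -> tuple[SvrModel, SplitRecord]:
    """Fit the global SVR S on a seeded random 75% of the labeled data."""
    if q.n_cells < 10:
        raise FitError(f"need at least 10 cells to train the global SVR, got {q.n_cells}")
    if not 0 < train_fraction < 1:
        raise FitError("train_fraction must be in (0, 1)")
    tr, te = split_indices(q.n_cells, train_fraction, seed)
    if tr.size < 2:
        raise FitError("fewer than 2 training points after the split")
    model = fit_svr(q.features[tr], q.labels[tr])
    rec = SplitRecord(
        tr, te, [q.cell_ids[i] for i in tr], [q.cell_ids[i] for i in te]
    )
    return model, rec


@dataclass
class ResidualDataset:
    """Per cell line the tuple (AUC, signed prediction error), AUC units."""

    cell_ids: list[str]
    auc: np.ndarray
    errors: np.ndarray  # e_i = Y_i - S(features_i)

    def __post_init__(self) -> None:
        self.auc = np.asarray(self.auc, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        n = len(self.cell_ids)
        if self.auc.shape != (n,) or self.errors.shape != (n,):
            raise DataError("residual dataset length mismatch")
        if not (np.all(np.isfinite(self.auc)) and np.all(np.isfinite(self.errors))):
            raise DataError("non-finite residual")

    def points(self) -> np.ndarray:
        return np.column_stack([self.auc, self.errors])


def compute_residuals(
    s: SvrModel, q: LabeledData, signed: bool = True
) -> ResidualDataset:
    """Signed residual e = Y - S(features) for every cell (training and held-out).

    Signed residuals preserve the over/under-prediction structure that the
    clustering exploits; ``signed=False`` gives absolute residuals for
    sensitivity analysis.
    """
    pred = s.predict(q.features)
    e = q.labels - pred
    if not signed:
        e = np.abs(e)
    return ResidualDataset(list(q.cell_ids), q.labels.copy(), e)


@dataclass
class ClusterPartition:
    """K-means partition of the residual tuples: disjoint, covering, non-empty."""

    K: int
    labels: np.ndarray     # (n_cells,), values 0..K-1
    centroids: np.ndarray  # (K, 2) in (AUC, error) space
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels, minlength=self.K)
        if len(counts) != self.K or np.any(counts == 0):
            raise InfeasibleK(f"partition has an empty cluster among K={self.K}")

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.labels == k)


def cluster_residuals(psi: ResidualDataset, K: int, seed: int = 0) -> ClusterPartition:
    """Seeded k-means++ on the raw (AUC, error) tuples, 10 restarts, best WCSS.

    No standardization is applied before clustering: both axes are already in
    AUC units.
    """
    n = len(psi.cell_ids)
    if K < 1:
        raise FitError("K must be >= 1")
    if K > n:
        raise FitError(f"K={K} exceeds the number of cells ({n})")
    X = psi.points()
    km = KMeans(n_clusters=K, init="k-means++", n_init=10, random_state=seed % (2**31))
    labels = km.fit_predict(X)
    return ClusterPartition(K, labels, km.cluster_centers_, list(psi.cell_ids))


def transfer_partition(z: ReducedDataset, part: ClusterPartition) -> ReducedDataset:
    """Carry the residual-space cluster labels onto the reduced dataset by id."""
    if set(z.cell_ids) != set(part.cell_ids):
        raise DataError("reduced dataset and partition cover different cells")
    label_of = dict(zip(part.cell_ids, part.labels))
    labels = np.array([label_of[c] for c in z.cell_ids], dtype=int)
    return ReducedDataset(list(z.cell_ids), z.auc.copy(), z.ordinate.copy(), z.p, labels)
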