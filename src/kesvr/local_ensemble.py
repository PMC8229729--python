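"""Per-cluster local SVRs and the neighbourhood-scored ensemble selection.

Every cluster of the reduced dataset trains its own SVR; for an input the K
candidate predictions are plotted as points (candidate AUC, PC score) in the
reduced plane, each candidate collects its cluster's points within radius r
(a closed Euclidean ball), and a candidate is scored by the mean Spearman
rank correlation between the input's target-gene profile and those of its
neighbours (the beta score).  The candidate with the highest beta wins.

The radius r is data-driven: the sorted list of per-cluster AUC spans (the
"radius ladder"), starting at the smallest span and escalating to the next
rung whenever every candidate has an empty neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .data_io import DataError
from .embedded_clustering import (
    FitError,
    LabeledData,
    ClusterPartition,
    SplitRecord,
    SvrModel,
    constant_model,
    fit_svr,
    split_indices,
)
from .embedding import ReducedDataset

#: clusters smaller than this are fitted on all members (no 75/25 split)
MIN_SPLIT_SIZE = 4


@dataclass
class LocalModelSet:
    """One fitted regressor per cluster, with its split record."""

    models: list[SvrModel]          # index = cluster label
    splits: list[SplitRecord]
    cluster_cell_ids: list[list[str]]

    @property
    def K(self) -> int:
        return len(self.models)


@dataclass
class RadiusLadder:
    """Sorted per-cluster AUC spans; the active radius is the smallest."""

    spans: np.ndarray  # ascending, one per cluster

    def __post_init__(self) -> None:
        self.spans = np.sort(np.asarray(self.spans, dtype=float))
        if self.spans.size == 0:
            raise DataError("empty radius ladder")
        if np.any(self.spans < 0):
            raise DataError("negative cluster span")

    @property
    def r(self) -> float:
        return float(self.spans[0])

    def rungs(self) -> np.ndarray:
        """Strictly increasing escalation values."""
        return np.unique(self.spans)


@dataclass
class PredictionTrace:
    """Full audit record of one ensemble selection."""

    input_id: str
    candidates: np.ndarray       # (K,) candidate AUC value per cluster
    ordinate: float              # PC score of the input
    neighbor_counts: np.ndarray  # (K,)
    betas: np.ndarray            # (K,) in [-1, 1]
    radius_used: float
    selected_cluster: Optional[int]
    selected_value: float
    fallback: bool = False       # True when the ladder was exhausted and the
                                 # global SVR supplied the value

    def __post_init__(self) -> None:
        if not self.fallback and self.selected_cluster is not None:
            assert self.selected_value == self.candidates[self.selected_cluster]


def train_local_svrs(
    q: LabeledData,
    partition: ClusterPartition,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> LocalModelSet:
    """Fit one SVR per cluster on a seeded per-cluster 75/25 split.

    Clusters with fewer than 4 members are fitted on all members (no split);
    singleton clusters get a constant predictor at the member's label.  The
    hyperparameter policy is identical to the global SVR.  The split seed for
    cluster k is ``seed + k`` so that a single-cluster partition reproduces
    the global split exactly.
    """
    if q.cell_ids != partition.cell_ids:
        raise DataError("labeled data and partition must cover the same cells in order")
    models: list[SvrModel] = []
    splits: list[SplitRecord] = []
    cluster_ids: list[list[str]] = []
    for k in range(partition.K):
        idx = partition.members(k)
        ids = [q.cell_ids[i] for i in idx]
        if idx.size < 2:
            model = constant_model(len(q.gene_ids), float(q.labels[idx].mean()))
            rec = SplitRecord(np.arange(idx.size), np.arange(0), ids, [])
        elif idx.size < MIN_SPLIT_SIZE:
            model = fit_svr(q.features[idx], q.labels[idx])
            rec = SplitRecord(np.arange(idx.size), np.arange(0), ids, [])
        else:
            tr, te = split_indices(idx.size, train_fraction, seed + k)
            model = fit_svr(q.features[idx[tr]], q.labels[idx[tr]])
            rec = SplitRecord(tr, te, [ids[i] for i in tr], [ids[i] for i in te])
        models.append(model)
        splits.append(rec)
        cluster_ids.append(ids)
    return LocalModelSet(models, splits, cluster_ids)


def predict_candidates(models: LocalModelSet, x_features: np.ndarray) -> np.ndarray:
    """The K candidate responses for one input, one per cluster."""
    x = np.asarray(x_features, dtype=float).reshape(1, -1)
    out = np.array([float(m.predict(x)[0]) for m in models.models])
    if not np.all(np.isfinite(out)):
        raise FitError("non-finite candidate prediction")
    return out


def compute_radius_ladder(z: ReducedDataset) -> RadiusLadder:
    """Per-cluster AUC span (max - min of the abscissa), sorted ascending."""
    if z.labels is None:
        raise DataError("reduced dataset is not clustered")
    spans = []
    for k in range(int(z.labels.max()) + 1):
        a = z.auc[z.labels == k]
        if a.size == 0:
            raise DataError(f"cluster {k} empty in reduced dataset")
        spans.append(a.max() - a.min())
    return RadiusLadder(np.array(spans))


def neighbors(
    cluster_auc: np.ndarray,
    cluster_ordinate: np.ndarray,
    point: tuple[float, float],
    r: float,
) -> np.ndarray:
    """Indices of cluster points within the closed Euclidean ball of radius r.

    Distances mix AUC and PC units unscaled, matching the raw reduced plane.
    """
    if r < 0:
        raise DataError("radius must be non-negative")
    d2 = (cluster_auc - point[0]) ** 2 + (cluster_ordinate - point[1]) ** 2
    return np.flatnonzero(d2 <= r * r)


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, np.atleast_2d(X))


def _centered_unit_ranks(R: np.ndarray) -> np.ndarray:
    """Rank rows centered and L2-normalised; all-tied rows become zero rows."""
    Rc = R - R.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Rc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = np.where(norms > 0, Rc / np.where(norms > 0, norms, 1.0), 0.0)
    return out


def spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation (rank, then Pearson); 0 if either is constant."""
    ra = _centered_unit_ranks(_rank_rows(a.reshape(1, -1)))[0]
    rb = _centered_unit_ranks(_rank_rows(b.reshape(1, -1)))[0]
    return float(ra @ rb)


def beta_score(
    input_features: np.ndarray,
    neighbor_ids: Sequence[str],
    training_features: dict[str, np.ndarray],
) -> float:
    """Mean Spearman correlation between the input's target-gene profile and
    each neighbour cell line's profile; 0 for an empty neighbourhood.

    A constant profile (all genes tied) has no rank signal and contributes 0.
    """
    if len(neighbor_ids) == 0:
        return 0.0
    vals = [spearman(np.asarray(input_features, float),
                     np.asarray(training_features[c], float))
            for c in neighbor_ids]
    return float(np.mean(vals))


@dataclass
class SelectionContext:
    """Everything the ensemble selection needs beyond the candidates."""

    z: ReducedDataset                 # clustered training reduced dataset
    ladder: RadiusLadder
    train_features: np.ndarray        # (n_cells, n_target_genes), training order
    train_unit_ranks: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.z.labels is None:
            raise DataError("selection context needs a clustered reduced dataset")
        if self.train_unit_ranks is None:
            self.train_unit_ranks = _centered_unit_ranks(_rank_rows(self.train_features))
        self.cluster_idx = [np.flatnonzero(self.z.labels == k)
                            for k in range(int(self.z.labels.max()) + 1)]


def select_prediction(
    input_id: str,
    input_features: np.ndarray,
    ordinate: float,
    candidates: np.ndarray,
    ctx: SelectionContext,
    global_prediction: Optional[float] = None,
    r_override: Optional[float] = None,
) -> PredictionTrace:
    """Pick the candidate with the highest beta score, escalating the radius.

    At the active radius every candidate collects neighbours in its own
    cluster; if ALL neighbourhoods are empty the radius escalates to the next
    ladder rung and the search repeats.  Ties in beta break by larger
    neighbour count, then lower cluster index.  If the ladder is exhausted
    with no neighbour anywhere, the global SVR's prediction is returned and
    flagged in the trace.
    """
    K = len(candidates)
    radii = [float(r_override)] if r_override is not None else list(ctx.ladder.rungs())
    x_rank = _centered_unit_ranks(_rank_rows(np.asarray(input_features, float)))[0]
    counts = np.zeros(K, dtype=int)
    betas = np.zeros(K)
    for r in radii:
        hoods = []
        for k in range(K):
            idx = ctx.cluster_idx[k]
            nb = neighbors(ctx.z.auc[idx], ctx.z.ordinate[idx], (candidates[k], ordinate), r)
            hoods.append(idx[nb])
        counts = np.array([h.size for h in hoods])
        if counts.sum() == 0:
            continue
        betas = np.zeros(K)
        for k in range(K):
            if counts[k] > 0:
                # Spearman of input vs each neighbour = dot product of
                # centered unit-norm rank vectors; beta is their mean
                betas[k] = float(np.mean(ctx.train_unit_ranks[hoods[k]] @ x_rank))
        sel = max(range(K), key=lambda k: (betas[k], counts[k], -k))
        return PredictionTrace(
            input_id, candidates, float(ordinate), counts, betas,
            float(r), sel, float(candidates[sel]),
        )
    if global_prediction is None:
        raise FitError("radius ladder exhausted and no global fallback available")
    return PredictionTrace(
        input_id, candidates, float(ordinate), counts, np.zeros(K),
        float(radii[-1]), None, float(global_prediction), fallback=True,
    )
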