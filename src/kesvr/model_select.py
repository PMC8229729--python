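"""The outer kESVR fitting loop, evaluation metrics, cross-validation and
the plain-SVR / linear-regression baselines.

For each candidate cluster count k the pipeline re-partitions the residual
tuples, trains k local SVRs, runs the ensemble selection for every cell line
and scores the model by the average of the MSE on the union of per-cluster
training splits and the MSE on the union of per-cluster testing splits.  The
k with the lowest average MSE is retained.  The same seed drives every k's
splits so the loop compares models, not split luck.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LinearRegression

from .data_io import (
    DataError,
    ExpressionMatrix,
    GeneSubset,
    ResponseVector,
    align,
)
from .embedded_clustering import (
    FitError,
    InfeasibleK,
    LabeledData,
    ClusterPartition,
    SplitRecord,
    SvrModel,
    cluster_residuals,
    compute_residuals,
    split_indices,
    train_global_svr,
    transfer_partition,
)
from .embedding import (
    PCAEmbedding,
    ReducedDataset,
    build_reduced_dataset,
    fit_pca,
    select_component,
)
from .local_ensemble import (
    LocalModelSet,
    PredictionTrace,
    RadiusLadder,
    SelectionContext,
    compute_radius_ladder,
    predict_candidates,
    select_prediction,
    train_local_svrs,
)

log = logging.getLogger("kesvr")


# ---------------------------------------------------------------------------
# metrics

def mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared error."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise DataError("mse needs two equal-length non-empty vectors")
    return float(np.mean((y_true - y_pred) ** 2))


def avg_mse(train_mse: float, test_mse: float) -> float:
    """The model-scoring metric: mean of the training- and testing-split MSEs."""
    return (train_mse + test_mse) / 2.0


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (may be negative)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise DataError("r_squared needs two equal-length vectors of >= 2 points")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise DataError("r_squared undefined for constant y_true")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def select_optimal_k(mse_values: Sequence[float], ks: Optional[Sequence[int]] = None) -> int:
    """The cluster count with the lowest average MSE (ties -> smallest k).

    Infeasible entries may be passed as NaN; they are never selected.
    """
    vals = np.asarray(mse_values, dtype=float)
    if ks is None:
        ks = list(range(1, len(vals) + 1))
    finite = np.isfinite(vals)
    if not finite.any():
        raise FitError("no feasible cluster count")
    best = min((vals[i], ks[i]) for i in range(len(vals)) if finite[i])
    return best[1]


# ---------------------------------------------------------------------------
# the fitted artifact

@dataclass
class KesvrModel:
    """Everything needed to predict with no refit."""

    drug_id: str
    seed: int
    embedding: PCAEmbedding
    p: int
    gene_subset: GeneSubset
    cell_ids: list[str]
    global_svr: SvrModel
    global_split: object
    partition: ClusterPartition
    local_models: LocalModelSet
    ladder: RadiusLadder
    z_train: ReducedDataset            # clustered, training cells
    train_features: np.ndarray         # target-gene features, training order
    train_labels: np.ndarray
    optimal_k: int
    k_table: list[dict]                # per k: {k, train_mse, test_mse, avg_mse, feasible}
    fit_traces: dict = field(default_factory=dict)   # cell id -> PredictionTrace
    _ctx: SelectionContext = field(default=None, repr=False)

    def context(self) -> SelectionContext:
        if self._ctx is None:
            self._ctx = SelectionContext(self.z_train, self.ladder, self.train_features)
        return self._ctx

    def predict(self, expr_new: ExpressionMatrix, r_override: Optional[float] = None,
                ) -> tuple[list[str], np.ndarray, list[PredictionTrace]]:
        return predict(self, expr_new, r_override=r_override)

    def __getstate__(self):
        state = self.__dict__.copy()
        state["_ctx"] = None  # rebuilt lazily; keeps archives lean
        return state


def _ensemble_predict_all(
    q: LabeledData,
    ordinates: np.ndarray,
    candidates_by_cell: np.ndarray,
    ctx: SelectionContext,
    global_pred: np.ndarray,
    r_override: Optional[float] = None,
) -> tuple[np.ndarray, list[PredictionTrace]]:
    psi = np.empty(q.n_cells)
    traces: list[PredictionTrace] = []
    for i in range(q.n_cells):
        tr = select_prediction(
            q.cell_ids[i], q.features[i], float(ordinates[i]),
            candidates_by_cell[i], ctx,
            global_prediction=float(global_pred[i]), r_override=r_override,
        )
        psi[i] = tr.selected_value
        traces.append(tr)
    return psi, traces


def fit_kesvr(
    expr: ExpressionMatrix,
    resp: ResponseVector,
    genes: Optional[GeneSubset] = None,
    k_max: int = 12,
    seed: int = 0,
    train_fraction: float = 0.75,
    p_override: Optional[int] = None,
) -> KesvrModel:
    """Fit the full pipeline and retain the cluster count with lowest avg MSE.

    Steps: align -> covariance PCA on the full gene set -> reduced dataset on
    component p (default 1) -> global SVR on the target genes (seeded 75%
    split) -> signed residuals for all cells -> for each k in 1..k_max:
    k-means partition of the residuals, local SVRs, ensemble selection for
    every cell, average (train + test) MSE -> argmin k.
    """
    if k_max < 1:
        raise FitError("k_max must be >= 1")
    expr_a, resp_a, subset = align(expr, resp, genes)
    embedding = fit_pca(expr_a)
    p = select_component(embedding, p_override)
    z = build_reduced_dataset(embedding, expr_a, resp_a, p)
    q = LabeledData.from_aligned(expr_a, resp_a, subset)
    global_svr, gsplit = train_global_svr(q, train_fraction, seed)
    psi_set = compute_residuals(global_svr, q)
    global_pred = global_svr.predict(q.features)

    k_table: list[dict] = []
    best: Optional[dict] = None
    for k in range(1, k_max + 1):
        try:
            partition = cluster_residuals(psi_set, k, seed)
        except (InfeasibleK, FitError) as exc:
            log.info("k=%d infeasible: %s", k, exc)
            k_table.append({"k": k, "train_mse": np.nan, "test_mse": np.nan,
                            "avg_mse": np.nan, "feasible": False})
            continue
        zc = transfer_partition(z, partition)
        local = train_local_svrs(q, partition, train_fraction, seed)
        ladder = compute_radius_ladder(zc)
        ctx = SelectionContext(zc, ladder, q.features)
        cands = np.column_stack([m.predict(q.features) for m in local.models])
        psi, traces = _ensemble_predict_all(q, z.ordinate, cands, ctx, global_pred)

        id_pos = {c: i for i, c in enumerate(q.cell_ids)}
        train_ids = [c for rec in local.splits for c in rec.train_ids]
        test_ids = [c for rec in local.splits for c in rec.test_ids]
        tr_idx = np.array([id_pos[c] for c in train_ids], dtype=int)
        te_idx = np.array([id_pos[c] for c in test_ids], dtype=int)
        train_mse = mse(q.labels[tr_idx], psi[tr_idx])
        if te_idx.size:
            test_mse = mse(q.labels[te_idx], psi[te_idx])
            score = avg_mse(train_mse, test_mse)
        else:  # every cluster below the split threshold
            test_mse = np.nan
            score = train_mse
        row = {"k": k, "train_mse": train_mse, "test_mse": test_mse,
               "avg_mse": score, "feasible": True}
        k_table.append(row)
        if best is None or score < best["score"]:
            best = {
                "score": score, "k": k, "partition": partition, "local": local,
                "ladder": ladder, "zc": zc,
                "traces": dict(zip(q.cell_ids, traces)),
            }

    if best is None:
        raise FitError("every cluster count was infeasible")
    optimal_k = select_optimal_k([r["avg_mse"] for r in k_table])
    assert optimal_k == best["k"]

    return KesvrModel(
        drug_id=resp.drug_id, seed=seed, embedding=embedding, p=p,
        gene_subset=subset, cell_ids=list(q.cell_ids),
        global_svr=global_svr, global_split=gsplit,
        partition=best["partition"], local_models=best["local"],
        ladder=best["ladder"], z_train=best["zc"],
        train_features=q.features, train_labels=q.labels,
        optimal_k=optimal_k, k_table=k_table, fit_traces=best["traces"],
    )


def predict(
    model: KesvrModel,
    expr_new: ExpressionMatrix,
    r_override: Optional[float] = None,
) -> tuple[list[str], np.ndarray, list[PredictionTrace]]:
    """Ensemble predictions for new cell lines with the stored artifacts.

    The new matrix must contain every gene of the stored embedding (the
    target genes are a subset); missing genes are a hard error listing them.
    """
    if expr_new.n_cells == 0:
        raise DataError("empty input matrix")
    have = set(expr_new.gene_ids)
    missing_targets = [g for g in model.gene_subset.gene_ids if g not in have]
    if missing_targets:
        raise DataError(
            "input matrix lacks target genes: " + ", ".join(missing_targets[:20])
        )
    missing = [g for g in model.embedding.gene_ids if g not in have]
    if missing:
        raise DataError(
            "input matrix lacks genes of the fitted embedding: " + ", ".join(missing[:20])
        )
    full = expr_new.gene_rows(model.embedding.gene_ids)
    ordinates = model.embedding.project(full, model.p)
    feats = expr_new.gene_rows(model.gene_subset.gene_ids).T
    global_pred = model.global_svr.predict(feats)
    ctx = model.context()
    q_like = LabeledData(list(expr_new.cell_ids), list(model.gene_subset.gene_ids),
                         feats, np.zeros(expr_new.n_cells))
    cands = np.column_stack([m.predict(feats) for m in model.local_models.models])
    psi, traces = _ensemble_predict_all(
        q_like, ordinates, cands, ctx, global_pred, r_override=r_override
    )
    return list(expr_new.cell_ids), psi, traces


# ---------------------------------------------------------------------------
# baselines

@dataclass
class BaselineReport:
    """Single 75/25-split evaluation mirroring the ensemble's scoring."""

    kind: str
    train_mse: float
    test_mse: float
    avg_mse: float
    predictions: np.ndarray  # over all cells, aligned order
    split: object


def baseline_fit(
    kind: str, q: LabeledData, seed: int = 0, train_fraction: float = 0.75
) -> tuple[object, BaselineReport]:
    """Plain linear-regression or plain-SVR arm under the identical protocol.

    The SVR arm uses the exact global-SVR procedure (same split, same
    hyperparameter policy), so it is the k=1 ensemble by construction.
    """
    if kind == "svr":
        model, rec = train_global_svr(q, train_fraction, seed)
        pred = model.predict(q.features)
    elif kind == "linear":
        tr, te = split_indices(q.n_cells, train_fraction, seed)
        rec = SplitRecord(tr, te, [q.cell_ids[i] for i in tr],
                          [q.cell_ids[i] for i in te])
        model = LinearRegression()
        model.fit(q.features[tr], q.labels[tr])
        pred = model.predict(q.features)
    else:
        raise DataError(f"unknown baseline kind {kind!r} (use 'linear' or 'svr')")
    tr_mse = mse(q.labels[rec.train_idx], pred[rec.train_idx])
    te_mse = mse(q.labels[rec.test_idx], pred[rec.test_idx])
    return model, BaselineReport(kind, tr_mse, te_mse, avg_mse(tr_mse, te_mse), pred, rec)


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class EvaluationReport:
    """Per-fold and summary metrics of a seeded cross-validation.

    ``rmse`` is the square root of each fold's held-out (pooled) MSE,
    averaged over folds and iterations; ``r2`` pools every held-out
    prediction of an iteration and is then averaged over iterations.
    """

    method: str
    folds: int
    iterations: int
    rows: list[dict]        # iteration, fold, train_mse, test_mse, avg_mse
    overall_avg_mse: float
    rmse: float
    r2: float
    fold_assignments: list  # per iteration: list of test-cell-id lists


def cross_validate(
    expr: ExpressionMatrix,
    resp: ResponseVector,
    genes: Optional[GeneSubset] = None,
    folds: int = 5,
    iterations: int = 1,
    seed: int = 0,
    k_max: int = 12,
    method: str = "kesvr",
) -> EvaluationReport:
    """Seeded k-fold cross-validation of kESVR or a baseline arm.

    Per fold the model is fitted on the other folds; the training MSE is its
    error on those cells and the testing MSE its error on the held-out fold;
    the fold average is their mean and the overall score the mean of fold
    averages (then of iterations).
    """
    if folds < 2:
        raise DataError("folds must be >= 2")
    if iterations < 1:
        raise DataError("iterations must be >= 1")
    expr_a, resp_a, subset = align(expr, resp, genes)
    n = expr_a.n_cells
    if folds > n:
        raise DataError(f"{folds} folds exceed the {n} aligned cells")
    rows: list[dict] = []
    assignments = []
    rmses, r2s = [], []
    for it in range(iterations):
        rng = np.random.default_rng(seed + it)
        perm = rng.permutation(n)
        fold_idx = np.array_split(perm, folds)
        assignments.append([[expr_a.cell_ids[i] for i in f] for f in fold_idx])
        pooled_true, pooled_pred = [], []
        for fi, test in enumerate(fold_idx):
            test = np.sort(test)
            train = np.sort(np.setdiff1d(perm, test))
            tr_cells = [expr_a.cell_ids[i] for i in train]
            te_cells = [expr_a.cell_ids[i] for i in test]
            e_tr = expr_a.subset_cells(tr_cells)
            r_tr = resp_a.subset_cells(tr_cells)
            e_te = expr_a.subset_cells(te_cells)
            if method == "kesvr":
                m = fit_kesvr(e_tr, r_tr, subset, k_max=k_max, seed=seed + it)
                _, pred_tr, _ = predict(m, e_tr)
                _, pred_te, _ = predict(m, e_te)
            elif method in ("svr", "linear"):
                q_tr = LabeledData.from_aligned(e_tr, r_tr, _intersect(subset, e_tr))
                bm, _ = baseline_fit(method, q_tr, seed=seed + it)
                feats_te = e_te.gene_rows(q_tr.gene_ids).T
                pred_tr = np.asarray(bm.predict(q_tr.features))
                pred_te = np.asarray(bm.predict(feats_te))
            else:
                raise DataError(f"unknown method {method!r}")
            y_tr = r_tr.auc
            y_te = resp_a.auc[test]
            tr_mse = mse(y_tr, pred_tr)
            te_mse = mse(y_te, pred_te)
            rows.append({"iteration": it, "fold": fi, "train_mse": tr_mse,
                         "test_mse": te_mse, "avg_mse": avg_mse(tr_mse, te_mse)})
            rmses.append(float(np.sqrt(te_mse)))
            pooled_true.extend(y_te)
            pooled_pred.extend(pred_te)
        r2s.append(r_squared(np.array(pooled_true), np.array(pooled_pred)))
    overall = float(np.mean([r["avg_mse"] for r in rows]))
    return EvaluationReport(method, folds, iterations, rows, overall,
                            float(np.mean(rmses)), float(np.mean(r2s)), assignments)


def _intersect(subset: GeneSubset, expr: ExpressionMatrix) -> GeneSubset:
    have = set(expr.gene_ids)
    return GeneSubset([g for g in subset.gene_ids if g in have])
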