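"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately naive: dense eigendecomposition for PCA,
quadratic all-pairs scans for neighbour search, rank-then-Pearson for
Spearman, manual kernel expansion for SVR predictions, and a literal replay
of the radius-escalation/argmax selection rule.  None of it shares code
with the package paths it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata


def pca_oracle(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of the genes x genes sample covariance.

    Returns (means, components[rows], variances) under the same sign
    convention as the package: largest-magnitude loading entry positive.
    """
    X = values.T.astype(float)                    # cells x genes
    means = X.mean(axis=0)
    C = np.cov(X, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order].T                # rows = components
    flip = np.sign(V[np.arange(V.shape[0]), np.abs(V).argmax(axis=1)])
    return means, V * flip[:, None], w


def spearman_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Rank both vectors, then Pearson; 0 when either vector is constant."""
    ra, rb = rankdata(a), rankdata(b)
    if np.std(ra) == 0 or np.std(rb) == 0:
        return 0.0
    return float(np.corrcoef(ra, rb)[0, 1])


def neighbors_oracle(points: np.ndarray, center: tuple[float, float], r: float) -> list[int]:
    """All-pairs scan: indices of points within the closed ball of radius r."""
    out = []
    for i, (x, y) in enumerate(points):
        if math.dist((x, y), center) <= r:
            out.append(i)
    return out


def svr_predict_oracle(model, X: np.ndarray) -> np.ndarray:
    """Re-evaluate the RBF kernel expansion of a fitted SvrModel by hand."""
    if model.kind == "constant":
        return np.full(np.atleast_2d(X).shape[0], model.constant)
    Xs = (np.atleast_2d(X) - model.feature_mean) / model.feature_scale
    sv = model._svr.support_vectors_
    dual = model._svr.dual_coef_[0]
    b = model._svr.intercept_[0]
    out = np.empty(Xs.shape[0])
    for i, x in enumerate(Xs):
        k = np.exp(-model.gamma * np.sum((sv - x) ** 2, axis=1))
        out[i] = dual @ k + b
    return out


def replay_selection(
    input_features: np.ndarray,
    ordinate: float,
    candidates: np.ndarray,
    cluster_labels: np.ndarray,
    z_auc: np.ndarray,
    z_ordinate: np.ndarray,
    train_features: np.ndarray,
    ladder_spans: np.ndarray,
    global_prediction: float,
    r_override: float | None = None,
):
    """Literal replay of the ensemble selection.

    For each escalation radius (strictly increasing ladder values): collect
    each candidate's neighbours in its own cluster by quadratic scan; if all
    neighbourhoods are empty escalate; otherwise score each candidate by the
    mean oracle-Spearman with its neighbours (empty -> 0) and take the
    argmax, ties broken by larger neighbour count then lower cluster index.
    Returns (selected_cluster, selected_value, radius, counts, betas,
    fallback).
    """
    K = len(candidates)
    radii = [r_override] if r_override is not None else sorted(set(ladder_spans))
    for r in radii:
        hoods = []
        for k in range(K):
            idx = np.flatnonzero(cluster_labels == k)
            pts = np.column_stack([z_auc[idx], z_ordinate[idx]])
            nb = neighbors_oracle(pts, (candidates[k], ordinate), r)
            hoods.append(idx[nb])
        counts = [len(h) for h in hoods]
        if sum(counts) == 0:
            continue
        betas = []
        for k in range(K):
            if counts[k] == 0:
                betas.append(0.0)
            else:
                betas.append(float(np.mean([
                    spearman_oracle(input_features, train_features[j])
                    for j in hoods[k]])))
        best = 0
        for k in range(1, K):
            if (betas[k], counts[k], -k) > (betas[best], counts[best], -best):
                best = k
        return best, float(candidates[best]), float(r), counts, betas, False
    return None, float(global_prediction), float(radii[-1]), [0] * K, [0.0] * K, True
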