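"""Principal-component reduction of expression data and the reduced 2-D dataset.

Each cell line is mapped to the point (AUC, principal-component projection):
drug response on the abscissa, the selected PC score on the ordinate.  All
clustering geometry, neighbour search and ensemble selection happen in this
plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_io import DataError, ExpressionMatrix, ResponseVector


@dataclass
class PCAEmbedding:
    """Covariance PCA of the full gene set (no per-gene scaling).

    ``components`` rows are orthonormal loading vectors over genes, ordered by
    explained variance; each row is sign-fixed so its largest-magnitude entry
    is positive (PCA sign is arbitrary, but the downstream neighbour geometry
    must be reproducible across runs and platforms).
    """

    gene_ids: list[str]
    gene_means: np.ndarray          # (n_genes,)
    components: np.ndarray          # (n_components, n_genes), orthonormal rows
    explained_variance: np.ndarray  # (n_components,), non-increasing, ddof=1

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def project(self, values: np.ndarray, p: int) -> np.ndarray:
        """Scores of column vectors (genes x cells) on 1-based component ``p``."""
        if not 1 <= p <= self.n_components:
            raise DataError(f"component {p} out of range 1..{self.n_components}")
        centered = values - self.gene_means[:, None]
        return self.components[p - 1] @ centered


@dataclass
class ReducedDataset:
    """Per cell line the 2-D point (AUC, PC score), optionally cluster-labelled."""

    cell_ids: list[str]
    auc: np.ndarray        # abscissa
    ordinate: np.ndarray   # PC score
    p: int                 # 1-based component index used
    labels: Optional[np.ndarray] = field(default=None)  # 0-based cluster labels

    def __post_init__(self) -> None:
        self.auc = np.asarray(self.auc, dtype=float)
        self.ordinate = np.asarray(self.ordinate, dtype=float)
        n = len(self.cell_ids)
        if self.auc.shape != (n,) or self.ordinate.shape != (n,):
            raise DataError("reduced dataset coordinates do not match cell ids")
        if not (np.all(np.isfinite(self.auc)) and np.all(np.isfinite(self.ordinate))):
            raise DataError("non-finite coordinate in reduced dataset")

    def points(self) -> np.ndarray:
        return np.column_stack([self.auc, self.ordinate])


def fit_pca(expr: ExpressionMatrix) -> PCAEmbedding:
    """Covariance PCA via thin SVD of the centered cells x genes matrix.

    The SVD route works through the min(N, G)-sized spectrum, so the usual
    G >> N expression shape (tens of thousands of genes, hundreds of cell
    lines) never forms a G x G covariance matrix.  Variances use ddof=1, so
    their sum equals the summed per-gene sample variance.
    """
    if expr.n_cells < 2:
        raise DataError("PCA needs at least 2 cell lines")
    X = expr.values.T.astype(float)            # cells x genes
    means = X.mean(axis=0)
    Xc = X - means
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2 / (expr.n_cells - 1)
    if var.sum() <= 0:
        raise DataError("degenerate expression data: zero variance across cell lines")
    # drop numerically-null directions so stored components stay meaningful
    keep = var > var[0] * 1e-12
    components = Vt[keep]
    var = var[keep]
    flip = np.sign(components[np.arange(components.shape[0]),
                              np.abs(components).argmax(axis=1)])
    components = components * flip[:, None]
    return PCAEmbedding(list(expr.gene_ids), means, components, var)


def select_component(embedding: PCAEmbedding, p_override: Optional[int] = None) -> int:
    """The component used for the reduced dataset.

    The first component is the variance-loss minimiser, so the default is
    p = 1; an explicit override is honoured for experimentation.
    """
    if p_override is None:
        return 1
    if not 1 <= p_override <= embedding.n_components:
        raise DataError(
            f"component override {p_override} out of range 1..{embedding.n_components}"
        )
    return p_override


def build_reduced_dataset(
    embedding: PCAEmbedding,
    expr: ExpressionMatrix,
    resp: ResponseVector,
    p: int,
) -> ReducedDataset:
    """Pair each aligned cell line's AUC with its projection on component ``p``."""
    if expr.cell_ids != resp.cell_ids:
        raise DataError("expression and response must be aligned first")
    if expr.gene_ids != embedding.gene_ids:
        raise DataError("expression genes differ from the embedding's genes")
    scores = embedding.project(expr.values, p)
    return ReducedDataset(list(expr.cell_ids), resp.auc.copy(), scores, p)
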