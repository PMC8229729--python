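"""Synthetic expression/response data with planted response regimes.

The generator emulates the shape of a cell-line drug screen: a tall
expression matrix in which a small set of target genes drives the response,
plus many pure-noise genes.  Cells are assigned to regimes; each regime
elevates its own disjoint block of marker genes (so regimes are separable
both in Euclidean distance and in rank profile) and maps a latent score - a fixed positive-weight combination of the target
genes - through its own response function (linear, quadratic or sinusoid).
A single global smooth regressor is therefore genuinely mis-specified on
multi-regime data, which is exactly the situation the local ensemble is
built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import DataError, ExpressionMatrix, GeneSubset, ResponseVector

#: per-gene |offset| between regimes, in units of the within-regime sd (1.0)
REGIME_OFFSET_SD = 4.0

#: spread of gene-specific baseline expression levels across target genes
BASELINE_SD = 4.0

#: baseline AUC level and within-regime response scales
_REGIME_FUNCS = ("linear", "quadratic", "sinusoid")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic screen."""

    n_cells: int = 300
    n_genes: int = 1000
    n_target_genes: int = 50
    n_regimes: int = 3
    noise_sd: float = 0.3          # AUC units
    missing_fraction: float = 0.0
    seed: int = 0
    drug_id: str = "synthetic_drug"

    def __post_init__(self) -> None:
        if self.n_target_genes > self.n_genes:
            raise DataError("n_target_genes exceeds n_genes")
        if self.n_regimes < 1:
            raise DataError("n_regimes must be >= 1")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise DataError("missing_fraction must be in [0, 1)")
        if self.n_cells < 2 or self.n_genes < 1:
            raise DataError("need at least 2 cells and 1 gene")


@dataclass
class SyntheticTruth:
    """The generator's ground truth, for recovery tests."""

    regime: np.ndarray            # (n_cells,) labels in 0..n_regimes-1
    noise_free: np.ndarray        # (n_cells,) response before noise
    target_gene_ids: list[str]
    weights: np.ndarray           # fixed positive latent-score weights, ||w||=1
    offsets: np.ndarray           # (n_regimes, n_target_genes) mean shifts
    regime_funcs: list[str]
    coefficients: dict = field(default_factory=dict)


def _regime_response(func: str, level: float, t: np.ndarray) -> np.ndarray:
    """Response as a function of the centered latent score t ~ N(0, 1).

    Regimes sit at distinct response levels (so they are recoverable from
    the residual plane) and follow distinct nonlinear shapes (so a single
    smooth global regressor is genuinely mis-specified).
    """
    if func == "linear":
        return level + 0.8 * t
    if func == "quadratic":
        return level + 0.5 * t**2
    if func == "sinusoid":
        return level + 1.0 * np.sin(2.0 * t)
    raise DataError(f"unknown regime function {func!r}")


#: vertical separation between consecutive regime response levels (AUC units)
REGIME_LEVEL_STEP = 3.5


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, ResponseVector, SyntheticTruth]:
    """Draw one fully seeded synthetic screen.

    Each cell carries a latent activity t ~ N(0, 1).  Target gene j reads
    ``offset[regime, j] + a_j * t + eps`` with fixed positive loadings a_j
    and per-gene noise, so cells with similar latent activity (hence similar
    response) also have similar expression rank profiles - the signal the
    ensemble's Spearman selection relies on.  Each regime elevates its own
    disjoint marker block of target genes by ``REGIME_OFFSET_SD`` x the
    within-regime sd, separating regimes both in expression space and in
    rank profile.  Non-target genes are N(0, 1) noise.  The response is the regime's function of the latent
    score - the fixed positive-weight combination of the target genes that
    recovers t - plus N(0, noise_sd) noise.
    """
    rng = np.random.default_rng(spec.seed)
    n, g, t = spec.n_cells, spec.n_genes, spec.n_target_genes
    regime = rng.integers(0, spec.n_regimes, size=n)
    # marker-gene structure: each regime elevates its own disjoint block of
    # target genes, so same-regime profiles are strongly rank-correlated and
    # cross-regime profiles are not
    offsets = np.zeros((spec.n_regimes, t))
    block = max(t // spec.n_regimes, 1)
    for m in range(spec.n_regimes):
        offsets[m, m * block: (m + 1) * block] = REGIME_OFFSET_SD
    latent = rng.standard_normal(n)
    loadings = rng.uniform(0.5, 1.5, size=t)
    eps_sd = 1.0
    # gene-specific baseline levels: the dominant structure of real expression
    # profiles, making any two cells' rank profiles substantially correlated
    baseline = rng.normal(0.0, BASELINE_SD, size=t)
    target = (baseline + offsets[regime] + np.outer(latent, loadings)
              + eps_sd * rng.standard_normal((n, t)))
    noise_genes = rng.standard_normal((n, g - t))
    # fixed positive weights recovering the latent activity from expression:
    # w . (x - baseline - offset) = t + small noise
    w = loadings / (loadings @ loadings)
    score = target @ w - (offsets @ w)[regime] - baseline @ w
    funcs = [_REGIME_FUNCS[m % len(_REGIME_FUNCS)] for m in range(spec.n_regimes)]
    levels = [2.0 + REGIME_LEVEL_STEP * m for m in range(spec.n_regimes)]
    noise_free = np.empty(n)
    for m in range(spec.n_regimes):
        sel = regime == m
        noise_free[sel] = _regime_response(funcs[m], levels[m], score[sel])
    auc = noise_free + rng.normal(0.0, spec.noise_sd, size=n)

    cell_ids = [f"C{i + 1:04d}" for i in range(n)]
    target_ids = [f"TG{j + 1:04d}" for j in range(t)]
    other_ids = [f"G{j + 1:05d}" for j in range(g - t)]
    values = np.vstack([target.T, noise_genes.T])
    expr = ExpressionMatrix(target_ids + other_ids, cell_ids, values)

    mask = np.ones(n, dtype=bool)
    if spec.missing_fraction > 0:
        n_missing = int(round(spec.missing_fraction * n))
        drop = rng.choice(n, size=n_missing, replace=False)
        mask[drop] = False
    auc_obs = np.where(mask, auc, np.nan)
    resp = ResponseVector(spec.drug_id, cell_ids, auc_obs)

    truth = SyntheticTruth(
        regime=regime, noise_free=noise_free, target_gene_ids=target_ids,
        weights=w, offsets=offsets, regime_funcs=funcs,
        coefficients={"offset_sd": REGIME_OFFSET_SD,
                      "levels": levels, "loadings": loadings, "eps_sd": eps_sd,
                      "baseline": baseline, "baseline_sd": BASELINE_SD,
                      "slopes": {"linear": 0.8, "quadratic": 0.5, "sinusoid": (1.0, 2.0)}},
    )
    return expr, resp, truth


#: the frozen worked example: small enough to audit by hand, rich enough to
#: exercise clustering, the radius ladder and the ensemble selection
WORKED_SPEC = SyntheticSpec(
    n_cells=60, n_genes=40, n_target_genes=8, n_regimes=3,
    noise_sd=0.3, missing_fraction=0.0, seed=844, drug_id="worked_drug",
)


def make_worked_fixture() -> tuple[ExpressionMatrix, ResponseVector, SyntheticTruth, GeneSubset]:
    """The deterministic ~60-cell fixture used throughout the test suite."""
    expr, resp, truth = generate(WORKED_SPEC)
    return expr, resp, truth, GeneSubset(list(truth.target_gene_ids))
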