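# Methods

## The model

`kesvr` predicts a drug's AUC for a cell line from gene expression by an
ensemble of local support vector regressions. The pipeline is described in
the README; this note records the assumptions, the numerical choices, and
what the synthetic benchmarks do and do not demonstrate.

The method rests on three assumptions:

- **Low-dimensional geometry.** Most of the expression variation relevant
  to grouping cell lines survives projection onto a leading principal
  component, so the plane `(AUC, PC score)` is an adequate arena for
  neighbour search. PCA is computed on the covariance (no per-gene
  scaling) of the *full* gene set; the SVR features are the *target-gene*
  subset. These two gene sets are deliberately independent inputs.
- **Residual structure is informative.** Cells that a single global SVR
  mispredicts in the same way (same response level, same signed error)
  form coherent subpopulations worth their own local model. Residuals are
  signed (`e = Y − Ŷ`); an absolute-residual switch exists for sensitivity
  analysis. Both k-means axes are in AUC units, so no standardization is
  applied before clustering.
- **Expression similarity predicts response similarity.** The ensemble
  selects among candidates by the mean Spearman correlation between the
  input's target-gene profile and the profiles of each candidate's
  neighbours. If rank similarity carries no response information, the
  selection degenerates and the k-loop falls back to `k = 1` — which is by
  construction a single plain SVR.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `p` | 1 | principal component used for the ordinate; the first component minimises variance loss. An override exists for experimentation; no automatic search over `p` is performed. |
| `train_fraction` | 0.75 | split used for the global and every local SVR. |
| `k_max` | 12 | upper end of the cluster-count loop (API/CLI default). The synthetic studies in the test suite and acceptance script use `k_max = 6`, which covers the planted 3-regime structure with headroom. |
| SVR `C` | 1.0 | regularization weight. |
| SVR `epsilon` | 0.1 × sd(train labels) | tube width scales with the response spread. |
| SVR `gamma` | median heuristic | `1/(2 m²)` with `m` the median pairwise Euclidean distance of the standardized training features; the standard width-free choice for RBF kernels. |
| k-means restarts | 10 | seeded k-means++ restarts, best within-cluster SS kept; makes the empirically observed stability of the residual clustering reproducible by construction. |
| `r` | ladder minimum | smallest per-cluster AUC span, escalating rung by rung when every neighbourhood is empty. |

Features are standardized to zero mean / unit variance inside the SVR
wrapper (parameters stored with the model); zero-variance features get
scale 1. Clusters with fewer than 4 members are fitted on all members
without a split; singletons become constant predictors at the member mean.

## Numerical and policy choices

- **PCA route.** Thin SVD of the centered cells × genes matrix, so the
  G ≫ N case (tens of thousands of genes) never forms a G × G covariance.
  Loading signs are fixed (largest-magnitude entry positive) because PCA
  sign is arbitrary but the neighbour geometry must be reproducible across
  runs and platforms. Variances use `ddof = 1`; components with variance
  below `1e-12` × the leading variance are dropped.
- **Neighbour metric.** The ball in the `(AUC, PC)` plane mixes units
  unscaled, matching the plane the model reasons in.
- **Spearman.** Rank (average ranks on ties), then Pearson — implemented
  as a dot product of centered unit-norm rank vectors so a cell's score
  against many neighbours vectorises. A constant profile has no rank
  signal and contributes 0.
- **Ties in β.** Larger neighbour count wins, then lower cluster index:
  deterministic, and favours the better-supported candidate.
- **Ladder exhaustion.** If even the largest rung yields no neighbour
  anywhere (possible only for inputs far outside the training geometry),
  the global SVR's prediction is returned and flagged in the trace so the
  case is auditable.
- **k-loop scoring.** "Training MSE" is the MSE of the *ensemble-selected*
  values over the union of per-cluster 75 % splits, "testing MSE" over the
  union of 25 % splits; their mean scores the cluster count. One seed
  drives every k's splits, so the loop compares models rather than split
  luck. A k whose k-means partition cannot be formed is skipped and
  recorded as infeasible (never selected).
- **Seeding.** The split seed of cluster `k` is `seed + k`, so a
  single-cluster partition reproduces the global/baseline split exactly;
  this makes the `k = 1` ensemble bit-identical to the plain-SVR baseline.
- **Missing responses.** Cell lines without an AUC for the modelled drug
  are excluded from training for that drug (models are per-drug, so
  nothing is lost across drugs). Alignment orders cells
  lexicographically, making every seeded split independent of file order.
  Fewer than 10 aligned cells is a hard error.
- **Expression units.** Taken as is — no log transform or z-scoring before
  PCA. A pre-scaling hook is deliberately absent; callers who want
  transformed inputs transform the matrix they pass in.
- **Cross-validation.** Seeded fold assignment; per fold the model is
  refitted on the remaining folds. RMSE is the square root of each fold's
  pooled held-out MSE, averaged over folds and iterations; R² pools every
  held-out prediction of an iteration. The pooling order is stated here
  because it is a genuine convention choice.
- **Rejected selection rules.** Four alternatives to the max-β rule
  (maximum average Spearman against the parent SVR's whole training set;
  β-weighted averaging of candidates; maximum neighbour count;
  neighbour-count-weighted averaging) are documented design alternatives
  and intentionally not implemented.

## The synthetic generator

`kesvr.synthetic.generate` emulates the *shape* of a public cell-line
screen — a tall matrix (default 1000 genes, 300 cells) in which a small
target-gene set (default 50) drives response — with a planted regime
structure the pipeline should recover:

- each cell has a latent activity `t ~ N(0,1)`; target gene `j` reads
  `baseline_j + offset[regime, j] + a_j t + ε`, with fixed positive
  loadings `a_j ~ U(0.5, 1.5)` and per-gene noise `ε ~ N(0, 1)`;
- gene-specific baseline levels (`N(0, 4)`) reproduce the dominant
  structure of real profiles: any two cells' rank profiles are
  substantially correlated, so rank similarity differences — not the
  trivial self-match of a training cell re-predicted — drive the β score;
- each regime elevates its own disjoint marker block of target genes by
  4 × the within-regime sd, separating regimes in Euclidean distance, in
  rank profile, and along leading principal components;
- regime `m` maps the latent score — the fixed positive-weight combination
  of target genes `w = a/(aᵀa)` that recovers `t` — through its own
  response function (linear `2 + 0.8t`, quadratic `5.5 + 0.5t²`, sinusoid
  `9 + sin 2t`), placing regimes at distinct response levels 3.5 AUC units
  apart, plus `N(0, noise_sd)` noise (default sd 0.3 AUC);
- non-target genes are `N(0,1)` noise; a requested fraction of responses
  can be masked; everything is driven by one seed.

The worked fixture (`tests/data/worked/`, regenerated bit-identically by
`make_worked_fixture`) is a 60-cell, 40-gene, 8-target-gene, 3-regime
instance of the same generator, committed together with
oracle-recomputed intermediates (PC ordinates, residuals, cluster labels,
one full selection trace).

**What passing these benchmarks shows — and does not.** On this generator
the ensemble recovers planted regimes from the residual plane (adjusted
Rand > 0.8 at the true k), beats the plain SVR on multi-regime screens,
and collapses to `k = 1` on structureless ones. Real screens differ in
ways the generator does not model: empirical expression distributions are
heavy-tailed and batch-structured, response regimes overlap and are not
equally populated, target-gene lists are noisy, and expression–response
similarity is far weaker. Passing here demonstrates correctness of the
machinery and the claimed qualitative behaviour, not expected accuracy on
any real dataset.

Problem sizes throughout the suite (300-cell screens, `k_max = 6`, 10
seeds per study) are the package's chosen benchmark scale: large enough
for every planted effect to be resolvable, small enough that the whole
suite runs on a laptop in well under a minute per study.

## Known limitations

- One drug per model; the `--all-drugs` style sweep is a thin outer loop
  left to the caller (each drug's model is independent).
- The joint optimisation over the component index `p` is not implemented;
  `p = 1` is used unless overridden.
- The β selection needs candidate neighbourhoods: for inputs far outside
  the training cloud the flagged global-SVR fallback answers, and its
  quality is that of the global model.
- MSE estimates from the k-loop are optimistic in absolute terms (the
  selection context contains the full clustered training set, including
  each evaluated cell's own point); they are used only to *compare*
  cluster counts under identical conditions. Held-out quality should be
  read from `cross_validate`, which refits per fold.
- No alternative clusterers (GMM, hierarchical) or cluster-quality indices
  for choosing k: the cluster count is selected by downstream MSE, which
  is the quantity the model is judged on.
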