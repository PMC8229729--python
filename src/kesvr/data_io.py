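"""Reading, writing and aligning expression / drug-response data, and model persistence.

Expression matrices are genes x cell lines (header row = cell-line ids,
first column = gene ids, tab- or comma-separated).  Response tables are
drugs x cell lines of AUC values with ``NA``/empty for missing screens.
Gene lists are plain text, one identifier per line, ``#`` comments allowed.
"""

from __future__ import annotations

import difflib
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd

log = logging.getLogger("kesvr")

ARCHIVE_FORMAT_VERSION = 1


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """Gene expression, genes x cell lines, units as supplied (unit-agnostic)."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_cells), finite

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.cell_ids, "cell-line id")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                "non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, cell {self.cell_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return ExpressionMatrix(list(self.gene_ids), list(cell_ids), self.values[:, idx])

    def gene_rows(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Rows for the given genes, in the given order (genes x cells)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise DataError(f"genes absent from matrix: {', '.join(missing[:20])}")
        return self.values[[pos[g] for g in gene_ids], :]


@dataclass
class ResponseVector:
    """AUC drug response of one drug across cell lines; NaN where unscreened."""

    drug_id: str
    cell_ids: list[str]
    auc: np.ndarray  # shape (n_cells,), NaN where missing
    mask: np.ndarray = field(default=None)  # True where response present

    def __post_init__(self) -> None:
        self.auc = np.asarray(self.auc, dtype=float)
        _check_unique(self.cell_ids, "cell-line id")
        if self.mask is None:
            self.mask = np.isfinite(self.auc)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.auc.shape != (len(self.cell_ids),) or self.mask.shape != self.auc.shape:
            raise DataError("response vector length does not match cell ids")
        if not np.all(np.isfinite(self.auc[self.mask])):
            raise DataError("non-finite AUC flagged as present")

    def subset_cells(self, cell_ids: Sequence[str]) -> "ResponseVector":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return ResponseVector(self.drug_id, list(cell_ids), self.auc[idx], self.mask[idx])


@dataclass
class GeneSubset:
    """The target-gene feature set used by every SVR (a subset of the matrix genes)."""

    gene_ids: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.gene_ids:
            seen.setdefault(g, None)
        self.gene_ids = list(seen)
        if not self.gene_ids:
            raise DataError("empty gene subset")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ModelArchive:
    """Metadata of a persisted fitted model."""

    format_version: int
    fingerprint: dict


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise DataError(f"duplicate {what}(s): {', '.join(sorted(set(dups)))}")


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _check_header_unique(path: str, sep: str, what: str) -> None:
    # pandas silently renames duplicate header entries, so check the raw line
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_unique(header, what)


def read_expression_matrix(path: str) -> ExpressionMatrix:
    """Parse a genes x cells table; delimiter sniffed from the header line.

    Duplicated identifiers and non-numeric cells are hard errors naming the
    offending coordinates; row/column order is preserved from the file.
    """
    sep = _sniff_sep(path)
    _check_header_unique(path, sep, "cell-line id")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    _check_unique([str(g) for g in df.index], "gene id")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for gi, g in enumerate(df.index):
            for ci, c in enumerate(df.columns):
                try:
                    float(df.iat[gi, ci])
                except ValueError:
                    raise DataError(
                        f"non-numeric expression value {df.iat[gi, ci]!r} at "
                        f"gene {g!r} (row {gi + 2}), cell {c!r} (column {ci + 2})"
                    ) from None
        raise
    return ExpressionMatrix([str(g) for g in df.index], [str(c) for c in df.columns], values)


def write_expression_matrix(expr: ExpressionMatrix, path: str) -> None:
    """Write the canonical tab-separated dialect (full float precision)."""
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_response_table(responses: Sequence["ResponseVector"], path: str) -> None:
    """Write drugs x cells, tab-separated, NA for missing; cells must agree."""
    cells = responses[0].cell_ids
    for r in responses[1:]:
        if r.cell_ids != cells:
            raise DataError("response vectors cover different cell lines")
    df = pd.DataFrame(
        [np.where(r.mask, r.auc, np.nan) for r in responses],
        index=[r.drug_id for r in responses],
        columns=cells,
    )
    df.index.name = "drug_id"
    df.to_csv(path, sep="\t", na_rep="NA")


_NA_TOKENS = {"", "NA", "NaN", "nan", "na", "N/A"}


def read_response_table(
    path: str, drug: str, orientation: str = "drugs_as_rows"
) -> ResponseVector:
    """Extract one drug's AUC row from a drugs x cells table.

    Missing entries (empty, "NA", "NaN") are flagged in the mask, never
    dropped.  An unknown drug id raises with near-match suggestions.
    """
    sep = _sniff_sep(path)
    _check_header_unique(path, sep, "column id")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if orientation == "cells_as_rows":
        df = df.T
    elif orientation != "drugs_as_rows":
        raise DataError(f"unknown response orientation {orientation!r}")
    drugs = [str(d) for d in df.index]
    if drug not in drugs:
        near = difflib.get_close_matches(drug, drugs, n=3)
        hint = f"; did you mean {', '.join(near)}?" if near else ""
        raise DataError(f"drug {drug!r} not found in response table{hint}")
    row = df.loc[drug]
    auc = np.array(
        [np.nan if str(v).strip() in _NA_TOKENS else float(v) for v in row], dtype=float
    )
    return ResponseVector(drug, [str(c) for c in df.columns], auc)


def read_gene_list(path: str) -> GeneSubset:
    """Plain-text gene list, one id per line; '#' starts a comment."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return GeneSubset(ids)


MIN_ALIGNED_CELLS = 10


def align(
    expr: ExpressionMatrix,
    resp: ResponseVector,
    genes: Optional[GeneSubset] = None,
) -> tuple[ExpressionMatrix, ResponseVector, GeneSubset]:
    """Restrict to cell lines shared by expression and (present) response.

    Cell order after alignment is sorted lexicographically so every seeded
    downstream split is reproducible regardless of file ordering.  The gene
    subset is intersected with the matrix genes (absent subset -> all genes).
    """
    present = {c for c, m in zip(resp.cell_ids, resp.mask) if m}
    common = sorted(set(expr.cell_ids) & present)
    if len(common) < MIN_ALIGNED_CELLS:
        raise DataError(
            f"only {len(common)} cell lines shared between expression and response "
            f"with AUC present; need at least {MIN_ALIGNED_CELLS} to split and cluster"
        )
    expr_a = expr.subset_cells(common)
    resp_a = resp.subset_cells(common)
    if genes is None:
        subset = GeneSubset(list(expr.gene_ids))
    else:
        in_matrix = set(expr.gene_ids)
        kept = [g for g in genes.gene_ids if g in in_matrix]
        n_dropped = len(genes.gene_ids) - len(kept)
        if n_dropped:
            log.warning(
                "%d of %d target genes absent from the expression matrix; using %d",
                n_dropped, len(genes.gene_ids), len(kept),
            )
        if not kept:
            raise DataError("no target gene present in the expression matrix")
        subset = GeneSubset(kept)
    return expr_a, resp_a, subset


def save_model(model, path: str) -> ModelArchive:
    """Persist a fitted model; the round trip reproduces predictions exactly."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise DataError(f"cannot write model archive: {parent!r} is not a writable directory")
    if getattr(model, "optimal_k", None) is None:
        raise DataError("refusing to save an unfitted model")
    fingerprint = {
        "drug_id": model.drug_id,
        "n_cells": len(model.cell_ids),
        "n_target_genes": len(model.gene_subset),
        "seed": model.seed,
    }
    payload = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "fingerprint": fingerprint,
        "model": model,
    }
    joblib.dump(payload, path)
    return ModelArchive(ARCHIVE_FORMAT_VERSION, fingerprint)


def load_model(path: str):
    """Load a model archive saved by :func:`save_model`."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # noqa: BLE001 - joblib raises a zoo of types
        raise DataError(f"could not read model archive {path!r}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise DataError(f"{path!r} is not a model archive")
    if payload["format_version"] != ARCHIVE_FORMAT_VERSION:
        raise DataError(
            f"model archive format {payload['format_version']} unsupported "
            f"(this build reads version {ARCHIVE_FORMAT_VERSION})"
        )
    return payload["model"]
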