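"""Normalizations applied before differential testing and scoring.

RNA counts are library-size log-normalized: ``ln(1 + scale * x / total)``.
ATAC peak counts are TF-IDF normalized with non-binarized term frequencies,
``ln(1 + scale * TF * IDF)`` where ``TF = x / cell_total`` and
``IDF = n_cells / peak_total``; a binarized-IDF variant is available via
``binarize_idf=True``.  Bulk replicate counts use DESeq-style
median-of-ratios size factors.  Natural log throughout; base-2 logs appear
only in reported fold changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import CellFeatureMatrix


@dataclass
class NormalizedMatrix:
    """Features x cells matrix of normalized signal with provenance."""

    values: sp.csr_matrix
    feature_ids: list[str]
    cell_ids: list[str]
    method: str

    def __post_init__(self) -> None:
        if self.method not in ("lognorm", "tfidf", "mean_centered", "none"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
            finite = np.isfinite(self.values.data).all()
        else:
            self.values = np.asarray(self.values, dtype=float)
            finite = np.isfinite(self.values).all()
        if not finite:
            raise ValueError("normalized matrix contains non-finite values")
        nf = self.values.shape[0]
        nc = self.values.shape[1]
        if nf != len(self.feature_ids) or nc != len(self.cell_ids):
            raise ValueError("normalized matrix shape does not match id lists")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    def row(self, feature_id: str) -> np.ndarray:
        i = self.feature_ids.index(feature_id)
        r = self.values[i]
        return r.toarray().ravel() if sp.issparse(r) else np.asarray(r).ravel()


def _check_cell_totals(totals: np.ndarray) -> None:
    if (totals <= 0).any():
        bad = int((totals <= 0).sum())
        raise ValueError(f"{bad} cells have zero total counts; filter them first")


def lognorm_rna(counts: CellFeatureMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Library-size normalize and log1p-transform RNA counts."""
    totals = counts.cell_totals()
    _check_cell_totals(totals)
    x = sp.csr_matrix(counts.values, dtype=float)
    inv = sp.diags(scale / totals)
    out = (x @ inv).tocsr()
    out.data = np.log1p(out.data)
    return NormalizedMatrix(out, list(counts.feature_ids), list(counts.cell_ids), "lognorm")


def tfidf_atac(
    counts: CellFeatureMatrix, scale: float = 1e4, binarize_idf: bool = False
) -> NormalizedMatrix:
    """TF-IDF normalize ATAC peak counts.

    Peaks with zero total count carry no information for IDF and are dropped
    with a warning.
    """
    totals = counts.cell_totals()
    _check_cell_totals(totals)
    feature_tot = counts.feature_totals()
    keep = feature_tot > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} peaks with zero total count before TF-IDF",
            stacklevel=2,
        )
    x = sp.csr_matrix(counts.values, dtype=float)[keep, :]
    feature_ids = [f for f, k in zip(counts.feature_ids, keep) if k]
    n_cells = counts.n_cells
    if binarize_idf:
        ncells_open = (x > 0).sum(axis=1)
        idf = n_cells / np.asarray(ncells_open, dtype=float).ravel()
    else:
        idf = n_cells / feature_tot[keep]
    tf = x @ sp.diags(1.0 / totals)
    out = (sp.diags(idf) @ tf).tocsr()
    out.data = np.log1p(scale * out.data)
    return NormalizedMatrix(out, feature_ids, list(counts.cell_ids), "tfidf")


def median_ratio_size_factors(bulk_counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors for a regions x samples count table.

    ``sf_j = median over regions of x_ij / geometric_mean_i``, taken over
    regions with positive counts in every sample.
    """
    x = np.asarray(bulk_counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a regions x samples table with >= 2 samples")
    pos = (x > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no region has positive counts in all samples")
    logs = np.log(x[pos])
    log_geomean = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geomean, axis=0))
    return sf


def mean_center(matrix: NormalizedMatrix | CellFeatureMatrix, axis: str = "features") -> NormalizedMatrix:
    """Subtract the per-feature (row) mean; output is dense."""
    if axis != "features":
        raise ValueError("only per-feature centering is supported")
    dense = matrix.to_dense().astype(float)
    dense -= dense.mean(axis=1, keepdims=True)
    return NormalizedMatrix(
        sp.csr_matrix(dense), list(matrix.feature_ids), list(matrix.cell_ids), "mean_centered"
    )
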