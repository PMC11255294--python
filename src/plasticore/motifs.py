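"""Per-cell motif accessibility deviations with background-matched z-scores.

For each motif the observed per-cell count in its member peaks is compared
with the count expected from each cell's depth and each peak's overall
accessibility; the fractional deviation is then z-scored against the same
statistic computed on background peak sets matched on mean accessibility
(and GC content when available).  This is the standard bias-corrected
deviation score used for transcription-factor activity inference from
scATAC data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellFeatureMatrix, MotifPeakMap

DEFAULT_N_BINS = 50
DEFAULT_N_BACKGROUND = 50


@dataclass
class MotifDeviationMatrix:
    """Motifs x cells raw deviations and background-corrected z-scores."""

    motif_ids: list[str]
    cell_ids: list[str]
    raw: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.motif_ids), len(self.cell_ids))
        if self.raw.shape != shape or self.z.shape != shape:
            raise ValueError("deviation matrices do not match id lists")
        if not np.isfinite(self.z).all():
            raise ValueError("non-finite z-scores")

    def z_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.motif_ids, columns=self.cell_ids)

    def raw_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.raw, index=self.motif_ids, columns=self.cell_ids)


def _equal_width_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin index per value; degenerate ranges collapse to one bin."""
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.zeros(len(values), dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(values, edges[1:-1], right=False), 0, n_bins - 1)
    return idx


def match_background_peaks(
    atac_counts: CellFeatureMatrix,
    motif_map: MotifPeakMap | None = None,
    n_bins: int = DEFAULT_N_BINS,
    n_background: int = DEFAULT_N_BACKGROUND,
    seed: int = 0,
) -> np.ndarray:
    """Sample accessibility-matched background peaks for every peak.

    Peaks are binned by log mean accessibility (equal-width bins; a GC
    dimension is added when ``motif_map.gc`` is provided) and each peak
    draws ``n_background`` backgrounds uniformly with replacement from its
    own bin.  Returns an ``(n_peaks, n_background)`` index array,
    deterministic under ``seed``.
    """
    n_peaks = atac_counts.n_features
    if n_peaks < 1:
        raise ValueError("no peaks")
    mean_acc = np.log1p(np.asarray(atac_counts.values.mean(axis=1)).ravel())
    bin_idx = _equal_width_bins(mean_acc, n_bins)
    if motif_map is not None and motif_map.gc is not None:
        gc_bins = _equal_width_bins(motif_map.gc, max(2, int(np.sqrt(n_bins))))
        bin_idx = bin_idx * (gc_bins.max() + 1) + gc_bins
    rng = np.random.default_rng(seed)
    out = np.empty((n_peaks, n_background), dtype=np.int64)
    for b in np.unique(bin_idx):
        members = np.flatnonzero(bin_idx == b)
        draws = rng.choice(members, size=(len(members), n_background), replace=True)
        out[members] = draws
    return out


def motif_deviations(
    atac_counts: CellFeatureMatrix,
    motif_map: MotifPeakMap,
    backgrounds: np.ndarray,
) -> MotifDeviationMatrix:
    """Bias-corrected motif deviation z-scores per cell.

    With expected fraction ``e_p = peak_total_p / grand_total`` the expected
    motif count for cell c is ``cell_total_c * sum_{p in motif} e_p``; the
    raw deviation is ``(observed - expected) / expected`` and the z-score
    standardizes it against the deviations of the matched background sets.
    Motifs whose expected count is zero are dropped with a warning.
    """
    if list(motif_map.peak_ids) != list(atac_counts.feature_ids):
        raise ValueError("motif map peaks must match the ATAC matrix features in order")
    X = sp.csr_matrix(atac_counts.values, dtype=float)
    peak_tot = np.asarray(X.sum(axis=1)).ravel()
    cell_tot = np.asarray(X.sum(axis=0)).ravel()
    grand = peak_tot.sum()
    if grand <= 0:
        raise ValueError("ATAC matrix is empty")
    e = peak_tot / grand

    M = sp.csr_matrix(motif_map.membership, dtype=float)
    motif_e = np.asarray(M @ e).ravel()
    keep = motif_e > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} motifs with zero expected count", stacklevel=2
        )
        M = M[keep]
        motif_e = motif_e[keep]
    motif_ids = [m for m, k in zip(motif_map.motif_ids, keep) if k]
    if M.shape[0] == 0:
        raise ValueError("no motif has a positive expected count")

    raw = _raw_deviation(M, X, e, cell_tot)
    n_background = backgrounds.shape[1]
    bg_sum = np.zeros_like(raw)
    bg_sumsq = np.zeros_like(raw)
    coo = sp.coo_matrix(M)
    for i in range(n_background):
        # remap every member peak to its i-th matched background
        cols = backgrounds[coo.col, i]
        Mi = sp.coo_matrix(
            (coo.data, (coo.row, cols)), shape=M.shape
        ).tocsr()  # duplicate hits accumulate, keeping set sizes matched
        dev_i = _raw_deviation(Mi, X, e, cell_tot)
        bg_sum += dev_i
        bg_sumsq += dev_i**2
    mean_bg = bg_sum / n_background
    var_bg = (bg_sumsq - n_background * mean_bg**2) / max(n_background - 1, 1)
    sd_bg = np.sqrt(np.maximum(var_bg, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_bg > 0, (raw - mean_bg) / sd_bg, 0.0)
    return MotifDeviationMatrix(motif_ids, list(atac_counts.cell_ids), raw, z)


def _raw_deviation(
    M: sp.spmatrix, X: sp.spmatrix, e: np.ndarray, cell_tot: np.ndarray
) -> np.ndarray:
    observed = np.asarray((M @ X).todense())
    expected = np.outer(np.asarray(M @ e).ravel(), cell_tot)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.where(expected > 0, (observed - expected) / expected, 0.0)
    return dev
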