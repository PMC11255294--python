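"""Per-cell signature scoring, rank-based cell classification, and
fragment-overlap aggregation at region sets, gene bodies, and TSS windows.

All overlap tests are half-open: a fragment ``[s, e)`` overlaps a region
``[a, b)`` iff ``max(s, a) < min(e, b)``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from .io import (
    CellFeatureMatrix,
    FragmentRecord,
    GenomicInterval,
    SignatureSet,
    merge_intervals,
)
from .normalize import NormalizedMatrix, tfidf_atac

logger = logging.getLogger(__name__)

UNDETERMINED = "Undetermined"
RANK_TIE_TOL = 1e-12


# ---------------------------------------------------------------------------
# expression-based scoring
# ---------------------------------------------------------------------------


def mean_expression_score(
    norm_rna: NormalizedMatrix, signature: SignatureSet
) -> tuple[pd.Series, float]:
    """Average normalized expression of a gene signature, per cell.

    Signature genes missing from the matrix are dropped (the returned
    fraction reports coverage); averaging is over present genes only.
    """
    if signature.kind != "gene":
        raise ValueError("mean_expression_score requires a gene signature")
    feature_set = set(norm_rna.feature_ids)
    present = [g for g in signature.members if g in feature_set]
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} is in the matrix")
    frac = len(present) / len(signature.members)
    if frac < 1.0:
        logger.info(
            "signature %s: %d/%d genes present", signature.name, len(present), len(signature)
        )
    idx = norm_rna.feature_ids
    rows = [idx.index(g) for g in present]
    dense = norm_rna.to_dense()
    scores = dense[rows].mean(axis=0)
    return pd.Series(scores, index=norm_rna.cell_ids, name=signature.name), frac


def rank_classifier(
    norm_rna: NormalizedMatrix, signatures: Sequence[SignatureSet]
) -> pd.DataFrame:
    """Classify each cell by the signature with the highest mean expression rank.

    Within each cell, all genes are ranked by normalized expression
    (ascending midranks, so the most expressed gene has the highest rank);
    each signature scores the mean rank of its present genes, and the cell
    takes the label of the top-scoring signature.  An exact tie of the
    maxima yields the label ``Undetermined``.
    """
    if len(signatures) < 2:
        raise ValueError("need >= 2 signatures to classify")
    feature_set = set(norm_rna.feature_ids)
    idx = {g: i for i, g in enumerate(norm_rna.feature_ids)}
    sig_rows = {}
    for s in signatures:
        if s.kind != "gene":
            raise ValueError("rank_classifier requires gene signatures")
        rows = [idx[g] for g in s.members if g in feature_set]
        if not rows:
            raise ValueError(f"signature {s.name!r} has no genes in the matrix")
        sig_rows[s.name] = np.array(rows)
    dense = norm_rna.to_dense()
    ranks = sps.rankdata(dense, axis=0)  # per cell across all genes
    table = pd.DataFrame(
        {name: ranks[rows].mean(axis=0) for name, rows in sig_rows.items()},
        index=norm_rna.cell_ids,
    )
    scores = table.to_numpy()
    order = np.sort(scores, axis=1)
    top_tie = (order[:, -1] - order[:, -2]) <= RANK_TIE_TOL
    labels = table.columns.to_numpy()[np.argmax(scores, axis=1)].astype(object)
    labels[top_tie] = UNDETERMINED
    table["label"] = labels
    return table


# ---------------------------------------------------------------------------
# fragment-overlap counting
# ---------------------------------------------------------------------------


def _fragment_arrays(fragments: Sequence[FragmentRecord]):
    chrom = np.array([f.chrom for f in fragments])
    start = np.array([f.start for f in fragments], dtype=np.int64)
    end = np.array([f.end for f in fragments], dtype=np.int64)
    barcode = np.array([f.barcode for f in fragments])
    count = np.array([f.count for f in fragments], dtype=np.int64)
    return chrom, start, end, barcode, count


def region_set_fragment_counts(
    fragments: Sequence[FragmentRecord],
    regions: Sequence[GenomicInterval],
    cell_ids: Sequence[str],
) -> CellFeatureMatrix:
    """Count fragment overlaps per (region, cell); regions are merged first.

    Overlapping regions in the input are merged into disjoint intervals; a
    fragment spanning several merged regions counts once in each.  Fragments
    from barcodes outside ``cell_ids`` are ignored.
    """
    merged = merge_intervals(regions) if regions else []
    if not merged:
        raise ValueError("empty region set")
    cell_ids = [str(c) for c in cell_ids]
    cell_idx = {c: i for i, c in enumerate(cell_ids)}
    region_ids = [r.key() for r in merged]

    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, r in enumerate(merged):
        by_chrom.setdefault(r.chrom, []).append((i, r))

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    if fragments:
        f_chrom, f_start, f_end, f_barcode, f_count = _fragment_arrays(fragments)
        f_cell = np.array([cell_idx.get(b, -1) for b in f_barcode])
        usable = f_cell >= 0
        for chrom, items in by_chrom.items():
            sel = usable & (f_chrom == chrom)
            if not sel.any():
                continue
            ridx = np.array([i for i, _ in items])
            rstart = np.array([r.start for _, r in items])
            rend = np.array([r.end for _, r in items])
            order = np.argsort(rstart)
            ridx, rstart, rend = ridx[order], rstart[order], rend[order]
            # disjoint sorted regions: overlaps of [s,e) are the index range
            # [searchsorted(rend, s, right), searchsorted(rstart, e, left))
            lo = np.searchsorted(rend, f_start[sel], side="right")
            hi = np.searchsorted(rstart, f_end[sel], side="left")
            span = hi - lo
            has = span > 0
            if not has.any():
                continue
            frag_ids = np.flatnonzero(sel)[has]
            lo, span = lo[has], span[has]
            rep_frag = np.repeat(frag_ids, span)
            offsets = np.concatenate([np.arange(s) for s in span])
            rep_region = ridx[np.repeat(lo, span) + offsets]
            rows.append(rep_region)
            cols.append(f_cell[rep_frag])
            vals.append(f_count[rep_frag])
    if rows:
        mat = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(merged), len(cell_ids)),
            dtype=np.int64,
        ).tocsr()
    else:
        mat = sp.csr_matrix((len(merged), len(cell_ids)), dtype=np.int64)
    return CellFeatureMatrix(mat, region_ids, cell_ids, "atac_peak")


def per_cell_region_score(
    region_counts: CellFeatureMatrix, normalize: str = "tfidf"
) -> pd.Series:
    """Normalize a regions x cells count matrix and average over regions per cell."""
    if region_counts.n_features < 1 or region_counts.n_cells < 1:
        raise ValueError("need >= 1 region and >= 1 cell")
    if normalize == "tfidf":
        norm = tfidf_atac(region_counts)
        dense = norm.to_dense()
    elif normalize == "none":
        dense = region_counts.to_dense().astype(float)
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return pd.Series(dense.mean(axis=0), index=region_counts.cell_ids, name="score")


def aggregate_gene_accessibility(
    fragments: Sequence[FragmentRecord],
    gene_regions: Sequence[GenomicInterval],
    cell_ids: Sequence[str],
    normalize: str = "tfidf",
) -> pd.Series:
    """Per-cell average accessibility over a set of gene-linked regions."""
    if not gene_regions:
        raise ValueError("empty gene region set")
    counts = region_set_fragment_counts(fragments, gene_regions, cell_ids)
    return per_cell_region_score(counts, normalize=normalize)


# ---------------------------------------------------------------------------
# strand-aware gene windows
# ---------------------------------------------------------------------------


def gene_window(gene: GenomicInterval, flank: int = 2000) -> GenomicInterval:
    """Gene body plus an upstream flank in gene orientation, clipped at 0."""
    if gene.strand == "+":
        start, end = max(0, gene.start - flank), gene.end
    elif gene.strand == "-":
        start, end = gene.start, gene.end + flank
    else:
        raise ValueError(f"gene {gene.key()!r} has no strand")
    return GenomicInterval(gene.chrom, start, end, gene.strand, gene.key())


def tss_window(
    gene: GenomicInterval, upstream: int = 300, downstream: int = 500
) -> GenomicInterval:
    """Window around the TSS in gene orientation (TSS = start for +, end for -)."""
    if gene.strand == "+":
        tss = gene.start
        start, end = tss - upstream, tss + downstream
    elif gene.strand == "-":
        tss = gene.end
        start, end = tss - downstream, tss + upstream
    else:
        raise ValueError(f"gene {gene.key()!r} has no strand")
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand, gene.key())


def _window_overlap_matrix(
    fragments: Sequence[FragmentRecord],
    windows: Sequence[GenomicInterval],
    col_of_barcode: dict[str, int],
    n_cols: int,
) -> sp.csr_matrix:
    """Windows x columns fragment-count overlaps; windows may overlap each other."""
    mat = sp.lil_matrix((len(windows), n_cols), dtype=np.int64)
    if fragments:
        f_chrom, f_start, f_end, f_barcode, f_count = _fragment_arrays(fragments)
        f_col = np.array([col_of_barcode.get(b, -1) for b in f_barcode])
        chrom_masks = {c: (f_chrom == c) & (f_col >= 0) for c in set(f_chrom)}
        for wi, w in enumerate(windows):
            sel = chrom_masks.get(w.chrom)
            if sel is None:
                continue
            hit = sel & (f_start < w.end) & (f_end > w.start)
            if not hit.any():
                continue
            cols = f_col[hit]
            cnts = f_count[hit]
            agg = np.bincount(cols, weights=cnts, minlength=n_cols)
            nz = np.flatnonzero(agg)
            mat[wi, nz] = agg[nz]
    return mat.tocsr()


def gene_activity_matrix(
    fragments: Sequence[FragmentRecord],
    gene_models: Sequence[GenomicInterval],
    cell_ids: Sequence[str] | None = None,
    flank: int = 2000,
    per: str = "cell",
    sample_of_barcode: dict[str, str] | None = None,
) -> CellFeatureMatrix:
    """Fragment counts over gene bodies plus an upstream flank.

    With ``per='cell'`` columns are nuclei (``cell_ids`` required); with
    ``per='sample'`` fragments are pooled by ``sample_of_barcode`` and
    columns are samples.
    """
    if not gene_models:
        raise ValueError("empty gene model set")
    windows = [gene_window(g, flank) for g in gene_models]
    if per == "cell":
        if cell_ids is None:
            raise ValueError("per='cell' requires cell_ids")
        cols = [str(c) for c in cell_ids]
        col_of = {c: i for i, c in enumerate(cols)}
    elif per == "sample":
        if sample_of_barcode is None:
            raise ValueError("per='sample' requires sample_of_barcode")
        cols = sorted(set(sample_of_barcode.values()))
        si = {s: i for i, s in enumerate(cols)}
        col_of = {b: si[s] for b, s in sample_of_barcode.items()}
    else:
        raise ValueError("per must be 'cell' or 'sample'")
    mat = _window_overlap_matrix(fragments, windows, col_of, len(cols))
    return CellFeatureMatrix(mat, [w.id for w in windows], cols, "gene_activity")


def tss_window_signal(
    fragments: Sequence[FragmentRecord],
    gene_models: Sequence[GenomicInterval],
    upstream: int = 300,
    downstream: int = 500,
) -> pd.Series:
    """Summed fragment counts in a strand-aware window around each gene's TSS."""
    if not gene_models:
        raise ValueError("empty gene model set")
    windows = [tss_window(g, upstream, downstream) for g in gene_models]
    col_of = {f.barcode: 0 for f in fragments}
    mat = _window_overlap_matrix(fragments, windows, col_of, 1)
    return pd.Series(
        np.asarray(mat.sum(axis=1)).ravel(), index=[w.id for w in windows], name="tss_signal"
    )


# ---------------------------------------------------------------------------
# lineage-specific sets by hierarchical clustering
# ---------------------------------------------------------------------------


def lineage_specific_sets(
    group_signal: pd.DataFrame, k_clusters: int
) -> dict[str, SignatureSet]:
    """Partition differential features into lineage-specific signatures.

    ``group_signal`` is features x groups (e.g. mean promoter signal per
    lineage, already restricted to significant features).  Rows are
    z-scored, clustered by average-linkage Euclidean hierarchical clustering
    cut at ``k_clusters``, and each cluster is assigned to the group where
    its mean z-scored signal peaks.
    """
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    if k_clusters > group_signal.shape[0]:
        raise ValueError("k_clusters exceeds the number of features")
    x = group_signal.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = list(group_signal.index[sd == 0][:5])
        raise ValueError(f"features with zero variance across groups: {bad}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    link = linkage(z, method="average", metric="euclidean")
    clusters = fcluster(link, t=k_clusters, criterion="maxclust")
    out: dict[str, SignatureSet] = {}
    assignments: dict[str, list[str]] = {}
    for c in np.unique(clusters):
        members = group_signal.index[clusters == c]
        centroid = z[clusters == c].mean(axis=0)
        group = group_signal.columns[int(np.argmax(centroid))]
        assignments.setdefault(str(group), []).extend(str(m) for m in members)
    for group, members in assignments.items():
        out[group] = SignatureSet(group, members, kind="gene")
    return out
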