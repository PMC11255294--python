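"""Readers, writers, and core containers for the formats the pipeline consumes.

All genomic coordinates in this package are 0-based, half-open (BED
convention): an interval ``[start, end)`` contains ``end - start`` bases, and
a fragment ``[100, 200)`` does not overlap a region ``[200, 300)``.  Matrix
Market files are 1-based on disk (the format standard) and converted to
0-based indices in memory.  Gzip compression is autodetected from the
``.gz`` extension.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

MODALITIES = ("rna", "atac_peak", "gene_activity", "motif_score")
STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CellFeatureMatrix:
    """Sparse features x cells matrix with identifiers attached.

    ``values`` holds nonnegative counts (integer dtype) or normalized signal
    (float dtype).  Feature and cell identifiers must be unique and match the
    matrix dimensions.
    """

    values: sp.csr_matrix
    feature_ids: list[str]
    cell_ids: list[str]
    modality: str = "rna"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        nf, nc = self.values.shape
        if nf != len(self.feature_ids):
            raise FormatError(
                f"matrix has {nf} rows but {len(self.feature_ids)} feature ids"
            )
        if nc != len(self.cell_ids):
            raise FormatError(
                f"matrix has {nc} columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative entries in count matrix")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def feature_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def cell_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cell_ids)}

    def subset_cells(self, cell_ids: Sequence[str]) -> "CellFeatureMatrix":
        idx = self.cell_index()
        cols = [idx[c] for c in cell_ids]
        return CellFeatureMatrix(
            self.values[:, cols], list(self.feature_ids), list(cell_ids), self.modality
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "CellFeatureMatrix":
        idx = self.feature_index()
        rows = [idx[f] for f in feature_ids]
        return CellFeatureMatrix(
            self.values[rows, :], list(feature_ids), list(self.cell_ids), self.modality
        )

    def to_dense(self) -> np.ndarray:
        return self.values.toarray()


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def key(self) -> str:
        return self.id or f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and max(self.start, other.start) < min(self.end, other.end)
        )


@dataclass(frozen=True)
class FragmentRecord:
    """A sequenced ATAC fragment assigned to a nucleus barcode."""

    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"fragment {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.count < 1:
            raise FormatError(f"fragment count {self.count} < 1")


@dataclass
class SignatureSet:
    """Named cell-type signature: a list of gene ids or genomic regions."""

    name: str
    members: list
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "region"):
            raise ValueError(f"signature kind must be 'gene' or 'region', got {self.kind!r}")
        if not self.members:
            raise FormatError(f"signature {self.name!r} is empty")
        keys = [m.key() if isinstance(m, GenomicInterval) else m for m in self.members]
        if len(set(keys)) != len(keys):
            raise FormatError(f"signature {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class MotifPeakMap:
    """Binary motifs x peaks membership, optionally with per-peak GC fraction."""

    motif_ids: list[str]
    peak_ids: list[str]
    membership: sp.csr_matrix
    gc: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.membership = sp.csr_matrix(self.membership)
        self.membership.data = (self.membership.data != 0).astype(np.int8)
        nm, npk = self.membership.shape
        if nm != len(self.motif_ids) or npk != len(self.peak_ids):
            raise FormatError("membership shape does not match id lists")
        sizes = np.asarray(self.membership.sum(axis=1)).ravel()
        if (sizes == 0).any():
            empty = [m for m, s in zip(self.motif_ids, sizes) if s == 0]
            raise FormatError(f"motifs with no member peaks: {empty[:5]}")
        if self.gc is not None:
            self.gc = np.asarray(self.gc, dtype=float)
            if self.gc.shape != (npk,):
                raise FormatError("gc vector length does not match peak count")
            if ((self.gc < 0) | (self.gc > 1)).any():
                raise FormatError("gc fractions must lie in [0, 1]")

    def motif_peaks(self, motif_id: str) -> list[str]:
        row = self.motif_ids.index(motif_id)
        cols = self.membership[row].indices
        return [self.peak_ids[c] for c in cols]


# ---------------------------------------------------------------------------
# file helpers
# ---------------------------------------------------------------------------


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# count matrices (Matrix Market + id lists)
# ---------------------------------------------------------------------------


def read_count_matrix(
    mtx_path: Union[str, Path],
    features_path: Union[str, Path],
    barcodes_path: Union[str, Path],
    modality: str = "rna",
) -> CellFeatureMatrix:
    """Read a sparse features x cells matrix with one-column id files.

    The MTX header dimensions must match the number of lines in the feature
    and barcode files; duplicate ids and negative entries are rejected.
    """
    mat = sp.csr_matrix(mmread(str(mtx_path)))
    features = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"MTX declares shape {mat.shape} but id files have "
            f"{len(features)} features / {len(barcodes)} barcodes"
        )
    return CellFeatureMatrix(mat, features, barcodes, modality)


def write_count_matrix(
    matrix: CellFeatureMatrix,
    mtx_path: Union[str, Path],
    features_path: Union[str, Path],
    barcodes_path: Union[str, Path],
) -> None:
    field = "integer" if np.issubdtype(matrix.values.dtype, np.integer) else "real"
    mmwrite(str(mtx_path), sp.coo_matrix(matrix.values), field=field)
    Path(features_path).write_text("".join(f"{f}\n" for f in matrix.feature_ids))
    Path(barcodes_path).write_text("".join(f"{c}\n" for c in matrix.cell_ids))


def _read_id_column(path: Union[str, Path]) -> list[str]:
    with _open_text(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


# ---------------------------------------------------------------------------
# BED regions
# ---------------------------------------------------------------------------


def read_regions_bed(path: Union[str, Path]) -> list[GenomicInterval]:
    """Parse BED3/BED6: columns chrom, start, end[, id, score, strand]."""
    regions: list[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = parts[3] if len(parts) >= 4 else ""
            strand = parts[5] if len(parts) >= 6 else "."
            try:
                regions.append(GenomicInterval(parts[0], start, end, strand, name))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions_bed(regions: Iterable[GenomicInterval], path: Union[str, Path]) -> None:
    with _open_text(path, "wt") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.key()}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------


def read_fragments(path: Union[str, Path]) -> list[FragmentRecord]:
    """Parse a 5-column fragments TSV (chrom, start, end, barcode, count)."""
    records: list[FragmentRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            try:
                rec = FragmentRecord(
                    parts[0], int(parts[1]), int(parts[2]), parts[3], int(parts[4])
                )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_fragments(records: Iterable[FragmentRecord], path: Union[str, Path]) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.barcode}\t{r.count}\n")


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------


def read_signatures(path: Union[str, Path]) -> list[SignatureSet]:
    """Read gene signatures from JSON: {"name": ["GeneA", "GeneB", ...], ...}."""
    with _open_text(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise FormatError("signature JSON must map names to member lists")
    sets = []
    for name, members in data.items():
        if not isinstance(members, list):
            raise FormatError(f"signature {name!r}: members must be a list")
        sets.append(SignatureSet(name, [str(m) for m in members], kind="gene"))
    return sets


def write_signatures(signatures: Iterable[SignatureSet], path: Union[str, Path]) -> None:
    data = {}
    for s in signatures:
        if s.kind != "gene":
            raise ValueError("JSON signature files hold gene sets; write regions as BED")
        data[s.name] = list(s.members)
    with _open_text(path, "wt") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


def read_region_signature(name: str, bed_path: Union[str, Path]) -> SignatureSet:
    """Load one region signature from a BED file."""
    return SignatureSet(name, read_regions_bed(bed_path), kind="region")


# ---------------------------------------------------------------------------
# motif-peak maps
# ---------------------------------------------------------------------------


def read_motif_map(path: Union[str, Path], peak_ids: Sequence[str]) -> MotifPeakMap:
    """Read a 2-column TSV (motif_id, peak_id) into a binary membership matrix.

    ``peak_ids`` fixes column order and is validated against the file: every
    referenced peak must exist in the ATAC matrix.
    """
    peak_idx = {p: i for i, p in enumerate(peak_ids)}
    motif_order: list[str] = []
    rows: list[int] = []
    cols: list[int] = []
    with _open_text(path) as fh:
        seen: dict[str, int] = {}
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected motif_id<TAB>peak_id")
            motif, peak = parts[0], parts[1]
            if peak not in peak_idx:
                raise FormatError(f"{path}:{lineno}: unknown peak {peak!r}")
            if motif not in seen:
                seen[motif] = len(motif_order)
                motif_order.append(motif)
            rows.append(seen[motif])
            cols.append(peak_idx[peak])
    if not motif_order:
        raise FormatError(f"{path}: no motif-peak pairs")
    mem = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(motif_order), len(peak_ids)),
    )
    mem.sum_duplicates()
    return MotifPeakMap(motif_order, list(peak_ids), mem.tocsr())


def write_motif_map(motif_map: MotifPeakMap, path: Union[str, Path]) -> None:
    with _open_text(path, "wt") as fh:
        coo = sp.coo_matrix(motif_map.membership)
        order = np.lexsort((coo.col, coo.row))
        for r, c in zip(coo.row[order], coo.col[order]):
            fh.write(f"{motif_map.motif_ids[r]}\t{motif_map.peak_ids[c]}\n")


def merge_intervals(regions: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping intervals (half-open: abutting intervals stay separate)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        rs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end, cur_ids = rs[0].start, rs[0].end, [rs[0].key()]
        for r in rs[1:]:
            if r.start < cur_end:  # strict: [a,b) and [b,c) do not merge
                cur_end = max(cur_end, r.end)
                cur_ids.append(r.key())
            else:
                merged.append(_merged_interval(chrom, cur_start, cur_end, cur_ids))
                cur_start, cur_end, cur_ids = r.start, r.end, [r.key()]
        merged.append(_merged_interval(chrom, cur_start, cur_end, cur_ids))
    return merged


def _merged_interval(chrom: str, start: int, end: int, ids: list[str]) -> GenomicInterval:
    name = ids[0] if len(ids) == 1 else f"{chrom}:{start}-{end}"
    return GenomicInterval(chrom, start, end, ".", name)
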