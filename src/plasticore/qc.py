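"""Nucleus-level quality control and the PCR-duplicate cap.

QC bounds are strict on both sides: a nucleus is kept only if its totals lie
strictly inside the configured windows and its mitochondrial fraction is
strictly below the cap.  Boundary values are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .io import CellFeatureMatrix


@dataclass(frozen=True)
class QCThresholds:
    """Strict per-nucleus bounds on library size and mitochondrial content."""

    rna_min: float = 1000
    rna_max: float = 25000
    atac_min: float = 5000
    atac_max: float = 70000
    mito_max: float = 0.20

    def __post_init__(self) -> None:
        if not self.rna_min < self.rna_max:
            raise ValueError("rna_min must be < rna_max")
        if not self.atac_min < self.atac_max:
            raise ValueError("atac_min must be < atac_max")
        if not 0 < self.mito_max < 1:
            raise ValueError("mito_max must lie in (0, 1)")


def filter_nuclei(
    rna: CellFeatureMatrix,
    atac: CellFeatureMatrix,
    mito_gene_ids: Sequence[str],
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[list[str], pd.DataFrame]:
    """Apply joint RNA/ATAC/mitochondrial QC over the shared barcodes.

    Returns the kept barcodes (in RNA column order) and a per-cell QC table
    with totals, mitochondrial fraction, and the keep decision for every
    shared barcode.
    """
    shared = [c for c in rna.cell_ids if c in set(atac.cell_ids)]
    if not shared:
        raise ValueError("RNA and ATAC matrices share no cell barcodes")
    mito = [g for g in mito_gene_ids if g in set(rna.feature_ids)]
    if mito_gene_ids is not None and len(mito_gene_ids) > 0 and not mito:
        raise ValueError("none of the designated mitochondrial genes is present")
    if not mito:
        raise ValueError("mitochondrial filtering requires a non-empty mito gene set")

    rna_s = rna.subset_cells(shared)
    atac_s = atac.subset_cells(shared)
    rna_tot = rna_s.cell_totals()
    atac_tot = atac_s.cell_totals()
    mito_tot = rna_s.subset_features(mito).cell_totals()
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(rna_tot > 0, mito_tot / np.maximum(rna_tot, 1), 0.0)

    t = thresholds
    keep = (
        (rna_tot > t.rna_min)
        & (rna_tot < t.rna_max)
        & (atac_tot > t.atac_min)
        & (atac_tot < t.atac_max)
        & (mito_frac < t.mito_max)
    )
    table = pd.DataFrame(
        {
            "cell_id": shared,
            "rna_total": rna_tot,
            "atac_total": atac_tot,
            "mito_fraction": mito_frac,
            "kept": keep,
        }
    ).set_index("cell_id")
    kept_ids = [c for c, k in zip(shared, keep) if k]
    return kept_ids, table


def filter_min_umi(rna: CellFeatureMatrix, min_umi: int = 200) -> list[str]:
    """Keep cells with total UMI count >= ``min_umi`` (discard "less than")."""
    totals = rna.cell_totals()
    return [c for c, t in zip(rna.cell_ids, totals) if t >= min_umi]


def cap_duplicates(read_keys: Sequence[Hashable], max_copies: int = 5) -> list[int]:
    """Keep at most ``max_copies`` occurrences of each identical sequence key.

    Returns the retained indices in input order: the first ``max_copies``
    occurrences of each key survive, later copies are dropped.
    """
    seen: dict[Hashable, int] = {}
    kept: list[int] = []
    for i, key in enumerate(read_keys):
        n = seen.get(key, 0)
        if n < max_copies:
            kept.append(i)
        seen[key] = n + 1
    return kept


def fragment_duplicate_key(chrom: str, start: int, end: int, strand: str = ".") -> tuple:
    """Coordinate-level stand-in for sequence identity when deduplicating."""
    return (chrom, start, end, strand)
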