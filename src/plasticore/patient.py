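"""Patient-pool workflow: derive condition-specific region sets from bulk
differential accessibility, score pooled single nuclei per sample at those
sets (with size-matched random control sets), and compare conditions with a
categorical linear model.

Scores are comparable across samples because TF-IDF is computed on the
merged cross-sample regions x nuclei matrix, not per sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FragmentRecord, GenomicInterval
from .scoring import per_cell_region_score, region_set_fragment_counts, gene_activity_matrix
from .stats import ConditionModelResult, nb_wald_differential, ols_condition_test


@dataclass
class PatientSample:
    """A pooled single-nucleus ATAC sample with a condition label."""

    sample_id: str
    condition: str
    fragments: list[FragmentRecord]

    def barcodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.fragments:
            seen.setdefault(f.barcode, None)
        return list(seen)


def derive_condition_regions(
    bulk_diff: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    direction: str = "up",
    padj_max: float = 0.05,
) -> list[GenomicInterval]:
    """Regions significant in the bulk test with the requested fold-change sign."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    by_id = {r.key(): r for r in regions}
    sig = bulk_diff["padj"] < padj_max
    if direction == "up":
        sig &= bulk_diff["log2fc"] > 0
    else:
        sig &= bulk_diff["log2fc"] < 0
    ids = bulk_diff.loc[sig.fillna(False), "feature_id"]
    out = [by_id[i] for i in ids if i in by_id]
    if not out:
        raise ValueError("no region passes the differential filter")
    return out


def sample_control_regions(
    shared_regions: Sequence[GenomicInterval], n: int, seed: int = 0
) -> list[GenomicInterval]:
    """Uniform sample of ``n`` regions without replacement (seeded)."""
    if n > len(shared_regions):
        raise ValueError("n exceeds the region pool")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(shared_regions), size=n, replace=False)
    return [shared_regions[i] for i in np.sort(idx)]


def score_patient_samples(
    samples: Sequence[PatientSample],
    regions: Sequence[GenomicInterval],
    normalize: str = "tfidf",
) -> pd.DataFrame:
    """Per-nucleus mean normalized signal at a region set, across samples.

    Fragment counts are computed per sample at the merged region set, the
    per-sample matrices are concatenated, TF-IDF is applied to the merged
    matrix, and each nucleus's score is its mean over regions.  Nuclei with
    zero fragments in the region set are dropped with a warning.  Returns a
    DataFrame with columns nucleus, sample_id, condition, score.
    """
    if not regions:
        raise ValueError("empty region set")
    all_frags: list[FragmentRecord] = []
    meta: dict[str, tuple[str, str]] = {}
    barcode_order: list[str] = []
    for s in samples:
        for b in s.barcodes():
            key = b if b.startswith(f"{s.sample_id}#") else f"{s.sample_id}#{b}"
            meta[key] = (s.sample_id, s.condition)
        for f in s.fragments:
            key = (
                f.barcode
                if f.barcode.startswith(f"{s.sample_id}#")
                else f"{s.sample_id}#{f.barcode}"
            )
            if key not in meta:
                meta[key] = (s.sample_id, s.condition)
            all_frags.append(
                FragmentRecord(f.chrom, f.start, f.end, key, f.count)
            )
    barcode_order = list(meta)
    counts = region_set_fragment_counts(all_frags, regions, barcode_order)
    totals = counts.cell_totals()
    nonzero = totals > 0
    if not nonzero.all():
        warnings.warn(
            f"dropping {int((~nonzero).sum())} nuclei with no fragments in the region set",
            stacklevel=2,
        )
        counts = counts.subset_cells([b for b, k in zip(barcode_order, nonzero) if k])
    scores = per_cell_region_score(counts, normalize=normalize)
    out = pd.DataFrame(
        {
            "nucleus": scores.index,
            "sample_id": [meta[b][0] for b in scores.index],
            "condition": [meta[b][1] for b in scores.index],
            "score": scores.to_numpy(),
        }
    ).reset_index(drop=True)
    return out


@dataclass
class ConditionComparison:
    """Linear-model report plus per-sample display summaries."""

    model: ConditionModelResult
    condition_means: pd.Series
    sample_means: pd.Series
    top90: pd.DataFrame  # per-sample top-90% score subset


def compare_conditions(
    score_table: pd.DataFrame,
    grouping: Mapping[str, str] | None = None,
    reference: str | None = None,
) -> ConditionComparison:
    """Fit scores ~ condition by OLS and summarize per-sample distributions.

    ``grouping`` optionally collapses condition labels into coarser
    categories before fitting (e.g. six patient conditions into four).  The
    ``top90`` table keeps, per sample, the ceil(0.9 * n) highest scores —
    the subset the violin displays show.
    """
    table = score_table.copy()
    if grouping is not None:
        table["condition"] = table["condition"].map(lambda c: grouping.get(c, c))
    model = ols_condition_test(table["score"], table["condition"], reference=reference)
    cond_means = table.groupby("condition")["score"].mean()
    samp_means = table.groupby("sample_id")["score"].mean()
    tops = []
    for sid, grp in table.groupby("sample_id"):
        k = math.ceil(0.9 * len(grp))
        tops.append(grp.nlargest(k, "score"))
    top90 = pd.concat(tops).reset_index(drop=True)
    return ConditionComparison(model, cond_means, samp_means, top90)


def gene_score_differential(
    samples: Sequence[PatientSample],
    gene_models: Sequence[GenomicInterval],
    flank: int = 2000,
) -> pd.DataFrame:
    """Differential per-gene accessibility between two sample conditions.

    Aggregates fragment counts over gene bodies plus the upstream flank per
    sample, then applies the NB Wald test with samples as replicates of
    their condition.
    """
    sample_of_barcode: dict[str, str] = {}
    all_frags: list[FragmentRecord] = []
    condition_of_sample: dict[str, str] = {}
    for s in samples:
        condition_of_sample[s.sample_id] = s.condition
        for f in s.fragments:
            key = (
                f.barcode
                if f.barcode.startswith(f"{s.sample_id}#")
                else f"{s.sample_id}#{f.barcode}"
            )
            sample_of_barcode[key] = s.sample_id
            all_frags.append(FragmentRecord(f.chrom, f.start, f.end, key, f.count))
    mat = gene_activity_matrix(
        all_frags, gene_models, flank=flank, per="sample", sample_of_barcode=sample_of_barcode
    )
    counts = pd.DataFrame(mat.to_dense(), index=mat.feature_ids, columns=mat.cell_ids)
    labels = [condition_of_sample[s] for s in counts.columns]
    return nb_wald_differential(counts, labels)
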