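"""Candidate-regulator ranking: combine differential expression of a
transcription factor's gene with differential accessibility of its motif.

A TF passes the filter when its gene is significantly upregulated in the
target cell group (adjusted p < 0.05, log2 fold change > 0) AND its motif's
deviation scores are significantly elevated there (adjusted p < 0.05,
positive mean shift).  Passing TFs are ranked by the average of the two
rank-sum AUCs.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

PADJ_MAX = 0.05


def candidate_regulators(
    rna_diff: pd.DataFrame,
    motif_diff: pd.DataFrame,
    tf_motif_map: Iterable[tuple[str, str]],
    padj_max: float = PADJ_MAX,
) -> pd.DataFrame:
    """Join RNA and motif differential tables over TF-to-motif pairs.

    ``rna_diff`` needs columns feature_id, auc, padj, avg_log2fc;
    ``motif_diff`` needs feature_id, auc, padj, delta (mean deviation
    shift).  One gene mapping to several motifs keeps its best-combined
    pair.  Output is sorted with passing TFs first, then descending
    combined AUC, ties broken by rna_auc then gene id.
    """
    pairs = list(tf_motif_map)
    if not pairs:
        raise ValueError("empty TF-to-motif map")
    rna = rna_diff.set_index("feature_id")
    motif = motif_diff.set_index("feature_id")
    rows = []
    for gene, motif_id in pairs:
        if gene not in rna.index or motif_id not in motif.index:
            continue
        r = rna.loc[gene]
        m = motif.loc[motif_id]
        passed = (
            (r["padj"] < padj_max)
            and (r["avg_log2fc"] > 0)
            and (m["padj"] < padj_max)
            and (m["delta"] > 0)
        )
        rows.append(
            {
                "tf_gene_id": gene,
                "motif_id": motif_id,
                "rna_auc": float(r["auc"]),
                "motif_auc": float(m["auc"]),
                "rna_padj": float(r["padj"]),
                "motif_padj": float(m["padj"]),
                "rna_log2fc": float(r["avg_log2fc"]),
                "motif_delta": float(m["delta"]),
                "combined": (float(r["auc"]) + float(m["auc"])) / 2.0,
                "passed_filter": bool(passed),
            }
        )
    if not rows:
        raise ValueError("no TF-to-motif pair matched both differential tables")
    out = pd.DataFrame(rows)
    # one gene, many motifs: keep the best combined score
    out = (
        out.sort_values(
            ["passed_filter", "combined", "rna_auc", "tf_gene_id"],
            ascending=[False, False, False, True],
        )
        .drop_duplicates("tf_gene_id", keep="first")
        .reset_index(drop=True)
    )
    out["rank"] = np.nan
    passed = out["passed_filter"]
    out.loc[passed, "rank"] = np.arange(1, int(passed.sum()) + 1)
    return out
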