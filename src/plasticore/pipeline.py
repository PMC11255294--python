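"""Config-driven end-to-end runs on simulated multiome data.

The pipeline sequences simulate -> QC -> normalize -> differential testing
-> motif deviations -> regulator ranking, writes every intermediate in the
package's text formats, and records a machine-readable manifest with seeds,
parameters, and per-stage shapes.  No stage mutates its inputs; all
randomness flows from the config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import (
    write_count_matrix,
    write_fragments,
    write_motif_map,
    write_regions_bed,
    write_signatures,
)
from .motifs import match_background_peaks, motif_deviations
from .normalize import lognorm_rna, tfidf_atac
from .qc import QCThresholds, filter_nuclei
from .regulators import candidate_regulators
from .simulate import SimConfig, generate_multiome
from .stats import differential_deviations, differential_features

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a run configuration is invalid."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("run config must be a YAML mapping")
    return cfg


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the simulated multiome workflow and return the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}, "config": config}

    sim_cfg = SimConfig(**_tupleize(config.get("simulate", {})))
    manifest["config"]["simulate"] = asdict(sim_cfg)

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        t0 = stage("simulate")
        rna, atac, fragments, signatures, motif_map, truth = generate_multiome(sim_cfg)
        write_count_matrix(rna, outdir / "rna.mtx", outdir / "genes.tsv", outdir / "barcodes.tsv")
        write_count_matrix(
            atac, outdir / "atac.mtx", outdir / "peaks.tsv", outdir / "barcodes_atac.tsv"
        )
        write_fragments(fragments, outdir / "fragments.tsv")
        write_signatures(signatures["genes"], outdir / "signatures.json")
        for sig in signatures["regions"]:
            write_regions_bed(sig.members, outdir / f"signature_{sig.name}.bed")
        write_motif_map(motif_map, outdir / "motif_map.tsv")
        truth.labels.to_csv(outdir / "true_labels.tsv", sep="\t")
        manifest["stages"]["simulate"] = {
            "rna_shape": [rna.n_features, rna.n_cells],
            "atac_shape": [atac.n_features, atac.n_cells],
            "n_fragments": len(fragments),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        t0 = stage("qc")
        qc_cfg = config.get("qc", {})
        thresholds = QCThresholds(**qc_cfg.get("thresholds", {}))
        kept, qc_table = filter_nuclei(rna, atac, truth.mito_genes, thresholds)
        qc_table.to_csv(outdir / "qc.tsv", sep="\t")
        if not kept:
            raise RuntimeError("no nucleus passed QC")
        rna_q, atac_q = rna.subset_cells(kept), atac.subset_cells(kept)
        manifest["stages"]["qc"] = {
            "n_input": int(qc_table.shape[0]),
            "n_kept": len(kept),
            "thresholds": asdict(thresholds),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        t0 = stage("normalize")
        norm_rna = lognorm_rna(rna_q)
        norm_atac = tfidf_atac(atac_q)
        manifest["stages"]["normalize"] = {
            "rna_method": norm_rna.method,
            "atac_method": norm_atac.method,
            "seconds": round(time.perf_counter() - t0, 3),
        }

        t0 = stage("diff")
        labels = truth.labels.loc[kept]
        target = config.get("diff", {}).get("target_group", sim_cfg.cell_types[0])
        rna_diff = differential_features(norm_rna, labels, target)
        rna_diff.to_csv(outdir / "rna_diff.tsv", sep="\t", index=False)
        manifest["stages"]["diff"] = {
            "target_group": target,
            "n_features": int(rna_diff.shape[0]),
            "n_significant": int(((rna_diff["padj"] < 0.05) & (rna_diff["avg_log2fc"] > 0)).sum()),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        t0 = stage("motifs")
        motif_cfg = config.get("motifs", {})
        backgrounds = match_background_peaks(
            atac_q,
            motif_map,
            n_bins=motif_cfg.get("n_bins", 50),
            n_background=motif_cfg.get("n_background", 50),
            seed=motif_cfg.get("seed", sim_cfg.seed + 1),
        )
        devs = motif_deviations(atac_q, motif_map, backgrounds)
        devs.z_frame().to_csv(outdir / "motif_z.tsv", sep="\t")
        manifest["stages"]["motifs"] = {
            "n_motifs": len(devs.motif_ids),
            "n_background": int(backgrounds.shape[1]),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        t0 = stage("regulators")
        motif_diff = differential_deviations(devs.z_frame(), labels, target)
        motif_diff.to_csv(outdir / "motif_diff.tsv", sep="\t", index=False)
        tf_map = default_tf_motif_map(truth, devs.motif_ids, list(rna_diff["feature_id"]))
        ranked = candidate_regulators(rna_diff, motif_diff, tf_map)
        ranked.to_csv(outdir / "regulators.tsv", sep="\t", index=False)
        manifest["stages"]["regulators"] = {
            "n_ranked": int(ranked.shape[0]),
            "n_passed": int(ranked["passed_filter"].sum()),
            "top": ranked.iloc[0]["tf_gene_id"] if len(ranked) else None,
            "seconds": round(time.perf_counter() - t0, 3),
        }
    except Exception as exc:  # annotate which stage failed
        done = set(manifest["stages"])
        order = ["simulate", "qc", "normalize", "diff", "motifs", "regulators"]
        current = next((s for s in order if s not in done), "unknown")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    return manifest


def default_tf_motif_map(truth, motif_ids, gene_ids) -> list[tuple[str, str]]:
    """Pair the planted regulator with its motif and each decoy motif with a
    distinct non-signature gene (taken from the tail of the gene list)."""
    sig = {g for gs in truth.signature_genes.values() for g in gs}
    sig.add(truth.regulator_gene)
    decoy_pool = [g for g in reversed(gene_ids) if g not in sig and g not in truth.mito_genes]
    pairs = [(truth.regulator_gene, truth.regulator_motif)]
    decoys = [m for m in motif_ids if m != truth.regulator_motif]
    if len(decoy_pool) < len(decoys):
        raise ValueError("not enough non-signature genes for decoy TFs")
    pairs.extend((decoy_pool[i], m) for i, m in enumerate(decoys))
    return pairs


def _tupleize(sim: dict) -> dict:
    out = dict(sim)
    for key in ("cell_types", "n_cells"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
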