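"""Synthetic multiome, bulk-ATAC, and patient-pool generators with planted
ground truth.

The generator emulates the statistical structure of a paired snRNA/snATAC
experiment on two or more lymphocyte populations: negative-binomial RNA
counts with per-cell library-size variation and a mitochondrial gene subset,
Poisson peak counts with cell-type-specific enrichment at signature peaks,
BED-style fragments placed inside peaks on a synthetic genome, and one
planted transcription-factor regulator whose motif peaks coincide with one
type's signature peaks and whose gene sits in that type's RNA signature.

The synthetic genome uses one chromosome per 1000 peaks; peaks are 500 bp
wide and spaced 2 kb apart, with 2 kb gene bodies interleaved between peaks
on alternating strands.  A single integer seed expands into independent
per-component substreams, so each stage is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    CellFeatureMatrix,
    FragmentRecord,
    GenomicInterval,
    MotifPeakMap,
    SignatureSet,
)

PEAK_WIDTH = 500
PEAK_SPACING = 2000
PEAKS_PER_CHROM = 1000
GENE_BODY = 2000
FRAGMENT_LENGTH = 100


@dataclass
class SimConfig:
    """Study conditions for the multiome simulator.

    ``rna_effect`` / ``atac_effect`` are fold-change multipliers applied to a
    cell type's own signature genes/peaks (> 1).  ``rna_dispersion`` is the
    NB dispersion alpha in the variance function ``mu + alpha * mu**2``.
    """

    cell_types: tuple[str, ...] = ("ILC2", "ILC1")
    n_cells: tuple[int, ...] = (300, 300)
    n_genes: int = 2000
    n_peaks: int = 2000
    signature_size_genes: int = 50
    signature_size_peaks: int = 100
    rna_effect: float = 4.0
    atac_effect: float = 4.0
    rna_dispersion: float = 0.5
    base_rna_mean: float = 0.5
    base_peak_rate: float = 0.1
    libsize_sigma: float = 0.3
    mito_fraction_mean: float = 0.05
    n_mito_genes: int = 10
    n_motifs: int = 60
    motif_size: int = 100
    regulator_overlap: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_types) != len(self.n_cells) or len(self.cell_types) < 2:
            raise ValueError("need >= 2 cell types with matching n_cells")
        if self.rna_effect < 1 or self.atac_effect < 1:
            raise ValueError("effect sizes must be >= 1")
        if not (0 <= self.mito_fraction_mean < 1):
            raise ValueError("mito_fraction_mean must lie in [0, 1)")
        if not (0 <= self.regulator_overlap <= 1):
            raise ValueError("regulator_overlap must lie in [0, 1]")
        if self.signature_size_genes * len(self.cell_types) + self.n_mito_genes > self.n_genes:
            raise ValueError("signature genes plus mito genes exceed n_genes")
        if self.signature_size_peaks * len(self.cell_types) > self.n_peaks:
            raise ValueError("signature peaks exceed n_peaks")
        if self.motif_size > self.n_peaks:
            raise ValueError("motif_size exceeds n_peaks")
        if min(self.n_cells) < 2:
            raise ValueError("each type needs >= 2 cells")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    labels: pd.Series  # barcode -> cell type
    signature_genes: dict[str, list[str]]
    signature_peaks: dict[str, list[str]]
    regulator_gene: str
    regulator_motif: str
    regulator_type: str
    mito_genes: list[str]
    differential_regions: list[str] = field(default_factory=list)
    planted_log2fc: float = 0.0
    positive_fraction: dict[str, float] = field(default_factory=dict)
    positive_nuclei: dict[str, list[str]] = field(default_factory=dict)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def synthetic_genome_peaks(n_peaks: int) -> list[GenomicInterval]:
    """Lay out ``n_peaks`` 500-bp peaks, 2 kb apart, 1000 per chromosome."""
    peaks = []
    for i in range(n_peaks):
        chrom = f"chr{i // PEAKS_PER_CHROM + 1}"
        start = (i % PEAKS_PER_CHROM) * PEAK_SPACING + PEAK_SPACING // 2
        peaks.append(GenomicInterval(chrom, start, start + PEAK_WIDTH, ".", f"peak_{i}"))
    return peaks


def synthetic_genome_genes(n_genes: int, gene_ids: list[str] | None = None) -> list[GenomicInterval]:
    """2-kb gene bodies on a gene chromosome, alternating strands, 6 kb apart."""
    genes = []
    per_chrom = 1000
    for i in range(n_genes):
        chrom = f"chrG{i // per_chrom + 1}"
        start = (i % per_chrom) * (GENE_BODY * 3) + GENE_BODY
        strand = "+" if i % 2 == 0 else "-"
        gid = gene_ids[i] if gene_ids else f"gene_{i}"
        genes.append(GenomicInterval(chrom, start, start + GENE_BODY, strand, gid))
    return genes


def generate_multiome(config: SimConfig):
    """Simulate a paired RNA+ATAC dataset with planted signatures.

    Returns ``(rna, atac, fragments, signatures, motif_map, truth)`` where
    ``signatures`` is a dict with gene and region signature sets per type.
    """
    cfg = config
    rngs = _substreams(cfg.seed, 6)
    rng_assign, rng_rna, rng_atac, rng_frag, rng_motif, rng_lib = rngs

    types = list(cfg.cell_types)
    barcodes = []
    labels = []
    for t, n in zip(types, cfg.n_cells):
        for j in range(n):
            barcodes.append(f"{t}_{j:04d}")
            labels.append(t)
    n_cells = len(barcodes)
    labels = pd.Series(labels, index=barcodes, name="cell_type")

    gene_ids = [f"gene_{i}" for i in range(cfg.n_genes - cfg.n_mito_genes)]
    mito_genes = [f"mt-gene_{i}" for i in range(cfg.n_mito_genes)]
    all_genes = gene_ids + mito_genes
    peak_ids = [f"peak_{i}" for i in range(cfg.n_peaks)]

    # planted signatures: disjoint leading blocks of genes/peaks per type
    signature_genes: dict[str, list[str]] = {}
    signature_peaks: dict[str, list[str]] = {}
    for ti, t in enumerate(types):
        g0 = ti * cfg.signature_size_genes
        p0 = ti * cfg.signature_size_peaks
        signature_genes[t] = gene_ids[g0 : g0 + cfg.signature_size_genes]
        signature_peaks[t] = peak_ids[p0 : p0 + cfg.signature_size_peaks]

    # RNA: NB via gamma-Poisson; per-cell library factor is log-normal
    lib = np.exp(rng_lib.normal(0.0, cfg.libsize_sigma, size=n_cells))
    mean_gene = np.full((len(gene_ids), n_cells), cfg.base_rna_mean)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    type_of_cell = labels.to_numpy()
    for t in types:
        cells_t = type_of_cell == t
        rows = [gene_index[g] for g in signature_genes[t]]
        mean_gene[np.ix_(rows, cells_t)] *= cfg.rna_effect
    # mitochondrial genes: tuned so the expected mito fraction matches the target
    non_mito_total = mean_gene.sum(axis=0)
    if cfg.n_mito_genes > 0 and cfg.mito_fraction_mean > 0:
        mito_per_gene = (
            cfg.mito_fraction_mean / (1.0 - cfg.mito_fraction_mean)
        ) * non_mito_total / cfg.n_mito_genes
        mean_mito = np.tile(mito_per_gene, (cfg.n_mito_genes, 1))
    else:
        mean_mito = np.zeros((cfg.n_mito_genes, n_cells))
    mean_all = np.vstack([mean_gene, mean_mito]) * lib[None, :]
    if cfg.rna_dispersion > 0:
        shape = 1.0 / cfg.rna_dispersion
        lam = rng_rna.gamma(shape, mean_all * cfg.rna_dispersion)
    else:
        lam = mean_all
    rna_counts = rng_rna.poisson(lam).astype(np.int64)
    rna = CellFeatureMatrix(sp.csr_matrix(rna_counts), all_genes, barcodes, "rna")

    # ATAC: Poisson peak counts with planted enrichment, same library factors
    rate = np.full((cfg.n_peaks, n_cells), cfg.base_peak_rate)
    peak_index = {p: i for i, p in enumerate(peak_ids)}
    for t in types:
        cells_t = type_of_cell == t
        rows = [peak_index[p] for p in signature_peaks[t]]
        rate[np.ix_(rows, cells_t)] *= cfg.atac_effect
    atac_counts = rng_atac.poisson(rate * lib[None, :]).astype(np.int64)
    atac = CellFeatureMatrix(sp.csr_matrix(atac_counts), peak_ids, barcodes, "atac_peak")

    # fragments: one record per count unit, placed uniformly inside the peak
    peaks = synthetic_genome_peaks(cfg.n_peaks)
    fragments = _fragments_from_peak_counts(atac_counts, peaks, barcodes, rng_frag)

    # motifs: motif_0 is the planted regulator for the first cell type
    reg_type = types[0]
    reg_gene = signature_genes[reg_type][0]
    n_from_sig = int(round(cfg.regulator_overlap * cfg.motif_size))
    n_from_sig = min(n_from_sig, len(signature_peaks[reg_type]))
    sig_rows = [peak_index[p] for p in signature_peaks[reg_type]]
    other_rows = np.setdiff1d(np.arange(cfg.n_peaks), sig_rows)
    rows_reg = np.concatenate(
        [
            rng_motif.choice(sig_rows, size=n_from_sig, replace=False),
            rng_motif.choice(other_rows, size=cfg.motif_size - n_from_sig, replace=False),
        ]
    )
    motif_rows = [np.sort(rows_reg)]
    motif_ids = ["motif_0"]
    for m in range(1, cfg.n_motifs):
        motif_rows.append(
            np.sort(rng_motif.choice(cfg.n_peaks, size=cfg.motif_size, replace=False))
        )
        motif_ids.append(f"motif_{m}")
    mem_rows = np.concatenate([np.full(len(r), i) for i, r in enumerate(motif_rows)])
    mem_cols = np.concatenate(motif_rows)
    membership = sp.coo_matrix(
        (np.ones(len(mem_rows), dtype=np.int8), (mem_rows, mem_cols)),
        shape=(cfg.n_motifs, cfg.n_peaks),
    ).tocsr()
    motif_map = MotifPeakMap(motif_ids, peak_ids, membership)

    peak_by_id = {p.id: p for p in peaks}
    signatures = {
        "genes": [SignatureSet(t, signature_genes[t], "gene") for t in types],
        "regions": [
            SignatureSet(t, [peak_by_id[p] for p in signature_peaks[t]], "region")
            for t in types
        ],
    }
    truth = GroundTruth(
        labels=labels,
        signature_genes=signature_genes,
        signature_peaks=signature_peaks,
        regulator_gene=reg_gene,
        regulator_motif="motif_0",
        regulator_type=reg_type,
        mito_genes=mito_genes,
    )
    return rna, atac, fragments, signatures, motif_map, truth


def _fragments_from_peak_counts(
    counts: np.ndarray,
    peaks: list[GenomicInterval],
    barcodes: list[str],
    rng: np.random.Generator,
) -> list[FragmentRecord]:
    fragments: list[FragmentRecord] = []
    coo = sp.coo_matrix(counts)
    order = np.lexsort((coo.col, coo.row))
    for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order]):
        peak = peaks[r]
        span = max(peak.width - FRAGMENT_LENGTH, 1)
        starts = peak.start + rng.integers(0, span, size=int(v))
        for s in starts:
            fragments.append(
                FragmentRecord(peak.chrom, int(s), int(s) + FRAGMENT_LENGTH, barcodes[c], 1)
            )
    return fragments


def generate_bulk_counts(
    n_regions: int = 2000,
    n_replicates_per_condition: int = 3,
    n_differential: int = 200,
    planted_log2fc: float = 2.0,
    dispersion: float = 0.05,
    base_mean: float = 100.0,
    libsize_sigma: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Replicate-level NB count table with planted differential regions.

    The first ``n_differential`` regions are shifted by ``planted_log2fc``
    (log2) in condition B; per-sample depth varies by a log-normal factor.
    Region base means are log-normal around ``base_mean`` so dispersion
    estimation sees a realistic mean range.
    """
    if n_differential > n_regions:
        raise ValueError("n_differential exceeds n_regions")
    if n_replicates_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng_mean, rng_counts, rng_lib = _substreams(seed, 3)
    n_samples = 2 * n_replicates_per_condition
    conditions = ["A"] * n_replicates_per_condition + ["B"] * n_replicates_per_condition
    sample_ids = [f"{c}_{i}" for i, c in enumerate(conditions)]
    base = base_mean * np.exp(rng_mean.normal(0.0, 0.5, size=n_regions))
    mean = np.tile(base[:, None], (1, n_samples))
    n_diff = n_differential if planted_log2fc != 0 else 0
    if n_diff:
        is_b = np.array([c == "B" for c in conditions])
        mean[np.ix_(np.arange(n_diff), is_b)] *= 2.0**planted_log2fc
    sf = np.exp(rng_lib.normal(0.0, libsize_sigma, size=n_samples))
    mean = mean * sf[None, :]
    shape = 1.0 / dispersion
    lam = rng_counts.gamma(shape, mean * dispersion)
    counts = rng_counts.poisson(lam).astype(np.int64)
    region_ids = [f"region_{i}" for i in range(n_regions)]
    table = pd.DataFrame(counts, index=region_ids, columns=sample_ids)
    table.attrs["conditions"] = conditions
    truth = GroundTruth(
        labels=pd.Series(conditions, index=sample_ids, name="condition"),
        signature_genes={},
        signature_peaks={},
        regulator_gene="",
        regulator_motif="",
        regulator_type="",
        mito_genes=[],
        differential_regions=region_ids[:n_diff],
        planted_log2fc=planted_log2fc,
    )
    return table, truth


def generate_patient_pools(
    n_samples_per_condition: dict[str, int],
    nuclei_per_sample: int = 100,
    n_signature_regions: int = 100,
    n_background_regions: int = 200,
    positive_fraction_by_condition: dict[str, float] | None = None,
    depth: float = 200.0,
    signature_boost: float = 4.0,
    seed: int = 0,
):
    """Pooled patient-like nuclei with condition-dependent signature fractions.

    Each nucleus is "signature-positive" with its condition's probability;
    positive nuclei place a ``signature_boost``-fold higher share of their
    fragments in signature regions, while background-region rates are shared
    by all nuclei.  Returns ``(fragments_by_sample, signature_regions,
    background_regions, truth)``.
    """
    if positive_fraction_by_condition is None:
        positive_fraction_by_condition = {c: 0.5 for c in n_samples_per_condition}
    for c, f in positive_fraction_by_condition.items():
        if not (0 <= f <= 1):
            raise ValueError(f"positive fraction for {c!r} outside [0, 1]")
    if n_signature_regions < 1 or n_background_regions < 1:
        raise ValueError("region sets must be non-empty")
    all_regions = synthetic_genome_peaks(n_signature_regions + n_background_regions)
    signature_regions = all_regions[:n_signature_regions]
    background_regions = all_regions[n_signature_regions:]

    rng_flags, rng_counts, rng_pos = _substreams(seed, 3)
    fragments_by_sample: dict[str, list[FragmentRecord]] = {}
    condition_of_sample: dict[str, str] = {}
    positive_nuclei: dict[str, list[str]] = {}
    regions_arr = signature_regions + background_regions
    n_reg = len(regions_arr)
    base_rate = depth / n_reg
    for cond, n_samp in n_samples_per_condition.items():
        frac = positive_fraction_by_condition[cond]
        for s in range(n_samp):
            sample_id = f"{cond}_s{s}"
            condition_of_sample[sample_id] = cond
            frags: list[FragmentRecord] = []
            pos_list: list[str] = []
            flags = rng_flags.random(nuclei_per_sample) < frac
            for j in range(nuclei_per_sample):
                barcode = f"{sample_id}#N{j:04d}"
                if flags[j]:
                    pos_list.append(barcode)
                rates = np.full(n_reg, base_rate)
                if flags[j]:
                    rates[:n_signature_regions] *= signature_boost
                counts = rng_counts.poisson(rates)
                for ri in np.flatnonzero(counts):
                    region = regions_arr[ri]
                    span = max(region.width - FRAGMENT_LENGTH, 1)
                    for s0 in rng_pos.integers(0, span, size=int(counts[ri])):
                        frags.append(
                            FragmentRecord(
                                region.chrom,
                                region.start + int(s0),
                                region.start + int(s0) + FRAGMENT_LENGTH,
                                barcode,
                                1,
                            )
                        )
            fragments_by_sample[sample_id] = frags
            positive_nuclei[sample_id] = pos_list
    truth = GroundTruth(
        labels=pd.Series(condition_of_sample, name="condition"),
        signature_genes={},
        signature_peaks={},
        regulator_gene="",
        regulator_motif="",
        regulator_type="",
        mito_genes=[],
        positive_fraction=dict(positive_fraction_by_condition),
        positive_nuclei=positive_nuclei,
    )
    return fragments_by_sample, signature_regions, background_regions, truth
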