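"""Synthetic cohorts with planted ground truth.

Generates every input the pipeline consumes — per-sample taxonomic
classification reports with k-mer statistics, host expression counts,
microbial abundance profiles with stage and batch structure, and
single-cell UMI matrices with barcode-linked microbial reads — so that
every stage of the analysis can be scored against a known answer without
any external download.

The taxonomic reports emulate the diagnostics a k-mer classifier attaches
to each taxon: genuine taxa produce many distinct k-mers (roughly one new
k-mer per read position up to the genome's capacity) and their read,
total-k-mer and unique-k-mer statistics rise and fall together across
samples.  Contaminants are planted in four separable signature classes:

``low_unique_kmers``
    too few distinct k-mers (below read_length − kmer_length + 1);
``low_total_kmers``
    total k-mer count not exceeding five-fold the read count;
``decorrelated``
    k-mer statistics statistically independent of read counts across
    samples;
``blacklist``
    genus name drawn from a published reagent-contaminant list.

An optional fifth class, ``depth_signature`` (read count independent of
sequencing depth, so relative abundance falls as depth rises), emulates
the frequency signature of reagent contamination and is off by default.

Expression counts are negative binomial with planted differential genes,
taxon abundances are Dirichlet-multinomial with planted stage shifts, and
planted gene–taxon couplings are linear in the centred log-ratio of the
taxon with Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "STAGES",
    "simulate_taxon_reports",
    "simulate_expression_and_profile",
    "simulate_interaction_stage",
    "simulate_single_cell",
]

STAGES = ("control", "NAFL", "Borderline", "NASH")

# Genus names used for planted blacklist contaminants; a superset ships
# with the decontamination module as the bundled default blacklist.
_BLACKLIST_GENERA = (
    "Bradyrhizobium",
    "Burkholderia",
    "Delftia",
    "Herbaspirillum",
    "Mesorhizobium",
    "Methylobacterium",
    "Phyllobacterium",
    "Rhodococcus",
    "Aquabacterium",
    "Variovorax",
)

_PHYLA = (
    "Proteobacteria",
    "Actinobacteria",
    "Firmicutes",
    "Bacteroidota",
    "Ascomycota",
    "Basidiomycota",
    "Fusobacteriota",
    "Uroviricota",
)


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults describe a desk-scale cohort with the structure of a
    multi-dataset liver RNA-seq study: four histological stages, several
    datasets acting as batches, overdispersed gene counts, a compositional
    microbial profile, and planted effects large enough to be recoverable
    at these sample sizes.
    """

    seed: int = 0
    n_datasets: int = 2
    samples_per_stage: dict = field(
        default_factory=lambda: {s: 20 for s in STAGES}
    )
    n_genes: int = 500
    n_taxa: int = 120
    n_contaminants: int = 24
    read_length: int = 150
    kmer_length: int = 31
    n_de_genes: int = 40
    de_log2fc: float = 2.0
    n_diff_taxa: int = 10
    da_log2fc: float = 2.5
    n_interactions: int = 10
    interaction_beta: float = 0.8
    noise_sd: float = 0.3
    batch_sd: float = 0.5
    n_cells: int = 600
    n_cell_types: int = 5
    fraction_carrying: float = 0.3
    n_depth_contaminants: int = 0

    def __post_init__(self):
        if self.kmer_length > self.read_length:
            raise ValueError("kmer_length must not exceed read_length")
        if self.n_contaminants > self.n_taxa:
            raise ValueError("n_contaminants must not exceed n_taxa")
        for name in (
            "n_datasets", "n_genes", "n_taxa", "n_contaminants",
            "n_de_genes", "n_diff_taxa", "n_interactions", "n_cells",
            "n_cell_types", "n_depth_contaminants",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_de_genes + self.n_interactions > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        if self.n_diff_taxa + self.n_interactions > self.n_taxa:
            raise ValueError("planted taxa exceed n_taxa")

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_stage.values())

    @property
    def kmer_threshold(self) -> int:
        return self.read_length - self.kmer_length + 1


@dataclass
class GroundTruth:
    """Planted truth for scoring pipeline output."""

    contaminant_taxa: dict = field(default_factory=dict)  # name -> class label
    de_genes: dict = field(default_factory=dict)          # name -> signed log2FC
    diff_taxa: dict = field(default_factory=dict)         # name -> signed log2 shift
    interaction_edges: list = field(default_factory=list)  # (gene, taxon, beta)
    active_cells: list = field(default_factory=list)       # barcodes

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _sample_ids(config: SimConfig):
    """Sample ids, stage labels and dataset labels, interleaved so every
    dataset contains every stage."""
    sids, stages, datasets = [], [], []
    for stage in STAGES:
        k = config.samples_per_stage.get(stage, 0)
        for i in range(k):
            sids.append(f"{stage}_{i:03d}")
            stages.append(stage)
            datasets.append(f"DS{i % config.n_datasets + 1}")
    return sids, np.array(stages), np.array(datasets)


def _taxon_names(config: SimConfig, rng) -> tuple[list, dict]:
    """Species names plus a lineage table (phylum..species)."""
    names, lineages = [], {}
    n_black = min(
        len(_BLACKLIST_GENERA),
        config.n_contaminants // 4 if config.n_contaminants else 0,
    )
    for i in range(config.n_taxa):
        phylum = _PHYLA[i % len(_PHYLA)]
        genus = f"Genus{i // 3:03d}"
        species = f"Species{i:04d}"
        names.append(species)
        lineages[species] = [phylum, f"Class{i % 11:02d}", f"Order{i % 17:02d}",
                             f"Family{i % 23:02d}", genus, species]
    return names, lineages


def simulate_taxon_reports(config: SimConfig):
    """Per-sample taxonomic report tables with planted contaminants.

    Returns
    -------
    reports : dict of sample_id -> DataFrame
        Columns: taxon_id, name, rank, lineage, reads, total_kmers,
        unique_kmers — the per-sample classification statistics the
        decontamination protocol consumes.
    truth : GroundTruth
        ``contaminant_taxa`` maps each planted contaminant to its
        signature class.
    """
    rng = np.random.default_rng(config.seed)
    sids, stages, datasets = _sample_ids(config)
    n_samples = len(sids)
    if n_samples == 0:
        raise ValueError("at least one sample is required")
    names, lineages = _taxon_names(config, rng)
    thr = config.kmer_threshold
    span = config.read_length - config.kmer_length + 1

    # split taxa into genuine + contaminant classes (round-robin)
    classes = ["low_unique_kmers", "low_total_kmers", "decorrelated", "blacklist"]
    contam_class: dict[str, str] = {}
    contam = list(names[: config.n_contaminants])
    for j, t in enumerate(contam):
        contam_class[t] = classes[j % len(classes)]
    depth_taxa = names[config.n_contaminants:
                       config.n_contaminants + config.n_depth_contaminants]
    for t in depth_taxa:
        contam_class[t] = "depth_signature"
    # blacklist contaminants get a blacklisted genus in their lineage
    bi = 0
    for t, c in contam_class.items():
        if c == "blacklist":
            lineages[t][4] = _BLACKLIST_GENERA[bi % len(_BLACKLIST_GENERA)]
            bi += 1

    # per-sample sequencing depth factor; genuine abundance scales with it
    depth = rng.lognormal(mean=0.0, sigma=0.6, size=n_samples)
    genome_cap = rng.integers(int(2e5), int(8e5), size=config.n_taxa)

    truth = GroundTruth(contaminant_taxa=dict(contam_class))
    reports = {}
    base_mu = rng.normal(np.log(60.0), 0.5, size=config.n_taxa)
    present = rng.random((n_samples, config.n_taxa)) < 0.92

    reads = np.zeros((n_samples, config.n_taxa), dtype=int)
    total = np.zeros_like(reads)
    unique = np.zeros_like(reads)
    for j, t in enumerate(names):
        cls = contam_class.get(t)
        if cls in (None, "blacklist"):
            r = np.round(depth * np.exp(base_mu[j] + rng.normal(0, 1.0, n_samples))).astype(int)
            r = np.maximum(r, 2)
            tot = np.round(r * span * rng.uniform(0.9, 1.0, n_samples)).astype(int)
            uni = np.minimum(
                np.round(r * span * rng.uniform(0.85, 0.95, n_samples)),
                genome_cap[j],
            ).astype(int)
            uni = np.minimum(uni, tot)
        elif cls == "low_unique_kmers":
            r = np.maximum(np.round(depth * np.exp(base_mu[j] + rng.normal(0, 1.0, n_samples))), 2).astype(int)
            tot = np.round(r * span * rng.uniform(0.8, 1.0, n_samples)).astype(int)
            # distinct k-mers saturate far below the single-read span
            frac = r / (r + np.median(r))
            uni = np.maximum(1, np.floor(frac * (thr - 1))).astype(int)
        elif cls == "low_total_kmers":
            # read floor keeps unique >= 0.9 * 2.0 * reads above the step-1
            # threshold, so these fail only the five-fold total-k-mer rule
            r_min = max(80, int(np.ceil(thr / 1.8)) + 1)
            r = np.maximum(np.round(depth * np.exp(base_mu[j] + rng.normal(0, 0.8, n_samples))), r_min).astype(int)
            tot = np.floor(r * rng.uniform(2.0, 4.8, n_samples)).astype(int)
            uni = np.round(tot * rng.uniform(0.9, 1.0, n_samples)).astype(int)
        elif cls == "decorrelated":
            # read floor keeps total kmers >= 3*thr so the shuffled unique
            # counts are never clipped below the step-1 threshold
            r_min = max(10, int(np.ceil(3 * thr / 45)))
            r = np.maximum(np.round(depth * np.exp(base_mu[j] + rng.normal(0, 1.0, n_samples))), r_min).astype(int)
            tot = np.round(50 * r * rng.uniform(0.9, 1.1, n_samples)).astype(int)
            uni = rng.integers(thr, 3 * thr, size=n_samples)
            uni = np.minimum(uni, tot)
        elif cls == "depth_signature":
            # constant input mass: relative abundance falls as depth rises
            r = np.maximum(np.round(np.exp(base_mu[j]) * rng.uniform(0.8, 1.25, n_samples)), 2).astype(int)
            tot = np.round(r * span * rng.uniform(0.9, 1.0, n_samples)).astype(int)
            uni = np.minimum(np.round(r * span * rng.uniform(0.85, 0.95, n_samples)), tot).astype(int)
        reads[:, j], total[:, j], unique[:, j] = r, tot, uni

    for i, sid in enumerate(sids):
        rows = []
        for j, t in enumerate(names):
            if not present[i, j]:
                continue
            rows.append(
                (j + 1000, t, "species", ";".join(lineages[t]),
                 int(reads[i, j]), int(total[i, j]), int(unique[i, j]))
            )
        reports[sid] = pd.DataFrame(
            rows,
            columns=["taxon_id", "name", "rank", "lineage",
                     "reads", "total_kmers", "unique_kmers"],
        )

    meta = pd.DataFrame(
        {"sample_id": sids, "stage": stages, "dataset": datasets}
    ).set_index("sample_id")
    return reports, meta, truth


def _dirichlet_multinomial(rng, alpha, depth):
    p = rng.dirichlet(alpha)
    return rng.multinomial(depth, p)


def simulate_expression_and_profile(config: SimConfig):
    """Host expression counts, microbial profile, metadata and truth.

    Expression is negative binomial on a log2 baseline, with planted
    differential genes shifted by ``de_log2fc`` (signed per gene) in every
    disease stage, an additive per-(dataset, gene) batch shift of standard
    deviation ``batch_sd`` on the log2 scale, and planted gene–taxon
    couplings in which a gene's log2 expression tracks
    ``interaction_beta`` times the centred log-ratio abundance of its
    partner taxon plus Gaussian noise of sd ``noise_sd``.

    The microbial profile is Dirichlet-multinomial; planted differential
    taxa have their concentration scaled by ``2**da_log2fc`` (signed) in
    disease stages.
    """
    rng = np.random.default_rng(config.seed + 1)
    sids, stages, datasets = _sample_ids(config)
    n = len(sids)
    genes = [f"GENE{g:05d}" for g in range(config.n_genes)]
    taxa = [f"Taxon{t:04d}" for t in range(config.n_taxa)]
    is_disease = (stages != "control").astype(float)

    truth = GroundTruth()

    # ---- microbial profile: Dirichlet-multinomial with stage shifts ----
    base_alpha = rng.lognormal(0.0, 1.0, size=config.n_taxa)
    diff_idx = rng.choice(config.n_taxa, size=config.n_diff_taxa, replace=False)
    diff_sign = rng.choice([-1.0, 1.0], size=config.n_diff_taxa)
    for k, j in enumerate(diff_idx):
        truth.diff_taxa[taxa[j]] = float(diff_sign[k] * config.da_log2fc)
    depth = rng.integers(20_000, 60_000, size=n)
    abundance = np.zeros((n, config.n_taxa), dtype=int)
    conc = 80.0  # Dirichlet concentration scale: overdispersion knob
    for i in range(n):
        alpha = base_alpha.copy()
        if is_disease[i]:
            alpha[diff_idx] *= 2.0 ** (diff_sign * config.da_log2fc)
        abundance[i] = _dirichlet_multinomial(rng, conc * alpha / alpha.sum(), depth[i])

    # CLR of the planted-coupling taxa (pseudocount 0.5)
    x = abundance + 0.5
    logx = np.log(x / x.sum(axis=1, keepdims=True))
    clr = logx - logx.mean(axis=1, keepdims=True)

    # ---- expression: NB with DE shifts, batch shifts, planted couplings ----
    base_log2 = rng.normal(6.0, 1.5, size=config.n_genes)
    de_idx = rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
    de_sign = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    for k, g in enumerate(de_idx):
        truth.de_genes[genes[g]] = float(de_sign[k] * config.de_log2fc)

    free = [g for g in range(config.n_genes) if g not in set(de_idx)]
    inter_genes = rng.choice(free, size=config.n_interactions, replace=False)
    non_diff = [j for j in range(config.n_taxa) if j not in set(diff_idx)]
    inter_taxa = rng.choice(non_diff, size=config.n_interactions, replace=False)
    if config.interaction_beta != 0:
        for g, j in zip(inter_genes, inter_taxa):
            truth.interaction_edges.append(
                (genes[g], taxa[j], float(config.interaction_beta))
            )

    ds_index = pd.Categorical(datasets).codes
    batch_shift = rng.normal(0.0, config.batch_sd,
                             size=(config.n_datasets, config.n_genes))
    log2mu = np.tile(base_log2, (n, 1)) + batch_shift[ds_index]
    for k, g in enumerate(de_idx):
        log2mu[:, g] += is_disease * de_sign[k] * config.de_log2fc
    if config.interaction_beta != 0:
        for g, j in zip(inter_genes, inter_taxa):
            log2mu[:, g] = (base_log2[g] + batch_shift[ds_index, g]
                            + config.interaction_beta * clr[:, j]
                            + rng.normal(0, config.noise_sd, n))

    mu = 2.0 ** log2mu
    nb_size = 20.0  # NB dispersion: var = mu + mu^2 / size
    p_nb = nb_size / (nb_size + mu)
    expr = rng.negative_binomial(nb_size, p_nb)

    expr_df = pd.DataFrame(expr, index=sids, columns=genes)
    abund_df = pd.DataFrame(abundance, index=sids, columns=taxa)
    meta = pd.DataFrame(
        {
            "sample_id": sids,
            "stage": stages,
            "dataset": datasets,
            "age": np.round(rng.normal(45, 15, n)).clip(18, 85),
            "sex": rng.choice(["F", "M"], size=n),
            "platform": ["PlatA" if d in ("DS1",) else "PlatB" for d in datasets],
        }
    ).set_index("sample_id")
    return expr_df, abund_df, meta, truth


def simulate_interaction_stage(
    n_samples: int = 80,
    n_genes: int = 100,
    n_taxa: int = 60,
    n_edges: int = 10,
    beta: float = 0.8,
    noise_sd: float = 0.3,
    seed: int = 0,
):
    """Distilled single-stage generator for the interaction chain.

    Produces a standardized sample × taxa predictor matrix (emulating the
    merged, CLR-transformed, batch-corrected taxa matrix), a sample × gene
    response matrix in which ``n_edges`` genes are linearly coupled to one
    taxon each (coefficient ``beta``, noise sd ``noise_sd``) and the rest
    are pure noise of matching variance, and the planted edge list.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, n_taxa))
    X = (X - X.mean(0)) / X.std(0, ddof=0)
    genes = [f"GENE{g:05d}" for g in range(n_genes)]
    taxa = [f"species|Taxon{t:04d}" for t in range(n_taxa)]
    edge_genes = rng.choice(n_genes, size=n_edges, replace=False)
    edge_taxa = rng.choice(n_taxa, size=n_edges, replace=False)
    Y = rng.normal(0, np.sqrt(beta**2 + noise_sd**2), size=(n_samples, n_genes))
    edges = []
    for g, t in zip(edge_genes, edge_taxa):
        Y[:, g] = beta * X[:, t] + rng.normal(0, noise_sd, n_samples)
        edges.append((genes[g], taxa[t], beta))
    Xdf = pd.DataFrame(X, columns=taxa)
    Ydf = pd.DataFrame(Y, columns=genes)
    return Ydf, Xdf, edges


def simulate_single_cell(config: SimConfig):
    """Cell × gene UMI matrix, type labels and barcode-linked microbial reads.

    UMI counts are Poisson with cell-type-specific rate signatures.  A
    configured fraction of cells carry at least one microbial read, with
    carriage concentrated in the first cell type (odds scaled 4:1).
    Planted active cells jointly exceed the 75th percentile of a
    designated cluster gene and carry the cluster's taxon.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_cells, n_types = config.n_cells, config.n_cell_types
    if n_cells < n_types or n_types < 1:
        raise ValueError("need n_cells >= n_cell_types >= 1")
    type_names = [f"CellType{t}" for t in range(n_types)]
    n_genes = min(config.n_genes, 200)
    genes = [f"GENE{g:05d}" for g in range(n_genes)]
    taxa = [f"Taxon{t:04d}" for t in range(min(config.n_taxa, 20))]
    barcodes = [f"BC{i:05d}" for i in range(n_cells)]

    labels = np.array([type_names[i % n_types] for i in range(n_cells)])
    rng.shuffle(labels)
    condition = np.where(rng.random(n_cells) < 0.5, "control", "NAFLD")

    # type signatures: each type over-expresses a block of genes
    rates = np.full((n_types, n_genes), 0.3)
    block = max(1, n_genes // n_types)
    for t in range(n_types):
        rates[t, t * block:(t + 1) * block] = 3.0
    type_idx = np.array([type_names.index(l) for l in labels])
    umi = rng.poisson(rates[type_idx])

    # microbial carriage, enriched in the first cell type (odds 4:1)
    w = np.where(labels == type_names[0], 4.0, 1.0)
    f = config.fraction_carrying
    if f <= 0:
        carry = np.zeros(n_cells, dtype=bool)
    elif f >= 1:
        carry = np.ones(n_cells, dtype=bool)
    else:
        p = f * w / (f * w + (1 - f))
        carry = rng.random(n_cells) < p
    taxa_reads = np.zeros((n_cells, len(taxa)), dtype=int)
    for i in np.where(carry)[0]:
        k = rng.integers(1, 4)
        cols = rng.choice(len(taxa), size=k, replace=False)
        taxa_reads[i, cols] = rng.poisson(1.0, size=k) + 1

    # plant active cells for a designated cluster (gene 0, taxon 0)
    truth = GroundTruth()
    n_active = max(1, n_cells // 20)
    active_idx = rng.choice(n_cells, size=n_active, replace=False)
    hi_gene = int(np.quantile(umi[:, 0], 0.75)) + 5
    hi_taxon = int(np.quantile(taxa_reads[:, 0], 0.75)) + 3
    for i in active_idx:
        umi[i, 0] = hi_gene + rng.integers(0, 3)
        taxa_reads[i, 0] = hi_taxon + rng.integers(0, 3)
        truth.active_cells.append(barcodes[i])

    umi_df = pd.DataFrame(umi, index=barcodes, columns=genes)
    reads_df = pd.DataFrame(taxa_reads, index=barcodes, columns=taxa)
    meta = pd.DataFrame(
        {"barcode": barcodes, "cell_type": labels, "condition": condition}
    ).set_index("barcode")
    return umi_df, meta, reads_df, truth
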