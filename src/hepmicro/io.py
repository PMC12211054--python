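"""Readers, writers, configuration and the end-to-end pipeline driver.

All outputs are plain text (TSV, MTX, JSON) with headers, so every stage
is diff-able and reproducible from the run manifest, which records the
configuration snapshot, package version, per-file checksums and the seed
trail.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from . import __version__

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_matrix",
    "write_matrix",
    "run_all",
]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their standard defaults.

    The defaults are the significance and effect-size cutoffs the analysis
    is defined by: DEGs at FDR < 0.05 and |log2FC| > 1.2, differential
    taxa at FDR < 0.05 and |log2FC| > 1, interaction edges at FDR < 0.01
    with stability >= 0.6 over 100 refits, enrichment at FDR < 0.05, and
    the 75th-percentile rule for active cells.
    """

    seed: int = 0
    deg_fdr: float = 0.05
    deg_log2fc: float = 1.2
    da_fdr: float = 0.05
    da_log2fc: float = 1.0
    edge_fdr: float = 0.01
    stability_cut: float = 0.6
    enrich_fdr: float = 0.05
    sc_quantile: float = 0.75
    # decontamination
    read_length: int = 150
    kmer_length: int = 31
    fold: float = 5.0
    alpha: float = 0.05
    min_samples: int = 5
    # rare-taxon filter
    min_rel: float = 1e-4
    min_prev: float = 0.10
    min_datasets: int = 2
    # interaction chain
    n_splits: int = 50
    n_stability: int = 100
    max_genes_interact: int = 30
    # sparse CCA
    cca_k: int = 5
    # synthetic cohort scale (used with --simulate)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def with_overrides(self, overrides: dict) -> "PipelineConfig":
        d = asdict(self)
        for k, v in overrides.items():
            if k not in d:
                raise KeyError(f"unknown config key {k!r}")
            cur = d[k]
            d[k] = type(cur)(v) if cur is not None and not isinstance(cur, dict) else v
        return PipelineConfig(**d)


@dataclass
class RunManifest:
    config: dict
    version: str
    checksums: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def record(self, path: Path):
        self.checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def save(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def read_matrix(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a named matrix from TSV (index in first column) or MTX.

    For MTX, sibling files ``<stem>.rownames.txt`` / ``<stem>.colnames.txt``
    supply the names.  Dimension or name mismatches raise with detail.
    """
    path = Path(path)
    if fmt is None:
        fmt = "MTX" if path.suffix == ".mtx" else "TSV"
    if fmt.upper() == "TSV":
        if path.stat().st_size == 0:
            raise ValueError(f"{path} is empty")
        return pd.read_csv(path, sep="\t", index_col=0)
    m = spio.mmread(path)
    m = m.toarray() if sparse.issparse(m) else np.asarray(m)
    rows = path.with_suffix("").with_suffix(".rownames.txt")
    cols = path.with_suffix("").with_suffix(".colnames.txt")
    rnames = (rows.read_text().split() if rows.exists()
              else [f"r{i}" for i in range(m.shape[0])])
    cnames = (cols.read_text().split() if cols.exists()
              else [f"c{i}" for i in range(m.shape[1])])
    if len(rnames) != m.shape[0] or len(cnames) != m.shape[1]:
        raise ValueError(
            f"{path}: name files declare {len(rnames)}x{len(cnames)} but the "
            f"matrix is {m.shape[0]}x{m.shape[1]}")
    return pd.DataFrame(m, index=rnames, columns=cnames)


def write_matrix(df: pd.DataFrame, path, fmt: str | None = None) -> Path:
    """Write a named matrix as TSV (12 significant digits) or MTX."""
    path = Path(path)
    if fmt is None:
        fmt = "MTX" if path.suffix == ".mtx" else "TSV"
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt.upper() == "TSV":
        df.to_csv(path, sep="\t", float_format="%.12g")
    else:
        spio.mmwrite(path, sparse.csr_matrix(df.to_numpy()))
        path.with_suffix("").with_suffix(".rownames.txt").write_text(
            "\n".join(map(str, df.index)))
        path.with_suffix("").with_suffix(".colnames.txt").write_text(
            "\n".join(map(str, df.columns)))
    return path


def run_all(config: PipelineConfig, out_dir, simulate: bool = True,
            skip: tuple = ()) -> RunManifest:
    """Execute the full chain on a synthetic cohort and write all outputs.

    Stages: simulate -> decontam -> profiles -> deg -> interact (per
    stage) -> cca -> sc.  Any stage failure propagates with the stage
    name; the manifest lists completed stages.  ``skip`` names stages to
    bypass (e.g. ("sc",)).
    """
    from . import synthetic_data as sd
    from . import decontam as dc
    from . import profiles as pr
    from . import host_expression as he
    from . import interaction_net as inet
    from . import cca as scca
    from . import single_cell as sc

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)
    if not simulate:
        raise NotImplementedError(
            "run_all currently drives the synthetic cohort; run individual "
            "subcommands on real inputs")

    def done(stage, *paths):
        manifest.stages.append(stage)
        for p in paths:
            manifest.record(Path(p))

    sim_kwargs = dict(config.sim)
    sim_kwargs.setdefault("seed", config.seed)
    cfg = sd.SimConfig(**sim_kwargs)
    manifest.seeds["master"] = config.seed

    # ---- simulate + decontam -------------------------------------------
    reports, rep_meta, truth_taxa = sd.simulate_taxon_reports(cfg)
    counts, filt = dc.run_decontam(
        reports, read_length=cfg.read_length, kmer_length=cfg.kmer_length,
        fold=config.fold, alpha=config.alpha, min_samples=config.min_samples,
        datasets=rep_meta["dataset"])
    p1 = write_matrix(counts, out / "decontam_counts.tsv")
    filt.removed.to_csv(out / "decontam_removed.tsv", sep="\t", index=False)
    done("decontam", p1, out / "decontam_removed.tsv")

    # ---- expression + microbial profile --------------------------------
    expr, abund, meta, truth = sd.simulate_expression_and_profile(cfg)
    profile = pr.MicrobialProfile(abund, meta)
    profile = pr.rare_taxon_filter(profile, config.min_rel, config.min_prev,
                                   config.min_datasets)
    clr = pr.clr_transform(profile)
    clr_bc = pr.MicrobialProfile(
        pr.remove_batch(clr.abundance, meta["dataset"],
                        covariates=meta[["stage"]]),
        meta, form="clr")
    shannon = pr.shannon_index(profile)
    dist = pr.aitchison_distance(clr_bc)
    f_stat, p_perm = pr.permanova(dist, meta.loc[dist.index, "stage"],
                                  n_perm=199, seed=config.seed)
    da = pr.differential_abundance(clr_bc, meta["stage"], "control",
                                   config.da_fdr, config.da_log2fc)
    shannon.to_csv(out / "shannon.tsv", sep="\t")
    da.to_csv(out / "diff_abundance.tsv", sep="\t", index=False)
    json.dump({"pseudo_F": f_stat, "p": p_perm},
              (out / "permanova.json").open("w"))
    done("profiles", out / "shannon.tsv", out / "diff_abundance.tsv")

    # ---- differential expression ---------------------------------------
    logexpr = he.vst(expr)
    logexpr = he.variance_filter(logexpr, 0.25)
    logexpr_bc = pr.remove_batch(logexpr, meta["dataset"],
                                 covariates=meta[["stage"]])
    deg_tables = {}
    for stage in ("NAFL", "Borderline", "NASH"):
        deg = he.moderated_de(logexpr_bc, meta["stage"], (stage, "control"),
                              fdr_cut=config.deg_fdr,
                              log2fc_cut=config.deg_log2fc)
        deg_tables[stage] = deg
        deg.to_csv(out / f"deg_{stage}.tsv", sep="\t", index=False)
    done("deg", *(out / f"deg_{s}.tsv" for s in deg_tables))

    # ---- interaction networks (per stage, capped gene set) -------------
    edges_by_stage = {}
    if "interact" not in skip:
        taxa_clr = clr_bc.abundance
        sd_cols = taxa_clr.std(axis=0, ddof=0)
        taxa_std = ((taxa_clr - taxa_clr.mean(0)) / sd_cols).loc[:, sd_cols > 0]
        taxa_std.columns = [f"species|{c}" for c in taxa_std.columns]
        for stage in sd.STAGES:
            sel = meta.index[meta["stage"] == stage]
            ranked = (deg_tables.get(stage, deg_tables["NASH"])
                      .sort_values("p"))
            genes = list(ranked["gene"].head(config.max_genes_interact))
            edges = inet.identify_interactions(
                logexpr_bc.loc[sel, genes], taxa_std.loc[sel], stage=stage,
                fdr_cut=config.edge_fdr, stability_cut=config.stability_cut,
                n_splits=config.n_splits, n_iter=config.n_stability,
                seed=config.seed + 11)
            edges_by_stage[stage] = edges
            edges.to_csv(out / f"edges_{stage}.tsv", sep="\t", index=False)
        net = inet.build_stage_networks(edges_by_stage)
        (out / "networks.json").write_text(json.dumps(net, indent=1))
        done("interact", out / "networks.json")

    # ---- sparse CCA -----------------------------------------------------
    if "cca" not in skip:
        Xg = logexpr_bc.iloc[:, : min(100, logexpr_bc.shape[1])]
        Xs = (Xg - Xg.mean(0)) / Xg.std(0, ddof=0)
        Zt = clr_bc.abundance
        Zs = ((Zt - Zt.mean(0)) / Zt.std(0, ddof=0)).dropna(axis=1)
        comps = scca.sparse_cca(Xs, Zs, K=config.cca_k, seed=config.seed)
        clusters = scca.extract_clusters(comps)
        rows = []
        for c in comps:
            for feat, w in c.v[c.v != 0].items():
                rows.append({"component": c.index, "side": "gene",
                             "feature": feat, "weight": w})
            for feat, w in c.u[c.u != 0].items():
                rows.append({"component": c.index, "side": "taxon",
                             "feature": feat, "weight": w})
        pd.DataFrame(rows).to_csv(out / "cca_components.tsv", sep="\t",
                                  index=False)
        done("cca", out / "cca_components.tsv")
    else:
        clusters = []

    # ---- single cell ----------------------------------------------------
    if "sc" not in skip:
        umi, cmeta, treads, sc_truth = sd.simulate_single_cell(cfg)
        carrying = sc.flag_microbe_carrying(treads)
        enr = sc.celltype_enrichment(cmeta, carrying)
        active_by_cluster = {}
        for cl in clusters[:1]:
            genes = [g for g in cl.genes.index if g in umi.columns]
            taxa = [t.split("|")[-1] for t in cl.taxa.index]
            taxa = [t for t in taxa if t in treads.columns]
            if genes and taxa:
                active_by_cluster[cl.index] = sc.active_interaction_cells(
                    umi, treads, genes, taxa, cmeta["condition"],
                    q=config.sc_quantile)
        enr.to_csv(out / "sc_enrichment.tsv", sep="\t", index=False)
        if active_by_cluster:
            summary = sc.summarize_active_by_type(cmeta, active_by_cluster)
            summary.to_csv(out / "sc_active.tsv", sep="\t", index=False)
        done("sc", out / "sc_enrichment.tsv")

    manifest.save(out / "manifest.json")
    return manifest
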