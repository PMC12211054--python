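"""Microbe-carrying cells and host-microbe co-localization at cell level.

Microbial reads surviving decontamination are linked to cell barcodes;
cells with at least one microbial read are "microbe-carrying", the rest
"microbe-free".  Carriage enrichment per cell type is a Fisher exact test
within each condition.  For an interaction cluster (paired gene and taxa
sets), a cell is an *active interaction cell* when it exceeds the 75th
percentile for at least one cluster gene and at least one cluster taxon,
percentiles taken across the cells of the same condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats_core import adjust_pvalues, fisher_exact

__all__ = [
    "flag_microbe_carrying",
    "celltype_enrichment",
    "active_interaction_cells",
    "summarize_active_by_type",
]


def flag_microbe_carrying(taxa_reads: pd.DataFrame) -> pd.Series:
    """True for every barcode with >= 1 microbial read (any taxon)."""
    if (taxa_reads.to_numpy() < 0).any():
        raise ValueError("negative microbial read counts")
    return taxa_reads.sum(axis=1) >= 1


def celltype_enrichment(meta: pd.DataFrame, carrying: pd.Series,
                        by_condition: bool = True) -> pd.DataFrame:
    """Fisher exact enrichment of microbe carriage per cell type.

    For each cell type (within each condition when ``by_condition``):
    2x2 table of (this type vs others) x (carrying vs not); one-sided
    (enrichment) and two-sided p, BH across types within condition.
    """
    if meta["cell_type"].nunique() < 2:
        raise ValueError("need at least two cell types")
    carrying = carrying.loc[meta.index]
    conditions = (meta["condition"].unique() if by_condition and
                  "condition" in meta.columns else ["all"])
    rows = []
    for cond in conditions:
        sel = (meta["condition"] == cond if cond != "all"
               else pd.Series(True, index=meta.index))
        sub, carry = meta.loc[sel], carrying.loc[sel]
        for ct in sub["cell_type"].unique():
            in_type = sub["cell_type"] == ct
            if in_type.sum() == 0:
                continue
            a = int((in_type & carry).sum())
            b = int((in_type & ~carry).sum())
            c = int((~in_type & carry).sum())
            d = int((~in_type & ~carry).sum())
            table = [[a, b], [c, d]]
            one = fisher_exact(table, alternative="greater")
            two = fisher_exact(table, alternative="two-sided")
            odds = (a * d) / (b * c) if b * c > 0 else float("inf")
            rows.append({"condition": cond, "cell_type": ct,
                         "n_cells": int(in_type.sum()), "n_carrying": a,
                         "odds_ratio": odds, "p_greater": one.p_value,
                         "p_two_sided": two.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = np.nan
        for cond in out["condition"].unique():
            m = out["condition"] == cond
            out.loc[m, "fdr"] = adjust_pvalues(
                out.loc[m, "p_two_sided"].to_numpy(), "BH").adjusted
    return out


def active_interaction_cells(umi: pd.DataFrame, taxa_reads: pd.DataFrame,
                             cluster_genes, cluster_taxa,
                             condition: pd.Series | None = None,
                             q: float = 0.75) -> pd.Series:
    """Flag cells active for one interaction cluster.

    A cell is active iff some cluster gene's expression strictly exceeds
    that gene's q-quantile and some cluster taxon's read count strictly
    exceeds that taxon's q-quantile, quantiles computed over the cells of
    the same condition (all cells if ``condition`` is None).  Quantiles
    use linear interpolation of the empirical distribution.
    """
    genes = [g for g in cluster_genes if g in umi.columns]
    taxa = [t for t in cluster_taxa if t in taxa_reads.columns]
    missing_g = sorted(set(cluster_genes) - set(genes))
    missing_t = sorted(set(cluster_taxa) - set(taxa))
    if not genes or not taxa:
        raise ValueError(
            f"cluster features absent from the cell data: genes {missing_g}, "
            f"taxa {missing_t}")
    if condition is None:
        condition = pd.Series("all", index=umi.index)
    condition = condition.loc[umi.index]
    active = pd.Series(False, index=umi.index)
    for cond in condition.unique():
        idx = condition.index[condition == cond]
        g_thr = umi.loc[idx, genes].quantile(q, axis=0)
        t_thr = taxa_reads.loc[idx, taxa].quantile(q, axis=0)
        g_hit = (umi.loc[idx, genes] > g_thr).any(axis=1)
        t_hit = (taxa_reads.loc[idx, taxa] > t_thr).any(axis=1)
        active.loc[idx] = (g_hit & t_hit).to_numpy()
    return active


def summarize_active_by_type(meta: pd.DataFrame,
                             active_by_cluster: dict) -> pd.DataFrame:
    """Active-cell counts and fractions per (cluster, cell type, condition).

    Fractions sum to one within each (cluster, condition) that has any
    active cell.
    """
    rows = []
    for cluster, active in active_by_cluster.items():
        active = active.loc[meta.index]
        for cond in meta["condition"].unique():
            sel = meta["condition"] == cond
            total_active = int((active & sel).sum())
            for ct in meta["cell_type"].unique():
                m = sel & (meta["cell_type"] == ct)
                n_active = int((active & m).sum())
                frac = n_active / total_active if total_active else 0.0
                rows.append({"cluster": cluster, "condition": cond,
                             "cell_type": ct, "n_cells": int(m.sum()),
                             "n_active": n_active, "fraction": frac})
    return pd.DataFrame(rows)
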