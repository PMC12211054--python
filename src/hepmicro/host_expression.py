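"""Host transcriptome preprocessing, moderated differential expression, GSEA.

Differential expression uses per-gene linear models with empirical-Bayes
variance moderation: residual variances s_g^2 (on d residual df) are
shrunk toward a scaled inverse-chi-square prior (d0, s0^2) fitted by the
method of moments on log s^2, and the moderated t-statistic is assessed on
d0 + d degrees of freedom.  With d0 = 0 this reduces exactly to the
ordinary t-test; with d0 -> infinity every gene uses the common prior
variance.

Gene set enrichment is the preranked, weighted Kolmogorov–Smirnov running
sum with a gene-label permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .stats_core import adjust_pvalues

__all__ = [
    "EbParams",
    "variance_filter",
    "vst",
    "fit_eb_params",
    "moderated_de",
    "enrichment_score",
    "preranked_gsea",
    "read_gmt",
]


@dataclass(frozen=True)
class EbParams:
    """Scaled inverse-chi-square prior for residual variances."""

    d0: float  # prior degrees of freedom, may be inf
    s0_sq: float

    def posterior_var(self, s2: np.ndarray, d: float) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s2, float), self.s0_sq)
        if self.d0 == 0:
            return np.asarray(s2, float)
        return (self.d0 * self.s0_sq + d * s2) / (self.d0 + d)


def variance_filter(expr: pd.DataFrame, quantile: float = 0.25) -> pd.DataFrame:
    """Drop genes whose variance falls strictly below the given quantile.

    ``expr`` is samples × genes.  Ties at the quantile are retained.
    """
    if not (0 <= quantile < 1):
        raise ValueError("quantile must be in [0, 1)")
    if expr.shape[0] < 2:
        raise ValueError("need at least two samples")
    if quantile == 0:
        return expr.copy()
    v = expr.var(axis=0, ddof=1)
    cut = v.quantile(quantile)
    return expr.loc[:, v >= cut]


def vst(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """Variance-flattening transform: log2(counts-per-million + prior).

    A simple library-normalized log transform; the offset damps the
    variance blow-up of low counts.  Doubling every count in a library
    leaves the output unchanged.
    """
    lib = counts.sum(axis=1).to_numpy(float)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    cpm = counts.to_numpy(float) / lib[:, None] * 1e6
    return pd.DataFrame(np.log2(cpm + prior), index=counts.index,
                        columns=counts.columns)


def _trigamma_inverse(x: float) -> float:
    """Invert the trigamma function by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_eb_params(s2: np.ndarray, d: float) -> EbParams:
    """Moment-fit the variance prior from observed residual variances.

    Works on z = log s^2: under s^2 ~ s0^2 F(d, d0), the excess of
    var(z) over trigamma(d/2) estimates trigamma(d0/2).  When the
    empirical spread does not exceed its sampling expectation the prior is
    degenerate (d0 = inf) and every gene shares s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need at least two positive residual variances")
    if d < 1:
        raise ValueError("residual df must be >= 1")
    if np.allclose(s2, s2[0], rtol=1e-12, atol=0):
        # no dispersion at all: the common value is the prior itself
        return EbParams(d0=float("inf"), s0_sq=float(s2[0]))
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    n = e.size
    emean = e.mean()
    evar = e.var(ddof=1) * (n - 1) / n  # match moment convention
    excess = evar - special.polygamma(1, d / 2)
    if excess <= 0:
        return EbParams(d0=float("inf"), s0_sq=float(np.exp(emean)))
    d0 = 2.0 * _trigamma_inverse(float(excess))
    s0_sq = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
    return EbParams(d0=float(d0), s0_sq=float(s0_sq))


def _design_matrix(n: int, indicator: np.ndarray,
                   covariates: pd.DataFrame | None) -> tuple[np.ndarray, list]:
    cols = [np.ones(n), indicator.astype(float)]
    names = ["intercept", "contrast"]
    if covariates is not None and covariates.shape[1] > 0:
        dm = pd.get_dummies(covariates, drop_first=True)
        for c in dm.columns:
            cols.append(dm[c].to_numpy(float))
            names.append(str(c))
    D = np.column_stack(cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        aliased = []
        for j in range(1, D.shape[1]):
            if np.linalg.matrix_rank(D[:, : j + 1]) < j + 1:
                aliased.append(names[j])
        raise ValueError(f"design is rank-deficient; aliased columns: {aliased}")
    return D, names


def moderated_de(expr: pd.DataFrame, groups, contrast: tuple[str, str],
                 covariates: pd.DataFrame | None = None,
                 fdr_cut: float = 0.05, log2fc_cut: float = 1.2,
                 eb: EbParams | None = None) -> pd.DataFrame:
    """Moderated differential expression, one disease stage vs control.

    ``expr`` is samples × genes on a log2 scale (see :func:`vst`);
    ``contrast`` is (disease_label, control_label).  Per gene, an OLS fit
    of expression on the disease indicator plus covariates gives the
    coefficient (log2FC) and residual variance; variances are moderated
    by the empirical-Bayes prior (fitted from all genes unless ``eb`` is
    supplied — pass ``EbParams(0, 1)`` for ordinary t-tests).

    Returns a table with gene, log2fc, t_mod, p, fdr, is_deg.
    """
    disease, control = contrast
    groups = pd.Series(np.asarray(groups), index=expr.index)
    mask = groups.isin([disease, control]).to_numpy()
    if mask.sum() < 3:
        raise ValueError("too few samples in the contrast")
    sub = expr.loc[mask]
    ind = (groups[mask] == disease).to_numpy()
    cov = covariates.loc[sub.index] if covariates is not None else None
    D, _ = _design_matrix(len(sub), ind, cov)
    n, p = D.shape
    d = n - p
    if d < 1:
        raise ValueError("no residual degrees of freedom")
    Y = sub.to_numpy(float)
    coef, _, _, _ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ coef
    s2 = (resid ** 2).sum(axis=0) / d
    xtx_inv = np.linalg.inv(D.T @ D)
    v_contrast = xtx_inv[1, 1]
    beta = coef[1]

    if eb is None:
        eb = fit_eb_params(s2[s2 > 0], d) if np.any(s2 > 0) else EbParams(0.0, 1.0)
    s2_post = eb.posterior_var(s2, d)
    df_total = d + (0 if np.isinf(eb.d0) else eb.d0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(s2_post * v_contrast)
    if np.isinf(eb.d0):
        pvals = 2 * sps.norm.sf(np.abs(t))
    else:
        pvals = 2 * sps.t.sf(np.abs(t), df=df_total)
    pvals = np.where(np.isfinite(t), pvals, 1.0)
    fdr = adjust_pvalues(pvals, "BH").adjusted
    out = pd.DataFrame({
        "gene": expr.columns, "log2fc": beta, "t_mod": t, "p": pvals,
        "fdr": fdr,
    })
    out["is_deg"] = (out["fdr"] < fdr_cut) & (out["log2fc"].abs() > log2fc_cut)
    return out


def enrichment_score(ranked_genes, scores, gene_set, weight: float = 1.0,
                     ) -> float:
    """Weighted KS running-sum enrichment score for one gene set.

    ``ranked_genes`` must already be ordered by decreasing score.  Hits
    advance the running sum by |score|^weight (normalized); misses
    retreat by 1/(N - N_hits).  ES is the extremum of the running sum.
    """
    members = set(gene_set)
    hits = np.fromiter((g in members for g in ranked_genes), bool,
                       count=len(ranked_genes))
    nh = hits.sum()
    n = hits.size
    if nh == 0 or nh == n:
        return 0.0
    w = np.abs(np.asarray(scores, float)) ** weight
    inc = np.where(hits, w, 0.0)
    denom = inc.sum()
    if denom == 0:  # all hit scores zero: fall back to unweighted
        inc = hits.astype(float)
        denom = nh
    steps = inc / denom - (~hits) / (n - nh)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(ranks: pd.Series, gene_sets: dict, weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 0,
                   min_size: int = 2) -> pd.DataFrame:
    """Preranked GSEA over a named collection of gene sets.

    ``ranks`` maps gene -> score; sets are intersected with the ranked
    universe and sets smaller than ``min_size`` after intersection are
    skipped.  The null permutes gene labels (equivalently: random sets of
    the same size); NES normalizes ES by the mean |null ES| of matching
    sign, and p-values are one-tailed against the matching-sign null.
    """
    ranks = ranks.sort_values(ascending=False)
    genes = list(ranks.index)
    scores = ranks.to_numpy(float)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gene_sets.items():
        inset = [g for g in members if g in ranks.index]
        if len(inset) < min_size:
            continue
        es = enrichment_score(genes, scores, inset, weight)
        k = len(inset)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm_set = rng.choice(len(genes), size=k, replace=False)
            null[b] = enrichment_score(genes, scores,
                                       [genes[i] for i in perm_set], weight)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same.size == 0:
            p = 1.0 / (n_perm + 1)
            nes = 0.0
        else:
            p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + same.size)
            nes = es / np.abs(same).mean()
        leading = _leading_edge(genes, scores, inset, weight, es)
        rows.append({"set_name": name, "es": es, "nes": nes, "p": p,
                     "size": k, "leading_edge": ",".join(leading)})
    out = pd.DataFrame(rows, columns=["set_name", "es", "nes", "p", "size",
                                      "leading_edge"])
    if len(out):
        out["fdr"] = adjust_pvalues(out["p"].to_numpy(), "BH").adjusted
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def _leading_edge(genes, scores, gene_set, weight, es):
    members = set(gene_set)
    hits = np.fromiter((g in members for g in genes), bool, count=len(genes))
    n, nh = hits.size, hits.sum()
    w = np.abs(np.asarray(scores, float)) ** weight
    inc = np.where(hits, w, 0.0)
    denom = inc.sum() or nh
    steps = inc / denom - (~hits) / (n - nh)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        return [g for g, h in zip(genes[: peak + 1], hits[: peak + 1]) if h]
    return [g for g, h in zip(genes[peak:], hits[peak:]) if h]


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
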