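"""Compositional preprocessing and community analysis of microbial profiles.

Microbial abundances from sequencing are compositional: only relative
information is meaningful, so the analysis lives in log-ratio space.  This
module provides the rare-taxon prevalence filter, the centred log-ratio
(CLR) transform, Shannon diversity, Aitchison distance (Euclidean distance
between CLR rows), principal coordinates analysis, a seeded PERMANOVA,
linear batch-effect removal, and per-taxon differential abundance by the
Wilcoxon rank-sum test with Benjamini–Hochberg control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa as _skbio_pcoa
from skbio import DistanceMatrix

from .stats_core import adjust_pvalues, wilcoxon_rank_sum

__all__ = [
    "MicrobialProfile",
    "rare_taxon_filter",
    "clr_transform",
    "shannon_index",
    "aitchison_distance",
    "pcoa",
    "permanova",
    "remove_batch",
    "differential_abundance",
]


@dataclass
class MicrobialProfile:
    """Sample × taxon abundance matrix with metadata and a form tag.

    ``form`` is one of ``counts``, ``relative``, ``clr``.  ``lineages``
    optionally maps taxon name -> ordered lineage (phylum..species) for
    rank materialization.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame | None = None
    form: str = "counts"
    lineages: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.form not in ("counts", "relative", "clr"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "counts" and (self.abundance.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self):
        return list(self.abundance.index)

    @property
    def taxa(self):
        return list(self.abundance.columns)

    def relative(self) -> "MicrobialProfile":
        if self.form == "relative":
            return self
        if self.form == "clr":
            raise ValueError("cannot recover relative abundances from CLR")
        a = self.abundance.to_numpy(float)
        rs = a.sum(axis=1, keepdims=True)
        if np.any(rs == 0):
            raise ValueError("all-zero sample row; cannot normalize")
        return replace(self, abundance=pd.DataFrame(
            a / rs, index=self.abundance.index, columns=self.abundance.columns),
            form="relative")

    def at_rank(self, level: int) -> "MicrobialProfile":
        """Materialize the profile at a lineage level by summing counts.

        ``level`` indexes the lineage list (0 = phylum .. 5 = species for
        six-level lineages).  Requires counts form and lineages.
        """
        if self.form != "counts":
            raise ValueError("rank materialization requires counts")
        if not self.lineages:
            raise ValueError("no lineage information attached")
        groups: dict[str, list] = {}
        for taxon in self.abundance.columns:
            lin = self.lineages.get(taxon, [taxon])
            key = lin[min(level, len(lin) - 1)]
            groups.setdefault(key, []).append(taxon)
        data = {k: self.abundance[cols].sum(axis=1) for k, cols in groups.items()}
        return replace(self, abundance=pd.DataFrame(data), lineages={})


def rare_taxon_filter(profile: MicrobialProfile, min_rel: float = 1e-4,
                      min_prev: float = 0.10, min_datasets: int = 2,
                      ) -> MicrobialProfile:
    """Drop rare taxa.

    A taxon is retained when it reaches relative abundance >= ``min_rel``
    in at least ``min_prev`` of the samples of at least one dataset, and
    is detected in at least ``min_datasets`` datasets.  With a single
    dataset the multi-dataset rule is relaxed (with a warning in the
    returned profile's meta — callers log it).
    """
    if profile.form != "counts":
        raise ValueError("rare_taxon_filter expects counts")
    if profile.abundance.empty:
        return profile
    rel = profile.relative().abundance
    meta = profile.meta
    if meta is None or "dataset" not in meta.columns:
        datasets = pd.Series("all", index=rel.index)
    else:
        datasets = meta.loc[rel.index, "dataset"]
    n_datasets = datasets.nunique()
    eff_min_ds = 1 if n_datasets == 1 else min_datasets

    reach = pd.Series(False, index=rel.columns)
    detected_in = pd.Series(0, index=rel.columns)
    for _, idx in rel.groupby(datasets).groups.items():
        sub = rel.loc[idx]
        prev = (sub >= min_rel).mean(axis=0)
        reach |= prev >= min_prev
        detected_in += (sub.sum(axis=0) > 0).astype(int)
    keep = reach & (detected_in >= eff_min_ds)
    return replace(profile, abundance=profile.abundance.loc[:, keep[keep].index],
                   lineages={t: l for t, l in profile.lineages.items()
                             if t in set(keep[keep].index)})


def default_pseudocount(profile: MicrobialProfile) -> float:
    """Half the smallest nonzero relative abundance, on the input scale."""
    a = profile.abundance.to_numpy(float)
    nz = a[a > 0]
    if nz.size == 0:
        raise ValueError("profile has no nonzero entries")
    if profile.form == "counts":
        return 0.5  # half of the smallest possible nonzero count
    return float(nz.min() / 2)


def clr_transform(profile: MicrobialProfile,
                  pseudocount: float | None = None) -> MicrobialProfile:
    """Centred log-ratio transform, per sample.

    x -> log((x + pseudocount) / g), g the geometric mean of
    (x + pseudocount).  Output rows sum to zero.  ``pseudocount`` defaults
    to half the smallest nonzero value (needed whenever zeros occur).
    """
    if profile.form == "clr":
        return profile
    a = profile.abundance.to_numpy(float)
    if pseudocount is None:
        pseudocount = default_pseudocount(profile)
    if pseudocount <= 0 and (a == 0).any():
        raise ValueError("zeros present: a positive pseudocount is required")
    x = a + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return replace(profile, abundance=pd.DataFrame(
        clr, index=profile.abundance.index, columns=profile.abundance.columns),
        form="clr")


def shannon_index(profile: MicrobialProfile, on_clr: bool = False) -> pd.Series:
    """Shannon diversity H = −Σ p_i ln p_i per sample, in nats.

    Computed on relative abundances.  ``on_clr=True`` instead min-shifts
    each CLR row to non-negative and renormalizes before applying the
    formula — a strict "diversity of the CLR profile" variant for
    fidelity with workflows that phrase it that way.
    """
    if on_clr:
        clr = profile if profile.form == "clr" else clr_transform(profile)
        a = clr.abundance.to_numpy(float)
        a = a - a.min(axis=1, keepdims=True)
        rs = a.sum(axis=1, keepdims=True)
        rs[rs == 0] = np.nan
        p = a / rs
    else:
        p = profile.relative().abundance.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    h = np.where(np.isnan(p).all(axis=1), np.nan, h)
    return pd.Series(h, index=profile.abundance.index, name="shannon")


def aitchison_distance(profile: MicrobialProfile,
                       pseudocount: float | None = None) -> pd.DataFrame:
    """Euclidean distance between CLR-transformed samples."""
    clr = profile if profile.form == "clr" else clr_transform(profile, pseudocount)
    d = squareform(pdist(clr.abundance.to_numpy(float), metric="euclidean"))
    return pd.DataFrame(d, index=clr.abundance.index, columns=clr.abundance.index)


def pcoa(distance: pd.DataFrame, k: int = 2):
    """Classical metric multidimensional scaling of a distance matrix.

    Double-centres the squared distances and eigendecomposes; axes are
    ordered by decreasing eigenvalue and axes with negative eigenvalues
    are dropped (their eigenvalues are still reported).

    Returns (coordinates DataFrame with up to k columns, eigenvalues array).
    """
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    index = distance.index if isinstance(distance, pd.DataFrame) else range(len(d))
    if np.allclose(d, 0):
        return (pd.DataFrame(np.zeros((d.shape[0], 0)), index=index),
                np.zeros(d.shape[0]))
    res = _skbio_pcoa(DistanceMatrix(d, ids=[str(i) for i in index]),
                      method="eigh", number_of_dimensions=d.shape[0])
    eigvals = res.eigvals.to_numpy()
    pos = eigvals > 1e-12
    coords = res.samples.to_numpy()[:, pos][:, :k]
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=index, columns=cols), eigvals


def permanova(distance: pd.DataFrame, labels, n_perm: int = 999,
              seed: int = 0) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F from among/within sums of squared distances; the p-value is
    the standard conservative estimator (1 + #{F_perm >= F}) / (1 + n_perm)
    with seeded label permutations.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    d = np.asarray(distance, dtype=float)
    labels = np.asarray(labels)
    if d.shape[0] != labels.size:
        raise ValueError("labels must match the distance matrix")
    uniq, inv = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    n = labels.size
    d2 = d ** 2
    sst = d2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(inv_labels):
        ssw = 0.0
        for g in range(uniq.size):
            idx = np.flatnonzero(inv_labels == g)
            if idx.size < 1:
                return np.nan
            sub = d2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        ssa = sst - ssw
        df_a, df_w = uniq.size - 1, n - uniq.size
        return (ssa / df_a) / (ssw / df_w)

    f_obs = pseudo_f(inv)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(inv)
        if pseudo_f(perm) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


def remove_batch(matrix: pd.DataFrame, batch, covariates: pd.DataFrame | None = None,
                 ) -> pd.DataFrame:
    """Subtract fitted batch terms from each feature (limma-style).

    Fits, per feature, a linear model with sum-to-zero batch indicators
    plus any covariates to preserve, and subtracts only the fitted batch
    component, so feature means and covariate-driven signal survive.
    """
    X = matrix.to_numpy(float)
    batch = pd.Categorical(pd.Series(batch, index=matrix.index))
    k = len(batch.categories)
    if k < 2:
        return matrix.copy()
    # sum-to-zero contrasts: k-1 columns
    B = np.zeros((len(matrix), k - 1))
    codes = batch.codes
    for j in range(k - 1):
        B[codes == j, j] = 1.0
    B[codes == k - 1, :] = -1.0
    design = [np.ones((len(matrix), 1)), B]
    if covariates is not None and covariates.shape[1] > 0:
        C = pd.get_dummies(covariates.loc[matrix.index], drop_first=True)
        design.append(C.to_numpy(float))
    D = np.hstack(design)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError(
            "batch is confounded with a preserved covariate (design is "
            "rank-deficient)")
    coef, *_ = np.linalg.lstsq(D, X, rcond=None)
    batch_cols = slice(1, k)
    fitted_batch = D[:, batch_cols] @ coef[batch_cols]
    return pd.DataFrame(X - fitted_batch, index=matrix.index,
                        columns=matrix.columns)


def differential_abundance(profile: MicrobialProfile, groups, control: str,
                           fdr_cut: float = 0.05, log2fc_cut: float = 1.0,
                           ) -> pd.DataFrame:
    """Per-taxon Wilcoxon rank-sum of disease vs control on CLR values.

    log2FC is the mean CLR difference rescaled to base 2; significance
    requires FDR < ``fdr_cut`` and |log2FC| > ``log2fc_cut``.  Returns one
    table with all non-control groups compared against the control.
    """
    if profile.form != "clr":
        raise ValueError("differential_abundance expects a CLR profile")
    groups = pd.Series(np.asarray(groups), index=profile.abundance.index)
    if control not in set(groups):
        raise ValueError(f"control label {control!r} absent from groups")
    rows = []
    a = profile.abundance
    ctrl = a.loc[groups == control]
    for g in [x for x in pd.unique(groups) if x != control]:
        dis = a.loc[groups == g]
        ps, fcs = [], []
        for taxon in a.columns:
            res = wilcoxon_rank_sum(dis[taxon].to_numpy(), ctrl[taxon].to_numpy())
            ps.append(res.p_value)
            fcs.append((dis[taxon].mean() - ctrl[taxon].mean()) / np.log(2))
        fdr = adjust_pvalues(np.array(ps), "BH").adjusted
        for taxon, p, q, fc in zip(a.columns, ps, fdr, fcs):
            rows.append({
                "group": g, "taxon": taxon, "log2fc": fc, "p": p, "fdr": q,
                "significant": bool(q < fdr_cut and abs(fc) > log2fc_cut),
            })
    return pd.DataFrame(rows)
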