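"""Host-gene <- microbiota interaction networks by penalized regression.

For each host gene (response) and a merged, standardized taxa matrix
(predictors spanning phylum to species), the chain is:

1. Lasso with the penalty chosen by leave-one-out cross-validation;
2. significance by multi sample-splitting: the model selects a support on
   one random half of the samples, ordinary least squares on the other
   half yields Bonferroni-scaled p-values for the selected taxa, and the
   per-taxon p is aggregated over splits by the scaled-median rule
   (gamma = 0.5), then Benjamini–Hochberg adjusted across the gene's taxa;
3. stability selection: the Lasso is refitted on random half subsamples
   with the penalty jittered multiplicatively, and a taxon's stability
   frequency is the fraction of refits in which its coefficient is
   nonzero;
4. retained edges need FDR < 0.01 and stability frequency >= 0.6; their
   strength is the Spearman correlation of the raw pair, and a
   multivariate regression on age/sex/platform supplies a
   confounder-adjusted p.

Networks are built per disease stage on that stage's samples only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

from .stats_core import adjust_pvalues, spearman

__all__ = [
    "LassoFit",
    "build_taxa_matrix",
    "lambda_max",
    "lasso_path_fit",
    "select_lambda_loocv",
    "interaction_pvalues",
    "stability_selection",
    "edge_strength",
    "confounder_adjust",
    "identify_interactions",
    "build_stage_networks",
]


@dataclass
class LassoFit:
    gene: str
    lam: float
    beta: pd.Series
    intercept: float

    @property
    def support(self) -> list:
        return list(self.beta.index[self.beta != 0])


def build_taxa_matrix(profiles: dict) -> pd.DataFrame:
    """Concatenate per-rank CLR profiles into one standardized matrix.

    ``profiles`` maps rank name -> samples × taxa DataFrame (same sample
    index).  Columns are prefixed ``rank|name`` so duplicates across
    ranks stay distinct, then standardized to zero mean, unit variance;
    constant columns are dropped.
    """
    blocks = []
    for rank, df in profiles.items():
        block = df.copy()
        block.columns = [f"{rank}|{c}" for c in df.columns]
        blocks.append(block)
    merged = pd.concat(blocks, axis=1)
    sd = merged.std(axis=0, ddof=0)
    keep = sd > 0
    merged = merged.loc[:, keep]
    return (merged - merged.mean(axis=0)) / merged.std(axis=0, ddof=0)


def lambda_max(y: np.ndarray, X: np.ndarray) -> float:
    """Smallest penalty at which the Lasso solution is all-zero."""
    n = len(y)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / n)


def lasso_path_fit(y, X, lam: float, gene: str = "") -> LassoFit:
    """Single Lasso fit, objective (1/2n)||y − Xb − b0||^2 + lam ||b||_1."""
    Xv = np.asarray(X, float)
    yv = np.asarray(y, float)
    if not (np.all(np.isfinite(Xv)) and np.all(np.isfinite(yv))):
        raise ValueError("non-finite input")
    cols = X.columns if isinstance(X, pd.DataFrame) else range(Xv.shape[1])
    if lam <= 0:
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(yv)), Xv]), yv, rcond=None)
        return LassoFit(gene, 0.0, pd.Series(beta[1:], index=cols),
                        float(beta[0]))
    model = Lasso(alpha=lam, fit_intercept=True, tol=1e-7, max_iter=50_000)
    with warnings.catch_warnings():
        # near-zero penalties on tiny subsamples stop at the iteration cap
        # with duality gaps ~1e-6; that accuracy is ample here
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xv, yv)
    return LassoFit(gene, float(lam), pd.Series(model.coef_, index=cols),
                    float(model.intercept_))


def _lambda_grid(y, X, n_lambdas: int = 30, ratio: float = 1e-3) -> np.ndarray:
    lm = lambda_max(np.asarray(y, float), np.asarray(X, float))
    if lm <= 0:
        lm = 1e-6
    return np.geomspace(lm, lm * ratio, n_lambdas)


def select_lambda_loocv(y, X, lambdas=None) -> float:
    """Penalty minimizing mean leave-one-out squared prediction error.

    The grid is log-spaced from lambda_max down to lambda_max/1000; ties
    resolve to the larger (sparser) penalty.  Deterministic.
    """
    yv = np.asarray(y, float)
    Xv = np.asarray(X, float)
    n = len(yv)
    if n < 3:
        raise ValueError("need n >= 3 for leave-one-out")
    if lambdas is None:
        lambdas = _lambda_grid(yv, Xv)
    lambdas = np.sort(np.asarray(lambdas, float))[::-1]
    errs = np.zeros((n, lambdas.size))
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        Xi, yi = Xv[mask], yv[mask]
        mu_x, mu_y = Xi.mean(0), yi.mean()
        # lasso_path works on centered data without intercept
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(Xi - mu_x, yi - mu_y, alphas=lambdas,
                                     tol=1e-6, max_iter=20_000)
        pred = (Xv[i] - mu_x) @ coefs + mu_y
        errs[i] = (yv[i] - pred) ** 2
    mean_err = errs.mean(axis=0)
    best = mean_err.min()
    # scan from the largest penalty down; first attaining the minimum wins
    idx = int(np.flatnonzero(mean_err <= best + 1e-12)[0])
    return float(lambdas[idx])


def interaction_pvalues(y, X, lam: float | None = None, n_splits: int = 50,
                        seed: int = 0) -> pd.Series:
    """Multi sample-splitting p-values for each predictor.

    Each split selects a Lasso support on one half (penalty ``lam``
    rescaled is used when given, otherwise chosen by cross-validation on
    that half) and computes OLS p-values on the other half, Bonferroni
    scaled by the support size; unselected predictors get p = 1.  The
    per-predictor aggregate is the scaled median min(1, 2 * median(p)).
    """
    yv = np.asarray(y, float)
    Xv = np.asarray(X, float)
    n, p = Xv.shape
    if n < 20:
        raise ValueError("multi sample-splitting needs n >= 20")
    cols = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(p)
    rng = np.random.default_rng(seed)
    pmat = np.ones((n_splits, p))
    for b in range(n_splits):
        perm = rng.permutation(n)
        half = n // 2
        a_idx, b_idx = perm[:half], perm[half:]
        Xa, ya = Xv[a_idx], yv[a_idx]
        Xb, yb = Xv[b_idx], yv[b_idx]
        if lam is None:
            lam_b = select_lambda_loocv(ya, Xa,
                                        _lambda_grid(ya, Xa, n_lambdas=15))
        else:
            lam_b = lam
        cap = len(b_idx) - 2
        for _ in range(30):
            fit = lasso_path_fit(ya, Xa, lam_b)
            sel = np.flatnonzero(fit.beta.to_numpy() != 0)
            if sel.size <= cap:
                break
            lam_b *= 1.5  # tighten until the support fits the test half
        if sel.size == 0:
            continue
        D = np.column_stack([np.ones(len(b_idx)), Xb[:, sel]])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            continue
        coef, _, _, _ = np.linalg.lstsq(D, yb, rcond=None)
        resid = yb - D @ coef
        dof = len(b_idx) - D.shape[1]
        if dof < 1:
            continue
        s2 = resid @ resid / dof
        cov = s2 * np.linalg.inv(D.T @ D)
        t = coef[1:] / np.sqrt(np.diag(cov)[1:])
        pv = 2 * sps.t.sf(np.abs(t), dof)
        pmat[b, sel] = np.minimum(1.0, pv * sel.size)
    agg = np.minimum(1.0, 2.0 * np.median(pmat, axis=0))
    return pd.Series(agg, index=cols)


def stability_selection(y, X, lam: float, n_iter: int = 100,
                        subsample: float = 0.5, perturb: float = 0.2,
                        seed: int = 0) -> pd.Series:
    """Selection frequency over subsampled, penalty-jittered refits."""
    yv = np.asarray(y, float)
    Xv = np.asarray(X, float)
    n, p = Xv.shape
    m = int(round(n * subsample))
    if m < 10:
        raise ValueError("subsample too small (need >= 10 samples)")
    cols = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(p)
    rng = np.random.default_rng(seed)
    counts = np.zeros(p)
    for _ in range(n_iter):
        idx = rng.choice(n, size=m, replace=False)
        lam_i = lam * np.exp(rng.uniform(-perturb, perturb))
        fit = lasso_path_fit(yv[idx], Xv[idx], lam_i)
        counts += (fit.beta.to_numpy() != 0)
    return pd.Series(counts / n_iter, index=cols)


def edge_strength(gene_values, taxon_values) -> float:
    res = spearman(gene_values, taxon_values)
    return float("nan") if res.undefined else float(res.statistic)


def confounder_adjust(gene_values, taxon_values,
                      covariates: pd.DataFrame | None) -> float:
    """p-value of the taxon term in gene ~ taxon + covariates."""
    y = np.asarray(gene_values, float)
    x = np.asarray(taxon_values, float)
    cols = [np.ones_like(x), x]
    names = ["intercept", "taxon"]
    if covariates is not None and covariates.shape[1] > 0:
        dm = pd.get_dummies(covariates, drop_first=True)
        for c in dm.columns:
            cols.append(dm[c].to_numpy(float))
            names.append(str(c))
    D = np.column_stack(cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        aliased = [names[j] for j in range(D.shape[1])
                   if np.linalg.matrix_rank(D[:, : j + 1]) < j + 1]
        raise ValueError(f"collinear covariates: {aliased}")
    coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    dof = len(y) - D.shape[1]
    if dof < 1:
        raise ValueError("no residual degrees of freedom")
    s2 = resid @ resid / dof
    se = np.sqrt(s2 * np.linalg.inv(D.T @ D)[1, 1])
    t = coef[1] / se
    return float(2 * sps.t.sf(abs(t), dof))


def identify_interactions(expr: pd.DataFrame, taxa: pd.DataFrame,
                          stage: str = "", covariates: pd.DataFrame | None = None,
                          fdr_cut: float = 0.01, stability_cut: float = 0.6,
                          n_splits: int = 50, n_iter: int = 100,
                          seed: int = 0) -> pd.DataFrame:
    """Run the full chain for every gene of one stage.

    ``expr`` (samples × genes) and ``taxa`` (samples × merged taxa,
    standardized) must share their sample index.  Returns the edge table
    with columns stage, gene, taxon, beta, p, fdr, stability_freq, rho,
    adj_p; only edges passing both the FDR and stability cuts are kept.
    """
    if not expr.index.equals(taxa.index):
        raise ValueError("expr and taxa must share the sample index")
    ss = np.random.SeedSequence(seed)
    rows = []
    Xv = taxa.to_numpy(float)
    for g, gene in enumerate(expr.columns):
        y = expr[gene].to_numpy(float)
        child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=(g,))
        s_split, s_stab = child.generate_state(2) % (2**31)
        lam = select_lambda_loocv(y, taxa)
        fit = lasso_path_fit(y, taxa, lam, gene)
        pvals = interaction_pvalues(y, taxa, lam=lam, n_splits=n_splits,
                                    seed=int(s_split))
        fdr = pd.Series(adjust_pvalues(pvals.to_numpy(), "BH").adjusted,
                        index=pvals.index)
        candidates = fdr.index[fdr < fdr_cut]
        if len(candidates) == 0:
            continue
        freq = stability_selection(y, taxa, lam, n_iter=n_iter,
                                   seed=int(s_stab))
        for taxon in candidates:
            if freq[taxon] < stability_cut:
                continue
            rho = edge_strength(y, taxa[taxon].to_numpy())
            adj_p = (confounder_adjust(y, taxa[taxon].to_numpy(), covariates)
                     if covariates is not None else float("nan"))
            rows.append({
                "stage": stage, "gene": gene, "taxon": taxon,
                "beta": float(fit.beta.get(taxon, 0.0)),
                "p": float(pvals[taxon]), "fdr": float(fdr[taxon]),
                "stability_freq": float(freq[taxon]), "rho": rho,
                "adj_p": adj_p,
            })
    return pd.DataFrame(rows, columns=["stage", "gene", "taxon", "beta", "p",
                                       "fdr", "stability_freq", "rho",
                                       "adj_p"])


def build_stage_networks(edges_by_stage: dict) -> dict:
    """Summarize per-stage edge tables and their cross-stage overlaps."""
    summary = {"stages": {}, "intersections": {}}
    sets = {}
    for stage, df in edges_by_stage.items():
        pairs = set(zip(df["gene"], df["taxon"])) if len(df) else set()
        sets[stage] = pairs
        degree = {}
        for g, t in pairs:
            degree[g] = degree.get(g, 0) + 1
            degree[t] = degree.get(t, 0) + 1
        taxa_deg = sorted(
            ((t, d) for t, d in degree.items()
             if len(df) and t in set(df["taxon"])),
            key=lambda kv: -kv[1])
        summary["stages"][stage] = {
            "n_edges": len(pairs),
            "n_genes": len({g for g, _ in pairs}),
            "n_taxa": len({t for _, t in pairs}),
            "degree": degree,
            "top_taxa": taxa_deg[:10],
        }
    names = list(sets)
    from itertools import combinations
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[s] for s in combo))
            summary["intersections"]["&".join(combo)] = sorted(
                [list(e) for e in inter])
    return summary
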