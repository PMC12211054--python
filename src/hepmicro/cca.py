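"""Sparse canonical correlation between gene and taxa matrices.

Penalized matrix decomposition of the cross-product matrix C = Z'X:
alternating maximization of u'Cv under unit L2 norms and L1 budgets on
each side, where each update is a soft-thresholded projection (the
threshold found by bisection so the L1 constraint is met exactly), with
rank-one deflation of C between components.  Components couple a sparse
set of taxa (u) with a sparse set of genes (v); cluster membership is the
nonzero support, and cluster genes are annotated by hypergeometric
pathway enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import adjust_pvalues, hypergeometric_enrichment

__all__ = [
    "CcaComponent",
    "InteractionCluster",
    "sparse_cca",
    "extract_clusters",
    "enrich_clusters",
]


@dataclass
class CcaComponent:
    index: int
    u: pd.Series  # taxa weights
    v: pd.Series  # gene weights
    canonical_correlation: float
    penalty_u: float
    penalty_v: float
    degenerate: bool = False
    objective_trace: list = field(default_factory=list)


@dataclass
class InteractionCluster:
    index: int
    genes: pd.Series
    taxa: pd.Series
    enriched_pathways: pd.DataFrame = field(default_factory=pd.DataFrame)


def _soft(a: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - lam, 0.0)


def _l1_projected(a: np.ndarray, c: float) -> np.ndarray:
    """Soft-threshold and L2-normalize so that ||out||_2 = 1, ||out||_1 <= c.

    The threshold is located by bisection on the L1 norm of the
    normalized vector, which decreases monotonically in the threshold.
    """
    norm = np.linalg.norm(a)
    if norm == 0:
        return a
    out = a / norm
    if np.sum(np.abs(out)) <= c:
        return out
    lo, hi = 0.0, np.abs(a).max()
    for _ in range(80):
        mid = (lo + hi) / 2
        s = _soft(a, mid)
        ns = np.linalg.norm(s)
        if ns == 0:
            hi = mid
            continue
        if np.sum(np.abs(s / ns)) > c:
            lo = mid
        else:
            hi = mid
    s = _soft(a, hi)
    ns = np.linalg.norm(s)
    return s / ns if ns > 0 else s


def _check_standardized(M: np.ndarray, name: str):
    mu = np.abs(M.mean(axis=0)).max()
    sd = M.std(axis=0, ddof=0)
    if mu > 1e-6 or np.abs(sd[sd > 0] - 1).max() > 1e-6:
        raise ValueError(f"{name} must be column-standardized")


def sparse_cca(X: pd.DataFrame, Z: pd.DataFrame, penalty_x: float | None = None,
               penalty_z: float | None = None, K: int = 10,
               max_iter: int = 200, tol: float = 1e-8, seed: int = 0,
               drop_below: float = 0.1) -> list:
    """Fit K sparse canonical components between genes (X) and taxa (Z).

    ``penalty_x``/``penalty_z`` are the L1 budgets c_v, c_u in
    [1, sqrt(dim)]; the default 0.3 * sqrt(dim) gives mid-range sparsity.
    Components with |canonical correlation| below ``drop_below`` are
    flagged degenerate and dropped from the returned list.  Sign
    indeterminacy is resolved by making the largest-|weight| taxa entry
    positive.
    """
    Xv = X.to_numpy(float)
    Zv = Z.to_numpy(float)
    _check_standardized(Xv, "X")
    _check_standardized(Zv, "Z")
    p, q = Xv.shape[1], Zv.shape[1]
    cv = penalty_x if penalty_x is not None else 0.3 * np.sqrt(p)
    cu = penalty_z if penalty_z is not None else 0.3 * np.sqrt(q)
    cv = float(np.clip(cv, 1.0, np.sqrt(p)))
    cu = float(np.clip(cu, 1.0, np.sqrt(q)))
    C = Zv.T @ Xv  # taxa × genes cross-product
    components = []
    for k in range(K):
        if np.allclose(C, 0):
            break
        # initialize from the leading singular vectors
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        u = U[:, 0]
        v = Vt[0]
        obj_prev = -np.inf
        trace = []
        for _ in range(max_iter):
            u = _l1_projected(C @ v, cu)
            v = _l1_projected(C.T @ u, cv)
            obj = float(u @ C @ v)
            trace.append(obj)
            if abs(obj - obj_prev) < tol * max(1.0, abs(obj)):
                break
            obj_prev = obj
        if np.all(u == 0) or np.all(v == 0):
            break
        # clean numerical dust so supports are exact, then fix the sign
        u[np.abs(u) < 1e-12] = 0.0
        v[np.abs(v) < 1e-12] = 0.0
        if u[np.argmax(np.abs(u))] < 0:
            u, v = -u, -v
        zu, xv = Zv @ u, Xv @ v
        if zu.std() == 0 or xv.std() == 0:
            cor = 0.0
        else:
            cor = float(np.corrcoef(zu, xv)[0, 1])
        comp = CcaComponent(
            index=k + 1,
            u=pd.Series(u, index=Z.columns),
            v=pd.Series(v, index=X.columns),
            canonical_correlation=cor,
            penalty_u=cu, penalty_v=cv,
            degenerate=abs(cor) < drop_below,
            objective_trace=trace,
        )
        d = float(u @ C @ v)
        C = C - d * np.outer(u, v)
        if not comp.degenerate:
            components.append(comp)
    return components


def extract_clusters(components, weight_floor: float = 0.0) -> list:
    """Cluster membership: features with |weight| strictly above the floor."""
    clusters = []
    for comp in components:
        genes = comp.v[comp.v.abs() > weight_floor]
        taxa = comp.u[comp.u.abs() > weight_floor]
        clusters.append(InteractionCluster(comp.index, genes, taxa))
    return clusters


def enrich_clusters(clusters, gene_sets: dict, universe, fdr_cut: float = 0.05,
                    ) -> list:
    """Hypergeometric pathway enrichment of each cluster's genes.

    ``universe`` is the background gene list; sets are intersected with it.
    Pathways are BH-adjusted within cluster and kept at FDR < ``fdr_cut``.
    """
    universe = set(universe)
    n_universe = len(universe)
    out = []
    for cl in clusters:
        members = set(cl.genes.index) & universe
        if not members:
            out.append(cl)
            continue
        rows = []
        for name, genes in gene_sets.items():
            gset = set(genes) & universe
            if not gset:
                continue
            hits = len(members & gset)
            p = hypergeometric_enrichment(hits, len(members), len(gset),
                                          n_universe)
            rows.append({"pathway": name, "hits": hits, "set_size": len(gset),
                         "p": p})
        df = pd.DataFrame(rows, columns=["pathway", "hits", "set_size", "p"])
        if len(df):
            df["fdr"] = adjust_pvalues(df["p"].to_numpy(), "BH").adjusted
            df = df.loc[df["fdr"] < fdr_cut].reset_index(drop=True)
        else:
            df["fdr"] = pd.Series(dtype=float)
        out.append(InteractionCluster(cl.index, cl.genes, cl.taxa, df))
    return out
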