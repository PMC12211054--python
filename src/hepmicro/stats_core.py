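"""Shared statistical primitives for the pipeline.

Rank tests, exact tests, multiple-testing control and correlation, with
deterministic tie handling (midranks plus variance tie-correction) and
explicit degenerate-input behaviour.  Every downstream stage — taxon
decontamination, differential abundance, interaction strength, enrichment —
routes its hypothesis tests through this module so that sidedness and
correction conventions are fixed in one place.

Conventions
-----------
* Two-sided p-values everywhere, except enrichment tests which are
  upper-tail one-sided.
* Undefined statistics (e.g. correlation of a constant vector) are
  *flagged*, never silently coerced to 0: ``TestResult.undefined`` is True
  and the p-value is NaN.  Downstream significance filters treat an
  undefined result as non-significant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "AdjustedPvalues",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "fisher_exact",
    "hypergeometric_enrichment",
    "spearman",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    undefined: bool = False

    @property
    def significant_at(self):  # pragma: no cover - convenience only
        return lambda alpha: (not self.undefined) and self.p_value < alpha


@dataclass(frozen=True)
class AdjustedPvalues:
    raw: np.ndarray
    adjusted: np.ndarray
    method: str


def _check_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum test.

    Exact enumeration when both groups have at most 8 observations and no
    ties are present; otherwise the tie-corrected normal approximation
    (with continuity correction).  Completely tied data yield p = 1.
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, (x.size, y.size), "wilcoxon_rank_sum")
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 8 and y.size <= 8 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return TestResult(
        float(res.statistic), float(res.pvalue), (x.size, y.size), "wilcoxon_rank_sum"
    )


def kruskal_wallis(groups) -> TestResult:
    """Kruskal–Wallis H test (tie-corrected) with chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least two groups")
    arrays = [_check_vector(g, f"group {i}") for i, g in enumerate(groups)]
    pooled = np.concatenate(arrays)
    ns = tuple(a.size for a in arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, ns, "kruskal_wallis")
    stat, p = sps.kruskal(*arrays)
    return TestResult(float(stat), float(p), ns, "kruskal_wallis")


def fisher_exact(table, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 contingency table.

    ``alternative`` may be ``"two-sided"`` or ``"greater"`` (enrichment of
    the [0, 0] cell).
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0):
        raise ValueError("table cells must be non-negative")
    if table.sum() < 1:
        raise ValueError("table total must be at least 1")
    stat, p = sps.fisher_exact(table, alternative=alternative)
    return TestResult(
        float(stat), float(p), tuple(int(v) for v in table.sum(axis=1)), "fisher_exact"
    )


def hypergeometric_enrichment(
    hits: int, cluster_size: int, set_size: int, universe: int
) -> float:
    """Upper-tail P(X >= hits) with X ~ Hypergeometric(universe, set_size, cluster_size).

    The canonical over-representation p-value: drawing ``cluster_size``
    genes from a universe containing ``set_size`` pathway members, the
    probability of observing at least ``hits`` members.
    """
    if min(hits, cluster_size, set_size, universe) < 0:
        raise ValueError("counts must be non-negative")
    if hits > min(cluster_size, set_size):
        raise ValueError("hits cannot exceed min(cluster_size, set_size)")
    if max(cluster_size, set_size) > universe:
        raise ValueError("cluster_size and set_size cannot exceed universe")
    # survival function is P(X > k), so shift by one
    return float(sps.hypergeom.sf(hits - 1, universe, set_size, cluster_size))


def _exact_spearman_p(rho: float, n: int) -> float:
    """Two-sided permutation p for Spearman rho by full enumeration (n <= 7)."""
    base = np.arange(n, dtype=float)
    target = abs(rho)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = sps.spearmanr(base, np.array(perm, dtype=float)).statistic
        if abs(r) >= target - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x, y) -> TestResult:
    """Tie-adjusted Spearman rank correlation.

    Exact permutation p-value for n <= 7 with untied data; otherwise the
    t-distribution approximation.  Constant input yields a flagged
    undefined result rather than a silent zero.
    """
    x = _check_vector(x, "x")
    y = _check_vector(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    if x.size < 3:
        raise ValueError("spearman requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(
            float("nan"), float("nan"), (x.size,), "spearman", undefined=True
        )
    rho = float(sps.spearmanr(x, y).statistic)
    no_ties = np.unique(x).size == x.size and np.unique(y).size == y.size
    if x.size <= 7 and no_ties:
        p = _exact_spearman_p(rho, x.size)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return TestResult(rho, p, (x.size,), "spearman")


def adjust_pvalues(p, method: str = "BH") -> AdjustedPvalues:
    """Benjamini–Hochberg step-up or Bonferroni adjustment."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("BH", "Bonferroni"):
        raise ValueError("method must be 'BH' or 'Bonferroni'")
    if p.size == 0:
        return AdjustedPvalues(p, p.copy(), method)
    mask = np.isfinite(p)
    adjusted = np.full(p.shape, np.nan)
    if mask.any():
        sm_method = "fdr_bh" if method == "BH" else "bonferroni"
        adjusted[mask] = multipletests(p[mask], method=sm_method)[1]
    return AdjustedPvalues(p, adjusted, method)
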