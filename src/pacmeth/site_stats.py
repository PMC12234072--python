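"""Site-comparison statistics: DMR-count chi-square, direction-ratio
Fisher tests, PAC class summaries and LMW:HMW ratio tests, PCA of
methylation levels, and ward.D hierarchical clustering.
"""

from __future__ import annotations

import logging
import math
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .diff_meth import adjust_bh
from .meth_io import UnitedMatrix

__all__ = [
    "two_prop_chisq",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "summarize_pac",
    "lmw_hmw_ratio",
    "kruskal_wallis",
    "pairwise_wilcoxon_bh",
    "pca_percent_meth",
    "hclust_ward",
    "cut_tree",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# proportion and count tests


def two_prop_chisq(x1: int, x2: int, n: float, correction: bool = False) -> tuple[float, float]:
    """Pooled two-proportion Pearson chi-square (df = 1).

    Compares x1/n vs x2/n (e.g. DMR counts against the number of possible
    DMR slots). No continuity correction by default; ``correction=True``
    applies Yates. As n grows the statistic converges to
    (x1 - x2)^2 / (x1 + x2).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if x1 == 0 and x2 == 0:
        return 0.0, 1.0
    p1, p2 = x1 / n, x2 / n
    pbar = (x1 + x2) / (2.0 * n)
    d = abs(p1 - p2)
    if correction:
        d = max(0.0, d - 1.0 / n)
    chi2 = d**2 / (pbar * (1 - pbar) * 2.0 / n)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@lru_cache(maxsize=100_000)
def _fisher_numerators(r1: int, r2: int, c1: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Support and exact integer numerators C(r1,a) C(r2,c1-a) of the
    hypergeometric table probabilities with margins (r1, r2, c1)."""
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = tuple(range(lo, hi + 1))
    nums = tuple(math.comb(r1, a) * math.comb(r2, c1 - a) for a in support)
    return support, nums


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric probabilities of
    all tables (at fixed margins) no more probable than the observed one.

    Computed in exact integer arithmetic, so probability ties are handled
    without floating-point tolerance.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 integer array")
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    if r1 == 0 or r2 == 0 or c1 == 0 or int(t[:, 1].sum()) == 0:
        return 1.0
    support, nums = _fisher_numerators(r1, r2, c1)
    obs = nums[support.index(a)]
    total = sum(nums)
    p_num = sum(v for v in nums if v <= obs)
    return p_num / total


def fisher_exact_rxc(table, rounds: int = 10_000, seed: int = 0) -> float:
    """Monte-Carlo Fisher exact p for a 2xK table (K <= 5), margins fixed.

    Simulated tables are multivariate-hypergeometric draws of the first
    row; p = (1 + #{P(sim) <= P(obs)}) / (1 + rounds) with a small
    relative guard against floating ties.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] > 5 or (t < 0).any():
        raise ValueError("table must be a non-negative 2xK integer array, K <= 5")
    col_tot = t.sum(axis=0)
    n1 = int(t[0].sum())
    if n1 == 0 or int(t[1].sum()) == 0 or (col_tot == 0).all():
        return 1.0

    from scipy.special import gammaln

    def logprob(row1: np.ndarray) -> float:
        row2 = col_tot - row1
        return float(
            (gammaln(col_tot + 1) - gammaln(row1 + 1) - gammaln(row2 + 1)).sum()
        )

    lp_obs = logprob(t[0])
    rng = np.random.default_rng(seed)
    sims = rng.multivariate_hypergeometric(col_tot, n1, size=rounds)
    lps = (
        gammaln(col_tot + 1)[None, :] - gammaln(sims + 1) - gammaln(col_tot - sims + 1)
    ).sum(axis=1)
    hits = int(np.count_nonzero(lps <= lp_obs + 1e-9))
    return (1.0 + hits) / (1.0 + rounds)


# ---------------------------------------------------------------------------
# PAC summaries and ratio tests

PAC_CLASSES = [
    "ΣParent LMW",
    "ΣAlkylated LMW",
    "ΣParent HMW",
    "ΣAlkylated HMW",
    "ΣParent HET",
    "ΣAlkylated HET",
    "ΣUSEPA16",
    "ΣAlkylated PAC",
    "ΣPAC",
]


def _per_bird_class_sums(table: pd.DataFrame) -> pd.DataFrame:
    t = table
    lmw = (t["rings"] <= 3) & ~t["heterocyclic"]
    hmw = (t["rings"] >= 4) & ~t["heterocyclic"]
    masks = {
        "ΣParent LMW": lmw & ~t["alkylated"],
        "ΣAlkylated LMW": lmw & t["alkylated"],
        "ΣParent HMW": hmw & ~t["alkylated"],
        "ΣAlkylated HMW": hmw & t["alkylated"],
        "ΣParent HET": t["heterocyclic"] & ~t["alkylated"],
        "ΣAlkylated HET": t["heterocyclic"] & t["alkylated"],
        "ΣUSEPA16": t["usepa16"],
        "ΣAlkylated PAC": t["alkylated"] & ~t["heterocyclic"],
        "ΣPAC": pd.Series(True, index=t.index),
    }
    out = {}
    for cls, mask in masks.items():
        out[cls] = t.loc[mask].groupby("bird_id")["concentration"].sum().reindex(
            t["bird_id"].unique(), fill_value=0.0
        )
    return pd.DataFrame(out)


def summarize_pac(table: pd.DataFrame, site: str) -> pd.DataFrame:
    """Mean/median/min/max/SD (sample SD, n-1) of per-bird class sums for
    one site: parent/alkylated x LMW/HMW, heterocyclics, USEPA16 and
    totals."""
    sub = table[table["site"] == site]
    if sub.empty:
        raise ValueError(f"no birds for site {site!r}")
    sums = _per_bird_class_sums(sub)
    return pd.DataFrame(
        {
            "mean": sums.mean(),
            "median": sums.median(),
            "min": sums.min(),
            "max": sums.max(),
            "sd": sums.std(ddof=1).fillna(0.0),
        }
    ).loc[PAC_CLASSES]


def lmw_hmw_ratio(table: pd.DataFrame, site: str) -> tuple[float, pd.Series]:
    """Site mean and per-bird LMW:HMW ratios (parent + alkylated,
    heterocyclics excluded); birds with zero HMW are dropped with a log
    note."""
    sub = table[table["site"] == site]
    if sub.empty:
        raise ValueError(f"no birds for site {site!r}")
    sums = _per_bird_class_sums(sub)
    lmw = sums["ΣParent LMW"] + sums["ΣAlkylated LMW"]
    hmw = sums["ΣParent HMW"] + sums["ΣAlkylated HMW"]
    ok = hmw > 0
    if (~ok).any():
        logger.info("lmw_hmw_ratio: %d birds with zero HMW excluded", int((~ok).sum()))
    ratios = (lmw[ok] / hmw[ok]).rename("lmw_hmw_ratio")
    return float(ratios.mean()), ratios


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and p across >= 2 groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def pairwise_wilcoxon_bh(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests for every pair of groups, with
    Benjamini-Hochberg adjustment across pairs. Returns a symmetric
    adjusted-p matrix."""
    names = list(groups)
    pairs = list(combinations(names, 2))
    raw = [
        stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue
        for a, b in pairs
    ]
    adj = adjust_bh(np.asarray(raw))
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for (a, b), q in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = q
    return mat


# ---------------------------------------------------------------------------
# multivariate views of the methylation matrix


def _complete_percent_matrix(matrix: UnitedMatrix) -> np.ndarray:
    pm = matrix.percent_methylation()
    complete = ~np.isnan(pm).any(axis=1)
    pm = pm[complete]
    if pm.shape[0] < 2:
        raise ValueError("need >= 2 loci with complete coverage")
    return pm.T  # samples x loci


def pca_percent_meth(matrix: UnitedMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of percent methylation (samples x loci), column-centered and
    unscaled. Returns per-sample scores and percent variance per
    component (sums to 100)."""
    if matrix.n_samples < 3:
        raise ValueError("PCA needs >= 3 samples")
    Y = _complete_percent_matrix(matrix)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Yc, full_matrices=False)
    scores = U * S
    var = S**2
    pct = 100.0 * var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    k = scores.shape[1]
    df = pd.DataFrame(
        scores, index=matrix.samples["sample_id"], columns=[f"PC{i + 1}" for i in range(k)]
    )
    return df, pct


def hclust_ward(matrix: UnitedMatrix) -> tuple[np.ndarray, list[str]]:
    """ward.D agglomerative clustering of samples.

    Distance is 1 - Pearson correlation between sample percent-methylation
    profiles; the Ward Lance-Williams update is applied to the unsquared
    distances (the ward.D convention, distinct from ward.D2). Ties are
    broken by the smallest cluster indices. Returns a scipy-style linkage
    matrix and the sample labels.
    """
    if matrix.n_samples < 2:
        raise ValueError("clustering needs >= 2 samples")
    Y = _complete_percent_matrix(matrix)
    D = 1.0 - np.corrcoef(Y)
    np.fill_diagonal(D, 0.0)
    return _ward_d_linkage(D), list(matrix.samples["sample_id"])


def _ward_d_linkage(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    d = D.astype(float).copy()
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    current = {i: i for i in range(n)}  # matrix row -> cluster id
    next_id = n
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]

    def get(i, j):
        return dist[(i, j) if i < j else (j, i)]

    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        # nearest pair; ties -> smallest (i, j)
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = get(i, j)
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, i, j)
        dij, i, j = best
        ci, cj = current[i], current[j]
        lo, hi = min(ci, cj), max(ci, cj)
        Z[step] = [lo, hi, dij, sizes[i] + sizes[j]]
        # Lance-Williams ward update into slot i
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dnew = (
                (ni + nk) * get(i, k) + (nj + nk) * get(j, k) - nk * dij
            ) / (ni + nj + nk)
            dist[(min(i, k), max(i, k))] = dnew
        sizes[i] = ni + nj
        current[i] = next_id
        next_id += 1
        active.remove(j)
    return Z


def cut_tree(Z: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster labels (0..k-1) from a linkage matrix at k clusters."""
    from scipy.cluster.hierarchy import fcluster

    return fcluster(Z, t=k, criterion="maxclust") - 1
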