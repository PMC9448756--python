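"""Cohort-level descriptive statistics over per-eye parameter tables.

Three utilities mirror the descriptive layer of the study design: a
tie-corrected Spearman correlation matrix, a Wilcoxon rank-sum comparison
(exact for small samples), and a two-cluster grouping of variables by their
profiles across eyes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = ["spearman_matrix", "rank_sum_test", "cluster_variables", "RankSumResult"]


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (tie-corrected ranks) and two-sided p-values.

    Missing values are dropped pairwise; a cell needs at least 3 complete
    pairs, and constant columns yield NaN.  The diagonal is exactly 1
    (p = 0 by convention).
    """
    cols = list(table.columns)
    n = len(cols)
    rho = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    for i, j in combinations(range(n), 2):
        x = pd.to_numeric(table[cols[i]], errors="coerce")
        y = pd.to_numeric(table[cols[j]], errors="coerce")
        ok = x.notna() & y.notna()
        if ok.sum() < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
            r, p = np.nan, np.nan
        else:
            r, p = stats.spearmanr(x[ok], y[ok])
        rho.iloc[i, j] = rho.iloc[j, i] = r
        pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval


@dataclass
class RankSumResult:
    statistic: float  # rank sum of the first sample
    pvalue: float
    method: str  # "exact" or "normal"


def rank_sum_test(a, b, exact_max_n: int = 10) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with tie correction.

    For samples with both sizes <= ``exact_max_n`` the null distribution of
    the rank sum is enumerated exhaustively over all rank assignments
    (midranks under ties); otherwise a tie-corrected normal approximation
    is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[:na].sum())

    if na <= exact_max_n and nb <= exact_max_n:
        n = na + nb
        mean = na * (n + 1) / 2.0
        obs_dev = abs(w - mean)
        hits = total = 0
        for subset in combinations(range(n), na):
            total += 1
            ws = sum(ranks[k] for k in subset)
            if abs(ws - mean) >= obs_dev - 1e-12:
                hits += 1
        return RankSumResult(statistic=w, pvalue=hits / total, method="exact")

    n = na + nb
    mean = na * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / ((n) * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values tied
        return RankSumResult(statistic=w, pvalue=1.0, method="normal")
    z = (w - mean) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return RankSumResult(statistic=w, pvalue=min(p, 1.0), method="normal")


def cluster_variables(table: pd.DataFrame, k: int = 2, seed: int = 0, n_restarts: int = 50) -> pd.DataFrame:
    """Group variables (columns) into ``k`` clusters by profile similarity.

    Columns are standardized across eyes and clustered with k-means on the
    variable vectors (one vector per column, one feature per eye).  The
    returned frame lists each variable's cluster and its R^2 with its own
    cluster, defined as the squared correlation with the cluster's first
    principal component.  Deterministic for a fixed ``seed``; cluster ids
    are relabelled by descending cluster size, then by first member name,
    so the partition is invariant to column order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cols = list(table.columns)
    if k > len(cols):
        raise ValueError(f"k={k} exceeds the number of variables ({len(cols)})")
    X = table[cols].apply(pd.to_numeric, errors="coerce")
    X = X.dropna(axis=0, how="any")
    Z = (X - X.mean()) / X.std(ddof=1)
    V = Z.to_numpy().T  # variables as samples

    if k == 1:
        assign = np.zeros(len(cols), dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        assign = km.fit_predict(V)

    # canonical relabelling: by descending size, ties broken by the
    # alphabetically first member
    groups: dict[int, list[int]] = {}
    for idx, c in enumerate(assign):
        groups.setdefault(int(c), []).append(idx)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(cols[i] for i in g)))
    relabel = {}
    for new_id, g in enumerate(ordered, start=1):
        for i in g:
            relabel[i] = new_id

    r2 = np.full(len(cols), np.nan)
    for g in ordered:
        sub = Z.iloc[:, g].to_numpy()
        # first principal component of the cluster's standardized variables
        _, _, vt = np.linalg.svd(sub - sub.mean(axis=0), full_matrices=False)
        pc1 = sub @ vt[0]
        for i in g:
            c = np.corrcoef(Z.iloc[:, i], pc1)[0, 1]
            r2[i] = c * c
    return pd.DataFrame(
        {"variable": cols, "cluster": [relabel[i] for i in range(len(cols))], "r2_own_cluster": r2}
    ).set_index("variable")
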