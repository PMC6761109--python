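"""Downstream statistics on the inferred TF activity matrix W.

Covers tumor-type association (per-TF Welch t-tests with BH-FDR),
one-vs-rest scans with top-k effect unions, hierarchical clustering of
samples in activity space, and activity–phenotype Spearman correlation
with a permutation p-value.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests


def group_association(
    W: pd.DataFrame,
    labels: Sequence[bool] | pd.Series,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-TF t-test of activity in a sample group vs all other samples.

    Effect size is mean(group) − mean(rest); the default test is Welch
    (unequal variance), with ``equal_var=True`` for the pooled-variance
    variant. p-values are BH-FDR adjusted across TFs. A TF with zero
    variance in both groups is recorded with p = 1 and flagged.
    """
    mask = np.asarray(labels, dtype=bool)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("both groups need at least 2 samples")
    A = W.to_numpy()[:, mask]
    B = W.to_numpy()[:, ~mask]
    effect = A.mean(axis=1) - B.mean(axis=1)
    tvals = np.empty(W.shape[0])
    pvals = np.empty(W.shape[0])
    degenerate = np.zeros(W.shape[0], dtype=bool)
    for i in range(W.shape[0]):
        if np.ptp(A[i]) == 0 and np.ptp(B[i]) == 0:
            tvals[i], pvals[i], degenerate[i] = 0.0, 1.0, True
            continue
        res = stats.ttest_ind(A[i], B[i], equal_var=equal_var)
        tvals[i], pvals[i] = res.statistic, res.pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"effect": effect, "t": tvals, "p": pvals, "q": qvals,
         "degenerate": degenerate},
        index=W.index,
    )


def onevsrest_scan(
    W: pd.DataFrame,
    type_labels: pd.Series,
    top_k: int = 20,
    equal_var: bool = False,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """One-vs-rest association per tumor type plus a top-k union table.

    Per type, TFs are ranked by |effect size|; the union of each
    comparison's top-k TFs forms the heatmap table of effects
    (TF × tumor type).
    """
    labels = pd.Series(type_labels).loc[W.columns]
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValueError("need at least 2 tumor types")
    tables = {}
    union: list[str] = []
    for t in types:
        tab = group_association(W, (labels == t).to_numpy(), equal_var=equal_var)
        tables[t] = tab
        top = tab["effect"].abs().sort_values(ascending=False).index[:top_k]
        union.extend(tf for tf in top if tf not in union)
    heat = pd.DataFrame({t: tables[t].loc[union, "effect"] for t in types})
    return tables, heat


def cluster_activities(
    W: pd.DataFrame,
    center: bool = True,
    metric: str = "correlation",
    method: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Hierarchically cluster samples by their (mean-centered) activity vectors.

    Rows (TFs) are centered by their mean across samples; samples are
    clustered with the given linkage and distance (default average linkage,
    correlation distance). Returns the scipy linkage matrix and the
    deterministic leaf order (sample ids).
    """
    if W.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    M = W.to_numpy(dtype=float)
    if center:
        M = M - M.mean(axis=1, keepdims=True)
    V = M.T  # samples × TFs
    if metric == "correlation" and np.any(np.ptp(V, axis=1) == 0):
        raise ValueError(
            "constant sample vector: correlation distance undefined; "
            "use metric='euclidean'"
        )
    Z = hierarchy.linkage(pdist(V, metric=metric), method=method)
    order = hierarchy.leaves_list(Z)
    return Z, [W.columns[i] for i in order]


def activity_phenotype_correlation(
    activity: Sequence[float],
    phenotype: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Spearman correlation of one TF's activity with a numeric phenotype.

    Reports rho, the asymptotic p, and a permutation p (phenotype order
    permuted; exhaustive when the number of permutations allows it,
    otherwise seeded Monte Carlo; two-sided on |rho|). Constant input is
    flagged with rho = NaN.
    """
    a = np.asarray(activity, dtype=float)
    ph = np.asarray(phenotype, dtype=float)
    if a.shape != ph.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(a) == 0 or np.ptp(ph) == 0:
        warnings.warn("constant vector: Spearman correlation undefined")
        return {"rho": np.nan, "p_asymptotic": np.nan, "p_permutation": np.nan,
                "degenerate": True}
    res = stats.spearmanr(a, ph)
    rho_obs = float(res.statistic)

    ranks_a = stats.rankdata(a)
    ranks_p = stats.rankdata(ph)

    def rho_of(perm_ranks: np.ndarray) -> float:
        return float(np.corrcoef(ranks_a, perm_ranks)[0, 1])

    if math.factorial(n) <= n_permutations:
        null = [rho_of(np.asarray(p)) for p in itertools.permutations(ranks_p)]
        count = sum(abs(r) >= abs(rho_obs) - 1e-12 for r in null)
        p_perm = count / len(null)
    else:
        rng = np.random.default_rng(seed)
        count = 1  # include the observed ordering
        for _ in range(n_permutations):
            if abs(rho_of(rng.permutation(ranks_p))) >= abs(rho_obs) - 1e-12:
                count += 1
        p_perm = count / (n_permutations + 1)
    return {"rho": rho_obs, "p_asymptotic": float(res.pvalue),
            "p_permutation": float(p_perm), "degenerate": False}
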