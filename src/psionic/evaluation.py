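"""Held-out-gene cross-validation, randomization controls and K selection.

Folds split *genes*, not samples: models trained on training-fold genes
predict the expression of test-fold genes in every sample, and performance
is the per-sample Spearman correlation between pooled held-out predictions
and measurements. Two negative controls destroy, respectively, motif
identity (shuffling motif labels within each peak) and peak location
(resampling each motif's peaks uniformly from the atlas).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score

from . import features as feat
from . import mtl


@dataclass
class CVResult:
    """Per-sample Spearman rho on held-out genes, pooled across folds."""

    rho: pd.Series                    # indexed by sample id
    folds: list[np.ndarray]           # test-gene ids per fold
    method: str
    seed: int
    predictions: pd.DataFrame | None = None

    @property
    def mean(self) -> float:
        return float(self.rho.mean())

    @property
    def sd(self) -> float:
        return float(self.rho.std(ddof=1))

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(len(self.rho))

    def summary(self) -> dict:
        return {"method": self.method, "mean_rho": self.mean,
                "sd_rho": self.sd, "se_rho": self.se, "n_samples": len(self.rho)}


def make_gene_folds(gene_ids: Sequence[str], n_folds: int = 10, seed: int = 0
                    ) -> list[np.ndarray]:
    """Seeded permutation split of genes into folds of near-equal size."""
    gene_ids = np.asarray(list(gene_ids))
    if n_folds > len(gene_ids):
        raise ValueError("n_folds exceeds the number of genes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(gene_ids))
    return [gene_ids[idx] for idx in np.array_split(perm, n_folds)]


def _fit_method(Xtr, Ytr, method: str, hyperparams: Mapping, seed: int):
    hp = dict(hyperparams)
    if method == "psionic":
        return mtl.fit_psionic(
            Xtr, Ytr,
            K=hp.get("K", 7),
            mu=hp.get("mu", 1e-3),
            lam=hp.get("lam", 1e-3),
            init=hp.get("init", "stl"),
            tol=hp.get("tol", 1e-6),
            max_iter=hp.get("max_iter", 200),
            seed=seed,
        )
    if method == "stl":
        return mtl.fit_stl_ridge(Xtr, Ytr, hp.get("lam_ridge", 0.01))
    raise ValueError(f"unknown method {method!r}")


def crossvalidate(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    method: str = "psionic",
    hyperparams: Mapping | None = None,
    folds: list[np.ndarray] | None = None,
    seed: int = 0,
    n_folds: int = 10,
    standardize: bool = True,
) -> CVResult:
    """Held-out-gene CV; per-sample Spearman rho over pooled held-out genes.

    Training uses only training-fold genes (feature standardization
    statistics included). A constant prediction vector for a sample yields
    rho = 0 with a warning.
    """
    hyperparams = hyperparams or {}
    X = X.loc[Y.index]
    if folds is None:
        folds = make_gene_folds(Y.index, n_folds=n_folds, seed=seed)
    preds = pd.DataFrame(np.nan, index=Y.index, columns=Y.columns)
    for test_genes in folds:
        train_genes = Y.index.difference(test_genes, sort=False)
        Xtr, Xte = X.loc[train_genes], X.loc[test_genes]
        if standardize:
            Xtr, stats_ = feat.standardize_features(Xtr)
            Xte, _ = feat.standardize_features(Xte, stats=stats_)
        model = _fit_method(Xtr, Y.loc[train_genes], method, hyperparams, seed)
        preds.loc[test_genes] = mtl.predict(Xte, model).to_numpy()
    rho = {}
    for sample in Y.columns:
        p = preds[sample].to_numpy()
        if np.ptp(p) == 0:
            warnings.warn(f"constant prediction for sample {sample!r}; rho set to 0")
            rho[sample] = 0.0
        else:
            rho[sample] = float(stats.spearmanr(p, Y[sample].to_numpy()).statistic)
    return CVResult(rho=pd.Series(rho), folds=folds, method=method, seed=seed,
                    predictions=preds)


# ---------------------------------------------------------------------------
# Randomization controls
# ---------------------------------------------------------------------------

def randomize_motif_hits(
    hits: pd.DataFrame,
    seed: int = 0,
    motif_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Shuffle motif identity within each peak (control 1).

    Per peak, the multiset of hit scores is reassigned to a uniformly drawn
    subset of motif labels of the same size (drawn without replacement from
    the motif universe). Peak hit counts are conserved exactly; motif
    identity is destroyed.
    """
    universe = np.asarray(sorted(set(motif_ids if motif_ids is not None
                                     else hits["motif_id"])))
    rng = np.random.default_rng(seed)
    out = []
    for peak, grp in hits.groupby("peak_id", sort=True):
        k = len(grp)
        drawn = rng.choice(universe, size=k, replace=False)
        scores = grp["score"].to_numpy()
        out.append(pd.DataFrame({"motif_id": drawn, "peak_id": peak, "score": scores}))
    return (pd.concat(out, ignore_index=True)[["motif_id", "peak_id", "score"]]
            if out else hits.iloc[:0].copy())


def randomize_peak_locations(
    atlas: feat.PeakAtlas,
    hits: pd.DataFrame,
    genes,
    seed: int = 0,
    flank: int = 100_000,
    motif_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Shuffle peak locations per motif, then rebuild features (control 2).

    For each motif, its hit-bearing peaks are replaced by an equal-size
    uniform sample of atlas peaks, its scores permuted onto them; the
    feature matrix is then rebuilt with the real assignment and
    aggregation operations.
    """
    rng = np.random.default_rng(seed)
    all_peaks = np.asarray(atlas.peak_ids)
    shuffled = []
    for motif, grp in hits.groupby("motif_id", sort=True):
        k = len(grp)
        if k > len(all_peaks):
            raise ValueError(f"motif {motif!r} has more hits than atlas peaks")
        drawn = rng.choice(all_peaks, size=k, replace=False)
        scores = rng.permutation(grp["score"].to_numpy())
        shuffled.append(pd.DataFrame({"motif_id": motif, "peak_id": drawn,
                                      "score": scores}))
    shuffled_hits = (pd.concat(shuffled, ignore_index=True)
                     if shuffled else hits.iloc[:0].copy())
    assignment = feat.assign_peaks_to_genes(atlas, genes, flank=flank)
    return feat.aggregate_motif_scores(
        assignment, shuffled_hits,
        motif_ids=motif_ids if motif_ids is not None
        else sorted(hits["motif_id"].unique()),
    )


def compare_methods(rho_a: Sequence[float], rho_b: Sequence[float]) -> float:
    """One-sided Wilcoxon signed-rank p for "A better than B" on paired rho.

    Exact distribution for n <= 25 (no zeros/ties), otherwise the normal
    approximation with continuity correction. All-zero differences give
    p = 1 with a warning.
    """
    a = np.asarray(rho_a, dtype=float)
    b = np.asarray(rho_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    n = len(d)
    if n > 25:
        res = stats.wilcoxon(d, alternative="greater", method="approx",
                             correction=True)
        return float(res.pvalue)
    has_ties = np.any(d == 0) or len(np.unique(np.abs(d[d != 0]))) < np.sum(d != 0)
    if not has_ties:
        res = stats.wilcoxon(d, alternative="greater", method="exact")
        return float(res.pvalue)
    return _signflip_exact_p(d)


def _signflip_exact_p(d: np.ndarray) -> float:
    """Exact one-sided signed-rank p by enumerating all 2^n sign patterns.

    Handles tied |differences| (and zeros, via average ranks) where the
    tabulated exact distribution does not apply.
    """
    d = np.asarray(d, dtype=float)
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(np.sum(ranks[d > 0]))
    total = 0
    count = 0
    chunk = 1 << min(n, 16)
    masks = np.arange(1 << n, dtype=np.uint64)
    for start in range(0, 1 << n, chunk):
        block = masks[start:start + chunk]
        bits = ((block[:, None] >> np.arange(n, dtype=np.uint64)) & 1).astype(bool)
        w = bits @ ranks
        count += int(np.sum(w >= w_obs - 1e-12))
        total += len(block)
    return count / total


def scan_K(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    K_values: Sequence[int],
    hyperparams: Mapping | None = None,
    folds: list[np.ndarray] | None = None,
    seed: int = 0,
    type_labels: pd.Series | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Prediction performance and subtype separation as K varies.

    For each K: held-out-gene CV mean rho, plus the silhouette score of
    samples in mean-centered W-space (correlation distance) grouped by
    tumor-type label — a proxy for how well the latent programs separate
    known subtypes. Fewer than two label classes → separation is NaN.
    """
    hyperparams = dict(hyperparams or {})
    if folds is None:
        folds = make_gene_folds(Y.index, seed=seed)
    rows = []
    for K in K_values:
        hp = dict(hyperparams, K=int(K))
        cv = crossvalidate(X, Y, "psionic", hp, folds=folds, seed=seed,
                           standardize=standardize)
        sep = np.nan
        if type_labels is not None and type_labels.nunique() >= 2:
            Xs = feat.standardize_features(X)[0] if standardize else X
            model = mtl.fit_psionic(Xs, Y, K=int(K), mu=hp.get("mu", 1e-3),
                                    lam=hp.get("lam", 1e-3), seed=seed)
            W = model.activities().to_numpy()
            Wc = W - W.mean(axis=1, keepdims=True)
            labels = pd.Series(type_labels).loc[model.sample_ids]
            try:
                sep = float(silhouette_score(Wc.T, labels.to_numpy(),
                                             metric="correlation"))
            except ValueError:
                sep = np.nan  # degenerate W (e.g. constant samples)
        rows.append({"K": int(K), "mean_rho": cv.mean, "sd_rho": cv.sd,
                     "separation": sep})
    return pd.DataFrame(rows)
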