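"""Seeded generators: synthetic regulatory genomes and expression cohorts.

The genome generator lays genes on synthetic chromosomes, scatters
accessible peaks inside each gene's ±100 kb regulatory window (plus
optional decoy peaks on a gene-free chromosome) and draws sparse
nonnegative motif hits, so the full feature pipeline can run without any
download. The cohort generator plants a ground-truth latent-program model
(L0, S0) with group-structured support — one program shared by every
group, the rest group-specific — and emits expression y_t as the
unit-normalized sum of X L0 s_t and Gaussian noise. All draws flow from a
single seeded generator, so regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import features as feat
from .io import GeneModel, GenomicInterval

# cohort composition mirrored at desk scale: five tumor types with sizes
# proportional to (92, 255, 57, 272, 47)
DEFAULT_GROUP_PROPORTIONS = (92, 255, 57, 272, 47)


@dataclass
class SyntheticCohort:
    """A planted-truth cohort: features, ground-truth model, expression."""

    X: pd.DataFrame                   # gene × TF features used for generation
    L0: np.ndarray                    # d × K_true latent programs
    S0: np.ndarray                    # K_true × T sample weights
    Y: pd.DataFrame                   # gene × sample unit-normalized expression
    labels: pd.Series                 # sample → group label
    sigma: np.ndarray                 # per-task noise s.d.
    oracle_r2: np.ndarray             # per-task variance explained by the truth
    supports: list[set]               # per-group latent-program support
    seed: int

    @property
    def W0(self) -> pd.DataFrame:
        """True activity matrix L0 S0 (TF × sample)."""
        return pd.DataFrame(self.L0 @ self.S0, index=self.X.columns,
                            columns=self.Y.columns)


def simulate_regulatory_genome(
    n_genes: int = 200,
    n_tfs: int = 30,
    mean_peaks_per_gene: float = 8.0,
    hit_prob: float = 0.1,
    score_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    decoy_frac: float = 0.1,
    flank: int = 100_000,
    seed: int = 0,
) -> tuple[list[GeneModel], feat.PeakAtlas, pd.DataFrame]:
    """Generate gene models, a peak atlas and a sparse motif-hit table.

    Genes sit on synthetic chromosomes with non-overlapping transcription
    units spaced far enough apart that regulatory windows rarely collide;
    per-gene peak counts are Poisson(``mean_peaks_per_gene``) with peaks
    placed uniformly inside the gene's window. ``decoy_frac`` of additional
    peaks land on a gene-free chromosome, hence outside every window. Hits
    are Bernoulli(``hit_prob``) per (peak, motif) with scores drawn from
    ``score_dist`` (default: 5 + Exp(1), mimicking −log10 p-values of
    scanner hits below 1e-5).
    """
    if min(n_genes, n_tfs) < 1 or mean_peaks_per_gene <= 0 or not 0 <= hit_prob <= 1:
        raise ValueError("generator parameters must be positive (hit_prob in [0,1])")
    rng = np.random.default_rng(seed)
    if score_dist is None:
        score_dist = lambda r, size: 5.0 + r.exponential(1.0, size=size)

    genes: list[GeneModel] = []
    peaks: list[GenomicInterval] = []
    genes_per_chrom = 25
    spacing = 2 * flank + 120_000        # keeps neighbouring windows mostly disjoint
    pid = 0
    for i in range(n_genes):
        chrom = f"chr{i // genes_per_chrom + 1}"
        offset = flank + 10_000 + (i % genes_per_chrom) * spacing
        tu_len = int(rng.integers(5_000, 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{i:04d}"
        genes.append(GeneModel(gid, chrom, strand, offset, offset + tu_len))
        n_peaks = int(rng.poisson(mean_peaks_per_gene))
        lo, hi = offset - flank, offset + tu_len + flank
        for _ in range(n_peaks):
            w = int(rng.integers(200, 1_000))
            start = int(rng.integers(lo, hi - w))
            peaks.append(GenomicInterval(chrom, start, start + w, f"p{pid:06d}"))
            pid += 1
    n_decoys = int(round(decoy_frac * len(peaks)))
    for _ in range(n_decoys):
        w = int(rng.integers(200, 1_000))
        start = int(rng.integers(0, 10_000_000))
        peaks.append(GenomicInterval("chrDecoy", start, start + w, f"p{pid:06d}"))
        pid += 1

    peak_ids = np.array([p.id for p in peaks])
    hit_mask = rng.random((len(peaks), n_tfs)) < hit_prob
    pi, mi = np.nonzero(hit_mask)
    motif_names = np.array([f"M{j:03d}" for j in range(n_tfs)])
    hits = pd.DataFrame({
        "motif_id": motif_names[mi],
        "peak_id": peak_ids[pi],
        "score": score_dist(rng, len(pi)),
    })
    atlas = feat.PeakAtlas(peaks, provenance={"synthetic": True, "seed": seed})
    return genes, atlas, hits


def _group_sizes(T: int, n_groups: int,
                 proportions: Sequence[float] | None) -> np.ndarray:
    if proportions is None:
        proportions = DEFAULT_GROUP_PROPORTIONS[:n_groups]
    props = np.asarray(proportions, dtype=float)[:n_groups]
    props = props / props.sum()
    sizes = np.floor(props * T).astype(int)
    sizes[sizes == 0] = 1
    while sizes.sum() < T:
        sizes[np.argmax(props - sizes / T)] += 1
    while sizes.sum() > T:
        sizes[np.argmax(sizes)] -= 1
    return sizes


def group_supports(K_true: int, n_groups: int, support_size: int,
                   shared_program: bool = True) -> list[set]:
    """Latent-program support per group.

    With ``shared_program`` (the default) program 0 belongs to every group
    and the remaining K−1 programs are handed out round-robin; without it
    the supports are built round-robin over all K programs, so groups can
    be fully disjoint (orthogonal regulatory programs).
    """
    if support_size > K_true:
        raise ValueError("support_size cannot exceed K_true")
    supports = []
    if shared_program:
        n_specific = K_true - 1
        for g in range(n_groups):
            sup = {0}
            for j in range(support_size - 1):
                if n_specific:
                    sup.add(1 + (g + j) % n_specific)
            supports.append(sup)
    else:
        for g in range(n_groups):
            supports.append({(g * support_size + j) % K_true
                             for j in range(support_size)})
    return supports


def simulate_cohort(
    X: pd.DataFrame,
    K_true: int = 4,
    T: int = 60,
    n_groups: int = 5,
    support_size: int = 2,
    coef_dist: Callable[[np.random.Generator, tuple], np.ndarray] | None = None,
    sigma: float | None = None,
    target_r2: float | None = 0.5,
    group_proportions: Sequence[float] | None = None,
    standardize: bool = True,
    shared_program: bool = True,
    seed: int = 0,
) -> SyntheticCohort:
    """Plant a latent-program model on X and generate a noisy expression cohort.

    L0 columns are drawn iid from ``coef_dist`` (default standard normal)
    and unit-normalized; each sample's s_t lives on its group's support
    (a group-coherent base vector plus jitter); y_t = X L0 s_t + eps, then
    unit L2 normalization per sample — the same order as the real
    pipeline. Noise is either a fixed ``sigma`` or calibrated per task so
    the oracle variance explained matches ``target_r2``.
    """
    if sigma is not None and sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma is None and target_r2 is None:
        raise ValueError("give either sigma or target_r2")
    rng = np.random.default_rng(seed)
    if coef_dist is None:
        coef_dist = lambda r, shape: r.standard_normal(shape)

    Xw = feat.standardize_features(X)[0] if standardize else X
    Xa = Xw.to_numpy(dtype=float)
    N, d = Xa.shape

    L0 = coef_dist(rng, (d, K_true))
    L0 = L0 / np.linalg.norm(L0, axis=0, keepdims=True)

    sizes = _group_sizes(T, n_groups, group_proportions)
    supports = group_supports(K_true, n_groups, support_size, shared_program)
    labels = []
    S0 = np.zeros((K_true, T))
    t = 0
    for g, size in enumerate(sizes):
        sup = sorted(supports[g])
        # group-coherent sign pattern, per-task magnitudes: tumors of a type
        # use their programs in a shared direction but with varying strength
        signs = rng.choice([-1.0, 1.0], len(sup))
        for _ in range(size):
            S0[sup, t] = signs * rng.uniform(0.3, 1.7, size=len(sup))
            labels.append(f"type{chr(ord('A') + g)}")
            t += 1

    signal = Xa @ (L0 @ S0)                       # N × T
    if target_r2 is not None:
        sd_sig = signal.std(axis=0, ddof=0)
        sig_t = sd_sig * np.sqrt((1.0 - target_r2) / target_r2)
    else:
        sig_t = np.full(T, float(sigma))
    eps = rng.standard_normal((N, T)) * sig_t
    raw = signal + eps
    var_sig = signal.var(axis=0, ddof=0)
    oracle_r2 = var_sig / (var_sig + eps.var(axis=0, ddof=0))
    norms = np.linalg.norm(raw, axis=0)
    sample_ids = [f"t{j:03d}" for j in range(T)]
    Y = pd.DataFrame(raw / norms, index=Xw.index, columns=sample_ids)
    return SyntheticCohort(
        X=Xw, L0=L0, S0=S0, Y=Y,
        labels=pd.Series(labels, index=sample_ids, name="group"),
        sigma=sig_t, oracle_r2=oracle_r2, supports=supports, seed=seed,
    )


def default_cohort(seed: int = 0,
                   n_genes: int = 1000,
                   n_tfs: int = 100,
                   K_true: int = 4,
                   T: int = 60,
                   target_r2: float = 0.5,
                   ) -> tuple[SyntheticCohort, tuple]:
    """The standard study-condition cohort: N=1000 genes, d=100 TFs, T=60
    samples in five groups, K_true=4, per-task oracle R² ≈ 0.5.

    Returns the cohort plus the (genes, atlas, hits, assignment) used to
    build its feature matrix, so randomization controls can rerun the
    feature pipeline.
    """
    genes, atlas, hits = simulate_regulatory_genome(
        n_genes=n_genes, n_tfs=n_tfs, seed=seed,
    )
    assignment = feat.assign_peaks_to_genes(atlas, genes)
    X = feat.aggregate_motif_scores(assignment, hits,
                                    motif_ids=sorted(hits["motif_id"].unique()))
    cohort = simulate_cohort(X, K_true=K_true, T=T, target_r2=target_r2,
                             seed=seed + 1)
    return cohort, (genes, atlas, hits, assignment)


def recovery_report(model, cohort: SyntheticCohort) -> dict:
    """How well a fitted model recovers the planted truth.

    Per task: Pearson(w_t fitted, w_t true). Latent programs are matched by
    maximum-|correlation| bipartite assignment with sign alignment (the
    factorization is only identifiable up to permutation and sign).
    """
    from scipy.optimize import linear_sum_assignment

    W_fit = model.L @ model.S
    W_true = cohort.L0 @ cohort.S0
    T = W_true.shape[1]
    per_task = np.array([
        _safe_pearson(W_fit[:, t], W_true[:, t]) for t in range(T)
    ])
    k = min(model.L.shape[1], cohort.L0.shape[1])
    C = np.zeros((model.L.shape[1], cohort.L0.shape[1]))
    for i in range(C.shape[0]):
        for j in range(C.shape[1]):
            C[i, j] = _safe_pearson(model.L[:, i], cohort.L0[:, j])
    rows, cols = linear_sum_assignment(-np.abs(np.nan_to_num(C)))
    matched = [abs(C[i, j]) for i, j in zip(rows[:k], cols[:k])]
    return {
        "per_task_activity_corr": per_task,
        "mean_activity_corr": float(np.nanmean(per_task)),
        "matched_program_corr": np.array(matched),
        "mean_program_corr": float(np.nanmean(matched)),
        "matching": list(zip(rows.tolist(), cols.tolist())),
    }


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])
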