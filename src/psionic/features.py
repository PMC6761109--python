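"""Gene × TF feature construction from a peak atlas, gene models and motif hits.

The pipeline mirrors a standard ATAC-based regulatory-feature build:

1. merge reproducible peaks across samples into one atlas
   (pairs overlapping by more than a fraction of the shorter interval);
2. assign each peak to its nearest gene, restricted to the transcription
   unit ± 100 kb window;
3. aggregate motif-hit scores per gene by taking, for each motif, the
   maximum score over the gene's assigned peaks;
4. filter motifs by TF expression (expressed in >=50% of samples of at
   least one sample group) and by target-set redundancy (Jaccard > 0.5).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, GenomicInterval


@dataclass
class PeakAtlas:
    """An ordered set of accessible regions with stable, unique peak ids."""

    intervals: list[GenomicInterval]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [iv.id for iv in self.intervals]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate peak ids in atlas")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def peak_ids(self) -> list[str]:
        return [iv.id for iv in self.intervals]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = defaultdict(list)
        for iv in self.intervals:
            out[iv.chrom].append(iv)
        return dict(out)


@dataclass
class PeakGeneAssignment:
    """Peak → gene mapping (at most one gene per peak) plus the reverse index."""

    peak_to_gene: dict[str, str]
    gene_ids: list[str]
    unassigned: set[str]

    @property
    def gene_to_peaks(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {g: set() for g in self.gene_ids}
        for p, g in self.peak_to_gene.items():
            idx[g].add(p)
        return idx

    def to_frame(self) -> pd.DataFrame:
        rows = [(p, g) for p, g in sorted(self.peak_to_gene.items())]
        rows += [(p, "") for p in sorted(self.unassigned)]
        return pd.DataFrame(rows, columns=["peak_id", "gene_id"])


def _overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def _merge_rule(a: GenomicInterval, b: GenomicInterval, frac: float, mode: str) -> bool:
    ov = _overlap(a, b)
    if ov <= 0:
        return False
    if mode == "shorter":
        return ov > frac * min(a.length, b.length)
    return ov > frac * a.length and ov > frac * b.length


def merge_reproducible_peaks(
    peak_sets: Sequence[Sequence[GenomicInterval]],
    overlap_frac: float = 0.75,
    mode: str = "shorter",
) -> PeakAtlas:
    """Merge reproducible peaks from several samples into one atlas.

    Two intervals are merged into their union when their overlap exceeds
    ``overlap_frac`` of the shorter interval (``mode='reciprocal'`` demands
    the fraction of both). Merging repeats until no pair qualifies; at each
    step the first qualifying pair in (chrom, start, end) order is merged, so
    the result is deterministic. Merged peak ids record their parents joined
    by ``|``.
    """
    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must be in (0, 1]")
    for si, pset in enumerate(peak_sets):
        ordered = sorted(pset, key=lambda iv: (iv.chrom, iv.start))
        for a, b in zip(ordered, ordered[1:]):
            if a.chrom == b.chrom and _overlap(a, b) > 0:
                raise ValueError(f"peak set {si} contains internally overlapping intervals")
    pool = [iv for pset in peak_sets for iv in pset]
    # ids may collide across input sets; qualify on collision
    seen: dict[str, int] = {}
    uniq = []
    for iv in pool:
        if iv.id in seen:
            seen[iv.id] += 1
            uniq.append(GenomicInterval(iv.chrom, iv.start, iv.end, f"{iv.id}.{seen[iv.id]}"))
        else:
            seen[iv.id] = 0
            uniq.append(iv)
    intervals = sorted(uniq, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.id))

    changed = True
    while changed:
        changed = False
        for i in range(len(intervals)):
            a = intervals[i]
            for j in range(i + 1, len(intervals)):
                b = intervals[j]
                if b.chrom != a.chrom or b.start >= a.end:
                    break
                if _merge_rule(a, b, overlap_frac, mode):
                    union = GenomicInterval(
                        a.chrom, min(a.start, b.start), max(a.end, b.end),
                        f"{a.id}|{b.id}",
                    )
                    intervals = intervals[:i] + intervals[i + 1:j] + intervals[j + 1:]
                    intervals.append(union)
                    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.id))
                    changed = True
                    break
            if changed:
                break
    return PeakAtlas(intervals, provenance={"n_input_sets": len(peak_sets)})


def assign_peaks_to_genes(
    atlas: PeakAtlas,
    genes: Sequence[GeneModel],
    flank: int = 100_000,
) -> PeakGeneAssignment:
    """Assign each peak to its nearest gene within the gene's extended window.

    A peak is a candidate for gene g iff it overlaps
    ``[tu_start - flank, tu_end + flank)``; among candidates it is assigned
    to the gene whose TSS is nearest to the peak midpoint (ties broken by
    smaller gene id). Peaks with no candidate gene are recorded as
    unassigned, as are peaks on chromosomes absent from the gene set
    (with a warning).
    """
    genes_by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        genes_by_chrom[g.chrom].append(g)

    peak_to_gene: dict[str, str] = {}
    unassigned: set[str] = set()
    warned_chroms: set[str] = set()
    for chrom, peaks in atlas.by_chrom().items():
        cands = genes_by_chrom.get(chrom)
        if not cands:
            if chrom not in warned_chroms:
                warnings.warn(f"no genes on chromosome {chrom!r}; peaks left unassigned")
                warned_chroms.add(chrom)
            unassigned.update(iv.id for iv in peaks)
            continue
        win_start = np.array([g.tu_start - flank for g in cands])
        win_end = np.array([g.tu_end + flank for g in cands])
        tss = np.array([g.tss for g in cands], dtype=float)
        gids = np.array([g.gene_id for g in cands])
        for iv in peaks:
            hit = (iv.start < win_end) & (iv.end > win_start)
            if not hit.any():
                unassigned.add(iv.id)
                continue
            dist = np.abs(iv.midpoint - tss[hit])
            cand_ids = gids[hit]
            best = dist.min()
            tied = cand_ids[dist == best]
            peak_to_gene[iv.id] = min(tied)
    return PeakGeneAssignment(
        peak_to_gene=peak_to_gene,
        gene_ids=sorted(g.gene_id for g in genes),
        unassigned=unassigned,
    )


def aggregate_motif_scores(
    assignment: PeakGeneAssignment,
    hits: pd.DataFrame,
    motif_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build X[g, m] = max over g's assigned peaks of score(peak, m).

    Genes with no assigned peak (or no hit) get zero entries. Columns are
    the sorted motif list; rows the sorted gene list. A hit on a peak id not
    present in the assignment's atlas is an error.
    """
    known = set(assignment.peak_to_gene) | set(assignment.unassigned)
    bad = set(hits["peak_id"]) - known
    if bad:
        raise ValueError(f"hits reference unknown peak ids, e.g. {sorted(bad)[:3]}")
    if motif_ids is None:
        motif_ids = sorted(hits["motif_id"].unique())
    else:
        motif_ids = sorted(motif_ids)
    genes = sorted(assignment.gene_ids)
    assigned = hits[hits["peak_id"].isin(assignment.peak_to_gene)]
    if len(assigned):
        tmp = assigned.assign(
            gene_id=assigned["peak_id"].map(assignment.peak_to_gene)
        )
        pivot = tmp.pivot_table(
            index="gene_id", columns="motif_id", values="score", aggfunc="max"
        )
    else:
        pivot = pd.DataFrame()
    X = pd.DataFrame(0.0, index=genes, columns=motif_ids)
    if len(pivot):
        common_cols = [c for c in pivot.columns if c in set(motif_ids)]
        X.loc[pivot.index, common_cols] = pivot[common_cols].fillna(0.0).to_numpy()
    X.index.name = "gene_id"
    X.columns.name = "motif_id"
    return X


def filter_tfs_by_expression(
    motif_ids: Iterable[str],
    expression: pd.DataFrame,
    tf_to_gene: Mapping[str, str],
    type_labels: pd.Series,
    min_frac: float = 0.5,
    expressed_threshold: float = 0.0,
) -> list[str]:
    """Keep motifs whose TF gene is expressed in >= ``min_frac`` of the samples
    of at least one sample group (expression on the pre-normalization scale).

    Motifs whose TF cannot be mapped to a gene in the matrix are dropped with
    a warning.
    """
    labels = pd.Series(type_labels)
    groups = labels.groupby(labels).groups
    for name, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty sample group {name!r}")
    retained = []
    for motif in sorted(set(motif_ids)):
        gene = tf_to_gene.get(motif)
        if gene is None or gene not in expression.index:
            warnings.warn(f"motif {motif!r} has no mappable expression gene; dropped")
            continue
        row = expression.loc[gene]
        for idx in groups.values():
            frac = float((row.loc[idx] > expressed_threshold).mean())
            if frac >= min_frac:
                retained.append(motif)
                break
    return retained


def jaccard(a: set, b: set) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b|; 0 when either set is empty."""
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def jaccard_redundancy_filter(
    target_sets: Mapping[str, set],
    threshold: float = 0.5,
) -> list[str]:
    """Iteratively drop redundant motifs by target-set Jaccard similarity.

    While any retained pair has Jaccard > ``threshold``: among motifs
    involved in a violating pair, compute each one's mean Jaccard against
    all other retained motifs and remove the motif with the largest mean
    (ties broken by removing the smaller motif id). Repeats to fixpoint.
    """
    retained = sorted(target_sets)
    while True:
        offenders: set[str] = set()
        for i, mi in enumerate(retained):
            for mj in retained[i + 1:]:
                if jaccard(target_sets[mi], target_sets[mj]) > threshold:
                    offenders.update((mi, mj))
        if not offenders:
            return retained
        def mean_j(m: str) -> float:
            others = [o for o in retained if o != m]
            if not others:
                return 0.0
            return float(np.mean([jaccard(target_sets[m], target_sets[o]) for o in others]))
        means = {m: mean_j(m) for m in offenders}
        best_mean = max(means.values())
        worst = min(m for m, v in means.items() if v == best_mean)
        retained = [m for m in retained if m != worst]


def regulatory_complexity(assignment: PeakGeneAssignment) -> pd.DataFrame:
    """Per-gene accessible-region counts and low/medium/high tertile labels.

    Boundaries sit at the 33rd and 66th percentiles of the count
    distribution; boundary ties fall into the lower class. Genes with no
    assigned peaks are included with count 0.
    """
    if not assignment.gene_ids:
        raise ValueError("assignment has no genes")
    counts = pd.Series(
        {g: len(p) for g, p in assignment.gene_to_peaks.items()}, name="n_peaks"
    ).sort_index()
    p33, p66 = np.percentile(counts.to_numpy(), [33, 66])
    labels = np.where(counts <= p33, "low", np.where(counts <= p66, "medium", "high"))
    return pd.DataFrame({"n_peaks": counts, "complexity": labels})


def promoter_filter(
    atlas: PeakAtlas,
    genes: Sequence[GeneModel],
    window: int = 2_000,
) -> PeakAtlas:
    """Keep only peaks overlapping any TSS ± ``window`` bp (promoter-only mode)."""
    tss_by_chrom: dict[str, list[int]] = defaultdict(list)
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    kept = []
    for iv in atlas:
        for t in tss_by_chrom.get(iv.chrom, ()):
            if iv.start < t + window and iv.end > t - window:
                kept.append(iv)
                break
    return PeakAtlas(kept, provenance=dict(atlas.provenance, promoter_only=True))


def standardize_features(
    X: pd.DataFrame,
    stats: tuple[pd.Series, pd.Series] | None = None,
) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """Z-score feature columns; zero-variance columns are dropped with a warning.

    Returns the standardized matrix and the (mean, sd) used, so held-out
    rows can be transformed with training-fold statistics.
    """
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        zero = sd[sd == 0].index
        if len(zero):
            warnings.warn(f"dropping {len(zero)} zero-variance feature column(s)")
            X = X.drop(columns=zero)
            mean = mean.drop(zero)
            sd = sd.drop(zero)
        stats = (mean, sd)
    mean, sd = stats
    Z = (X[mean.index] - mean) / sd
    return Z, stats
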