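"""Feature construction: merging, assignment, aggregation, filters, complexity."""

import numpy as np
import pandas as pd
import pytest

from psionic import features as feat
from psionic.io import GeneModel, GenomicInterval


def iv(chrom, start, end, iid):
    return GenomicInterval(chrom, start, end, iid)


# ---------------------------------------------------------------------------
# Peak merging
# ---------------------------------------------------------------------------

def test_merge_overlapping_pair_merges():
    atlas = feat.merge_reproducible_peaks(
        [[iv("chr1", 0, 100, "a")], [iv("chr1", 10, 110, "b")]], 0.75)
    assert len(atlas) == 1
    merged = atlas.intervals[0]
    assert (merged.start, merged.end) == (0, 110)
    assert set(merged.id.split("|")) == {"a", "b"}


def test_merge_small_overlap_kept_separate():
    atlas = feat.merge_reproducible_peaks(
        [[iv("chr1", 0, 100, "a")], [iv("chr1", 80, 200, "b")]], 0.75)
    assert len(atlas) == 2


def test_merge_empty_input_gives_empty_atlas():
    assert len(feat.merge_reproducible_peaks([], 0.75)) == 0


def test_merge_rejects_internally_overlapping_set():
    with pytest.raises(ValueError, match="internally overlapping"):
        feat.merge_reproducible_peaks(
            [[iv("chr1", 0, 100, "a"), iv("chr1", 50, 150, "b")]], 0.75)


def _brute_force_merge(intervals, frac):
    """O(n^2) pairwise fixpoint applying the shorter-interval overlap rule."""
    items = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end, i.id))
    while True:
        hit = None
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a.chrom != b.chrom:
                    continue
                ov = min(a.end, b.end) - max(a.start, b.start)
                if ov > frac * min(a.length, b.length):
                    hit = (i, j)
                    break
            if hit:
                break
        if hit is None:
            return items
        i, j = hit
        a, b = items[i], items[j]
        union = GenomicInterval(a.chrom, min(a.start, b.start),
                                max(a.end, b.end), f"{a.id}|{b.id}")
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [union]
        items.sort(key=lambda i: (i.chrom, i.start, i.end, i.id))


def test_merge_matches_brute_force_oracle(rng):
    sets = []
    for s in range(4):
        # non-overlapping intervals within each input set
        pos = np.cumsum(rng.integers(220, 500, size=50))  # gaps keep sets internally disjoint
        sets.append([
            iv("chr1", int(p), int(p + rng.integers(20, 200)), f"s{s}p{k}")
            for k, p in enumerate(pos)
        ])
    got = feat.merge_reproducible_peaks(sets, 0.75)
    want = _brute_force_merge([i for st in sets for i in st], 0.75)
    assert [(i.chrom, i.start, i.end) for i in got.intervals] == \
           [(i.chrom, i.start, i.end) for i in want]


# ---------------------------------------------------------------------------
# Peak → gene assignment
# ---------------------------------------------------------------------------

def test_assign_peak_in_gene_body():
    genes = [GeneModel("g1", "chr1", "+", 1000, 5000)]
    atlas = feat.PeakAtlas([iv("chr1", 2000, 2500, "p")])
    a = feat.assign_peaks_to_genes(atlas, genes)
    assert a.peak_to_gene == {"p": "g1"}


def test_assign_peak_beyond_flank_unassigned():
    genes = [GeneModel("g1", "chr1", "+", 1_000_000, 1_010_000)]
    atlas = feat.PeakAtlas([iv("chr1", 849_000, 849_500, "p")])  # 150 kb upstream
    a = feat.assign_peaks_to_genes(atlas, genes, flank=100_000)
    assert a.peak_to_gene == {} and a.unassigned == {"p"}


def test_assign_nearest_tss_wins():
    genes = [GeneModel("near", "chr1", "+", 10_000, 20_000),
             GeneModel("far", "chr1", "+", 40_000, 50_000)]
    atlas = feat.PeakAtlas([iv("chr1", 21_000, 21_500, "p")])
    a = feat.assign_peaks_to_genes(atlas, genes)
    # midpoint 21250: 11250 from 'near' TSS (10000), 18750 from 'far' (40000)
    assert a.peak_to_gene["p"] == "near"


def test_assign_translation_invariance(small_genome):
    genes, atlas, _ = small_genome
    shift = 12_345
    genes2 = [GeneModel(g.gene_id, g.chrom, g.strand,
                        g.tu_start + shift, g.tu_end + shift) for g in genes]
    atlas2 = feat.PeakAtlas([GenomicInterval(p.chrom, p.start + shift,
                                             p.end + shift, p.id) for p in atlas])
    a1 = feat.assign_peaks_to_genes(atlas, genes)
    a2 = feat.assign_peaks_to_genes(atlas2, genes2)
    assert a1.peak_to_gene == a2.peak_to_gene
    assert a1.unassigned == a2.unassigned


def _brute_force_assign(atlas, genes, flank):
    out = {}
    for p in atlas:
        best = None
        for g in genes:
            if g.chrom != p.chrom:
                continue
            if p.start < g.tu_end + flank and p.end > g.tu_start - flank:
                d = abs(p.midpoint - g.tss)
                if best is None or d < best[0] or (d == best[0] and g.gene_id < best[1]):
                    best = (d, g.gene_id)
        if best:
            out[p.id] = best[1]
    return out


def test_assign_matches_all_pairs_oracle(rng):
    genes = []
    pos = 150_000
    for i in range(30):
        ln = int(rng.integers(2_000, 40_000))
        genes.append(GeneModel(f"g{i:02d}", "chr1", "+", pos, pos + ln))
        pos += ln + int(rng.integers(10_000, 180_000))
    peaks = []
    for k in range(300):
        s = int(rng.integers(0, pos))
        peaks.append(iv("chr1", s, s + int(rng.integers(100, 800)), f"p{k}"))
    atlas = feat.PeakAtlas(peaks)
    got = feat.assign_peaks_to_genes(atlas, genes, flank=100_000)
    assert got.peak_to_gene == _brute_force_assign(atlas, genes, 100_000)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _toy_assignment():
    return feat.PeakGeneAssignment(
        peak_to_gene={"p1": "g1", "p2": "g1", "p3": "g2"},
        gene_ids=["g1", "g2", "g3"],
        unassigned={"p4"},
    )


def test_aggregate_takes_max_and_zero_fills():
    hits = pd.DataFrame({
        "motif_id": ["m", "m", "m"],
        "peak_id": ["p1", "p2", "p4"],
        "score": [3.1, 7.2, 9.9],
    })
    X = feat.aggregate_motif_scores(_toy_assignment(), hits)
    assert X.loc["g1", "m"] == 7.2          # max over the gene's peaks
    assert X.loc["g2", "m"] == 0.0          # no hit on assigned peak
    assert (X.loc["g3"] == 0).all()         # gene with no peaks: all-zero row


def test_aggregate_rejects_unknown_peak():
    hits = pd.DataFrame({"motif_id": ["m"], "peak_id": ["nope"], "score": [1.0]})
    with pytest.raises(ValueError, match="unknown peak"):
        feat.aggregate_motif_scores(_toy_assignment(), hits)


def test_aggregate_monotone_in_hits(small_genome, small_assignment):
    _, _, hits = small_genome
    motifs = sorted(hits["motif_id"].unique())
    X0 = feat.aggregate_motif_scores(small_assignment, hits.iloc[:-50], motifs)
    X1 = feat.aggregate_motif_scores(small_assignment, hits, motifs)
    assert (X1.to_numpy() >= X0.to_numpy() - 1e-15).all()


def test_aggregate_matches_triple_loop_oracle(rng, small_assignment):
    peaks = list(small_assignment.peak_to_gene) + list(small_assignment.unassigned)
    motifs = [f"M{j}" for j in range(10)]
    rows = []
    for p in peaks:
        for m in motifs:
            if rng.random() < 0.08:
                rows.append((m, p, float(rng.random() * 10)))
    hits = pd.DataFrame(rows, columns=["motif_id", "peak_id", "score"])
    X = feat.aggregate_motif_scores(small_assignment, hits, motifs)
    score = {(r[1], r[0]): r[2] for r in rows}
    for g in small_assignment.gene_ids:
        gpeaks = small_assignment.gene_to_peaks[g]
        for m in motifs:
            want = max([score.get((p, m), 0.0) for p in gpeaks] or [0.0])
            assert X.loc[g, m] == want


# ---------------------------------------------------------------------------
# TF filters
# ---------------------------------------------------------------------------

def _expr_fixture():
    # 5 samples in group A, 5 in B
    cols = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
    labels = pd.Series(["A"] * 5 + ["B"] * 5, index=cols)
    expr = pd.DataFrame(0.0, index=["tf1", "tf2"], columns=cols)
    expr.loc["tf1", ["a0", "a1", "a2"]] = 5.0          # 60% of group A
    expr.loc["tf2", ["a0", "a1", "b0", "b1"]] = 5.0    # 40% of each group
    return expr, labels


def test_expression_filter_trivial_cases():
    expr, labels = _expr_fixture()
    kept = feat.filter_tfs_by_expression(
        ["m1", "m2"], expr, {"m1": "tf1", "m2": "tf2"}, labels)
    assert kept == ["m1"]


def test_expression_filter_unmappable_dropped():
    expr, labels = _expr_fixture()
    with pytest.warns(UserWarning, match="no mappable"):
        kept = feat.filter_tfs_by_expression(
            ["m1", "mX"], expr, {"m1": "tf1"}, labels)
    assert kept == ["m1"]


def test_expression_filter_matches_fraction_oracle(rng):
    n_tf, n_samp = 25, 30
    cols = [f"s{j}" for j in range(n_samp)]
    labels = pd.Series(rng.choice(["A", "B", "C"], n_samp), index=cols)
    expr = pd.DataFrame(
        rng.random((n_tf, n_samp)) * (rng.random((n_tf, n_samp)) < 0.5),
        index=[f"tf{i}" for i in range(n_tf)], columns=cols)
    motifs = [f"m{i}" for i in range(n_tf)]
    tf_map = {f"m{i}": f"tf{i}" for i in range(n_tf)}
    kept = feat.filter_tfs_by_expression(motifs, expr, tf_map, labels)
    want = []
    for i in range(n_tf):
        ok = False
        for grp in ("A", "B", "C"):
            cols_g = labels[labels == grp].index
            if len(cols_g) and (expr.loc[f"tf{i}", cols_g] > 0).mean() >= 0.5:
                ok = True
        if ok:
            want.append(f"m{i}")
    assert kept == sorted(want)


def test_jaccard_filter_identical_sets_drop_one():
    sets = {"a": {1, 2, 3}, "b": {1, 2, 3}, "c": {9}}
    kept = feat.jaccard_redundancy_filter(sets, 0.5)
    assert "c" in kept and len(kept) == 2


def test_jaccard_filter_disjoint_all_kept():
    sets = {"a": {1}, "b": {2}, "c": {3}}
    assert feat.jaccard_redundancy_filter(sets, 0.5) == ["a", "b", "c"]


def _brute_force_jaccard_filter(sets, thr):
    kept = sorted(sets)
    def J(x, y):
        if not sets[x] or not sets[y]:
            return 0.0
        return len(sets[x] & sets[y]) / len(sets[x] | sets[y])
    while True:
        offenders = set()
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if J(a, b) > thr:
                    offenders |= {a, b}
        if not offenders:
            return kept
        means = {m: np.mean([J(m, o) for o in kept if o != m]) for m in offenders}
        mx = max(means.values())
        kept = [m for m in kept if m != min(k for k, v in means.items() if v == mx)]


def test_jaccard_filter_matches_fixpoint_oracle(rng):
    universe = list(range(40))
    sets = {f"m{i}": set(rng.choice(universe, size=rng.integers(3, 20),
                                    replace=False).tolist())
            for i in range(10)}
    assert feat.jaccard_redundancy_filter(sets, 0.5) == \
        _brute_force_jaccard_filter(sets, 0.5)


# ---------------------------------------------------------------------------
# Regulatory complexity
# ---------------------------------------------------------------------------

def test_complexity_tertiles_small():
    a = feat.PeakGeneAssignment(
        peak_to_gene={"p1": "g1", "p2": "g2", "p3": "g2",
                      "p4": "g3", "p5": "g3", "p6": "g3"},
        gene_ids=["g1", "g2", "g3"], unassigned=set())
    cc = feat.regulatory_complexity(a)
    assert list(cc["complexity"]) == ["low", "medium", "high"]
    assert list(cc["n_peaks"]) == [1, 2, 3]


def test_complexity_equal_counts_all_low():
    a = feat.PeakGeneAssignment(
        peak_to_gene={"p1": "g1", "p2": "g2"},
        gene_ids=["g1", "g2"], unassigned=set())
    cc = feat.regulatory_complexity(a)
    assert set(cc["complexity"]) == {"low"}     # boundary ties go down


def test_complexity_classes_balanced_for_distinct_counts(rng):
    n = 90
    counts = rng.permutation(n)                 # distinct 0..n-1
    a = feat.PeakGeneAssignment(
        peak_to_gene={f"p{i}_{k}": f"g{i:03d}"
                      for i in range(n) for k in range(counts[i])},
        gene_ids=[f"g{i:03d}" for i in range(n)], unassigned=set())
    cc = feat.regulatory_complexity(a)
    sizes = cc["complexity"].value_counts()
    assert all(abs(sizes[c] - n / 3) <= 1 for c in ("low", "medium", "high"))


# ---------------------------------------------------------------------------
# Promoter filter and standardization
# ---------------------------------------------------------------------------

def test_promoter_filter_keeps_tss_proximal_peaks():
    genes = [GeneModel("g", "chr1", "+", 10_000, 30_000)]
    atlas = feat.PeakAtlas([iv("chr1", 9_500, 9_800, "prox"),
                            iv("chr1", 25_000, 25_400, "distal")])
    sub = feat.promoter_filter(atlas, genes, window=2_000)
    assert sub.peak_ids == ["prox"]


def test_standardize_features_drops_constant_columns(rng):
    X = pd.DataFrame(rng.random((20, 3)), columns=["a", "b", "c"])
    X["c"] = 1.0
    with pytest.warns(UserWarning, match="zero-variance"):
        Z, stats = feat.standardize_features(X)
    assert list(Z.columns) == ["a", "b"]
    np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(Z.std(axis=0, ddof=0), 1, rtol=1e-12)
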