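"""Motif statistics on differential chromatin accessibility.

Consumes a per-peak log2 fold-change table (differential accessibility
between two conditions, computed upstream) and a motif → peak membership
map, and asks whether the peaks carrying a motif shift up or down in
accessibility: a one-sided two-sample KS test in each direction against
the background atlas, plus occurrence counts within the top-k most
differentially open/closed peaks with a log2 frequency-ratio effect size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EnrichmentResult:
    motif_id: str
    ks_stat_up: float
    p_up: float
    ks_stat_down: float
    p_down: float
    fg_up: int
    fg_down: int
    bg: int
    effect_up: float
    effect_down: float


def _validate_diff(diff: pd.DataFrame) -> pd.DataFrame:
    if not {"peak_id", "log2fc"}.issubset(diff.columns):
        raise ValueError("differential table needs columns peak_id, log2fc")
    if diff["peak_id"].duplicated().any():
        raise ValueError("duplicate peak ids in differential table")
    if not np.isfinite(diff["log2fc"]).all():
        raise ValueError("non-finite log2 fold changes")
    return diff


def motif_shift_test(
    diff: pd.DataFrame,
    members: Iterable[str],
    min_members: int = 10,
    background: str = "all",
    exact_below: int = 30,
) -> dict:
    """One-sided KS shift test of member-peak log2FCs against the background.

    ``background='all'`` compares against the full differential table
    (members included); ``'rest'`` excludes them. Both directions are
    reported: *up* tests whether member fold changes are stochastically
    larger (chromatin more open where the motif sits), *down* the reverse.
    The exact small-sample KS distribution is used when the smaller sample
    has fewer than ``exact_below`` points.
    """
    diff = _validate_diff(diff)
    members = set(members)
    if not members:
        raise ValueError("empty member set")
    unknown = members - set(diff["peak_id"])
    if unknown:
        raise ValueError(f"member peaks absent from table, e.g. {sorted(unknown)[:3]}")
    if len(members) < min_members:
        raise ValueError(f"fewer than {min_members} member peaks")
    is_member = diff["peak_id"].isin(members).to_numpy()
    fg = diff.loc[is_member, "log2fc"].to_numpy()
    bg = (diff["log2fc"].to_numpy() if background == "all"
          else diff.loc[~is_member, "log2fc"].to_numpy())
    if bg.size == 0:
        raise ValueError("empty background")
    method = "exact" if min(fg.size, bg.size) < exact_below else "asymp"
    # alternative='greater' (resp. 'less') tests whether the member CDF lies
    # above (below) the background CDF, i.e. member values smaller (larger)
    up = stats.ks_2samp(fg, bg, alternative="less", method=method)
    down = stats.ks_2samp(fg, bg, alternative="greater", method=method)
    return {
        "ks_stat_up": float(up.statistic), "p_up": float(up.pvalue),
        "ks_stat_down": float(down.statistic), "p_down": float(down.pvalue),
        "n_members": int(fg.size), "n_background": int(bg.size),
    }


def topk_occurrence(
    diff: pd.DataFrame,
    members: Iterable[str],
    k: int = 5000,
    pseudocount: float = 0.5,
) -> dict:
    """Motif occurrence in the k most differentially open / closed peaks.

    fg_up counts member peaks within the top-k by log2FC (fg_down the
    bottom-k); bg counts members among all differential peaks. The effect
    size is the log2 frequency ratio log2((fg/k) / (bg/N)) with a
    pseudocount on the counts. Ties at rank k break by peak id.
    """
    diff = _validate_diff(diff)
    members = set(members)
    n_total = len(diff)
    if k > n_total:
        raise ValueError("k exceeds the number of differential peaks")
    ordered = diff.sort_values(["log2fc", "peak_id"], ascending=[False, True])
    top = set(ordered["peak_id"].iloc[:k])
    bottom = set(
        diff.sort_values(["log2fc", "peak_id"], ascending=[True, True])
        ["peak_id"].iloc[:k]
    )
    fg_up = len(members & top)
    fg_down = len(members & bottom)
    bg = len(members & set(diff["peak_id"]))

    def effect(fg: int) -> float:
        return float(np.log2(((fg + pseudocount) / k) / ((bg + pseudocount) / n_total)))

    return {"fg_up": fg_up, "fg_down": fg_down, "bg": bg,
            "effect_up": effect(fg_up), "effect_down": effect(fg_down),
            "k": k, "n_total": n_total}


def adjust_bonferroni(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment min(1, p*m); m defaults to the vector length."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


def enrichment_scan(
    diff: pd.DataFrame,
    membership: Mapping[str, set] | pd.DataFrame,
    k: int = 5000,
    min_members: int = 10,
    background: str = "all",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Run the shift test and top-k occurrence for every motif.

    ``membership`` is either motif → set of peak ids or a two-column
    (motif_id, peak_id) table. Motifs below the membership floor are
    skipped. KS p-values are Bonferroni-adjusted across tested motifs,
    separately per direction.
    """
    if isinstance(membership, pd.DataFrame):
        membership = {m: set(g["peak_id"]) for m, g in membership.groupby("motif_id")}
    rows = []
    for motif in sorted(membership):
        mem = membership[motif] & set(diff["peak_id"])
        if len(mem) < min_members:
            continue
        shift = motif_shift_test(diff, mem, min_members=min_members,
                                 background=background)
        occ = topk_occurrence(diff, mem, k=min(k, len(diff)),
                              pseudocount=pseudocount)
        rows.append({"motif_id": motif, **shift,
                     **{kk: occ[kk] for kk in
                        ("fg_up", "fg_down", "bg", "effect_up", "effect_down")}})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_up_bonf"] = adjust_bonferroni(table["p_up"])
        table["p_down_bonf"] = adjust_bonferroni(table["p_down"])
    return table
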