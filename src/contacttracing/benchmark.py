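"""Ranked-list comparison and external-signature validation utilities.

Top-N interaction lists from different inference methods are compared with the
overlap coefficient (intersection over minimum set size, which corrects for
unequal list lengths).  Predicted up-regulated response genes are validated
against reference cytokine-response rankings with a weighted KS running-sum
connectivity score, and matched vs unmatched score distributions are compared
with a one-sided Mann-Whitney test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

# cell-type groups considered "roughly matched" when comparing response
# signatures across databases; editable by callers
DEFAULT_MATCH_GROUPS = (
    frozenset({"tumor", "epithelial", "fibroblast", "stromal"}),
    frozenset({"macrophage", "mmdsc", "pdc", "cdc", "pmn", "gr-mdsc", "monocyte"}),
    frozenset({"tcell", "bcell", "nk"}),
)


def set_similarity(x, y, kind: str = "overlap") -> float:
    """Overlap coefficient |x&y|/min(|x|,|y|) or Jaccard |x&y|/|x|y|; empty
    inputs score 0."""
    x, y = set(x), set(y)
    inter = len(x & y)
    if kind == "overlap":
        denom = min(len(x), len(y))
    elif kind == "jaccard":
        denom = len(x | y)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return inter / denom if denom else 0.0


def overlap_matrix(ranked_lists: dict, top_n: int, kind: str = "overlap") -> pd.DataFrame:
    """Pairwise overlap coefficients of each named ranking's top-N keys."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    names = list(ranked_lists)
    tops = {name: set(list(ranked_lists[name])[:top_n]) for name in names}
    out = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            out.loc[a, b] = set_similarity(tops[a], tops[b], kind=kind)
    return out


def connectivity_score(up_genes, reference_ranking) -> float:
    """Weighted KS running-sum enrichment of a gene set in a reference ranking.

    Walking down the ranking, hits increment the running sum by 1/n_hits and
    misses decrement it by 1/n_misses; the score is the signed maximum
    deviation, positive when ``up_genes`` concentrate at the top, in [-1, 1].
    Returns NaN (with a warning) when the set does not intersect the ranking.
    """
    ref = list(reference_ranking)
    up = set(up_genes)
    hits = np.array([g in up for g in ref], dtype=bool)
    n_hit = int(hits.sum())
    n_miss = len(ref) - n_hit
    if n_hit == 0 or n_miss == 0:
        logger.warning("connectivity score undefined: gene set and ranking do not "
                       "partition the reference")
        return float("nan")
    steps = np.where(hits, 1.0 / n_hit, -1.0 / n_miss)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def matched_vs_all(scores_all, scores_matched):
    """One-sided Mann-Whitney test that matched connectivity scores exceed the
    full distribution.  Returns (U, p, median_all, median_matched)."""
    a = np.asarray(scores_all, dtype=float)
    m = np.asarray(scores_matched, dtype=float)
    if a.size == 0 or m.size == 0:
        raise ValueError("both score groups must be non-empty")
    if np.unique(np.concatenate([a, m])).size == 1:
        logger.warning("identical constant groups: test degenerate, p = 0.5")
        return float(a.size * m.size / 2), 0.5, float(np.median(a)), float(np.median(m))
    method = "exact" if (a.size <= 8 and m.size <= 8) else "auto"
    res = mannwhitneyu(m, a, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue), float(np.median(a)), float(np.median(m))


def in_matched_group(cell_type_a: str, cell_type_b: str,
                     groups=DEFAULT_MATCH_GROUPS) -> bool:
    """Whether two cell-type labels fall in the same broad compartment."""
    a, b = cell_type_a.lower(), cell_type_b.lower()
    return any(a in g and b in g for g in groups)


def upregulated_response_genes(target_table: pd.DataFrame,
                               interaction_table: pd.DataFrame,
                               interaction_fdr: float = 0.05) -> set:
    """Condition-specific up-regulated response genes: positive target-test
    log2FC and interaction-test FDR below the cut."""
    up = set(target_table.loc[target_table["log2fc"] > 0, "gene"])
    sig = set(interaction_table.loc[interaction_table["fdr"] < interaction_fdr, "gene"])
    return up & sig
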