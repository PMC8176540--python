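"""Greedy minimum-subset construction and round-robin ranking.

Selection runs in two stages.  First a greedy set-cover pass over the
gene masks builds a minimum subset H*: at each step the gene whose
current mask covers the most still-uncovered samples is picked (ties
broken by smaller RPOS, then by gene identifier), the picked gene's
covered samples are removed from every remaining mask, and the loop
stops when r genes are chosen or no mask has a 1 left.  Second, the
genes outside H* are split by their relative dominant class, each group
is sorted by ascending RPOS, and the two groups are interleaved
round-robin (class-0 group first) into one ranked list.  The final set
T takes the first r genes of H*, topped up from the ranked list when
H* is shorter than r.

All tie-breaks are total (popcount, then RPOS, then gene identifier),
so the selected set is deterministic and invariant to the order in
which genes are stored.
"""

from __future__ import annotations

import numpy as np

from .core import (
    GeneMaskMatrix,
    GeneScoreRecord,
    LabeledExpressionData,
    SelectionConfig,
    SelectionResult,
)
from .scoring import score_all_genes

__all__ = ["greedy_minimum_subset", "round_robin_rank", "select_genes"]


def greedy_minimum_subset(
    masks: GeneMaskMatrix,
    scores: list[GeneScoreRecord],
    max_size: int | None,
) -> list[str]:
    """Greedy coverage over gene masks; returns gene ids in pick order.

    ``max_size=None`` runs to full coverage (until every mask is zero).
    """
    bits = masks.bits.copy()
    p = bits.shape[0]
    if len(scores) != p:
        raise ValueError("masks and scores are not aligned")
    rpos = np.array([rec.rpos for rec in scores])
    active = np.ones(p, dtype=bool)
    picked: list[int] = []
    while max_size is None or len(picked) < max_size:
        pop = bits.sum(axis=1)
        pop[~active] = -1
        best_pop = pop.max()
        if best_pop <= 0:
            break
        cand = np.flatnonzero(pop == best_pop)
        cand = cand[rpos[cand] == rpos[cand].min()]
        # residual tie: smallest gene id, so the pick is invariant to how
        # the genes happen to be stored
        j = min((int(c) for c in cand), key=lambda c: scores[c].gene_id)
        picked.append(j)
        active[j] = False
        bits &= ~bits[j]  # drop covered samples from every remaining mask
    return [scores[j].gene_id for j in picked]


def round_robin_rank(
    scores: list[GeneScoreRecord], excluded: set[str]
) -> list[str]:
    """Rank the genes outside ``excluded`` by interleaving the two RDC
    groups, each in ascending-RPOS order (ties by gene id)."""
    groups: dict[int, list[str]] = {0: [], 1: []}
    order = sorted(
        (rec for rec in scores if rec.gene_id not in excluded),
        key=lambda rec: (rec.rpos, rec.gene_id),
    )  # RPOS ties fall back to gene id for storage-order invariance
    for rec in order:
        groups[rec.rdc].append(rec.gene_id)
    ranked: list[str] = []
    g0, g1 = groups[0], groups[1]
    for k in range(max(len(g0), len(g1))):
        if k < len(g0):
            ranked.append(g0[k])
        if k < len(g1):
            ranked.append(g1[k])
    return ranked


def select_genes(
    data: LabeledExpressionData, cfg: SelectionConfig
) -> SelectionResult:
    """Run scoring and both selection stages; returns the ordered set T of
    size min(r, p) with per-gene provenance."""
    r = cfg.n_genes
    if r < 1:
        raise ValueError("n_genes must be >= 1")
    scores, masks = score_all_genes(data, cfg)
    h_star = greedy_minimum_subset(
        masks, scores, max_size=None if cfg.greedy_full_cover else r
    )
    ranked = round_robin_rank(scores, excluded=set(h_star))
    if r <= len(h_star):
        final = h_star[:r]
    else:
        final = h_star + ranked[: r - len(h_star)]
    provenance = {
        g: ("min_subset" if i < len(h_star) else "ranked")
        for i, g in enumerate(final)
    }
    return SelectionResult(
        min_subset=tuple(h_star),
        ranked_rest=tuple(ranked),
        final=tuple(final),
        provenance=provenance,
    )
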