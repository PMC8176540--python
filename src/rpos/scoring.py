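"""Sample-set partitioning, gene masks, and the RPOS score.

For a gene j with class core intervals R_{j,0}, R_{j,1}, overlap region
R^v_j and total core interval R_j:

* the non-outlier set N_j holds the samples whose expression lies inside
  their own class's core interval;
* N_j splits into the overlapped set O_j (values inside R^v_j) and the
  non-overlapped set O'_j (the rest);
* the gene mask marks the samples in O'_j — those the gene classifies
  unambiguously — and drives the greedy coverage stage;
* the score

      RPOS_j = 4 * (len(R^v_j)/len(R_j)) * (|O_j|/|N_j|) * phi_0 * phi_1,

  with phi_c = |O_{j,c}|/|O_j| the class shares of the overlapped
  samples, lies in [0, 1]; the factor 4 is the normalising maximum of
  1/(phi_0*phi_1).  Smaller RPOS means a more discriminative gene.

Degenerate genes are scored by convention: no overlapped samples means
a maximally discriminative gene (score 0), while a zero-length total
interval (constant gene) or empty non-outlier set carries no
discriminative geometry and scores 1.

The relative dominant class (RDC) is the class with the larger fraction
of mask-marked samples — the class the gene separates better.
"""

from __future__ import annotations

import numpy as np

from .core import (
    GeneIntervalProfile,
    GeneMaskMatrix,
    GeneScoreRecord,
    LabeledExpressionData,
    SelectionConfig,
)
from .intervals import gene_profile

__all__ = [
    "non_outlier_set",
    "partition_overlap",
    "gene_mask_row",
    "rpos_score",
    "relative_dominant_class",
    "score_all_genes",
]


def non_outlier_set(gene_row, labels, profile: GeneIntervalProfile) -> set[int]:
    """Indices of samples whose value lies in their own class core interval
    (closed endpoints)."""
    gene_row = np.asarray(gene_row, dtype=float)
    labels = np.asarray(labels)
    own = [profile.class0_interval, profile.class1_interval]
    return {i for i in range(gene_row.size) if own[labels[i]].contains(gene_row[i])}


def partition_overlap(
    nonoutlier: set[int], gene_row, profile: GeneIntervalProfile
) -> tuple[set[int], set[int]]:
    """Split the non-outlier set into (non-overlapped O', overlapped O) by
    membership of the value in the overlap region."""
    gene_row = np.asarray(gene_row, dtype=float)
    overlapped = {i for i in nonoutlier if profile.overlap.contains(gene_row[i])}
    return nonoutlier - overlapped, overlapped


def gene_mask_row(gene_row, labels, profile: GeneIntervalProfile) -> np.ndarray:
    """Binary mask of length n: 1 for samples in O'_j (inside their own class
    interval and outside the overlap region), 0 otherwise."""
    gene_row = np.asarray(gene_row, dtype=float)
    nonoutlier = non_outlier_set(gene_row, labels, profile)
    nonoverlapped, _ = partition_overlap(nonoutlier, gene_row, profile)
    mask = np.zeros(gene_row.size, dtype=bool)
    mask[sorted(nonoverlapped)] = True
    return mask


def rpos_score(
    profile: GeneIntervalProfile,
    nonoutlier: set[int],
    overlapped: set[int],
    per_class_overlap_counts: tuple[int, int],
) -> float:
    """The robust proportional overlapping score of one gene, in [0, 1]."""
    n_non = len(nonoutlier)
    n_ov = len(overlapped)
    len_total = profile.total.length()
    if n_non == 0 or len_total == 0.0:
        return 1.0
    if n_ov == 0:
        return 0.0
    c0, c1 = per_class_overlap_counts
    phi0 = c0 / n_ov
    phi1 = c1 / n_ov
    return 4.0 * (profile.overlap.length() / len_total) * (n_ov / n_non) * phi0 * phi1


def relative_dominant_class(mask_row, labels) -> int:
    """Class with the larger fraction of mask-marked samples; ties go to
    class 0."""
    mask_row = np.asarray(mask_row).astype(bool)
    labels = np.asarray(labels)
    frac = [mask_row[labels == c].mean() for c in (0, 1)]
    return 0 if frac[0] >= frac[1] else 1


def score_gene(gene_row, labels, cfg: SelectionConfig) -> tuple[GeneScoreRecord, np.ndarray]:
    """Score a single gene; returns its record and mask row.

    Composes the definitional operations above; ``score_all_genes`` is
    the vectorised equivalent for whole matrices.
    """
    gene_row = np.asarray(gene_row, dtype=float)
    labels = np.asarray(labels)
    profile = gene_profile(gene_row, labels, cfg)
    nonoutlier = non_outlier_set(gene_row, labels, profile)
    nonoverlapped, overlapped = partition_overlap(nonoutlier, gene_row, profile)
    counts = (
        sum(1 for i in overlapped if labels[i] == 0),
        sum(1 for i in overlapped if labels[i] == 1),
    )
    mask = np.zeros(gene_row.size, dtype=bool)
    mask[sorted(nonoverlapped)] = True
    rec = GeneScoreRecord(
        gene_id="",
        rpos=rpos_score(profile, nonoutlier, overlapped, counts),
        rdc=relative_dominant_class(mask, labels),
        n_nonoutlier=len(nonoutlier),
        n_overlapped=len(overlapped),
        n_overlapped_by_class=counts,
    )
    return rec, mask


def score_all_genes(
    data: LabeledExpressionData, cfg: SelectionConfig
) -> tuple[list[GeneScoreRecord], GeneMaskMatrix]:
    """Score every gene of a labeled matrix; vectorised across genes.

    Returns one record per gene in input order and the aligned mask
    matrix.  Identical, up to floating-point representation of the same
    operations, to applying ``score_gene`` row by row.
    """
    Z = data.values
    labels = data.labels
    p, n = Z.shape

    lo = np.empty((2, p))
    hi = np.empty((2, p))
    for c in (0, 1):
        Xc = Z[:, labels == c]
        q1, q3 = np.quantile(Xc, [0.25, 0.75], axis=1, method="linear")
        if cfg.dispersion == "mad":
            med = np.median(Xc, axis=1)
            disp = np.median(np.abs(Xc - med[:, None]), axis=1)
        else:
            disp = q3 - q1
        lo[c] = q1 - cfg.mad_multiplier * disp
        hi[c] = q3 + cfg.mad_multiplier * disp

    ov_lo = np.maximum(lo[0], lo[1])
    ov_hi = np.minimum(hi[0], hi[1])
    ov_empty = ov_lo > ov_hi
    ov_len = np.where(ov_empty, 0.0, ov_hi - ov_lo)
    tot_lo = np.minimum(lo[0], lo[1])
    tot_hi = np.maximum(hi[0], hi[1])
    tot_len = tot_hi - tot_lo

    own_lo = np.where(labels[None, :] == 0, lo[0][:, None], lo[1][:, None])
    own_hi = np.where(labels[None, :] == 0, hi[0][:, None], hi[1][:, None])
    nonoutlier = (Z >= own_lo) & (Z <= own_hi)
    in_overlap = (~ov_empty[:, None]) & (Z >= ov_lo[:, None]) & (Z <= ov_hi[:, None])
    overlapped = nonoutlier & in_overlap
    mask = nonoutlier & ~in_overlap  # O'_j rows

    n_non = nonoutlier.sum(axis=1)
    n_ov = overlapped.sum(axis=1)
    n_ov_c = np.stack(
        [(overlapped & (labels[None, :] == c)).sum(axis=1) for c in (0, 1)]
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        phi = n_ov_c / n_ov  # nan where n_ov == 0, patched below
        score = 4.0 * (ov_len / tot_len) * (n_ov / n_non) * phi[0] * phi[1]
    score = np.where(n_ov == 0, 0.0, score)
    score = np.where((n_non == 0) | (tot_len == 0.0), 1.0, score)

    frac = np.stack(
        [mask[:, labels == c].mean(axis=1) for c in (0, 1)]
    )
    rdc = np.where(frac[0] >= frac[1], 0, 1)

    records = [
        GeneScoreRecord(
            gene_id=data.gene_ids[j],
            rpos=float(score[j]),
            rdc=int(rdc[j]),
            n_nonoutlier=int(n_non[j]),
            n_overlapped=int(n_ov[j]),
            n_overlapped_by_class=(int(n_ov_c[0, j]), int(n_ov_c[1, j])),
        )
        for j in range(p)
    ]
    return records, GeneMaskMatrix(bits=mask)
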