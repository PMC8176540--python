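"""Core domain types for overlap-based gene selection.

The central object is a labeled expression matrix ``Z`` of shape
(p genes, n samples) with a binary class label per sample.  Interval
geometry (per-class core intervals, their overlap, their total span)
and the selection configuration/result containers live here so that
every stage of the pipeline shares one vocabulary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "Interval",
    "GeneIntervalProfile",
    "LabeledExpressionData",
    "GeneMaskMatrix",
    "GeneScoreRecord",
    "SelectionConfig",
    "SelectionResult",
]


class ValidationError(ValueError):
    """Raised when input data violate the structural contract."""


@dataclass(frozen=True)
class Interval:
    """A closed interval [lo, hi], possibly empty.

    Membership tests use closed endpoints: a value exactly on a boundary
    belongs to the interval.  An empty interval has length 0 and contains
    nothing.
    """

    lo: float = 0.0
    hi: float = 0.0
    empty: bool = False

    def __post_init__(self) -> None:
        if not self.empty and self.lo > self.hi:
            raise ValueError(f"lo={self.lo} > hi={self.hi} in non-empty interval")

    @classmethod
    def empty_interval(cls) -> "Interval":
        return cls(0.0, 0.0, empty=True)

    def length(self) -> float:
        return 0.0 if self.empty else self.hi - self.lo

    def contains(self, x: float) -> bool:
        return (not self.empty) and self.lo <= x <= self.hi


@dataclass(frozen=True)
class GeneIntervalProfile:
    """Per-gene interval geometry: the two class core intervals, their
    intersection (overlap region) and their total span."""

    class0_interval: Interval
    class1_interval: Interval
    overlap: Interval
    total: Interval


class LabeledExpressionData:
    """Expression matrix with binary labels, genes in rows.

    Parameters
    ----------
    values
        Matrix of shape (p, n): expression of gene j in sample i.
    gene_ids, sample_ids
        Unique identifiers for rows and columns.
    labels
        Integer class codes in {0, 1}, one per sample.
    class_names
        The original two label values, in the sorted order that was
        mapped onto (0, 1).
    """

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        labels: np.ndarray,
        class_names: tuple = ("0", "1"),
    ) -> None:
        values = np.asarray(values, dtype=float)
        labels = np.asarray(labels)
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        p, n = values.shape
        if len(gene_ids) != p:
            raise ValidationError(f"{len(gene_ids)} gene ids for {p} genes")
        if len(sample_ids) != n or len(labels) != n:
            raise ValidationError("sample ids/labels do not match matrix width")
        if not np.all(np.isfinite(values)):
            j, i = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value for gene {gene_ids[j]!r}, "
                f"sample {sample_ids[i]!r}"
            )
        if len(set(gene_ids)) != p:
            raise ValidationError("gene ids are not unique")
        uniq = np.unique(labels)
        if not (uniq.size == 2 and set(uniq.tolist()) == {0, 1}):
            raise ValidationError(
                f"labels must contain exactly the two classes 0 and 1, got {uniq}"
            )
        for c in (0, 1):
            n_c = int(np.sum(labels == c))
            if n_c < 2:
                raise ValidationError(f"class {c} has {n_c} sample(s); at least 2 required")
            if n_c < 4:
                warnings.warn(
                    f"class {c} has only {n_c} samples; quartile-based intervals "
                    "will be unstable",
                    stacklevel=2,
                )
        self.values = values
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.labels = labels.astype(int)
        self.class_names = class_names

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_indices(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    # -- constructors / views -------------------------------------------
    @classmethod
    def from_raw_labels(
        cls,
        values: np.ndarray,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        raw_labels: Sequence,
    ) -> "LabeledExpressionData":
        """Map two arbitrary label values onto {0, 1} by sorted order."""
        distinct = set(raw_labels)
        if len(distinct) != 2:
            raise ValidationError(
                f"expected exactly 2 distinct labels, got {len(distinct)}: "
                f"{sorted(map(str, distinct))}"
            )
        try:
            ordered = sorted(distinct)
        except TypeError:  # mixed types; fall back to string order
            ordered = sorted(distinct, key=str)
        mapping = {ordered[0]: 0, ordered[1]: 1}
        labels = np.array([mapping[v] for v in raw_labels])
        return cls(values, gene_ids, sample_ids, labels,
                   class_names=(ordered[0], ordered[1]))

    def subset_samples(self, idx: np.ndarray) -> "LabeledExpressionData":
        idx = np.asarray(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return LabeledExpressionData(
                self.values[:, idx],
                self.gene_ids,
                [self.sample_ids[i] for i in idx],
                self.labels[idx],
                class_names=self.class_names,
            )

    def subset_genes(self, idx: Sequence[int]) -> "LabeledExpressionData":
        idx = list(idx)
        return LabeledExpressionData(
            self.values[idx, :],
            [self.gene_ids[j] for j in idx],
            self.sample_ids,
            self.labels,
            class_names=self.class_names,
        )


@dataclass
class GeneMaskMatrix:
    """Binary matrix (p, n): entry 1 marks a sample that gene j places in
    its own class core interval and outside the overlap region — i.e. a
    sample the gene classifies unambiguously."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits).astype(bool)

    def popcounts(self) -> np.ndarray:
        return self.bits.sum(axis=1)


@dataclass(frozen=True)
class GeneScoreRecord:
    """Per-gene score summary.

    ``rpos`` is the robust proportional overlapping score in [0, 1]
    (smaller = more discriminative); ``rdc`` is the relative dominant
    class the gene distinguishes better.
    """

    gene_id: str
    rpos: float
    rdc: int
    n_nonoutlier: int
    n_overlapped: int
    n_overlapped_by_class: tuple


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable parameters of interval construction and selection.

    mad_multiplier
        Width multiplier on the dispersion added around the quartiles
        when building class core intervals (default 0.9).
    dispersion
        'mad' (robust, default) or 'iqr' (baseline variant).
    n_genes
        Number of genes r in the final selected set.
    greedy_full_cover
        If True the greedy stage runs until all masks are exhausted
        rather than stopping at r picks.
    """

    mad_multiplier: float = 0.9
    dispersion: str = "mad"
    n_genes: int = 10
    positive_class: int = 1
    seed: int = 0
    greedy_full_cover: bool = False

    def __post_init__(self) -> None:
        if self.mad_multiplier < 0:
            raise ValueError("mad_multiplier must be >= 0")
        if self.dispersion not in ("mad", "iqr"):
            raise ValueError(f"dispersion must be 'mad' or 'iqr', got {self.dispersion!r}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    def with_n_genes(self, r: int) -> "SelectionConfig":
        return replace(self, n_genes=r)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the two-stage selection.

    min_subset
        Greedy minimum subset H*, in pick order.
    ranked_rest
        Remaining genes ranked round-robin across the two RDC groups.
    final
        The ordered selected set T of size min(r, p).
    provenance
        Per final gene: 'min_subset' or 'ranked'.
    """

    min_subset: tuple
    ranked_rest: tuple
    final: tuple
    provenance: dict = field(default_factory=dict)
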