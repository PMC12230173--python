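"""Pairwise genotype identity and contiguous site-pattern ("continuity") analysis.

Over an ordered panel of taxa (one representative sample each), a homozygous
biallelic site supports genomic continuity when its allele changes exactly
once along the order: taxa ``1..k`` carry one allele, taxa ``k+1..n`` the
other (label ``split_k``). Sites whose allele switches more than once are
non-contiguous. For a seven-taxon panel the split types are displayed with
the letters A–F (A = ``split_1`` — variants specific to the first taxon, and
so on). The fraction of examined sites that are contiguous measures how close
the panel's genomes come to a one-dimensional continuum between the two
extreme taxa.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import VariantTable

__all__ = [
    "NONCONTIGUOUS",
    "PatternAssignment",
    "ContinuityTable",
    "pairwise_identity",
    "select_hom_biallelic",
    "classify_patterns",
    "continuity_summary",
    "continuity_table_from_counts",
    "best_order",
]

NONCONTIGUOUS = "NONCONTIGUOUS"
_LETTERS = "ABCDEFGHI"


def split_label(k: int, n_taxa: int) -> str:
    """Display label for a contiguous split after position k (1-based)."""
    if n_taxa == 7:
        return _LETTERS[k - 1]
    return f"split_{k}"


@dataclass
class PatternAssignment:
    """Per-locus continuity pattern over an ordered taxon panel.

    ``split_after[i]`` is k (1..n-1) for a contiguous split after the k-th
    taxon, or 0 for a non-contiguous site.
    """

    order: list[str]
    locus_indices: np.ndarray
    split_after: np.ndarray

    @property
    def n_taxa(self) -> int:
        return len(self.order)

    def labels(self) -> list[str]:
        return [
            split_label(k, self.n_taxa) if k > 0 else NONCONTIGUOUS
            for k in self.split_after
        ]


@dataclass
class ContinuityTable:
    """Counts and percentages per split type, plus the continuity total.

    Percent denominators use the examined (homozygous-biallelic) total;
    cumulative percentages are computed from cumulative counts, then rounded.
    """

    type_labels: list[str]
    counts: list[int]
    examined: int

    def __post_init__(self) -> None:
        if sum(self.counts) > self.examined:
            raise ValueError("split-type counts exceed examined total")

    @property
    def continuity_total(self) -> int:
        return sum(self.counts)

    @property
    def continuity_percent(self) -> float:
        return round(self.continuity_total / self.examined * 100.0, 2)

    @property
    def noncontiguous(self) -> int:
        return self.examined - self.continuity_total

    def percents(self) -> list[float]:
        return [round(c / self.examined * 100.0, 2) for c in self.counts]

    def cumulative_percents(self) -> list[float]:
        cum = np.cumsum(self.counts)
        return [round(c / self.examined * 100.0, 2) for c in cum]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "GROUP": self.type_labels,
                "SNP_num": self.counts,
                "Percent": self.percents(),
                "Cumulative_percentage": self.cumulative_percents(),
            }
        )


def pairwise_identity(table: VariantTable, samples: Sequence[str]) -> pd.DataFrame:
    """Symmetric matrix of identical-genotype locus counts between samples.

    Two genotypes are identical when both samples are called and carry the
    same unordered allele pair (same homozygote, or same heterozygote). The
    diagonal holds each sample's called-locus count.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    cols = table.sample_indices(samples)
    gt = table.gt[:, cols, :]  # (L, S, 2), pairs sorted ascending
    called = (gt >= 0).all(axis=2)
    n = len(samples)
    mat = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        mat[i, i] = int(called[:, i].sum())
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            same = (gt[:, i, :] == gt[:, j, :]).all(axis=1)
            mat[i, j] = mat[j, i] = int((both & same).sum())
    return pd.DataFrame(mat, index=samples, columns=samples)


def select_hom_biallelic(
    table: VariantTable, samples: Sequence[str]
) -> np.ndarray:
    """Loci where every sample is called homozygous and exactly 2 alleles occur.

    Returns the retained locus indices. "Biallelic" is assessed across the
    listed panel samples only: monomorphic sites and sites with three or more
    observed alleles are excluded.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("samples must be nonempty")
    cols = table.sample_indices(samples)
    gt = table.gt[:, cols, :]
    called_hom = ((gt >= 0).all(axis=2)) & (gt[:, :, 0] == gt[:, :, 1])
    all_hom = called_hom.all(axis=1)
    alleles = gt[:, :, 0]  # valid where all_hom
    amin = alleles.min(axis=1)
    amax = alleles.max(axis=1)
    two = amin != amax
    # exactly two distinct: every allele equals min or max, and min != max
    only_two = ((alleles == amin[:, None]) | (alleles == amax[:, None])).all(axis=1)
    return np.flatnonzero(all_hom & two & only_two)


def classify_patterns(
    subset: np.ndarray, table: VariantTable, order: Sequence[str]
) -> PatternAssignment:
    """Assign each homozygous-biallelic locus a contiguous-split label.

    ``split_k`` iff the homozygous allele changes exactly once along *order*,
    between positions k and k+1; otherwise non-contiguous.
    """
    order = list(order)
    cols = table.sample_indices(order)
    subset = np.asarray(subset, dtype=np.intp)
    gt = table.gt[subset][:, cols, :]
    if ((gt < 0).any(axis=(1, 2)) | (gt[:, :, 0] != gt[:, :, 1]).any(axis=1)).any():
        raise ValueError(
            "subset contains loci with missing or heterozygous panel calls; "
            "build it with select_hom_biallelic over the same ordered samples"
        )
    alleles = gt[:, :, 0]  # (K, n)
    changes = alleles[:, 1:] != alleles[:, :-1]  # (K, n-1)
    n_changes = changes.sum(axis=1)
    change_pos = np.argmax(changes, axis=1) + 1  # first change index, 1-based k
    split_after = np.where(n_changes == 1, change_pos, 0).astype(np.int64)
    return PatternAssignment(
        order=order, locus_indices=subset, split_after=split_after
    )


def continuity_summary(assignment: PatternAssignment) -> ContinuityTable:
    """Tabulate split-type counts, percents, cumulative percents."""
    n = assignment.n_taxa
    counts = [
        int((assignment.split_after == k).sum()) for k in range(1, n)
    ]
    labels = [split_label(k, n) for k in range(1, n)]
    return ContinuityTable(
        type_labels=labels, counts=counts, examined=len(assignment.split_after)
    )


def continuity_table_from_counts(
    counts: Sequence[int], examined: int, n_taxa: int | None = None
) -> ContinuityTable:
    """Build a ContinuityTable directly from split-type counts.

    Useful for re-deriving percentages and the continuity total from published
    count tables without the underlying genotypes.
    """
    counts = [int(c) for c in counts]
    n = n_taxa if n_taxa is not None else len(counts) + 1
    labels = [split_label(k, n) for k in range(1, len(counts) + 1)]
    return ContinuityTable(type_labels=labels, counts=counts, examined=examined)


def best_order(
    subset: np.ndarray, table: VariantTable, samples: Sequence[str]
) -> tuple[list[str], int]:
    """Exhaustively find the taxon order maximizing the continuity total.

    Orders are evaluated up to reversal symmetry (a reversed order yields the
    same continuity total); ties break lexicographically on the sample-id
    sequence. Exhaustive search is limited to 10 samples.
    """
    samples = list(samples)
    if len(samples) > 10:
        raise ValueError(
            "exhaustive order search is limited to 10 samples; heuristic "
            "ordering is out of scope"
        )
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    cols = table.sample_indices(samples)
    subset = np.asarray(subset, dtype=np.intp)
    alleles = table.gt[subset][:, cols, 0]  # (K, n); hom-biallelic guaranteed
    best: tuple[list[str], int] | None = None
    for perm in itertools.permutations(range(len(samples))):
        names = [samples[i] for i in perm]
        if names > names[::-1]:  # evaluate each order once, up to reversal
            continue
        a = alleles[:, perm]
        n_changes = (a[:, 1:] != a[:, :-1]).sum(axis=1)
        score = int((n_changes == 1).sum())
        if best is None or score > best[1] or (score == best[1] and names < best[0]):
            best = (names, score)
    return best
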