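"""Discovery of diagnostic (fixed-difference) loci between two parental groups.

A locus is *diagnostic* when every individual of parental group P is called
and homozygous for one allele, every individual of group M is called and
homozygous for a different allele. In an F1 hybrid of the two species, every
diagnostic locus is expected to be heterozygous, which is the basis of the
hybrid-identification analysis downstream.

By default discovery runs in *complete-case* mode: loci where any candidate
hybrid is uncalled are dropped as well, so each candidate's downstream group
counts share the diagnostic total as a common denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .variant_io import VariantTable

__all__ = ["DiagnosticSet", "find_diagnostic_loci", "diagnostic_summary"]


@dataclass
class DiagnosticSet:
    """Diagnostic loci plus the allele fixed in each parental group.

    ``locus_indices`` index rows of the source :class:`VariantTable`;
    ``allele_p[i]`` / ``allele_m[i]`` are allele indices into that locus's
    allele list, with ``allele_p != allele_m`` everywhere.
    """

    locus_indices: np.ndarray
    allele_p: np.ndarray
    allele_m: np.ndarray

    def __post_init__(self) -> None:
        self.locus_indices = np.asarray(self.locus_indices, dtype=np.intp)
        self.allele_p = np.asarray(self.allele_p, dtype=np.int32)
        self.allele_m = np.asarray(self.allele_m, dtype=np.int32)
        if not (
            len(self.locus_indices) == len(self.allele_p) == len(self.allele_m)
        ):
            raise ValueError("locus/allele arrays must have equal length")
        if np.any(self.allele_p == self.allele_m):
            raise ValueError("allele_p must differ from allele_m at every locus")

    @property
    def total(self) -> int:
        return len(self.locus_indices)

    def __len__(self) -> int:
        return self.total

    def to_frame(self, table: VariantTable):
        """Tabular view: chrom, pos, ref, parental alleles, vtype."""
        import pandas as pd

        rows = []
        for k, i in enumerate(self.locus_indices):
            loc = table.loci[i]
            rows.append(
                {
                    "chrom": loc.chrom,
                    "pos": loc.pos,
                    "ref": loc.ref,
                    "allele_p": loc.alleles[self.allele_p[k]],
                    "allele_m": loc.alleles[self.allele_m[k]],
                    "vtype": loc.vtype,
                }
            )
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "allele_p", "allele_m", "vtype"]
        )


def _fixed_hom_allele(
    gt: np.ndarray, cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per locus: is the group all-called, all-homozygous, all one allele?

    Returns (mask, allele) where ``allele`` is valid only where ``mask``.
    """
    sub = gt[:, cols, :]  # (L, g, 2)
    called = (sub >= 0).all(axis=2)  # (L, g)
    hom = called & (sub[:, :, 0] == sub[:, :, 1])
    all_hom = hom.all(axis=1)
    first = sub[:, 0, 0]
    consistent = (sub[:, :, 0] == first[:, None]).all(axis=1)
    return all_hom & consistent, first


def find_diagnostic_loci(
    table: VariantTable,
    group_p: Sequence[str],
    group_m: Sequence[str],
    require_candidate_calls: Iterable[str] = (),
) -> DiagnosticSet:
    """Find loci fixed for distinct homozygous alleles in the two groups.

    Parameters
    ----------
    table:
        Genotype matrix.
    group_p, group_m:
        Disjoint, nonempty parental sample groups.
    require_candidate_calls:
        Additional samples (normally the candidate hybrids) that must also be
        called at a locus for it to be retained — complete-case mode. Pass an
        empty sequence to disable.

    Multi-allelic records can qualify: only the two parental alleles matter,
    further declared ALTs are ignored.
    """
    group_p, group_m = list(group_p), list(group_m)
    if not group_p or not group_m:
        raise ValueError("both parental groups must be nonempty")
    if set(group_p) & set(group_m):
        raise ValueError(
            f"parental groups overlap: {sorted(set(group_p) & set(group_m))}"
        )
    if table.n_loci == 0:
        empty = np.empty(0, dtype=np.intp)
        return DiagnosticSet(empty, np.empty(0, np.int32), np.empty(0, np.int32))

    cols_p = table.sample_indices(group_p)
    cols_m = table.sample_indices(group_m)
    ok_p, allele_p = _fixed_hom_allele(table.gt, cols_p)
    ok_m, allele_m = _fixed_hom_allele(table.gt, cols_m)
    keep = ok_p & ok_m & (allele_p != allele_m)

    cand = list(require_candidate_calls)
    if cand:
        cols_c = table.sample_indices(cand)
        keep &= (table.gt[:, cols_c, :] >= 0).all(axis=(1, 2))

    idx = np.flatnonzero(keep)
    return DiagnosticSet(idx, allele_p[idx], allele_m[idx])


def diagnostic_summary(diag: DiagnosticSet, table: VariantTable) -> dict:
    """Per-chromosome and per-variant-type counts of the diagnostic set."""
    per_chrom: dict[str, int] = {}
    per_vtype = {"SNP": 0, "INDEL": 0}
    for i in diag.locus_indices:
        loc = table.loci[i]
        per_chrom[loc.chrom] = per_chrom.get(loc.chrom, 0) + 1
        per_vtype[loc.vtype] += 1
    return {"total": diag.total, "per_chrom": per_chrom, "per_vtype": per_vtype}
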