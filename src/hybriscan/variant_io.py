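"""Reading and writing VCF/BED and the in-memory genotype matrix.

The central container is :class:`VariantTable`: a loci x samples matrix of
genotype calls with per-sample total depth (DP) and per-allele depths (AD),
plus locus metadata (chromosome, position, alleles, SNP/INDEL class). All
downstream analyses — diagnostic-locus discovery, hybrid classification,
continuity patterns — operate on this table.

Internally genotypes are held as a ``(n_loci, n_samples, 2)`` integer array of
allele indices (``-1`` marks a missing call), depths as ``(n_loci, n_samples)``
integers and allele depths as a ``(n_loci, n_samples, max_alleles)`` array
padded with ``-1`` where AD was absent. VCF access goes through pysam.
"""

from __future__ import annotations

import io
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeCall",
    "Locus",
    "VariantTable",
    "GeneIntervals",
    "VcfParseError",
    "BedParseError",
    "parse_variants",
    "write_variants",
    "load_intervals",
    "map_loci_to_genes",
]


class VcfParseError(ValueError):
    """Raised when a VCF header or record cannot be interpreted."""


class BedParseError(ValueError):
    """Raised for malformed BED input; carries the offending line number."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one locus.

    ``alleles`` is an ascending pair of allele indices into the locus allele
    list, or ``(MISSING, MISSING)`` for an uncalled genotype. ``dp`` is the
    total read depth; ``ad`` the per-allele read depths (``None`` when the
    caller did not emit AD). ``sum(ad) <= dp`` is deliberately not assumed.
    """

    alleles: tuple[int, int]
    dp: int = 0
    ad: tuple[int, ...] | None = None

    @property
    def is_missing(self) -> bool:
        return self.alleles[0] == MISSING or self.alleles[1] == MISSING

    @property
    def is_homozygous(self) -> bool:
        return not self.is_missing and self.alleles[0] == self.alleles[1]

    @property
    def is_heterozygous(self) -> bool:
        return not self.is_missing and self.alleles[0] != self.alleles[1]


@dataclass(frozen=True)
class Locus:
    """A variant site: chromosome, 1-based position, REF and ALT alleles."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    vtype: str = field(init=False)

    def __post_init__(self) -> None:
        is_snp = len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)
        object.__setattr__(self, "vtype", "SNP" if is_snp else "INDEL")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alts)


class VariantTable:
    """Loci x samples matrix of genotype calls with depths.

    Parameters
    ----------
    loci:
        Sequence of :class:`Locus`; stored sorted by (chrom, pos).
    samples:
        Unique sample identifiers, column order of the matrices.
    gt:
        ``(L, S, 2)`` array of allele indices, ``-1`` for missing.
    dp:
        ``(L, S)`` array of total depths.
    ad:
        ``(L, S, A_max)`` array of per-allele depths, ``-1`` padding for
        alleles beyond a locus's allele count or absent AD fields.
    """

    def __init__(
        self,
        loci: Sequence[Locus],
        samples: Sequence[str],
        gt: np.ndarray,
        dp: np.ndarray,
        ad: np.ndarray,
    ) -> None:
        samples = list(samples)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        loci = list(loci)
        gt = np.asarray(gt, dtype=np.int32)
        dp = np.asarray(dp, dtype=np.int64)
        ad = np.asarray(ad, dtype=np.int64)
        L, S = len(loci), len(samples)
        if gt.shape != (L, S, 2) or dp.shape != (L, S) or ad.shape[:2] != (L, S):
            raise ValueError(
                f"shape mismatch: {L} loci x {S} samples vs "
                f"gt {gt.shape}, dp {dp.shape}, ad {ad.shape}"
            )
        order = sorted(range(L), key=lambda i: (loci[i].chrom, loci[i].pos))
        self.loci: list[Locus] = [loci[i] for i in order]
        self.samples: list[str] = samples
        idx = np.asarray(order, dtype=np.intp)
        self.gt = gt[idx]
        self.dp = dp[idx]
        self.ad = ad[idx]
        self._sample_index: dict[str, int] = {s: j for j, s in enumerate(samples)}

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"unknown sample id: {sample!r}") from None

    def sample_indices(self, samples: Iterable[str]) -> np.ndarray:
        return np.asarray([self.sample_index(s) for s in samples], dtype=np.intp)

    def call(self, locus_idx: int, sample: str | int) -> GenotypeCall:
        j = sample if isinstance(sample, int) else self.sample_index(sample)
        a = self.gt[locus_idx, j]
        n_alleles = len(self.loci[locus_idx].alleles)
        ad_row = self.ad[locus_idx, j, :n_alleles]
        ad = tuple(int(x) for x in ad_row) if (ad_row >= 0).all() else None
        return GenotypeCall(
            alleles=(int(a[0]), int(a[1])), dp=int(self.dp[locus_idx, j]), ad=ad
        )

    # boolean masks used throughout the pipeline
    def called_mask(self) -> np.ndarray:
        """(L, S) True where the genotype is called."""
        return (self.gt >= 0).all(axis=2)

    def hom_mask(self) -> np.ndarray:
        """(L, S) True where called and homozygous."""
        return self.called_mask() & (self.gt[:, :, 0] == self.gt[:, :, 1])

    def positions(self) -> np.ndarray:
        return np.asarray([loc.pos for loc in self.loci], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.asarray([loc.chrom for loc in self.loci], dtype=object)

    def locus_keys(self) -> list[tuple[str, int]]:
        return [(loc.chrom, loc.pos) for loc in self.loci]

    def __repr__(self) -> str:
        return f"VariantTable({self.n_loci} loci x {self.n_samples} samples)"


@dataclass
class GeneIntervals:
    """Gene intervals in BED convention: 0-based half-open [start, end)."""

    records: list[tuple[str, int, int, str]]

    def __len__(self) -> int:
        return len(self.records)

    def trees(self) -> dict[str, IntervalTree]:
        by_chrom: dict[str, IntervalTree] = {}
        for chrom, start, end, gene_id in self.records:
            by_chrom.setdefault(chrom, IntervalTree()).addi(start, end, gene_id)
        return by_chrom


def _materialize(source) -> tuple[str, bool]:
    """Return a filesystem path for *source*; flag says whether it is a temp copy."""
    if isinstance(source, (str, os.PathLike)):
        return os.fspath(source), False
    text = source.read()
    if isinstance(text, bytes):
        text = text.decode()
    tmp = tempfile.NamedTemporaryFile(
        "w", suffix=".vcf", delete=False, encoding="utf-8"
    )
    tmp.write(text)
    tmp.close()
    return tmp.name, True


def parse_variants(source) -> VariantTable:
    """Read a multi-sample VCF (path or file-like) into a :class:`VariantTable`.

    GT is required per record; DP and AD are read when present. ``./.`` (or any
    genotype with a missing allele) maps to a missing call; phased separators
    are treated as unphased. When DP is absent it defaults to ``sum(AD)``, and
    to 0 when both are absent. Symbolic alleles (``<DEL>`` etc.) are rejected.
    """
    path, is_tmp = _materialize(source)
    try:
        try:
            vcf = pysam.VariantFile(path)
        except (ValueError, OSError) as exc:
            raise VcfParseError(f"malformed VCF header: {exc}") from exc
        with vcf:
            samples = list(vcf.header.samples)
            if len(set(samples)) != len(samples):
                raise VcfParseError("duplicate sample id in VCF header")
            loci: list[Locus] = []
            gt_rows, dp_rows, ad_rows = [], [], []
            max_alleles = 1
            try:
                records = list(vcf)
            except (ValueError, OSError) as exc:
                raise VcfParseError(f"malformed VCF record: {exc}") from exc
            for line_no, rec in enumerate(records, start=1):
                alts = tuple(rec.alts) if rec.alts else ()
                for allele in (rec.ref, *alts):
                    if allele is None or any(c in "<>[]" for c in allele):
                        raise VcfParseError(
                            f"record {line_no} ({rec.chrom}:{rec.pos}): "
                            f"symbolic or breakend allele {allele!r} not supported"
                        )
                loci.append(Locus(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alts=alts))
                n_alleles = 1 + len(alts)
                max_alleles = max(max_alleles, n_alleles)
                gt_row, dp_row, ad_row = [], [], []
                for s in samples:
                    call = rec.samples[s]
                    alleles = call.get("GT", (None, None))
                    if (
                        alleles is None
                        or len(alleles) != 2
                        or any(a is None for a in alleles)
                    ):
                        pair = (MISSING, MISSING)
                    else:
                        if any(a < 0 or a >= n_alleles for a in alleles):
                            raise VcfParseError(
                                f"record {line_no} ({rec.chrom}:{rec.pos}): "
                                f"GT allele index out of range for sample {s}"
                            )
                        pair = tuple(sorted(int(a) for a in alleles))
                    ad = call.get("AD", None)
                    if ad is not None and all(x is None for x in ad):
                        ad = None
                    if ad is not None:
                        ad = [0 if x is None else int(x) for x in ad]
                    dp = call.get("DP", None)
                    if dp is None:
                        dp = int(sum(ad)) if ad is not None else 0
                    gt_row.append(pair)
                    dp_row.append(int(dp))
                    ad_row.append(ad)
                gt_rows.append(gt_row)
                dp_rows.append(dp_row)
                ad_rows.append(ad_row)
    finally:
        if is_tmp:
            os.unlink(path)

    L, S = len(loci), len(samples)
    gt = np.full((L, S, 2), MISSING, dtype=np.int32)
    dp = np.zeros((L, S), dtype=np.int64)
    ad = np.full((L, S, max_alleles), MISSING, dtype=np.int64)
    for i in range(L):
        for j in range(S):
            gt[i, j] = gt_rows[i][j]
            dp[i, j] = dp_rows[i][j]
            row_ad = ad_rows[i][j]
            if row_ad is not None:
                ad[i, j, : len(row_ad)] = row_ad
    return VariantTable(loci, samples, gt, dp, ad)


def write_variants(table: VariantTable, dest) -> None:
    """Write *dest* (path or text file-like) as VCF 4.2 with GT:DP:AD.

    Round-trips through :func:`parse_variants`: genotypes, DP, AD and locus
    fields are preserved exactly.
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    for chrom in dict.fromkeys(loc.chrom for loc in table.loci):
        header.contigs.add(chrom)
    for s in table.samples:
        header.add_sample(s)

    tmp = tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False)
    tmp.close()
    try:
        with pysam.VariantFile(tmp.name, "w", header=header) as out:
            for i, loc in enumerate(table.loci):
                rec = out.new_record(
                    contig=loc.chrom,
                    start=loc.pos - 1,
                    stop=loc.pos - 1 + len(loc.ref),
                    alleles=loc.alleles if loc.alts else (loc.ref, "."),
                )
                rec.id = None
                for j, s in enumerate(table.samples):
                    a = table.gt[i, j]
                    if a[0] == MISSING or a[1] == MISSING:
                        rec.samples[s]["GT"] = (None, None)
                    else:
                        rec.samples[s]["GT"] = (int(a[0]), int(a[1]))
                    rec.samples[s]["DP"] = int(table.dp[i, j])
                    n_alleles = len(loc.alleles)
                    ad_row = table.ad[i, j, :n_alleles]
                    if (ad_row >= 0).all():
                        rec.samples[s]["AD"] = tuple(int(x) for x in ad_row)
                out.write(rec)
        with open(tmp.name, "r", encoding="utf-8") as fh:
            text = fh.read()
    finally:
        os.unlink(tmp.name)

    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        dest.write(text)


def load_intervals(source) -> GeneIntervals:
    """Read BED4 (chrom, start, end, name) gene intervals.

    Coordinates stay 0-based half-open; records keep file order; overlapping
    intervals are retained unmerged.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source.read()
    records: list[tuple[str, int, int, str]] = []
    for line_no, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise BedParseError(f"line {line_no}: expected >=4 BED columns")
        chrom, start_s, end_s, gene_id = fields[0], fields[1], fields[2], fields[3]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise BedParseError(f"line {line_no}: non-integer coordinate") from exc
        if start >= end:
            raise BedParseError(f"line {line_no}: start {start} >= end {end}")
        if not gene_id:
            raise BedParseError(f"line {line_no}: empty gene id")
        records.append((chrom, start, end, gene_id))
    return GeneIntervals(records)


def map_loci_to_genes(
    table: VariantTable, genes: GeneIntervals
) -> dict[int, set[str]]:
    """Map each locus index to the set of gene ids whose interval contains it.

    A locus at 1-based position ``p`` falls in a 0-based half-open interval
    ``[start, end)`` iff ``start <= p - 1 < end``. Loci on chromosomes absent
    from the BED, or outside every interval, map to the empty set.
    """
    trees = genes.trees()
    mapping: dict[int, set[str]] = {}
    for i, loc in enumerate(table.loci):
        tree = trees.get(loc.chrom)
        if tree is None:
            mapping[i] = set()
        else:
            mapping[i] = {iv.data for iv in tree.at(loc.pos - 1)}
    return mapping


def intervals_to_bed(genes: GeneIntervals, dest) -> None:
    """Write gene intervals back out as BED4."""
    lines = [
        f"{chrom}\t{start}\t{end}\t{gene_id}\n"
        for chrom, start, end, gene_id in genes.records
    ]
    if isinstance(dest, (str, os.PathLike)):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.writelines(lines)
    else:
        dest.writelines(lines)
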