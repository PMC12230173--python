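"""Ground-truthed simulation of transcriptome-based genotyping of F1 hybrids.

The generator emulates the data-generating process behind RNA-seq genotyping
of a two-species cross:

* two parental species fixed for opposite alleles at *diagnostic* loci, plus
  background loci whose alleles are shared across species;
* loci grouped into non-overlapping genes; one expression level per gene
  (log-normal across genes) drives read depth at every locus of that gene
  (Poisson, identical mean for every sample);
* candidate hybrids are true F1s — heterozygous at every diagnostic locus;
* a fraction of genes show monoallelic (parent-of-origin) expression: in a
  candidate, every read at such a gene carries the expressed parent's allele,
  so its diagnostic loci are called homozygous in all candidates (the ASE /
  Group C mechanism);
* elsewhere, reads split Binomial(depth, 1/2) between a heterozygote's
  alleles, so at low depth one allele can go unsampled and the site is
  miscalled homozygous (the allelic-dropout / Group D mechanism).

Genotype calling is deliberately simple and explicit: an allele is *present*
when it has at least ``min_allele_reads`` reads; two present alleles give a
heterozygous call, one present allele gives a homozygous call provided total
depth reaches ``min_call_depth``, anything else is missing.

The :class:`TruthSet` retains everything needed to score recovery: true
genotypes, the ASE gene set and expressed parent, expression levels, and the
locus-to-gene assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostic_loci import DiagnosticSet
from .hybrid_classification import HybridClassification
from .variant_io import GeneIntervals, Locus, VariantTable, MISSING

__all__ = [
    "SimulationParams",
    "TruthSet",
    "RecoveryReport",
    "sample_truth",
    "simulate_genotyping",
    "evaluate_recovery",
    "call_genotypes",
    "simulate_panel",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationParams:
    """Study-design and noise parameters of the simulated experiment.

    Defaults mirror the source study's design — 3 parental individuals per
    species and 4 candidate F1 hybrids on a 12-chromosome genome — at reduced
    locus scale, with an overall mean locus depth of ~40 reads and ~10% of
    genes monoallelically expressed.
    """

    n_loci_diag: int = 10_000
    n_loci_bg: int = 5_000
    n_parents_per_species: int = 3
    n_candidates: int = 4
    n_genes: int = 3_000
    ase_gene_fraction: float = 0.1
    ase_parent_bias: float = 0.5  # probability the expressed allele is maternal (M)
    ase_depth_factor: float = 0.5  # silencing one allele halves transcript output
    expr_log_mean: float = float(np.log(40.0) - 0.5)  # mean depth 40 at sd 1
    expr_log_sd: float = 1.0
    depth_scale: float = 1.0  # reads per unit expression
    min_call_depth: int = 3  # DP below which a single-allele call is MISSING
    min_allele_reads: int = 2  # reads required to deem an allele present
    indel_fraction: float = 0.15
    n_chromosomes: int = 12
    chromosome_length: int = 10_000_000
    gene_length: int = 2_000
    candidate_generation: str = "F1"  # or "F2" (selfed, ~50% heterozygosity)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_loci_diag", "n_loci_bg", "n_parents_per_species",
                     "n_candidates", "n_genes", "n_chromosomes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ase_gene_fraction", "ase_parent_bias", "indel_fraction",
                     "ase_depth_factor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_allele_reads < 1:
            raise ValueError("min_allele_reads must be >= 1")
        if self.candidate_generation not in ("F1", "F2"):
            raise ValueError("candidate_generation must be 'F1' or 'F2'")

    @property
    def n_loci(self) -> int:
        return self.n_loci_diag + self.n_loci_bg

    def sample_names(self) -> tuple[list[str], list[str], list[str]]:
        p = [f"P_{i + 1}" for i in range(self.n_parents_per_species)]
        m = [f"M_{i + 1}" for i in range(self.n_parents_per_species)]
        c = [f"F1_{i + 1}" for i in range(self.n_candidates)]
        return p, m, c

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Simulator ground truth, aligned 1:1 with the emitted VariantTable rows."""

    params: SimulationParams
    parents_p: list[str]
    parents_m: list[str]
    candidates: list[str]
    # per-locus arrays, sorted by (chrom, pos) — same order as the VariantTable
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    vtype: np.ndarray
    gene_index: np.ndarray
    is_diagnostic: np.ndarray
    allele_p: np.ndarray  # -1 at background loci
    allele_m: np.ndarray
    true_gt: np.ndarray  # (L, S, 2) over parents_p + parents_m + candidates
    # per-gene table: gene_id, chrom, start, end, expression, is_ase, expressed_parent
    genes: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return self.parents_p + self.parents_m + self.candidates

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def locus_index(self) -> dict[tuple[str, int], int]:
        return {
            (str(c), int(p)): i for i, (c, p) in enumerate(zip(self.chrom, self.pos))
        }

    def locus_is_ase(self) -> np.ndarray:
        """Per-locus: does the locus sit in a monoallelically expressed gene?"""
        return self.genes["is_ase"].to_numpy()[self.gene_index]

    def ase_locus_fraction(self) -> float:
        """Fraction of diagnostic loci lying in ASE genes."""
        d = self.is_diagnostic
        return float(self.locus_is_ase()[d].mean()) if d.any() else 0.0

    def gene_intervals(self) -> GeneIntervals:
        return GeneIntervals(
            [
                (row.chrom, int(row.start), int(row.end), row.gene_id)
                for row in self.genes.itertuples()
            ]
        )

    def loci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
                "vtype": self.vtype,
                "gene_id": self.genes["gene_id"].to_numpy()[self.gene_index],
                "is_diagnostic": self.is_diagnostic,
                "allele_p": self.allele_p,
                "allele_m": self.allele_m,
            }
        )


def _rng(seed: int, label: str) -> np.random.Generator:
    """Named substream: independent generator derived from (seed, label)."""
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


def sample_truth(params: SimulationParams, seed: int | None = None) -> TruthSet:
    """Draw the ground truth: genes, loci, alleles, true genotypes, ASE set."""
    if seed is None:
        seed = params.seed
    rng = _rng(seed, "truth")
    n_loci, n_genes = params.n_loci, params.n_genes
    if n_genes < 1 or n_loci < n_genes:
        raise ValueError("need 1 <= n_genes <= total loci (each gene holds >=1 locus)")
    if params.gene_length > params.chromosome_length:
        raise ValueError("gene longer than chromosome")

    # non-overlapping gene intervals, round-robin across chromosomes
    chrom_names = [f"chr{i + 1:02d}" for i in range(params.n_chromosomes)]
    genes_per_chrom = [
        len(range(c, n_genes, params.n_chromosomes))
        for c in range(params.n_chromosomes)
    ]
    rows = []
    g = 0
    for c, n_on_chrom in enumerate(genes_per_chrom):
        if n_on_chrom == 0:
            continue
        span = params.chromosome_length // n_on_chrom
        if span < params.gene_length:
            raise ValueError(
                f"{n_on_chrom} genes of {params.gene_length} bp exceed "
                f"chromosome capacity {params.chromosome_length} bp"
            )
        for slot in range(n_on_chrom):
            start = slot * span
            rows.append(
                {
                    "gene_id": f"gene{g + 1:05d}",
                    "chrom": chrom_names[c],
                    "start": start,
                    "end": start + params.gene_length,
                }
            )
            g += 1
    genes = pd.DataFrame(rows)

    genes["expression"] = rng.lognormal(
        mean=params.expr_log_mean, sigma=params.expr_log_sd, size=n_genes
    )
    genes["is_ase"] = rng.random(n_genes) < params.ase_gene_fraction
    expressed = np.where(rng.random(n_genes) < params.ase_parent_bias, "M", "P")
    genes["expressed_parent"] = np.where(genes["is_ase"], expressed, "")

    # each gene holds at least one locus; the rest distributed uniformly
    if params.gene_length * n_genes < n_loci:
        raise ValueError("loci exceed gene capacity (unique positions per gene)")
    loci_per_gene = np.ones(n_genes, dtype=np.int64)
    extra = n_loci - n_genes
    while True:
        alloc = loci_per_gene + rng.multinomial(extra, np.full(n_genes, 1 / n_genes))
        if (alloc <= params.gene_length).all():
            loci_per_gene = alloc
            break

    chrom_arr = np.empty(n_loci, dtype=object)
    pos_arr = np.empty(n_loci, dtype=np.int64)
    gene_idx = np.empty(n_loci, dtype=np.int64)
    cursor = 0
    for gi, k in enumerate(loci_per_gene):
        k = int(k)
        offs = rng.choice(params.gene_length, size=k, replace=False)
        start = int(genes.at[gi, "start"])
        chrom_arr[cursor : cursor + k] = genes.at[gi, "chrom"]
        pos_arr[cursor : cursor + k] = start + 1 + offs  # 1-based, inside [start,end)
        gene_idx[cursor : cursor + k] = gi
        cursor += k

    is_diag = np.zeros(n_loci, dtype=bool)
    is_diag[rng.choice(n_loci, size=params.n_loci_diag, replace=False)] = True

    # alleles
    ref = np.empty(n_loci, dtype=object)
    alt = np.empty(n_loci, dtype=object)
    vtype = np.empty(n_loci, dtype=object)
    is_indel = rng.random(n_loci) < params.indel_fraction
    base_i = rng.integers(0, 4, size=n_loci)
    shift = rng.integers(1, 4, size=n_loci)
    base2_i = rng.integers(0, 4, size=n_loci)
    ins = rng.random(n_loci) < 0.5
    for i in range(n_loci):
        b = _BASES[base_i[i]]
        if not is_indel[i]:
            ref[i], alt[i], vtype[i] = b, _BASES[(base_i[i] + shift[i]) % 4], "SNP"
        elif ins[i]:
            ref[i], alt[i], vtype[i] = b, b + _BASES[base2_i[i]], "INDEL"
        else:
            ref[i], alt[i], vtype[i] = b + _BASES[base2_i[i]], b, "INDEL"

    allele_p = np.full(n_loci, -1, dtype=np.int64)
    allele_m = np.full(n_loci, -1, dtype=np.int64)
    which = rng.integers(0, 2, size=n_loci)
    allele_p[is_diag] = which[is_diag]
    allele_m[is_diag] = 1 - which[is_diag]

    # true genotypes
    n_par = params.n_parents_per_species
    names_p, names_m, names_c = params.sample_names()
    S = 2 * n_par + params.n_candidates
    gt = np.empty((n_loci, S, 2), dtype=np.int32)

    # background classes: monomorphic hom-ref / hom-alt / all-heterozygous
    bg_class = rng.choice(3, size=n_loci, p=[0.4, 0.3, 0.3])
    for i in range(n_loci):
        if is_diag[i]:
            gt[i, :n_par] = allele_p[i]
            gt[i, n_par : 2 * n_par] = allele_m[i]
            gt[i, 2 * n_par :] = (0, 1)
        elif bg_class[i] == 0:
            gt[i] = 0
        elif bg_class[i] == 1:
            gt[i] = 1
        else:
            gt[i] = (0, 1)

    if params.candidate_generation == "F2" and params.n_candidates:
        # selfed F1: diagnostic-locus genotypes segregate 1:2:1
        diag_rows = np.flatnonzero(is_diag)
        draws = rng.choice(3, size=(len(diag_rows), params.n_candidates),
                           p=[0.25, 0.5, 0.25])
        for r, i in enumerate(diag_rows):
            for j in range(params.n_candidates):
                col = 2 * n_par + j
                if draws[r, j] == 0:
                    gt[i, col] = allele_p[i]
                elif draws[r, j] == 2:
                    gt[i, col] = allele_m[i]
                else:
                    gt[i, col] = (0, 1)

    order = np.lexsort((pos_arr, chrom_arr.astype(str)))
    return TruthSet(
        params=params,
        parents_p=names_p,
        parents_m=names_m,
        candidates=names_c,
        chrom=chrom_arr[order],
        pos=pos_arr[order],
        ref=ref[order],
        alt=alt[order],
        vtype=vtype[order],
        gene_index=gene_idx[order],
        is_diagnostic=is_diag[order],
        allele_p=allele_p[order],
        allele_m=allele_m[order],
        true_gt=gt[order],
        genes=genes,
    )


def call_genotypes(
    ad: np.ndarray, dp: np.ndarray, params: SimulationParams
) -> np.ndarray:
    """Apply the read-threshold calling rule to allele depths.

    ``ad`` is ``(..., 2)``, ``dp`` broadcastable to ``ad[..., 0]``. Returns a
    ``(..., 2)`` genotype array: two present alleles -> (0, 1); one present
    allele with DP >= min_call_depth -> homozygote; otherwise missing.
    """
    ad = np.asarray(ad)
    dp = np.asarray(dp)
    present = ad >= params.min_allele_reads
    n_present = present.sum(axis=-1)
    gt = np.full(ad.shape[:-1] + (2,), MISSING, dtype=np.int32)
    het = n_present == 2
    gt[het] = (0, 1)
    single = (n_present == 1) & (dp >= params.min_call_depth)
    hom_allele = np.argmax(present, axis=-1)
    gt[single, 0] = hom_allele[single]
    gt[single, 1] = hom_allele[single]
    return gt


def simulate_genotyping(
    truth: TruthSet, params: SimulationParams | None = None, seed: int | None = None
) -> VariantTable:
    """Sequence and call the truth: depths, allele reads, genotype calls.

    Per sample per locus, depth ~ Poisson(depth_scale x gene expression).
    Homozygotes put every read on their allele. Heterozygotes split reads
    Binomial(depth, 1/2) — except candidates at diagnostic loci of ASE genes,
    where every read carries the expressed parent's allele. Calls follow
    :func:`call_genotypes`; DP and AD are recorded in the emitted table.
    """
    if params is None:
        params = truth.params
    if seed is None:
        seed = params.seed
    rng = _rng(seed, "genotyping")
    L = truth.n_loci
    S = len(truth.samples)
    expr = truth.genes["expression"].to_numpy()[truth.gene_index]
    lam = np.broadcast_to((params.depth_scale * expr)[:, None], (L, S)).copy()
    # silencing one haplotype cuts a candidate's transcript output at ASE genes
    n_cand_ = len(truth.candidates)
    if n_cand_:
        gene_ase = truth.locus_is_ase()
        lam[np.ix_(gene_ase, np.arange(S - n_cand_, S))] *= params.ase_depth_factor
    dp = rng.poisson(lam).astype(np.int64)

    gt_true = truth.true_gt
    ad = np.zeros((L, S, 2), dtype=np.int64)
    is_het = gt_true[:, :, 0] != gt_true[:, :, 1]
    hom_allele = gt_true[:, :, 0]

    # homozygotes: all reads on the true allele
    hom = ~is_het
    ad[hom & (hom_allele == 0), 0] = dp[hom & (hom_allele == 0)]
    ad[hom & (hom_allele == 1), 1] = dp[hom & (hom_allele == 1)]

    # ASE: candidates at diagnostic loci of monoallelic genes express one parent
    n_cand = len(truth.candidates)
    is_cand = np.zeros(S, dtype=bool)
    if n_cand:
        is_cand[-n_cand:] = True
    locus_ase = truth.locus_is_ase() & truth.is_diagnostic
    expressed_parent = truth.genes["expressed_parent"].to_numpy()[truth.gene_index]
    ase_allele = np.where(expressed_parent == "M", truth.allele_m, truth.allele_p)
    ase_cells = is_het & locus_ase[:, None] & is_cand[None, :]
    for a in (0, 1):
        sel = ase_cells & (ase_allele[:, None] == a)
        ad[sel, a] = dp[sel]

    # remaining heterozygotes: binomial read split
    bin_cells = is_het & ~ase_cells
    n_bin = int(bin_cells.sum())
    if n_bin:
        reads0 = rng.binomial(dp[bin_cells], 0.5)
        ad[bin_cells, 0] = reads0
        ad[bin_cells, 1] = dp[bin_cells] - reads0

    gt_called = call_genotypes(ad, dp, params)

    loci = [
        Locus(chrom=str(c), pos=int(p), ref=str(r), alts=(str(a),))
        for c, p, r, a in zip(truth.chrom, truth.pos, truth.ref, truth.alt)
    ]
    return VariantTable(loci, truth.samples, gt_called, dp, ad)


@dataclass
class RecoveryReport:
    """How well classification recovered the simulated truth."""

    confusion: dict[str, pd.DataFrame]  # candidate -> true x called counts
    estimated_c_fraction: float  # |C| / diagnostic total from the classification
    true_ase_fraction: float  # ASE-locus fraction among the classified loci
    sensitivity: dict[str, float]  # 'ase' -> P(C | ase), 'het' -> P(A | het)
    specificity: dict[str, float]
    n_loci: int

    @property
    def c_fraction_error(self) -> float:
        return self.estimated_c_fraction - self.true_ase_fraction


def evaluate_recovery(
    truth: TruthSet, classification: HybridClassification, table: VariantTable
) -> RecoveryReport:
    """Confusion of true {het, ase} classes vs called groups {A, C, D}.

    The classification's diagnostic loci are joined to the truth by
    (chrom, pos); a locus the truth does not know is an error. True class is
    'ase' for loci of monoallelically expressed genes and 'het' otherwise
    (candidates are true heterozygotes at every diagnostic locus); dropout is
    a property of the realized calls, visible as true-het loci called into D.
    """
    tindex = truth.locus_index()
    keys = table.locus_keys()
    truth_rows = []
    for i in classification.diag.locus_indices:
        key = keys[i]
        if key not in tindex:
            raise ValueError(f"locus {key[0]}:{key[1]} absent from the truth set")
        truth_rows.append(tindex[key])
    truth_rows = np.asarray(truth_rows, dtype=np.intp)
    locus_ase = truth.locus_is_ase()[truth_rows]
    is_diag = truth.is_diagnostic[truth_rows]
    if not is_diag.all():
        raise ValueError("classification contains non-diagnostic truth loci")
    true_class = np.where(locus_ase, "ase", "het")

    confusion: dict[str, pd.DataFrame] = {}
    sens_ase, sens_het, spec_ase, spec_het = [], [], [], []
    for cand in classification.candidates:
        called = np.where(
            classification.group_mask(cand, "A"),
            "A",
            np.where(classification.c_mask, "C", "D"),
        )
        df = pd.crosstab(
            pd.Series(true_class, name="true"),
            pd.Series(called, name="called"),
        ).reindex(index=["het", "ase"], columns=["A", "C", "D"], fill_value=0)
        confusion[cand] = df
        n_ase = int((true_class == "ase").sum())
        n_het = int((true_class == "het").sum())
        if n_ase:
            sens_ase.append(df.loc["ase", "C"] / n_ase)
            spec_het.append((df.loc["ase", "C"] + df.loc["ase", "D"]) / n_ase)
        if n_het:
            sens_het.append(df.loc["het", "A"] / n_het)
            spec_ase.append((df.loc["het", "A"] + df.loc["het", "D"]) / n_het)

    est_c = classification.c_mask.mean() if classification.total else 0.0
    return RecoveryReport(
        confusion=confusion,
        estimated_c_fraction=float(est_c),
        true_ase_fraction=float(locus_ase.mean()) if len(truth_rows) else 0.0,
        sensitivity={
            "ase": float(np.mean(sens_ase)) if sens_ase else float("nan"),
            "het": float(np.mean(sens_het)) if sens_het else float("nan"),
        },
        specificity={
            "ase": float(np.mean(spec_ase)) if spec_ase else float("nan"),
            "het": float(np.mean(spec_het)) if spec_het else float("nan"),
        },
        n_loci=int(len(truth_rows)),
    )


def simulate_panel(
    order: Sequence[str],
    type_counts: Sequence[int],
    n_noncontiguous: int,
    seed: int,
    chrom: str = "chr01",
    depth: int = 50,
) -> VariantTable:
    """Build a homozygous-biallelic panel table with planted split patterns.

    ``type_counts[k-1]`` loci are contiguous splits after position k of
    *order*; ``n_noncontiguous`` loci get allele vectors with >= 2 changes.
    Allele polarity is randomized per locus. Used for continuity-analysis
    testing and demonstration.
    """
    order = list(order)
    n = len(order)
    if len(type_counts) != n - 1:
        raise ValueError(f"need {n - 1} split-type counts for {n} taxa")
    if n < 3 and n_noncontiguous:
        raise ValueError("non-contiguous patterns require >= 3 taxa")
    rng = _rng(seed, "panel")
    vectors: list[np.ndarray] = []
    for k, count in enumerate(type_counts, start=1):
        for _ in range(count):
            v = np.zeros(n, dtype=np.int32)
            v[k:] = 1
            if rng.random() < 0.5:
                v = 1 - v
            vectors.append(v)
    while len(vectors) < sum(type_counts) + n_noncontiguous:
        v = rng.integers(0, 2, size=n).astype(np.int32)
        changes = int((v[1:] != v[:-1]).sum())
        if changes >= 2:
            vectors.append(v)
    perm = rng.permutation(len(vectors))
    vectors = [vectors[i] for i in perm]

    L = len(vectors)
    loci = []
    gt = np.empty((L, n, 2), dtype=np.int32)
    dp = np.full((L, n), depth, dtype=np.int64)
    ad = np.zeros((L, n, 2), dtype=np.int64)
    for i, v in enumerate(vectors):
        ref_i, alt_shift = rng.integers(0, 4), rng.integers(1, 4)
        ref = str(_BASES[ref_i])
        alt = str(_BASES[(ref_i + alt_shift) % 4])
        loci.append(Locus(chrom=chrom, pos=100 * (i + 1), ref=ref, alts=(alt,)))
        gt[i, :, 0] = v
        gt[i, :, 1] = v
        ad[i, np.arange(n), v] = depth
    return VariantTable(loci, order, gt, dp, ad)
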