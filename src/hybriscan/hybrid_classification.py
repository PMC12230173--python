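"""Group A/B/C/D classification of candidate-hybrid genotypes at diagnostic loci.

At a diagnostic locus a true F1 hybrid carries one allele from each parental
species. In transcriptome-derived genotypes two artifacts break that
expectation: allele-specific expression (ASE), where a whole gene transcribes
only one parental allele and every heterozygote in it is called homozygous in
every hybrid; and allelic dropout, where low expression leaves one allele
unsampled at random. Per candidate, each diagnostic locus is labelled:

* ``A`` — heterozygous with exactly the two parental alleles (expected F1);
* ``B`` — anything else (unexpectedly homozygous or aberrant);
* ``C`` (subset of B, shared across candidates) — ALL candidates homozygous
  for one identical parental allele: the ASE signature;
* ``D`` — the remaining B loci, attributed to dropout / random error.

So per candidate |A| + |B| = diagnostic total and B = C ∪ D with C ∩ D = ∅.
Group depth summaries and Welch t-tests (A vs B, C vs D) quantify the
depth-dependence of the artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .diagnostic_loci import DiagnosticSet
from .variant_io import VariantTable

__all__ = [
    "HybridClassification",
    "GroupDepthSummary",
    "TTestResult",
    "classify_groups",
    "depth_summary",
    "compare_depths",
    "subsample_loci",
    "windowed_density",
    "genes_for_group",
    "percent",
    "group_percentages",
]

GROUPS = ("A", "B", "C", "D")


def percent(count: float, total: float, ndigits: int = 2) -> float:
    """Share of *total* as a percentage, rounded half-to-even to 2 decimals."""
    if total == 0:
        raise ValueError("total must be nonzero")
    return round(count / total * 100.0, ndigits)


def group_percentages(counts: Mapping[str, int], total: int) -> dict[str, float]:
    """Per-group percentages of the diagnostic total (2 decimals)."""
    return {g: percent(c, total) for g, c in counts.items()}


@dataclass
class TTestResult:
    """Welch two-sample t-test between two depth vectors."""

    t: float
    df: float
    p_value: float
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float

    def format_p(self, floor: float = 2.2e-16) -> str:
        """Display convention used in reports: very small p shown as a bound."""
        return f"< {floor:g}" if self.p_value < floor else f"{self.p_value:.4g}"


@dataclass
class HybridClassification:
    """Per-candidate A/B labels, the shared ASE set C, and per-candidate D."""

    candidates: list[str]
    diag: DiagnosticSet
    # (n_diag_loci, n_candidates) array of "A"/"B" labels
    labels: np.ndarray
    # boolean over diagnostic loci: shared homozygous-parental (ASE) set
    c_mask: np.ndarray
    # QC: candidate calls involving a non-parental allele, (locus_k, candidate) pairs
    non_parental: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.diag.total

    def group_mask(self, candidate: str, group: str) -> np.ndarray:
        """Boolean mask over diagnostic loci for one candidate's group."""
        j = self.candidates.index(candidate)
        a = self.labels[:, j] == "A"
        if group == "A":
            return a
        if group == "B":
            return ~a
        if group == "C":
            return self.c_mask
        if group == "D":
            return ~a & ~self.c_mask
        raise ValueError(f"unknown group {group!r}")

    def counts(self) -> dict[str, dict[str, int]]:
        return {
            cand: {g: int(self.group_mask(cand, g).sum()) for g in GROUPS}
            for cand in self.candidates
        }

    def percentages(self) -> dict[str, dict[str, float]]:
        return {
            cand: group_percentages(cnt, self.total)
            for cand, cnt in self.counts().items()
        }


def classify_groups(
    table: VariantTable,
    diag: DiagnosticSet,
    candidates: Sequence[str],
) -> HybridClassification:
    """Label each candidate's genotype at each diagnostic locus.

    Requires every candidate called at every diagnostic locus (guaranteed when
    the diagnostic set was built in complete-case mode). The shared set C is
    computed jointly over all candidates; with a single candidate ASE cannot
    be separated from dropout, C is empty and a warning is recorded.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate")
    cols = table.sample_indices(candidates)
    idx = diag.locus_indices
    gt = table.gt[idx][:, cols, :]  # (K, C, 2)
    if (gt < 0).any():
        k, j = np.argwhere((gt < 0).any(axis=2))[0]
        raise ValueError(
            f"candidate {candidates[j]!r} has a missing call at diagnostic locus "
            f"{table.loci[idx[k]].chrom}:{table.loci[idx[k]].pos}; rebuild the "
            "diagnostic set in complete-case mode (require_candidate_calls)"
        )

    ap = diag.allele_p[:, None]
    am = diag.allele_m[:, None]
    lo = np.minimum(ap, am)
    hi = np.maximum(ap, am)
    # genotype pairs are stored sorted ascending
    is_a = (gt[:, :, 0] == lo) & (gt[:, :, 1] == hi)  # (K, C)

    hom = gt[:, :, 0] == gt[:, :, 1]
    hom_allele = gt[:, :, 0]
    all_hom = hom.all(axis=1)
    shared = (hom_allele == hom_allele[:, 0:1]).all(axis=1)
    parental = (hom_allele[:, 0] == diag.allele_p) | (
        hom_allele[:, 0] == diag.allele_m
    )
    if len(candidates) >= 2:
        c_mask = all_hom & shared & parental
    else:
        c_mask = np.zeros(diag.total, dtype=bool)

    labels = np.where(is_a, "A", "B")

    non_parental: list[tuple[int, str]] = []
    has_np = ~((gt[:, :, 0] == ap) | (gt[:, :, 0] == am)) | ~(
        (gt[:, :, 1] == ap) | (gt[:, :, 1] == am)
    )
    for k, j in np.argwhere(has_np):
        non_parental.append((int(k), candidates[j]))

    warnings = []
    if len(candidates) < 2:
        warnings.append(
            "single candidate: ASE (Group C) cannot be separated from dropout; "
            "all Group B loci were assigned to D"
        )
    if len(candidates) >= 2 and (all_hom & shared & ~parental).any():
        n_bad = int((all_hom & shared & ~parental).sum())
        warnings.append(
            f"{n_bad} loci shared-homozygous for a NON-parental allele were "
            "assigned to D (flagged in non_parental)"
        )
    return HybridClassification(
        candidates=candidates,
        diag=diag,
        labels=labels,
        c_mask=c_mask,
        non_parental=non_parental,
        warnings=warnings,
    )


@dataclass
class GroupDepthSummary:
    """Per candidate per group: n, mean depth; plus per-candidate overall mean.

    ``mean`` is ``None`` for an empty group (never reported as 0).
    """

    per_group: dict[str, dict[str, dict]]  # candidate -> group -> {n, mean}
    overall: dict[str, float]  # candidate -> mean depth over all diagnostic loci
    depths: dict[str, dict[str, np.ndarray]]  # candidate -> group -> depth vector


def depth_summary(
    cls: HybridClassification, table: VariantTable
) -> GroupDepthSummary:
    """Mean per-candidate DP over each group's loci (2-decimal reporting)."""
    idx = cls.diag.locus_indices
    per_group: dict[str, dict[str, dict]] = {}
    overall: dict[str, float] = {}
    depths: dict[str, dict[str, np.ndarray]] = {}
    for cand in cls.candidates:
        j = table.sample_index(cand)
        dp = table.dp[idx, j].astype(float)
        per_group[cand] = {}
        depths[cand] = {}
        for g in GROUPS:
            vec = dp[cls.group_mask(cand, g)]
            depths[cand][g] = vec
            per_group[cand][g] = {
                "n": int(vec.size),
                "mean": round(float(vec.mean()), 2) if vec.size else None,
            }
        overall[cand] = round(float(dp.mean()), 2) if dp.size else None
    return GroupDepthSummary(per_group=per_group, overall=overall, depths=depths)


def compare_depths(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Welch (unequal-variance) two-sided two-sample t-test on depth vectors.

    The raw p-value is kept; any "< 2.2e-16"-style flooring is purely a
    display convention (see :meth:`TTestResult.format_p`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each depth vector needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and float(x.mean()) == float(y.mean()):
        # degenerate identical-constant case: no evidence of difference
        df = float(x.size + y.size - 2)
        return TTestResult(0.0, df, 1.0, x.size, y.size, float(x.mean()), float(y.mean()))
    res = stats.ttest_ind(x, y, equal_var=False)
    return TTestResult(
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        n_x=int(x.size),
        n_y=int(y.size),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
    )


def subsample_loci(loci: Sequence, n: int, seed: int) -> list:
    """Uniform sample of *n* loci without replacement, reproducible by seed."""
    loci = list(loci)
    if n > len(loci):
        raise ValueError(f"cannot sample {n} from {len(loci)} loci")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(loci), size=n, replace=False)
    return [loci[i] for i in idx]


def windowed_density(
    loci_indices: np.ndarray,
    reference_indices: np.ndarray,
    table: VariantTable,
    window_bp: int,
) -> dict:
    """Per-chromosome windowed counts of a locus subset, with uniformity test.

    Bins are 1-based windows ``[k*w+1, (k+1)*w]``. For each chromosome a
    chi-square statistic compares the subset's window profile against the
    profile expected from the reference set (e.g. Group-A loci vs all
    diagnostic loci), asking whether the subset is distributed like the
    reference — the paper-style "even distribution" check.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    chroms = table.chroms()
    pos = table.positions()
    out: dict[str, dict] = {}
    ref_chroms = set(chroms[reference_indices]) | set(chroms[loci_indices])
    for chrom in sorted(ref_chroms):
        ref_pos = pos[reference_indices][chroms[reference_indices] == chrom]
        sub_pos = pos[loci_indices][chroms[loci_indices] == chrom]
        max_pos = int(max(ref_pos.max() if ref_pos.size else 0,
                          sub_pos.max() if sub_pos.size else 0))
        n_bins = max(1, -(-max_pos // window_bp))
        edges = np.arange(0, (n_bins + 1) * window_bp + 1, window_bp) + 0.5
        sub_counts, _ = np.histogram(sub_pos, bins=edges[: n_bins + 1])
        ref_counts, _ = np.histogram(ref_pos, bins=edges[: n_bins + 1])
        entry: dict = {"counts": sub_counts, "reference_counts": ref_counts}
        keep = ref_counts > 0
        if sub_pos.size and keep.sum() >= 2:
            expected = ref_counts[keep] / ref_counts[keep].sum() * sub_pos.size
            chi2, p = stats.chisquare(sub_counts[keep], expected)
            entry["chi2"] = float(chi2)
            entry["p_value"] = float(p)
        else:
            entry["chi2"] = None
            entry["p_value"] = None
        out[chrom] = entry
    return out


def genes_for_group(
    group_locus_indices: np.ndarray, locus_to_genes: Mapping[int, set]
) -> tuple[int, list[str]]:
    """Distinct genes hit by a group's loci (loci outside any gene ignored)."""
    genes: set[str] = set()
    for i in group_locus_indices:
        genes |= locus_to_genes.get(int(i), set())
    return len(genes), sorted(genes)
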