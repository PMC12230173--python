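# Methods

## Diagnostic loci

A locus is diagnostic for the parental pair (P, M) when (a) every P
individual is called and homozygous for one allele `a_p`, (b) every M
individual is called and homozygous for one allele `a_m`, and (c)
`a_p ≠ a_m`. Records declaring more than two ALT alleles can qualify as long
as the parental groups themselves expose exactly two alleles; the remaining
declared alleles are ignored. Within-group missing calls disqualify a locus
(strict complete case within parents): with only a handful of individuals
per species there is no sound frequency-based relaxation, and the non-goal
of statistical diagnosticity (allowing within-group polymorphism) is
deliberate.

By default the filter also requires every *candidate* to be called
(`require_candidate_calls`), so that each candidate's group counts share the
diagnostic total as a common denominator and A + B = total holds exactly per
candidate. Discovery is invariant to sample order within groups and to
swapping the P/M labels (up to allele relabeling), and adding an individual
to a parental group can only shrink the set — both properties are tested.

## Group classification

Per candidate, a diagnostic locus is **A** iff the genotype is heterozygous
with exactly `{a_p, a_m}`; anything else is **B**. The ASE set **C** is
computed jointly: a locus enters C iff *all* candidates are homozygous
there, share one identical genotype, and that allele is parental. C ⊆ B for
every candidate by construction, and **D** = B \ C per candidate. Rationale
for the parental-allele requirement: monoallelic expression can only expose
an allele the F1 actually carries, i.e. a parental one. A shared homozygous
*non-parental* genotype is a calling artifact, not ASE: it goes to D and is
QC-flagged (`HybridClassification.non_parental`), as are heterozygous calls
containing a non-parental allele. With a single candidate the C criterion is
undefined; C is empty, all B goes to D, and a warning is recorded.

The classifier is verified against an independently written brute-force
classifier over every genotype combination for two and three candidates at a
biallelic locus.

## Depth statistics

Group depth summaries are means of the candidate's per-locus DP over each
group (2-decimal reporting; empty groups report an undefined marker, never
0). Depth contrasts use Welch's unequal-variance two-sample t-test
(scipy), two-sided, with Welch–Satterthwaite degrees of freedom — group
sizes and variances differ by construction, so the pooled-variance test
would be wrong. Raw p-values are kept everywhere; the conventional
"< 2.2e-16" display floor is applied only at the presentation layer.
Identical constant vectors return t = 0, p = 1 rather than NaN.

Percentages are rounded half-to-even to 2 decimals; per candidate the
A/C/D percentages sum to 100 within 0.02 (rounding slack). Cumulative
percentages in the continuity table are computed from cumulative *counts*
and then rounded — rounding the cumulative sum of rounded percentages does
not reproduce standard published tables of this kind, summing-to-total does.

## Continuity patterns

The panel analysis keeps loci where every panel sample is called homozygous
and exactly two alleles are observed *across the panel* (monomorphic and
3+-allele sites are excluded; exclusion counts are reported). A locus is
`split_k` when its allele vector along the taxon order changes exactly once,
after position k; otherwise non-contiguous. Classification is invariant
under allele relabeling and order reversal (split_k ↔ split_{n−k}), and the
split labels partition the examined total — all property-tested, plus an
exhaustive check of all 2⁷ − 2 binary vectors for a seven-taxon panel.
`best_order` scores every permutation up to reversal symmetry (ties break
lexicographically); it is capped at 10 samples because the search is
exhaustive by design — heuristic ordering is out of scope.

## The simulator

`sample_truth` draws the experiment: non-overlapping 2 kb gene intervals
placed round-robin over 12 chromosomes of 10 Mb; every gene holds ≥ 1 locus;
loci get unique positions inside their gene. Parental species are fixed for
opposite alleles at the planted diagnostic loci. Background loci are
monomorphic-homozygous (reference or alternate) or heterozygous in *every*
sample — classes that cannot satisfy the fixed-difference criterion under
any realization of the calling noise, which is what makes exact
planted-truth recovery a meaningful test. Candidates are true F1s
(heterozygous at every diagnostic locus); an optional selfed-F2 mode
segregates candidate genotypes 1:2:1 to demonstrate the ~50% heterozygosity
expected outside the F1 generation.

`simulate_genotyping` draws, per sample and locus, depth ~
`Poisson(depth_scale × gene expression)` with one log-normal expression
value per gene shared by all samples (expression differences between
individuals are not modelled). Homozygotes put all reads on their allele.
Heterozygotes split reads `Binomial(depth, 1/2)`. In a monoallelically
expressed gene, a candidate's reads all carry the expressed parent's allele,
and the candidate's depth at that gene is scaled by `ase_depth_factor`
(default 0.5): silencing one haplotype halves transcript output, which is
why shared-ASE loci run at roughly half the depth of comparable Group-A loci
while still sitting clearly above dropout loci. ASE is applied at
candidates' diagnostic loci; parents are homozygous there, so monoallelic
expression is unobservable in them, and for the all-heterozygous background
class no parent-of-origin is defined.

Genotype calling is the package's own explicit rule, not a reimplementation
of a likelihood-based caller: an allele is present with ≥ `min_allele_reads`
reads (default 2); two present alleles → heterozygote; one present allele
and DP ≥ `min_call_depth` (default 3) → homozygote; otherwise missing. The
heterozygote→homozygote miscall rate at fixed depth d then has the closed
form `P[Bin(d,½) ≤ r−1] + P[Bin(d,½) ≥ d−r+1]` with r = min_allele_reads,
which the tests verify empirically over 10⁵ draws.

### Default parameters

| parameter | default | why |
|---|---|---|
| n_loci_diag / n_loci_bg | 10,000 / 5,000 | the two-species design at reduced locus scale; large enough for stable group fractions, small enough for fast tests |
| n_parents_per_species / n_candidates | 3 / 4 | the sampling design the analysis targets |
| expr_log_mean / expr_log_sd | log 40 − ½ / 1.0 | overall mean locus depth ≈ 40 reads, a typical RNA-seq genotyping depth, with realistic between-gene spread |
| ase_gene_fraction | 0.10 | ~10% monoallelically expressed genes, the upper end of what leaf-tissue F1 transcriptomes show |
| ase_parent_bias | 0.5 | no preferred silenced parent a priori; per-gene parent-of-origin |
| ase_depth_factor | 0.5 | one silenced haplotype ≈ half the transcript output |
| min_allele_reads / min_call_depth | 2 / 3 | minimal thresholds that make dropout analytically tractable |
| indel_fraction | 0.15 | loci are a SNP/INDEL mix; both are treated identically throughout |

Under these defaults a run classifies ≈ 88–89% of surviving diagnostic loci
as A, ≈ 9% as C and ≈ 2–3% as D, with mean depths ordered A > C > D and the
A-vs-B Welch test rejecting decisively. Note the simulated D share is
smaller than real transcriptome studies tend to report; the calling rule
here is sharper than a likelihood-based caller at depths of 3–10 reads,
and no alignment or reference bias is modelled.

## What the simulator does not model

Read-level effects (FASTQ, alignment, mapping and reference bias),
overdispersed depth (negative-binomial is a config extension, default off),
partial ASE (allelic imbalance short of complete silencing — undetectable
from GT fields alone, and formal allele-depth ASE tests are a stated
non-goal), between-sample expression variation, genotyping-error modes other
than dropout, and linkage/recombination structure in the F2 mode. Passing
recovery tests therefore demonstrate the *logic* of the classification on
data generated by the stated mechanisms, not calibrated error rates for any
particular real dataset.

## Numerical and interface choices

* VCF I/O through pysam; multi-allelic records are kept at parse time
  (downstream filters decide), phasing is discarded, symbolic alleles are
  rejected. DP defaults to sum(AD) when absent, 0 when both are absent;
  `sum(AD) ≤ DP` is not assumed. Round-trips are lossless for GT/DP/AD and
  locus fields.
* Coordinates: VCF positions are 1-based, BED intervals 0-based half-open; a
  locus at position p lies in [start, end) iff start ≤ p − 1 < end; both
  boundaries are tested.
* All randomness flows from one seed through named substreams
  (`SeedSequence([seed, crc32(label)])`), so stages re-run independently and
  byte-identically.
* Problem sizes in the test suite (planted-recovery sweeps at the 10k-locus
  default, recovery experiments at 2,000 diagnostic loci × 20 seeds) were
  chosen to keep the full suite in the tens of seconds while leaving the
  measured fractions' sampling noise well inside the asserted bounds.
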