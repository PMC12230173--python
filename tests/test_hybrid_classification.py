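"""Group A/B/C/D classification, depth summaries, Welch tests, density bins."""

import itertools

import numpy as np
import pytest
from scipy import stats

import hybriscan as hs

from conftest import make_table

AA, TT, AT = (0, 0), (1, 1), (0, 1)


def brute_force_labels(candidate_genotypes, allele_p=0, allele_m=1):
    """Independent re-statement of the grouping rule for one locus.

    Returns one label per candidate from {A, C, D}.
    """
    parental = {allele_p, allele_m}
    a_flags = [set(g) == parental for g in candidate_genotypes]
    homs = [g[0] == g[1] for g in candidate_genotypes]
    shared_c = (
        len(candidate_genotypes) >= 2
        and all(homs)
        and len({g[0] for g in candidate_genotypes}) == 1
        and candidate_genotypes[0][0] in parental
    )
    out = []
    for is_a in a_flags:
        if is_a:
            out.append("A")
        elif shared_c:
            out.append("C")
        else:
            out.append("D")
    return out


def classify_one_locus(candidate_genotypes, alleles=("A", "T")):
    """Run the real classifier on a single hand-built locus."""
    n = len(candidate_genotypes)
    row = [AA, TT] + list(candidate_genotypes)
    t = make_table([row], alleles=alleles)
    parents = ["s1"], ["s2"]
    cands = [f"s{j + 3}" for j in range(n)]
    diag = hs.find_diagnostic_loci(t, *parents, require_candidate_calls=cands)
    assert diag.total == 1
    cls = hs.classify_groups(t, diag, cands)
    return [
        "A" if cls.group_mask(c, "A")[0]
        else ("C" if cls.c_mask[0] else "D")
        for c in cands
    ]


class TestClassifyGroups:
    def test_expected_f1_heterozygote_is_group_a(self):
        assert classify_one_locus([AT, AT, AT, AT]) == ["A"] * 4

    def test_all_candidates_same_parental_homozygote_is_group_c(self):
        # the ASE signature: all four F1s homozygous for one parental allele
        assert classify_one_locus([TT, TT, TT, TT]) == ["C"] * 4

    def test_lone_homozygote_is_group_d(self):
        assert classify_one_locus([TT, AT, AT, AT]) == ["D", "A", "A", "A"]

    def test_exhaustive_enumeration_matches_brute_force(self):
        # every genotype combination for 2 candidates at a biallelic locus
        gts = [AA, AT, TT]
        for combo in itertools.product(gts, repeat=2):
            assert classify_one_locus(list(combo)) == brute_force_labels(combo), combo

    def test_exhaustive_three_candidates_matches_brute_force(self):
        gts = [AA, AT, TT]
        for combo in itertools.product(gts, repeat=3):
            assert classify_one_locus(list(combo)) == brute_force_labels(combo), combo

    def test_non_parental_allele_goes_to_b_with_qc_flag(self):
        # candidate het with a third (non-parental) allele is not "normal
        # heterozygosity": lands in D and is QC-flagged
        labels = classify_one_locus([(0, 2), AT], alleles=("A", "T", "C"))
        assert labels[0] == "D" and labels[1] == "A"

    def test_shared_non_parental_homozygote_is_d_not_c(self):
        t = make_table([[AA, TT, (2, 2), (2, 2)]], alleles=("A", "T", "C"))
        diag = hs.find_diagnostic_loci(
            t, ["s1"], ["s2"], require_candidate_calls=["s3", "s4"]
        )
        cls = hs.classify_groups(t, diag, ["s3", "s4"])
        assert not cls.c_mask[0]
        assert len(cls.non_parental) == 2
        assert any("NON-parental" in w for w in cls.warnings)

    def test_single_candidate_has_empty_c_and_warning(self):
        t = make_table([[AA, TT, TT]])
        diag = hs.find_diagnostic_loci(t, ["s1"], ["s2"], ["s3"])
        cls = hs.classify_groups(t, diag, ["s3"])
        assert cls.counts()["s3"] == {"A": 0, "B": 1, "C": 0, "D": 1}
        assert any("single candidate" in w for w in cls.warnings)

    def test_missing_candidate_call_errors_toward_complete_case(self):
        t = make_table([[AA, TT, None]])
        diag = hs.find_diagnostic_loci(t, ["s1"], ["s2"])  # no complete-case
        with pytest.raises(ValueError, match="complete-case"):
            hs.classify_groups(t, diag, ["s3"])

    def test_partition_and_percentage_invariants(self, small_sim):
        params, truth, table = small_sim
        diag = hs.find_diagnostic_loci(
            table, truth.parents_p, truth.parents_m, truth.candidates
        )
        cls = hs.classify_groups(table, diag, truth.candidates)
        for cand in truth.candidates:
            c = cls.counts()[cand]
            assert c["A"] + c["B"] == diag.total
            assert c["C"] + c["D"] == c["B"]
            p = cls.percentages()[cand]
            assert abs(p["A"] + p["C"] + p["D"] - 100.0) <= 0.02
            # C is shared: homozygous in every candidate there
            assert (cls.labels[cls.c_mask, :] == "B").all()


class TestDepthSummary:
    def test_means_match_direct_recomputation(self, small_sim):
        params, truth, table = small_sim
        diag = hs.find_diagnostic_loci(
            table, truth.parents_p, truth.parents_m, truth.candidates
        )
        cls = hs.classify_groups(table, diag, truth.candidates)
        ds = hs.depth_summary(cls, table)
        cand = truth.candidates[0]
        j = table.sample_index(cand)
        for g in ("A", "C", "D"):
            mask = cls.group_mask(cand, g)
            expect = table.dp[diag.locus_indices[mask], j].mean()
            assert ds.per_group[cand][g]["mean"] == pytest.approx(
                round(float(expect), 2)
            )
        overall = table.dp[diag.locus_indices, j].mean()
        assert ds.overall[cand] == pytest.approx(round(float(overall), 2))

    def test_simple_mean_values(self):
        t = make_table([[AA, TT, AT]], dp=[[10, 10, 20]])
        diag = hs.find_diagnostic_loci(t, ["s1"], ["s2"], ["s3"])
        cls = hs.classify_groups(t, diag, ["s3"])
        ds = hs.depth_summary(cls, t)
        assert ds.per_group["s3"]["A"] == {"n": 1, "mean": 20.0}

    def test_empty_group_mean_is_none_not_zero(self):
        t = make_table([[AA, TT, AT]])
        diag = hs.find_diagnostic_loci(t, ["s1"], ["s2"], ["s3"])
        cls = hs.classify_groups(t, diag, ["s3"])
        ds = hs.depth_summary(cls, t)
        assert ds.per_group["s3"]["D"]["mean"] is None


class TestCompareDepths:
    def test_identical_vectors_give_t0_p1(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = hs.compare_depths(x, x.copy())
        assert res.t == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_clear_separation_and_sign(self):
        x = np.array([1.0, 2.0, 3.0])
        res = hs.compare_depths(x, x + 100)
        assert res.p_value < 1e-3 and res.t < 0
        assert hs.compare_depths(x + 100, x).t > 0

    def test_matches_textbook_welch_formula(self):
        rng = np.random.default_rng(2024)
        x = rng.normal(10, 3, size=50)
        y = rng.normal(12, 5, size=50)
        res = hs.compare_depths(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_too_small_vectors_error(self):
        with pytest.raises(ValueError):
            hs.compare_depths(np.array([1.0]), np.array([1.0, 2.0]))

    def test_p_value_display_floor_is_presentation_only(self):
        res = hs.TTestResult(50.0, 100.0, 1e-30, 10, 10, 1.0, 2.0)
        assert res.p_value == 1e-30
        assert res.format_p() == "< 2.2e-16"


class TestSubsampleLoci:
    def test_full_sample_is_identity_as_set(self):
        loci = list(range(20))
        assert set(hs.subsample_loci(loci, 20, seed=1)) == set(loci)

    def test_zero_gives_empty(self):
        assert hs.subsample_loci(list(range(5)), 0, seed=1) == []

    def test_same_seed_reproduces(self):
        loci = list(range(100))
        assert hs.subsample_loci(loci, 10, 3) == hs.subsample_loci(loci, 10, 3)

    def test_oversampling_errors(self):
        with pytest.raises(ValueError):
            hs.subsample_loci([1, 2], 3, seed=0)


class TestWindowedDensity:
    def _table(self, positions, chrom="chr1"):
        loci = [hs.Locus(chrom, p, "A", ("T",)) for p in positions]
        L = len(loci)
        return hs.VariantTable(
            loci, ["s1"], np.zeros((L, 1, 2)), np.zeros((L, 1)), np.zeros((L, 1, 2))
        )

    def test_window_boundaries(self):
        w = 1000
        t = self._table([1, w, w + 1])
        idx = np.arange(3)
        out = hs.windowed_density(idx, idx, t, w)
        assert out["chr1"]["counts"].tolist() == [2, 1]

    def test_empty_subset_all_zero(self):
        t = self._table([10, 20])
        out = hs.windowed_density(np.array([], dtype=int), np.arange(2), t, 5)
        assert out["chr1"]["counts"].sum() == 0

    def test_uniform_subset_calibration_under_null(self):
        # a uniformly drawn subset of uniform loci should rarely reject
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            pos = np.sort(rng.choice(10_000_00, size=400, replace=False)) + 1
            t = self._table(pos.tolist())
            sub = rng.choice(400, size=150, replace=False)
            out = hs.windowed_density(sub, np.arange(400), t, 100_000)
            if out["chr1"]["p_value"] is not None and out["chr1"]["p_value"] < 0.01:
                rejections += 1
        assert rejections <= 5  # >=95% of replicates keep the null


class TestGenesForGroup:
    def test_distinct_gene_count(self):
        mapping = {0: {"geneA"}, 1: {"geneA"}, 2: {"geneA"}}
        n, genes = hs.genes_for_group(np.array([0, 1, 2]), mapping)
        assert n == 1 and genes == ["geneA"]

    def test_loci_outside_genes_count_zero(self):
        n, genes = hs.genes_for_group(np.array([0, 1]), {0: set(), 1: set()})
        assert n == 0 and genes == []

    def test_matches_brute_force_distinct_count(self, small_sim):
        params, truth, table = small_sim
        diag = hs.find_diagnostic_loci(
            table, truth.parents_p, truth.parents_m, truth.candidates
        )
        mapping = hs.map_loci_to_genes(table, truth.gene_intervals())
        n, genes = hs.genes_for_group(diag.locus_indices, mapping)
        expect = set()
        for i in diag.locus_indices:
            expect |= mapping[int(i)]
        assert n == len(expect) and set(genes) == expect
        assert n > 0
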