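"""AFS, Tajima's D, Hudson FST, PBS, outlier genes, LD and PCA."""

import numpy as np
import pandas as pd
import pytest

from migrasv.io import MISSING, GeneAnnotation, GenomeLayout, SVRecord
from migrasv.popgen import (
    AlleleCounts,
    allele_counts,
    folded_afs,
    fst_genomewide,
    hudson_fst,
    ld_profile,
    pbs,
    pbs_outlier_genes,
    pbs_outlier_loci,
    pca,
    sample_colinear_controls,
    svtype_categories,
    tajimas_d,
)
from migrasv.synth import simulate_ld_cohort, simulate_neutral_spectrum
from tests.conftest import make_matrix, random_matrix


class TestFoldedAFS:
    def test_singleton_goes_to_bin_one(self):
        dosages = np.zeros((1, 10), dtype=np.int16)
        dosages[0, 0] = 1
        afs = folded_afs(make_matrix(dosages))["all"]
        assert afs.bins[1] == 1 and afs.bins.sum() == 1

    def test_frequency_half_folds_to_top_bin(self):
        dosages = np.ones((1, 10), dtype=np.int16)
        afs = folded_afs(make_matrix(dosages))["all"]
        assert afs.bins[10] == 1  # n/2 = 10 copies of each allele

    def test_bin_totals_conserve_polymorphic_loci(self):
        matrix = random_matrix(12, 300, seed=4, maf_lo=0.0, maf_hi=1.0)
        cats = svtype_categories(matrix.loci)
        out = folded_afs(matrix, cats)
        total = sum(a.n_polymorphic + a.n_monomorphic_excluded for a in out.values())
        assert total == 300

    def test_indel_pooling(self):
        loci = [
            SVRecord(id="a", chrom="c", start=0, end=100, svtype="DEL", length=100),
            SVRecord(id="b", chrom="c", start=5000, end=5001, svtype="INS", length=60),
            SVRecord(id="c", chrom="c", start=9000, end=9900, svtype="INV", length=900),
        ]
        assert list(svtype_categories(loci)) == ["INDEL", "INDEL", "INV"]

    def test_neutral_simulation_matches_folded_law(self):
        n_ind, n_loci = 10, 5000
        matrix = simulate_neutral_spectrum(n_ind, n_loci, seed=9)
        afs = folded_afs(matrix)["all"]
        n = 2 * n_ind
        i = np.arange(1, n // 2 + 1)
        expected = 1.0 / i + 1.0 / (n - i)
        expected[-1] = 1.0 / (n // 2)  # i = n-i: one class only
        expected = expected / expected.sum() * afs.n_polymorphic
        observed = afs.bins[1:]
        chi2 = ((observed - expected) ** 2 / expected).sum()
        from scipy.stats import chi2 as chi2_dist

        p = chi2_dist.sf(chi2, df=len(i) - 1)
        assert p > 0.01


def tajima_oracle(dosages):
    """Independent textbook implementation (direct constant-by-constant)."""
    dosages = np.asarray(dosages)
    n = 2 * dosages.shape[1]
    k = dosages.sum(axis=1)
    keep = (k > 0) & (k < n)
    S = keep.sum()
    p = k[keep] / n
    pi = (n / (n - 1)) * np.sum(2 * p * (1 - p))
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_excess_rare_alleles_negative(self):
        dosages = np.zeros((40, 5), dtype=np.int16)
        dosages[:, 0] = 1  # every locus a singleton
        assert tajimas_d(make_matrix(dosages)) < 0

    def test_excess_intermediate_alleles_positive(self):
        dosages = np.ones((40, 5), dtype=np.int16)  # all p = 0.5
        assert tajimas_d(make_matrix(dosages)) > 0

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(11)
        dosages = rng.binomial(2, rng.uniform(0.02, 0.98, 50)[:, None], (50, 10)).astype(np.int16)
        matrix = make_matrix(dosages)
        assert tajimas_d(matrix) == pytest.approx(tajima_oracle(dosages), abs=1e-10)

    def test_no_polymorphic_loci_is_an_error(self):
        with pytest.raises(ValueError):
            tajimas_d(make_matrix(np.zeros((5, 10), dtype=np.int16)))

    def test_loci_with_missing_data_dropped(self):
        rng = np.random.default_rng(12)
        dosages = rng.integers(0, 3, (30, 8)).astype(np.int16)
        with_missing = dosages.copy()
        with_missing[5, 0] = MISSING
        full_wo = tajimas_d(make_matrix(np.delete(dosages, 5, axis=0)))
        assert tajimas_d(make_matrix(with_missing)) == pytest.approx(full_wo)


def hudson_oracle(p1, p2, n1, n2):
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


class TestHudsonFst:
    def test_equal_frequencies_give_negative_finite_sample_fst(self):
        n = 40
        c = AlleleCounts(n=np.array([n]), k=np.array([n // 2]))
        num, den, fst = hudson_fst(c, c)
        assert fst[0] < 0
        assert num[0] == pytest.approx(-2 * 0.25 / (n - 1))

    def test_opposite_fixation_gives_one(self):
        c1 = AlleleCounts(n=np.array([40]), k=np.array([40]))
        c2 = AlleleCounts(n=np.array([40]), k=np.array([0]))
        assert hudson_fst(c1, c2)[2][0] == pytest.approx(1.0)

    def test_matches_formula_oracle_on_random_configurations(self):
        rng = np.random.default_rng(13)
        n1 = 2 * rng.integers(2, 60, size=1000)
        n2 = 2 * rng.integers(2, 60, size=1000)
        k1 = rng.integers(0, n1 + 1)
        k2 = rng.integers(0, n2 + 1)
        num, den, fst = hudson_fst(AlleleCounts(n1, k1), AlleleCounts(n2, k2))
        onum, oden = hudson_oracle(k1 / n1, k2 / n2, n1, n2)
        assert np.allclose(num, onum, atol=1e-12)
        assert np.allclose(den, oden, atol=1e-12)

    def test_symmetry_and_allele_relabel_invariance(self):
        rng = np.random.default_rng(14)
        n = np.full(200, 40)
        k1, k2 = rng.integers(1, 40, 200), rng.integers(1, 40, 200)
        a, b = AlleleCounts(n, k1), AlleleCounts(n, k2)
        assert np.allclose(hudson_fst(a, b)[2], hudson_fst(b, a)[2])
        flipped = hudson_fst(AlleleCounts(n, n - k1), AlleleCounts(n, n - k2))[2]
        assert np.allclose(hudson_fst(a, b)[2], flipped)

    def test_same_allele_fixation_is_undefined(self):
        c = AlleleCounts(n=np.array([40]), k=np.array([0]))
        assert np.isnan(hudson_fst(c, c)[2][0])

    def test_genomewide_reduces_to_single_locus(self):
        num, den = np.array([0.02]), np.array([0.4])
        assert fst_genomewide(num, den) == pytest.approx(0.05)

    def test_genomewide_recovers_balding_nichols_target(self):
        from migrasv.synth import simulate_genotypes, simulate_group_frequencies, simulate_svs, make_layout

        layout = make_layout()
        loci = simulate_svs(layout, 5000, seed=20)
        _, freqs = simulate_group_frequencies(5000, ["A", "B"], F=0.02, seed=21)
        matrix, _ = simulate_genotypes(loci, freqs, {"A": 50, "B": 50}, seed=22)
        counts = allele_counts(matrix, {"A": list(range(50)), "B": list(range(50, 100))})
        num, den, _ = hudson_fst(counts["A"], counts["B"])
        assert fst_genomewide(num, den) == pytest.approx(0.02, abs=0.005)


class TestPBS:
    def three_pop_counts(self, seed=30, n_loci=500, selected=None):
        from migrasv.synth import simulate_genotypes, simulate_group_frequencies, simulate_svs, make_layout

        layout = make_layout()
        loci = simulate_svs(layout, n_loci, seed=seed)
        _, freqs = simulate_group_frequencies(
            n_loci, ["NW", "SW", "SE"], F=0.02, selected=selected or [], seed=seed + 1
        )
        matrix, _ = simulate_genotypes(loci, freqs, {"NW": 19, "SW": 28, "SE": 12}, seed=seed + 2)
        return allele_counts(
            matrix, {"NW": list(range(19)), "SW": list(range(19, 47)), "SE": list(range(47, 59))}
        )

    def test_zero_fst_gives_zero_pbs(self):
        n = np.full(3, 40)
        k = np.array([10, 20, 30])
        c = AlleleCounts(n, k)
        res = pbs({"A": c, "B": c, "C": c})
        # identical counts: pairwise FST < 0, clamped to 0 -> PBS 0
        for values in res.pbs.values():
            assert np.allclose(values, 0.0)

    def test_printed_formula_case(self):
        # FST(SE,NW)=FST(SE,SW)=0.5, FST(NW,SW)=0 => PBS_SE=-ln(0.5), others 0
        t = -np.log(0.5)
        pbs_se = 0.5 * (t + t - 0.0)
        assert pbs_se == pytest.approx(-np.log(0.5))

    def test_conservation_identity(self):
        counts = self.three_pop_counts()
        res = pbs(counts)
        total = sum(res.pbs.values())
        t_half = 0.5 * sum(res.branch_t.values())
        assert np.allclose(total, t_half, atol=1e-12)

    def test_branch_specific_shift_ranks_in_focal_tail_only(self):
        counts = self.three_pop_counts(seed=40, n_loci=2000, selected=[(10, "SE", 0.6)])
        res = pbs(counts)
        pos = np.flatnonzero(res.locus_index == 10)[0]
        se_rank = (res.pbs["SE"] >= res.pbs["SE"][pos]).mean()
        assert se_rank <= 0.01
        assert res.pbs["NW"][pos] < np.quantile(res.pbs["NW"], 0.95)
        assert res.pbs["SW"][pos] < np.quantile(res.pbs["SW"], 0.95)


class TestPBSOutlierGenes:
    def test_quantile_keeps_five_of_hundred(self):
        values = np.arange(100.0)
        assert pbs_outlier_loci(values, 0.95).sum() == 5

    def test_ties_at_threshold_included(self):
        values = np.array([0.0] * 95 + [1.0] * 5 + [1.0])  # 6 tied at threshold
        assert pbs_outlier_loci(values, 0.95).sum() == 6

    def test_overlapping_genes_reported_once(self):
        loci = [SVRecord(id=f"l{i}", chrom="chr1", start=100 + 10_000 * i,
                         end=300 + 10_000 * i, svtype="DEL", length=200) for i in range(20)]
        counts = {
            g: AlleleCounts(np.full(20, 40), np.arange(1, 21) + off)
            for g, off in (("A", 0), ("B", 3), ("C", 6))
        }
        res = pbs(counts)
        genes = GeneAnnotation(pd.DataFrame({
            "gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"],
            "start": [0, 150], "end": [400, 500], "strand": ["+", "-"],
        }))
        out = pbs_outlier_genes(res, loci, genes, quantile=0.0)  # all loci outliers
        assert out["A"].count("g1") == 1 and out["A"].count("g2") == 1

    def test_matches_all_pairs_overlap_oracle(self):
        rng = np.random.default_rng(55)
        loci = [SVRecord(id=f"l{i}", chrom="chr1", start=int(s), end=int(s) + 200,
                         svtype="DEL", length=200)
                for i, s in enumerate(rng.integers(0, 95_000, size=60))]
        gene_rows = [{"gene_id": f"g{i}", "chrom": "chr1", "start": int(s),
                      "end": int(s) + 800, "strand": "+"}
                     for i, s in enumerate(rng.integers(0, 95_000, size=40))]
        genes = GeneAnnotation(pd.DataFrame(gene_rows))
        counts = {
            g: AlleleCounts(np.full(60, 40), rng.integers(1, 40, size=60))
            for g in ("A", "B", "C")
        }
        res = pbs(counts)
        out = pbs_outlier_genes(res, loci, genes, quantile=0.9)
        for group in ("A", "B", "C"):
            mask = pbs_outlier_loci(res.pbs[group], 0.9)
            expected = set()
            for li in res.locus_index[mask]:
                for row in gene_rows:
                    if row["start"] < loci[int(li)].end and loci[int(li)].start < row["end"]:
                        expected.add(row["gene_id"])
            assert set(out[group]) == expected


class TestLDProfile:
    def test_perfectly_correlated_snps(self):
        rng = np.random.default_rng(66)
        base = rng.binomial(2, 0.5, 40).astype(np.int16)
        matrix = make_matrix(np.stack([base, base]), spacing=100)
        layout = GenomeLayout({"chr1": 100_000})
        inv = SVRecord(id="inv", chrom="chr1", start=0, end=500, svtype="INV", length=500)
        dosage = np.zeros(40, dtype=np.int16)  # all major homozygotes
        with pytest.warns(UserWarning):
            profs = ld_profile(matrix, [(inv, dosage)], layout, seed=1)
        major = next(p for p in profs if p.stratum == "inversion-major-homozygotes")
        assert np.nanmax(major.mean_r2) == pytest.approx(1.0)

    def test_independent_snps_null_r2(self):
        rng = np.random.default_rng(67)
        n = 400
        dosages = rng.binomial(2, 0.5, size=(30, n)).astype(np.int16)
        matrix = make_matrix(dosages, spacing=100)
        layout = GenomeLayout({"chr1": 1_000_000})
        inv = SVRecord(id="inv", chrom="chr1", start=0, end=3000, svtype="INV", length=3000)
        dosage = np.zeros(n, dtype=np.int16)
        with pytest.warns(UserWarning):
            profs = ld_profile(matrix, [(inv, dosage)], layout, seed=2)
        major = next(p for p in profs if p.stratum == "inversion-major-homozygotes")
        mean = np.nansum(major.mean_r2 * major.n_pairs) / major.n_pairs.sum()
        assert mean == pytest.approx(1 / (n - 1), abs=3 / (n - 1))

    def test_inversion_strata_retain_ld_controls_decay(self):
        matrix, inversions, layout = simulate_ld_cohort(seed=8)
        profs = {p.stratum: p for p in ld_profile(matrix, inversions, layout, seed=9)}
        for stratum in ("inversion-major-homozygotes", "inversion-minor-homozygotes"):
            prof = profs[stratum]
            last = np.flatnonzero(np.isfinite(prof.mean_r2))[-1]
            assert prof.mean_r2[last] >= 0.8
        control = profs["colinear-control"]
        beyond = control.mean_r2[4:]  # > 2 kb, past the simulated 500-bp scale
        assert np.nanmean(beyond) < 0.2

    def test_control_regions_never_overlap_inversions(self):
        layout = GenomeLayout({"chr1": 1_000_000})
        inversions = [("chr1", 50_000, 60_000), ("chr1", 100_000, 110_000)]
        rng = np.random.default_rng(3)
        controls = sample_colinear_controls(inversions, layout, rng, n_control=20)
        for chrom, s, e in controls:
            for _, is_, ie in inversions:
                assert not (is_ < e and s < ie)


class TestPCA:
    def test_two_duplicated_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(70)
        a = rng.binomial(2, 0.5, 60).astype(np.int16)
        b = rng.binomial(2, 0.5, 60).astype(np.int16)
        # 10 copies of individual profile a, 10 of b over 60 loci
        cols = np.column_stack([a] * 10 + [b] * 10)
        matrix = make_matrix(cols)
        res = pca(matrix, min_maf=0.0)
        pc1 = res.scores[:, 0]
        assert (pc1[:10].std() < 1e-8) and (pc1[10:].std() < 1e-8)
        assert abs(pc1[0] - pc1[-1]) > 1e-6

    def test_eigenvalue_sum_conserves_standardized_variance(self):
        matrix = random_matrix(20, 50, seed=71)
        res = pca(matrix, min_maf=0.0)
        X = matrix.dosages.astype(float).T
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        assert res.eigenvalues.sum() == pytest.approx(np.sum(Z**2) / Z.shape[1])

    def test_scores_match_svd_oracle_up_to_sign(self):
        matrix = random_matrix(20, 50, seed=72)
        res = pca(matrix, min_maf=0.0)
        X = matrix.dosages.astype(float).T
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        U, s, _ = np.linalg.svd(Z / np.sqrt(Z.shape[1]), full_matrices=False)
        oracle = U * s
        for k in range(5):
            dot = np.dot(res.scores[:, k], oracle[:, k])
            assert np.allclose(res.scores[:, k], np.sign(dot) * oracle[:, k], atol=1e-8)

    def test_eigenvalues_non_increasing_and_nonnegative(self):
        res = pca(random_matrix(15, 40, seed=73), min_maf=0.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert np.all(res.eigenvalues >= 0)
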