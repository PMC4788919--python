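"""Format round-trips, HWE testing, QC filters, breed proportions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pleioscan import io as psio
from pleioscan.data import GenotypeMatrix, QcReport
from pleioscan.qc import (
    breed_proportions,
    hwe_test,
    mean_fill_missing,
    sample_qc_filter,
    snp_qc_filter,
)


def make_geno(dosages, chrom=None, pos=None):
    dosages = np.asarray(dosages, dtype=float)
    n_animals, n_snps = dosages.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(n_snps)],
            "chrom": chrom or ["1"] * n_snps,
            "pos_bp": pos or list(range(1, n_snps + 1)),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    return GenotypeMatrix(
        animals=[f"a{i}" for i in range(n_animals)], snps=snps, dosages=dosages
    )


class TestIO:
    def test_vcf_roundtrip(self, tmp_path):
        geno = make_geno([[0, 1], [1, 2], [2, np.nan]])
        path = tmp_path / "g.vcf"
        psio.write_vcf(geno, path)
        back = psio.read_genotypes(path)
        assert back.animals == geno.animals
        np.testing.assert_array_equal(back.dosages, geno.dosages)
        pd.testing.assert_frame_equal(back.snps, geno.snps)

    def test_vcf_gt_encoding_and_missing(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tx\ty\tz\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t./.\t0/0\t1/1\n"
        )
        geno = psio.read_genotypes(vcf)
        np.testing.assert_array_equal(geno.dosages[:, 0], [0, 1, 2])
        assert np.isnan(geno.dosages[0, 1])
        assert geno.snps["pos_bp"].tolist() == [100, 200]

    def test_vcf_multiallelic_skipped_with_warning(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tx\n"
            "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
            "1\t200\trs2\tA\tG\t.\t.\t.\tGT\t0/1\n"
        )
        with pytest.warns(UserWarning, match="multi-allelic"):
            geno = psio.read_genotypes(vcf)
        assert geno.n_snps == 1
        assert geno.snps["snp_id"].tolist() == ["rs2"]

    def test_tsv_roundtrip(self, tmp_path, tiny_cohort):
        geno = tiny_cohort.genotypes
        path = tmp_path / "g.tsv"
        psio.write_tsv(geno, path)
        back = psio.read_genotypes(path, fmt="tsv")
        np.testing.assert_array_equal(back.dosages, geno.dosages)
        assert back.animals == geno.animals
        pd.testing.assert_frame_equal(back.snps, geno.snps)

    def test_pedigree_phenotype_roundtrip(self, tmp_path, tiny_cohort):
        pped = tmp_path / "ped.csv"
        ppheno = tmp_path / "pheno.csv"
        psio.write_pedigree(tiny_cohort.pedigree, pped)
        psio.write_phenotypes(tiny_cohort.phenotypes, ppheno)
        ped = psio.read_pedigree(pped)
        pheno = psio.read_phenotypes(ppheno)
        pd.testing.assert_frame_equal(ped, tiny_cohort.pedigree)
        pd.testing.assert_frame_equal(
            pheno, tiny_cohort.phenotypes, check_dtype=False
        )

    def test_duplicate_snp_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate snp_id"):
            geno = make_geno([[0, 1]])
            geno.snps.loc[1, "snp_id"] = "s0"
            GenotypeMatrix(geno.animals, geno.snps, geno.dosages)


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_symmetric_extreme_case(self):
        # expected 25/50/25 -> chi2 = 25 + 50 + 25 = 100
        p = hwe_test(50, 0, 50)
        assert p == pytest.approx(stats.chi2.sf(100, df=1))

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 3)

    @given(
        st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_chi2_oracle(self, aa, ab, bb):
        if aa + ab + bb == 0:
            return
        n = aa + ab + bb
        p_a = (2 * aa + ab) / (2 * n)
        if p_a in (0, 1):
            assert hwe_test(aa, ab, bb) == 1.0
            return
        exp = np.array([p_a**2, 2 * p_a * (1 - p_a), (1 - p_a) ** 2]) * n
        chi2 = (((np.array([aa, ab, bb]) - exp) ** 2) / exp).sum()
        assert hwe_test(aa, ab, bb) == pytest.approx(
            float(stats.chi2.sf(chi2, df=1)), rel=1e-10
        )


class TestFilters:
    def test_snp_filter_hand_enumeration(self):
        # 10 SNPs x 20 animals, with engineered violations
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(20, 10)).astype(float)
        d[:, 0] = 0.0                       # monomorphic -> MAF fail
        d[0:2, 1] = np.nan                  # call rate 0.9 < 0.95 -> fail
        d[:10, 2], d[10:, 2] = 0.0, 2.0     # extreme HWE -> fail
        d[:, 3] = [1.0] * 19 + [0.0]        # fine (MAF 0.475... ok)
        geno = make_geno(d)
        kept, report = snp_qc_filter(geno)
        # recompute survivors by hand
        expect = []
        for j in range(10):
            col = d[:, j]
            obs = col[~np.isnan(col)]
            call = len(obs) / 20
            p = obs.mean() / 2
            maf = min(p, 1 - p)
            counts = [(obs == g).sum() for g in (0, 1, 2)]
            hwe = hwe_test(*counts)
            if call >= 0.95 and maf >= 0.01 and hwe >= 1e-5:
                expect.append(f"s{j}")
        assert kept.snps["snp_id"].tolist() == expect
        assert report.n_in - sum(report.removed_by.values()) == report.n_out

    def test_passing_snp_retained(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        d[:3, 0] = np.nan  # call rate 0.97
        kept, rep = snp_qc_filter(make_geno(d))
        assert kept.n_snps == 1 and rep.n_out == 1

    def test_sample_filter(self):
        d = np.ones((20, 10))
        d[0, :2] = 0.0  # keep polymorphic-ish; not relevant here
        d[5, :3] = np.nan   # call rate 0.7 -> removed
        d[11, :2] = np.nan  # call rate 0.8 -> removed
        geno = make_geno(d)
        kept, rep = sample_qc_filter(geno)
        assert kept.n_animals == 18
        assert rep.removed_by["call_rate"] == 2

    def test_complete_matrix_unchanged_by_sample_filter(self, tiny_cohort):
        kept, rep = sample_qc_filter(tiny_cohort.genotypes)
        assert kept.n_animals == tiny_cohort.genotypes.n_animals
        assert rep.n_in == rep.n_out

    def test_qc_report_consistency_enforced(self):
        with pytest.raises(ValueError):
            QcReport(axis="snp", n_in=10, n_out=8, removed_by={"maf": 1})


class TestMeanFill:
    def test_fill_is_column_mean(self):
        geno = make_geno([[0.0], [2.0], [np.nan]])
        filled = mean_fill_missing(geno)
        assert filled.dosages[2, 0] == pytest.approx(1.0)

    def test_no_missing_identity(self):
        geno = make_geno([[0, 1], [1, 2]])
        filled = mean_fill_missing(geno)
        np.testing.assert_array_equal(filled.dosages, geno.dosages)

    def test_all_missing_snp_errors(self):
        geno = make_geno([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="snp_qc_filter"):
            mean_fill_missing(geno)


class TestBreedProportions:
    def test_recursion_matches_hand_computation(self, toy_pedigree):
        frac = breed_proportions(toy_pedigree).set_index("animal")
        assert frac.loc["G1"].tolist() == [0.5, 0.5]
        assert frac.loc["H1"].tolist() == [0.75, 0.25]
        assert frac.loc["I1"].tolist() == [0.625, 0.375]

    def test_simulated_fractions_consistent(self, tiny_cohort):
        ped = tiny_cohort.pedigree
        from pleioscan.data import breed_columns

        cols = breed_columns(ped)
        founders_only = ped.copy()
        nonfounder = founders_only["sire"] != "0"
        founders_only.loc[nonfounder, cols] = np.nan
        frac = breed_proportions(founders_only).set_index("animal")
        np.testing.assert_allclose(
            frac.loc[ped["animal"], cols].to_numpy(dtype=float),
            ped[cols].to_numpy(dtype=float),
            atol=1e-12,
        )

    def test_missing_founder_fractions_error(self):
        ped = pd.DataFrame(
            {
                "animal": ["X"],
                "sire": ["0"],
                "dam": ["0"],
                "breed_1": [np.nan],
            }
        )
        with pytest.raises(ValueError, match="breed"):
            breed_proportions(ped)
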