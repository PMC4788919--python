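"""Gene models, SNP thinning, candidate-gene rules, overlap permutation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pleioscan.annotate import (
    candidate_genes,
    dedup_by_window,
    overlap_permutation_test,
    read_gene_models,
)


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand"])


def snp_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp", "p"])


class TestGeneModels:
    def test_bed_coordinate_conversion(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr1\t99\t200\tGENE1\t0\t+\n")
        genes = read_gene_models(bed)
        assert genes.loc[0, "start"] == 100
        assert genes.loc[0, "end"] == 200
        assert genes.loc[0, "gene_id"] == "GENE1"

    def test_gff3_gene_features_only(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t100\t500\t.\t+\t.\tID=g1;Name=GENE1\n"
            "1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=m1;Parent=g1\n"
            "2\tsrc\tgene\t900\t1200\t.\t-\t.\tID=g2;Name=GENE2\n"
        )
        genes = read_gene_models(gff)
        assert genes["gene_id"].tolist() == ["GENE1", "GENE2"]
        assert genes["start"].tolist() == [100, 900]

    def test_gff3_without_genes_warns(self, tmp_path):
        gff = tmp_path / "m.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=m1\n"
        )
        with pytest.warns(UserWarning, match="gene"):
            genes = read_gene_models(gff)
        assert genes.empty

    def test_bed_roundtrip_lossless(self, tmp_path):
        genes = genes_frame([("G1", "1", 100, 200, "+"),
                             ("G2", "2", 400, 900, "-")])
        bed = tmp_path / "rt.bed"
        with open(bed, "w") as fh:
            for g in genes.itertuples(index=False):
                fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t"
                         f"{g.strand}\n")
        back = read_gene_models(bed)
        pd.testing.assert_frame_equal(back, genes)


class TestDedup:
    def test_close_pair_keeps_smaller_p(self):
        snps = snp_frame([("a", "1", 100_000, 1e-8), ("b", "1", 130_000, 1e-6)])
        out = dedup_by_window(snps)
        assert out["snp_id"].tolist() == ["a"]

    def test_distant_pair_kept(self):
        snps = snp_frame([("a", "1", 100_000, 1e-8), ("b", "1", 170_001, 1e-6)])
        out = dedup_by_window(snps)
        assert set(out["snp_id"]) == {"a", "b"}

    def test_matches_bruteforce_greedy(self):
        rng = np.random.default_rng(0)
        snps = snp_frame(
            [
                (f"s{i}", "1", int(rng.integers(1, 500_000)),
                 float(10 ** rng.uniform(-10, -2)))
                for i in range(10)
            ]
        )
        out = dedup_by_window(snps, window_bp=60_000)
        # brute-force the same greedy definition
        order = snps.sort_values(["p", "chrom", "pos_bp"])
        kept = []
        for row in order.itertuples(index=False):
            if all(abs(row.pos_bp - k) > 60_000 for k in kept):
                kept.append(row.pos_bp)
        assert sorted(out["pos_bp"]) == sorted(kept)

    def test_invariant_no_close_pairs_remain(self):
        rng = np.random.default_rng(1)
        snps = snp_frame(
            [
                (f"s{i}", str(rng.integers(1, 3)),
                 int(rng.integers(1, 10**6)),
                 float(rng.random()))
                for i in range(50)
            ]
        )
        out = dedup_by_window(snps, window_bp=60_000)
        for _, grp in out.groupby("chrom"):
            pos = np.sort(grp["pos_bp"].to_numpy())
            assert (np.diff(pos) > 60_000).all()


class TestCandidateGenes:
    GENES = genes_frame(
        [
            ("NEAR", "1", 1_000_000, 1_050_000, "+"),
            ("FAR", "1", 1_090_000, 1_095_000, "+"),
            ("LONE", "2", 5_000_000, 5_010_000, "-"),
        ]
    )

    def test_single_gene_within_window(self):
        snps = snp_frame([("a", "1", 990_000, 1e-8)])  # 10 kb upstream NEAR
        calls = candidate_genes(snps, self.GENES)
        assert calls.loc[0, "gene_id"] == "NEAR"
        assert calls.loc[0, "distance_bp"] == 10_000
        assert calls.loc[0, "rule"] == "window"

    def test_inside_gene_distance_zero(self):
        snps = snp_frame([("a", "1", 1_020_000, 1e-8)])
        calls = candidate_genes(snps, self.GENES)
        assert calls.loc[0, "distance_bp"] == 0

    def test_two_genes_keeps_nearest_only(self):
        # SNP 5 kb from NEAR's end, 25 kb from FAR's start
        snps = snp_frame([("a", "1", 1_065_000, 1e-8)])
        calls = candidate_genes(snps, self.GENES)
        assert len(calls) == 1
        assert calls.loc[0, "gene_id"] == "NEAR"

    def test_expansion_flags_nearest_gene(self):
        snps = snp_frame([("a", "2", 4_922_000, 1e-8)])  # 78 kb upstream LONE
        assert candidate_genes(snps, self.GENES).empty
        calls = candidate_genes(snps, self.GENES, expand=True)
        assert calls.loc[0, "gene_id"] == "LONE"
        assert calls.loc[0, "rule"] == "expanded"
        assert calls.loc[0, "distance_bp"] == 78_000

    def test_one_gene_per_snp(self):
        rng = np.random.default_rng(2)
        snps = snp_frame(
            [(f"s{i}", "1", int(rng.integers(900_000, 1_200_000)), 1e-8)
             for i in range(20)]
        )
        calls = candidate_genes(snps, self.GENES, expand=True)
        assert calls["snp_id"].is_unique


class TestOverlap:
    @staticmethod
    def _fixture():
        rng = np.random.default_rng(0)
        genes = genes_frame(
            [(f"g{i}", "1", 100_000 * (i + 1), 100_000 * (i + 1) + 20_000, "+")
             for i in range(20)]
        )
        # significant SNPs planted inside genes g0..g4 only
        rows = []
        for i in range(5):
            rows.append((f"hit{i}", "1", 100_000 * (i + 1) + 5_000, 1e-6))
        for i in range(30):
            rows.append((f"null{i}", "1", int(rng.integers(3e6, 9e6)), 0.5))
        meta = snp_frame(rows)
        return meta, genes

    def test_target_equals_universe_gives_p_one(self):
        meta, genes = self._fixture()
        res = overlap_permutation_test(meta, genes, genes, n_perm=100, seed=1)
        assert res.p_joint == pytest.approx(1.0)

    def test_no_significant_snps_gives_p_one(self):
        meta, genes = self._fixture()
        null_meta = meta.assign(p=0.9)
        res = overlap_permutation_test(null_meta, genes.head(5), genes,
                                       n_perm=100, seed=1)
        assert res.observed_snps == 0
        assert res.p_joint == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """Planted enrichment on a 20-gene universe with 5 targets: the
        permutation P matches the exact probability over all C(20,5)
        subsets within Monte-Carlo error."""
        meta, genes = self._fixture()
        targets = genes.head(5)  # the enriched genes
        n_perm = 2000
        res = overlap_permutation_test(meta, targets, genes, n_perm=n_perm,
                                       seed=3)
        # exhaustive: each gene g0..g4 carries exactly one significant SNP
        exact_ge = 0
        total = 0
        for combo in itertools.combinations(range(20), 5):
            n_hit = sum(1 for g in combo if g < 5)
            total += 1
            if n_hit >= res.observed_genes and n_hit >= res.observed_snps:
                exact_ge += 1
        p_exact = exact_ge / total
        mc_err = 2 * np.sqrt(max(p_exact, 1 / n_perm)
                             * (1 - p_exact) / n_perm)
        assert res.observed_snps == 5 and res.observed_genes == 5
        assert abs(res.p_joint - max(p_exact, 1 / (n_perm + 1))) <= max(
            mc_err, 2 / n_perm
        )

    def test_seed_reproducibility_and_mc_error(self):
        meta, genes = self._fixture()
        targets = genes.head(5)
        a = overlap_permutation_test(meta, targets, genes, n_perm=500, seed=9)
        b = overlap_permutation_test(meta, targets, genes, n_perm=500, seed=9)
        assert a.p_joint == b.p_joint
        c = overlap_permutation_test(meta, targets, genes, n_perm=500, seed=10)
        p = a.p_joint
        assert abs(c.p_joint - p) <= 4 * np.sqrt(p * (1 - p) / 500) + 1e-9

    def test_universe_smaller_than_target_errors(self):
        meta, genes = self._fixture()
        with pytest.raises(ValueError):
            overlap_permutation_test(meta, genes, genes.head(3))

    def test_unmapped_targets_excluded_with_warning(self):
        meta, genes = self._fixture()
        targets = pd.concat(
            [genes.head(3),
             genes_frame([("missing", "9", 1, 2, "+")])]
        )
        with pytest.warns(UserWarning, match="not present"):
            res = overlap_permutation_test(meta, targets, genes, n_perm=50,
                                           seed=0)
        assert res.n_target == 3
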