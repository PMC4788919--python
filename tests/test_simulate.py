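"""Synthetic-cohort generator: structure, determinism, genetics."""

import numpy as np
import pandas as pd
import pytest

from pleioscan.data import UNKNOWN_PARENT, breed_columns
from pleioscan.simulate import (
    SimConfig,
    plant_qtl,
    simulate_cohort,
    simulate_genotypes,
    simulate_pedigree,
)


def small_cfg(**kw):
    base = dict(
        n_sires=5, n_dams_per_sire=2, n_offspring_per_dam=3, n_breeds=3,
        n_snps=200, n_chromosomes=2, n_traits=4, n_qtl_groups=2,
        qtl_per_group=1, seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestPedigree:
    def test_counts_and_structure(self):
        cfg = small_cfg()
        ped = simulate_pedigree(cfg)
        offspring = ped[ped["sire"] != UNKNOWN_PARENT]
        assert len(offspring) == 5 * 2 * 3
        assert offspring["sire"].nunique() == 5
        sires = set(ped.loc[ped["sire"] == UNKNOWN_PARENT, "animal"])
        assert set(offspring["sire"]).issubset(sires)
        frac = ped[breed_columns(ped)].to_numpy(dtype=float)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)

    def test_midparent_breed_fractions(self):
        cfg = small_cfg()
        ped = simulate_pedigree(cfg).set_index("animal")
        cols = breed_columns(ped.reset_index())
        for row in ped.itertuples():
            if row.sire == UNKNOWN_PARENT:
                continue
            mid = (ped.loc[row.sire, cols].to_numpy(dtype=float)
                   + ped.loc[row.dam, cols].to_numpy(dtype=float)) / 2
            np.testing.assert_allclose(
                ped.loc[row.Index, cols].to_numpy(dtype=float), mid
            )

    def test_deterministic_for_fixed_seed(self):
        a = simulate_cohort(small_cfg())
        b = simulate_cohort(small_cfg())
        pd.testing.assert_frame_equal(a.pedigree, b.pedigree)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_sires=0)
        with pytest.raises(ValueError):
            small_cfg(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            small_cfg(heritabilities=[1.2, 0.3, 0.3, 0.3])


class TestGenotypes:
    def test_dosage_domain_and_mendelian_bound(self):
        cfg = small_cfg()
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        assert set(np.unique(geno.dosages)).issubset({0.0, 1.0, 2.0})
        idx = {a: i for i, a in enumerate(geno.animals)}
        for row in ped.itertuples():
            if row.sire == UNKNOWN_PARENT:
                continue
            child = geno.dosages[idx[row.animal]]
            midparent = (geno.dosages[idx[row.sire]]
                         + geno.dosages[idx[row.dam]]) / 2
            assert np.all(np.abs(child - midparent) <= 1.0)

    def test_ld_decay_creates_adjacent_correlation(self):
        cfg = small_cfg(n_snps=600, n_sires=40, ld_decay=0.9, breed_af_sd=0.0,
                        n_breeds=1)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        founders = (ped["sire"] == UNKNOWN_PARENT).to_numpy()
        G = geno.dosages[founders]
        chrom = geno.snps["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        r = np.array([
            np.corrcoef(G[:, j], G[:, j + 1])[0, 1]
            for j in np.flatnonzero(same)
            if G[:, j].std() > 0 and G[:, j + 1].std() > 0
        ])
        cfg0 = small_cfg(n_snps=600, n_sires=40, ld_decay=0.0, breed_af_sd=0.0,
                         n_breeds=1)
        geno0 = simulate_genotypes(simulate_pedigree(cfg0), cfg0)
        G0 = geno0.dosages[founders]
        r0 = np.array([
            np.corrcoef(G0[:, j], G0[:, j + 1])[0, 1]
            for j in np.flatnonzero(same)
            if G0[:, j].std() > 0 and G0[:, j + 1].std() > 0
        ])
        # with ld_decay=0 adjacent r^2 is at the independent-loci noise
        # floor; with ld_decay=0.9 it is far above it
        assert np.mean(r**2) > 5 * np.mean(r0**2)
        assert abs(np.mean(r0)) < 0.05

    def test_parent_offspring_genotype_correlation(self):
        # single breed, no allele-frequency stratification, so the
        # pedigree expectation of 0.5 applies
        cfg = small_cfg(n_snps=2000, n_sires=30, ld_decay=0.0,
                        n_breeds=1, breed_af_sd=0.0)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        # centre each SNP so the shared allele-frequency component does
        # not inflate the across-loci correlation within a pair
        D = geno.dosages - geno.dosages.mean(axis=0)
        idx = {a: i for i, a in enumerate(geno.animals)}
        offspring = ped[ped["sire"] != UNKNOWN_PARENT]
        rs = []
        for row in offspring.itertuples():
            rs.append(np.corrcoef(D[idx[row.animal]], D[idx[row.sire]])[0, 1])
        # pedigree expectation ~0.5 for parent-offspring pairs
        assert abs(np.mean(rs) - 0.5) < 0.1


class TestQtl:
    def test_group_counts_balanced(self):
        cfg = small_cfg(n_qtl_groups=3, qtl_per_group=2, n_snps=400)
        geno = simulate_genotypes(simulate_pedigree(cfg), cfg)
        truth = plant_qtl(geno, cfg)
        assert len(truth.qtl_ids) == 6
        counts = np.bincount(truth.qtl_group)
        assert (counts == 2).all()

    def test_pattern_correlation_structure(self):
        tpl = np.array([
            [0.3, 0.3, 0.3, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.3, -0.3, 0.3],
        ])
        cfg = small_cfg(n_traits=6, n_qtl_groups=2, qtl_per_group=3,
                        n_snps=800, group_effect_patterns=tpl,
                        qtl_pattern_jitter=0.01)
        geno = simulate_genotypes(simulate_pedigree(cfg), cfg)
        truth = plant_qtl(geno, cfg)
        within, between = [], []
        for i in range(6):
            for j in range(i + 1, 6):
                r = np.corrcoef(truth.qtl_effects[i], truth.qtl_effects[j])[0, 1]
                (within if truth.qtl_group[i] == truth.qtl_group[j]
                 else between).append(r)
        assert np.mean(within) > 0.9
        assert np.mean(np.abs(between)) < 0.3

    def test_zero_perturbation_gives_identical_patterns(self):
        cfg = small_cfg(qtl_per_group=2, n_snps=400, qtl_pattern_jitter=0.0,
                        qtl_scale_sd=0.0)
        geno = simulate_genotypes(simulate_pedigree(cfg), cfg)
        truth = plant_qtl(geno, cfg)
        for g in range(cfg.n_qtl_groups):
            rows = truth.qtl_effects[truth.qtl_group == g]
            np.testing.assert_allclose(
                rows, np.tile(rows[0], (len(rows), 1))
            )

    def test_qtl_on_map_and_spaced(self):
        cfg = small_cfg(n_snps=400)
        geno = simulate_genotypes(simulate_pedigree(cfg), cfg)
        truth = plant_qtl(geno, cfg)
        snps = geno.snps.set_index("snp_id")
        assert all(q in snps.index for q in truth.qtl_ids)
        pos = snps.loc[truth.qtl_ids]
        for c, grp in pos.groupby("chrom"):
            p = np.sort(grp["pos_bp"].to_numpy())
            assert (np.diff(p) >= cfg.qtl_min_spacing_bp).all()


class TestPhenotypes:
    def test_missing_rate_zero_gives_complete_table(self):
        cfg = small_cfg(missing_rate=0.0)
        cohort = simulate_cohort(cfg)
        assert not cohort.phenotypes[cohort.trait_names].isna().any().any()

    def test_missingness_applied(self, tiny_cohort):
        frac = tiny_cohort.phenotypes[tiny_cohort.trait_names].isna().mean()
        assert 0.0 < frac.mean() < 0.15

    def test_null_trait_variance_matches_residual(self):
        cfg = small_cfg(
            n_sires=60, n_offspring_per_dam=5, missing_rate=0.0,
            qtl_per_group=0, heritabilities=[0.3] * 4,
            trait_residual_correlation=None,
        )
        cfg.fixed_effects.cohort_sd = 0.0
        cfg.fixed_effects.sex_effect_sd = 0.0
        cfg.fixed_effects.birth_rear_sd = 0.0
        cfg.fixed_effects.breed_intercept_sd = 0.0
        cfg.fixed_effects.age_slope_sd = 0.0
        cohort = simulate_cohort(cfg)
        var = cohort.phenotypes[cohort.trait_names].var()
        # no fixed effects: total variance = additive + residual = 1
        assert np.all(np.abs(var - 1.0) < 0.15)

    def test_realized_heritability_near_target(self, default_cohort):
        c = default_cohort
        tbv = c.truth.true_breeding_values.loc[c.offspring_ids]
        from pleioscan.linindex import correct_for_fixed_effects

        yc = correct_for_fixed_effects(c.phenotypes, c.trait_names)
        realized = tbv.var().to_numpy() / yc.var().to_numpy()
        assert np.all(np.abs(realized - c.config.heritabilities) < 0.05)

    def test_qtl_variance_matches_2pq_beta2(self, default_cohort):
        c = default_cohort
        idx = c.genotypes.snp_indices(c.truth.qtl_ids)
        G = c.genotypes.dosages[:, idx]
        p = G.mean(axis=0) / 2
        expected = ((2 * p * (1 - p))[:, None] * c.truth.qtl_effects**2).sum(0)
        qtl_part = (G - 2 * p) @ c.truth.qtl_effects
        observed = qtl_part.var(axis=0)
        np.testing.assert_allclose(observed, expected, rtol=0.15, atol=0.01)
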