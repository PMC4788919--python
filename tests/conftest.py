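import numpy as np
import pandas as pd
import pytest

from pleioscan.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small cohort config for fast unit tests: 72 offspring, 300 SNPs on
    2 chromosomes, 5 traits, 2 planted QTL."""
    return SimConfig(
        n_sires=12,
        n_dams_per_sire=2,
        n_offspring_per_dam=3,
        n_breeds=3,
        n_snps=300,
        n_chromosomes=2,
        n_traits=5,
        n_qtl_groups=2,
        qtl_per_group=1,
        qtl_effect_sd=0.5,
        missing_rate=0.05,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    return simulate_cohort(tiny_cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-scale cohort (2,000 offspring, 5,000 SNPs, 12 traits, 9
    grouped QTL, complete phenotypes) shared by the simulation-heavy
    tests."""
    return simulate_cohort(SimConfig(seed=1, missing_rate=0.0))


@pytest.fixture(scope="session")
def default_scan(default_cohort):
    """Per-trait scans + multi-trait results on the default cohort."""
    from pleioscan.lmm import run_gwas
    from pleioscan.meta import MultiTraitScan, assemble_t_matrix

    c = default_cohort
    records, vcs = run_gwas(
        c.phenotypes, c.genotypes, c.pedigree, c.trait_names
    )
    tmat = assemble_t_matrix(records)
    results = MultiTraitScan(tmat).fit()
    return {"records": records, "vcs": vcs, "tmat": tmat, "meta": results}


@pytest.fixture()
def toy_pedigree():
    """Hand-built 4-generation pedigree with breed fractions on founders."""
    rows = [
        # animal, sire, dam, breed_1, breed_2
        ("F1", "0", "0", 1.0, 0.0),
        ("F2", "0", "0", 0.0, 1.0),
        ("F3", "0", "0", 1.0, 0.0),
        ("F4", "0", "0", 0.0, 1.0),
        ("G1", "F1", "F2", np.nan, np.nan),   # (0.5, 0.5)
        ("G2", "F3", "F4", np.nan, np.nan),   # (0.5, 0.5)
        ("H1", "F1", "G2", np.nan, np.nan),   # (0.75, 0.25)
        ("I1", "G1", "H1", np.nan, np.nan),   # (0.625, 0.375)
    ]
    return pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "breed_1", "breed_2"]
    )
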