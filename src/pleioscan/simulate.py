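"""Synthetic multi-breed half-sib cohorts with known ground truth.

The generator emulates the data structure the analysis assumes: a
multi-breed sheep-style cohort of half-sib families (each sire mated to
several dams, each dam with several genotyped offspring), LD-structured
biallelic SNPs on a handful of chromosomes, a block of correlated traits
with moderate heritabilities, grouped pleiotropic QTL whose per-trait
effect vectors follow shared group templates, nuisance fixed effects
(cohort, sex, birth/rear type, age) and per-trait missingness.

Founder linkage disequilibrium comes from a first-order haplotype chain:
each haplotype walks a latent uniform that is carried over to the next SNP
with probability ``ld_decay`` and redrawn otherwise, so adjacent SNPs on a
haplotype are correlated while marginal allele frequencies are preserved.
Offspring genotypes arise by Mendelian gamete sampling with a uniform
Poisson crossover process (mean one crossover per 100 Mb).  Breed
structure is real: founder allele frequencies are shifted per breed and
each breed carries its own trait intercept, so fitting breed fractions
genuinely removes stratification.

All randomness flows from ``SimConfig.seed``; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pleioscan.data import SNP_MAP_COLUMNS, UNKNOWN_PARENT, GenotypeMatrix


@dataclass
class FixedEffectSpec:
    """Levels and effect scales (trait-SD units) of the nuisance fixed
    effects attached to each phenotyped animal."""

    n_cohorts: int = 4
    cohort_sd: float = 0.3
    sex_effect_sd: float = 0.2
    n_birth_rear: int = 3
    birth_rear_sd: float = 0.15
    age_range_days: tuple[int, int] = (134, 705)
    age_slope_sd: float = 0.0005
    breed_intercept_sd: float = 0.3


@dataclass
class SimConfig:
    """Configuration of a simulated cohort.

    Defaults produce ~2,000 genotyped offspring (100 sires x 4 dams x 5
    offspring) across 9 breeds, 5,000 SNPs on five 100-Mb chromosomes, 12
    correlated traits with heritabilities spanning 0.05-0.50, and 3 QTL
    groups of 3 QTL each — small enough that the full pipeline runs on a
    single CPU in minutes while preserving the family, breed and LD
    structure the method exploits.
    """

    n_sires: int = 100
    n_dams_per_sire: int = 4
    n_offspring_per_dam: int = 5
    n_breeds: int = 9
    breed_mixing: float = 0.2
    n_snps: int = 5000
    n_chromosomes: int = 5
    chrom_length_bp: int = 100_000_000
    ld_decay: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    breed_af_sd: float = 0.1
    n_traits: int = 12
    heritabilities: np.ndarray | None = None
    trait_residual_correlation: np.ndarray | float | None = 0.3
    n_qtl_groups: int = 3
    qtl_per_group: int = 3
    group_effect_patterns: np.ndarray | None = None
    qtl_effect_sd: float = 0.2
    qtl_scale_sd: float = 0.2
    qtl_pattern_jitter: float = 0.02
    qtl_maf_min: float = 0.05
    qtl_min_spacing_bp: int = 4_000_000
    missing_rate: float = 0.05
    fixed_effects: FixedEffectSpec = field(default_factory=FixedEffectSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sires", "n_dams_per_sire", "n_offspring_per_dam",
                     "n_breeds", "n_snps", "n_chromosomes", "n_traits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.heritabilities is None:
            self.heritabilities = np.linspace(0.05, 0.50, self.n_traits)
        self.heritabilities = np.asarray(self.heritabilities, dtype=float)
        if len(self.heritabilities) != self.n_traits:
            raise ValueError("need one heritability per trait")
        if ((self.heritabilities <= 0) | (self.heritabilities >= 1)).any():
            raise ValueError("heritabilities must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    # per-stage independent random streams derived from the master seed
    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stage])

    @property
    def n_qtl(self) -> int:
        return self.n_qtl_groups * self.qtl_per_group

    @property
    def trait_names(self) -> list[str]:
        return [f"trait_{i + 1:02d}" for i in range(self.n_traits)]

    def residual_correlation(self) -> np.ndarray:
        """Trait x trait residual correlation matrix (validated PD)."""
        r = self.trait_residual_correlation
        if r is None:
            r = 0.0
        if np.isscalar(r):
            mat = np.full((self.n_traits, self.n_traits), float(r))
            np.fill_diagonal(mat, 1.0)
        else:
            mat = np.asarray(r, dtype=float)
        if mat.shape != (self.n_traits, self.n_traits):
            raise ValueError("trait_residual_correlation has wrong shape")
        if not np.allclose(mat, mat.T):
            raise ValueError("trait_residual_correlation must be symmetric")
        if np.linalg.eigvalsh(mat).min() <= 1e-10:
            raise ValueError("trait_residual_correlation must be positive-definite")
        return mat

    def group_templates(self) -> np.ndarray:
        """Group x trait effect templates (trait-SD units per B-allele copy).

        Defaults to mutually orthogonal random patterns, each zeroed on its
        weakest third of traits and scaled so the root-mean-square of the
        non-zero entries equals ``qtl_effect_sd``.
        """
        if self.group_effect_patterns is not None:
            tpl = np.asarray(self.group_effect_patterns, dtype=float)
            if tpl.shape != (self.n_qtl_groups, self.n_traits):
                raise ValueError("group_effect_patterns has wrong shape")
            return tpl
        rng = self.rng(9)
        raw = rng.standard_normal((self.n_traits, self.n_qtl_groups))
        q, _ = np.linalg.qr(raw)
        tpl = q.T[: self.n_qtl_groups].copy()
        for g in range(self.n_qtl_groups):
            cut = np.quantile(np.abs(tpl[g]), 1.0 / 3.0)
            tpl[g, np.abs(tpl[g]) < cut] = 0.0
            nz = tpl[g] != 0
            tpl[g, nz] *= self.qtl_effect_sd / np.sqrt((tpl[g, nz] ** 2).mean())
        return tpl


@dataclass
class GroundTruth:
    """What was actually planted: QTL identities, group labels, per-trait
    effects, true breeding values and true variance components."""

    qtl_ids: list[str]
    qtl_group: np.ndarray
    qtl_effects: np.ndarray  # (n_qtl, n_traits), trait-SD units
    true_breeding_values: pd.DataFrame | None = None
    variance_components_true: pd.DataFrame | None = None


@dataclass
class SimulatedCohort:
    config: SimConfig
    pedigree: pd.DataFrame
    genotypes: GenotypeMatrix
    truth: GroundTruth
    phenotypes: pd.DataFrame

    @property
    def trait_names(self) -> list[str]:
        return self.config.trait_names

    @property
    def offspring_ids(self) -> list[str]:
        return list(self.phenotypes["animal"])


def simulate_pedigree(cfg: SimConfig) -> pd.DataFrame:
    """Three-generation half-sib pedigree with per-animal breed fractions.

    Founder sires and dams are purebred; with probability ``breed_mixing``
    a dam belongs to a different breed than her mate, producing crossbred
    offspring whose fractions are the parental means.
    """
    rng = cfg.rng(1)
    k = cfg.n_breeds
    breed_cols = [f"breed_{b + 1}" for b in range(k)]
    rows = []
    sire_ids = [f"S{i + 1:04d}" for i in range(cfg.n_sires)]
    sire_breed = rng.integers(0, k, size=cfg.n_sires)
    for sid, b in zip(sire_ids, sire_breed):
        frac = np.zeros(k)
        frac[b] = 1.0
        rows.append([sid, UNKNOWN_PARENT, UNKNOWN_PARENT, *frac])
    dam_counter = 0
    offspring_counter = 0
    for si, sid in enumerate(sire_ids):
        for _ in range(cfg.n_dams_per_sire):
            dam_counter += 1
            did = f"D{dam_counter:05d}"
            if k > 1 and rng.random() < cfg.breed_mixing:
                other = [b for b in range(k) if b != sire_breed[si]]
                db = int(rng.choice(other))
            else:
                db = int(sire_breed[si])
            dfrac = np.zeros(k)
            dfrac[db] = 1.0
            rows.append([did, UNKNOWN_PARENT, UNKNOWN_PARENT, *dfrac])
            sfrac = np.zeros(k)
            sfrac[sire_breed[si]] = 1.0
            for _ in range(cfg.n_offspring_per_dam):
                offspring_counter += 1
                oid = f"O{offspring_counter:06d}"
                rows.append([oid, sid, did, *((sfrac + dfrac) / 2.0)])
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", *breed_cols])


def _snp_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    rows = []
    snp = 0
    for c in range(cfg.n_chromosomes):
        want = int(per_chrom[c])
        draw = np.unique(
            rng.integers(1, cfg.chrom_length_bp + 1, size=want, dtype=np.int64)
        )
        while len(draw) < want:  # collisions are vanishingly rare
            extra = rng.integers(1, cfg.chrom_length_bp + 1,
                                 size=want - len(draw), dtype=np.int64)
            draw = np.unique(np.concatenate([draw, extra]))
        pos = np.sort(draw)
        for p in pos:
            snp += 1
            rows.append([f"snp_{snp:05d}", str(c + 1), int(p), "A", "B"])
    return pd.DataFrame(rows, columns=SNP_MAP_COLUMNS)


def simulate_genotypes(ped: pd.DataFrame, cfg: SimConfig) -> GenotypeMatrix:
    """Founder haplotypes with first-order LD, offspring by Mendelian
    gamete sampling.  Dosages are complete (no missing calls)."""
    rng = cfg.rng(2)
    snps = _snp_map(cfg, rng)
    n_snps = len(snps)
    chrom = snps["chrom"].to_numpy()
    pos = snps["pos_bp"].to_numpy()
    chrom_start = np.r_[True, chrom[1:] != chrom[:-1]]

    base_p = rng.uniform(*cfg.maf_range, size=n_snps)
    flip = rng.random(n_snps) < 0.5  # which allele is the minor one
    base_p = np.where(flip, 1.0 - base_p, base_p)
    breed_shift = rng.normal(0.0, cfg.breed_af_sd, size=(cfg.n_breeds, n_snps))
    breed_p = np.clip(base_p[None, :] + breed_shift, 0.01, 0.99)

    from pleioscan.data import breed_columns

    bcols = breed_columns(ped)
    animals = list(ped["animal"])
    index = {a: i for i, a in enumerate(animals)}
    is_founder = (
        (ped["sire"] == UNKNOWN_PARENT) & (ped["dam"] == UNKNOWN_PARENT)
    ).to_numpy()
    founder_breed = ped.loc[is_founder, bcols].to_numpy().argmax(axis=1)

    n_animals = len(animals)
    haps = np.zeros((n_animals, 2, n_snps), dtype=np.int8)

    # founder haplotypes: latent-uniform chain, reset at chromosome starts
    founder_rows = np.flatnonzero(is_founder)
    n_hap = 2 * len(founder_rows)
    u = np.empty((n_hap, n_snps))
    fresh = rng.random((n_hap, n_snps))
    keep = rng.random((n_hap, n_snps)) < cfg.ld_decay
    u[:, 0] = fresh[:, 0]
    for j in range(1, n_snps):
        if chrom_start[j]:
            u[:, j] = fresh[:, j]
        else:
            u[:, j] = np.where(keep[:, j], u[:, j - 1], fresh[:, j])
    p_rows = breed_p[np.repeat(founder_breed, 2)]
    alleles = (u < p_rows).astype(np.int8)
    haps[founder_rows] = alleles.reshape(len(founder_rows), 2, n_snps)

    # Mendelian gamete sampling with Poisson crossovers (~1 per 100 Mb)
    chrom_ids = pd.unique(chrom)
    chrom_slices = {c: np.flatnonzero(chrom == c) for c in chrom_ids}
    mean_xo = cfg.chrom_length_bp / 1e8

    def gamete(parent_row: int) -> np.ndarray:
        g = np.empty(n_snps, dtype=np.int8)
        for c in chrom_ids:
            idx = chrom_slices[c]
            cpos = pos[idx]
            n_xo = rng.poisson(mean_xo)
            start = rng.integers(0, 2)
            if n_xo == 0:
                which = np.full(len(idx), start)
            else:
                xo = np.sort(rng.integers(1, cfg.chrom_length_bp + 1, size=n_xo))
                which = (start + np.searchsorted(xo, cpos)) % 2
            g[idx] = np.where(
                which == 0, haps[parent_row, 0, idx], haps[parent_row, 1, idx]
            )
        return g

    sires = ped["sire"].to_numpy()
    dams = ped["dam"].to_numpy()
    for i in range(n_animals):
        if is_founder[i]:
            continue
        haps[i, 0] = gamete(index[sires[i]])
        haps[i, 1] = gamete(index[dams[i]])

    dosages = haps.sum(axis=1).astype(float)
    return GenotypeMatrix(animals=animals, snps=snps, dosages=dosages)


def plant_qtl(geno: GenotypeMatrix, cfg: SimConfig) -> GroundTruth:
    """Pick QTL SNPs (MAF-eligible, spaced apart within chromosomes) and
    assign each a group and a per-trait effect vector derived from its
    group template."""
    rng = cfg.rng(3)
    maf = geno.maf()
    eligible = np.flatnonzero(maf >= cfg.qtl_maf_min)
    if len(eligible) < cfg.n_qtl:
        raise ValueError(
            f"only {len(eligible)} SNPs with MAF >= {cfg.qtl_maf_min}; "
            f"cannot host {cfg.n_qtl} QTL"
        )
    chrom = geno.snps["chrom"].to_numpy()
    pos = geno.snps["pos_bp"].to_numpy()
    order = rng.permutation(eligible)
    chosen: list[int] = []
    for j in order:
        ok = all(
            chrom[j] != chrom[k] or abs(int(pos[j]) - int(pos[k])) >= cfg.qtl_min_spacing_bp
            for k in chosen
        )
        if ok:
            chosen.append(int(j))
        if len(chosen) == cfg.n_qtl:
            break
    if len(chosen) < cfg.n_qtl:
        raise ValueError(
            "could not place all QTL with the required spacing; "
            "reduce qtl counts or spacing"
        )
    chosen = sorted(chosen)
    groups = np.repeat(np.arange(cfg.n_qtl_groups), cfg.qtl_per_group)
    groups = groups[rng.permutation(cfg.n_qtl)]
    templates = cfg.group_templates()
    scale = np.exp(rng.normal(0.0, cfg.qtl_scale_sd, size=cfg.n_qtl))
    effects = templates[groups] * scale[:, None]
    effects = effects + rng.normal(
        0.0, cfg.qtl_pattern_jitter, size=effects.shape
    ) * (templates[groups] != 0)
    qtl_ids = [geno.snps["snp_id"].iloc[j] for j in chosen]
    return GroundTruth(qtl_ids=qtl_ids, qtl_group=groups, qtl_effects=effects)


def simulate_phenotypes(
    geno: GenotypeMatrix,
    ped: pd.DataFrame,
    truth: GroundTruth,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Trait values for all non-founder (phenotyped) animals.

    trait = breed intercept + fixed effects + sum(QTL dosage x effect)
            + pedigree-correlated polygenic value + correlated residual.

    Per trait, the polygenic variance is target h^2 minus the variance
    already explained by the planted QTL (floored at zero), and the
    residual variance is 1 - h^2, so the realized narrow-sense
    heritability matches the target.  Breeding values (polygenic + QTL)
    and true variance components are recorded on ``truth``.
    """
    rng = cfg.rng(4)
    R = cfg.residual_correlation()
    L = np.linalg.cholesky(R)
    n_traits = cfg.n_traits
    h2 = cfg.heritabilities

    animals = list(geno.animals)
    index = {a: i for i, a in enumerate(animals)}
    is_founder = (
        (ped["sire"] == UNKNOWN_PARENT) & (ped["dam"] == UNKNOWN_PARENT)
    ).to_numpy()

    qtl_idx = geno.snp_indices(truth.qtl_ids)
    G_qtl = geno.dosages[:, qtl_idx]
    p_qtl = G_qtl.mean(axis=0) / 2.0
    var_qtl = (2 * p_qtl * (1 - p_qtl))[:, None] * truth.qtl_effects**2
    var_qtl_trait = var_qtl.sum(axis=0)
    sigma2_poly = np.maximum(h2 - var_qtl_trait, 0.0)
    sigma2_resid = 1.0 - h2

    # polygenic values down the pedigree, correlated across traits
    sd_poly = np.sqrt(sigma2_poly)
    u = np.zeros((len(animals), n_traits))
    sires = ped["sire"].to_numpy()
    dams = ped["dam"].to_numpy()
    z = rng.standard_normal((len(animals), n_traits)) @ L.T
    for i, a in enumerate(ped["animal"]):
        row = index[a]
        if is_founder[i]:
            u[row] = z[row] * sd_poly
        else:
            mid = 0.5 * (u[index[sires[i]]] + u[index[dams[i]]])
            u[row] = mid + z[row] * (np.sqrt(0.5) * sd_poly)

    qtl_genetic = (G_qtl - 2 * p_qtl) @ truth.qtl_effects
    tbv = u + qtl_genetic

    # fixed effects for phenotyped (non-founder) animals
    fx = cfg.fixed_effects
    pheno_animals = [a for a, f in zip(ped["animal"], is_founder) if not f]
    n = len(pheno_animals)
    rows = [index[a] for a in pheno_animals]

    cohort = rng.integers(0, fx.n_cohorts, size=n)
    sex = rng.integers(0, 2, size=n)
    birth_rear = rng.integers(0, fx.n_birth_rear, size=n)
    age = rng.integers(fx.age_range_days[0], fx.age_range_days[1] + 1, size=n)

    cohort_eff = rng.normal(0, fx.cohort_sd, size=(fx.n_cohorts, n_traits))
    sex_eff = rng.normal(0, fx.sex_effect_sd, size=(2, n_traits))
    br_eff = rng.normal(0, fx.birth_rear_sd, size=(fx.n_birth_rear, n_traits))
    age_slope = rng.normal(0, fx.age_slope_sd, size=n_traits)
    breed_eff = rng.normal(0, fx.breed_intercept_sd, size=(cfg.n_breeds, n_traits))

    from pleioscan.data import breed_columns

    bfrac = ped.set_index("animal").loc[pheno_animals, breed_columns(ped)].to_numpy()
    age_c = age - age.mean()

    fixed = (
        cohort_eff[cohort]
        + sex_eff[sex]
        + br_eff[birth_rear]
        + np.outer(age_c, age_slope)
        + bfrac @ breed_eff
    )
    resid = (rng.standard_normal((n, n_traits)) @ L.T) * np.sqrt(sigma2_resid)
    y = fixed + tbv[rows] + resid

    if cfg.missing_rate > 0:
        mask = rng.random((n, n_traits)) < cfg.missing_rate
        y = np.where(mask, np.nan, y)

    pheno = pd.DataFrame(
        {
            "animal": pheno_animals,
            "cohort": [f"c{c + 1}" for c in cohort],
            "sex": np.where(sex == 0, "F", "M"),
            "birth_rear": [f"br{b + 1}" for b in birth_rear],
            "age": age,
        }
    )
    for t, name in enumerate(cfg.trait_names):
        pheno[name] = y[:, t]

    truth.true_breeding_values = pd.DataFrame(
        tbv, index=animals, columns=cfg.trait_names
    )
    truth.variance_components_true = pd.DataFrame(
        {
            "trait": cfg.trait_names,
            "sigma2_additive": sigma2_poly + var_qtl_trait,
            "sigma2_polygenic": sigma2_poly,
            "sigma2_qtl": var_qtl_trait,
            "sigma2_residual": sigma2_resid,
            "h2_target": h2,
        }
    )
    return pheno


def simulate_cohort(cfg: SimConfig | None = None, **overrides) -> SimulatedCohort:
    """Run the full generator: pedigree, genotypes, QTL, phenotypes."""
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a SimConfig or keyword overrides, not both")
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    if cfg.n_qtl > 0 and cfg.qtl_effect_sd > 0:
        truth = plant_qtl(geno, cfg)
    else:
        truth = GroundTruth(
            qtl_ids=[], qtl_group=np.array([], dtype=int),
            qtl_effects=np.zeros((0, cfg.n_traits)),
        )
    pheno = simulate_phenotypes(geno, ped, truth, cfg)
    return SimulatedCohort(
        config=cfg, pedigree=ped, genotypes=geno, truth=truth, phenotypes=pheno
    )
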