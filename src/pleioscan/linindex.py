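"""Linear trait indices, sire-family validation splits, and index GWAS.

For a SNP with estimated per-trait effects ``b`` (trait units) and a
trait (co)variance matrix ``C`` estimated from the SNP effects of all
scanned SNPs, the linear index

    y_I = b' C^{-1} y

is the linear combination of traits with maximum correlation to the
SNP's genotype — the multiple-regression predictor of genotype from
phenotype.  Treating y_I as a derived trait allows (a) validating a
discovery-sample association in an independent sample with a single
one-df test, and (b) scanning the genome for further SNPs sharing the
same pattern of pleiotropic effects.

Validation splits are made at the sire-family level: all offspring of a
sire land in the same subset, so no animal in the validation set has a
paternal half sib in the discovery set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from pleioscan.data import UNKNOWN_PARENT, GenotypeMatrix
from pleioscan.kinship import AMatrix, build_amatrix
from pleioscan.lmm import (
    PolygenicModel,
    build_design,
    infer_covariates,
    run_gwas,
)
from pleioscan.meta import MultiTraitScan, assemble_t_matrix, fdr
from pleioscan.leads import select_window_top


# ---------------------------------------------------------------------
# trait covariance and missing-phenotype fill
# ---------------------------------------------------------------------

def trait_effect_covariance(
    betas: pd.DataFrame, ridge_rel: float = 1e-6, cond_max: float = 1e12
) -> tuple[pd.DataFrame, float]:
    """Trait x trait covariance of estimated SNP effects across SNPs.

    ``betas`` is SNP x trait (trait units per allele copy).  If the
    covariance is rank-deficient or ill-conditioned, a ridge scaled to
    the mean diagonal is added (returned as the second element).
    """
    arr = betas.dropna(axis=0, how="any").to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 SNPs to estimate the covariance")
    C = np.cov(arr, rowvar=False)
    C = np.atleast_2d(C)
    eig = np.linalg.eigvalsh(C)
    ridge_used = 0.0
    if eig.min() <= 0 or eig.max() / max(eig.min(), 1e-300) > cond_max:
        ridge_used = ridge_rel * float(np.diag(C).mean())
        warnings.warn(
            "SNP-effect covariance is ill-conditioned; "
            f"adding ridge {ridge_used:g}",
            stacklevel=2,
        )
        C = C + ridge_used * np.eye(len(C))
    return (
        pd.DataFrame(C, index=betas.columns, columns=betas.columns),
        ridge_used,
    )


def fill_missing_phenotypes(
    yc: pd.DataFrame,
    cov: pd.DataFrame | np.ndarray | None = None,
    means: pd.Series | None = None,
) -> pd.DataFrame:
    """Fill missing (fixed-effect-corrected) trait values by their
    conditional expectation given the animal's observed traits under a
    joint normal with the given trait covariance.

    ``yc`` is animal x trait.  When ``cov`` is omitted it is estimated
    from the table itself (pairwise complete).  Animals with every trait
    missing are dropped with a warning.  Observed cells are untouched.
    """
    traits = list(yc.columns)
    Y = yc.to_numpy(dtype=float).copy()
    all_missing = np.isnan(Y).all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} animal(s) with no observed "
            "traits",
            stacklevel=2,
        )
        yc = yc.loc[~all_missing]
        Y = Y[~all_missing]
    if means is None:
        mu = np.nanmean(Y, axis=0)
    else:
        mu = pd.Series(means).reindex(traits).to_numpy(dtype=float)
    if cov is None:
        C = pd.DataFrame(Y, columns=traits).cov(min_periods=2).to_numpy()
        if np.isnan(C).any():
            raise ValueError("cannot estimate covariance: too much missingness")
    elif isinstance(cov, pd.DataFrame):
        C = cov.loc[traits, traits].to_numpy(dtype=float)
    else:
        C = np.asarray(cov, dtype=float)

    missing = np.isnan(Y)
    patterns: dict[bytes, np.ndarray] = {}
    for i, row in enumerate(missing):
        patterns.setdefault(row.tobytes(), []).append(i)
    for key, rows in patterns.items():
        pat = np.frombuffer(key, dtype=bool)
        if not pat.any():
            continue
        obs = ~pat
        C_oo = C[np.ix_(obs, obs)]
        C_mo = C[np.ix_(pat, obs)]
        sol = linalg.solve(C_oo, (Y[np.ix_(rows, obs)] - mu[obs]).T,
                           assume_a="sym")
        Y[np.ix_(rows, pat)] = mu[pat] + (C_mo @ sol).T
    return pd.DataFrame(Y, index=yc.index, columns=traits)


def build_linear_index(
    b: pd.Series | np.ndarray,
    C: pd.DataFrame | np.ndarray,
    y: pd.DataFrame,
) -> pd.Series:
    """Per-animal index values y_I = b' C^{-1} y.

    ``b``: per-trait SNP effects (trait units); ``C``: trait covariance;
    ``y``: complete animal x trait table.  The weights are w = C^{-1} b,
    so y_I = y @ w.
    """
    traits = list(y.columns)
    if isinstance(b, pd.Series):
        b = b.reindex(traits).to_numpy(dtype=float)
    else:
        b = np.asarray(b, dtype=float)
    if isinstance(C, pd.DataFrame):
        C = C.loc[traits, traits].to_numpy(dtype=float)
    w = linalg.solve(np.asarray(C, dtype=float), b, assume_a="pos")
    vals = y.to_numpy(dtype=float) @ w
    return pd.Series(vals, index=y.index, name="y_I")


def linear_index_weights(b, C) -> np.ndarray:
    """w = C^{-1} b (per-trait weights of the index)."""
    if isinstance(C, pd.DataFrame):
        C = C.to_numpy(dtype=float)
    if isinstance(b, pd.Series):
        b = b.to_numpy(dtype=float)
    return linalg.solve(np.asarray(C, dtype=float),
                        np.asarray(b, dtype=float), assume_a="pos")


# ---------------------------------------------------------------------
# sire-family split
# ---------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Sire-family allocation of phenotyped animals to n_sets subsets.

    All offspring of one sire share one label, so the validation subset
    shares no paternal half sibs with the discovery subsets.
    """

    labels: pd.Series  # animal -> set label in 1..n_sets
    validation_set: int
    n_sets: int
    seed: int
    sire_sets: dict[str, int] = field(default_factory=dict)

    @property
    def validation_animals(self) -> list[str]:
        return list(self.labels.index[self.labels == self.validation_set])

    @property
    def discovery_animals(self) -> list[str]:
        return list(self.labels.index[self.labels != self.validation_set])


def make_split(ped: pd.DataFrame, n_sets: int = 5, seed: int = 0) -> SplitPlan:
    """Randomise sires into n_sets groups; one group (chosen at random)
    is the validation set, the rest the discovery (reference) set."""
    offspring = ped[ped["sire"] != UNKNOWN_PARENT]
    if offspring.empty:
        raise ValueError("pedigree contains no animals with a known sire")
    sires = sorted(offspring["sire"].unique())
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sires))
    assignment = {}
    for pos, idx in enumerate(order):
        assignment[sires[idx]] = (pos % n_sets) + 1
    labels = offspring["sire"].map(assignment)
    labels.index = offspring["animal"].to_numpy()
    validation_set = int(rng.integers(1, n_sets + 1))
    plan = SplitPlan(
        labels=labels, validation_set=validation_set, n_sets=n_sets,
        seed=seed, sire_sets=assignment,
    )
    # split integrity: a sire must never appear in two sets
    check = offspring.assign(lab=labels.to_numpy()).groupby("sire")["lab"].nunique()
    assert (check == 1).all(), "sire assigned to multiple sets"
    return plan


# ---------------------------------------------------------------------
# fixed-effect correction
# ---------------------------------------------------------------------

def correct_for_fixed_effects(
    pheno: pd.DataFrame,
    traits: list[str],
    categorical: list[str] | None = None,
    numeric: list[str] | None = None,
    fit_animals: list[str] | None = None,
) -> pd.DataFrame:
    """Phenotypes minus estimated fixed effects (OLS per trait).

    When ``fit_animals`` is given, coefficients are estimated on those
    animals only (e.g. the discovery set) and applied to all, avoiding
    leakage of validation information.  Missing values stay missing.
    """
    if categorical is None and numeric is None:
        categorical, numeric = infer_covariates(pheno, traits)
    X, _ = build_design(pheno, categorical, numeric)
    fit_mask = (
        pheno["animal"].isin(fit_animals).to_numpy()
        if fit_animals is not None
        else np.ones(len(pheno), dtype=bool)
    )
    out = {}
    for trait in traits:
        y = pheno[trait].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        use = obs & fit_mask
        if use.sum() <= X.shape[1]:
            raise ValueError(f"too few records to correct trait {trait!r}")
        coef, *_ = np.linalg.lstsq(X[use], y[use], rcond=None)
        resid = np.full_like(y, np.nan)
        resid[obs] = y[obs] - X[obs] @ coef
        out[trait] = resid
    return pd.DataFrame(out, index=pheno["animal"].to_numpy())


# ---------------------------------------------------------------------
# validation machinery
# ---------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Per-SNP discovery/validation index associations and threshold
    summaries (counts, FDR, percent same direction)."""

    per_snp: pd.DataFrame
    summary: pd.DataFrame
    n_tested: int


def _index_association(
    y_index: pd.Series,
    snp_id: str,
    geno: GenotypeMatrix,
    ped: pd.DataFrame,
    amatrix: AMatrix,
    eigen_cache: dict,
) -> tuple[float, float]:
    """beta and P of `y_I ~ mean + SNP + animal(polygenic) + error`."""
    frame = pd.DataFrame({"animal": y_index.index, "_yI": y_index.to_numpy()})
    model = PolygenicModel.from_tables(
        "_yI", frame, ped, amatrix=amatrix, categorical=[], numeric=[],
    )
    key = tuple(model.animal_ids)
    if key not in eigen_cache:
        eigen_cache[key] = linalg.eigh(model.A)
    res = model.fit(eigen=eigen_cache[key])
    rec = res.scan(geno, snp_ids=[snp_id])
    return float(rec["beta"].iloc[0]), float(rec["p"].iloc[0])


def validate_multitrait(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    ped: pd.DataFrame,
    traits: list[str],
    split: SplitPlan,
    amatrix: AMatrix | None = None,
    categorical: list[str] | None = None,
    numeric: list[str] | None = None,
    window_bp: int = 1_000_000,
    p_discovery: float = 1e-5,
    thresholds: tuple = (1e-4, 1e-3, 1e-2, 5e-2),
) -> ValidationReport:
    """Discovery-sample multi-trait scan, window-top hit selection, and
    linear-index validation of each hit in the held-out sample.

    For each discovery hit the index weights come from discovery-only
    quantities (per-trait effects b and SNP-effect covariance C); the
    index built on validation phenotypes is then regressed on the SNP
    with a polygenic animal effect, and the sign of the validation
    effect is compared with the discovery-side effect.
    """
    if amatrix is None:
        amatrix = build_amatrix(ped)
    if categorical is None and numeric is None:
        categorical, numeric = infer_covariates(pheno, traits)

    disc = set(split.discovery_animals)
    pheno_disc = pheno[pheno["animal"].isin(disc)].reset_index(drop=True)
    records, _ = run_gwas(
        pheno_disc, geno, ped, traits, amatrix=amatrix,
        categorical=categorical, numeric=numeric,
    )
    meta = MultiTraitScan(assemble_t_matrix(records)).fit().records
    hits = select_window_top(meta, window_bp=window_bp, p_max=p_discovery)
    if hits.empty:
        return ValidationReport(
            per_snp=pd.DataFrame(
                columns=["snp_id", "discovery_p", "beta_disc", "beta_val",
                         "p_val", "same_direction"]
            ),
            summary=pd.DataFrame(
                columns=["p_threshold", "n_validated", "fdr_pct",
                         "pct_same_direction"]
            ),
            n_tested=0,
        )

    betas = assemble_t_matrix(records, value="beta")
    C, _ = trait_effect_covariance(betas)

    # fixed-effect-corrected, filled phenotypes (coefficients and fill
    # covariance estimated on the discovery side only)
    yc = correct_for_fixed_effects(
        pheno, traits, categorical, numeric,
        fit_animals=split.discovery_animals,
    )
    yc_disc = yc.loc[yc.index.isin(disc)]
    fill_cov = yc_disc.cov(min_periods=2)
    fill_mu = yc_disc.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y_disc = fill_missing_phenotypes(yc_disc, cov=fill_cov, means=fill_mu)
        y_val = fill_missing_phenotypes(
            yc.loc[~yc.index.isin(disc)], cov=fill_cov, means=fill_mu
        )

    eigen_cache: dict = {}
    rows = []
    for hit in hits.itertuples(index=False):
        b = betas.loc[hit.snp_id]
        w = linear_index_weights(b, C)
        yi_disc = pd.Series(y_disc.to_numpy() @ w, index=y_disc.index)
        yi_val = pd.Series(y_val.to_numpy() @ w, index=y_val.index)
        beta_d, _ = _index_association(
            yi_disc, hit.snp_id, geno, ped, amatrix, eigen_cache
        )
        beta_v, p_v = _index_association(
            yi_val, hit.snp_id, geno, ped, amatrix, eigen_cache
        )
        rows.append(
            {
                "snp_id": hit.snp_id,
                "discovery_p": hit.p,
                "beta_disc": beta_d,
                "beta_val": beta_v,
                "p_val": p_v,
                "same_direction": bool(np.sign(beta_v) == np.sign(beta_d)),
            }
        )
    per_snp = pd.DataFrame(rows)
    n_tested = len(per_snp)
    summary_rows = []
    for thr in thresholds:
        ok = per_snp[per_snp["p_val"] < thr]
        a = len(ok)
        summary_rows.append(
            {
                "p_threshold": thr,
                "n_validated": a,
                "fdr_pct": 100 * fdr(thr, a, n_tested) if a else np.inf,
                "pct_same_direction": (
                    100.0 * ok["same_direction"].mean() if a else np.nan
                ),
            }
        )
    return ValidationReport(
        per_snp=per_snp, summary=pd.DataFrame(summary_rows), n_tested=n_tested
    )


# ---------------------------------------------------------------------
# index GWAS: recruiting further QTL to the lead-SNP groups
# ---------------------------------------------------------------------

@dataclass
class IndexGwasResults:
    index_records: dict[str, pd.DataFrame]  # lead snp_id -> scan records
    recruits: pd.DataFrame  # snp_id, group, best_lead, index_p


def index_gwas(
    lead_ids: list[str],
    lead_groups: pd.Series,
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    ped: pd.DataFrame,
    traits: list[str],
    records: dict[str, pd.DataFrame] | None = None,
    amatrix: AMatrix | None = None,
    categorical: list[str] | None = None,
    numeric: list[str] | None = None,
    p_recruit: float = 5e-7,
) -> IndexGwasResults:
    """GWAS of each lead's linear index, with every lead fitted
    simultaneously as covariates; SNPs significant for at least one index
    join the group of the lead with which they associate most strongly.

    ``lead_groups`` maps lead snp_id -> cluster group label.
    """
    if amatrix is None:
        amatrix = build_amatrix(ped)
    if categorical is None and numeric is None:
        categorical, numeric = infer_covariates(pheno, traits)
    if records is None:
        records, _ = run_gwas(
            pheno, geno, ped, traits, amatrix=amatrix,
            categorical=categorical, numeric=numeric,
        )
    betas = assemble_t_matrix(records, value="beta")
    C, _ = trait_effect_covariance(betas)
    yc = correct_for_fixed_effects(pheno, traits, categorical, numeric)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y_full = fill_missing_phenotypes(yc)

    index_pheno = pd.DataFrame({"animal": y_full.index})
    index_traits = []
    for lead in lead_ids:
        b = betas.loc[lead]
        w = linear_index_weights(b, C)
        name = f"index_{lead}"
        index_pheno[name] = y_full.to_numpy() @ w
        index_traits.append(name)

    index_records, _ = run_gwas(
        index_pheno, geno, ped, index_traits, amatrix=amatrix,
        covariate_snps=lead_ids, categorical=[], numeric=[],
    )
    by_lead = {
        lead: index_records[f"index_{lead}"] for lead in lead_ids
    }

    # recruits: best (smallest) index P per SNP, thresholded
    stacked = []
    for lead, rec in by_lead.items():
        sub = rec[rec["estimable"]][["snp_id", "chrom", "pos_bp", "p"]].copy()
        sub["lead"] = lead
        stacked.append(sub)
    allrec = pd.concat(stacked, ignore_index=True)
    allrec = allrec[~allrec["snp_id"].isin(lead_ids)]
    best = (
        allrec.sort_values("p")
        .groupby("snp_id", sort=False)
        .head(1)
    )
    recruits = best[best["p"] < p_recruit].copy()
    recruits["group"] = recruits["lead"].map(lead_groups)
    recruits = (
        recruits.rename(columns={"p": "index_p", "lead": "best_lead"})
        .sort_values(["chrom", "pos_bp"])
        .reset_index(drop=True)
    )
    return IndexGwasResults(index_records=by_lead, recruits=recruits)
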