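"""Lead-SNP selection and conditional (joint-fit) re-analysis.

Lead SNPs tag putatively independent pleiotropic QTL: on each chromosome
the most significant multi-trait SNPs are taken greedily in ascending
P-value order, subject to a minimum pairwise spacing and a per-chromosome
cap.  Conditioning then refits every single-trait scan with all leads as
simultaneous covariates and recomputes the multi-trait statistic, so any
remaining signal near a lead indicates imperfect tagging or extra QTL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pleioscan.data import GenotypeMatrix
from pleioscan.kinship import AMatrix, build_amatrix
from pleioscan.lmm import PolygenicModel, run_gwas
from pleioscan.meta import MultiTraitScan, assemble_t_matrix


@dataclass
class LeadSnpSet:
    """Selected lead SNPs with the selection parameters used."""

    table: pd.DataFrame  # snp_id, chrom, pos_bp, p (genome order)
    p_max: float
    min_spacing_bp: int
    max_per_chrom: int

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    def __len__(self) -> int:
        return len(self.table)


def select_window_top(
    meta: pd.DataFrame, window_bp: int = 1_000_000, p_max: float = 1e-5
) -> pd.DataFrame:
    """Most significant SNP per fixed 1-Mb window, thresholded at p_max.

    The genome is partitioned into half-open windows [k*W, (k+1)*W) per
    chromosome; within each window the minimum-P SNP is retained if its P
    is at most p_max.  Ties break by genome position.
    """
    rec = meta.dropna(subset=["p"]).copy()
    rec["window"] = rec["pos_bp"].astype(np.int64) // int(window_bp)
    rec = rec.sort_values(["chrom", "window", "p", "pos_bp"])
    top = rec.groupby(["chrom", "window"], sort=False).head(1)
    top = top[top["p"] <= p_max]
    return (
        top.drop(columns="window")
        .sort_values(["chrom", "pos_bp"])
        .reset_index(drop=True)
    )


def select_lead_snps(
    meta: pd.DataFrame,
    p_max: float = 1e-5,
    min_spacing_bp: int = 4_000_000,
    max_per_chrom: int = 3,
) -> LeadSnpSet:
    """Greedy per-chromosome lead selection by ascending P.

    A candidate is accepted when it is at least ``min_spacing_bp`` from
    every already-accepted lead on its chromosome, up to
    ``max_per_chrom`` leads; ties in P break by genome order.
    """
    rec = meta.dropna(subset=["p"])
    rec = rec[rec["p"] <= p_max]
    if rec.empty:
        warnings.warn(f"no SNP passes p <= {p_max:g}; empty lead set",
                      stacklevel=2)
        return LeadSnpSet(
            table=meta.iloc[0:0][["snp_id", "chrom", "pos_bp", "p"]],
            p_max=p_max, min_spacing_bp=min_spacing_bp,
            max_per_chrom=max_per_chrom,
        )
    chosen = []
    for chrom, grp in rec.groupby("chrom", sort=False):
        grp = grp.sort_values(["p", "pos_bp"])
        accepted: list[int] = []
        for row in grp.itertuples(index=False):
            if len(accepted) >= max_per_chrom:
                break
            if all(abs(int(row.pos_bp) - a) >= min_spacing_bp for a in accepted):
                accepted.append(int(row.pos_bp))
                chosen.append(row)
    table = (
        pd.DataFrame(chosen)[["snp_id", "chrom", "pos_bp", "p"]]
        .sort_values(["chrom", "pos_bp"])
        .reset_index(drop=True)
    )
    return LeadSnpSet(table=table, p_max=p_max,
                      min_spacing_bp=min_spacing_bp,
                      max_per_chrom=max_per_chrom)


@dataclass
class ConditionalResults:
    """Per-trait conditional scans, conditional multi-trait records, and
    the joint-fit effects of the leads themselves."""

    records: dict[str, pd.DataFrame]
    meta: pd.DataFrame
    lead_effects: pd.DataFrame  # lead x trait signed t from the joint fit


def conditional_pipeline(
    leads: LeadSnpSet | list[str],
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    ped: pd.DataFrame,
    traits: list[str],
    amatrix: AMatrix | None = None,
    categorical: list[str] | None = None,
    numeric: list[str] | None = None,
    ridge: float = 1e-6,
) -> ConditionalResults:
    """Rerun all single-trait scans fitting every lead simultaneously,
    then the multi-trait statistic; each lead's own effect comes from a
    joint fit with the other leads as covariates."""
    lead_ids = leads.snp_ids if isinstance(leads, LeadSnpSet) else list(leads)
    if amatrix is None:
        amatrix = build_amatrix(ped)
    records, _ = run_gwas(
        pheno, geno, ped, traits, amatrix=amatrix,
        covariate_snps=lead_ids or None,
        categorical=categorical, numeric=numeric,
    )
    tmat = assemble_t_matrix(records)
    meta = MultiTraitScan(tmat).fit(ridge=ridge).records

    lead_effects = (
        joint_lead_fit(lead_ids, pheno, geno, ped, traits, amatrix=amatrix,
                       categorical=categorical, numeric=numeric)
        if lead_ids
        else pd.DataFrame(
            columns=["snp_id", "chrom", "pos_bp", "trait", "beta", "se",
                     "t", "p", "n_used"]
        )
    )
    return ConditionalResults(records=records, meta=meta,
                              lead_effects=lead_effects)


def joint_lead_fit(
    lead_ids: list[str],
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    ped: pd.DataFrame,
    traits: list[str],
    amatrix: AMatrix | None = None,
    categorical: list[str] | None = None,
    numeric: list[str] | None = None,
) -> pd.DataFrame:
    """Per-trait GLS fit of all leads simultaneously.

    Each lead's effect, SE and signed t are its coefficient in the joint
    regression containing the fixed effects and every other lead, under
    the null-model covariance — i.e. the effect conditional on the other
    leads.
    """
    from scipy import linalg as sla
    from scipy import stats as sstats

    if amatrix is None:
        amatrix = build_amatrix(ped)
    lead_cols = geno.snp_indices(lead_ids)
    snp_info = geno.snps.iloc[lead_cols]
    rows_out = []
    eigen_cache: dict[tuple, tuple] = {}
    for trait in traits:
        model = PolygenicModel.from_tables(
            trait, pheno, ped, amatrix=amatrix,
            categorical=categorical, numeric=numeric,
        )
        key = tuple(model.animal_ids)
        if key not in eigen_cache:
            eigen_cache[key] = sla.eigh(model.A)
        res = model.fit(eigen=eigen_cache[key])
        rows = geno.animal_indices(model.animal_ids)
        L = geno.dosages[np.ix_(rows, lead_cols)]
        if np.isnan(L).any():
            means = np.nanmean(L, axis=0)
            L = np.where(np.isnan(L), means, L)
        Lw = (res._U.T @ L) * res._sw[:, None]
        Lr = Lw - res._Q @ (res._Q.T @ Lw)
        gram = Lr.T @ Lr
        cov = sla.pinvh(gram)
        beta = cov @ (Lr.T @ res._yr)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        dof = res.vc.n - model.X.shape[1] - len(lead_ids)
        p = 2.0 * sstats.t.sf(np.abs(t), df=max(dof, 1))
        rows_out.append(
            pd.DataFrame(
                {
                    "snp_id": snp_info["snp_id"].to_numpy(),
                    "chrom": snp_info["chrom"].to_numpy(),
                    "pos_bp": snp_info["pos_bp"].to_numpy(),
                    "trait": trait,
                    "beta": beta,
                    "se": se,
                    "t": t,
                    "p": p,
                    "n_used": res.vc.n,
                }
            )
        )
    return pd.concat(rows_out, ignore_index=True)
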