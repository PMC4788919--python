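"""Genotype and sample quality control.

The default thresholds follow common practice for medium-density SNP array
data in livestock: SNPs are dropped when their call rate is below 95 %,
their minor allele frequency below 0.01, or their Hardy-Weinberg
goodness-of-fit P-value below 1e-5; animals are dropped when their average
call rate is below 90 %.  SNP filters are applied before sample filters,
and sample call rates are computed on the post-SNP-filter matrix, so the
combined result is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from pleioscan.data import GenotypeMatrix, QcReport, breed_columns, check_pedigree
from pleioscan.data import UNKNOWN_PARENT


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-df chi-squared goodness-of-fit P-value for Hardy-Weinberg
    equilibrium, with expected genotype counts derived from the sample
    allele frequency.  Monomorphic samples return P = 1.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p_a = (2 * counts[0] + counts[1]) / (2 * n)
    if p_a in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p_a**2, 2 * p_a * (1 - p_a), (1 - p_a) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    """Vectorised HWE P-value per SNP (hard calls only; fractional dosages
    are rounded to the nearest genotype for counting)."""
    d = np.round(geno.dosages)
    counts = np.stack(
        [np.nansum(d == g, axis=0) for g in (0.0, 1.0, 2.0)], axis=1
    ).astype(float)
    n = counts.sum(axis=1)
    pvals = np.ones(geno.n_snps)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = (2 * counts[:, 0] + counts[:, 1]) / (2 * n)
        poly = (n > 0) & (p_a > 0) & (p_a < 1)
        exp = np.stack(
            [p_a**2, 2 * p_a * (1 - p_a), (1 - p_a) ** 2], axis=1
        ) * n[:, None]
        chi2 = np.where(poly, ((counts - exp) ** 2 / np.where(exp > 0, exp, 1)).sum(axis=1), 0.0)
    pvals[poly] = stats.chi2.sf(chi2[poly], df=1)
    return pvals


def snp_qc_filter(
    geno: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop SNPs failing call-rate, MAF or HWE thresholds.

    A SNP failing several filters is counted once, under the first failing
    filter in the order call rate, MAF, HWE.
    """
    call = geno.snp_call_rate()
    maf = geno.maf()
    hwe = hwe_pvalues(geno)
    fail_call = call < call_rate_min
    fail_maf = ~fail_call & (np.isnan(maf) | (maf < maf_min))
    fail_hwe = ~fail_call & ~fail_maf & (hwe < hwe_p_min)
    keep = ~(fail_call | fail_maf | fail_hwe)
    report = QcReport(
        axis="snp",
        n_in=geno.n_snps,
        n_out=int(keep.sum()),
        removed_by={
            "call_rate": int(fail_call.sum()),
            "maf": int(fail_maf.sum()),
            "hwe": int(fail_hwe.sum()),
        },
        thresholds={
            "call_rate": call_rate_min,
            "maf": maf_min,
            "hwe": hwe_p_min,
        },
        empty_result=not keep.any(),
        n_missing_calls=int(np.isnan(geno.dosages).sum()),
    )
    return geno.subset_snps(keep), report


def sample_qc_filter(
    geno: GenotypeMatrix, call_rate_min: float = 0.90
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop animals whose average call rate is below the threshold."""
    call = geno.animal_call_rate()
    keep = call >= call_rate_min
    report = QcReport(
        axis="animal",
        n_in=geno.n_animals,
        n_out=int(keep.sum()),
        removed_by={"call_rate": int((~keep).sum())},
        thresholds={"call_rate": call_rate_min},
        empty_result=not keep.any(),
    )
    kept = [a for a, k in zip(geno.animals, keep) if k]
    return geno.subset_animals(kept), report


def mean_fill_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-SNP mean dosage.

    The result may hold fractional dosages; downstream regression treats
    the dosage as a continuous covariate.  An all-missing SNP cannot be
    filled and raises, pointing at :func:`snp_qc_filter`.
    """
    d = geno.dosages.copy()
    missing = np.isnan(d)
    if not missing.any():
        return GenotypeMatrix(list(geno.animals), geno.snps.copy(), d)
    all_missing = missing.all(axis=0)
    if all_missing.any():
        snp = geno.snps.loc[np.flatnonzero(all_missing)[0], "snp_id"]
        raise ValueError(
            f"SNP {snp!r} has no called genotypes; remove it with "
            "snp_qc_filter before mean imputation"
        )
    means = np.nanmean(d, axis=0)
    d[missing] = np.broadcast_to(means, d.shape)[missing]
    return GenotypeMatrix(list(geno.animals), geno.snps.copy(), d)


def breed_proportions(ped: pd.DataFrame) -> pd.DataFrame:
    """Breed fractions for every animal, from founder assignments.

    Founders must carry breed fractions in ``breed_*`` columns; every
    non-founder receives the mean of its parents' fractions, computed in
    generation order.  Animals with one unknown parent treat that parent
    as carrying the average founder composition of the known parent
    (i.e. the known parent's fractions are reused), which keeps fractions
    summing to one.
    """
    check_pedigree(ped)
    cols = breed_columns(ped)
    if not cols:
        raise ValueError("pedigree has no breed_* fraction columns")
    frac = ped.set_index("animal")[cols].astype(float)
    sire = ped.set_index("animal")["sire"]
    dam = ped.set_index("animal")["dam"]
    known = frac.notna().all(axis=1)
    todo = set(frac.index[~known])
    resolved = set(frac.index[known])
    while todo:
        progressed = False
        for animal in sorted(todo):
            s, d = sire[animal], dam[animal]
            s_ok = s == UNKNOWN_PARENT or s in resolved
            d_ok = d == UNKNOWN_PARENT or d in resolved
            if not (s_ok and d_ok):
                continue
            if s == UNKNOWN_PARENT and d == UNKNOWN_PARENT:
                raise ValueError(
                    f"founder {animal!r} has no breed fractions assigned"
                )
            if s == UNKNOWN_PARENT:
                frac.loc[animal] = frac.loc[d]
            elif d == UNKNOWN_PARENT:
                frac.loc[animal] = frac.loc[s]
            else:
                frac.loc[animal] = (frac.loc[s] + frac.loc[d]) / 2.0
            resolved.add(animal)
            todo.discard(animal)
            progressed = True
        if not progressed:
            raise ValueError(
                f"cannot resolve breed fractions for {sorted(todo)[:5]}: "
                "parent missing from pedigree or cyclic"
            )
    total = frac.sum(axis=1)
    if not np.allclose(total, 1.0, atol=1e-9):
        bad = total.index[~np.isclose(total, 1.0, atol=1e-9)][0]
        raise ValueError(f"breed fractions for {bad!r} do not sum to 1")
    return frac.reset_index()
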