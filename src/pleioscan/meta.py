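"""Multi-trait chi-squared meta-analysis over signed t-values, and the
closed-form FDR estimator.

Per SNP i the statistic is the quadratic form

    chi2_i = t_i' V^{-1} t_i,    df = number of traits,

where ``t_i`` stacks the signed t-values of SNP i across the single-trait
scans and ``V`` is the trait x trait correlation matrix of those t-values
estimated over all scanned SNPs.  Under the null (no association with any
trait) the t-values are approximately jointly normal with correlation V,
so chi2_i follows a chi-squared distribution with one degree of freedom
per trait.

The false discovery rate at a P-value threshold P, with A of T tested
SNPs declared significant, is estimated as

    FDR = P * (1 - A/T) / ((A/T) * (1 - P)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats


def assemble_t_matrix(
    records: dict[str, pd.DataFrame], value: str = "t"
) -> pd.DataFrame:
    """Stack per-trait scan records into a SNP x trait matrix of signed
    t-values (or betas via ``value="beta"``).

    SNPs flagged inestimable in any trait are dropped listwise so the
    degrees of freedom stay constant across SNPs; the count of dropped
    SNPs is stored in ``result.attrs["n_dropped"]`` and the SNP map in
    ``result.attrs["snp_map"]``.
    """
    if not records:
        raise ValueError("no per-trait records given")
    cols = {}
    snp_map = None
    for trait, rec in records.items():
        ser = rec.set_index("snp_id")[value]
        cols[trait] = ser
        if snp_map is None:
            snp_map = rec[["snp_id", "chrom", "pos_bp"]].set_index("snp_id")
    tmat = pd.DataFrame(cols)
    n_before = len(tmat)
    tmat = tmat.dropna(axis=0, how="any")
    tmat.attrs["n_dropped"] = n_before - len(tmat)
    tmat.attrs["snp_map"] = snp_map.loc[tmat.index].reset_index()
    return tmat


@dataclass
class VMatrix:
    """Trait x trait correlation of signed t-values, with the ridge
    actually applied before inversion."""

    traits: list[str]
    corr: np.ndarray
    ridge_used: float
    condition: float

    def inverse(self) -> np.ndarray:
        m = self.corr + self.ridge_used * np.eye(len(self.traits))
        return linalg.inv(m)


def estimate_v(
    tmat: pd.DataFrame, ridge: float = 1e-6, cond_max: float = 1e12
) -> VMatrix:
    """Pairwise Pearson correlation of the t-value columns over all SNPs.

    Signal SNPs are included (their contribution is diluted across the
    genome).  If the correlation matrix is ill-conditioned the ridge is
    recorded and later added to the diagonal before inversion.
    """
    traits = list(tmat.columns)
    if len(traits) < 2:
        corr = np.ones((len(traits), len(traits)))
        return VMatrix(traits=traits, corr=corr, ridge_used=0.0, condition=1.0)
    if len(tmat) < 10 * len(traits):
        warnings.warn(
            f"only {len(tmat)} SNPs for {len(traits)} traits; the t-value "
            "correlation matrix will be noisy",
            stacklevel=2,
        )
    corr = np.corrcoef(tmat.to_numpy(dtype=float), rowvar=False)
    eig = np.linalg.eigvalsh(corr)
    cond = float(eig.max() / max(eig.min(), 1e-300)) if eig.min() > 0 else math.inf
    ridge_used = 0.0
    if cond > cond_max:
        ridge_used = ridge
        warnings.warn(
            "t-value correlation matrix is ill-conditioned "
            f"(condition number {cond:.2e}); adding ridge {ridge:g}",
            stacklevel=2,
        )
    return VMatrix(traits=traits, corr=corr, ridge_used=ridge_used,
                   condition=cond)


def multi_trait_chisq(tmat: pd.DataFrame, v: VMatrix) -> pd.DataFrame:
    """Per-SNP quadratic form t' V^{-1} t with df = number of traits."""
    if list(tmat.columns) != list(v.traits):
        raise ValueError("trait ordering of t-matrix and V disagree")
    T = tmat.to_numpy(dtype=float)
    m = v.corr + v.ridge_used * np.eye(len(v.traits))
    try:
        c, low = linalg.cho_factor(m)
    except linalg.LinAlgError:
        raise linalg.LinAlgError(
            "V is singular; re-estimate with a ridge (estimate_v ridge>0)"
        ) from None
    sol = linalg.cho_solve((c, low), T.T)
    chi2 = np.einsum("ij,ji->i", T, sol)
    df = len(v.traits)
    out = pd.DataFrame(
        {
            "snp_id": tmat.index.to_numpy(),
            "chi2": chi2,
            "df": df,
            "p": stats.chi2.sf(chi2, df=df),
        }
    )
    snp_map = tmat.attrs.get("snp_map")
    if snp_map is not None:
        out = out.merge(snp_map, on="snp_id", how="left")
        out = out[["snp_id", "chrom", "pos_bp", "chi2", "df", "p"]]
    return out


def fdr(p_threshold: float, n_significant: int, n_tested: int) -> float:
    """Closed-form FDR estimate at a P-value threshold.

    Returns a fraction; multiply by 100 for percent.  With no significant
    SNPs the estimator is undefined and +inf is returned with a warning.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_significant <= n_tested:
        raise ValueError("n_significant must lie in [0, n_tested]")
    if n_significant == 0:
        warnings.warn("no significant SNPs: FDR undefined, returning inf",
                      stacklevel=2)
        return math.inf
    ratio = n_significant / n_tested
    return p_threshold * (1.0 - ratio) / (ratio * (1.0 - p_threshold))


def fdr_percent(p_threshold: float, n_significant: int, n_tested: int,
                ndigits: int = 2) -> float:
    """FDR as a percentage, rounded for reporting."""
    return round(100.0 * fdr(p_threshold, n_significant, n_tested), ndigits)


def fdr_table(
    p_values: np.ndarray, thresholds, n_tested: int | None = None
) -> pd.DataFrame:
    """Counts and FDR estimates at a ladder of P-value thresholds."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if n_tested is None:
        n_tested = len(p)
    rows = []
    for thr in thresholds:
        a = int((p < thr).sum())
        rows.append(
            {
                "p_threshold": thr,
                "n_significant": a,
                "n_tested": n_tested,
                "fdr": fdr(thr, a, n_tested) if a > 0 else math.inf,
            }
        )
    return pd.DataFrame(rows)


def qq_points(p_values) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 P for a quantile-quantile plot."""
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[~np.isnan(p)]
    n = len(p)
    if n == 0:
        raise ValueError("no P-values given")
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(p, 1e-300, 1.0))
    return expected[::-1], observed[::-1]


class MultiTraitScan:
    """Multi-trait meta-analysis model over a SNP x trait t-matrix."""

    def __init__(self, tmat: pd.DataFrame) -> None:
        self.tmat = tmat

    @classmethod
    def from_records(cls, records: dict[str, pd.DataFrame]) -> "MultiTraitScan":
        return cls(assemble_t_matrix(records))

    def fit(self, ridge: float = 1e-6, cond_max: float = 1e12
            ) -> "MultiTraitResults":
        v = estimate_v(self.tmat, ridge=ridge, cond_max=cond_max)
        rec = multi_trait_chisq(self.tmat, v)
        return MultiTraitResults(self, v, rec)


class MultiTraitResults:
    """Fitted multi-trait scan: per-SNP chi2/P records, the V matrix, and
    FDR/Q-Q reporting helpers."""

    def __init__(self, model: MultiTraitScan, v: VMatrix,
                 records: pd.DataFrame) -> None:
        self.model = model
        self.v = v
        self.records = records

    def fdr(self, p_threshold: float) -> float:
        a = int((self.records["p"] < p_threshold).sum())
        return fdr(p_threshold, a, len(self.records))

    def fdr_table(self, thresholds=(1e-5, 5e-7)) -> pd.DataFrame:
        return fdr_table(self.records["p"].to_numpy(), thresholds)

    def qq_points(self) -> tuple[np.ndarray, np.ndarray]:
        return qq_points(self.records["p"].to_numpy())

    def plot_qq(self, ax=None):
        """Quantile-quantile plot of the multi-trait P-values."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        exp, obs = self.qq_points()
        ax.plot(exp, obs, ".", ms=3)
        lim = max(exp.max(), obs.max())
        ax.plot([0, lim], [0, lim], lw=1, color="0.6")
        ax.set_xlabel("expected $-\\log_{10} P$")
        ax.set_ylabel("observed $-\\log_{10} P$")
        return ax

    def plot_manhattan(self, ax=None, sig_line: float = 5e-7):
        """Manhattan plot (requires chrom/pos columns in the records)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        rec = self.records.dropna(subset=["p"])
        if "chrom" not in rec.columns:
            raise ValueError("records carry no genome coordinates")
        offset = 0
        ticks, labels = [], []
        for i, (chrom, grp) in enumerate(rec.groupby("chrom", sort=False)):
            x = grp["pos_bp"].to_numpy() + offset
            ax.scatter(x, -np.log10(np.clip(grp["p"], 1e-300, 1)),
                       s=4, color=f"C{i % 2}")
            ticks.append(offset + grp["pos_bp"].max() / 2)
            labels.append(str(chrom))
            offset += grp["pos_bp"].max()
        ax.axhline(-math.log10(sig_line), lw=1, color="0.4", ls="--")
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("$-\\log_{10} P$")
        return ax

    def summary(self) -> str:
        n = len(self.records)
        lines = [
            f"Multi-trait scan: {n} SNPs x {len(self.v.traits)} traits",
            f"  V condition number {self.v.condition:.3g}"
            + (f" (ridge {self.v.ridge_used:g})" if self.v.ridge_used else ""),
        ]
        for thr in (1e-5, 5e-7):
            a = int((self.records["p"] < thr).sum())
            f = fdr(thr, a, n) if a else math.inf
            lines.append(
                f"  P < {thr:g}: {a} significant SNPs, FDR {100 * f:.2f}%"
            )
        return "\n".join(lines)
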