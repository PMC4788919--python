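"""Core in-memory containers: genotype matrix with SNP map, QC report.

Conventions used throughout the package:

* Pedigrees are :class:`pandas.DataFrame` objects with columns ``animal``,
  ``sire``, ``dam`` (the string ``"0"`` marks an unknown parent) plus
  optional breed-fraction columns named ``breed_*`` that sum to 1 per
  animal.
* Phenotype tables are DataFrames with an ``animal`` column, one column per
  trait (``NaN`` = missing record) and any number of fixed-effect covariate
  columns (categorical or numeric).
* Genotype dosages count copies of the B allele (0/1/2); ``NaN`` marks a
  missing call.  Positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele_a", "allele_b"]


@dataclass
class GenotypeMatrix:
    """Animal x SNP dosage store with its SNP map.

    Parameters
    ----------
    animals : list of str
        Animal identifiers, one per dosage row.
    snps : pandas.DataFrame
        SNP map with columns ``snp_id, chrom, pos_bp, allele_a, allele_b``;
        ``snp_id`` must be unique and positions strictly increasing within
        a chromosome.
    dosages : ndarray of shape (n_animals, n_snps)
        Counts of the B allele in {0, 1, 2}; NaN marks a missing call.
        Fractional dosages are permitted after mean imputation.
    """

    animals: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.animals), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.animals)} animals x {len(self.snps)} SNPs"
            )
        if self.snps["snp_id"].duplicated().any():
            dups = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"]
            raise ValueError(f"duplicate snp_id: {dups.iloc[0]!r}")
        with np.errstate(invalid="ignore"):
            bad = np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(
                self.dosages, initial=0
            ) > 2
        if bad:
            raise ValueError("dosages must lie in [0, 2]")
        self.snps = self.snps.reset_index(drop=True)
        self.snps["chrom"] = self.snps["chrom"].astype(str)
        self.snps["pos_bp"] = self.snps["pos_bp"].astype(np.int64)

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_indices(self, snp_ids) -> np.ndarray:
        """Column indices of the given SNP ids (raises on unknown id)."""
        lookup = pd.Index(self.snps["snp_id"])
        idx = lookup.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = np.asarray(list(snp_ids))[idx < 0]
            raise KeyError(f"unknown snp_id(s): {missing[:5].tolist()}")
        return idx

    def animal_indices(self, ids) -> np.ndarray:
        lookup = pd.Index(self.animals)
        idx = lookup.get_indexer(list(ids))
        if (idx < 0).any():
            missing = np.asarray(list(ids))[idx < 0]
            raise KeyError(f"unknown animal id(s): {missing[:5].tolist()}")
        return idx

    def subset_animals(self, ids) -> "GenotypeMatrix":
        idx = self.animal_indices(ids)
        return GenotypeMatrix(
            animals=list(ids), snps=self.snps.copy(), dosages=self.dosages[idx]
        )

    def subset_snps(self, mask_or_ids) -> "GenotypeMatrix":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = self.snp_indices(arr)
        return GenotypeMatrix(
            animals=list(self.animals),
            snps=self.snps.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    # --- per-SNP / per-animal summaries -------------------------------
    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def animal_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def allele_freq_b(self) -> np.ndarray:
        """Frequency of the B allele per SNP (missing calls ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq_b()
        return np.minimum(p, 1.0 - p)

    def genotype_counts(self) -> np.ndarray:
        """(n_snps, 3) counts of AA / AB / BB genotypes (hard calls only)."""
        counts = np.empty((self.n_snps, 3), dtype=int)
        for g in (0, 1, 2):
            counts[:, g] = np.nansum(self.dosages == g, axis=0)
        return counts


@dataclass
class QcReport:
    """Summary of a quality-control pass over one axis of the matrix.

    ``n_in - sum(removed_by.values()) == n_out`` always holds; a unit that
    fails several filters is attributed to the first failing filter in the
    order the filters are applied.
    """

    axis: str
    n_in: int
    n_out: int
    removed_by: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    empty_result: bool = False
    n_missing_calls: int = 0

    def __post_init__(self) -> None:
        if self.n_in - sum(self.removed_by.values()) != self.n_out:
            raise ValueError("inconsistent QC report: in - removed != out")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"filter": name, "removed": n, "threshold": self.thresholds.get(name)}
            for name, n in self.removed_by.items()
        ]
        rows.append({"filter": "total", "removed": self.n_in - self.n_out,
                     "threshold": None})
        return pd.DataFrame(rows)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = ", ".join(f"{k}={v}" for k, v in self.removed_by.items())
        return (f"QcReport({self.axis}: {self.n_in} -> {self.n_out}; "
                f"removed {parts})")


def check_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Validate pedigree column layout and return it unchanged."""
    for col in ("animal", "sire", "dam"):
        if col not in ped.columns:
            raise ValueError(f"pedigree missing required column {col!r}")
    if ped["animal"].duplicated().any():
        dup = ped.loc[ped["animal"].duplicated(), "animal"].iloc[0]
        raise ValueError(f"duplicate animal id in pedigree: {dup!r}")
    return ped


def breed_columns(ped: pd.DataFrame) -> list[str]:
    return [c for c in ped.columns if c.startswith("breed_")]
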