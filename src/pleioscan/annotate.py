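"""Candidate-gene annotation and cross-species gene-overlap testing.

Significant SNPs are first thinned (one SNP per 60-kb neighbourhood,
keeping the most significant), then mapped to the nearest gene within a
+-30 kb window; where several genes crowd a 2-Mb region only the nearest
is retained, and optionally a SNP with no gene inside the window is
annotated with the single nearest gene, flagged ``expanded``.

The overlap test asks whether SNPs significant in the multi-trait scan
fall near a supplied gene list (e.g. genes associated with body
composition in another species) more often than near randomly drawn gene
sets of the same size from a gene universe.  Significance is the
add-one-corrected permutation probability of seeing jointly as many
overlapping SNPs and as many hit genes as observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_models(path, fmt: str = "auto") -> pd.DataFrame:
    """Gene models as a DataFrame (1-based inclusive coordinates).

    BED (0-based half-open) is converted on read; from GFF3 only ``gene``
    features are taken (a file with no gene features yields an empty
    table with a warning).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    if fmt == "bed":
        cols = ["chrom", "start", "end", "gene_id", "score", "strand"]
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
        df.columns = cols[: df.shape[1]]
        if "gene_id" not in df.columns:
            df["gene_id"] = [f"feature_{i + 1}" for i in range(len(df))]
        if "strand" not in df.columns:
            df["strand"] = "."
        out = df[["gene_id", "chrom", "start", "end", "strand"]].copy()
        out["start"] = out["start"].astype(int) + 1  # half-open -> 1-based
        out["end"] = out["end"].astype(int)
    elif fmt == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        rows = []
        for feat in db.features_of_type("gene"):
            name = (
                feat.attributes.get("Name", [None])[0]
                or feat.attributes.get("ID", [feat.id])[0]
            )
            rows.append([name, str(feat.seqid), feat.start, feat.end,
                         feat.strand or "."])
        out = pd.DataFrame(rows, columns=GENE_COLUMNS)
        if out.empty:
            warnings.warn(f"no 'gene' features found in {path.name}",
                          stacklevel=2)
    else:
        raise ValueError(f"unknown gene model format {fmt!r}")
    out["chrom"] = out["chrom"].astype(str)
    if (out["start"] > out["end"]).any():
        raise ValueError("gene with start > end")
    if out["gene_id"].duplicated().any():
        dup = out.loc[out["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    return out.reset_index(drop=True)


def dedup_by_window(snps: pd.DataFrame, window_bp: int = 60_000) -> pd.DataFrame:
    """Thin significant SNPs: greedy by ascending P, a SNP is kept only
    if no already-kept SNP on the same chromosome lies within
    ``window_bp``.  Ties break by genome order."""
    rec = snps.dropna(subset=["p"]).sort_values(["p", "chrom", "pos_bp"])
    kept_pos: dict[str, list[int]] = {}
    keep_idx = []
    for row in rec.itertuples():
        positions = kept_pos.setdefault(row.chrom, [])
        if all(abs(int(row.pos_bp) - q) > window_bp for q in positions):
            positions.append(int(row.pos_bp))
            keep_idx.append(row.Index)
    return (
        snps.loc[keep_idx]
        .sort_values(["chrom", "pos_bp"])
        .reset_index(drop=True)
    )


def _snp_gene_distance(pos: int, start: int, end: int) -> int:
    if pos < start:
        return start - pos
    if pos > end:
        return pos - end
    return 0


def candidate_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 30_000,
    dense_region_bp: int = 2_000_000,
    expand: bool = False,
) -> pd.DataFrame:
    """Nearest-gene candidate call per SNP.

    Genes within ``window_bp`` of the SNP are candidates; if several fall
    within one ``dense_region_bp`` neighbourhood only the nearest is
    retained (rule ``window``).  With ``expand=True`` a SNP with no gene
    in the window is annotated with the single nearest gene on the
    chromosome, flagged ``expanded``.  Distances are SNP to nearest gene
    edge, zero inside the gene; strand is ignored.
    """
    calls = []
    by_chrom = {c: g.reset_index(drop=True) for c, g in genes.groupby("chrom")}
    for row in snps.itertuples(index=False):
        chrom_genes = by_chrom.get(str(row.chrom))
        if chrom_genes is None or chrom_genes.empty:
            continue
        dist = np.array(
            [
                _snp_gene_distance(int(row.pos_bp), int(g.start), int(g.end))
                for g in chrom_genes.itertuples(index=False)
            ]
        )
        within = np.flatnonzero(dist <= window_bp)
        if len(within) > 0:
            # several genes in one dense neighbourhood -> nearest only
            nearest = within[np.argmin(dist[within])]
            calls.append(
                {
                    "snp_id": row.snp_id,
                    "gene_id": chrom_genes["gene_id"].iloc[nearest],
                    "distance_bp": int(dist[nearest]),
                    "rule": "window",
                }
            )
        elif expand:
            nearest = int(np.argmin(dist))
            calls.append(
                {
                    "snp_id": row.snp_id,
                    "gene_id": chrom_genes["gene_id"].iloc[nearest],
                    "distance_bp": int(dist[nearest]),
                    "rule": "expanded",
                }
            )
    return pd.DataFrame(calls, columns=["snp_id", "gene_id", "distance_bp",
                                        "rule"])


@dataclass
class OverlapResult:
    """Observed overlap, permutation null summaries, and empirical
    P-values (add-one corrected, so never exactly zero)."""

    observed_snps: int
    observed_genes: int
    n_target: int
    n_universe: int
    n_permutations: int
    seed: int
    p_joint: float
    p_snps: float
    p_genes: float
    null_snps_mean: float
    null_genes_mean: float


def overlap_permutation_test(
    meta: pd.DataFrame,
    target_genes: pd.DataFrame,
    universe_genes: pd.DataFrame,
    p_sig: float = 1e-3,
    window_bp: int = 30_000,
    n_perm: int = 1000,
    seed: int = 0,
) -> OverlapResult:
    """Permutation test of SNP-gene-list overlap.

    Observed statistics: number of significant SNPs (meta ``p`` < p_sig)
    within ``window_bp`` of any target gene, and number of target genes
    with at least one such SNP.  The null draws ``len(target)`` genes
    uniformly without replacement from the universe ``n_perm`` times.
    Target genes that cannot be matched to the universe (by gene_id) are
    reported and excluded.
    """
    if len(universe_genes) < len(target_genes):
        raise ValueError("universe smaller than target gene list")
    uni = universe_genes.reset_index(drop=True)
    target_ids = set(target_genes["gene_id"])
    mapped = uni.index[uni["gene_id"].isin(target_ids)].to_numpy()
    n_unmapped = len(target_ids) - len(mapped)
    if n_unmapped:
        warnings.warn(
            f"{n_unmapped} target gene(s) not present in the universe; "
            "excluded",
            stacklevel=2,
        )

    sig = meta.dropna(subset=["p"])
    sig = sig[sig["p"] < p_sig]

    # per-universe-gene: indices of significant SNPs within the window
    gene_snp_sets: list[np.ndarray] = []
    sig = sig.reset_index(drop=True)
    chrom_pos = {
        c: (grp.index.to_numpy(), grp["pos_bp"].to_numpy(dtype=np.int64))
        for c, grp in sig.groupby("chrom")
    }
    for g in uni.itertuples(index=False):
        entry = chrom_pos.get(str(g.chrom))
        if entry is None:
            gene_snp_sets.append(np.empty(0, dtype=int))
            continue
        idx, pos = entry
        lo, hi = int(g.start) - window_bp, int(g.end) + window_bp
        inside = (pos >= lo) & (pos <= hi)
        gene_snp_sets.append(idx[inside])

    def counts(gene_rows: np.ndarray) -> tuple[int, int]:
        sets = [gene_snp_sets[i] for i in gene_rows]
        hit_genes = sum(1 for s in sets if len(s) > 0)
        if hit_genes == 0:
            return 0, 0
        n_snps = len(np.unique(np.concatenate([s for s in sets if len(s)])))
        return n_snps, hit_genes

    obs_snps, obs_genes = counts(mapped)
    rng = np.random.default_rng(seed)
    null_snps = np.empty(n_perm, dtype=int)
    null_genes = np.empty(n_perm, dtype=int)
    ge_joint = ge_snps = ge_genes = 0
    for b in range(n_perm):
        draw = rng.choice(len(uni), size=len(mapped), replace=False)
        s, g = counts(draw)
        null_snps[b], null_genes[b] = s, g
        ge_snps += s >= obs_snps
        ge_genes += g >= obs_genes
        ge_joint += (s >= obs_snps) and (g >= obs_genes)
    return OverlapResult(
        observed_snps=obs_snps,
        observed_genes=obs_genes,
        n_target=len(mapped),
        n_universe=len(uni),
        n_permutations=n_perm,
        seed=seed,
        p_joint=(1 + ge_joint) / (n_perm + 1),
        p_snps=(1 + ge_snps) / (n_perm + 1),
        p_genes=(1 + ge_genes) / (n_perm + 1),
        null_snps_mean=float(null_snps.mean()),
        null_genes_mean=float(null_genes.mean()),
    )
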