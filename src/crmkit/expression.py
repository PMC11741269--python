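"""qPCR arithmetic and single-nucleus expression statistics.

ChIP-qPCR enrichment is percent input,
``100 / 2^(Cp_ChIP - (Cp_input - log2(dilution)))``; RT-qPCR fold changes
use the delta-delta-Cp method. The single-cell side takes a cells x genes
count matrix with cluster labels (an AnnData), applies a detected-genes QC
cutoff, normalizes each cell to the median depth and log1p-transforms, and
from that computes cluster z-score localization of gene sets, per-gene
coefficients of variation (COV), and SE/RE expression-robustness contrasts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GeneAnnotation
from .superenhancers import EnhancerRanking

__all__ = [
    "percent_input",
    "ddcp_fold_change",
    "DdcpResult",
    "qc_filter",
    "normalize_log1p",
    "zscore_localization",
    "cov_per_gene",
    "robustness_contrast",
    "se_gene_linking",
]

logger = logging.getLogger(__name__)


def percent_input(cp_chip: float, cp_input: float, dilution_factor: float = 1.0) -> float:
    """ChIP-qPCR percent input from crossing-point values.

    The input Cp is first corrected for its dilution (an input diluted
    ``d``-fold would have crossed log2(d) cycles earlier undiluted).
    """
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    exponent = cp_chip - (cp_input - np.log2(dilution_factor))
    return float(100.0 / 2.0**exponent)


@dataclass(frozen=True)
class DdcpResult:
    fold_change: float
    sd: float | None = None
    pvalue: float | None = None


def ddcp_fold_change(
    treat: tuple[np.ndarray | float, np.ndarray | float],
    ctrl: tuple[np.ndarray | float, np.ndarray | float],
) -> DdcpResult:
    """Delta-delta-Cp fold change of treatment over control.

    ``treat`` and ``ctrl`` are (Cp_target, Cp_reference) pairs; scalars give
    the plain 2^-ddCp fold change, replicate arrays additionally give the
    SD of per-replicate fold changes and a two-tailed Welch t p-value on the
    dCp values.
    """
    t_target, t_ref = np.atleast_1d(np.asarray(treat[0], float)), np.atleast_1d(
        np.asarray(treat[1], float)
    )
    c_target, c_ref = np.atleast_1d(np.asarray(ctrl[0], float)), np.atleast_1d(
        np.asarray(ctrl[1], float)
    )
    d_treat = t_target - t_ref
    d_ctrl = c_target - c_ref
    ddcp = d_treat.mean() - d_ctrl.mean()
    fc = float(2.0**-ddcp)
    if len(d_treat) > 1 and len(d_ctrl) > 1:
        per_rep = 2.0 ** -(d_treat - d_ctrl.mean())
        _, p = stats.ttest_ind(d_treat, d_ctrl, equal_var=False)
        return DdcpResult(fold_change=fc, sd=float(per_rep.std(ddof=1)), pvalue=float(p))
    return DdcpResult(fold_change=fc)


# ---------------------------------------------------------------------------
# Single-nucleus statistics
# ---------------------------------------------------------------------------


def qc_filter(adata: ad.AnnData, min_genes_per_cell: int = 1500) -> ad.AnnData:
    """Drop cells detecting fewer than ``min_genes_per_cell`` genes, then
    genes detected in no remaining cell."""
    if min_genes_per_cell < 0:
        raise ValueError("min_genes_per_cell must be >= 0")
    adata = adata.copy()
    sc.pp.calculate_qc_metrics(adata, inplace=True, percent_top=None, log1p=False)
    keep = adata.obs["n_genes_by_counts"] >= min_genes_per_cell
    if not keep.any():
        raise ValueError("QC filter removed every cell")
    adata = adata[keep].copy()
    sc.pp.filter_genes(adata, min_cells=1)
    return adata


def normalize_log1p(adata: ad.AnnData) -> ad.AnnData:
    """Median-depth normalization followed by log1p (done once, flagged)."""
    if adata.uns.get("crmkit_normalized"):
        return adata
    adata = adata.copy()
    sc.pp.normalize_total(adata)  # target_sum=None -> median depth
    sc.pp.log1p(adata)
    adata.uns["crmkit_normalized"] = True
    return adata


def _dense(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def zscore_localization(
    adata: ad.AnnData,
    gene_set: list[str],
    cluster_key: str = "cluster",
) -> tuple[pd.DataFrame, pd.Series]:
    """Cluster-localization z-scores of a gene set.

    Per gene, cluster means of normalized log1p expression are z-scored
    across clusters (ddof=1, matching how such tables are typically
    standardized with pandas). Returns (genes x clusters z table, gene-set
    mean z per cluster). Genes absent from the matrix are skipped with a
    warning; constant genes get z = 0 everywhere.
    """
    if cluster_key not in adata.obs:
        raise ValueError(f"missing obs column {cluster_key!r}")
    clusters = pd.Categorical(adata.obs[cluster_key])
    if len(clusters.categories) < 2:
        raise ValueError("need >= 2 clusters")
    adata = normalize_log1p(adata)
    present = [g for g in gene_set if g in adata.var_names]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        logger.warning("%d gene(s) absent from matrix, skipped: %s",
                       len(missing), ", ".join(missing[:5]))
    X = _dense(adata[:, present])
    means = pd.DataFrame(
        {g: 0.0 for g in present}, index=clusters.categories, dtype=float
    )
    for i, cat in enumerate(clusters.categories):
        means.iloc[i] = X[np.asarray(clusters == cat)].mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    centered = means - means.mean(axis=0)
    z = centered.divide(sd.replace(0.0, np.nan), axis=1).fillna(0.0)
    return z.T, z.mean(axis=1)


def cov_per_gene(adata: ad.AnnData, min_mean: float = 0.01) -> pd.DataFrame:
    """Per-gene coefficient of variation of depth-normalized expression.

    COV = sample SD / mean across all retained cells, computed on linear
    (median-depth-normalized, not log) expression so it is invariant under
    scaling a gene's values; genes with mean below ``min_mean`` are excluded.
    Columns: mean, sd, cov.
    """
    if min_mean <= 0:
        raise ValueError("min_mean must be > 0")
    if adata.uns.get("crmkit_normalized"):
        raise ValueError("cov_per_gene expects raw (unlogged) counts")
    adata = adata.copy()
    sc.pp.normalize_total(adata)  # target_sum=None -> median depth
    X = _dense(adata)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    df = pd.DataFrame({"mean": mean, "sd": sd}, index=adata.var_names)
    df = df[df["mean"] >= min_mean]
    df["cov"] = df["sd"] / df["mean"]
    return df


def robustness_contrast(
    cov_table: pd.DataFrame,
    groups: dict[str, list[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression level and COV contrasts between named gene groups.

    Returns (per-group summary, pairwise Mann-Whitney tests with BH
    adjustment, run separately on mean expression and COV). Empty groups
    (no genes in the table) are excluded with a warning; with a single
    usable group only summaries are returned.
    """
    usable: dict[str, pd.DataFrame] = {}
    for name, genes in groups.items():
        sub = cov_table.loc[cov_table.index.intersection(genes)]
        if len(sub) == 0:
            logger.warning("group %r has no genes in the COV table; excluded", name)
            continue
        usable[name] = sub
    summary = pd.DataFrame(
        {
            "n_genes": {k: len(v) for k, v in usable.items()},
            "mean_expression": {k: v["mean"].mean() for k, v in usable.items()},
            "mean_cov": {k: v["cov"].mean() for k, v in usable.items()},
        }
    )
    summary.index.name = "group"
    rows = []
    for (na, a), (nb, b) in itertools.combinations(usable.items(), 2):
        for metric in ("mean", "cov"):
            _, p = stats.mannwhitneyu(a[metric], b[metric], alternative="two-sided")
            rows.append({"group_a": na, "group_b": nb, "metric": metric, "pvalue": p})
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "metric", "pvalue"])
    if len(tests):
        _, padj, _, _ = multipletests(tests["pvalue"], method="fdr_bh")
        tests["padj"] = padj
    return summary, tests


def se_gene_linking(
    ranking: EnhancerRanking,
    genes: GeneAnnotation,
    window: int = 20_000,
) -> dict[str, list[str]]:
    """Partition genes by their nearest enhancer class within ``window``.

    A gene joins the SE set if any SE locus lies within ``window`` bp of its
    gene body (SE takes precedence), else the RE set if an RE locus is that
    close, else the no-enhancer set.
    """
    ranking._require_labels()
    out: dict[str, list[str]] = {"SE": [], "RE": [], "none": []}
    pools = {"SE": ranking.se_loci.by_chrom(), "RE": ranking.re_loci.by_chrom()}

    def near(chrom: str, gs: int, ge: int, pool: dict) -> bool:
        for iv in pool.get(chrom, []):
            gap = max(iv.start - ge, gs - iv.end, 0)
            if gap <= window:
                return True
        return False

    for row in genes.df.itertuples(index=False):
        if near(row.chrom, row.start, row.end, pools["SE"]):
            out["SE"].append(row.gene_id)
        elif near(row.chrom, row.start, row.end, pools["RE"]):
            out["RE"].append(row.gene_id)
        else:
            out["none"].append(row.gene_id)
    return out
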