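"""Zygotic/localized gene selection, peak-to-gene assignment, a lightweight
differential-expression caller, and direct-target calling.

A direct target of a factor is a gene whose expression changes at least
``fold``-fold (with adjusted p below ``padj_max``) in that factor's morphant
and that has a binding site of the factor within ``window`` bp of the gene
body. Genes passing for both factors are joint targets; the joint / A-only /
B-only partition is disjoint by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GeneAnnotation, PeakSet

__all__ = [
    "select_zygotic",
    "select_localized",
    "assign_peaks_to_genes",
    "simple_de",
    "TargetCall",
    "call_direct_targets",
]

logger = logging.getLogger(__name__)


def select_zygotic(
    tc: pd.DataFrame,
    maternal_max: float = 1.0,
    min_zygotic_lfc: float = 1.0,
    pseudocount: float = 1.0,
) -> list[str]:
    """Select zygotically expressed genes from an abundance timecourse.

    ``tc``: genes x timepoints (columns ordered, first column = pre-ZGA
    0 hpf). A gene is zygotic iff its 0 hpf abundance is at most
    ``maternal_max`` (no maternal deposit) and some later timepoint rises at
    least ``min_zygotic_lfc`` log2-fold over 0 hpf (with pseudocount).
    """
    if tc.shape[1] < 2:
        raise ValueError("timecourse needs a 0 hpf column plus later timepoints")
    t0 = tc.iloc[:, 0].to_numpy(dtype=float)
    later = tc.iloc[:, 1:].to_numpy(dtype=float)
    lfc = np.log2((later + pseudocount) / (t0[:, None] + pseudocount))
    keep = (t0 <= maternal_max) & (lfc.max(axis=1) >= min_zygotic_lfc)
    return tc.index[keep].tolist()


def select_localized(
    de_tissue: pd.DataFrame, fold: float = 2.0, top_n: int = 250
) -> list[str]:
    """Top tissue-enriched genes: |log2FC| >= log2(fold), ranked by FDR.

    ``de_tissue`` compares the two tissues and carries columns
    ``log2FC`` and ``padj`` indexed by gene. Returns up to ``top_n`` ids in
    ascending adjusted-p order (a warning is logged when fewer pass).
    """
    passing = de_tissue[de_tissue["log2FC"].abs() >= np.log2(fold)]
    ranked = passing.sort_values(["padj", "log2FC"], key=None, kind="stable")
    if len(ranked) < top_n:
        logger.warning(
            "only %d genes pass the %g-fold filter (requested top %d)",
            len(ranked), fold, top_n,
        )
    return ranked.index[:top_n].tolist()


def assign_peaks_to_genes(
    peaks: PeakSet,
    genes: GeneAnnotation,
    window: int = 20_000,
    mode: str = "gene_body",
) -> pd.DataFrame:
    """Nearest gene for each peak, within a distance window.

    Distance is 0 when the peak overlaps the gene body, otherwise the bp gap
    between the peak edge and the nearest gene-body edge (``mode='tss'``
    measures to the TSS instead). Ties go to the smaller distance, then the
    lexicographically first gene id. Peaks farther than ``window`` from every
    gene are omitted. Columns: chrom, peak_start, peak_end, gene_id, distance.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if mode not in ("gene_body", "tss"):
        raise ValueError(f"unknown mode {mode!r}")
    gdf = genes.df
    rows = []
    for chrom, g in gdf.groupby("chrom", sort=True):
        if mode == "tss":
            gs = g["tss"].to_numpy()
            ge = gs + 1
        else:
            gs = g["start"].to_numpy()
            ge = g["end"].to_numpy()
        ids = g["gene_id"].to_numpy()
        for iv in peaks.by_chrom().get(chrom, []):
            # gap is 0 on overlap; otherwise the positive edge-to-edge distance
            d = np.maximum.reduce(
                [gs - iv.end, iv.start - ge, np.zeros(len(gs), dtype=np.int64)]
            )
            best = d.min() if len(d) else None
            if best is None or best > window:
                continue
            cand = ids[d == best]
            rows.append(
                {
                    "chrom": chrom,
                    "peak_start": iv.start,
                    "peak_end": iv.end,
                    "gene_id": sorted(cand)[0],
                    "distance": int(best),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "peak_start", "peak_end", "gene_id", "distance"])


def _median_of_ratios(counts: pd.DataFrame) -> np.ndarray:
    """DESeq-style size factors over all columns of a gene x sample table."""
    logc = np.log(counts.to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        log_geo = logc.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene expressed in every sample; cannot size-normalize")
    sf = np.exp(np.median(logc[usable] - log_geo[usable, None], axis=0))
    return sf


def simple_de(
    counts_treat: pd.DataFrame,
    counts_ctrl: pd.DataFrame,
    pseudocount: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Lightweight two-group differential expression on count tables.

    Size factors by median-of-ratios over the pooled samples; per-gene
    log2FC = log2((mean normalized treat + pc) / (mean normalized ctrl + pc));
    pooled-variance two-sample t-test on log2(normalized + pc) (the two
    groups share a variance model, as in standard RNA-seq callers, and the
    pooled test stays calibrated at 2-3 replicates where the Welch
    approximation is visibly conservative); Benjamini-Hochberg adjustment.
    Accepts external DE tables instead wherever a DEResult is consumed.
    Returns gene-indexed columns: baseMean, log2FC, pvalue, padj.
    """
    if counts_treat.shape[1] < 2 or counts_ctrl.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    if not counts_treat.index.equals(counts_ctrl.index):
        counts_ctrl = counts_ctrl.loc[counts_treat.index]
    if counts_treat.to_numpy().sum() == 0 or counts_ctrl.to_numpy().sum() == 0:
        raise ValueError("a group has zero total counts")
    pooled = pd.concat([counts_treat, counts_ctrl], axis=1)
    sf = _median_of_ratios(pooled)
    norm = pooled.to_numpy(dtype=float) / sf
    nt = counts_treat.shape[1]
    treat, ctrl = norm[:, :nt], norm[:, nt:]
    base_mean = norm.mean(axis=1)
    log2fc = np.log2((treat.mean(axis=1) + pseudocount) / (ctrl.mean(axis=1) + pseudocount))
    lt = np.log2(treat + pseudocount)
    lc = np.log2(ctrl + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(lt, lc, axis=1, equal_var=True)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # zero-variance-in-both ties
    _, padj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {"baseMean": base_mean, "log2FC": log2fc, "pvalue": pvals, "padj": padj},
        index=counts_treat.index,
    )


@dataclass(frozen=True)
class TargetCall:
    """One direct-target gene call."""

    gene_id: str
    attribution: str  # "A", "B" or "joint"
    direction: str    # "activated" (down in morphant) or "repressed"
    distance_a: int | None
    distance_b: int | None


def _factor_targets(
    de: pd.DataFrame, assign: pd.DataFrame, fold: float, padj_max: float
) -> dict[str, tuple[str, int]]:
    """gene -> (direction, min peak distance) for one factor."""
    if len(assign):
        dist = assign.groupby("gene_id")["distance"].min()
    else:
        dist = pd.Series(dtype=int)
    lfc_cut = np.log2(fold)
    hits = de[(de["log2FC"].abs() >= lfc_cut) & (de["padj"] <= padj_max)]
    out = {}
    for gid, row in hits.iterrows():
        if gid in dist.index:
            direction = "activated" if row["log2FC"] < 0 else "repressed"
            out[gid] = (direction, int(dist[gid]))
    return out


def call_direct_targets(
    deA: pd.DataFrame,
    deB: pd.DataFrame,
    assignA: pd.DataFrame,
    assignB: pd.DataFrame,
    fold: float = 2.0,
    padj_max: float = 0.05,
) -> tuple[list[TargetCall], pd.DataFrame]:
    """Call per-factor direct targets and their joint/exclusive partition.

    DE tables give log2FC as morphant over wild-type, so a negative fold
    change means the factor normally activates the gene. Returns the calls
    plus a (attribution x direction) count table; for joint targets the
    direction is factor A's (the two can disagree only for genes regulated
    in opposite senses, which stay joint and are counted under A's sign).
    """
    ta = _factor_targets(deA, assignA, fold, padj_max)
    tb = _factor_targets(deB, assignB, fold, padj_max)
    calls: list[TargetCall] = []
    for gid in sorted(set(ta) | set(tb)):
        in_a, in_b = gid in ta, gid in tb
        attribution = "joint" if (in_a and in_b) else ("A" if in_a else "B")
        direction = ta[gid][0] if in_a else tb[gid][0]
        calls.append(
            TargetCall(
                gene_id=gid,
                attribution=attribution,
                direction=direction,
                distance_a=ta[gid][1] if in_a else None,
                distance_b=tb[gid][1] if in_b else None,
            )
        )
    counts = pd.DataFrame(
        0, index=["joint", "A", "B"], columns=["activated", "repressed"]
    )
    for c in calls:
        counts.loc[c.attribution, c.direction] += 1
    counts.index.name = "attribution"
    return calls, counts
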