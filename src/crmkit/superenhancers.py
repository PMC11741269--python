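"""Rank-order super-enhancer calling.

Enhancer peaks are stitched into loci (optionally dropping peaks near a
TSS), each locus is scored by background-subtracted signal, loci are ranked
ascending by net signal on a min-max-scaled "hockey stick" curve, and the
cutoff is the curve point where the discrete slope first exceeds 1. Loci
strictly above the cutoff signal are super-enhancers (SEs); the rest are
regular enhancers (REs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, SignalTrack, merge

__all__ = [
    "EnhancerRanking",
    "SeComparison",
    "stitch",
    "rank_loci",
    "find_cutoff",
    "compare_se_sets",
    "se_association",
]

DEFAULT_STITCH_GAP = 12_500
DEFAULT_TSS_EXCLUSION = 2_500


@dataclass
class EnhancerRanking:
    """Stitched loci ranked ascending by net (background-subtracted) signal.

    ``x`` is the scaled rank in [0,1], ``y`` the signal scaled to max 1.
    ``labels`` is None until :func:`find_cutoff` has run.
    """

    loci: list[GenomicInterval]          # in ascending-net order
    n_constituents: np.ndarray
    raw: np.ndarray
    background: np.ndarray
    net: np.ndarray
    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray | None = None     # "SE"/"RE"
    cutoff_y: float | None = None
    cutoff_index: int | None = None      # first index labelled SE, or n

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def se_loci(self) -> PeakSet:
        self._require_labels()
        return PeakSet("SE", [iv for iv, l in zip(self.loci, self.labels) if l == "SE"])

    @property
    def re_loci(self) -> PeakSet:
        self._require_labels()
        return PeakSet("RE", [iv for iv, l in zip(self.loci, self.labels) if l == "RE"])

    def _require_labels(self) -> None:
        if self.labels is None:
            raise ValueError("ranking is unlabeled; run find_cutoff first")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.loci],
                "start": [iv.start for iv in self.loci],
                "end": [iv.end for iv in self.loci],
                "n_constituents": self.n_constituents,
                "raw_signal": self.raw,
                "background_signal": self.background,
                "net_signal": self.net,
                "rank": np.arange(len(self.loci)),
                "scaled_rank": self.x,
                "scaled_signal": self.y,
            }
        )
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def to_bed(self) -> PeakSet:
        """SE/RE calls as BED-ready intervals: label in name, y scaled 0-1000."""
        self._require_labels()
        ivs = [
            GenomicInterval(iv.chrom, iv.start, iv.end, score=float(1000 * y), name=l)
            for iv, y, l in zip(self.loci, self.y, self.labels)
        ]
        return PeakSet("enhancers", ivs)


def stitch(
    peaks: PeakSet,
    stitch_gap: int = DEFAULT_STITCH_GAP,
    tss: dict[str, np.ndarray] | None = None,
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
) -> PeakSet:
    """Merge enhancer peaks separated by <= stitch_gap into stitched loci.

    When TSS positions are supplied, peaks whose edge lies within
    ``tss_exclusion`` of a TSS are removed before stitching (promoter
    proximity disqualifies a peak from the enhancer landscape).
    """
    if tss is not None:
        kept = []
        for iv in peaks:
            pos = tss.get(iv.chrom)
            if pos is not None and len(pos):
                # distance 0 when the TSS falls inside the peak
                d = np.maximum.reduce(
                    [iv.start - pos, pos - (iv.end - 1), np.zeros(len(pos), dtype=np.int64)]
                ).min()
                if d <= tss_exclusion:
                    continue
            kept.append(iv)
        peaks = PeakSet(peaks.label, kept)
    return merge(peaks, max_gap=stitch_gap, label=f"{peaks.label}:stitched")


def rank_loci(
    loci: PeakSet,
    signal: SignalTrack,
    background: SignalTrack | None = None,
) -> EnhancerRanking:
    """Score stitched loci and sort ascending by net signal.

    net = max(signal sum - background sum, 0) over the locus. Ties in net
    signal are broken by wider locus first, then coordinates, so the
    ordering is total and deterministic.
    """
    if len(loci) == 0:
        raise ValueError("no loci to rank")
    ivs = list(loci)
    raw = np.zeros(len(ivs))
    bg = np.zeros(len(ivs))
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(ivs):
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        starts = np.array([ivs[i].start for i in idx])
        ends = np.array([ivs[i].end for i in idx])
        raw[idx] = signal.window_sums(chrom, starts, ends)
        if background is not None:
            bg[idx] = background.window_sums(chrom, starts, ends)
    net = np.maximum(raw - bg, 0.0)
    if net.max() == 0.0:
        raise ValueError("no signal: every locus has zero net signal")
    widths = np.array([iv.width for iv in ivs])
    # ascending net; ties: wider first, then coordinates
    order = sorted(
        range(len(ivs)),
        key=lambda i: (net[i], -widths[i], ivs[i].chrom, ivs[i].start, ivs[i].end),
    )
    ivs = [ivs[i] for i in order]
    ncons = np.array([int(iv.name) if iv.name.isdigit() else 1 for iv in ivs])
    raw, bg, net = raw[order], bg[order], net[order]
    n = len(ivs)
    x = np.arange(n) / (n - 1) if n > 1 else np.zeros(1)
    y = net / net.max()
    return EnhancerRanking(
        loci=ivs, n_constituents=ncons, raw=raw, background=bg, net=net, x=x, y=y
    )


def find_cutoff(ranking: EnhancerRanking) -> EnhancerRanking:
    """Label loci SE/RE at the point where the scaled curve's slope passes 1.

    Scanning the min-max-scaled (x, y) curve by ascending x, the cutoff is
    the y of the first point at which the discrete slope to the next point
    exceeds 1. Loci with scaled signal strictly above that y are SEs; ties
    at the cutoff stay RE. If the slope never exceeds 1 (flat or perfectly
    diagonal curve) no locus is an SE. A single locus is RE by convention.
    """
    n = len(ranking)
    x, y = ranking.x, ranking.y
    cutoff_y: float | None = None
    if n >= 2:
        dx = np.diff(x)
        dy = np.diff(y)
        slopes = dy / dx
        above = np.nonzero(slopes > 1.0)[0]
        if len(above):
            cutoff_y = float(y[above[0]])
    if cutoff_y is None:
        labels = np.array(["RE"] * n)
        cut_idx = n
    else:
        is_se = y > cutoff_y
        labels = np.where(is_se, "SE", "RE")
        cut_idx = int(np.argmax(is_se)) if is_se.any() else n
    ranking.labels = labels
    ranking.cutoff_y = cutoff_y
    ranking.cutoff_index = cut_idx
    return ranking


def call_super_enhancers(
    peaks: PeakSet,
    signal: SignalTrack,
    background: SignalTrack | None = None,
    stitch_gap: int = DEFAULT_STITCH_GAP,
    tss: dict[str, np.ndarray] | None = None,
    tss_exclusion: int = DEFAULT_TSS_EXCLUSION,
) -> EnhancerRanking:
    """stitch -> rank -> cutoff in one call."""
    loci = stitch(peaks, stitch_gap=stitch_gap, tss=tss, tss_exclusion=tss_exclusion)
    return find_cutoff(rank_loci(loci, signal, background=background))


@dataclass
class SeComparison:
    """Shared and tissue-unique SE regions between two landscapes."""

    shared_regions: PeakSet      # merged spans containing SEs of both sides
    a_unique: PeakSet
    b_unique: PeakSet
    a_shared: PeakSet            # A-side loci overlapping B (per-side view)
    b_shared: PeakSet

    @property
    def counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared_regions),
            "a_unique": len(self.a_unique),
            "b_unique": len(self.b_unique),
            "a_shared": len(self.a_shared),
            "b_shared": len(self.b_shared),
        }


def compare_se_sets(seA: PeakSet, seB: PeakSet) -> SeComparison:
    """Partition two SE sets into shared and tissue-unique regions (>=1 bp)."""
    def hits(query: PeakSet, subject: PeakSet) -> list[bool]:
        by_chrom = subject.by_chrom()
        out = []
        for iv in query:
            others = by_chrom.get(iv.chrom, [])
            out.append(
                any(min(o.end, iv.end) - max(o.start, iv.start) >= 1 for o in others)
            )
        return out

    a_hit = hits(seA, seB)
    b_hit = hits(seB, seA)
    a_shared = [iv for iv, h in zip(seA, a_hit) if h]
    b_shared = [iv for iv, h in zip(seB, b_hit) if h]
    pooled = PeakSet("pooled", a_shared + [
        iv for iv in b_shared
        if (iv.chrom, iv.start, iv.end) not in {(a.chrom, a.start, a.end) for a in a_shared}
    ]) if (a_shared or b_shared) else PeakSet("pooled")
    shared = merge(pooled, max_gap=0, label="shared") if len(pooled) else PeakSet("shared")
    return SeComparison(
        shared_regions=shared,
        a_unique=PeakSet(f"{seA.label}:unique", [iv for iv, h in zip(seA, a_hit) if not h]),
        b_unique=PeakSet(f"{seB.label}:unique", [iv for iv, h in zip(seB, b_hit) if not h]),
        a_shared=PeakSet(f"{seA.label}:shared", a_shared),
        b_shared=PeakSet(f"{seB.label}:shared", b_shared),
    )


def se_association(
    categories: dict[str, PeakSet], ranking: EnhancerRanking
) -> pd.DataFrame:
    """SE vs RE association of region categories (e.g. FSE / coactivator-only).

    For each category: number of regions overlapping an SE locus, number
    overlapping only RE loci, the SE fraction among enhancer-overlapping
    regions, and its enrichment over the landscape-wide SE fraction.
    """
    ranking._require_labels()
    se = ranking.se_loci.by_chrom()
    re_ = ranking.re_loci.by_chrom()

    def any_hit(iv: GenomicInterval, pool: dict[str, list[GenomicInterval]]) -> bool:
        return any(
            min(o.end, iv.end) - max(o.start, iv.start) >= 1
            for o in pool.get(iv.chrom, [])
        )

    n_se_all = int((ranking.labels == "SE").sum())
    overall = n_se_all / len(ranking)
    rows = []
    for name, regions in categories.items():
        n_se = sum(any_hit(iv, se) for iv in regions)
        n_re = sum(1 for iv in regions if not any_hit(iv, se) and any_hit(iv, re_))
        denom = n_se + n_re
        frac = n_se / denom if denom else float("nan")
        rows.append(
            {
                "category": name,
                "n_regions": len(regions),
                "n_se": n_se,
                "n_re": n_re,
                "se_fraction": frac,
                "enrichment": frac / overall if denom and overall > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("category")
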