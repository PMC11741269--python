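"""Temporal occupancy classes and TF/coactivator co-occupancy.

Peaks from three developmental stages are single-linkage clustered by
overlap; each cluster's stage-membership pattern is one of the seven
nonempty subsets of the three stages and maps to a display class label
(Roman numerals I-VII). The same clustering, run across two transcription
factors and a coactivator, yields co-occupancy calls; regions carrying all
three factors are the fully co-occupied (FSE) regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, SignalTrack

__all__ = [
    "ROMAN_CLASS_MAP",
    "TemporalClassAssignment",
    "CoOccupancyCall",
    "temporal_classify",
    "co_occupancy",
    "class_signal_summary",
    "percent_overlap",
    "replicate_overlap_filter",
]

# Display mapping from stage-membership pattern (indices into the ordered
# early->late stage triple) to Roman numerals. This is the numbering in
# which the stage-unique patterns are I, III and VI and the persistent
# pattern is VII; figure numbering differs between factors, so the mapping
# is presentation only and can be swapped.
ROMAN_CLASS_MAP: dict[frozenset[int], str] = {
    frozenset({0}): "I",
    frozenset({0, 1}): "II",
    frozenset({1}): "III",
    frozenset({1, 2}): "IV",
    frozenset({0, 2}): "V",
    frozenset({2}): "VI",
    frozenset({0, 1, 2}): "VII",
}

ALL_PATTERNS: list[frozenset[int]] = sorted(
    ROMAN_CLASS_MAP, key=lambda p: (len(p), sorted(p))
)


def pattern_label(pattern: frozenset[int], mapping: dict[frozenset[int], str] | None = None) -> str:
    return (mapping or ROMAN_CLASS_MAP)[frozenset(pattern)]


def _single_linkage_clusters(
    sources: list[PeakSet], min_bp: int
) -> list[tuple[GenomicInterval, list[tuple[int, int]]]]:
    """Cluster peaks pooled from several sets by >= min_bp overlap.

    Returns (locus interval = union span, [(source index, peak index)]) per
    cluster. Exact single linkage under a start-sorted sweep: a new peak
    joins the open cluster iff it shares min_bp bases with the member whose
    end is maximal, which is the member it overlaps most.
    """
    tagged: list[tuple[GenomicInterval, int, int]] = []
    for si, ps in enumerate(sources):
        for pi, iv in enumerate(ps):
            tagged.append((iv, si, pi))
    tagged.sort(key=lambda t: t[0].sort_key())
    clusters: list[tuple[GenomicInterval, list[tuple[int, int]]]] = []
    cur: list[tuple[GenomicInterval, int, int]] = []
    cur_chrom, cur_start, cur_end = "", 0, 0
    for iv, si, pi in tagged:
        joins = (
            cur
            and iv.chrom == cur_chrom
            and min(cur_end, iv.end) - iv.start >= min_bp
        )
        if joins:
            cur.append((iv, si, pi))
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                clusters.append(
                    (GenomicInterval(cur_chrom, cur_start, cur_end),
                     [(s, p) for _, s, p in cur])
                )
            cur = [(iv, si, pi)]
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur:
        clusters.append(
            (GenomicInterval(cur_chrom, cur_start, cur_end), [(s, p) for _, s, p in cur])
        )
    return clusters


@dataclass
class TemporalClassAssignment:
    """Per-locus stage membership over three ordered stages."""

    stage_labels: tuple[str, str, str]
    loci: list[GenomicInterval]
    patterns: list[frozenset[int]]
    members: list[list[tuple[int, int]]]  # per locus: (stage index, peak index)
    class_map: dict[frozenset[int], str] = field(
        default_factory=lambda: dict(ROMAN_CLASS_MAP)
    )

    def labels(self) -> list[str]:
        return [self.class_map[p] for p in self.patterns]

    def class_counts(self) -> dict[str, int]:
        out = {self.class_map[p]: 0 for p in ALL_PATTERNS}
        for p in self.patterns:
            out[self.class_map[p]] += 1
        return out

    def per_stage_peak_totals(self) -> list[int]:
        """Peaks contributed by each stage, summed over loci (partition check)."""
        totals = [0, 0, 0]
        for mem in self.members:
            for si, _ in mem:
                totals[si] += 1
        return totals

    def loci_for_class(self, label: str) -> PeakSet:
        ivs = [
            self.loci[i].__class__(
                self.loci[i].chrom, self.loci[i].start, self.loci[i].end, name=label
            )
            for i, p in enumerate(self.patterns)
            if self.class_map[p] == label
        ]
        return PeakSet(label, ivs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.loci],
                "start": [iv.start for iv in self.loci],
                "end": [iv.end for iv in self.loci],
                "pattern": [
                    "".join(
                        self.stage_labels[i] if i in p else "-" for i in range(3)
                    )
                    for p in self.patterns
                ],
                "class": self.labels(),
                "n_peaks": [len(m) for m in self.members],
            }
        )


def temporal_classify(
    stage1: PeakSet, stage2: PeakSet, stage3: PeakSet, min_bp: int = 1
) -> TemporalClassAssignment:
    """Assign each overlap-linked locus one of the 7 temporal classes.

    Stages must be ordered early -> late. Every input peak lands in exactly
    one locus; a locus' class is determined by which stages contributed at
    least one peak.
    """
    stages = [stage1, stage2, stage3]
    clusters = _single_linkage_clusters(stages, min_bp)
    loci, patterns, members = [], [], []
    for iv, mem in clusters:
        loci.append(iv)
        patterns.append(frozenset(si for si, _ in mem))
        members.append(mem)
    return TemporalClassAssignment(
        stage_labels=(stage1.label, stage2.label, stage3.label),
        loci=loci,
        patterns=patterns,
        members=members,
    )


@dataclass
class CoOccupancyCall:
    """A maximal union of mutually overlapping peaks and its factor flags."""

    region: GenomicInterval
    has_tfA: bool
    has_tfB: bool
    has_coact: bool
    member_ids: list[tuple[int, int]]

    @property
    def is_fse(self) -> bool:
        return self.has_tfA and self.has_tfB and self.has_coact

    @property
    def is_cobound(self) -> bool:
        return self.has_tfA and self.has_tfB


def co_occupancy(
    tfA: PeakSet, tfB: PeakSet, coact: PeakSet, min_bp: int = 1
) -> list[CoOccupancyCall]:
    """Call co-occupied regions across two TFs and a coactivator.

    Regions are maximal single-linkage unions of overlapping peaks; a region
    flagged for all three inputs is a fully co-occupied (FSE) region.
    """
    clusters = _single_linkage_clusters([tfA, tfB, coact], min_bp)
    calls = []
    for iv, mem in clusters:
        src = {si for si, _ in mem}
        calls.append(
            CoOccupancyCall(
                region=iv,
                has_tfA=0 in src,
                has_tfB=1 in src,
                has_coact=2 in src,
                member_ids=mem,
            )
        )
    return calls


def fse_regions(calls: list[CoOccupancyCall], label: str = "FSE") -> PeakSet:
    return PeakSet(label, [c.region for c in calls if c.is_fse])


def class_signal_summary(
    assignment: TemporalClassAssignment,
    tracks: dict[str, SignalTrack],
    window: int = 2000,
) -> pd.DataFrame:
    """Mean windowed signal per temporal class for each named track.

    Windows of total width ``window`` are centered on each locus' anchor
    (summit when present, midpoint otherwise). Rows: classes; columns:
    track names.
    """
    labels = assignment.labels()
    class_order = [ROMAN_CLASS_MAP[p] for p in ALL_PATTERNS]
    out = pd.DataFrame(0.0, index=class_order, columns=list(tracks))
    half = window // 2
    anchors = np.array([iv.anchor for iv in assignment.loci])
    chroms = np.array([iv.chrom for iv in assignment.loci])
    lab_arr = np.array(labels) if labels else np.empty(0, dtype=str)
    for tname, track in tracks.items():
        sums = np.zeros(len(assignment.loci))
        for chrom in np.unique(chroms):
            m = chroms == chrom
            starts = anchors[m] - half
            sums[m] = track.window_sums(chrom, starts, starts + window)
        for cls in class_order:
            sel = lab_arr == cls
            if sel.any():
                out.loc[cls, tname] = float(sums[sel].mean())
    out.index.name = "class"
    return out


@dataclass(frozen=True)
class Percentage:
    value: float
    rounded: int


def percent_overlap(subset_count: int, total_count: int) -> Percentage:
    """Share of ``total_count`` covered by ``subset_count``, as a percentage.

    Returns both the exact value and the nearest-integer percent the way
    such overlaps are quoted in figure legends.
    """
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if not 0 <= subset_count <= total_count:
        raise ValueError("subset_count must lie in [0, total_count]")
    value = 100.0 * subset_count / total_count
    return Percentage(value=value, rounded=int(round(value)))


def replicate_overlap_filter(rep1: PeakSet, rep2: PeakSet, min_bp: int = 1) -> PeakSet:
    """Keep rep1 peaks supported by an overlapping rep2 peak.

    A plain both-replicates concordance filter (a deliberately simple stand-in
    for reproducibility-rate procedures, which are out of scope).
    """
    by_chrom = rep2.by_chrom()
    kept = []
    for iv in rep1:
        others = by_chrom.get(iv.chrom, [])
        starts = np.array([o.start for o in others])
        ends = np.array([o.end for o in others])
        if len(others) and np.any(
            np.minimum(ends, iv.end) - np.maximum(starts, iv.start) >= min_bp
        ):
            kept.append(iv)
    return PeakSet(rep1.label, kept)
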