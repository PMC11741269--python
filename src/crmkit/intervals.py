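"""Core genomic-interval data model and standard-format I/O.

All coordinates are 0-based half-open (BED convention). GFF3 input is
converted on read. Strand is ignored for peaks and signal and used only to
place a gene's TSS. Every downstream stage — temporal peak classification,
co-occupancy calling, enhancer stitching/ranking, peak-to-gene assignment —
is built on the overlap/merge algebra and windowed signal sums defined here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "SignalTrack",
    "GeneAnnotation",
    "read_intervals",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gff3_genes",
    "overlaps",
    "overlap_length",
    "merge",
    "window_sum",
    "aggregate_profile",
]


class FormatError(ValueError):
    """A standard-format file failed to parse; message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome.

    ``summit`` is an absolute base position (not an offset) when present.
    """

    chrom: str
    start: int
    end: int
    summit: int | None = None
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside {self.chrom}:{self.start}-{self.end}"
            )
        if self.score < 0:
            raise ValueError(f"negative score: {self.score}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def anchor(self) -> int:
        """Summit when present, otherwise midpoint; used to center windows."""
        return self.summit if self.summit is not None else (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class PeakSet:
    """An ordered, labelled collection of intervals (one stage/factor)."""

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=GenomicInterval.sort_key)
        seen: set[tuple[str, int, int]] = set()
        for iv in self.intervals:
            k = (iv.chrom, iv.start, iv.end)
            if k in seen:
                raise ValueError(f"duplicate interval {k} in PeakSet {self.label!r}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "summit": [iv.summit for iv in self.intervals],
            }
        )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared bases between two intervals (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff a and b share at least ``min_bp`` bases.

    Half-open arithmetic: [100,300) and [300,400) do not overlap.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return overlap_length(a, b) >= min_bp


def merge(peaks: PeakSet, max_gap: int = 0, label: str | None = None) -> PeakSet:
    """Merge intervals separated by at most ``max_gap`` bases.

    Output intervals are pairwise separated by more than max_gap; the union
    of covered bases is preserved (max_gap=0 merges only touching/overlapping
    intervals). Idempotent. Merged intervals lose summits; score is the max
    of contributors; name lists the number of constituents.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[GenomicInterval] = []
    for chrom, ivs in sorted(peaks.by_chrom().items()):
        cur_start, cur_end = ivs[0].start, ivs[0].end
        cur_score, n = ivs[0].score, 1
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
                cur_score = max(cur_score, iv.score)
                n += 1
            else:
                out.append(
                    GenomicInterval(chrom, cur_start, cur_end, score=cur_score, name=str(n))
                )
                cur_start, cur_end, cur_score, n = iv.start, iv.end, iv.score, 1
        out.append(GenomicInterval(chrom, cur_start, cur_end, score=cur_score, name=str(n)))
    return PeakSet(label if label is not None else peaks.label, out)


# ---------------------------------------------------------------------------
# Signal tracks (bedGraph-backed step functions)
# ---------------------------------------------------------------------------


class SignalTrack:
    """Sparse per-base coverage: per-chromosome sorted, non-overlapping runs.

    Stored as three aligned numpy arrays per chromosome (starts, ends,
    values); bases not covered by a run have value 0.
    """

    def __init__(self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if runs:
            for chrom, (s, e, v) in runs.items():
                self.add_runs(chrom, s, e, v)

    def add_runs(
        self,
        chrom: str,
        starts: Sequence[int],
        ends: Sequence[int],
        values: Sequence[float],
    ) -> None:
        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        v = np.asarray(values, dtype=np.float64)
        if not (len(s) == len(e) == len(v)):
            raise ValueError("runs arrays must align")
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if np.any(e <= s):
            raise ValueError(f"empty run on {chrom}")
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"overlapping runs on {chrom}")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError(f"signal values must be finite and nonnegative on {chrom}")
        self._runs[chrom] = (s, e, v)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self._runs.get(chrom, (empty, empty, np.empty(0, dtype=np.float64)))

    def window_sums(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised sums of per-base value over many [start,end) windows.

        Uses a cumulative integral of the step function evaluated at the
        window edges; windows extending past coverage (or below 0) pick up 0.
        """
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        s, e, v = self.runs(chrom)
        if len(s) == 0:
            return np.zeros(len(starts), dtype=np.float64)
        # breakpoints of the step function and the integral up to each one
        bp = np.empty(2 * len(s), dtype=np.int64)
        bp[0::2], bp[1::2] = s, e
        seg = np.zeros(2 * len(s), dtype=np.float64)
        seg[1::2] = (e - s) * v  # integral gained once the run ends
        cum = np.concatenate([[0.0], np.cumsum(seg)])  # integral at each breakpoint

        def integral_at(pos: np.ndarray) -> np.ndarray:
            idx = np.searchsorted(bp, pos, side="right")
            base = cum[idx]
            # inside a run (odd idx): add partial bases since run start
            inside = (idx % 2) == 1
            run_i = idx[inside] // 2
            base[inside] += (pos[inside] - s[run_i]) * v[run_i]
            return base

        lo = np.clip(starts, 0, None)
        hi = np.maximum(ends, lo)
        return integral_at(hi) - integral_at(lo)


def window_sum(track: SignalTrack, interval: GenomicInterval) -> float:
    """Sum of per-base signal within the interval; uncovered bases add 0."""
    return float(
        track.window_sums(
            interval.chrom, np.array([interval.start]), np.array([interval.end])
        )[0]
    )


def aggregate_profile(
    track: SignalTrack,
    regions: PeakSet,
    flank: int,
    bin: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Region x bin matrix of signal sums around each region's anchor.

    Each row covers [anchor-flank, anchor+flank) in fixed-width bins
    (summit-anchored when the peak has a summit, midpoint otherwise).
    Windows reaching past the chromosome start are zero-padded, never
    truncated. Returns (matrix, column means) — the means are the metaplot.
    """
    if flank <= 0 or bin <= 0 or flank % bin != 0:
        raise ValueError("flank must be a positive multiple of bin")
    n_bins = 2 * flank // bin
    mat = np.zeros((len(regions), n_bins), dtype=np.float64)
    offsets = np.arange(n_bins) * bin - flank
    for i, iv in enumerate(regions):
        starts = iv.anchor + offsets
        mat[i] = track.window_sums(iv.chrom, starts, starts + bin)
    colmeans = mat.mean(axis=0) if len(regions) else np.zeros(n_bins)
    return mat, colmeans


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


class GeneAnnotation:
    """Gene models with strand-aware TSS, backed by a DataFrame.

    Columns: gene_id, chrom, start, end (half-open), strand, tss.
    TSS = start on '+', end-1 on '-'.
    """

    COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        missing = [c for c in ("gene_id", "chrom", "start", "end", "strand") if c not in df]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if (df["start"] >= df["end"]).any():
            raise ValueError("gene start must be < end")
        tss = np.where(df["strand"].to_numpy() == "-", df["end"].to_numpy() - 1,
                       df["start"].to_numpy())
        df = df.assign(tss=tss)
        self.df = df[self.COLUMNS].sort_values(
            ["chrom", "start", "end", "gene_id"], kind="stable"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> list[str]:
        return self.df["gene_id"].tolist()

    def tss_positions(self) -> dict[str, np.ndarray]:
        return {
            chrom: g["tss"].to_numpy()
            for chrom, g in self.df.groupby("chrom", sort=True)
        }

    def to_gff3(self, path: str | Path) -> None:
        """Write gene features; internal half-open 0-based -> GFF3 1-based inclusive."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in self.df.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\tcrmkit\tgene\t{row.start + 1}\t{row.end}\t.\t"
                    f"{row.strand}\t.\tID={row.gene_id}\n"
                )


def read_gff3_genes(path: str | Path) -> GeneAnnotation:
    """Read gene features from GFF3 (1-based inclusive -> half-open internal)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            try:
                s, e = int(start), int(end)
            except ValueError as err:
                raise FormatError(f"{path}: line {lineno}: bad coordinates") from err
            gid = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gid = kv[3:]
                    break
            if not gid:
                raise FormatError(f"{path}: line {lineno}: gene feature lacks ID attribute")
            if s < 1 or e < s:
                raise FormatError(f"{path}: line {lineno}: invalid GFF3 span {s}-{e}")
            rows.append((gid, chrom, s - 1, e, strand if strand in "+-" else "+"))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GeneAnnotation(df)


# ---------------------------------------------------------------------------
# BED / narrowPeak / bedGraph I/O
# ---------------------------------------------------------------------------


def _parse_bed_line(parts: list[str], dialect: str, lineno: int, path: str) -> GenomicInterval:
    try:
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
    except (IndexError, ValueError) as err:
        raise FormatError(f"{path}: line {lineno}: malformed {dialect} record") from err
    name = parts[3] if len(parts) > 3 else ""
    try:
        score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
    except ValueError as err:
        raise FormatError(f"{path}: line {lineno}: bad score") from err
    summit = None
    if dialect == "narrowPeak":
        if len(parts) < 10:
            raise FormatError(f"{path}: line {lineno}: narrowPeak needs 10 columns")
        try:
            offset = int(parts[9])
        except ValueError as err:
            raise FormatError(f"{path}: line {lineno}: bad summit offset") from err
        if offset >= 0:
            summit = start + offset
    if start >= end or start < 0:
        raise FormatError(f"{path}: line {lineno}: invalid interval {start}-{end}")
    try:
        return GenomicInterval(chrom, start, end, summit=summit, score=max(score, 0.0),
                               name=name)
    except ValueError as err:
        raise FormatError(f"{path}: line {lineno}: {err}") from err


def read_intervals(path: str | Path, dialect: str = "bed", label: str | None = None) -> PeakSet:
    """Read BED3/BED6 or ENCODE narrowPeak into a PeakSet.

    narrowPeak column 10 (summit offset from start) becomes an absolute
    summit; offset -1 means no summit. Records come out sorted.
    """
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            ivs.append(_parse_bed_line(line.split("\t"), dialect, lineno, str(path)))
    return PeakSet(label if label is not None else Path(path).stem, ivs)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write BED6 in deterministic (chrom, start) order."""
    with open(path, "w") as fh:
        for iv in sorted(peaks, key=GenomicInterval.sort_key):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{int(round(iv.score))}\t.\n"
            )


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a bedGraph coverage file into a SignalTrack."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except (IndexError, ValueError) as err:
                raise FormatError(f"{path}: line {lineno}: malformed bedGraph record") from err
            per_chrom.setdefault(chrom, []).append((s, e, v))
    track = SignalTrack()
    for chrom, rows in per_chrom.items():
        s, e, v = zip(*rows)
        track.add_runs(chrom, s, e, v)
    return track


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write runs in deterministic order; zero-valued runs are kept."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            s, e, v = track.runs(chrom)
            for i in range(len(s)):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")
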