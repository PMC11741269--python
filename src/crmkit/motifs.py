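"""PWM scanning around peak summits: positional histograms and
combinatorial motif content.

PWMs arrive as JASPAR-style plain-text count matrices (parsed with
Biopython) or are built from consensus strings for controlled fixtures. A
hit is a window whose log2-odds score against background reaches the PWM's
threshold (default: 80% of its maximal score); both strands are scanned and
positions containing N score -inf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .intervals import PeakSet

__all__ = [
    "Pwm",
    "read_jaspar",
    "MotifHistogram",
    "scan",
    "summit_histogram",
    "combinatorial_content",
]

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """Position weight matrix with a log2-odds score threshold.

    ``probs`` is length x 4 (A,C,G,T) probabilities; ``background`` the
    genomic base composition. ``threshold`` defaults to ``threshold_frac``
    of the maximal attainable log2-odds score.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float | None = None
    threshold_frac: float = 0.8

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be length x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        # small floor keeps log-odds finite for zero-probability entries
        floored = np.maximum(self.probs, 1e-4)
        self.log_odds = np.log2(floored / self.background)
        if self.threshold is None:
            self.threshold = self.threshold_frac * self.max_score
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.5,
                    **kw) -> "Pwm":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(name, counts / counts.sum(axis=1, keepdims=True), **kw)

    @classmethod
    def from_consensus(cls, name: str, consensus: str, p_match: float = 0.97, **kw) -> "Pwm":
        """A sharp PWM putting ``p_match`` on each consensus base."""
        probs = np.full((len(consensus), 4), (1 - p_match) / 3)
        for i, b in enumerate(consensus.upper()):
            probs[i, _BASE_INDEX[b]] = p_match
        return cls(name, probs, **kw)


def read_jaspar(path: str | Path, **kw) -> list[Pwm]:
    """Read JASPAR-format plain-text count matrices via Biopython."""
    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([[m.counts[b][i] for b in ALPHABET] for i in range(m.length)])
            out.append(Pwm.from_counts(m.name or m.matrix_id, counts, **kw))
    return out


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[arr == ord(b)] = i
    return code


def scan(seq: str, pwm: Pwm) -> list[tuple[int, str, float]]:
    """All PWM hits on both strands of ``seq``.

    Returns (offset, strand, score) triples, offset relative to the sequence
    start (the leftmost base of the matched window on the forward
    coordinate system, for both strands). Sequences shorter than the motif
    yield no hits.
    """
    m = len(pwm)
    hits: list[tuple[int, str, float]] = []
    if len(seq) < m:
        return hits
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        code = _encode(s)
        n = len(code) - m + 1
        # rows: base code 0..3 plus a -inf sentinel row for N; columns: positions
        lo = np.vstack([pwm.log_odds.T, np.full((1, m), -np.inf)])
        scores = np.zeros(n)
        for j in range(m):
            scores = scores + lo[code[j : j + n], j]
        for off in np.nonzero(scores >= pwm.threshold)[0]:
            fwd_off = int(off) if strand == "+" else len(seq) - int(off) - m
            hits.append((fwd_off, strand, float(scores[off])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


@dataclass
class MotifHistogram:
    """Positional motif-occurrence histogram around peak summits."""

    bin_edges: np.ndarray                      # offsets from summit, len = n_bins+1
    counts: pd.DataFrame                       # n_bins x motifs, integer counts
    presence: pd.DataFrame                     # peaks x motifs, boolean

    @property
    def total_hits(self) -> int:
        return int(self.counts.to_numpy().sum())


def summit_histogram(
    peaks: PeakSet,
    genome_seqs: dict[str, str],
    pwms: list[Pwm],
    flank: int = 1000,
    bin: int = 20,
) -> MotifHistogram:
    """Histogram of motif-midpoint offsets from peak summits.

    Each peak contributes the window [summit-flank, summit+flank); peaks
    without a summit use their midpoint (logged). Defaults give a 2 kb
    window in 100 bins of 20 bp.
    """
    if flank <= 0 or bin <= 0 or flank % bin != 0:
        raise ValueError("flank must be a positive multiple of bin")
    n_bins = 2 * flank // bin
    edges = np.arange(n_bins + 1) * bin - flank
    counts = pd.DataFrame(0, index=range(n_bins), columns=[p.name for p in pwms])
    presence = pd.DataFrame(
        False, index=range(len(peaks)), columns=[p.name for p in pwms]
    )
    n_no_summit = 0
    for i, iv in enumerate(peaks):
        if iv.summit is None:
            n_no_summit += 1
        anchor = iv.anchor
        chrom_seq = genome_seqs[iv.chrom]
        lo = anchor - flank
        hi = anchor + flank
        pad_left = max(0, -lo)
        seq = "N" * pad_left + chrom_seq[max(lo, 0) : hi]
        seq = seq + "N" * (2 * flank - len(seq))
        for pwm in pwms:
            hits = scan(seq, pwm)
            if hits:
                presence.iloc[i, presence.columns.get_loc(pwm.name)] = True
            for off, _strand, _score in hits:
                midpoint = off + len(pwm) // 2 - flank  # offset from summit
                b = (midpoint + flank) // bin
                if 0 <= b < n_bins:
                    counts.iloc[b, counts.columns.get_loc(pwm.name)] += 1
    if n_no_summit:
        logger.info("%d peaks lacked a summit; midpoint used", n_no_summit)
    return MotifHistogram(bin_edges=edges, counts=counts, presence=presence)


def combinatorial_content(
    peaks: PeakSet,
    genome_seqs: dict[str, str],
    pwmA: Pwm,
    pwmB: Pwm,
    flank: int = 1000,
) -> dict[str, float]:
    """Per-peak presence of two motifs within +/-flank of the summit.

    Returns the four disjoint proportions (a_only, b_only, both, neither),
    which sum to 1 over nonempty input.
    """
    hist = summit_histogram(peaks, genome_seqs, [pwmA, pwmB], flank=flank, bin=flank)
    a = hist.presence[pwmA.name].to_numpy()
    b = hist.presence[pwmB.name].to_numpy()
    n = len(peaks)
    if n == 0:
        return {"a_only": 0.0, "b_only": 0.0, "both": 0.0, "neither": 0.0}
    return {
        "a_only": float((a & ~b).sum() / n),
        "b_only": float((~a & b).sum() / n),
        "both": float((a & b).sum() / n),
        "neither": float((~a & ~b).sum() / n),
    }
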