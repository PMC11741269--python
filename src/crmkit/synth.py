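"""Seeded synthetic-data generators with planted ground truth.

Every pipeline input — genome/gene annotation, stage-resolved TF peak sets
with known temporal classes, a coverage track with planted super-enhancer
loci, wild-type/morphant count tables with planted direct targets, a
clustered single-nucleus count matrix with planted "robust" genes and
cluster markers, and summit-centered sequences with planted motif sites —
can be generated from a single integer seed, so that each downstream stage
is testable against exactly known truth without any external download.

All generators are pure functions of (seed, parameters). A global seed fans
out to per-generator child streams through numpy SeedSequence spawn keys
(one fixed key per generator, listed in CHILD_KEYS).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd

from .dynamics import ALL_PATTERNS, ROMAN_CLASS_MAP
from .intervals import GeneAnnotation, GenomicInterval, PeakSet, SignalTrack

__all__ = [
    "CHILD_KEYS",
    "child_rng",
    "SyntheticTruth",
    "gen_genome_and_genes",
    "gen_stage_peaks",
    "gen_enhancer_peaks",
    "gen_signal_with_ses",
    "gen_morphant_counts",
    "gen_sc_matrix",
    "gen_peak_sequences",
    "gen_cooccupancy_peaks",
    "gen_target_effects",
    "genes_near",
    "DEFAULT_CLUSTERS",
]

# fixed spawn key per generator: the documented fan-out of the global seed
CHILD_KEYS = {
    "genome": 0,
    "stage_peaks": 1,
    "enhancer_peaks": 2,
    "signal": 3,
    "morphant_wt": 4,
    "morphant_A": 5,
    "morphant_B": 6,
    "sc_matrix": 7,
    "sequences": 8,
    "base_means": 9,
    "cooccupancy": 10,
    "targets": 11,
}

# 13 cell states: 5 ectodermal, 4 mesodermal, 4 endodermal (INP = inner
# neural plate, INPB = its border, INNE/ONNE = inner/outer non-neural
# ectoderm, ONE = outer neural ectoderm)
DEFAULT_CLUSTERS = pd.DataFrame(
    {
        "cluster": [
            "INP", "INPB", "INNE", "ONE", "ONNE",
            "meso_1", "meso_2", "meso_3", "meso_4",
            "endo_1", "endo_2", "endo_3", "endo_4",
        ],
        "germ_layer": ["ectoderm"] * 5 + ["mesoderm"] * 4 + ["endoderm"] * 4,
        "proportion": [0.12, 0.10, 0.10, 0.08, 0.08,
                       0.07, 0.07, 0.06, 0.06,
                       0.07, 0.07, 0.06, 0.06],
    }
)


def child_rng(seed: int, generator: str) -> np.random.Generator:
    """Per-generator random stream derived from the one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(CHILD_KEYS[generator],))
    )


@dataclass
class SyntheticTruth:
    """Everything planted by the generators, JSON-serializable.

    Each field references records actually emitted by its generator; the
    parameter record plus the seed fully determine all outputs.
    """

    seed: int
    params: dict = field(default_factory=dict)
    peak_classes: list[dict] = field(default_factory=list)   # locus + class label
    se_loci: list[dict] = field(default_factory=list)        # planted SE spans
    direct_targets: dict[str, dict[str, float]] = field(default_factory=dict)
    robust_genes: list[str] = field(default_factory=list)
    cluster_markers: dict[str, list[str]] = field(default_factory=dict)
    motif_presence: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------


def _place_blocks(
    rng: np.random.Generator, chrom_len: int, lengths: np.ndarray
) -> np.ndarray:
    """Non-overlapping start positions for blocks of given lengths.

    Distributes the free space uniformly: equivalent to dropping the blocks
    into the chromosome without overlap. Raises when they cannot fit.
    """
    total = int(lengths.sum())
    free = chrom_len - total
    if free < 0:
        raise ValueError(
            f"cannot place {len(lengths)} blocks of total length {total} "
            f"in a chromosome of length {chrom_len}"
        )
    cuts = np.sort(rng.integers(0, free + 1, size=len(lengths)))
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return cuts + offsets


def _split_counts(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


# ---------------------------------------------------------------------------
# genome and genes
# ---------------------------------------------------------------------------


def gen_genome_and_genes(
    seed: int,
    n_chroms: int = 4,
    chrom_len: int = 10_000_000,
    n_genes: int = 800,
    gene_len_range: tuple[int, int] = (2_000, 8_000),
) -> tuple[GeneAnnotation, dict[str, int]]:
    """Uniformly placed, non-overlapping genes with random strands."""
    rng = child_rng(seed, "genome")
    chrom_sizes = {f"chr{i + 1}": chrom_len for i in range(n_chroms)}
    rows = []
    counts = _split_counts(n_genes, n_chroms)
    gi = 0
    for chrom, k in zip(chrom_sizes, counts):
        if k == 0:
            continue
        lengths = rng.integers(gene_len_range[0], gene_len_range[1] + 1, size=k)
        starts = _place_blocks(rng, chrom_len, lengths)
        strands = rng.choice(np.array(["+", "-"]), size=k)
        for j in range(k):
            gi += 1
            rows.append(
                (f"g{gi:05d}", chrom, int(starts[j]), int(starts[j] + lengths[j]),
                 str(strands[j]))
            )
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GeneAnnotation(df), chrom_sizes


# ---------------------------------------------------------------------------
# stage-resolved peaks with planted temporal classes
# ---------------------------------------------------------------------------


def gen_stage_peaks(
    seed: int,
    chrom_sizes: dict[str, int],
    class_counts: tuple[int, ...] = (60, 40, 30, 50, 40, 35, 45),
    peak_width: int = 400,
    stage_labels: tuple[str, str, str] = ("st8", "st9", "st10.5"),
) -> tuple[dict[str, PeakSet], SyntheticTruth]:
    """Three stage PeakSets whose loci realize the 7 temporal classes.

    ``class_counts`` follows the order of the 7 membership patterns sorted
    by (size, stages): stage1-only, stage2-only, stage3-only, the three
    pairs, then persistent. A multi-stage locus emits one peak per member
    stage, jittered by at most peak_width/4 so the stage peaks still
    overlap; loci are spaced far enough apart (>= 2 x peak_width between
    anchors) that peaks of different loci never touch.
    """
    if len(class_counts) != 7:
        raise ValueError("class_counts must have 7 entries")
    rng = child_rng(seed, "stage_peaks")
    n_loci = int(sum(class_counts))
    patterns: list[frozenset[int]] = []
    for pat, cnt in zip(ALL_PATTERNS, class_counts):
        patterns.extend([pat] * cnt)
    order = rng.permutation(n_loci)
    patterns = [patterns[i] for i in order]

    chroms = list(chrom_sizes)
    per_chrom = _split_counts(n_loci, len(chroms))
    block = 2 * peak_width  # anchor block guaranteeing cross-locus separation
    anchors: list[tuple[str, int]] = []
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        starts = _place_blocks(rng, chrom_sizes[chrom], np.full(k, 2 * block))
        for s in starts:
            anchors.append((chrom, int(s) + block))  # center of the block

    stage_ivs: dict[str, list[GenomicInterval]] = {s: [] for s in stage_labels}
    truth_rows = []
    half = peak_width // 2
    jmax = peak_width // 4
    for li, ((chrom, center), pat) in enumerate(zip(anchors, patterns)):
        for si in sorted(pat):
            jitter = int(rng.integers(-jmax, jmax + 1))
            start = center - half + jitter
            iv = GenomicInterval(
                chrom, start, start + peak_width,
                summit=start + half,
                score=float(np.round(rng.uniform(10, 1000), 2)),
                name=f"locus{li:05d}",
            )
            stage_ivs[stage_labels[si]].append(iv)
        truth_rows.append(
            {
                "chrom": chrom,
                "center": center,
                "pattern": sorted(pat),
                "class": ROMAN_CLASS_MAP[pat],
            }
        )
    peaksets = {s: PeakSet(s, ivs) for s, ivs in stage_ivs.items()}
    truth = SyntheticTruth(
        seed=seed,
        params={
            "class_counts": list(class_counts),
            "peak_width": peak_width,
            "stage_labels": list(stage_labels),
        },
        peak_classes=truth_rows,
    )
    return peaksets, truth


# ---------------------------------------------------------------------------
# enhancer landscape and planted super-enhancers
# ---------------------------------------------------------------------------


def gen_enhancer_peaks(
    seed: int,
    chrom_sizes: dict[str, int],
    n_peaks: int = 200,
    peak_width: int = 1_000,
    min_spacing: int = 30_000,
) -> PeakSet:
    """Isolated enhancer peaks spaced beyond any sane stitching gap, so each
    stitches to its own regular-enhancer locus."""
    rng = child_rng(seed, "enhancer_peaks")
    chroms = list(chrom_sizes)
    per_chrom = _split_counts(n_peaks, len(chroms))
    ivs = []
    block = peak_width + min_spacing
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        starts = _place_blocks(rng, chrom_sizes[chrom], np.full(k, block))
        for s in starts:
            s = int(s) + min_spacing // 2
            ivs.append(
                GenomicInterval(chrom, s, s + peak_width, summit=s + peak_width // 2)
            )
    return PeakSet("enhancers", ivs)


def gen_signal_with_ses(
    seed: int,
    peaks: PeakSet,
    chrom_sizes: dict[str, int],
    n_se: int = 5,
    se_span: int = 20_000,
    se_amp: float = 10.0,
    re_amp: float = 1.0,
    noise_sd: float = 0.25,
    n_se_constituents: int = 8,
    constituent_width: int = 1_000,
    noise_bin: int = 200,
    near_genes: GeneAnnotation | None = None,
    gene_offset: int = 5_000,
    avoid_tss: dict[str, np.ndarray] | None = None,
    tss_margin: int = 2_500,
) -> tuple[SignalTrack, PeakSet, SyntheticTruth]:
    """Coverage track over an enhancer landscape with planted SE clusters.

    Each planted SE is a cluster of ``n_se_constituents`` peaks spread over
    ~``se_span`` bp (the ~20 kb scale of embryonic super-enhancers) carrying
    amplitude ``se_amp``; the input peaks carry ``re_amp``. Gaussian noise
    of SD ``noise_sd`` (truncated at 0) perturbs the per-bin amplitude. SE
    clusters are placed at least 2 x 12,500 bp + span away from every other
    peak so default-gap stitching keeps them as separate loci.

    When ``near_genes`` is given, each SE span is planted ``gene_offset`` bp
    downstream of a distinct randomly chosen gene, so SE-to-gene linking has
    a planted answer; the chosen gene id is recorded with each SE span.

    Returns (track, all peaks including SE constituents, truth with the
    planted SE spans).
    """
    rng = child_rng(seed, "signal")
    margin = 2 * 12_500 + se_span
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for iv in peaks:
        occupied[iv.chrom].append((iv.start, iv.end))

    def conflicts(chrom: str, lo: int, hi: int) -> bool:
        if any(s - margin < hi and lo < e + margin for s, e in occupied[chrom]):
            return True
        if avoid_tss is not None:
            pos = avoid_tss.get(chrom)
            # keep TSSs out of the span so promoter exclusion cannot remove
            # planted constituents before stitching
            if pos is not None and np.any(
                (pos >= lo - tss_margin) & (pos < hi + tss_margin)
            ):
                return True
        return False

    se_spans: list[tuple[str, int, int, str | None]] = []
    chroms = list(chrom_sizes)
    attempts = 0
    used_genes: set[str] = set()
    gene_rows = list(near_genes.df.itertuples(index=False)) if near_genes is not None else []
    while len(se_spans) < n_se:
        attempts += 1
        if attempts > 10_000 * max(n_se, 1):
            raise ValueError("cannot place SE clusters: genome too crowded")
        if near_genes is not None:
            row = gene_rows[int(rng.integers(len(gene_rows)))]
            if row.gene_id in used_genes:
                continue
            chrom, lo, gid = row.chrom, int(row.end) + gene_offset, row.gene_id
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            lo = int(rng.integers(margin, chrom_sizes[chrom] - se_span - margin))
            gid = None
        if lo < 0 or lo + se_span > chrom_sizes[chrom]:
            continue
        if not conflicts(chrom, lo, lo + se_span):
            se_spans.append((chrom, lo, lo + se_span, gid))
            occupied[chrom].append((lo, lo + se_span))
            if gid is not None:
                used_genes.add(gid)

    gap = (
        (se_span - n_se_constituents * constituent_width) // max(n_se_constituents - 1, 1)
        if n_se_constituents > 1 else 0
    )
    all_ivs = list(peaks)
    se_constituents: list[GenomicInterval] = []
    for si, (chrom, lo, hi, _gid) in enumerate(se_spans):
        for j in range(n_se_constituents):
            s = lo + j * (constituent_width + gap)
            iv = GenomicInterval(
                chrom, s, s + constituent_width,
                summit=s + constituent_width // 2, name=f"se{si}",
            )
            se_constituents.append(iv)
            all_ivs.append(iv)

    track = SignalTrack()
    runs: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_sizes}

    def add_peak_signal(iv: GenomicInterval, amp: float) -> None:
        for s in range(iv.start, iv.end, noise_bin):
            e = min(s + noise_bin, iv.end)
            v = amp + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            runs[iv.chrom].append((s, e, max(v, 0.0)))

    for iv in peaks:
        add_peak_signal(iv, re_amp)
    for iv in se_constituents:
        add_peak_signal(iv, se_amp)
    for chrom, rr in runs.items():
        if rr:
            s, e, v = zip(*sorted(rr))
            track.add_runs(chrom, s, e, v)

    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_se": n_se, "se_span": se_span, "se_amp": se_amp,
            "re_amp": re_amp, "noise_sd": noise_sd,
            "n_se_constituents": n_se_constituents,
            "constituent_width": constituent_width,
        },
        se_loci=[
            {"chrom": c, "start": s, "end": e, "gene_id": g}
            for c, s, e, g in se_spans
        ],
    )
    return track, PeakSet("enhancers+se", all_ivs), truth


# ---------------------------------------------------------------------------
# co-occupancy: second TF and coactivator derived from a reference peak set
# ---------------------------------------------------------------------------


def gen_cooccupancy_peaks(
    seed: int,
    tfA: PeakSet,
    chrom_sizes: dict[str, int],
    n_cobound: int = 60,
    n_fse: int = 40,
    n_b_unique: int = 50,
    n_coact_only: int = 30,
    peak_width: int = 400,
) -> tuple[PeakSet, PeakSet, SyntheticTruth]:
    """A second TF and a coactivator with planted co-occupancy structure.

    ``n_cobound`` of tfA's peaks get an overlapping (jitter <= width/4) tfB
    peak; ``n_fse`` of those co-bound sites additionally get a coactivator
    peak (the planted fully co-occupied regions). ``n_b_unique`` tfB peaks
    and ``n_coact_only`` coactivator peaks are placed in free space, far from
    everything else.
    """
    if n_fse > n_cobound or n_cobound > len(tfA):
        raise ValueError("need n_fse <= n_cobound <= len(tfA)")
    rng = child_rng(seed, "cooccupancy")
    jmax = peak_width // 4
    a_ivs = list(tfA)
    picked = rng.choice(len(a_ivs), size=n_cobound, replace=False)
    fse_pick = set(picked[:n_fse].tolist())

    def jittered(iv: GenomicInterval, name: str) -> GenomicInterval:
        j = int(rng.integers(-jmax, jmax + 1))
        w = iv.width
        return GenomicInterval(
            iv.chrom, iv.start + j, iv.start + j + w,
            summit=iv.start + j + w // 2, name=name,
        )

    b_ivs = [jittered(a_ivs[i], "cobound") for i in picked]
    coact_ivs = [jittered(a_ivs[i], "fse") for i in picked if i in fse_pick]

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for iv in list(tfA) + b_ivs + coact_ivs:
        occupied[iv.chrom].append((iv.start, iv.end))
    margin = 4 * peak_width
    chroms = list(chrom_sizes)

    def place_free(n: int, name: str) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 20_000 * max(n, 1):
                raise ValueError("cannot place unique peaks: genome too crowded")
            chrom = chroms[int(rng.integers(len(chroms)))]
            s = int(rng.integers(0, chrom_sizes[chrom] - peak_width))
            if any(a - margin < s + peak_width and s < b + margin
                   for a, b in occupied[chrom]):
                continue
            iv = GenomicInterval(chrom, s, s + peak_width,
                                 summit=s + peak_width // 2, name=name)
            out.append(iv)
            occupied[chrom].append((s, s + peak_width))
        return out

    b_ivs += place_free(n_b_unique, "b_unique")
    coact_ivs += place_free(n_coact_only, "coact_only")
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_cobound": n_cobound, "n_fse": n_fse,
            "n_b_unique": n_b_unique, "n_coact_only": n_coact_only,
        },
    )
    return PeakSet("tfB", b_ivs), PeakSet("coact", coact_ivs), truth


# ---------------------------------------------------------------------------
# direct-target planting
# ---------------------------------------------------------------------------


def genes_near(genes: GeneAnnotation, peaks: PeakSet, window: int = 20_000) -> set[str]:
    """Gene ids that are the nearest gene of at least one peak within window.

    Generator-side arithmetic mirroring the peak-to-gene assignment rule
    (edge-to-edge gap, 0 on overlap; nearest gene wins, ties by lexicographic
    id), so planted targets are exactly recoverable by assignment-based
    target calling.
    """
    out: set[str] = set()
    gene_rows: dict[str, list] = {}
    for row in genes.df.itertuples(index=False):
        gene_rows.setdefault(row.chrom, []).append(row)
    for iv in peaks:
        best_gap, best_id = None, None
        for row in gene_rows.get(iv.chrom, []):
            gap = max(iv.start - row.end, row.start - iv.end, 0)
            if best_gap is None or gap < best_gap or (gap == best_gap and row.gene_id < best_id):
                best_gap, best_id = gap, row.gene_id
        if best_gap is not None and best_gap <= window:
            out.add(best_id)
    return out


def gen_target_effects(
    seed: int,
    genes: GeneAnnotation,
    peaksA: PeakSet,
    peaksB: PeakSet,
    window: int = 20_000,
    n_joint: int = 10,
    n_a_only: int = 15,
    n_b_only: int = 20,
    effect_lfc: float = 2.0,
    frac_repressed: float = 0.3,
) -> tuple[dict[str, float], dict[str, float], SyntheticTruth]:
    """Plant per-factor knockdown effects on genes with nearby binding.

    Joint targets draw genes near both factors' peaks; exclusive targets
    near exactly one factor's. Effects are signed log2 changes in the
    morphant of magnitude ``effect_lfc`` (negative = activated target,
    positive = repressed; a ``frac_repressed`` share is repressed).
    """
    rng = child_rng(seed, "targets")
    near_a = genes_near(genes, peaksA, window)
    near_b = genes_near(genes, peaksB, window)
    pools = {
        "joint": sorted(near_a & near_b),
        "A": sorted(near_a - near_b),
        "B": sorted(near_b - near_a),
    }
    wanted = {"joint": n_joint, "A": n_a_only, "B": n_b_only}
    for k, n in wanted.items():
        if len(pools[k]) < n:
            raise ValueError(
                f"only {len(pools[k])} candidate genes for {k!r} targets, need {n}"
            )
    effectsA: dict[str, float] = {}
    effectsB: dict[str, float] = {}
    rows = []
    for kind, n in wanted.items():
        chosen = rng.choice(np.array(pools[kind]), size=n, replace=False)
        for g in chosen:
            sign = 1.0 if rng.random() < frac_repressed else -1.0
            eff = sign * effect_lfc
            if kind in ("joint", "A"):
                effectsA[str(g)] = eff
            if kind in ("joint", "B"):
                effectsB[str(g)] = eff
            rows.append(
                {
                    "gene_id": str(g),
                    "attribution": kind,
                    "direction": "repressed" if sign > 0 else "activated",
                    "log2_effect": eff,
                }
            )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "window": window, "n_joint": n_joint, "n_a_only": n_a_only,
            "n_b_only": n_b_only, "effect_lfc": effect_lfc,
            "frac_repressed": frac_repressed,
        },
        direct_targets={
            r["gene_id"]: {
                "attribution": r["attribution"],
                "direction": r["direction"],
                "log2_effect": r["log2_effect"],
            }
            for r in rows
        },
    )
    return effectsA, effectsB, truth


# ---------------------------------------------------------------------------
# morphant RNA-seq counts
# ---------------------------------------------------------------------------


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float, n_reps: int
) -> np.ndarray:
    """Gamma-Poisson draws with Var = mu + dispersion * mu^2."""
    mu = np.repeat(means[:, None], n_reps, axis=1)
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def gen_morphant_counts(
    seed: int,
    gene_ids: list[str],
    effects: dict[str, float],
    n_reps: int = 3,
    dispersion: float = 0.05,
    mean_range: tuple[float, float] = (50.0, 2000.0),
    base_means: np.ndarray | None = None,
    stream: str = "morphant_A",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wild-type and morphant negative-binomial count tables.

    ``effects`` maps planted target genes to signed log2 effects of the
    knockdown: the morphant mean is wild-type mean x 2^effect, so negative
    effects mark genes the factor activates (down in the morphant) and
    positive effects genes it represses. All other genes are null.
    ``base_means`` lets two factors share one wild-type expression baseline.
    """
    if n_reps < 2:
        raise ValueError("need n_reps >= 2")
    rng = child_rng(seed, stream)
    n = len(gene_ids)
    if base_means is None:
        mrng = child_rng(seed, "base_means")
        base_means = np.exp(
            mrng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n)
        )
    eff = np.zeros(n)
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g, e in effects.items():
        eff[idx[g]] = e
    wt = _nb_counts(rng, base_means, dispersion, n_reps)
    mo = _nb_counts(rng, base_means * 2.0**eff, dispersion, n_reps)
    wt_df = pd.DataFrame(wt, index=gene_ids, columns=[f"wt_{i+1}" for i in range(n_reps)])
    mo_df = pd.DataFrame(mo, index=gene_ids, columns=[f"mo_{i+1}" for i in range(n_reps)])
    return wt_df, mo_df


# ---------------------------------------------------------------------------
# single-nucleus matrix
# ---------------------------------------------------------------------------


def gen_sc_matrix(
    seed: int,
    gene_ids: list[str],
    clusters: pd.DataFrame | None = None,
    robust_genes: list[str] | None = None,
    n_cells: int = 2_000,
    depth: float = 1.0,
    base_log_mean: float = -0.7,
    base_log_sd: float = 0.8,
    robust_mean_boost: float = 4.0,
    robust_log_sd: float = 0.25,
    n_markers_per_cluster: int = 2,
    marker_boost: float = 8.0,
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Clustered Poisson-lognormal single-nucleus counts.

    Per cell and gene, counts ~ Poisson(depth x exp(Normal(log m_g,
    sigma_g))). Background genes have lognormal cell-to-cell sigma
    ``base_log_sd``; planted robust genes get ``robust_mean_boost`` x the
    mean and the smaller ``robust_log_sd`` — elevated expression with
    depressed dispersion, the signature of super-enhancer-driven genes.
    Each cluster also receives ``n_markers_per_cluster`` planted marker
    genes boosted only within that cluster (for z-score localization tests).
    """
    if clusters is None:
        clusters = DEFAULT_CLUSTERS
    if not np.isclose(clusters["proportion"].sum(), 1.0):
        raise ValueError("cluster proportions must sum to 1")
    rng = child_rng(seed, "sc_matrix")
    genes = list(gene_ids)
    n_genes = len(genes)
    robust = list(robust_genes or [])
    missing = set(robust) - set(genes)
    if missing:
        raise ValueError(f"robust genes not in gene list: {sorted(missing)[:5]}")

    # per-gene baseline mean and cell-to-cell lognormal sigma
    log_mean = rng.normal(base_log_mean, 0.5, size=n_genes)
    sigma = np.full(n_genes, base_log_sd)
    gidx = {g: i for i, g in enumerate(genes)}
    for g in robust:
        log_mean[gidx[g]] += np.log(robust_mean_boost)
        sigma[gidx[g]] = robust_log_sd

    # disjoint cluster markers drawn from non-robust genes
    pool = [g for g in genes if g not in set(robust)]
    need = n_markers_per_cluster * len(clusters)
    if need > len(pool):
        raise ValueError("not enough genes to plant cluster markers")
    marker_genes = list(rng.choice(np.array(pool), size=need, replace=False))
    markers: dict[str, list[str]] = {}
    for i, row in enumerate(clusters.itertuples(index=False)):
        markers[row.cluster] = marker_genes[
            i * n_markers_per_cluster : (i + 1) * n_markers_per_cluster
        ]

    # cells per cluster: largest-remainder rounding to exactly n_cells
    props = clusters["proportion"].to_numpy()
    raw = props * n_cells
    ncell = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - ncell))[: n_cells - ncell.sum()]:
        ncell[i] += 1

    X = np.zeros((n_cells, n_genes), dtype=np.int64)
    labels: list[str] = []
    row0 = 0
    for (ci, crow), k in zip(enumerate(clusters.itertuples(index=False)), ncell):
        if k == 0:
            continue
        lm = log_mean.copy()
        for g in markers[crow.cluster]:
            lm[gidx[g]] += np.log(marker_boost)
        rates = depth * np.exp(rng.normal(lm, sigma, size=(k, n_genes)))
        X[row0 : row0 + k] = rng.poisson(rates)
        labels.extend([crow.cluster] * k)
        row0 += k

    adata = ad.AnnData(
        X=X.astype(np.float64),
        obs=pd.DataFrame(
            {"cluster": pd.Categorical(labels, categories=list(clusters["cluster"]))},
            index=[f"cell{i:05d}" for i in range(n_cells)],
        ),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_cells": n_cells, "depth": depth,
            "robust_mean_boost": robust_mean_boost,
            "robust_log_sd": robust_log_sd, "base_log_sd": base_log_sd,
            "marker_boost": marker_boost,
        },
        robust_genes=robust,
        cluster_markers=markers,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# sequences with planted motif sites
# ---------------------------------------------------------------------------


def gen_peak_sequences(
    seed: int,
    n_peaks: int = 100,
    length: int = 2_000,
    plant: dict[str, tuple[str, float]] | None = None,
    max_offset_from_center: int = 400,
) -> tuple[dict[str, str], PeakSet, SyntheticTruth]:
    """Random sequences, one per peak, with consensus sites planted.

    ``plant`` maps a motif name to (consensus string, fraction of peaks
    carrying the site). Sites land within ``max_offset_from_center`` of the
    summit, on a random strand, at non-clashing positions. Each peak lives
    on its own pseudo-chromosome ``seq####`` with the summit at the center.
    Chance occurrences of a planted consensus (either strand) elsewhere in
    a sequence are mutated away, so presence-of-motif truth is exact.
    """
    rng = child_rng(seed, "sequences")
    plant = plant or {}
    bases = np.array(list("ACGT"))
    rc = str.maketrans("ACGT", "TGCA")
    seqs: dict[str, str] = {}
    ivs = []
    presence: dict[str, list[int]] = {name: [] for name in plant}
    carrier_sets = {
        name: set(rng.choice(n_peaks, size=int(round(frac * n_peaks)), replace=False))
        for name, (_cons, frac) in plant.items()
    }
    next_base = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for i in range(n_peaks):
        seq = list(rng.choice(bases, size=length))
        center = length // 2
        planted_sites: dict[str, list[tuple[int, int]]] = {n: [] for n in plant}
        used: list[tuple[int, int]] = []
        for name, (cons, _frac) in plant.items():
            if i not in carrier_sets[name]:
                continue
            site = cons.upper()
            if rng.random() < 0.5:
                site = site.translate(rc)[::-1]
            for _ in range(100):
                off = center + int(
                    rng.integers(-max_offset_from_center, max_offset_from_center + 1)
                )
                if 0 <= off <= length - len(site) and all(
                    off + len(site) <= s or off >= e for s, e in used
                ):
                    break
            else:
                raise RuntimeError("could not place motif site without clash")
            seq[off : off + len(site)] = list(site)
            used.append((off, off + len(site)))
            planted_sites[name].append((off, off + len(site)))
            presence[name].append(i)
        # scrub chance occurrences so presence truth is exact
        dirty = True
        guard = 0
        while dirty:
            dirty = False
            guard += 1
            if guard > 50:
                raise RuntimeError("motif scrubbing did not converge")
            s = "".join(seq)
            for name, (cons, _frac) in plant.items():
                ok = set(planted_sites[name])
                for pat in {cons.upper(), cons.upper().translate(rc)[::-1]}:
                    start = s.find(pat)
                    while start != -1:
                        span = (start, start + len(pat))
                        if span not in ok:
                            for p in range(*span):
                                if all(p < a or p >= b for a, b in used):
                                    seq[p] = next_base[seq[p]]
                                    dirty = True
                                    break
                            else:
                                raise RuntimeError("chance motif inside planted sites")
                            s = "".join(seq)
                        start = s.find(pat, start + 1)
        chrom = f"seq{i:04d}"
        seqs[chrom] = "".join(seq)
        ivs.append(GenomicInterval(chrom, 0, length, summit=center, name=chrom))
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_peaks": n_peaks, "length": length,
            "plant": {k: [v[0], v[1]] for k, v in plant.items()},
        },
        motif_presence=presence,
    )
    return seqs, PeakSet("synthetic_peaks", ivs), truth
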