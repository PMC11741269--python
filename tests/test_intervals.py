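import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crmkit.intervals import (
    GenomicInterval,
    PeakSet,
    SignalTrack,
    aggregate_profile,
    merge,
    overlap_length,
    overlaps,
    read_bedgraph,
    read_gff3_genes,
    read_intervals,
    window_sum,
    write_bed,
    write_bedgraph,
)
from crmkit.intervals import FormatError, GeneAnnotation

# ---------------------------------------------------------------------------
# GenomicInterval / PeakSet basics
# ---------------------------------------------------------------------------


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 300, 300)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 300, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 100)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 100, 300, summit=300)


def test_anchor_is_summit_else_midpoint():
    assert GenomicInterval("chr1", 100, 300, summit=150).anchor == 150
    assert GenomicInterval("chr1", 100, 301).anchor == 200


def test_peakset_rejects_duplicates():
    iv = GenomicInterval("chr1", 0, 10)
    with pytest.raises(ValueError):
        PeakSet("x", [iv, GenomicInterval("chr1", 0, 10, name="other")])


# ---------------------------------------------------------------------------
# overlaps / merge
# ---------------------------------------------------------------------------


def test_overlaps_half_open_abutting_is_false():
    a = GenomicInterval("chr1", 100, 300)
    b = GenomicInterval("chr1", 300, 400)
    assert not overlaps(a, b)


def test_overlaps_min_bp_threshold():
    a = GenomicInterval("chr1", 100, 300)
    b = GenomicInterval("chr1", 250, 450)
    assert overlap_length(a, b) == 50
    assert overlaps(a, b, min_bp=1)
    assert overlaps(a, b, min_bp=50)
    assert not overlaps(a, b, min_bp=51)


def test_overlaps_different_chromosomes():
    a = GenomicInterval("chr1", 100, 300)
    b = GenomicInterval("chr2", 100, 300)
    assert not overlaps(a, b)


def test_merge_single_interval_unchanged():
    ps = PeakSet("x", [GenomicInterval("chr1", 5, 10)])
    out = merge(ps, max_gap=1_000_000)
    assert [(iv.start, iv.end) for iv in out] == [(5, 10)]


def test_merge_gap_boundary():
    ps = PeakSet("x", [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 5000, 6000)])
    merged = merge(ps, max_gap=4000)
    assert [(iv.start, iv.end) for iv in merged] == [(0, 6000)]
    two = merge(ps, max_gap=3999)
    assert len(two) == 2


iv_strategy = st.builds(
    lambda c, s, w: GenomicInterval(f"chr{c}", s, s + w),
    st.integers(1, 3), st.integers(0, 1000), st.integers(1, 100),
)


def _dedup(ivs):
    seen, out = set(), []
    for iv in ivs:
        k = (iv.chrom, iv.start, iv.end)
        if k not in seen:
            seen.add(k)
            out.append(iv)
    return out


@settings(max_examples=50, deadline=None)
@given(st.lists(iv_strategy, max_size=30), st.integers(0, 50))
def test_merge_idempotent_and_permutation_invariant(ivs, gap):
    ivs = _dedup(ivs)
    once = merge(PeakSet("x", ivs), max_gap=gap)
    twice = merge(once, max_gap=gap)
    spans = lambda ps: [(iv.chrom, iv.start, iv.end) for iv in ps]
    assert spans(once) == spans(twice)
    shuffled = merge(PeakSet("x", list(reversed(ivs))), max_gap=gap)
    assert spans(once) == spans(shuffled)
    # union of covered bases preserved
    covered = lambda ps: {(iv.chrom, p) for iv in ps for p in range(iv.start, iv.end)}
    assert covered(once) >= covered(PeakSet("x", ivs))
    # output pairwise separated by > gap
    by_chrom = once.by_chrom()
    for chrom_ivs in by_chrom.values():
        for a, b in zip(chrom_ivs, chrom_ivs[1:]):
            assert b.start - a.end > gap


@settings(max_examples=50, deadline=None)
@given(iv_strategy, iv_strategy, st.integers(1, 50))
def test_overlaps_symmetric(a, b, min_bp):
    assert overlaps(a, b, min_bp) == overlaps(b, a, min_bp)


# ---------------------------------------------------------------------------
# SignalTrack / window sums / profiles
# ---------------------------------------------------------------------------


def test_window_sum_empty_track_is_zero():
    assert window_sum(SignalTrack(), GenomicInterval("chr1", 0, 100)) == 0.0


def test_window_sum_constant_coverage():
    t = SignalTrack({"chr1": (np.array([0]), np.array([10000]), np.array([1.0]))})
    assert window_sum(t, GenomicInterval("chr1", 100, 300)) == 200.0


def test_window_sum_partial_run():
    t = SignalTrack({"chr1": (np.array([0]), np.array([150]), np.array([2.0]))})
    assert window_sum(t, GenomicInterval("chr1", 100, 300)) == 100.0


def test_window_sum_additive_over_partition():
    rng = np.random.default_rng(0)
    starts = np.arange(0, 1000, 50)
    t = SignalTrack({"chr1": (starts, starts + 40, rng.uniform(0, 5, len(starts)))})
    whole = window_sum(t, GenomicInterval("chr1", 10, 910))
    parts = sum(
        window_sum(t, GenomicInterval("chr1", s, s + 100)) for s in range(10, 910, 100)
    )
    assert whole == pytest.approx(parts)


def test_track_rejects_overlapping_runs():
    with pytest.raises(ValueError):
        SignalTrack({"chr1": (np.array([0, 5]), np.array([10, 15]), np.array([1.0, 1.0]))})


def test_aggregate_profile_zero_track():
    regions = PeakSet("r", [GenomicInterval("chr1", 1000, 1400, summit=1200)])
    mat, means = aggregate_profile(SignalTrack(), regions, flank=100, bin=20)
    assert mat.shape == (1, 10)
    assert not mat.any() and not means.any()


def test_aggregate_profile_uniform_value():
    t = SignalTrack({"chr1": (np.array([0]), np.array([100000]), np.array([1.0]))})
    regions = PeakSet("r", [GenomicInterval("chr1", 40000, 40400, summit=40200)])
    mat, means = aggregate_profile(t, regions, flank=1000, bin=20)
    assert np.all(mat == 20.0)
    assert np.all(means == 20.0)


def test_aggregate_profile_column_count_at_25kb():
    t = SignalTrack()
    regions = PeakSet("r", [GenomicInterval("chr1", 50000, 50001)])
    mat, _ = aggregate_profile(t, regions, flank=25000, bin=100)
    assert mat.shape[1] == 500


def test_aggregate_profile_left_edge_zero_padded():
    t = SignalTrack({"chr1": (np.array([0]), np.array([1000]), np.array([3.0]))})
    regions = PeakSet("r", [GenomicInterval("chr1", 0, 10, summit=0)])
    mat, _ = aggregate_profile(t, regions, flank=100, bin=10)
    assert mat.shape == (1, 20)
    assert np.all(mat[0, :10] == 0.0)  # windows before base 0 pad with zeros
    assert np.all(mat[0, 10:] == 30.0)


def test_aggregate_profile_column_means_oracle():
    rng = np.random.default_rng(1)
    starts = np.arange(0, 5000, 100)
    t = SignalTrack({"chr1": (starts, starts + 80, rng.uniform(0, 2, len(starts)))})
    regions = PeakSet(
        "r", [GenomicInterval("chr1", s, s + 50, summit=s + 25) for s in range(1000, 3000, 500)]
    )
    mat, means = aggregate_profile(t, regions, flank=200, bin=20)
    assert means == pytest.approx(mat.mean(axis=0))
    # brute-force per-bin sums
    for i, iv in enumerate(regions):
        for b in range(mat.shape[1]):
            lo = iv.anchor - 200 + b * 20
            assert mat[i, b] == pytest.approx(
                window_sum(t, GenomicInterval("chr1", max(lo, 0), lo + 20))
                if lo + 20 > 0 else 0.0
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_read_bed3(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t300\n")
    ps = read_intervals(p)
    assert len(ps) == 1
    iv = ps[0]
    assert (iv.chrom, iv.start, iv.end, iv.summit) == ("chr1", 100, 300, None)


def test_read_narrowpeak_summit_offset(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text("chr1\t100\t300\tpeak1\t500\t.\t8.5\t12.0\t10.0\t50\n")
    iv = read_intervals(p, dialect="narrowPeak")[0]
    assert iv.summit == 150
    p.write_text("chr1\t100\t300\tpeak1\t500\t.\t8.5\t12.0\t10.0\t-1\n")
    assert read_intervals(p, dialect="narrowPeak")[0].summit is None


def test_read_empty_file_gives_empty_peakset(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("")
    assert len(read_intervals(p)) == 0


def test_malformed_bed_names_line_number(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t300\nchr1\tnope\t400\n")
    with pytest.raises(FormatError, match="line 2"):
        read_intervals(p)


def test_bed_round_trip(tmp_path):
    ps = PeakSet("x", [GenomicInterval("chr2", 5, 9, name="a", score=7.0),
                       GenomicInterval("chr1", 0, 10)])
    path = tmp_path / "out.bed"
    write_bed(ps, path)
    back = read_intervals(path)
    assert [(iv.chrom, iv.start, iv.end) for iv in back] == [
        ("chr1", 0, 10), ("chr2", 5, 9)
    ]


def test_bedgraph_round_trip(tmp_path):
    t = SignalTrack({"chr1": (np.array([0, 100]), np.array([50, 200]),
                              np.array([1.5, 2.0]))})
    path = tmp_path / "sig.bedgraph"
    write_bedgraph(t, path)
    back = read_bedgraph(path)
    s, e, v = back.runs("chr1")
    assert list(s) == [0, 100] and list(e) == [50, 200] and list(v) == [1.5, 2.0]


def test_gff3_round_trip_and_tss_strand(tmp_path):
    import pandas as pd

    ann = GeneAnnotation(pd.DataFrame({
        "gene_id": ["gA", "gB"],
        "chrom": ["chr1", "chr1"],
        "start": [100, 500],
        "end": [200, 700],
        "strand": ["+", "-"],
    }))
    assert dict(zip(ann.df["gene_id"], ann.df["tss"])) == {"gA": 100, "gB": 699}
    path = tmp_path / "genes.gff3"
    ann.to_gff3(path)
    back = read_gff3_genes(path)
    assert back.df[["gene_id", "chrom", "start", "end", "strand", "tss"]].equals(
        ann.df[["gene_id", "chrom", "start", "end", "strand", "tss"]]
    )


def test_gff3_missing_id_errors(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text("chr1\tsrc\tgene\t1\t100\t.\t+\t.\tName=x\n")
    with pytest.raises(FormatError, match="line 1"):
        read_gff3_genes(p)
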