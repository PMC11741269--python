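import numpy as np
import pandas as pd
import pytest

from crmkit.dynamics import temporal_classify
from crmkit.intervals import GenomicInterval, window_sum
from crmkit.motifs import Pwm, scan
from crmkit.superenhancers import call_super_enhancers
from crmkit.synth import (
    DEFAULT_CLUSTERS,
    child_rng,
    gen_cooccupancy_peaks,
    gen_genome_and_genes,
    gen_morphant_counts,
    gen_peak_sequences,
    gen_sc_matrix,
    gen_signal_with_ses,
    gen_stage_peaks,
    gen_target_effects,
    genes_near,
)
from crmkit.targets import assign_peaks_to_genes
from crmkit.expression import cov_per_gene

SIZES = {"chr1": 2_000_000, "chr2": 2_000_000}


def test_child_streams_differ_and_are_deterministic():
    a = child_rng(0, "genome").integers(0, 1_000_000, 5)
    b = child_rng(0, "genome").integers(0, 1_000_000, 5)
    c = child_rng(0, "stage_peaks").integers(0, 1_000_000, 5)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def test_gen_genome_deterministic_gff3(tmp_path):
    g1, _ = gen_genome_and_genes(3, n_chroms=2, chrom_len=1_000_000, n_genes=40)
    g2, _ = gen_genome_and_genes(3, n_chroms=2, chrom_len=1_000_000, n_genes=40)
    p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
    g1.to_gff3(p1)
    g2.to_gff3(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_gen_genome_zero_genes():
    g, sizes = gen_genome_and_genes(0, n_genes=0)
    assert len(g) == 0 and len(sizes) == 4


def test_gen_genome_counts_and_unique_ids():
    g, sizes = gen_genome_and_genes(1, n_chroms=2, chrom_len=5_000_000, n_genes=100)
    assert len(g) == 100
    assert g.df["gene_id"].is_unique
    assert set(g.df["chrom"]) == {"chr1", "chr2"}
    # genes do not overlap within a chromosome
    for _, sub in g.df.groupby("chrom"):
        s = sub.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()


# ---------------------------------------------------------------------------
# stage peaks
# ---------------------------------------------------------------------------


def test_stage_peaks_reclassification_recovers_all_patterns():
    peaks, truth = gen_stage_peaks(5, SIZES, class_counts=(1,) * 7)
    labels = list(peaks)
    a = temporal_classify(peaks[labels[0]], peaks[labels[1]], peaks[labels[2]])
    assert sorted(a.labels()) == sorted(r["class"] for r in truth.peak_classes)
    assert len(a.loci) == 7


def test_stage_peaks_zero_counts():
    peaks, _ = gen_stage_peaks(5, SIZES, class_counts=(0,) * 7)
    assert all(len(ps) == 0 for ps in peaks.values())


def test_stage_peaks_persistent_only_mutual_overlap():
    peaks, _ = gen_stage_peaks(5, SIZES, class_counts=(0, 0, 0, 0, 0, 0, 10))
    sets = list(peaks.values())
    assert all(len(ps) == 10 for ps in sets)
    a = temporal_classify(*sets)
    assert a.labels() == ["VII"] * 10


def test_stage_peaks_class_counts_honored():
    counts = (3, 2, 4, 1, 2, 3, 5)
    peaks, truth = gen_stage_peaks(8, SIZES, class_counts=counts)
    labels = list(peaks)
    a = temporal_classify(peaks[labels[0]], peaks[labels[1]], peaks[labels[2]])
    got = a.class_counts()
    want = pd.Series([r["class"] for r in truth.peak_classes]).value_counts()
    assert all(got[k] == want.get(k, 0) for k in got)
    assert sum(got.values()) == sum(counts)


# ---------------------------------------------------------------------------
# signal / super-enhancers
# ---------------------------------------------------------------------------


def test_signal_no_ses_closed_form():
    from crmkit.synth import gen_enhancer_peaks

    peaks = gen_enhancer_peaks(2, SIZES, n_peaks=20, peak_width=1000)
    track, all_peaks, _ = gen_signal_with_ses(
        2, peaks, SIZES, n_se=0, noise_sd=0.0, re_amp=1.5
    )
    assert len(all_peaks) == len(peaks)
    for iv in peaks:
        assert window_sum(track, iv) == pytest.approx(1.5 * iv.width)


def test_signal_planted_ses_top_ranked():
    from crmkit.synth import gen_enhancer_peaks

    sizes = {"chr1": 5_000_000, "chr2": 5_000_000}
    peaks = gen_enhancer_peaks(4, sizes, n_peaks=40)
    track, all_peaks, truth = gen_signal_with_ses(
        4, peaks, sizes, n_se=5, se_amp=10.0, re_amp=1.0, noise_sd=0.0
    )
    ranking = call_super_enhancers(all_peaks, track, tss=None)
    se = ranking.se_loci
    assert len(se) == 5
    planted = {(d["chrom"], d["start"]) for d in truth.se_loci}
    assert {(iv.chrom, iv.start) for iv in se} == planted


def test_signal_same_seed_identical():
    from crmkit.synth import gen_enhancer_peaks

    peaks = gen_enhancer_peaks(2, SIZES, n_peaks=10)
    t1, _, _ = gen_signal_with_ses(2, peaks, SIZES, n_se=1, noise_sd=0.3)
    t2, _, _ = gen_signal_with_ses(2, peaks, SIZES, n_se=1, noise_sd=0.3)
    for chrom in t1.chroms:
        for a, b in zip(t1.runs(chrom), t2.runs(chrom)):
            assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# morphant counts
# ---------------------------------------------------------------------------


def test_morphant_null_genes_small_lfc_and_determinism():
    genes = [f"g{i:04d}" for i in range(500)]
    wt, mo = gen_morphant_counts(6, genes, effects={}, n_reps=3)
    wt2, mo2 = gen_morphant_counts(6, genes, effects={}, n_reps=3)
    assert wt.equals(wt2) and mo.equals(mo2)
    lfc = np.log2((mo.mean(axis=1) + 1) / (wt.mean(axis=1) + 1))
    assert abs(lfc.mean()) < 0.05
    assert np.percentile(np.abs(lfc), 99) < 1.0


def test_morphant_planted_effect_converges():
    genes = [f"g{i:04d}" for i in range(50)]
    base = np.full(50, 5_000.0)
    wt, mo = gen_morphant_counts(
        7, genes, effects={"g0000": -2.0}, n_reps=20, dispersion=1e-6, base_means=base
    )
    lfc = np.log2(mo.loc["g0000"].mean() / wt.loc["g0000"].mean())
    assert lfc == pytest.approx(-2.0, abs=0.05)


def test_morphant_requires_two_replicates():
    with pytest.raises(ValueError):
        gen_morphant_counts(0, ["g1"], {}, n_reps=1)


# ---------------------------------------------------------------------------
# single-nucleus matrix
# ---------------------------------------------------------------------------


def test_sc_matrix_zero_cells():
    adata, _ = gen_sc_matrix(0, [f"g{i}" for i in range(30)], n_cells=0)
    assert adata.n_obs == 0 and adata.n_vars == 30


def test_sc_matrix_cluster_sizes_and_labels():
    adata, truth = gen_sc_matrix(1, [f"g{i}" for i in range(50)], n_cells=260)
    assert adata.n_obs == 260
    assert list(adata.obs["cluster"].cat.categories) == list(DEFAULT_CLUSTERS["cluster"])
    assert set(truth.cluster_markers) == set(DEFAULT_CLUSTERS["cluster"])


def test_sc_matrix_marker_localizes_to_its_cluster():
    from crmkit.expression import zscore_localization

    genes = [f"g{i:03d}" for i in range(60)]
    adata, truth = gen_sc_matrix(2, genes, n_cells=1300)
    for cluster, markers in list(truth.cluster_markers.items())[:4]:
        z, _ = zscore_localization(adata, markers)
        for g in markers:
            assert z.loc[g].idxmax() == cluster


def test_sc_matrix_robust_genes_have_lower_cov():
    genes = [f"g{i:03d}" for i in range(100)]
    robust = genes[:10]
    adata, truth = gen_sc_matrix(3, genes, robust_genes=robust, n_cells=1000)
    cov = cov_per_gene(adata, min_mean=0.001)
    r = cov.loc[cov.index.intersection(robust), "cov"].mean()
    b = cov.loc[cov.index.difference(robust), "cov"].mean()
    assert r < b


def test_sc_matrix_rejects_bad_proportions_and_unknown_robust():
    bad = DEFAULT_CLUSTERS.copy()
    bad.loc[0, "proportion"] = 0.5
    with pytest.raises(ValueError):
        gen_sc_matrix(0, ["g1"], clusters=bad)
    with pytest.raises(ValueError):
        gen_sc_matrix(0, ["g1"], robust_genes=["ghost"], n_cells=10)


# ---------------------------------------------------------------------------
# sequences with planted motifs
# ---------------------------------------------------------------------------


def test_peak_sequences_presence_truth_is_exact():
    fox = "TGTTTAC"
    seqs, peaks, truth = gen_peak_sequences(
        9, n_peaks=40, length=600, plant={"FOX": (fox, 0.5)}
    )
    pwm = Pwm.from_consensus("FOX", fox)
    planted = set(truth.motif_presence["FOX"])
    assert len(planted) == 20  # round(0.5 * 40)
    for i, (chrom, seq) in enumerate(sorted(seqs.items())):
        assert bool(scan(seq, pwm)) == (i in planted)


def test_peak_sequences_deterministic():
    s1, _, _ = gen_peak_sequences(4, n_peaks=5, length=300, plant={"F": ("TGTTTAC", 1.0)})
    s2, _, _ = gen_peak_sequences(4, n_peaks=5, length=300, plant={"F": ("TGTTTAC", 1.0)})
    assert s1 == s2


# ---------------------------------------------------------------------------
# co-occupancy and target planting
# ---------------------------------------------------------------------------


def test_cooccupancy_planted_structure():
    from crmkit.dynamics import co_occupancy, fse_regions

    stage_peaks, _ = gen_stage_peaks(11, SIZES, class_counts=(0, 0, 40, 0, 0, 0, 0))
    tfa = stage_peaks[list(stage_peaks)[2]]
    tfb, coact, _ = gen_cooccupancy_peaks(
        11, tfa, SIZES, n_cobound=20, n_fse=12, n_b_unique=10, n_coact_only=5
    )
    assert len(tfb) == 30 and len(coact) == 17
    calls = co_occupancy(tfa, tfb, coact)
    assert sum(c.is_cobound for c in calls) == 20
    assert len(fse_regions(calls)) == 12


def test_target_effects_respect_binding_structure():
    genes, sizes = gen_genome_and_genes(12, n_chroms=2, chrom_len=4_000_000, n_genes=300)
    stage_peaks, _ = gen_stage_peaks(12, sizes, class_counts=(0, 0, 60, 0, 0, 0, 0))
    tfa = stage_peaks[list(stage_peaks)[2]]
    tfb, _, _ = gen_cooccupancy_peaks(
        12, tfa, sizes, n_cobound=30, n_fse=10, n_b_unique=40, n_coact_only=5
    )
    effA, effB, truth = gen_target_effects(
        12, genes, tfa, tfb, n_joint=4, n_a_only=5, n_b_only=6
    )
    assert len(truth.direct_targets) == 15
    near_a = genes_near(genes, tfa, 20_000)
    near_b = genes_near(genes, tfb, 20_000)
    for g, rec in truth.direct_targets.items():
        if rec["attribution"] == "joint":
            assert g in near_a and g in near_b and g in effA and g in effB
        elif rec["attribution"] == "A":
            assert g in near_a and g not in near_b and g in effA and g not in effB
        else:
            assert g in near_b and g not in near_a and g in effB and g not in effA


def test_genes_near_matches_assignment_rule():
    genes, sizes = gen_genome_and_genes(13, n_chroms=2, chrom_len=3_000_000, n_genes=200)
    stage_peaks, _ = gen_stage_peaks(13, sizes, class_counts=(0, 0, 30, 0, 0, 0, 0))
    peaks = stage_peaks[list(stage_peaks)[2]]
    assigned = set(assign_peaks_to_genes(peaks, genes, window=20_000)["gene_id"])
    assert genes_near(genes, peaks, 20_000) == assigned
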