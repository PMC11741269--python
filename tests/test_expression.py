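import anndata as ad
import numpy as np
import pandas as pd
import pytest

from crmkit.expression import (
    cov_per_gene,
    ddcp_fold_change,
    percent_input,
    qc_filter,
    robustness_contrast,
    se_gene_linking,
    zscore_localization,
)
from crmkit.intervals import GeneAnnotation, GenomicInterval, PeakSet, SignalTrack
from crmkit.superenhancers import find_cutoff, rank_loci

# ---------------------------------------------------------------------------
# qPCR arithmetic
# ---------------------------------------------------------------------------


def test_percent_input_hand_values():
    assert percent_input(30, 25, 1) == pytest.approx(3.125)
    assert percent_input(28, 27, 2) == pytest.approx(25.0)
    # CpChIP equal to dilution-corrected input -> 100%
    assert percent_input(24.0, 25.0, 2.0) == pytest.approx(100.0)


def test_percent_input_rejects_dilution_below_one():
    with pytest.raises(ValueError):
        percent_input(30, 25, 0.5)


def test_ddcp_scalar_values():
    assert ddcp_fold_change((20.0, 18.0), (20.0, 18.0)).fold_change == pytest.approx(1.0)
    # ddCp = -2 -> fold 4
    assert ddcp_fold_change((18.0, 18.0), (20.0, 18.0)).fold_change == pytest.approx(4.0)
    # ddCp = +1 -> fold 0.5
    assert ddcp_fold_change((21.0, 18.0), (20.0, 18.0)).fold_change == pytest.approx(0.5)


def test_ddcp_replicates_give_sd_and_pvalue():
    res = ddcp_fold_change(
        (np.array([18.0, 18.2, 17.8]), np.array([18.0, 18.0, 18.0])),
        (np.array([20.0, 20.1, 19.9]), np.array([18.0, 18.0, 18.0])),
    )
    assert res.fold_change == pytest.approx(4.0, rel=0.05)
    assert res.sd is not None and res.sd > 0
    assert res.pvalue is not None and 0 < res.pvalue < 0.05


# ---------------------------------------------------------------------------
# single-nucleus statistics
# ---------------------------------------------------------------------------


def _adata(X, clusters):
    X = np.asarray(X, dtype=np.float64)
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(
            {"cluster": pd.Categorical(clusters)},
            index=[f"c{i}" for i in range(X.shape[0])],
        ),
        var=pd.DataFrame(index=pd.Index([f"g{j}" for j in range(X.shape[1])])),
    )


def test_qc_filter_cutoff_zero_is_identity():
    a = _adata([[1, 0], [0, 2]], ["x", "y"])
    out = qc_filter(a, min_genes_per_cell=0)
    assert out.shape == a.shape


def test_qc_filter_boundary_and_gene_cascade():
    # cell0 detects 2 genes, cell1 detects 1 (below cutoff 2); gene g2 only in cell1
    a = _adata([[1, 1, 0], [0, 0, 5]], ["x", "y"])
    out = qc_filter(a, min_genes_per_cell=2)
    assert list(out.obs_names) == ["c0"]
    assert list(out.var_names) == ["g0", "g1"]  # g2 cascaded away


def test_qc_filter_all_cells_removed_errors():
    a = _adata([[1, 0], [0, 1]], ["x", "y"])
    with pytest.raises(ValueError):
        qc_filter(a, min_genes_per_cell=10)


def _equal_depth_adata(log_values, clusters):
    """One cell per entry; gene g0 has given log1p values; filler gene g1
    equalizes each cell's total so depth normalization is the identity."""
    lin = np.expm1(np.asarray(log_values, dtype=np.float64))
    total = lin.max() + 100.0
    X = np.stack([lin, total - lin], axis=1)
    return _adata(X, clusters)


def test_zscore_hand_arithmetic_cluster_means_0_0_10():
    a = _equal_depth_adata([0.0, 0.0, 10.0], ["c1", "c2", "c3"])
    z, set_score = zscore_localization(a, ["g0"])
    assert np.allclose(z.loc["g0"], [-0.577, -0.577, 1.155], atol=1e-3)
    assert np.allclose(set_score, z.loc["g0"])


def test_zscore_constant_gene_is_zero():
    a = _equal_depth_adata([2.0, 2.0, 2.0], ["c1", "c2", "c3"])
    z, _ = zscore_localization(a, ["g0"])
    assert np.allclose(z.loc["g0"], 0.0)


def test_zscore_missing_gene_warns_and_sums_to_zero(caplog):
    rng = np.random.default_rng(0)
    a = _adata(rng.poisson(5.0, size=(60, 8)), ["a", "b", "c"] * 20)
    with caplog.at_level("WARNING"):
        z, _ = zscore_localization(a, ["g0", "g1", "ghost"])
    assert any("ghost" in r.message for r in caplog.records)
    assert list(z.index) == ["g0", "g1"]
    assert np.allclose(z.sum(axis=1), 0.0, atol=1e-9)


def test_cov_hand_arithmetic_values_1_2_3():
    # three cells with equal totals; g0 depth-normalized values are 1,2,3
    lin = np.array([1.0, 2.0, 3.0])
    X = np.stack([lin, 10.0 - lin], axis=1)
    a = _adata(X, ["x", "y", "z"])
    cov = cov_per_gene(a, min_mean=0.01)
    assert cov.loc["g0", "mean"] == pytest.approx(2.0)
    assert cov.loc["g0", "sd"] == pytest.approx(1.0)
    assert cov.loc["g0", "cov"] == pytest.approx(0.5)


def test_cov_constant_gene_zero_and_low_mean_excluded():
    X = np.array([[5.0, 5.0, 0.0], [5.0, 5.0, 0.0], [5.0, 5.0, 0.0]])
    a = _adata(X, ["x", "y", "z"])
    cov = cov_per_gene(a, min_mean=0.01)
    assert cov.loc["g0", "cov"] == 0.0
    assert "g2" not in cov.index  # all-zero gene excluded by min_mean


def test_cov_scale_invariant_per_gene():
    rng = np.random.default_rng(1)
    lin = rng.uniform(1, 5, size=50)
    X1 = np.stack([lin, 10.0 - lin], axis=1)
    X2 = np.stack([7.0 * lin, 10.0 - lin], axis=1)
    # equalize depths in both so normalization does not couple the genes
    X2[:, 1] = X1.sum(axis=1) * 7.0 - X2[:, 0]
    c1 = cov_per_gene(_adata(X1, ["x"] * 50), min_mean=0.001)
    c2 = cov_per_gene(_adata(X2, ["x"] * 50), min_mean=0.001)
    assert c1.loc["g0", "cov"] == pytest.approx(c2.loc["g0", "cov"])


def test_robustness_contrast_identical_groups():
    rng = np.random.default_rng(2)
    cov = pd.DataFrame(
        {"mean": rng.uniform(1, 2, 40), "sd": rng.uniform(0, 1, 40)},
        index=[f"g{i}" for i in range(40)],
    )
    cov["cov"] = cov["sd"] / cov["mean"]
    genes = list(cov.index)
    summary, tests = robustness_contrast(cov, {"p": genes, "q": genes})
    assert summary.loc["p", "mean_cov"] == pytest.approx(summary.loc["q", "mean_cov"])
    assert (tests["pvalue"] > 0.9).all()


def test_robustness_contrast_single_group_no_tests(caplog):
    cov = pd.DataFrame({"mean": [1.0], "sd": [0.5], "cov": [0.5]}, index=["g0"])
    with caplog.at_level("WARNING"):
        summary, tests = robustness_contrast(cov, {"p": ["g0"], "empty": ["ghost"]})
    assert list(summary.index) == ["p"]
    assert len(tests) == 0


def _labeled_ranking():
    spans = [(i * 200_000, i * 200_000 + 1000) for i in range(4)]
    loci = PeakSet("l", [GenomicInterval("chr1", s, e) for s, e in spans])
    runs = (
        np.array([s for s, _ in spans]),
        np.array([e for _, e in spans]),
        np.array([1.0, 1.0, 1.0, 50.0]),
    )
    track = SignalTrack({"chr1": runs})
    return find_cutoff(rank_loci(loci, track))  # last locus SE, others RE


def test_se_gene_linking_boundary_and_precedence():
    r = _labeled_ranking()
    se_start = 3 * 200_000  # [600000, 601000) is the SE
    genes = GeneAnnotation(pd.DataFrame({
        "gene_id": ["near_se", "boundary_out", "near_re", "nowhere"],
        "chrom": ["chr1"] * 4,
        # near_se overlaps the SE; boundary_out is 20,001 bp from every locus
        "start": [se_start + 100, se_start + 1000 + 20_001, 5_000, 3_000_000],
        "end": [se_start + 200, se_start + 1000 + 20_101, 6_000, 3_001_000],
        "strand": ["+"] * 4,
    }))
    sets = se_gene_linking(r, genes, window=20_000)
    assert "near_se" in sets["SE"]
    assert "near_re" in sets["RE"]
    assert "boundary_out" in sets["none"] and "nowhere" in sets["none"]
    # SE precedence: a gene between the SE and an RE goes to the SE set
    genes2 = GeneAnnotation(pd.DataFrame({
        "gene_id": ["both"], "chrom": ["chr1"],
        "start": [se_start - 15_000], "end": [se_start - 14_000], "strand": ["+"],
    }))
    # also within 20kb of RE at 400,000-401,000? distance is 184,000 -> no;
    # construct an RE-proximal and SE-proximal gene explicitly instead
    genes3 = GeneAnnotation(pd.DataFrame({
        "gene_id": ["g_mid"], "chrom": ["chr1"],
        "start": [se_start - 10_000], "end": [se_start - 9_000], "strand": ["+"],
    }))
    assert se_gene_linking(r, genes2, window=20_000)["SE"] == ["both"]
    assert se_gene_linking(r, genes3, window=20_000)["SE"] == ["g_mid"]
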