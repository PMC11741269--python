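"""Config-driven orchestration of the full synthetic-data analysis.

Stages run in dependency order: simulate -> temporal classification ->
co-occupancy -> super-enhancer calling -> differential expression and
direct-target calling -> motif profiling -> single-nucleus statistics.
Every stage writes plain-text outputs under the config's output directory;
a JSON report records per-stage record counts (recomputed, not copied),
parameter echo, output checksums and wall times. Reruns with the same
config are byte-identical on every data output.
"""

from __future__ import annotations

import hashlib
import importlib.metadata
import importlib.resources
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
from scipy.sparse import csr_matrix

from . import dynamics, expression, motifs, superenhancers, synth, targets
from .config import PipelineConfig, validate_config
from .intervals import PeakSet, write_bed, write_bedgraph

__all__ = ["run_pipeline", "demo_config"]

FOX_CONSENSUS = "TGTTTAC"
SOX_CONSENSUS = "AACAATG"


def demo_config() -> PipelineConfig:
    """The bundled demo configuration (synthetic run at zero noise)."""
    path = importlib.resources.files("crmkit.data") / "demo.yaml"
    return validate_config(str(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


class _Report:
    def __init__(self, cfg: PipelineConfig):
        self.data = {
            "config": cfg.to_dict(),
            "stages": {},
            "counts": {},
            "checksums": {},
            "versions": {
                "crmkit": importlib.metadata.version("crmkit"),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        self._t0 = time.perf_counter()

    def stage_done(self, name: str) -> None:
        t = time.perf_counter()
        self.data["stages"][name] = {"wall_s": round(t - self._t0, 3)}
        self._t0 = t


def run_pipeline(config: PipelineConfig | str | Path | dict | None) -> dict:
    """Run all stages on synthetic inputs; returns the report dict."""
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    syn, prm = cfg.synthetic, cfg.params
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "peaks").mkdir(exist_ok=True)
    (out / "sc").mkdir(exist_ok=True)
    rep = _Report(cfg)
    counts = rep.data["counts"]
    truth = synth.SyntheticTruth(seed=cfg.seed, params={"synthetic": dict(syn)})

    # ---- simulate ---------------------------------------------------------
    genes, chrom_sizes = synth.gen_genome_and_genes(
        cfg.seed, n_chroms=syn["n_chroms"], chrom_len=syn["chrom_len"],
        n_genes=syn["n_genes"],
    )
    genes.to_gff3(out / "genes.gff3")
    stage_peaks, truth_peaks = synth.gen_stage_peaks(
        cfg.seed, chrom_sizes,
        class_counts=tuple(syn["class_counts"]), peak_width=syn["peak_width"],
    )
    stage_labels = truth_peaks.params["stage_labels"]
    for label, ps in stage_peaks.items():
        write_bed(ps, out / "peaks" / f"tfA_{label}.bed")
    tfA_late = stage_peaks[stage_labels[2]]
    tfB, coact, truth_co = synth.gen_cooccupancy_peaks(
        cfg.seed, tfA_late, chrom_sizes,
        n_cobound=syn["n_cobound"], n_fse=syn["n_fse"],
        n_b_unique=syn["n_b_unique"], n_coact_only=syn["n_coact_only"],
        peak_width=syn["peak_width"],
    )
    write_bed(tfB, out / "peaks" / "tfB.bed")
    write_bed(coact, out / "peaks" / "coact.bed")
    truth.peak_classes = truth_peaks.peak_classes
    counts["genes"] = len(genes)
    counts["tfA_peaks_per_stage"] = {l: len(p) for l, p in stage_peaks.items()}
    rep.stage_done("simulate")

    # ---- temporal classification -----------------------------------------
    assignment = dynamics.temporal_classify(
        *[stage_peaks[l] for l in stage_labels], min_bp=prm["min_bp"]
    )
    _write_tsv(assignment.to_frame(), out / "classes.tsv", index=False)
    counts["temporal_loci"] = len(assignment.loci)
    counts["class_counts"] = assignment.class_counts()
    rep.stage_done("classify")

    # ---- co-occupancy ------------------------------------------------------
    calls = dynamics.co_occupancy(tfA_late, tfB, coact, min_bp=prm["min_bp"])
    fse = dynamics.fse_regions(calls)
    write_bed(fse, out / "fse.bed")
    n_cobound = sum(c.is_cobound for c in calls)
    n_a_coact = sum(c.has_tfA and c.has_coact for c in calls)
    n_b_coact = sum(c.has_tfB and c.has_coact for c in calls)
    counts["cobound_regions"] = n_cobound
    counts["fse_regions"] = len(fse)
    counts["pct_fse_of_tfA_coact"] = (
        dynamics.percent_overlap(len(fse), n_a_coact).rounded if n_a_coact else None
    )
    counts["pct_fse_of_tfB_coact"] = (
        dynamics.percent_overlap(len(fse), n_b_coact).rounded if n_b_coact else None
    )
    rep.stage_done("co-occupancy")

    # ---- super-enhancers ---------------------------------------------------
    enhancers = synth.gen_enhancer_peaks(
        cfg.seed, chrom_sizes, n_peaks=syn["n_enhancers"]
    )
    tss = genes.tss_positions()
    track, enh_all, truth_se = synth.gen_signal_with_ses(
        cfg.seed, enhancers, chrom_sizes,
        n_se=syn["n_se"], se_span=syn["se_span"], se_amp=syn["se_amp"],
        re_amp=syn["re_amp"], noise_sd=syn["noise_sd"],
        near_genes=genes, avoid_tss=tss, tss_margin=prm["tss_exclusion"],
    )
    write_bedgraph(track, out / "signal.bedgraph")
    write_bed(enh_all, out / "peaks" / "enhancers.bed")
    ranking = superenhancers.call_super_enhancers(
        enh_all, track,
        stitch_gap=prm["stitch_gap"], tss=tss, tss_exclusion=prm["tss_exclusion"],
    )
    _write_tsv(ranking.to_frame(), out / "enhancer_ranking.tsv", index=False)
    write_bed(ranking.to_bed(), out / "enhancers_called.bed")
    truth.se_loci = truth_se.se_loci
    counts["stitched_loci"] = len(ranking)
    counts["se_count"] = int((ranking.labels == "SE").sum())
    counts["re_count"] = int((ranking.labels == "RE").sum())
    assoc = superenhancers.se_association({"FSE": fse, "coact": coact}, ranking)
    _write_tsv(assoc, out / "se_association.tsv")
    rep.stage_done("super-enhancers")

    # ---- morphant DE and direct targets ------------------------------------
    effectsA, effectsB, truth_t = synth.gen_target_effects(
        cfg.seed, genes, tfA_late, tfB, window=prm["window"],
        n_joint=syn["n_joint"], n_a_only=syn["n_a_only"], n_b_only=syn["n_b_only"],
        effect_lfc=syn["effect_lfc"], frac_repressed=syn["frac_repressed"],
    )
    truth.direct_targets = truth_t.direct_targets
    gene_ids = genes.gene_ids
    mrng = synth.child_rng(cfg.seed, "base_means")
    base_means = np.exp(
        mrng.uniform(
            np.log(syn["mean_range"][0]), np.log(syn["mean_range"][1]),
            size=len(gene_ids),
        )
    )
    de_tables = {}
    for factor, effects, stream in (
        ("A", effectsA, "morphant_A"), ("B", effectsB, "morphant_B")
    ):
        wt, mo = synth.gen_morphant_counts(
            cfg.seed, gene_ids, effects, n_reps=syn["n_reps"],
            dispersion=syn["dispersion"], base_means=base_means, stream=stream,
        )
        _write_tsv(wt, out / f"counts_wt_{factor}.tsv")
        _write_tsv(mo, out / f"counts_mo_{factor}.tsv")
        de = targets.simple_de(mo, wt, pseudocount=prm["pseudocount"])
        _write_tsv(de, out / f"de_{factor}.tsv")
        de_tables[factor] = de
    assignA = targets.assign_peaks_to_genes(tfA_late, genes, window=prm["window"])
    assignB = targets.assign_peaks_to_genes(tfB, genes, window=prm["window"])
    _write_tsv(assignA, out / "peak_gene_A.tsv", index=False)
    _write_tsv(assignB, out / "peak_gene_B.tsv", index=False)
    calls_t, partition = targets.call_direct_targets(
        de_tables["A"], de_tables["B"], assignA, assignB,
        fold=prm["fold"], padj_max=prm["padj_max"],
    )
    target_df = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id, "attribution": c.attribution,
                "direction": c.direction,
                "distance_a": c.distance_a, "distance_b": c.distance_b,
            }
            for c in calls_t
        ],
        columns=["gene_id", "attribution", "direction", "distance_a", "distance_b"],
    )
    _write_tsv(target_df, out / "direct_targets.tsv", index=False)
    _write_tsv(partition, out / "target_partition.tsv")
    counts["direct_targets"] = len(calls_t)
    counts["target_partition"] = {
        k: int(v) for k, v in partition.sum(axis=1).items()
    }
    rep.stage_done("targets")

    # ---- motif profiles ----------------------------------------------------
    seqs, mpeaks, truth_m = synth.gen_peak_sequences(
        cfg.seed, n_peaks=syn["n_motif_peaks"], length=syn["motif_seq_len"],
        plant={
            "FOX": (FOX_CONSENSUS, syn["fox_fraction"]),
            "SOX": (SOX_CONSENSUS, syn["sox_fraction"]),
        },
    )
    truth.motif_presence = truth_m.motif_presence
    pwm_path = importlib.resources.files("crmkit.data") / "motifs.jaspar"
    pwms = {p.name: p for p in motifs.read_jaspar(str(pwm_path))}
    hist = motifs.summit_histogram(
        mpeaks, seqs, [pwms["FOX"], pwms["SOX"]],
        flank=prm["flank"], bin=prm["bin"],
    )
    _write_tsv(hist.counts, out / "motif_histogram.tsv")
    props = motifs.combinatorial_content(
        mpeaks, seqs, pwms["FOX"], pwms["SOX"], flank=prm["flank"]
    )
    _write_tsv(pd.Series(props, name="proportion").to_frame(), out / "motif_proportions.tsv")
    counts["motif_hits"] = hist.total_hits
    counts["motif_proportions"] = props
    rep.stage_done("motifs")

    # ---- single-nucleus statistics -----------------------------------------
    robust = [d["gene_id"] for d in truth.se_loci if d.get("gene_id")]
    adata, truth_sc = synth.gen_sc_matrix(
        cfg.seed, gene_ids, robust_genes=robust, n_cells=syn["n_cells"]
    )
    truth.robust_genes = truth_sc.robust_genes
    truth.cluster_markers = truth_sc.cluster_markers
    sio.mmwrite(str(out / "sc" / "matrix.mtx"), csr_matrix(adata.X))
    adata.obs.to_csv(out / "sc" / "cells.tsv", sep="\t")
    pd.Series(adata.var_names, name="gene_id").to_csv(
        out / "sc" / "genes.tsv", sep="\t", index=False
    )
    filtered = expression.qc_filter(adata, min_genes_per_cell=prm["qc_min_genes"])
    gene_sets = expression.se_gene_linking(ranking, genes, window=prm["window"])
    z, set_score = expression.zscore_localization(
        filtered, list(truth.cluster_markers.values())[0]
    )
    _write_tsv(z, out / "sc" / "marker_zscores.tsv")
    cov = expression.cov_per_gene(filtered, min_mean=prm["cov_min_mean"])
    _write_tsv(cov, out / "sc" / "cov.tsv")
    groups = {
        "SE_target": [g for g in truth.robust_genes],
        "SE": gene_sets["SE"],
        "RE": gene_sets["RE"],
        "no_enhancer": gene_sets["none"],
    }
    summary, tests = expression.robustness_contrast(cov, groups)
    _write_tsv(summary, out / "sc" / "robustness_summary.tsv")
    _write_tsv(tests, out / "sc" / "robustness_tests.tsv", index=False)
    counts["sc_cells_pass_qc"] = int(filtered.n_obs)
    counts["sc_clusters"] = int(len(filtered.obs["cluster"].cat.categories))
    counts["se_linked_genes"] = len(gene_sets["SE"])
    rep.stage_done("sc-stats")

    # ---- report ------------------------------------------------------------
    truth.to_json(out / "truth.json")
    data_files = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name not in ("report.json", "MANIFEST.tsv")
    )
    rep.data["checksums"] = {
        str(p.relative_to(out)): _sha256(p) for p in data_files
    }
    manifest = pd.DataFrame(
        {
            "path": [str(p.relative_to(out)) for p in data_files],
            "sha256": [rep.data["checksums"][str(p.relative_to(out))] for p in data_files],
        }
    )
    _write_tsv(manifest, out / "MANIFEST.tsv", index=False)
    # cross-stage consistency, recomputed
    assert counts["se_count"] + counts["re_count"] == counts["stitched_loci"]
    assert sum(counts["target_partition"].values()) == counts["direct_targets"]
    with open(out / "report.json", "w") as fh:
        json.dump(rep.data, fh, indent=1, sort_keys=True)
    return rep.data
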