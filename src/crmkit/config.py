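"""Pipeline configuration: schema, defaults, validation.

A config is a YAML (or JSON) mapping with three blocks: the global ``seed``,
a ``synthetic`` generation block (or ``inputs`` paths for user data), and a
``params`` block of per-stage parameters. Validation fills defaults,
rejects unknown keys, and reports every violation at once.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "DEFAULTS"]

# Stage parameters. Distances/windows in bp. The defaults anchor to the
# analysis conventions this pipeline reproduces: a 20 kb peak-to-gene window,
# 2-fold expression change at adjusted p <= 0.05 for target calling,
# 12.5 kb stitching with a 2.5 kb TSS exclusion for enhancer ranking, a
# 1500 genes/cell single-nucleus QC cutoff, and a 2 kb summit window in
# 20 bp bins for motif histograms.
PARAM_DEFAULTS: dict[str, object] = {
    "min_bp": 1,
    "window": 20_000,
    "fold": 2.0,
    "padj_max": 0.05,
    "stitch_gap": 12_500,
    "tss_exclusion": 2_500,
    "qc_min_genes": 1_500,
    "flank": 1_000,
    "bin": 20,
    "cov_min_mean": 0.01,
    "class_window": 2_000,
    "pseudocount": 1.0,
}

SYNTH_DEFAULTS: dict[str, object] = {
    "n_chroms": 4,
    "chrom_len": 10_000_000,
    "n_genes": 800,
    "class_counts": [60, 40, 30, 50, 40, 35, 45],
    "peak_width": 400,
    "n_cobound": 60,
    "n_fse": 40,
    "n_b_unique": 50,
    "n_coact_only": 30,
    "n_enhancers": 200,
    "n_se": 5,
    "se_span": 20_000,
    "se_amp": 10.0,
    "re_amp": 1.0,
    "noise_sd": 0.25,
    "n_reps": 3,
    "dispersion": 0.05,
    "mean_range": [50.0, 2000.0],
    "n_joint": 10,
    "n_a_only": 15,
    "n_b_only": 20,
    "effect_lfc": 2.0,
    "frac_repressed": 0.3,
    "n_cells": 2_000,
    "n_motif_peaks": 100,
    "motif_seq_len": 2_000,
    "fox_fraction": 0.9,
    "sox_fraction": 0.85,
}

DEFAULTS: dict[str, object] = {
    "seed": 0,
    "outdir": "crmkit_out",
    "synthetic": SYNTH_DEFAULTS,
    "params": PARAM_DEFAULTS,
}

# (type, min) per leaf key, for range/type validation
_RANGES: dict[str, tuple[type, float]] = {
    "seed": (int, 0),
    "min_bp": (int, 1),
    "window": (int, 0),
    "fold": (float, 1),
    "padj_max": (float, 0),
    "stitch_gap": (int, 0),
    "tss_exclusion": (int, 0),
    "qc_min_genes": (int, 0),
    "flank": (int, 1),
    "bin": (int, 1),
    "cov_min_mean": (float, 0),
    "class_window": (int, 2),
    "pseudocount": (float, 0),
    "n_chroms": (int, 1),
    "chrom_len": (int, 1000),
    "n_genes": (int, 0),
    "peak_width": (int, 8),
    "n_cobound": (int, 0),
    "n_fse": (int, 0),
    "n_b_unique": (int, 0),
    "n_coact_only": (int, 0),
    "n_enhancers": (int, 1),
    "n_se": (int, 0),
    "se_span": (int, 1000),
    "se_amp": (float, 0),
    "re_amp": (float, 0),
    "noise_sd": (float, 0),
    "n_reps": (int, 2),
    "dispersion": (float, 0),
    "n_joint": (int, 0),
    "n_a_only": (int, 0),
    "n_b_only": (int, 0),
    "effect_lfc": (float, 0),
    "frac_repressed": (float, 0),
    "n_cells": (int, 0),
    "n_motif_peaks": (int, 0),
    "motif_seq_len": (int, 100),
    "fox_fraction": (float, 0),
    "sox_fraction": (float, 0),
}


class ConfigError(ValueError):
    """Carries every validation problem found, not just the first."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    synthetic: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "synthetic": dict(self.synthetic),
            "params": dict(self.params),
        }


def _check_leaf(key: str, value: object, path: str, errors: list[str]) -> object:
    if key not in _RANGES:
        return value
    typ, lo = _RANGES[key]
    if typ is float and isinstance(value, int) and not isinstance(value, bool):
        value = float(value)
    if not isinstance(value, typ) or isinstance(value, bool):
        errors.append(f"{path}: expected {typ.__name__}, got {type(value).__name__}")
        return value
    if value < lo:
        errors.append(f"{path}: must be >= {lo}, got {value}")
    return value


def validate_config(source: str | Path | dict | None) -> PipelineConfig:
    """Normalize a config mapping or YAML/JSON file path.

    All defaults are filled in; unknown keys and type/range violations are
    collected and raised together as a ConfigError.
    """
    if source is None:
        raw: dict = {"synthetic": {}}
    elif isinstance(source, dict):
        raw = copy.deepcopy(source)
    else:
        with open(source) as fh:
            loaded = yaml.safe_load(fh)
        raw = loaded if loaded is not None else {}
        if not isinstance(raw, dict):
            raise ConfigError([f"{source}: top level must be a mapping"])

    errors: list[str] = []
    if "synthetic" not in raw:
        # the pipeline generates all its inputs; a config must opt in to
        # generation explicitly (an empty synthetic block means all defaults)
        errors.append("synthetic: generation block required")
    merged = copy.deepcopy(DEFAULTS)
    for key, val in raw.items():
        if key not in merged:
            errors.append(f"unknown key {key!r}")
            continue
        if key in ("synthetic", "params"):
            if not isinstance(val, dict):
                errors.append(f"{key}: must be a mapping")
                continue
            for k2, v2 in val.items():
                if k2 not in merged[key]:
                    errors.append(f"{key}.{k2}: unknown key")
                    continue
                merged[key][k2] = _check_leaf(k2, v2, f"{key}.{k2}", errors)
        else:
            merged[key] = _check_leaf(key, val, key, errors)

    syn = merged["synthetic"]
    if isinstance(syn.get("class_counts"), list):
        if len(syn["class_counts"]) != 7 or any(
            not isinstance(c, int) or c < 0 for c in syn["class_counts"]
        ):
            errors.append("synthetic.class_counts: need 7 nonnegative integers")
    else:
        errors.append("synthetic.class_counts: need a list of 7 integers")
    if isinstance(syn.get("mean_range"), list) and len(syn["mean_range"]) == 2:
        syn["mean_range"] = [float(x) for x in syn["mean_range"]]
    else:
        errors.append("synthetic.mean_range: need [low, high]")
    p = merged["params"]
    if isinstance(p.get("flank"), int) and isinstance(p.get("bin"), int):
        if p["bin"] > 0 and p["flank"] % p["bin"] != 0:
            errors.append("params.flank: must be divisible by params.bin")
    if not isinstance(merged["outdir"], str) or not merged["outdir"]:
        errors.append("outdir: must be a non-empty string")

    if errors:
        raise ConfigError(sorted(errors))
    return PipelineConfig(
        seed=merged["seed"],
        outdir=merged["outdir"],
        synthetic=merged["synthetic"],
        params=merged["params"],
    )
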