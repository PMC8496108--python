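"""End-to-end driver: simulate/load -> QC -> blocks -> coding -> CV reports.

The pipeline takes a nested configuration dictionary with sections

    simulate: SimConfig fields (or 'vcf'/'gff'/'pheno' paths under 'input')
    qc:       maf_min, hwe_alpha, thin_window, outlier_k_sd
    blocks:   mode ('fixed' | 'gene'), kb (fixed mode), split/extension kb
    cv:       models (list of 1..6), folds, seed
    output:   dir (optional; TSV reports are written there)

Unknown sections or keys are errors. All randomness flows from the
configured seeds, and a rerun with the same configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, fields as dc_fields
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import io as hio
from .blocks import BlockSet, block_stats, build_fixed_blocks, build_gene_blocks
from .coding import build_design_matrices, build_grms
from .config import SimConfig
from .crossval import make_folds, run_cv
from .genotypes import PhasedGenotypes
from .qc import filter_phenotype_outliers, snp_qc, thin_genotypes
from .simulate import simulate_genes, simulate_genotypes, simulate_phenotypes

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

_SECTIONS = {"input", "simulate", "qc", "blocks", "cv", "output"}
_QC_KEYS = {"maf_min", "hwe_alpha", "thin_window", "outlier_k_sd"}
_BLOCK_KEYS = {
    "mode", "kb", "split_min_kb", "split_max_kb", "small_gene_kb",
    "extension_kb",
}
_CV_KEYS = {"models", "folds", "seed"}
_INPUT_KEYS = {"vcf", "gff", "pheno"}
_OUTPUT_KEYS = {"dir"}


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Run the full analysis; returns a dict of result tables and objects.

    Stages: data acquisition (simulation or file input), phenotype outlier
    removal, SNP QC and thinning, block construction, design/relationship
    matrices, per-model cross-validation. Any stage failure aborts with the
    stage name attached.
    """
    unknown = set(config) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    stage = "configure"
    try:
        results: dict[str, Any] = {}
        qc_cfg = dict(config.get("qc", {}))
        _check_keys("qc", qc_cfg, _QC_KEYS)
        blk_cfg = dict(config.get("blocks", {}))
        _check_keys("blocks", blk_cfg, _BLOCK_KEYS)
        cv_cfg = dict(config.get("cv", {}))
        _check_keys("cv", cv_cfg, _CV_KEYS)
        out_cfg = dict(config.get("output", {}))
        _check_keys("output", out_cfg, _OUTPUT_KEYS)

        mode = blk_cfg.get("mode", "fixed")
        if mode not in {"fixed", "gene"}:
            raise ValueError(f"blocks.mode must be 'fixed' or 'gene', got {mode!r}")

        stage = "acquire data"
        genes: Optional[pd.DataFrame] = None
        if "input" in config:
            in_cfg = dict(config["input"])
            _check_keys("input", in_cfg, _INPUT_KEYS)
            genotypes = hio.read_phased_vcf(in_cfg["vcf"])
            pheno = hio.read_phenotypes(in_cfg["pheno"])
            if "gff" in in_cfg:
                genes = hio.read_gff3_genes(in_cfg["gff"])
            sim_cfg = None
        else:
            sim_keys = {f.name for f in dc_fields(SimConfig)}
            sim_given = dict(config.get("simulate", {}))
            _check_keys("simulate", sim_given, sim_keys)
            sim_cfg = SimConfig(**sim_given)
            genotypes = simulate_genotypes(sim_cfg)
            genes = simulate_genes(sim_cfg)

        if mode == "gene" and genes is None:
            raise ValueError("gene-based blocks requested but no gene annotation")

        stage = "snp qc"
        retained = snp_qc(
            genotypes,
            maf_min=qc_cfg.get("maf_min", 0.05),
            hwe_alpha=qc_cfg.get("hwe_alpha", 1e-5),
        )
        genotypes_qc = genotypes.subset_snps(retained)
        thin_window = qc_cfg.get("thin_window", 1)
        if thin_window > 1:
            kept = thin_genotypes(genotypes_qc, thin_window)
            genotypes_qc = genotypes_qc.subset_snps(kept)
        results["n_snps_retained"] = genotypes_qc.n_snps

        stage = "blocks"
        if mode == "fixed":
            blocks = build_fixed_blocks(genotypes_qc, blk_cfg.get("kb", 500))
        else:
            blocks = build_gene_blocks(
                genes,
                genotypes_qc,
                split_min_kb=blk_cfg.get("split_min_kb", 200),
                split_max_kb=blk_cfg.get("split_max_kb", 500),
                small_gene_kb=blk_cfg.get("small_gene_kb", 50),
                extension_kb=blk_cfg.get("extension_kb", 100),
            )
        if len(blocks) == 0:
            raise ValueError("no haplotype blocks with >= 2 SNPs")
        results["blocks"] = blocks
        results["block_stats"] = block_stats(blocks, genotypes_qc)

        stage = "phenotypes"
        if sim_cfg is not None:
            pheno, truth = simulate_phenotypes(genotypes_qc, blocks, sim_cfg)
            results["truth"] = truth
        trait_cols = [
            c for c in pheno.columns if c not in ("id", "year_season")
        ]
        if not trait_cols:
            raise ValueError("phenotype table has no trait columns")

        stage = "coding"
        dm = build_design_matrices(genotypes_qc, blocks)
        grms = build_grms(dm)
        results["design"] = dm
        results["grms"] = grms
        results["genotypes"] = genotypes_qc
        results["genes"] = genes
        results["phenotypes"] = pheno

        stage = "cross-validation"
        models = cv_cfg.get("models", [6])
        for mid in models:
            if mid in (1, 2, 3, 4) and len(blocks) == 0:
                raise ValueError(f"model {mid} needs haplotype blocks")
        folds = cv_cfg.get("folds", 10)
        seed = cv_cfg.get("seed", 0)
        k_sd = qc_cfg.get("outlier_k_sd")
        reports = []
        cv_objects = {}
        for trait in trait_cols:
            y = pheno[trait].to_numpy(dtype=float)
            labels = pheno["year_season"].to_numpy()
            if k_sd is not None:
                keep = filter_phenotype_outliers(y, k_sd).kept_mask
                y = np.where(keep, y, np.nan)
            ok = ~np.isnan(y)
            # outlier individuals are dropped from this trait entirely
            idx = np.flatnonzero(ok)
            sub_grms = {
                c: g[np.ix_(idx, idx)] for c, g in grms.by_component().items()
            }
            plan = make_folds(idx.size, folds, seed)
            for mid in models:
                rep = run_cv(y[idx], labels[idx], sub_grms, mid, plan)
                cv_objects[(trait, mid)] = rep
                reports.append(
                    {
                        "trait": trait,
                        "model": mid,
                        "blocking": mode
                        if mode == "gene"
                        else f"{blk_cfg.get('kb', 500):g}kb",
                        "r_observed_original": rep.r_observed_original,
                        "r_observed_original_sd": rep.r_observed_original_sd,
                        "r_observed_corrected": rep.r_observed_corrected,
                        "r_observed_corrected_sd": rep.r_observed_corrected_sd,
                        "R0j": rep.R0j,
                        "R0jp": rep.R0jp,
                        "h2_g": rep.h2_g_mean,
                    }
                )
        cv_table = pd.DataFrame(reports)
        results["cv"] = cv_table
        results["cv_reports"] = cv_objects

        stage = "write reports"
        if "dir" in out_cfg:
            out_dir = Path(out_cfg["dir"])
            out_dir.mkdir(parents=True, exist_ok=True)
            hio.write_blocks(blocks, out_dir / "blocks.tsv")
            cv_table.to_csv(out_dir / "cv_report.tsv", sep="\t", index=False)
            with open(out_dir / "run_info.json", "w") as fh:
                json.dump(
                    {
                        "seed": seed,
                        "n_individuals": genotypes_qc.n_individuals,
                        "n_snps_retained": int(genotypes_qc.n_snps),
                        "n_blocks": len(blocks),
                        "models": list(models),
                        "simulated": sim_cfg is not None,
                        "sim_config": asdict(sim_cfg) if sim_cfg else None,
                    },
                    fh,
                    indent=2,
                    default=str,
                )
        return results
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
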