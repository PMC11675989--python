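"""End-to-end orchestration: simulate/ingest -> QC -> prune -> per-breed IBC
-> behavioral PCA -> fixed-effect adjustment -> GRM -> heritability -> GWAS
-> gene windows -> risk scores, with every stage artifact written as TSV and
a JSON run manifest recording parameters, seeds, and QC accounting."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, behavior, genes, genio, grs, relatedness, simdata, varcomp

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "fearscan_out"
    seed: int = 0
    # either a simulation block ...
    sim: simdata.SimConfig | None = None
    # ... or input paths
    bed_path: str | None = None
    metadata_path: str | None = None
    behavior_path: str | None = None
    gene_annotation_path: str | None = None
    # thresholds (defaults = the study parameters)
    maf_min: float = 0.05
    call_rate_min: float = 0.90
    prune_window: int = 200
    prune_step: int = 50
    prune_r2: float = 0.6
    alpha: float = 0.05
    flank: int = 500_000
    merge_gap: int = 1_000_000
    sd_mult: float = 1.0
    grs_reporting_p: float = 4.0e-5
    min_breed_n: int = 10
    assoc_mode: str = "fast"
    stages: tuple[str, ...] = (
        "qc", "ibc", "behavior", "h2", "gwas", "genes", "grs",
    )

    def validate(self) -> None:
        if self.sim is None and self.bed_path is None:
            raise ValueError("config needs either a simulation block or input paths")
        if not (0 <= self.maf_min < 0.5 and 0 < self.call_rate_min <= 1):
            raise ValueError("maf_min/call_rate_min out of range")
        if self.sim is not None:
            self.sim.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.sim = simdata.SimConfig(**sim)
        return cfg


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False)
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items() if not isinstance(v, dict)
        },
        "stages": {},
        "checksums": {},
    }

    # -- ingest or simulate ------------------------------------------------
    if config.sim is not None:
        sim_cfg = config.sim
        geno, variants, samples, truth = simdata.simulate_genotypes(sim_cfg)
        behav, truth = simdata.simulate_phenotypes(geno, samples, sim_cfg, truth)
        genio.write_genotypes(geno, variants, samples, out / "cohort")
        manifest["checksums"]["samples.tsv"] = _write(samples, out / "samples.tsv")
        manifest["checksums"]["behavior.tsv"] = _write(behav, out / "behavior.tsv")
    else:
        geno, variants, samples = genio.read_genotypes(config.bed_path)
        if config.metadata_path:
            samples = pd.read_csv(config.metadata_path, sep="\t")
        behav = pd.read_csv(config.behavior_path, sep="\t")
        truth = None

    # -- QC + prune --------------------------------------------------------
    geno_qc, var_qc, report = genio.qc_filter(
        geno, variants, maf_min=config.maf_min, call_rate_min=config.call_rate_min
    )
    geno_filled = genio.fill_sporadic_missing(geno_qc)
    kept = genio.ld_prune(
        geno_filled, window=config.prune_window, step=config.prune_step,
        r2_max=config.prune_r2,
    )
    keep_idx = [i for i, v in enumerate(geno_filled.variant_ids) if v in set(kept)]
    report.n_removed_prune = geno_filled.n_variants - len(keep_idx)
    report.n_retained = len(keep_idx)
    report.check()
    geno_pruned = geno_filled.subset_variants(keep_idx)
    var_pruned = var_qc.iloc[keep_idx].reset_index(drop=True)
    manifest["stages"]["qc"] = report.__dict__
    manifest["checksums"]["qc_report.tsv"] = _write(report.to_frame(), out / "qc_report.tsv")

    # -- per-breed IBC -----------------------------------------------------
    if "ibc" in config.stages:
        rows = []
        for breed, sub in samples.groupby("breed"):
            if len(sub) < config.min_breed_n:
                logger.info("breed %s excluded from IBC (n=%d < %d)",
                            breed, len(sub), config.min_breed_n)
                manifest["stages"].setdefault("ibc_excluded", []).append(
                    {"breed": str(breed), "n": int(len(sub)),
                     "reason": f"n < {config.min_breed_n}"}
                )
                continue
            idx = sub.index.to_numpy()
            g_b = geno.subset_samples(idx)
            g_b_qc, _, _ = genio.qc_filter(
                g_b, variants, maf_min=config.maf_min, call_rate_min=config.call_rate_min
            )
            g_b_filled = genio.fill_sporadic_missing(g_b_qc)
            kept_b = set(genio.ld_prune(
                g_b_filled, window=config.prune_window, step=config.prune_step,
                r2_max=config.prune_r2,
            ))
            g_b_pruned = g_b_filled.subset_variants(
                [i for i, v in enumerate(g_b_filled.variant_ids) if v in kept_b]
            )
            res = relatedness.compute_ibc(g_b_pruned, group=str(breed))
            rows.append(res.to_frame())
        if rows:
            ibc_table = pd.concat(rows, ignore_index=True)
            manifest["checksums"]["ibc.tsv"] = _write(ibc_table, out / "ibc.tsv")
            manifest["stages"]["ibc"] = {"n_groups": int(ibc_table["group"].nunique())}

    # -- GRMs and PCs ------------------------------------------------------
    grm_centered = relatedness.compute_grm(geno_pruned, "centered")
    grm_vs = relatedness.compute_grm(geno_pruned, "variance_standardized")
    pcs = relatedness.grm_pcs(grm_vs, k=2)

    # -- behavioral PCA + adjustment ---------------------------------------
    comp = behavior.fit_pca_varimax(behav)
    manifest["stages"]["behavior"] = {
        "kmo": comp.kmo,
        "explained_cumulative": comp.cumulative_explained,
        "labels": comp.labels,
    }
    manifest["checksums"]["component_scores.tsv"] = _write(
        comp.scores, out / "component_scores.tsv"
    )
    adjusted: dict[str, behavior.AdjustedPhenotype] = {}
    for label in simdata.GENETIC_COMPONENTS:
        if label not in comp.labels:
            continue
        adj = behavior.adjust_phenotype(
            comp.scores[label], samples, grm_pcs=pcs, alpha=config.alpha
        )
        adjusted[label] = adj
        manifest["stages"].setdefault("adjustment", {})[label] = {
            "retained": adj.retained_effects,
            "candidate_p": {k: float(v) for k, v in adj.candidate_pvalues.items()},
        }
    adj_table = pd.DataFrame(
        {"sample_id": samples["sample_id"].values}
        | {lab: adj.values.values for lab, adj in adjusted.items()}
    )
    manifest["checksums"]["adjusted_phenotypes.tsv"] = _write(
        adj_table, out / "adjusted_phenotypes.tsv"
    )

    # -- heritability ------------------------------------------------------
    if "h2" in config.stages:
        h2_rows = []
        for label, adj in adjusted.items():
            res = varcomp.reml_h2(adj.values.to_numpy(), grm_centered)
            h2_rows.append(
                {"phenotype": label, "h2": res.h2, "se": res.se_h2,
                 "sigma_g2": res.sigma_g2, "sigma_e2": res.sigma_e2,
                 "converged": res.converged}
            )
        h2_table = pd.DataFrame(h2_rows)
        manifest["checksums"]["heritability.tsv"] = _write(h2_table, out / "heritability.tsv")
        manifest["stages"]["h2"] = h2_rows

    # -- GWAS + genes + GRS ------------------------------------------------
    if "gwas" in config.stages:
        thresholds = assoc.significance_thresholds(
            geno_pruned.n_variants, alpha=config.alpha,
            reporting_p=config.grs_reporting_p,
        )
        manifest["stages"]["thresholds"] = {
            "n_variants": thresholds.n_variants,
            "bonferroni_p": thresholds.bonferroni_p,
            "suggestive_p": thresholds.suggestive_p,
            "reporting_p": thresholds.reporting_p,
        }
        gene_table = (
            genes.read_gene_annotation(config.gene_annotation_path)
            if config.gene_annotation_path else None
        )
        for label, adj in adjusted.items():
            rec = assoc.lmm_assoc(
                adj.values.to_numpy(), geno_pruned, grm_centered,
                variants=var_pruned, mode=config.assoc_mode,
            )
            manifest["checksums"][f"assoc_{label}.tsv"] = _write(
                rec, out / f"assoc_{label}.tsv"
            )
            _, _, lines = assoc.manhattan_qq_data(rec, thresholds)
            manifest["stages"].setdefault("gwas", {})[label] = {
                "lambda_gc": lines["lambda_gc"],
                "n_below_reporting": int((rec["wald_p"] < thresholds.reporting_p).sum()),
            }
            hits = rec[rec["wald_p"] < thresholds.reporting_p]
            if "genes" in config.stages and gene_table is not None and len(hits):
                wins = genes.build_windows(hits, flank=config.flank, merge_gap=config.merge_gap)
                cand = genes.candidate_table(genes.annotate_windows(wins, gene_table))
                manifest["checksums"][f"genes_{label}.tsv"] = _write(
                    cand, out / f"genes_{label}.tsv"
                )
            if "grs" in config.stages and len(hits):
                snp_set = hits["id"].tolist()
                cg = grs.compute_cgrs(geno_pruned, rec, snp_set)
                wg = grs.compute_wgrs(geno_pruned, rec, snp_set)
                bins = grs.bin_by_sd(adj.values, sd_mult=config.sd_mult)
                score_table = pd.DataFrame(
                    {"sample_id": geno_pruned.sample_ids, "cgrs": cg.values,
                     "wgrs": wg.values, "bin": bins.labels.values}
                )
                manifest["checksums"][f"grs_{label}.tsv"] = _write(
                    score_table, out / f"grs_{label}.tsv"
                )
                try:
                    cmp_w = grs.compare_grs_groups(wg, bins, mode="two_group")
                    manifest["stages"].setdefault("grs", {})[label] = {
                        "snp_set_size": len(snp_set),
                        "wgrs_anova_p": cmp_w.anova_p,
                        "note": "in-sample effect estimates; descriptive separation",
                    }
                except ValueError as err:
                    manifest["stages"].setdefault("grs", {})[label] = {"error": str(err)}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
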