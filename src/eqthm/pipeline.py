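"""Pipeline driver: simulate -> preprocess -> annotate -> scan -> dhmr ->
enrich, with TSV/CSV artifacts, a resolved-config copy and per-stage count
logging. Every artifact header carries the seed and a config hash so a run
can be reproduced exactly."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import annotate, dhmr, enrichment, preprocess, scan, simulate
from .config import PipelineConfig
from .io import read_matrix, write_matrix

log = logging.getLogger(__name__)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineState:
    """In-memory handoff between stages (mirrors the on-disk artifacts)."""

    config: PipelineConfig
    data: Optional[simulate.SimulatedData] = None
    hmc: Optional[preprocess.HmcMatrix] = None
    cis_pairs: Optional[pd.DataFrame] = None
    scan_result: Optional[scan.ScanResult] = None
    dhmr_candidates: Optional[pd.DataFrame] = None
    dhmrs: Optional[pd.DataFrame] = None
    enrichment_tables: dict = field(default_factory=dict)


def _meta(config: PipelineConfig) -> dict:
    return {"seed": config.synth.seed, "config_hash": config_hash(config)}


def stage_simulate(state: PipelineState, out_dir: str) -> None:
    cfg = state.config
    state.data = simulate.simulate_dataset(cfg.synth)
    d = state.data
    meta = _meta(cfg)
    write_matrix(d.betas.bs, os.path.join(out_dir, "betas_bs.tsv"), meta)
    write_matrix(d.betas.oxbs, os.path.join(out_dir, "betas_oxbs.tsv"), meta)
    write_matrix(d.expression, os.path.join(out_dir, "expression.tsv"), meta)
    write_matrix(d.covariates, os.path.join(out_dir, "covariates.tsv"), meta)
    write_matrix(d.cpgs.set_index("cpg_id"),
                 os.path.join(out_dir, "cpg_annotation.tsv"), meta)
    write_matrix(d.genes.set_index("gene_id"),
                 os.path.join(out_dir, "gene_models.tsv"), meta)
    write_matrix(d.truth.cpgs.set_index("cpg_id"),
                 os.path.join(out_dir, "truth_cpgs.tsv"), meta)
    write_matrix(d.truth.pairs.set_index("cpg_id"),
                 os.path.join(out_dir, "truth_pairs.tsv"), meta)
    write_matrix(d.truth.regions.set_index("region_id"),
                 os.path.join(out_dir, "truth_regions.tsv"), meta)
    log.info("simulate: %d CpGs x %d samples, %d genes", len(d.cpgs),
             cfg.synth.n_samples, len(d.genes))


def stage_preprocess(state: PipelineState, out_dir: str) -> None:
    cfg = state.config
    d = state.data
    state.hmc = preprocess.estimate_5hmc(d.betas, eps=cfg.m_value_eps)
    state.hmc.systematic = preprocess.classify_systematic(
        state.hmc.hmc, tau=cfg.tau, min_frac=cfg.min_frac)
    meta = _meta(cfg)
    write_matrix(state.hmc.hmc, os.path.join(out_dir, "hmc.tsv"), meta)
    write_matrix(state.hmc.m_values, os.path.join(out_dir, "mvalues.tsv"), meta)
    write_matrix(state.hmc.systematic.to_frame(),
                 os.path.join(out_dir, "systematic_flags.tsv"), meta)
    log.info("preprocess: grand mean 5hmC %.4f, %d/%d systematic",
             float(state.hmc.hmc.to_numpy().mean()),
             int(state.hmc.systematic.sum()), len(state.hmc.systematic))


def stage_annotate(state: PipelineState, out_dir: str) -> None:
    cfg = state.config
    state.cis_pairs = annotate.build_cis_pairs(state.data.cpgs,
                                               state.data.genes,
                                               window=cfg.window)
    write_matrix(state.cis_pairs.set_index("cpg_id"),
                 os.path.join(out_dir, "cis_pairs.tsv"), _meta(cfg))
    log.info("annotate: %d cis pairs", len(state.cis_pairs))


def stage_scan(state: PipelineState, out_dir: str) -> None:
    cfg = state.config
    d = state.data
    selected = scan.screen_covariates(state.hmc.m_values, d.expression,
                                      d.covariates, n_pcs=cfg.n_pcs,
                                      alpha=cfg.screen_alpha)
    log.info("scan: selected covariates %s", selected)
    cov = d.covariates[selected] if selected else None
    state.scan_result = scan.run_scan(state.hmc.m_values, d.expression, cov,
                                      state.cis_pairs, n_perm=cfg.n_perm,
                                      seed=cfg.synth.seed,
                                      fdr_level=cfg.fdr_level)
    res = state.scan_result
    res.associations.to_csv(os.path.join(out_dir, "eqthm_results.csv"),
                            index=False, float_format="%.6g")
    res.gene_nulls.to_csv(os.path.join(out_dir, "gene_nulls.csv"),
                          index=False, float_format="%.6g")
    with open(os.path.join(out_dir, "scan_summary.txt"), "w") as fh:
        fh.write(f"seed: {cfg.synth.seed}\n"
                 f"config_hash: {config_hash(cfg)}\n"
                 f"covariates: {','.join(selected) or '(none)'}\n"
                 f"n_pairs_tested: {res.n_pairs_tested}\n"
                 f"n_genes: {len(res.gene_nulls)}\n"
                 f"empirical_threshold_pt: {res.pt}\n"
                 f"n_eqthms: {len(res.eqthms)}\n")


def stage_dhmr(state: PipelineState, out_dir: str) -> None:
    cfg = state.config
    state.dhmr_candidates, state.dhmrs = dhmr.scan_dhmrs(
        state.scan_result.associations, state.data.cpgs,
        seed_thresh=cfg.seed_thresh, max_gap=cfg.max_gap,
        max_lag=cfg.max_lag, bin_width=cfg.acf_bin_width,
        alpha=cfg.alpha, min_cpgs=cfg.min_cpgs)
    cols = ["gene_id", "chrom", "start", "end", "n_cpgs", "p_region", "p_sidak"]
    state.dhmrs[cols].to_csv(os.path.join(out_dir, "dhmrs.csv"),
                             index=False, float_format="%.6g")
    annotate.regions_to_bed(state.dhmrs, os.path.join(out_dir, "dhmrs.bed"))


def stage_enrich(state: PipelineState, out_dir: str) -> None:
    cfg = state.config
    d = state.data
    hmc = state.hmc
    flags = hmc.systematic
    cpgs = d.cpgs.set_index("cpg_id").loc[flags.index]
    tables = {}
    tables["cgi"] = enrichment.enrichment_by_category(flags, cpgs["cgi_class"])
    tables["chromhmm"] = enrichment.enrichment_by_category(flags,
                                                          cpgs["chromhmm"])
    enr = pd.concat([t.assign(universe=k) for k, t in tables.items()],
                    ignore_index=True)
    enr.to_csv(os.path.join(out_dir, "enrichment.csv"), index=False,
               float_format="%.6g")
    summary = enrichment.summarize_5hmc(hmc.hmc, flags)
    state_means = enrichment.per_sample_category_means(hmc.hmc,
                                                      cpgs["chromhmm"])
    F, p = enrichment.anova_repeated(state_means)
    summary["chromhmm_anova_F"] = F
    summary["chromhmm_anova_p"] = p
    quart = preprocess.expression_quartiles(d.expression)
    summary["expression_quartile_sizes"] = quart.value_counts().to_dict()
    state.enrichment_tables = {"tables": tables, "summary": summary}
    with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
        for key, val in summary.items():
            fh.write(f"{key}: {val}\n")
    log.info("enrich: %s", summary)


STAGES = [
    ("simulate", "run_simulate", stage_simulate),
    ("preprocess", "run_preprocess", stage_preprocess),
    ("annotate", "run_annotate", stage_annotate),
    ("scan", "run_scan", stage_scan),
    ("dhmr", "run_dhmr", stage_dhmr),
    ("enrich", "run_enrich", stage_enrich),
]


def run_pipeline(config: PipelineConfig,
                 out_dir: Optional[str] = None) -> PipelineState:
    """Execute the toggled stages in order; raises RuntimeError naming the
    failing stage. Artifacts land under ``out_dir``."""
    config.validate()
    out_dir = out_dir or config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    config.to_yaml(os.path.join(out_dir, "resolved_config.yaml"))
    state = PipelineState(config=config)
    for name, toggle, fn in STAGES:
        if not getattr(config, toggle):
            continue
        try:
            fn(state, out_dir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return state


def load_matrix(path: str) -> pd.DataFrame:
    """Convenience: matrix without metadata; errors name the path."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing input: {path}")
    df, _ = read_matrix(path)
    return df
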