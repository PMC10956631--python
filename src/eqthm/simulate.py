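"""Synthetic EPIC-like paired BS/oxBS + expression data with known truth.

The generator emulates the features of a placental hydroxymethylome that the
downstream statistics depend on: a strongly right-skewed 5hmC distribution
with a low grand mean and a small "systematic" subset with clearly elevated
5hmC, CGI-dependent 5mC/5hmC structure (low methylation in islands, high in
open sea), covariate confounding shared between the methylome and the
transcriptome (infant sex, birthweight percentile, syncytiotrophoblast
proportion), planted cis 5hmC->expression effects on the M-value scale, and
planted contiguous DHMRs driven by a shared per-sample regional factor.

Everything lives on one synthetic autosome with 1-based positions; the cis
logic under the +/-1 Mb rule is intra-chromosomal, so one chromosome
suffices. The same seed always yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotate import assign_cgi_region, collapse_chromhmm, collapse_gene_compartments
from .config import ConfigError, SynthConfig
from .preprocess import BetaPairMatrix, classify_systematic, to_m_values

#: clip range for per-CpG background (non-systematic) true 5hmC means; the
#: upper bound keeps background means strictly below the 0.10 systematic
#: threshold so planted structure is identifiable
BACKGROUND_MEAN_RANGE = (5e-4, 0.095)
#: clip range for per-CpG systematic true 5hmC means
SYSTEMATIC_MEAN_RANGE = (0.11, 0.35)
SYSTEMATIC_MEAN_SD = 0.03
#: mean 5mC by CGI class (islands hypomethylated, open sea hypermethylated)
M5C_BY_CGI = {"island": 0.08, "shore": 0.35, "shelf": 0.55, "open sea": 0.65}
M5C_CONCENTRATION = 50.0
M5C_SAMPLE_CONCENTRATION = 150.0
DHMR_FACTOR_MEAN_SHIFT = 0.07
#: background CpGs are kept this far from planted DHMR clusters so the
#: planted region boundary is unambiguous ground truth (the 1 kb
#: autocorrelation window otherwise smears corrected p onto neighbours)
DHMR_ISOLATION_BP = 1500


@dataclass
class TruthPlan:
    """Planted layout decided at genome time: which CpGs are systematic and
    where the cis effects and DHMR clusters live."""

    systematic_ids: np.ndarray
    eqthm_pairs: pd.DataFrame      # cpg_id, gene_id, beta1
    dhmr_regions: pd.DataFrame     # region_id, gene_id, start, end, cpg_ids


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    cpgs: pd.DataFrame             # cpg_id, true_mean, systematic (realized)
    pairs: pd.DataFrame            # cpg_id, gene_id, beta1
    regions: pd.DataFrame          # region_id, gene_id, start, end, n_cpgs, cpg_ids
    hmc_true: pd.DataFrame         # CpG x sample noise-free 5hmC
    dhmr_factors: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SimulatedData:
    cpgs: pd.DataFrame
    genes: pd.DataFrame
    covariates: pd.DataFrame
    betas: BetaPairMatrix
    truth: TruthTable
    expression: pd.DataFrame


def _rngs(config: SynthConfig) -> dict[str, np.random.Generator]:
    names = ("genome", "covariates", "methylome", "expression")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _confounder(covariates: pd.DataFrame) -> np.ndarray:
    """Shared per-sample confounding score loading on both 5hmC and
    expression (unit variance when covariates vary)."""
    def z(x):
        s = np.std(x)
        return (x - np.mean(x)) / s if s > 0 else np.zeros_like(x, dtype=float)

    conf = (z(covariates["sex"].to_numpy(dtype=float))
            + z(covariates["bw_pct"].to_numpy())
            + z(covariates["stb"].to_numpy()))
    s = np.std(conf)
    return conf / s if s > 0 else conf


def simulate_covariates(config: SynthConfig,
                        rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Infant sex (0/1), birthweight percentile, syncytiotrophoblast
    proportion for each sample."""
    rng = rng or _rngs(config)["covariates"]
    n = config.n_samples
    return pd.DataFrame({
        "sex": rng.integers(0, 2, n),
        "bw_pct": rng.uniform(0, 100, n),
        "stb": rng.beta(0.55 * 30, 0.45 * 30, n),
    }, index=pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="sample_id"))


def simulate_genome(config: SynthConfig):
    """Lay out one chromosome: non-overlapping stranded genes, CGIs, CpGs
    with compartment/CGI/ChromHMM annotation, and the planted-truth plan.

    Returns (cpg_annotation, gene_models, plan). Every gene contains at
    least one CpG; planted DHMR clusters are dense runs of
    ``dhmr_span_cpgs`` CpGs spaced ``dhmr_cpg_spacing`` bp inside their
    gene's body.
    """
    config.validate()
    rng = _rngs(config)["genome"]
    n_genes, n_cpgs = config.n_genes, config.n_cpgs

    # --- genes: stick placement with random gaps, margin at both ends
    lengths = rng.integers(8_000, 60_000, n_genes)
    margin = min(100_000, config.chrom_length // 20)
    free = config.chrom_length - 2 * margin - int(lengths.sum())
    if free < n_genes:
        raise ConfigError("chromosome too short for the requested genes")
    gaps = rng.multinomial(free, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    starts = margin + np.cumsum(gaps[:-1]) + np.concatenate(
        ([0], np.cumsum(lengths[:-1])))
    ends = starts + lengths - 1
    strand = rng.choice(["+", "-"], n_genes)
    genes = pd.DataFrame({
        "gene_id": [f"G{i:04d}" for i in range(1, n_genes + 1)],
        "chrom": config.chrom, "strand": strand,
        "start": starts, "end": ends,
        "tss": np.where(strand == "+", starts, ends),
        "tts": np.where(strand == "+", ends, starts),
        "body_start": starts, "body_end": ends,
    })

    # --- CpG islands: most promoters + some intergenic
    island_centers = []
    promoter_genes = rng.choice(n_genes, size=max(1, int(0.6 * n_genes)),
                                replace=False)
    island_centers.extend(int(genes["tss"].iloc[i]) for i in promoter_genes)
    island_centers.extend(
        rng.integers(margin, config.chrom_length - margin, max(1, n_genes // 2)))
    half = 500
    raw_islands = np.array([(max(1, int(c) - half), int(c) + half)
                            for c in island_centers])
    raw_islands = raw_islands[np.argsort(raw_islands[:, 0])]
    merged = [list(raw_islands[0])]
    for s, e in raw_islands[1:]:  # merge overlaps so distances are well defined
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    islands = np.asarray(merged)

    # --- planted genes (DHMR genes first, then eQTHM genes, all distinct)
    planted = rng.choice(n_genes, size=config.n_true_dhmr + config.n_true_eqthm,
                         replace=False)
    dhmr_gene_idx = planted[:config.n_true_dhmr]
    eqthm_gene_idx = planted[config.n_true_dhmr:]

    # --- CpG positions
    pos_list = []
    # one CpG mid-body per gene guarantees >=1 cis CpG everywhere
    pos_list.append(((starts + ends) // 2).astype(np.int64))
    cluster_pos = {}
    for k, gi in enumerate(dhmr_gene_idx):
        span = (config.dhmr_span_cpgs - 1) * config.dhmr_cpg_spacing
        lo = int(starts[gi]) + 1000
        anchor = min(lo, int(ends[gi]) - span - 1)
        p = anchor + config.dhmr_cpg_spacing * np.arange(config.dhmr_span_cpgs)
        cluster_pos[f"R{k + 1:03d}"] = (genes["gene_id"].iloc[gi], p)
        pos_list.append(p.astype(np.int64))
    n_left = n_cpgs - sum(len(p) for p in pos_list)
    n_island = max(0, int(0.25 * n_left))
    if n_island and len(islands):
        which = rng.integers(0, len(islands), n_island)
        pos_list.append(islands[which, 0]
                        + rng.integers(0, 2 * half, n_island).astype(np.int64))
    n_rest = n_left - n_island
    if n_rest > 0:
        pos_list.append(rng.integers(1, config.chrom_length, n_rest).astype(np.int64))
    cluster_all = (np.concatenate([pp for _, pp in cluster_pos.values()])
                   if cluster_pos else np.empty(0, dtype=np.int64))

    def _near_cluster(p):
        if not len(cluster_all):
            return np.zeros(len(p), dtype=bool)
        near = np.zeros(len(p), dtype=bool)
        for c in cluster_all:
            near |= np.abs(p - c) <= DHMR_ISOLATION_BP
        return near & ~np.isin(p, cluster_all)

    pos = np.unique(np.concatenate(pos_list))
    pos = pos[~_near_cluster(pos)]
    while len(pos) < n_cpgs:  # top up after collisions/isolation removals
        extra = rng.integers(1, config.chrom_length, n_cpgs - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
        pos = pos[~_near_cluster(pos)]
    if len(pos) > n_cpgs:  # safeguard; drop random non-cluster positions
        droppable = np.where(~np.isin(pos, cluster_all))[0]
        pos = np.delete(pos, rng.choice(droppable, len(pos) - n_cpgs,
                                        replace=False))
    pos = np.sort(pos)
    cpg_ids = np.array([f"cg{i:07d}" for i in range(1, len(pos) + 1)])
    id_of_pos = dict(zip(pos.tolist(), cpg_ids))

    # --- CGI class from distance to nearest island
    isl_start, isl_end = islands[:, 0], islands[:, 1]
    j = np.searchsorted(isl_start, pos, side="right") - 1
    d_prev = np.where(j >= 0, np.maximum(pos - isl_end[np.clip(j, 0, None)], 0),
                      np.iinfo(np.int64).max)
    jn = np.clip(j + 1, 0, len(isl_start) - 1)
    d_next = np.where(j + 1 < len(isl_start), np.maximum(isl_start[jn] - pos, 0),
                      np.iinfo(np.int64).max)
    dist = np.minimum(d_prev, d_next)
    inside = (j >= 0) & (pos <= isl_end[np.clip(j, 0, None)])
    dist = np.where(inside, 0, dist)
    cgi_class = assign_cgi_region(dist)

    # --- nearest gene, compartments, chromatin states
    g_start, g_end = genes["start"].to_numpy(), genes["end"].to_numpy()
    g_strand = np.where(genes["strand"].to_numpy() == "+", 1, -1)
    g_tss, g_tts = genes["tss"].to_numpy(), genes["tts"].to_numpy()
    gj = np.searchsorted(g_start, pos, side="right") - 1
    prev_i = np.clip(gj, 0, None)
    next_i = np.clip(gj + 1, 0, n_genes - 1)
    d_prev_g = np.where(gj >= 0, np.maximum(pos - g_end[prev_i], 0), 1 << 60)
    d_next_g = np.where(gj + 1 < n_genes, np.maximum(g_start[next_i] - pos, 0), 1 << 60)
    nearest = np.where(d_prev_g <= d_next_g, prev_i, next_i)

    compartments = []
    chromhmm = []
    u = rng.uniform(size=len(pos))
    u2 = rng.uniform(size=len(pos))
    for i, p in enumerate(pos):
        gi = nearest[i]
        s = g_strand[gi]
        d_tss = (p - g_tss[gi]) * s
        d_tts = (p - g_tts[gi]) * s
        raw = []
        if d_tss < 0:
            if d_tss >= -200:
                raw.append("TSS200")
            elif d_tss >= -1500:
                raw.append("TSS1500")
        elif d_tts <= 0:  # inside
            prop = d_tss / (d_tss - d_tts) if (d_tss - d_tts) else 0.0
            if prop < 0.10:
                raw.append("5'UTR")
            elif prop < 0.15:
                raw.append("1stExon")
            elif prop > 0.90:
                raw.append("3'UTR")
            else:
                raw.append("ExonBnd" if u2[i] < 0.05 else "Body")
        collapsed = sorted(collapse_gene_compartments(raw))
        compartments.append(";".join(collapsed))

        if abs(d_tss) <= 300:
            state = "active TSS" if u[i] < 0.8 else "bivalent TSS"
        elif -2000 <= d_tss < 0 or (0 < d_tts <= 2000):
            state = "flanking active TSS"
        elif d_tss >= 0 and d_tts <= 0:
            state = ("strong transcription" if u[i] < 0.5
                     else "weak transcription" if u[i] < 0.8
                     else "genic enhancers")
        else:
            state = ("enhancers" if u[i] < 0.15
                     else "quiescent" if u[i] < 0.65
                     else "polycomb repressed" if u[i] < 0.75
                     else "weak polycomb repressed" if u[i] < 0.85
                     else "bivalent enhancer" if u[i] < 0.90
                     else "flanking active TSS")
        chromhmm.append(collapse_chromhmm(state))

    cpgs = pd.DataFrame({
        "cpg_id": cpg_ids, "chrom": config.chrom, "pos": pos,
        "compartments": compartments, "cgi_class": cgi_class,
        "chromhmm": chromhmm,
        "nearest_gene": genes["gene_id"].to_numpy()[nearest],
    })

    # --- systematic CpGs: weighted toward open sea, forced for DHMR members
    weights = pd.Series(cpgs["cgi_class"]).map(
        {"island": 0.1, "shore": 1.0, "shelf": 1.5, "open sea": 3.0}).to_numpy()
    cluster_ids = [id_of_pos[int(p)] for _, pp in cluster_pos.values() for p in pp]
    n_sys = int(round(config.frac_systematic * len(pos)))
    forced = np.isin(cpg_ids, cluster_ids)
    w = weights.copy()
    w[forced] = 0.0
    n_draw = max(0, n_sys - int(forced.sum()))
    drawn = rng.choice(len(pos), size=min(n_draw, int((w > 0).sum())),
                       replace=False, p=w / w.sum()) if n_draw else []
    sys_mask = forced.copy()
    sys_mask[np.asarray(drawn, dtype=int)] = True
    systematic_ids = cpg_ids[sys_mask]

    # --- planted eQTHM pairs: a systematic CpG in each chosen gene's window
    pair_rows = []
    for gi in eqthm_gene_idx:
        left = min(g_tss[gi], g_tts[gi]) - 1_000_000
        right = max(g_tss[gi], g_tts[gi]) + 1_000_000
        cand = np.where(sys_mask & (pos >= left) & (pos <= right))[0]
        cand = cand[~np.isin(cpg_ids[cand], cluster_ids)]
        if len(cand) == 0:
            raise ConfigError(
                f"planted gene {genes['gene_id'].iloc[gi]} has no systematic "
                "cis CpG; increase n_cpgs or frac_systematic")
        pick = cand[rng.integers(0, len(cand))]
        pair_rows.append((cpg_ids[pick], genes["gene_id"].iloc[gi],
                          config.effect_beta1))
    eqthm_pairs = pd.DataFrame(pair_rows, columns=["cpg_id", "gene_id", "beta1"])

    region_rows = []
    for rid, (gid, pp) in cluster_pos.items():
        members = [id_of_pos[int(p)] for p in pp]
        region_rows.append((rid, gid, int(pp.min()), int(pp.max()),
                            len(members), ";".join(members)))
    dhmr_regions = pd.DataFrame(
        region_rows,
        columns=["region_id", "gene_id", "start", "end", "n_cpgs", "cpg_ids"])

    plan = TruthPlan(systematic_ids=systematic_ids, eqthm_pairs=eqthm_pairs,
                     dhmr_regions=dhmr_regions)
    return cpgs, genes, plan


def simulate_methylomes(config: SynthConfig, annot: pd.DataFrame,
                        plan: TruthPlan,
                        covariates: Optional[pd.DataFrame] = None,
                        rng: Optional[np.random.Generator] = None):
    """Draw true 5hmC and 5mC and emit noisy clamped BS/oxBS beta pairs.

    True per-CpG 5hmC means are right-skewed (Beta) around
    ``base_hmc_mean`` for background CpGs and normal around
    ``systematic_hmc_mean`` for planted systematic CpGs; per-sample values
    are Beta draws around those means, capped at 1 - 5mC so betaBS never
    clamps when noise_sd = 0. The truth table's systematic flag is the
    realized classification of the noise-free matrix under the
    >=0.10-in->=50%-of-samples rule.

    Returns (BetaPairMatrix, TruthTable).
    """
    rng = rng or _rngs(config)["methylome"]
    if covariates is None:
        covariates = simulate_covariates(config)
    n_cpg, n = len(annot), config.n_samples
    samples = covariates.index
    sys_mask = annot["cpg_id"].isin(plan.systematic_ids).to_numpy()

    # per-CpG 5mC mean by CGI class
    m5c_mean = annot["cgi_class"].map(M5C_BY_CGI).to_numpy()
    m5c_i = rng.beta(m5c_mean * M5C_CONCENTRATION,
                     (1 - m5c_mean) * M5C_CONCENTRATION)
    m5c_i = np.clip(m5c_i, 0.01, 0.70)

    # per-CpG true 5hmC mean
    kappa = config.hmc_mean_concentration
    mean_i = np.empty(n_cpg)
    bg = rng.beta(config.base_hmc_mean * kappa,
                  (1 - config.base_hmc_mean) * kappa, n_cpg)
    mean_i[:] = np.clip(bg, *BACKGROUND_MEAN_RANGE)
    if sys_mask.any():
        mean_i[sys_mask] = np.clip(
            rng.normal(config.systematic_hmc_mean, SYSTEMATIC_MEAN_SD,
                       int(sys_mask.sum())), *SYSTEMATIC_MEAN_RANGE)

    conf = _confounder(covariates)
    mult = np.exp(config.cov_h_strength * conf)            # per-sample
    mean_ij = np.clip(mean_i[:, None] * mult[None, :], 1e-4, 0.5)

    # planted DHMR regions: shared per-sample factor shifts member means
    factors = {}
    id_index = pd.Index(annot["cpg_id"])
    for reg in plan.dhmr_regions.itertuples(index=False):
        f = rng.normal(0.0, 1.0, n)
        factors[reg.region_id] = f
        rows = id_index.get_indexer(reg.cpg_ids.split(";"))
        mean_ij[rows, :] = np.clip(
            mean_i[rows, None] + DHMR_FACTOR_MEAN_SHIFT * f[None, :], 0.02, 0.5)

    ks = config.hmc_sample_concentration
    h = rng.beta(mean_ij * ks, (1 - mean_ij) * ks)
    m5c_ij = rng.beta(m5c_i[:, None] * M5C_SAMPLE_CONCENTRATION,
                      (1 - m5c_i[:, None]) * M5C_SAMPLE_CONCENTRATION
                      * np.ones((1, n)))
    h = np.minimum(h, 1.0 - m5c_ij)
    # store the float-embedded value (m5c + h) - m5c as the truth so the
    # noise-free beta difference reproduces it bit-exactly
    h = (m5c_ij + h) - m5c_ij

    e_bs = rng.normal(0.0, config.noise_sd, (n_cpg, n)) if config.noise_sd else 0.0
    e_ox = rng.normal(0.0, config.noise_sd, (n_cpg, n)) if config.noise_sd else 0.0
    beta_bs = np.clip(m5c_ij + h + e_bs, 0.0, 1.0)
    beta_ox = np.clip(m5c_ij + e_ox, 0.0, 1.0)

    idx = pd.Index(annot["cpg_id"], name="cpg_id")
    pairs = BetaPairMatrix(
        bs=pd.DataFrame(beta_bs, index=idx, columns=samples),
        oxbs=pd.DataFrame(beta_ox, index=idx, columns=samples))
    hmc_true = pd.DataFrame(h, index=idx, columns=samples)
    realized = classify_systematic(hmc_true, tau=0.10, min_frac=0.5)
    truth = TruthTable(
        cpgs=pd.DataFrame({"cpg_id": annot["cpg_id"].to_numpy(),
                           "true_mean": mean_i,
                           "systematic": realized.to_numpy()}),
        pairs=plan.eqthm_pairs.copy(),
        regions=plan.dhmr_regions.copy(),
        hmc_true=hmc_true,
        dhmr_factors=pd.DataFrame(factors, index=samples).T,
    )
    return pairs, truth


def simulate_expression(config: SynthConfig, genes: pd.DataFrame,
                        truth: TruthTable, covariates: pd.DataFrame,
                        rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """log2-normalized-count-scale expression with planted cis effects.

    For planted pairs, y gains effect_beta1 x centred M(true 5hmC) at the
    planted CpG; planted DHMR genes gain their regional factor; all genes
    gain covariate terms through the shared confounding score plus Gaussian
    noise. Non-planted genes are independent of 5hmC given covariates.
    """
    rng = rng or _rngs(config)["expression"]
    n = len(covariates)
    gene_ids = genes["gene_id"].to_numpy()
    planted_genes = set(truth.pairs["gene_id"]) | set(truth.regions["gene_id"])
    missing = planted_genes - set(gene_ids)
    if missing:
        raise ConfigError(f"planted genes missing from gene table: {sorted(missing)}")

    conf = _confounder(covariates)
    baseline = rng.normal(5.0, 1.5, len(gene_ids))
    loadings = rng.normal(1.0, 0.3, len(gene_ids))
    y = (baseline[:, None]
         + config.cov_expr_strength * loadings[:, None] * conf[None, :])

    expr = pd.DataFrame(y, index=pd.Index(gene_ids, name="gene_id"),
                        columns=covariates.index)
    for p in truth.pairs.itertuples(index=False):
        m = to_m_values(truth.hmc_true.loc[p.cpg_id].to_numpy())
        expr.loc[p.gene_id] += p.beta1 * (m - m.mean())
    for reg in truth.regions.itertuples(index=False):
        f = truth.dhmr_factors.loc[reg.region_id].to_numpy()
        expr.loc[reg.gene_id] += config.dhmr_factor_effect * f
    if config.expr_noise_sd:
        expr += rng.normal(0.0, config.expr_noise_sd, expr.shape)
    return expr


def simulate_dataset(config: SynthConfig) -> SimulatedData:
    """End-to-end generation of one dataset under ``config``."""
    config.validate()
    rngs = _rngs(config)
    cpgs, genes, plan = simulate_genome(config)
    covariates = simulate_covariates(config, rng=rngs["covariates"])
    betas, truth = simulate_methylomes(config, cpgs, plan, covariates,
                                       rng=rngs["methylome"])
    expression = simulate_expression(config, genes, truth, covariates,
                                     rng=rngs["expression"])
    return SimulatedData(cpgs=cpgs, genes=genes, covariates=covariates,
                         betas=betas, truth=truth, expression=expression)
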