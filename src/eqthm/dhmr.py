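"""Region-level scan for differentially hydroxymethylated regions (DHMRs).

The approach follows the comb-p recipe: nominal per-CpG association
p-values are corrected for autocorrelation with neighbouring CpGs (within
1 kb) by the Stouffer-Liptak method, maximal runs of probes with corrected
p below a seed threshold (1e-4) and inter-probe gaps <= 1 kb become
candidate regions, each candidate gets a regional Stouffer-Liptak p over
its member CpGs (raw member p-values, so nothing is combined twice), and
that regional p is Sidak-adjusted with exponent total searched bases /
region width. Regions with adjusted p < 0.05 and >= 3 CpGs are significant.
The scan runs per gene over that gene's cis probes; the autocorrelation
model is pooled across genes for stability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class AcfModel:
    """Correlation of probe z-scores by distance bin on (0, max_lag]."""

    bin_edges: np.ndarray      # e.g. [0, 250, 500, 750, 1000]
    rho: np.ndarray            # one value per bin, floored at 0
    max_lag: int = 1000

    def rho_at(self, dist) -> np.ndarray:
        """rho for pairwise distances; 0 beyond max_lag, 1 at distance 0."""
        d = np.asarray(dist, dtype=float)
        idx = np.clip(np.searchsorted(self.bin_edges, d, side="left") - 1,
                      0, len(self.rho) - 1)
        out = np.where(d <= 0, 1.0,
                       np.where(d > self.max_lag, 0.0, self.rho[idx]))
        return out


def _z(p: np.ndarray) -> np.ndarray:
    return stats.norm.isf(np.clip(p, 1e-300, 1 - 1e-16))


def estimate_autocorrelation(p_values, positions, max_lag: int = 1000,
                             bin_width: int = 250) -> AcfModel:
    """Distance-binned Pearson correlation of z = Phi^-1(1 - p).

    Every probe pair whose distance falls in a bin contributes one (z_i,
    z_j) observation; negative estimates are floored at 0 because the
    combined-statistic variance they feed must stay positive. Bins with
    fewer than two pairs get rho = 0 with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    pos = np.asarray(positions)
    if len(p) < 2:
        raise ValueError("need at least 2 probes")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    z = _z(p)
    edges = np.arange(0, max_lag + bin_width, bin_width)
    n_bins = len(edges) - 1
    pairs_x: list[list[float]] = [[] for _ in range(n_bins)]
    pairs_y: list[list[float]] = [[] for _ in range(n_bins)]
    for i in range(len(pos)):
        j = i + 1
        while j < len(pos) and pos[j] - pos[i] <= max_lag:
            d = pos[j] - pos[i]
            b = min(int(np.searchsorted(edges, d, side="left")) - 1, n_bins - 1)
            pairs_x[b].append(z[i])
            pairs_y[b].append(z[j])
            j += 1
    rho = np.zeros(n_bins)
    for b in range(n_bins):
        if len(pairs_x[b]) < 2:
            warnings.warn(f"ACF bin ({edges[b]}, {edges[b + 1]}] has "
                          f"{len(pairs_x[b])} pair(s); rho set to 0")
            continue
        x, y = np.asarray(pairs_x[b]), np.asarray(pairs_y[b])
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"ACF bin ({edges[b]}, {edges[b + 1]}] degenerate; "
                          "rho set to 0")
            continue
        rho[b] = max(0.0, float(np.corrcoef(x, y)[0, 1]))
    return AcfModel(bin_edges=edges, rho=rho, max_lag=max_lag)


def _stouffer_liptak(z: np.ndarray, pos: np.ndarray, acf: AcfModel) -> float:
    """Combined Z over one set of probes under the fitted correlation."""
    k = len(z)
    d = np.abs(pos[:, None] - pos[None, :])
    iu = np.triu_indices(k, 1)
    sigma_sum = float(acf.rho_at(d[iu]).sum()) if k > 1 else 0.0
    denom = np.sqrt(max(k + 2.0 * sigma_sum, 1e-12))
    return float(z.sum() / denom)


def stouffer_liptak_correct(p_values, positions, acf: AcfModel) -> np.ndarray:
    """Autocorrelation-corrected p per probe: combine each probe with its
    neighbours within ``acf.max_lag`` bp. An isolated probe keeps its
    original p (k = 1); two perfectly correlated identical probes also keep
    it (the doubled z cancels against the sqrt(2 + 2rho) = 2 denominator)."""
    p = np.asarray(p_values, dtype=float)
    pos = np.asarray(positions)
    z = _z(p)
    out = np.empty_like(p)
    lo = np.searchsorted(pos, pos - acf.max_lag, side="left")
    hi = np.searchsorted(pos, pos + acf.max_lag, side="right")
    for i in range(len(p)):
        zz = z[lo[i]:hi[i]]
        pp = pos[lo[i]:hi[i]]
        out[i] = stats.norm.sf(_stouffer_liptak(zz, pp, acf))
    return out


def build_regions(corrected_p, positions, seed_thresh: float = 1e-4,
                  max_gap: int = 1000) -> list[tuple[int, int]]:
    """Maximal runs of probes with corrected p < seed_thresh whose
    consecutive members are <= max_gap bp apart; returns (start_idx,
    end_idx) inclusive index pairs into the sorted probe arrays."""
    p = np.asarray(corrected_p, dtype=float)
    pos = np.asarray(positions)
    below = np.flatnonzero(p < seed_thresh)
    regions = []
    i = 0
    while i < len(below):
        j = i
        while (j + 1 < len(below)
               and below[j + 1] == below[j] + 1
               and pos[below[j + 1]] - pos[below[j]] <= max_gap):
            j += 1
        regions.append((int(below[i]), int(below[j])))
        i = j + 1
    return regions


def sidak_adjust(p_region: float, width: int, total_bases: int) -> float:
    """Regional multiple-testing adjustment 1 - (1 - p)^(total_bases/width),
    clipped to [p_region, 1]."""
    if width <= 0:
        raise ValueError("region width must be positive")
    if total_bases < width:
        raise ValueError("total_bases must be >= region width")
    exponent = total_bases / width
    adj = -np.expm1(exponent * np.log1p(-min(p_region, 1.0 - 1e-16)))
    return float(min(max(adj, p_region), 1.0))


def call_dhmrs(candidates: pd.DataFrame, alpha: float = 0.05,
               min_cpgs: int = 3) -> pd.DataFrame:
    """Keep candidate regions with Sidak-adjusted p < alpha and >= min_cpgs
    member CpGs."""
    if candidates.empty:
        return candidates.copy()
    keep = (candidates["p_sidak"] < alpha) & (candidates["n_cpgs"] >= min_cpgs)
    return candidates[keep].reset_index(drop=True)


def scan_dhmrs(associations: pd.DataFrame, cpg_annotation: pd.DataFrame,
               seed_thresh: float = 1e-4, max_gap: int = 1000,
               max_lag: int = 1000, bin_width: int = 250,
               alpha: float = 0.05, min_cpgs: int = 3,
               chrom: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene comb-p scan over the cis association table.

    ``associations`` needs cpg_id/gene_id/p_nominal; probe positions come
    from ``cpg_annotation`` (cpg_id, chrom, pos). The autocorrelation model
    is estimated once from all within-gene probe series pooled into the
    distance bins. Returns (candidates, significant) region tables with
    chrom/start/end/gene_id/n_cpgs/cpg_ids/p_region/p_sidak/width/
    total_bases.
    """
    ann = cpg_annotation.set_index("cpg_id")
    assoc = associations.copy()
    assoc["pos"] = ann["pos"].reindex(assoc["cpg_id"]).to_numpy()
    if chrom is None:
        chrom = str(ann["chrom"].iloc[0]) if len(ann) else "chr?"
    assoc = assoc.sort_values(["gene_id", "pos"], kind="stable")

    # pooled ACF across genes: concatenate per-gene series with gaps larger
    # than max_lag between them so cross-gene pairs never form
    zs, ps = [], []
    offset = 0
    for _, grp in assoc.groupby("gene_id", sort=False):
        pos = grp["pos"].to_numpy()
        if len(pos) < 2:
            continue
        ps.append(pos - pos[0] + offset)
        zs.append(grp["p_nominal"].to_numpy())
        offset = ps[-1][-1] + max_lag + bin_width + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if ps:
            acf = estimate_autocorrelation(np.concatenate(zs),
                                           np.concatenate(ps),
                                           max_lag=max_lag,
                                           bin_width=bin_width)
        else:
            acf = AcfModel(bin_edges=np.arange(0, max_lag + bin_width,
                                               bin_width),
                           rho=np.zeros(max_lag // bin_width),
                           max_lag=max_lag)
    log.info("scan_dhmrs: pooled ACF rho by bin = %s", np.round(acf.rho, 3))

    rows = []
    for gene_id, grp in assoc.groupby("gene_id", sort=False):
        pos = grp["pos"].to_numpy()
        p = grp["p_nominal"].to_numpy()
        ids = grp["cpg_id"].to_numpy()
        if len(pos) < 1:
            continue
        corrected = stouffer_liptak_correct(p, pos, acf)
        total_bases = int(pos.max() - pos.min() + 1) if len(pos) > 1 else 1
        for i0, i1 in build_regions(corrected, pos, seed_thresh, max_gap):
            members = slice(i0, i1 + 1)
            z = _z(p[members])
            p_region = float(stats.norm.sf(
                _stouffer_liptak(z, pos[members].astype(float), acf)))
            width = int(pos[i1] - pos[i0] + 1)
            p_sidak = sidak_adjust(p_region, width, max(total_bases, width))
            rows.append({
                "gene_id": gene_id, "chrom": chrom,
                "start": int(pos[i0]), "end": int(pos[i1]),
                "n_cpgs": i1 - i0 + 1, "cpg_ids": ";".join(ids[members]),
                "p_region": p_region, "p_sidak": p_sidak,
                "width": width, "total_bases": total_bases,
            })
    candidates = pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "start", "end", "n_cpgs", "cpg_ids",
        "p_region", "p_sidak", "width", "total_bases"])
    significant = call_dhmrs(candidates, alpha=alpha, min_cpgs=min_cpgs)
    log.info("scan_dhmrs: %d candidate regions, %d significant",
             len(candidates), len(significant))
    return candidates, significant
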