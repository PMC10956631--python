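"""QC filtering, 5hmC estimation from BS/oxBS beta pairs, M-values,
systematic-5hmC classification, expression filtering and quartiles.

The 5hmC estimator is the clamped beta difference
``max(betaBS - betaOxBS, 0)``: the BS channel reads 5mC + 5hmC, the oxBS
channel 5mC only, so their difference estimates the hydroxymethylated
proportion. Signal-level maximum-likelihood estimation from raw intensities
is out of scope; the estimator is a single pluggable function should one
want to swap it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class QCError(ValueError):
    """Raised when QC removes everything or inputs are inconsistent."""


@dataclass
class BetaPairMatrix:
    """Paired BS and oxBS beta matrices (CpG rows x sample columns)."""

    bs: pd.DataFrame
    oxbs: pd.DataFrame
    detection_p: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if not self.bs.index.equals(self.oxbs.index) or \
           not self.bs.columns.equals(self.oxbs.columns):
            raise QCError("BS and oxBS matrices must share row and column ids")
        if self.detection_p is not None and (
                not self.bs.index.equals(self.detection_p.index)
                or not self.bs.columns.equals(self.detection_p.columns)):
            raise QCError("detection_p must be indexed like the beta matrices")
        for name, df in (("bs", self.bs), ("oxbs", self.oxbs)):
            vals = df.to_numpy()
            if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise QCError(f"{name} betas outside [0,1]")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.bs.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.bs.columns


@dataclass
class HmcMatrix:
    """Estimated 5hmC proportions with their M-values and systematic flags."""

    hmc: pd.DataFrame
    m_values: pd.DataFrame
    systematic: Optional[pd.Series] = None


def qc_filter(pairs: BetaPairMatrix,
              crossreactive_list: Sequence[str] = (),
              snp_list: Sequence[str] = (),
              p_thresh: float = 0.01,
              probe_fail_max_samples: int = 1,
              sample_fail_frac: float = 0.02) -> BetaPairMatrix:
    """Remove failing samples, then listed and detection-failing probes.

    Samples are dropped when detection p > ``p_thresh`` in more than
    ``sample_fail_frac`` of probes; then probes on the cross-reactive or
    SNP-overlap lists are dropped, as are probes failing detection in more
    than ``probe_fail_max_samples`` of the surviving samples. Sample-level
    exclusion runs first so probe failure counts reflect retained samples.
    """
    det = pairs.detection_p
    keep_samples = pairs.sample_ids
    if det is not None:
        frac_fail = (det > p_thresh).mean(axis=0)
        keep_samples = pairs.sample_ids[(frac_fail <= sample_fail_frac).to_numpy()]
        log.info("qc_filter: removed %d/%d samples (detection p > %g in > %g%% of probes)",
                 len(pairs.sample_ids) - len(keep_samples), len(pairs.sample_ids),
                 p_thresh, 100 * sample_fail_frac)
    listed = set(crossreactive_list) | set(snp_list)
    keep = ~pairs.cpg_ids.isin(listed)
    n_listed = int((~keep).sum())
    if det is not None:
        n_fail = (det.loc[:, keep_samples] > p_thresh).sum(axis=1)
        keep &= (n_fail <= probe_fail_max_samples).to_numpy()
    keep_probes = pairs.cpg_ids[keep]
    n_det = len(pairs.cpg_ids) - n_listed - len(keep_probes)
    log.info("qc_filter: removed %d listed + %d detection-failing probes; %d probes remain",
             n_listed, max(n_det, 0), len(keep_probes))
    if len(keep_probes) == 0 or len(keep_samples) == 0:
        raise QCError(
            f"QC removed everything ({len(keep_probes)} probes x "
            f"{len(keep_samples)} samples remain)")
    return BetaPairMatrix(
        bs=pairs.bs.loc[keep_probes, keep_samples],
        oxbs=pairs.oxbs.loc[keep_probes, keep_samples],
        detection_p=None if det is None else det.loc[keep_probes, keep_samples],
    )


def estimate_5hmc(pairs: BetaPairMatrix, eps: float = 1e-6) -> HmcMatrix:
    """5hmC betas as the non-negative BS - oxBS difference, plus M-values."""
    hmc = (pairs.bs - pairs.oxbs).clip(lower=0.0)
    return HmcMatrix(hmc=hmc, m_values=to_m_values(hmc, eps=eps))


def to_m_values(beta, eps: float = 1e-6):
    """logit2 transform M = log2(beta / (1 - beta)), beta clamped to
    [eps, 1 - eps] so a 5hmC proportion of exactly 0 stays finite."""
    arr = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m


def min_samples_required(n_samples: int, min_frac: float = 0.5) -> int:
    """Samples needed to call a CpG systematic: floor(min_frac * n).

    With 227 samples and min_frac 0.5 this is 113, i.e. "at least 50%" under
    the floor convention.
    """
    return math.floor(min_frac * n_samples)


def classify_systematic(hmc: pd.DataFrame, tau: float = 0.10,
                        min_frac: float = 0.5) -> pd.Series:
    """Flag CpGs with 5hmC >= tau in at least floor(min_frac * n) samples."""
    if hmc.shape[1] < 1:
        raise QCError("classify_systematic needs at least one sample")
    k_min = min_samples_required(hmc.shape[1], min_frac)
    counts = (hmc.to_numpy() >= tau).sum(axis=1)
    return pd.Series(counts >= k_min, index=hmc.index, name="systematic")


DEFAULT_BAD_SUBSTRINGS = ("LOC", "orf", "KIAA", "NCRNA", "MIR")
SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


def filter_transcripts(counts: pd.DataFrame, gene_table: pd.DataFrame,
                       cpm_thresh: float = 1.0, max_low_samples: int = 30,
                       bad_substrings: Iterable[str] = DEFAULT_BAD_SUBSTRINGS,
                       ) -> pd.DataFrame:
    """Expression filtering: CPM, poorly-defined names, sex chromosomes.

    Removes genes with CPM < ``cpm_thresh`` in more than ``max_low_samples``
    samples, genes whose name contains any of the listed substrings
    (case-sensitive, as printed on transcript names), and genes on sex
    chromosomes; returns log2(CPM + 1). ``gene_table`` maps gene_id -> chrom.
    """
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise QCError("samples with zero library size")
    cpm = counts.div(lib, axis=1) * 1e6
    n_low = (cpm < cpm_thresh).sum(axis=1)
    keep = n_low <= max_low_samples
    n_cpm = int((~keep).sum())
    name_bad = counts.index.to_series().apply(
        lambda g: any(s in g for s in bad_substrings))
    keep &= ~name_bad
    chrom = gene_table.set_index("gene_id")["chrom"].reindex(counts.index)
    keep &= ~chrom.isin(SEX_CHROMS).to_numpy()
    log.info("filter_transcripts: removed %d low-CPM, %d bad-name, "
             "%d sex-chromosome genes; %d remain", n_cpm,
             int(name_bad.sum()), int(chrom.isin(SEX_CHROMS).sum()),
             int(keep.sum()))
    if not keep.any():
        raise QCError("expression filtering removed every gene")
    return np.log2(cpm.loc[keep] + 1.0)


def expression_quartiles(expression: pd.DataFrame) -> pd.Series:
    """Quartile label (Q1 lowest .. Q4 highest) by rank of per-gene mean.

    Quartile sizes are balanced to within one gene; ties in mean expression
    are broken by the stable input (gene-id) order for determinism. With n
    not divisible by 4, the lower quartiles take the extra genes (e.g. 101
    genes -> sizes 26/25/25/25).
    """
    n = expression.shape[0]
    if n < 4:
        raise ValueError("expression_quartiles needs at least 4 genes")
    means = expression.mean(axis=1).to_numpy()
    order = np.argsort(means, kind="stable")
    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    labels = np.empty(n, dtype=object)
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = f"Q{q}"
        start += size
    return pd.Series(labels, index=expression.index, name="quartile")
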