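"""Fisher's-exact enrichment across annotation categories, one-way
repeated-measures ANOVA, and descriptive 5hmC summaries.

The enrichment odds ratio is the cross-product (a*d)/(b*c) on the 2x2 of
flagged-vs-category counts with a Woolf (log-OR normal) 95% CI; the exact
two-sided p comes from hypergeometric tail summation. The conditional-MLE
odds ratio used by R's fisher.test is available behind ``or_method``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = float(stats.norm.ppf(0.975))


@dataclass
class Contingency2x2:
    """Counts with a = flagged-and-in-category, b = flagged-not-in-category,
    c = unflagged-in-category, d = unflagged-not-in-category."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    def as_table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class EnrichmentResult:
    category: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    counts: Contingency2x2
    zero_cell_corrected: bool = False


def fisher_enrichment_from_counts(a: int, b: int, c: int, d: int,
                                  category: str = "",
                                  or_method: str = "cross-product",
                                  ) -> EnrichmentResult:
    """Enrichment OR, Woolf 95% CI and exact two-sided p from a 2x2.

    A zero cell triggers the Haldane-Anscombe +0.5 correction for the OR
    and CI (flagged in the result); the exact p always uses the raw counts.
    """
    counts = Contingency2x2(a, b, c, d)
    table = counts.as_table()
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("every margin must be positive for an odds ratio")
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = (x + 0.5 if corrected else x for x in (a, b, c, d))
    if or_method == "cross-product":
        oratio = (aa * dd) / (bb * cc)
    elif or_method == "conditional-mle":
        oratio = float(stats.contingency.odds_ratio(
            table, kind="conditional").statistic)
    else:
        raise ValueError(f"unknown or_method: {or_method!r}")
    se_log = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = np.log((aa * dd) / (bb * cc))
    ci_low = float(np.exp(log_or - Z_95 * se_log))
    ci_high = float(np.exp(log_or + Z_95 * se_log))
    return EnrichmentResult(category=category, odds_ratio=float(oratio),
                            ci_low=ci_low, ci_high=ci_high, p_value=p,
                            counts=counts, zero_cell_corrected=corrected)


def fisher_enrichment(flag, category, category_value=None,
                      or_method: str = "cross-product") -> EnrichmentResult:
    """Enrichment of a boolean flag within a category over a universe.

    ``flag`` and ``category`` are aligned boolean arrays (or ``category`` a
    label array with ``category_value`` naming the level of interest).
    """
    flag = np.asarray(flag, dtype=bool)
    if category_value is not None:
        in_cat = np.asarray(category) == category_value
        name = str(category_value)
    else:
        in_cat = np.asarray(category, dtype=bool)
        name = ""
    if flag.shape != in_cat.shape:
        raise ValueError("flag and category must align")
    a = int(np.sum(flag & in_cat))
    b = int(np.sum(flag & ~in_cat))
    c = int(np.sum(~flag & in_cat))
    d = int(np.sum(~flag & ~in_cat))
    return fisher_enrichment_from_counts(a, b, c, d, category=name,
                                         or_method=or_method)


def enrichment_by_category(flag: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """One Fisher enrichment per observed category label (each level vs the
    rest of the universe)."""
    rows = []
    for level in pd.unique(labels.dropna()):
        res = fisher_enrichment(flag.to_numpy(), labels.to_numpy(), level)
        rows.append({"category": level, "a": res.counts.a, "b": res.counts.b,
                     "c": res.counts.c, "d": res.counts.d,
                     "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p_value": res.p_value})
    return pd.DataFrame(rows)


def anova_repeated(per_sample_category_means: pd.DataFrame) -> tuple[float, float]:
    """One-way within-subject ANOVA on a (sample x category) table of means.

    F = MS_condition / MS_(condition x subject), p from F with (k-1),
    (k-1)(n-1) degrees of freedom. Every sample must have a value for every
    category.
    """
    X = per_sample_category_means.to_numpy(dtype=float)
    n, k = X.shape
    if k < 2 or n < 2:
        raise ValueError("need >=2 categories and >=2 subjects")
    if np.isnan(X).any():
        raise ValueError("missing cells: every sample needs every category")
    grand = X.mean()
    ss_cond = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((X - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        return np.inf, 0.0
    F = float(ms_cond / ms_err)
    p = float(stats.f.sf(F, df_cond, df_err))
    return F, p


def per_sample_category_means(hmc: pd.DataFrame,
                              labels: pd.Series) -> pd.DataFrame:
    """Mean 5hmC over each category's CpGs, per sample (the repeated-
    measures unit for the ANOVA); rows = samples, columns = categories."""
    labels = labels.reindex(hmc.index)
    out = {}
    for level in pd.unique(labels.dropna()):
        out[level] = hmc.loc[(labels == level).to_numpy()].mean(axis=0)
    return pd.DataFrame(out)


def summarize_5hmc(hmc: pd.DataFrame, systematic: pd.Series) -> dict:
    """Grand-mean and systematic-subset summary on the percent scale."""
    systematic = systematic.reindex(hmc.index).fillna(False).astype(bool)
    n_cpgs = hmc.shape[0]
    n_sys = int(systematic.sum())
    vals = hmc.to_numpy(dtype=float)
    out = {
        "n_cpgs": n_cpgs,
        "n_systematic": n_sys,
        "pct_systematic": 100.0 * n_sys / n_cpgs if n_cpgs else float("nan"),
        "grand_mean_pct": 100.0 * float(vals.mean()) if vals.size else float("nan"),
        "systematic_mean_pct": (100.0 * float(
            vals[systematic.to_numpy()].mean()) if n_sys else float("nan")),
    }
    return out
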