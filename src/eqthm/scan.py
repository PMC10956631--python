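"""cis eQTHM scanning: covariate screening, per-pair linear models,
permutation null, beta-MLE empirical p-values, BH FDR, and the empirical
significance threshold.

The per-pair model is ``y = b0 + b1*HM + T*alpha + eps`` where y is a gene's
normalized expression, HM the 5hmC M-values at one CpG, and T the selected
covariates; b1 is tested with a two-sided t-test on n - k - 2 degrees of
freedom (k covariates). The scan path residualizes both sides on [1, T]
once (Frisch-Waugh-Lovell), which is algebraically identical to the full
OLS fit and makes the 1,000-permutation null affordable: each permutation
shuffles the expression sample labels once (the same shuffle for every
gene), re-residualizes, and records each gene's minimum nominal p over its
cis CpGs. A beta distribution is MLE-fitted to each gene's permutation
minima; the gene's empirical p is the fitted beta CDF at its observed
minimum p. Genes are BH-corrected across empirical p-values, and the
empirical threshold pt is the largest empirical p among genes with q below
the FDR level; a pair is an eQTHM when its nominal p < pt and its gene's
q < 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- screening

def _top_pcs(matrix: pd.DataFrame, n_pcs: int) -> np.ndarray:
    """Sample scores of the top principal components of a (feature x sample)
    matrix; columns are PCs."""
    X = matrix.to_numpy(dtype=float).T            # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_pcs, len(s))
    return u[:, :k] * s[:k]


def _assoc_p(candidate: pd.Series, pc: np.ndarray) -> float:
    """Univariate association p of one candidate with one PC: simple linear
    regression for continuous candidates, one-way ANOVA for categorical."""
    x = candidate.to_numpy()
    numeric = np.issubdtype(np.asarray(x).dtype, np.number)
    if numeric and len(np.unique(x)) > 2:
        r, p = stats.pearsonr(x.astype(float), pc)
        return float(p)
    groups = [pc[x == lev] for lev in pd.unique(x)]
    groups = [g for g in groups if len(g) > 1]
    if len(groups) < 2:
        return 1.0
    return float(stats.f_oneway(*groups).pvalue)


def screen_covariates(mvalues: pd.DataFrame, expression: pd.DataFrame,
                      candidates: pd.DataFrame, n_pcs: int = 5,
                      alpha: float = 0.05) -> list[str]:
    """Candidates associated (p < alpha) with >=1 of the top PCs of *both*
    the 5hmC M-value matrix and the expression matrix.

    Zero-variance candidates are skipped with a warning. Continuous
    candidates (numeric, >2 levels) are tested by simple regression against
    each PC; categorical ones by one-way ANOVA.
    """
    pcs_h = _top_pcs(mvalues, n_pcs)
    pcs_e = _top_pcs(expression, n_pcs)
    selected = []
    for name in candidates.columns:
        cand = candidates[name]
        if cand.nunique() < 2:
            warnings.warn(f"covariate {name!r} has zero variance; skipped")
            continue
        hit_h = any(_assoc_p(cand, pcs_h[:, j]) < alpha
                    for j in range(pcs_h.shape[1]))
        hit_e = hit_h and any(_assoc_p(cand, pcs_e[:, j]) < alpha
                              for j in range(pcs_e.shape[1]))
        if hit_h and hit_e:
            selected.append(name)
    return selected


# ---------------------------------------------------------- per-pair model

class CollinearityError(ValueError):
    pass


def fit_cis_model(y, hm, covariates=None):
    """OLS of y on [1, hm, covariates]; returns (beta1, se, t, p) for hm.

    p is two-sided from the t distribution on n - k - 2 degrees of freedom
    with k covariate columns.
    """
    y = np.asarray(y, dtype=float)
    hm = np.asarray(hm, dtype=float)
    n = len(y)
    cols = [np.ones(n), hm]
    names = ["intercept", "hm"]
    if covariates is not None:
        T = np.asarray(covariates, dtype=float)
        if T.ndim == 1:
            T = T[:, None]
        for j in range(T.shape[1]):
            cols.append(T[:, j])
            names.append(f"covariate_{j}")
    X = np.column_stack(cols)
    if np.ptp(hm) == 0:
        raise CollinearityError("hm is constant")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [names[j] for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise CollinearityError(f"collinear design; offending columns: {bad}")
    df = n - X.shape[1]
    if df < 1:
        raise ValueError("not enough samples for the requested model")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta1 = float(coef[1])
    if se == 0.0:
        t_stat = np.inf if beta1 > 0 else (-np.inf if beta1 < 0 else 0.0)
        p = 0.0 if beta1 != 0 else 1.0
    else:
        t_stat = beta1 / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return beta1, se, t_stat, p


# ------------------------------------------------------------ scan internals

def _covariate_basis(n: int, covariates: Optional[pd.DataFrame]) -> np.ndarray:
    """Orthonormal basis of span([1, T]) for residualization."""
    cols = [np.ones(n)]
    if covariates is not None and covariates.shape[1] > 0:
        cols.extend(covariates[c].to_numpy(dtype=float)
                    for c in covariates.columns)
    X = np.column_stack(cols)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return M - Q @ (Q.T @ M)


@dataclass
class _PairIndex:
    """Pairs sorted by gene with reduceat boundaries."""

    ci: np.ndarray          # CpG column index per pair
    gi: np.ndarray          # gene column index per pair
    gene_ids: np.ndarray    # unique gene ids in scan order
    starts: np.ndarray      # reduceat offsets into the pair arrays


def _index_pairs(cis_pairs: pd.DataFrame, cpg_ids: pd.Index,
                 gene_ids: pd.Index) -> tuple[pd.DataFrame, _PairIndex]:
    pairs = cis_pairs[cis_pairs["cpg_id"].isin(cpg_ids)
                      & cis_pairs["gene_id"].isin(gene_ids)].copy()
    pairs["_ci"] = cpg_ids.get_indexer(pairs["cpg_id"])
    pairs["_gi"] = gene_ids.get_indexer(pairs["gene_id"])
    pairs = pairs.sort_values(["_gi", "_ci"], kind="stable").reset_index(drop=True)
    gi = pairs["_gi"].to_numpy()
    boundaries = np.flatnonzero(np.diff(gi, prepend=-1))
    idx = _PairIndex(ci=pairs["_ci"].to_numpy(), gi=gi,
                     gene_ids=gene_ids.to_numpy()[gi[boundaries]],
                     starts=boundaries)
    return pairs, idx


def _pair_r2(Hc: np.ndarray, Yr: np.ndarray, shh_c: np.ndarray,
             syy: np.ndarray, gi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair cross-products and squared correlations of residualized
    columns; Hc is the gathered (n x n_pairs) CpG residual matrix."""
    shy = np.einsum("ij,ij->j", Hc, Yr[:, gi])
    r2 = shy ** 2 / (shh_c * syy[gi])
    return shy, np.minimum(r2, 1.0)


def _r2_to_p(r2: np.ndarray, df: int) -> np.ndarray:
    t2 = r2 * df / np.maximum(1.0 - r2, 1e-300)
    return 2.0 * stats.t.sf(np.sqrt(t2), df)


def permutation_null(expression: pd.DataFrame, mvalues: pd.DataFrame,
                     covariates: Optional[pd.DataFrame],
                     cis_pairs: pd.DataFrame, n_perm: int = 1000,
                     seed: int = 0,
                     shuffle_covariates: bool = False) -> pd.DataFrame:
    """Per-gene minimum nominal p across its cis CpGs under label shuffling.

    Each of the ``n_perm`` permutations shuffles the expression matrix's
    sample labels once (shared across genes) while 5hmC and covariates stay
    fixed; the permuted expression is re-residualized on the covariates
    before testing. With ``shuffle_covariates=True`` the covariate rows are
    shuffled jointly with the expression (the alternative reading of
    "shuffled sample identifiers": covariates travel with y instead of
    staying attached to the 5hmC side). Returns a (gene x n_perm) frame.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    n = mvalues.shape[1]
    Q = _covariate_basis(n, covariates)
    k = Q.shape[1] - 1
    df = n - 2 - k
    H = _residualize(mvalues.to_numpy(dtype=float).T, Q)
    Y_raw = expression.to_numpy(dtype=float).T
    shh = np.einsum("ij,ij->j", H, H)
    _, idx = _index_pairs(cis_pairs, mvalues.index, expression.index)
    ok = shh[idx.ci] > 1e-12
    if not ok.all():
        log.warning("permutation_null: dropping %d pairs with constant 5hmC",
                    int((~ok).sum()))
    ci, gi = idx.ci[ok], idx.gi[ok]
    starts = np.flatnonzero(np.diff(gi, prepend=-1))
    gene_ids = expression.index.to_numpy()[gi[starts]]
    Hc = H[:, ci]
    shh_c = shh[ci]
    rng = np.random.default_rng(seed)
    out = np.empty((len(gene_ids), n_perm))
    # with jointly shuffled covariates, residualizing permuted y on the
    # permuted basis equals permuting the fixed residuals
    Yr_fixed = _residualize(Y_raw, Q) if shuffle_covariates else None
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yp = Yr_fixed[perm] if shuffle_covariates \
            else _residualize(Y_raw[perm], Q)
        syy = np.einsum("ij,ij->j", Yp, Yp)
        _, r2 = _pair_r2(Hc, Yp, shh_c, np.maximum(syy, 1e-300), gi)
        out[:, b] = np.maximum.reduceat(r2, starts)
    min_p = _r2_to_p(out, df)
    return pd.DataFrame(min_p, index=pd.Index(gene_ids, name="gene_id"),
                        columns=[f"perm{b + 1}" for b in range(n_perm)])


# --------------------------------------------------------------- beta MLE

def _beta_mle_matrix(X: np.ndarray, tol: float = 1e-8, max_iter: int = 200):
    """Row-wise beta MLE by damped Newton from method-of-moments starts.

    X is (rows x n) with values in (0, 1). Returns (a, b) arrays. The
    iteration stops when the per-observation gradient norm falls below
    ``tol`` (or the step stalls); the best-likelihood iterate is kept, so
    the result never falls below the method-of-moments start.
    """
    n = X.shape[1]
    s1 = np.log(X).mean(axis=1)
    s2 = np.log1p(-X).mean(axis=1)
    m = X.mean(axis=1)
    v = X.var(axis=1)
    if np.any(v <= 0):
        raise ValueError("degenerate sample: all values equal")
    c = np.clip(m * (1 - m) / v - 1.0, 1e-3, None)
    a = np.clip(m * c, 1e-3, None)
    b = np.clip((1 - m) * c, 1e-3, None)

    def loglik(a, b):
        return (a - 1) * s1 + (b - 1) * s2 - special.betaln(a, b)

    best_a, best_b = a.copy(), b.copy()
    best_ll = loglik(a, b)
    active = np.ones(len(a), dtype=bool)
    for _ in range(max_iter):
        psi_ab = special.digamma(a + b)
        ga = s1 - special.digamma(a) + psi_ab
        gb = s2 - special.digamma(b) + psi_ab
        tri_ab = special.polygamma(1, a + b)
        haa = -special.polygamma(1, a) + tri_ab
        hbb = -special.polygamma(1, b) + tri_ab
        hab = tri_ab
        det = haa * hbb - hab * hab
        det = np.where(np.abs(det) < 1e-300, -1e-300, det)
        da = -(hbb * ga - hab * gb) / det
        db = -(haa * gb - hab * ga) / det
        step = np.ones_like(a)
        for _ in range(60):  # damp into the positive quadrant
            bad = ((a + step * da <= 0) | (b + step * db <= 0)) & active
            if not bad.any():
                break
            step[bad] *= 0.5
        na = np.where(active, a + step * da, a)
        nb = np.where(active, b + step * db, b)
        ll = loglik(na, nb)
        improve = ll >= best_ll
        best_a = np.where(improve, na, best_a)
        best_b = np.where(improve, nb, best_b)
        best_ll = np.maximum(ll, best_ll)
        a, b = na, nb
        gnorm = np.maximum(np.abs(ga), np.abs(gb))
        active = gnorm > tol
        if not active.any():
            break
    return best_a, best_b


def fit_beta_mle(perm_min_p: Sequence[float], tol: float = 1e-8):
    """Beta(a, b) maximum-likelihood fit to one vector of permutation
    minimum p-values (values in (0,1), >=10 of them, non-degenerate)."""
    x = np.asarray(perm_min_p, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 permutation p-values")
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("permutation p-values must lie strictly in (0,1)")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values equal")
    a, b = _beta_mle_matrix(x[None, :], tol=tol)
    return float(a[0]), float(b[0])


def empirical_pvalue(p_min_obs, a, b):
    """Beta CDF (regularized incomplete beta) of the observed minimum p."""
    return special.betainc(np.asarray(a, dtype=float),
                           np.asarray(b, dtype=float),
                           np.asarray(p_min_obs, dtype=float))


def bh_fdr(p_vector) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_vector, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def empirical_threshold(gene_nulls: pd.DataFrame,
                        fdr_level: float = 0.05) -> Optional[float]:
    """pt = highest empirical p among genes with BH q < fdr_level, or None
    when no gene is significant (in which case no eQTHMs are called)."""
    sig = gene_nulls[gene_nulls["q_bh"] < fdr_level]
    if sig.empty:
        return None
    return float(sig["p_empirical"].max())


# ----------------------------------------------------------------- results

@dataclass
class ScanResult:
    associations: pd.DataFrame
    gene_nulls: pd.DataFrame
    pt: Optional[float]
    n_pairs_tested: int
    eqthms: pd.DataFrame


def call_eqthms(associations: pd.DataFrame, gene_nulls: pd.DataFrame,
                pt: Optional[float], mvalues: pd.DataFrame,
                expression: pd.DataFrame, fdr_level: float = 0.05,
                rule: str = "literal") -> pd.DataFrame:
    """Flag significant pairs and attach the Pearson correlation between the
    CpG's M-values and the gene's expression (covariate-free, descriptive).

    ``rule='literal'`` (default) compares each pair's nominal p directly to
    the empirical threshold pt; ``rule='beta-inverted'`` converts pt to a
    per-gene nominal threshold through the inverse of the gene's fitted
    beta null (the GTEx-style variant). Both also require gene q <
    fdr_level.
    """
    cols = ["gene_id", "p_empirical", "q_bh"]
    if rule == "beta-inverted":
        cols += ["a", "b"]
    assoc = associations.merge(gene_nulls[cols], on="gene_id", how="left")
    if pt is None:
        assoc["is_eqthm"] = False
    elif rule == "literal":
        assoc["is_eqthm"] = ((assoc["p_nominal"] < pt)
                             & (assoc["q_bh"] < fdr_level))
    elif rule == "beta-inverted":
        gene_thresh = special.betaincinv(assoc["a"].to_numpy(),
                                         assoc["b"].to_numpy(), pt)
        assoc["is_eqthm"] = ((assoc["p_nominal"].to_numpy() < gene_thresh)
                             & (assoc["q_bh"] < fdr_level))
    else:
        raise ValueError(f"unknown call rule: {rule!r}")
    r = np.full(len(assoc), np.nan)
    hits = np.flatnonzero(assoc["is_eqthm"].to_numpy())
    for i in hits:
        m = mvalues.loc[assoc["cpg_id"].iat[i]].to_numpy(dtype=float)
        y = expression.loc[assoc["gene_id"].iat[i]].to_numpy(dtype=float)
        r[i] = stats.pearsonr(m, y).statistic
    assoc["r"] = r
    return assoc


def run_scan(mvalues: pd.DataFrame, expression: pd.DataFrame,
             covariates: Optional[pd.DataFrame], cis_pairs: pd.DataFrame,
             n_perm: int = 1000, seed: int = 0,
             fdr_level: float = 0.05) -> ScanResult:
    """Full cis scan: observed statistics, permutation null, beta-MLE
    empirical p-values, BH FDR, threshold, and eQTHM calls.

    ``mvalues`` (CpG x sample) and ``expression`` (gene x sample) must share
    sample columns; ``covariates`` is sample x covariate (numeric) or None.
    """
    if not mvalues.columns.equals(expression.columns):
        raise ValueError("mvalues and expression must share sample columns")
    n = mvalues.shape[1]
    Q = _covariate_basis(n, covariates)
    k = Q.shape[1] - 1
    df = n - 2 - k
    if df < 1:
        raise ValueError("not enough samples for the covariate-adjusted model")

    H = _residualize(mvalues.to_numpy(dtype=float).T, Q)
    Yr = _residualize(expression.to_numpy(dtype=float).T, Q)
    shh = np.einsum("ij,ij->j", H, H)
    syy = np.einsum("ij,ij->j", Yr, Yr)
    pairs, idx = _index_pairs(cis_pairs, mvalues.index, expression.index)
    ok = shh[idx.ci] > 1e-12
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("run_scan: dropping %d pairs with constant 5hmC", n_dropped)
    pairs = pairs.loc[ok].reset_index(drop=True)
    ci, gi = idx.ci[ok], idx.gi[ok]
    starts = np.flatnonzero(np.diff(gi, prepend=-1))
    gene_ids = expression.index.to_numpy()[gi[starts]]

    Hc = H[:, ci]
    shh_c = shh[ci]
    shy, r2 = _pair_r2(Hc, Yr, shh_c, np.maximum(syy, 1e-300), gi)
    beta1 = shy / shh_c
    rss = np.maximum(syy[gi] - shy ** 2 / shh_c, 0.0)
    se = np.sqrt(rss / df / shh_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, beta1 / se,
                          np.sign(beta1) * np.inf)
    p_nominal = _r2_to_p(r2, df)
    associations = pd.DataFrame({
        "cpg_id": pairs["cpg_id"], "gene_id": pairs["gene_id"],
        "zone": pairs.get("zone"), "distance": pairs.get("distance"),
        "beta1": beta1, "se": se, "t": t_stat, "p_nominal": p_nominal,
    })

    # permutation null reuses the residualized CpG side
    rng = np.random.default_rng(seed)
    Y_raw = expression.to_numpy(dtype=float).T
    max_r2 = np.empty((len(gene_ids), n_perm))
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yp = _residualize(Y_raw[perm], Q)
        syyp = np.maximum(np.einsum("ij,ij->j", Yp, Yp), 1e-300)
        _, r2p = _pair_r2(Hc, Yp, shh_c, syyp, gi)
        max_r2[:, b] = np.maximum.reduceat(r2p, starts)
    perm_min_p = _r2_to_p(max_r2, df)

    # clamp away exact 0/1 before the beta MLE (the likelihood diverges
    # there); the bound is purely numerical — a data-scale floor such as
    # 1/(2*n_perm) would push genuine small minima up and thin the fitted
    # tail, making empirical p-values anti-conservative
    clamped = np.clip(perm_min_p, 1e-12, 1.0 - 1e-12)
    a, b_shape = _beta_mle_matrix(clamped)
    p_min_obs = np.minimum.reduceat(p_nominal, starts)
    p_emp = empirical_pvalue(np.clip(p_min_obs, 0.0, 1.0), a, b_shape)
    q = bh_fdr(p_emp)
    gene_nulls = pd.DataFrame({
        "gene_id": gene_ids, "p_min_obs": p_min_obs, "a": a, "b": b_shape,
        "p_empirical": p_emp, "q_bh": q,
    })
    pt = empirical_threshold(gene_nulls, fdr_level)
    associations = call_eqthms(associations, gene_nulls, pt, mvalues,
                               expression, fdr_level)
    eqthms = associations[associations["is_eqthm"]].reset_index(drop=True)
    log.info("run_scan: %d pairs, %d genes, pt=%s, %d eQTHMs",
             len(associations), len(gene_ids), pt, len(eqthms))
    return ScanResult(associations=associations, gene_nulls=gene_nulls,
                      pt=pt, n_pairs_tested=len(associations), eqthms=eqthms)
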