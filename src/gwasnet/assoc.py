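"""Mixed-model single-SNP association with a kinship random effect.

The scan follows the efficient mixed-model association (EMMA) scheme: for
each trait y (one genetic mean per accession) the model is

    y = X beta + u + eps,   u ~ N(0, sigma_g^2 K),  eps ~ N(0, sigma_e^2 I)

with K an identity-by-state genetic-similarity matrix. K is
spectral-decomposed once; the variance ratio delta = sigma_e^2 / sigma_g^2
is estimated by maximum likelihood under the null (intercept-only) model
via a grid search over ln(delta) with local refinement, and then reused
for every SNP's generalized-least-squares fixed-effect test (the
"population parameters previously determined" approximation). Per-SNP
p-values come from the F(1, n-2) distribution of the GLS test.

Significance is called per trait by an empirical-percentile rule: the
bottom q-quantile (default 0.1%) of that trait's p-value distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = ["kinship", "KinshipEigen", "emma_scan", "ols_scan",
           "AssocResult", "SignificanceCalls", "significance_calls",
           "inflation_factor"]

DELTA_LOG_RANGE = (-10.0, 10.0)  # ln(delta) search interval
DELTA_GRID_POINTS = 100


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def kinship(geno: pd.DataFrame) -> pd.DataFrame:
    """Identity-by-state allele-sharing similarity between accessions.

    For inbred {0, 1} dosages this is the fraction of SNPs at which two
    accessions carry the same allele: 1 for identical genotypes, 0 for
    complete opposites. Diagonal is exactly 1.
    """
    X = geno.to_numpy(dtype=float)
    if X.shape[1] == 0:
        raise ValueError("kinship requires at least one SNP")
    if np.isnan(X).any():
        raise ValueError("missing genotypes not supported")
    m = X.shape[1]
    K = (X @ X.T + (1.0 - X) @ (1.0 - X).T) / m
    np.fill_diagonal(K, 1.0)
    return pd.DataFrame(K, index=geno.index, columns=geno.index)


@dataclass
class KinshipEigen:
    """Cached spectral decomposition of a (ridge-repaired) kinship matrix."""

    values: np.ndarray
    vectors: np.ndarray
    accessions: list[str]
    ridge: float = 0.0

    @classmethod
    def from_kinship(cls, K: pd.DataFrame, tol: float = 1e-8
                     ) -> "KinshipEigen":
        A = K.to_numpy(dtype=float)
        A = (A + A.T) / 2.0
        w = np.linalg.eigvalsh(A)
        ridge = 0.0
        if w.min() < -tol:
            ridge = -w.min() + 1e-6
            A = A + ridge * np.eye(len(A))
            logger.warning("kinship not PSD (min eig %.3g); "
                           "ridge %.3g applied", w.min(), ridge)
        vals, vecs = np.linalg.eigh(A)
        vals = np.clip(vals, 0.0, None)
        return cls(values=vals, vectors=vecs,
                   accessions=list(K.index), ridge=ridge)


# ---------------------------------------------------------------------------
# ML variance components under the null model
# ---------------------------------------------------------------------------


def _null_ml_delta(yt: np.ndarray, ones_t: np.ndarray, lam: np.ndarray
                   ) -> tuple[float, float, float]:
    """Maximize the full ML over delta for y = mu + u + eps.

    Works in the eigenbasis of K: yt = U'y, ones_t = U'1. Returns
    (delta, sigma_g2, loglik). Grid over ln(delta) then bounded local
    refinement around the best grid point.
    """
    n = len(yt)

    def negll(log_delta: float) -> float:
        delta = math.exp(log_delta)
        w = 1.0 / (lam + delta)
        xwx = np.sum(w * ones_t * ones_t)
        xwy = np.sum(w * ones_t * yt)
        mu = xwy / xwx
        r = yt - mu * ones_t
        sigma_g2 = np.sum(w * r * r) / n
        ll = -0.5 * (n * math.log(2 * math.pi * sigma_g2)
                     + np.sum(np.log(lam + delta)) + n)
        return -ll

    grid = np.linspace(*DELTA_LOG_RANGE, DELTA_GRID_POINTS)
    vals = np.array([negll(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded")
    best = res.x if res.fun <= vals[i] else grid[i]
    delta = math.exp(best)
    w = 1.0 / (lam + delta)
    xwx = np.sum(w * ones_t * ones_t)
    mu = np.sum(w * ones_t * yt) / xwx
    r = yt - mu * ones_t
    sigma_g2 = float(np.sum(w * r * r) / n)
    return delta, sigma_g2, -negll(math.log(delta))


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------


@dataclass
class AssocResult:
    """Per-trait scan output: one row per tested SNP plus the trait's
    variance components."""

    trait: str
    table: pd.DataFrame  # snp, chrom, pos, beta, stat, p
    sigma_g2: float
    sigma_e2: float
    delta: float
    loglik: float
    n_skipped: int = 0
    method: str = "emma"

    @property
    def pvalues(self) -> pd.Series:
        return self.table.set_index("snp")["p"]


def _gls_snp_tests(yt: np.ndarray, Xt: np.ndarray, ones_t: np.ndarray,
                   w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized 2-parameter GLS (intercept + SNP) tests in the eigenbasis.

    Returns (beta, F statistic, p) arrays over SNP columns of Xt.
    """
    n, m = Xt.shape
    sw = np.sqrt(w)
    a = sw * ones_t            # scaled intercept column
    ys = sw * yt
    B = Xt * sw[:, None]       # scaled SNP columns
    aa = a @ a
    ay = a @ ys
    ab = a @ B                 # (m,)
    bb = np.einsum("ij,ij->j", B, B)
    by = B.T @ ys
    yy = ys @ ys
    det = aa * bb - ab * ab
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_snp = (aa * by - ab * ay) / det
        beta_int = (ay - ab * beta_snp) / aa
        rss1 = (yy - 2 * (beta_int * ay + beta_snp * by)
                + beta_int ** 2 * aa + 2 * beta_int * beta_snp * ab
                + beta_snp ** 2 * bb)
        rss0 = yy - ay * ay / aa
        df = n - 2
        F = (rss0 - rss1) / (rss1 / df)
    F = np.where(det <= 1e-12, np.nan, F)
    F = np.clip(F, 0.0, None)
    p = stats.f.sf(F, 1, df)
    return beta_snp, F, p


def emma_scan(
    geno: pd.DataFrame,
    means: pd.DataFrame,
    K: pd.DataFrame | KinshipEigen,
    trait: str,
    min_mac: int = 2,
) -> AssocResult:
    """Mixed-model association scan of one trait over all SNPs.

    Accessions are aligned on the intersection of genotype rows, the
    trait's non-missing means and the kinship index. SNPs that are
    monomorphic (minor-allele count below ``min_mac``) among the used
    accessions are skipped (p = NaN) and logged.
    """
    eig = K if isinstance(K, KinshipEigen) else KinshipEigen.from_kinship(K)
    y_all = means[trait].dropna()
    acc = [a for a in eig.accessions if a in geno.index and a in y_all.index]
    if len(acc) < 3:
        raise ValueError("need at least 3 phenotyped accessions")
    if acc != eig.accessions:
        # re-decompose on the subset
        sel = [eig.accessions.index(a) for a in acc]
        Kfull = pd.DataFrame(
            (eig.vectors * eig.values) @ eig.vectors.T,
            index=eig.accessions, columns=eig.accessions)
        eig = KinshipEigen.from_kinship(Kfull.iloc[sel, sel])
    y = y_all.loc[acc].to_numpy(dtype=float)
    X = geno.loc[acc].to_numpy(dtype=float)
    n, m = X.shape

    U, lam = eig.vectors, eig.values
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)
    delta, sigma_g2, loglik = _null_ml_delta(yt, ones_t, lam)
    sigma_e2 = delta * sigma_g2
    w = 1.0 / (lam + delta)

    mac = np.minimum(X.sum(axis=0), n - X.sum(axis=0))
    usable = mac >= min_mac
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("trait %s: %d SNPs skipped (MAC < %d)",
                    trait, n_skipped, min_mac)
    Xt = U.T @ X
    beta = np.full(m, np.nan)
    Fst = np.full(m, np.nan)
    p = np.full(m, np.nan)
    if usable.any():
        b, f, pv = _gls_snp_tests(yt, Xt[:, usable], ones_t, w)
        beta[usable], Fst[usable], p[usable] = b, f, pv
    table = pd.DataFrame({
        "snp": geno.columns, "beta": beta, "stat": Fst, "p": p})
    return AssocResult(trait=trait, table=table, sigma_g2=sigma_g2,
                       sigma_e2=sigma_e2, delta=delta, loglik=loglik,
                       n_skipped=n_skipped, method="emma")


def ols_scan(geno: pd.DataFrame, means: pd.DataFrame, trait: str,
             min_mac: int = 2) -> AssocResult:
    """Naive per-SNP ordinary-least-squares scan (no kinship correction).

    Provided as the structure-unaware baseline the mixed model is judged
    against (genomic inflation comparison).
    """
    y_all = means[trait].dropna()
    acc = [a for a in geno.index if a in y_all.index]
    y = y_all.loc[acc].to_numpy(dtype=float)
    X = geno.loc[acc].to_numpy(dtype=float)
    n, m = X.shape
    mac = np.minimum(X.sum(axis=0), n - X.sum(axis=0))
    usable = mac >= min_mac
    beta = np.full(m, np.nan)
    Fst = np.full(m, np.nan)
    p = np.full(m, np.nan)
    if usable.any():
        b, f, pv = _gls_snp_tests(y, X[:, usable], np.ones(n), np.ones(n))
        beta[usable], Fst[usable], p[usable] = b, f, pv
    table = pd.DataFrame({
        "snp": geno.columns, "beta": beta, "stat": Fst, "p": p})
    return AssocResult(trait=trait, table=table, sigma_g2=0.0,
                       sigma_e2=float(np.var(y)), delta=math.inf,
                       loglik=math.nan, n_skipped=int((~usable).sum()),
                       method="ols")


def inflation_factor(pvalues: np.ndarray) -> float:
    """Genomic inflation lambda: median chi-square(1) quantile of the
    observed p-values over the null median (0.4549)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


# ---------------------------------------------------------------------------
# empirical-percentile significance
# ---------------------------------------------------------------------------


@dataclass
class SignificanceCalls:
    """Per-trait significant SNP sets under the bottom-q percentile rule."""

    q: float
    snps: dict[str, set[str]] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def n_calls(self, trait: str) -> int:
        return len(self.snps.get(trait, set()))


def significance_calls(
    results: AssocResult | list[AssocResult],
    q: float = 0.001,
) -> SignificanceCalls:
    """Flag, per trait, the SNPs in the bottom q-quantile of p-values.

    The realized threshold is the k-th smallest p-value with
    k = ceil(q * N) over the N tested (non-NaN) SNPs; every SNP with
    p <= threshold is flagged, so ties at the threshold are all included
    (the call count can exceed k, which is logged). With all p-values
    identical the call set is empty (no distribution to take a tail of).
    """
    if isinstance(results, AssocResult):
        results = [results]
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile q={q} outside (0, 1)")
    out = SignificanceCalls(q=q)
    for res in results:
        tab = res.table.dropna(subset=["p"])
        n = len(tab)
        if n == 0:
            out.snps[res.trait] = set()
            out.thresholds[res.trait] = math.nan
            continue
        if n < 1.0 / q:
            logger.warning("trait %s: only %d p-values for q=%g percentile",
                           res.trait, n, q)
        p = tab["p"].to_numpy()
        if np.all(p == p[0]):
            logger.warning("trait %s: all p-values identical; no calls",
                           res.trait)
            out.snps[res.trait] = set()
            out.thresholds[res.trait] = math.nan
            continue
        k = max(int(math.ceil(q * n)), 1)
        thr = float(np.sort(p)[k - 1])
        flagged = set(tab.loc[tab["p"] <= thr, "snp"])
        if len(flagged) > k:
            logger.info("trait %s: %d ties at threshold (k=%d)",
                        res.trait, len(flagged) - k, k)
        out.snps[res.trait] = flagged
        out.thresholds[res.trait] = thr
    return out


def expected_calls_per_trait(n_snps: int, q: float = 0.001) -> int:
    """Closed-form expected flagged-SNP count under the percentile rule."""
    return max(int(math.ceil(q * n_snps)), 1)
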