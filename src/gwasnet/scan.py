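"""Genomic hotspot scanning and cross-dataset candidate overlap.

Hotspots: genes are placed in genome order; the per-gene count of traits
with a called association is smoothed by a 25-gene sliding mean within
each chromosome, and windows exceeding the 95th percentile of a
position-shuffling bootstrap null are flagged.

Overlap: candidate gene sets from multiple datasets are intersected into
Venn sectors and compared against the independence expectation (products
of per-dataset marginal candidate frequencies) with a chi-square test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneCallTable

logger = logging.getLogger(__name__)

__all__ = ["hotspot_windows", "hotspot_bootstrap", "HotspotProfile",
           "dataset_overlap", "OverlapResult"]


# ---------------------------------------------------------------------------
# sliding-window hotspot profile
# ---------------------------------------------------------------------------


@dataclass
class HotspotProfile:
    """Per-gene trait counts and chromosome-local sliding-window means."""

    window: int
    gene_counts: pd.DataFrame      # gene, chrom, order, n_traits
    window_means: pd.DataFrame     # chrom, window_index, start_gene, mean
    threshold: float | None = None
    flagged: pd.DataFrame | None = None
    n_boot: int = 0
    level: float = 0.95


def _window_means_1d(counts: np.ndarray, window: int) -> np.ndarray:
    if len(counts) < window:
        return np.empty(0)
    c = np.concatenate([[0.0], np.cumsum(counts, dtype=float)])
    return (c[window:] - c[:-window]) / window


def hotspot_windows(
    table: GeneCallTable,
    genes: pd.DataFrame,
    window: int = 25,
) -> HotspotProfile:
    """Sliding mean of traits-affected-per-gene over consecutive genes.

    Counts, per gene, the number of traits it is called for, orders genes
    by their genome order index, and averages over every run of
    ``window`` consecutive genes within a chromosome (windows never span
    chromosome boundaries). A window mean above 1 means each gene in the
    span affects on average more than one trait.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n_traits = table.calls.sum(axis=1)
    gc = genes[["gene", "chrom", "order"]].copy()
    gc["n_traits"] = gc["gene"].map(n_traits).fillna(0).astype(int)
    gc = gc.sort_values("order", kind="mergesort").reset_index(drop=True)
    rows = []
    for chrom, sub in gc.groupby("chrom", sort=False):
        counts = sub["n_traits"].to_numpy()
        wm = _window_means_1d(counts, window)
        for i, m in enumerate(wm):
            rows.append((chrom, i, sub["gene"].iloc[i], float(m)))
    window_means = pd.DataFrame(
        rows, columns=["chrom", "window_index", "start_gene", "mean"])
    return HotspotProfile(window=window, gene_counts=gc,
                          window_means=window_means)


def hotspot_bootstrap(
    profile: HotspotProfile,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> HotspotProfile:
    """Bootstrap null for the window means by shuffling gene positions.

    Each replicate permutes the observed per-gene trait counts across
    genome positions (a draw without replacement, preserving the count
    distribution exactly), recomputes every window mean, and pools them;
    the threshold is the ``level`` percentile of the pooled bootstrap
    window-mean distribution — a single genome-wide line. Observed
    windows strictly above it are flagged.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d is low for a stable %g percentile",
                       n_boot, level)
    rng = np.random.default_rng(seed)
    counts = profile.gene_counts["n_traits"].to_numpy().astype(float)
    chrom_sizes = [len(sub) for _, sub in
                   profile.gene_counts.groupby("chrom", sort=False)]
    if counts.max() == 0:
        profile.threshold = 0.0
        profile.flagged = profile.window_means.iloc[0:0].copy()
        profile.n_boot = n_boot
        profile.level = level
        return profile
    pooled = []
    w = profile.window
    for _ in range(n_boot):
        perm = rng.permutation(counts)
        off = 0
        for size in chrom_sizes:
            pooled.append(_window_means_1d(perm[off:off + size], w))
            off += size
    pooled_arr = np.concatenate(pooled)
    threshold = float(np.quantile(pooled_arr, level))
    flagged = profile.window_means[
        profile.window_means["mean"] > threshold].copy()
    profile.threshold = threshold
    profile.flagged = flagged
    profile.n_boot = n_boot
    profile.level = level
    return profile


# ---------------------------------------------------------------------------
# cross-dataset overlap
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    """Venn-sector counts vs. independence expectation for 3 datasets."""

    sectors: pd.DataFrame  # sector, observed, observed_pct, expected_pct, chi2
    chi2: float
    p: float
    df: int
    n_universe: int
    n_excluded: int
    datasets: tuple[str, ...] = ()


def dataset_overlap(
    tables: dict[str, GeneCallTable | set[str]],
    universe: set[str],
    exclusion: set[str] | None = None,
) -> OverlapResult:
    """Compare observed candidate-set overlap to the independence model.

    A gene is a dataset's candidate when called for >= 1 trait. The
    exclusion set (e.g. genes inside known LD blocks around large-effect
    loci, which co-associate without being causal) is removed from every
    candidate set and from the universe before counting. Expected sector
    probabilities are products of the per-dataset marginal candidate
    frequencies; the chi-square statistic sums over all 2^k membership
    cells (including the all-negative cell), with degrees of freedom
    2^k - 1 - k since the marginals are estimated from the data.
    """
    exclusion = exclusion or set()
    if not exclusion <= universe:
        raise ValueError("exclusion set must be contained in the universe")
    names = tuple(tables)
    base = universe - exclusion
    if not base:
        raise ValueError("universe is empty after exclusion")
    cand = {}
    for name, t in tables.items():
        s = t.called_genes() if isinstance(t, GeneCallTable) else set(t)
        cand[name] = (s & base)
    k = len(names)
    n = len(base)
    marg = {name: len(cand[name]) / n for name in names}

    rows = []
    chi2 = 0.0
    union = set().union(*cand.values())
    for pattern in itertools.product([True, False], repeat=k):
        cell = set(base)
        for name, inside in zip(names, pattern):
            cell &= cand[name] if inside else (base - cand[name])
        obs = len(cell)
        p_exp = 1.0
        for name, inside in zip(names, pattern):
            p_exp *= marg[name] if inside else (1.0 - marg[name])
        exp = n * p_exp
        contrib = (obs - exp) ** 2 / exp if exp > 0 else 0.0
        chi2 += contrib
        label = "&".join(name for name, inside in zip(names, pattern)
                         if inside) or "none"
        rows.append((label, obs,
                     100.0 * obs / len(union) if union else np.nan,
                     100.0 * exp / len(union) if union else np.nan,
                     contrib))
    df = 2 ** k - 1 - k
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    sectors = pd.DataFrame(rows, columns=[
        "sector", "observed", "observed_pct", "expected_pct", "chi2"])
    return OverlapResult(sectors=sectors, chi2=float(chi2), p=p, df=df,
                         n_universe=n, n_excluded=len(exclusion),
                         datasets=names)
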