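"""Gene-level candidate calling from SNP significance calls.

SNPs are mapped to genes by interval containment in the gene's ±1 kb
window; a gene-trait association is called when the number of significant
SNPs in that window meets one of three criteria: at least 1, at least 2,
or at least 20% of the window's SNPs. Recovery statistics score the calls
against a list of independently validated genes, and a polygenic mixed
model estimates how much phenotypic variance the candidate-gene SNPs
jointly explain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import KinshipEigen, SignificanceCalls, _null_ml_delta

logger = logging.getLogger(__name__)

__all__ = ["snp_gene_index", "SnpGeneIndex", "call_genes", "GeneCallTable",
           "recovery_stats", "candidate_snps", "explained_variance",
           "CRITERIA"]

CRITERIA = ("min1", "min2", "frac20")


# ---------------------------------------------------------------------------
# SNP -> gene window mapping
# ---------------------------------------------------------------------------


@dataclass
class SnpGeneIndex:
    """Bidirectional SNP <-> gene-window mapping."""

    flank: int
    snp_to_genes: dict[str, set[str]] = field(default_factory=dict)
    gene_to_snps: dict[str, set[str]] = field(default_factory=dict)

    @property
    def gene_snp_count(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.gene_to_snps.items()}


def snp_gene_index(
    snp_map: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 1000,
) -> SnpGeneIndex:
    """Map each SNP to every gene whose window [start-flank, end+flank]
    contains it (1-based inclusive at both boundaries).

    A SNP inside two overlapping windows maps to both genes. Genes and
    SNPs must share chromosome naming.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    index = SnpGeneIndex(flank=flank)
    index.gene_to_snps = {g: set() for g in genes["gene"]}
    for chrom, snps_c in snp_map.groupby("chrom"):
        genes_c = genes[genes["chrom"] == chrom]
        pos = snps_c["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos_sorted = pos[order]
        ids_sorted = snps_c["snp"].to_numpy()[order]
        for _, g in genes_c.iterrows():
            lo = np.searchsorted(pos_sorted, g["start"] - flank, side="left")
            hi = np.searchsorted(pos_sorted, g["end"] + flank, side="right")
            for snp in ids_sorted[lo:hi]:
                index.gene_to_snps[g["gene"]].add(snp)
                index.snp_to_genes.setdefault(snp, set()).add(g["gene"])
    return index


# ---------------------------------------------------------------------------
# gene-trait calling
# ---------------------------------------------------------------------------


@dataclass
class GeneCallTable:
    """Boolean gene-by-trait association calls under one criterion."""

    dataset: str
    criterion: str
    calls: pd.DataFrame       # genes x traits, bool
    sig_counts: pd.DataFrame  # genes x traits, int significant window SNPs
    total_snps: pd.Series     # per-gene window SNP count

    def called_genes(self, trait: str | None = None) -> set[str]:
        """Genes called for the given trait, or for >= 1 trait if None."""
        if trait is None:
            mask = self.calls.any(axis=1)
        else:
            mask = self.calls[trait]
        return set(self.calls.index[mask])


def call_genes(
    calls: SignificanceCalls,
    index: SnpGeneIndex,
    criterion: str = "min2",
    dataset: str = "dataset",
) -> GeneCallTable:
    """Call gene-trait associations from per-trait significant SNP sets.

    criterion:
      - ``min1``   : >= 1 significant SNP in the gene window
      - ``min2``   : >= 2 significant SNPs in the gene window
      - ``frac20`` : significant / total window SNPs >= 0.20

    Genes with zero window SNPs are excluded from all criteria (their
    rows are all-False and their ratio undefined).
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; "
                         f"expected one of {CRITERIA}")
    genes = sorted(index.gene_to_snps)
    traits = sorted(calls.snps)
    totals = pd.Series({g: len(index.gene_to_snps[g]) for g in genes})
    counts = pd.DataFrame(0, index=genes, columns=traits, dtype=int)
    for trait in traits:
        sig = calls.snps[trait]
        for g in genes:
            counts.loc[g, trait] = len(index.gene_to_snps[g] & sig)
    if criterion == "min1":
        booleans = counts >= 1
    elif criterion == "min2":
        booleans = counts >= 2
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = counts.div(totals.replace(0, np.nan), axis=0)
        booleans = (frac >= 0.20).fillna(False)
    booleans = booleans & (totals > 0).to_numpy()[:, None]
    return GeneCallTable(dataset=dataset, criterion=criterion,
                         calls=booleans, sig_counts=counts,
                         total_snps=totals)


# ---------------------------------------------------------------------------
# recovery statistics
# ---------------------------------------------------------------------------


def recovery_stats(
    table: GeneCallTable | pd.Series,
    baits: pd.DataFrame | set[str],
    validated_subset: set[str] | list[str],
) -> dict:
    """Score candidate calls against known (bait) and validated genes.

    ``table`` may be a full GeneCallTable or simply a boolean Series
    indexed by gene (True = called for >= 1 trait), so printed per-gene
    indicator columns can be scored directly. A validated gene counts as
    recovered when called for at least one trait; the empirical
    false-negative rate is ``1 - recovered / |validated_subset|``.
    """
    validated = set(validated_subset)
    if not validated:
        raise ValueError("validated subset is empty")
    bait_ids = set(baits["gene"]) if isinstance(baits, pd.DataFrame) \
        else set(baits)
    if not validated <= bait_ids:
        raise ValueError("validated subset must be contained in the baits")
    if isinstance(table, GeneCallTable):
        called = table.called_genes()
        meta = {"dataset": table.dataset, "criterion": table.criterion}
    else:
        called = set(table.index[table.astype(bool)])
        meta = {"dataset": "indicator", "criterion": "as-given"}
    recovered = validated & called
    return {
        **meta,
        "n_called": len(called),
        "frac_called_are_baits":
            len(called & bait_ids) / len(called) if called else math.nan,
        "frac_baits_called": len(called & bait_ids) / len(bait_ids),
        "n_validated": len(validated),
        "n_recovered": len(recovered),
        "false_negative_rate": 1.0 - len(recovered) / len(validated),
    }


# ---------------------------------------------------------------------------
# variance explained by candidate SNPs
# ---------------------------------------------------------------------------


def candidate_snps(table: GeneCallTable, index: SnpGeneIndex) -> set[str]:
    """All SNPs within the window of any called gene."""
    out: set[str] = set()
    for g in table.called_genes():
        out |= index.gene_to_snps[g]
    return out


def explained_variance(
    geno: pd.DataFrame,
    means: pd.DataFrame,
    trait: str,
) -> float:
    """Proportion of phenotypic variance captured by a SNP subset.

    Builds a standardized-genotype genomic relationship matrix
    G = Z Z' / m from the supplied (candidate) SNPs, fits the polygenic
    model ``y = mu + g + eps`` with ``g ~ N(0, sigma_g^2 G)`` by maximum
    likelihood, and returns ``sigma_g^2 / (sigma_g^2 + sigma_e^2)``.

    ``geno`` should already be restricted to the candidate SNPs (e.g.
    those within 1 kb of significant genes).
    """
    y_all = means[trait].dropna()
    acc = [a for a in geno.index if a in y_all.index]
    if len(acc) < 10:
        raise ValueError("need at least 10 phenotyped accessions")
    X = geno.loc[acc].to_numpy(dtype=float)
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate SNP")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if not keep.any():
        raise ValueError("all candidate SNPs monomorphic in these accessions")
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    G = Z @ Z.T / Z.shape[1]
    w = np.linalg.eigvalsh((G + G.T) / 2.0)
    if w.min() < -1e-8 or Z.shape[1] == 1:
        G = G + 1e-6 * np.eye(len(G))
        logger.warning("GRM ridge-repaired (min eig %.3g, m=%d)",
                       w.min(), Z.shape[1])
    eig = KinshipEigen.from_kinship(
        pd.DataFrame(G, index=acc, columns=acc))
    y = y_all.loc[acc].to_numpy(dtype=float)
    yt = eig.vectors.T @ y
    ones_t = eig.vectors.T @ np.ones(len(acc))
    delta, sigma_g2, _ = _null_ml_delta(yt, ones_t, eig.values)
    sigma_e2 = delta * sigma_g2
    return float(sigma_g2 / (sigma_g2 + sigma_e2))
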