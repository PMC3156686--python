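"""Phenotype statistics on replicated accession panels.

Per-accession genetic means from an additive accession + replicate-block
model, fixed-effects variance partitioning with accession nested in
structure, derived (sum / ratio) traits, and neighbor-joining trait trees
from Spearman rank correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "genetic_means", "variance_partition", "TraitRecipe", "derived_traits",
    "trait_tree",
]


# ---------------------------------------------------------------------------
# genetic means
# ---------------------------------------------------------------------------


def genetic_means(
    reps: pd.DataFrame,
    context: str | None = None,
) -> pd.DataFrame:
    """Least-squares accession means adjusted for replicate-block effects.

    Fits, per trait, the two-factor additive model
    ``value ~ accession + replicate`` with sum-to-zero block coding, so
    each accession coefficient is its expected value in an average block.
    In a balanced design with no block effects this reduces to the raw
    arithmetic accession mean. An accession with no non-missing value at
    all is absent from the output (logged); one missing only for some
    traits gets NaN in those columns.

    Parameters
    ----------
    reps : long-format table with columns
        (accession, replicate, context, trait, value)
    context : restrict to one context label if given; otherwise all rows
        are pooled (replicate labels are taken as block identifiers
        within their context).
    """
    df = reps.dropna(subset=["value"])
    if context is not None:
        df = df[df["context"] == context]
    if df.empty:
        raise ValueError("no phenotype records after filtering")
    # block identity: replicate nested in context
    df = df.assign(block=df["context"].astype(str) + ":"
                   + df["replicate"].astype(str))
    accessions = sorted(df["accession"].unique())
    out = {}
    for trait, sub in df.groupby("trait", sort=True):
        present = sorted(sub["accession"].unique())
        missing = set(accessions) - set(present)
        if missing:
            logger.warning("trait %s: accessions with no data dropped: %s",
                           trait, sorted(missing))
        acc_idx = pd.Categorical(sub["accession"],
                                 categories=present).codes
        blocks = sorted(sub["block"].unique())
        blk_idx = pd.Categorical(sub["block"], categories=blocks).codes
        n_acc, n_blk = len(present), len(blocks)
        A = np.zeros((len(sub), n_acc))
        A[np.arange(len(sub)), acc_idx] = 1.0
        # sum-to-zero block contrasts (last block = -sum of others)
        B = np.zeros((len(sub), max(n_blk - 1, 0)))
        for j in range(n_blk - 1):
            B[blk_idx == j, j] = 1.0
            B[blk_idx == n_blk - 1, j] = -1.0
        X = np.hstack([A, B]) if n_blk > 1 else A
        beta, *_ = np.linalg.lstsq(X, sub["value"].to_numpy(), rcond=None)
        col = pd.Series(np.nan, index=accessions, dtype=float)
        col.loc[present] = beta[:n_acc]
        out[trait] = col
    means = pd.DataFrame(out)
    means.index.name = "accession"
    return means


# ---------------------------------------------------------------------------
# variance partitioning
# ---------------------------------------------------------------------------


def _design_blocks(
    sub: pd.DataFrame, structure: pd.Series
) -> list[tuple[str, np.ndarray]]:
    """Full-rank-ish one-hot design blocks for the nested ANOVA, in the
    fitted model's term order: S, A(S), T, R(T), T:S, T:A(S)."""
    acc = sub["accession"].to_numpy()
    struct = structure.loc[acc].to_numpy()
    ctx = sub["context"].to_numpy()
    rep = sub["replicate"].to_numpy()

    def onehot(labels: np.ndarray, drop_first: bool = True) -> np.ndarray:
        cats = pd.Categorical(labels)
        M = np.zeros((len(labels), len(cats.categories)))
        M[np.arange(len(labels)), cats.codes] = 1.0
        return M[:, 1:] if drop_first else M

    S = onehot(struct)
    A = onehot(acc)  # accession is nested: its dummies span A(S) given S
    T = onehot(ctx)
    R = onehot(np.char.add(np.char.add(ctx.astype(str), ":"),
                           rep.astype(str)))
    TS = _interact(onehot(ctx, False), onehot(struct, False))
    TA = _interact(onehot(ctx, False), onehot(acc, False))
    return [("S", S), ("A(S)", A), ("T", T), ("R(T)", R),
            ("T:S", TS), ("T:A(S)", TA)]


def _interact(M1: np.ndarray, M2: np.ndarray) -> np.ndarray:
    out = np.einsum("ij,ik->ijk", M1, M2).reshape(len(M1), -1)
    return out


def variance_partition(
    reps: pd.DataFrame,
    structure: pd.Series,
) -> pd.DataFrame:
    """Partition phenotypic variance by sequential (type-I) sums of squares.

    Fits, per trait, the fixed-effects nested ANOVA
    ``y = mu + S + A(S) + T + R(T) + T:S + T:A(S) + eps`` where S is
    subpopulation structure, A(S) accession nested in structure, T the
    context (treatment or tissue) and R(T) the replicate block nested in
    context. Terms are attributed variance in that model order; each
    term's partial R-squared (eta-squared) is its sequential sum of
    squares over the total. Broad-sense heritability is the A(S) entry;
    the structure-associated fraction is the S entry.

    Aliased terms (no residual degrees of freedom added by a term) get
    NaN eta-squared rather than 0.

    Returns a DataFrame indexed by trait with one eta^2 column per term
    plus model R2, F, p-value and degrees of freedom.
    """
    df = reps.dropna(subset=["value"])
    if df["context"].nunique() < 2:
        raise ValueError("variance partition requires both contexts")
    missing = set(df["accession"].unique()) - set(structure.index)
    if missing:
        raise ValueError(f"no structure label for accessions: {missing}")

    rows = []
    term_names = ["S", "A(S)", "T", "R(T)", "T:S", "T:A(S)"]
    for trait, sub in df.groupby("trait", sort=True):
        y = sub["value"].to_numpy(dtype=float)
        n = len(y)
        ss_total = np.sum((y - y.mean()) ** 2)
        blocks = _design_blocks(sub, structure)
        X = np.ones((n, 1))
        rss_prev = ss_total
        rank_prev = 1
        etas, dfs = {}, {}
        for name, B in blocks:
            X = np.hstack([X, B])
            Q, R_ = np.linalg.qr(X)
            keep = np.abs(np.diag(R_)) > 1e-8 * max(np.abs(np.diag(R_)).max(), 1.0)
            rank = int(keep.sum())
            fitted = Q[:, keep] @ (Q[:, keep].T @ y)
            rss = float(np.sum((y - fitted) ** 2))
            d_rank = rank - rank_prev
            if d_rank <= 0:
                etas[name] = np.nan  # aliased with earlier terms
                dfs[name] = 0
            else:
                etas[name] = (rss_prev - rss) / ss_total
                dfs[name] = d_rank
            rss_prev, rank_prev = rss, rank
        rss_full = rss_prev
        df_model = rank_prev - 1
        df_resid = n - rank_prev
        r2 = 1.0 - rss_full / ss_total if ss_total > 0 else np.nan
        if df_resid > 0 and df_model > 0 and rss_full > 0:
            F = (ss_total - rss_full) / df_model / (rss_full / df_resid)
            p = float(stats.f.sf(F, df_model, df_resid))
        else:
            F, p = np.nan, np.nan
        row = {"trait": trait, **{f"eta2_{t}": etas[t] for t in term_names},
               "R2": r2, "F": F, "p": p,
               "df_model": df_model, "df_resid": df_resid,
               **{f"df_{t}": dfs[t] for t in term_names}}
        rows.append(row)
    out = pd.DataFrame(rows).set_index("trait")
    return out


# ---------------------------------------------------------------------------
# derived traits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitRecipe:
    """Definition of a derived trait.

    kind='sum' : weighted sum of operand traits (weights default to 1).
    kind='ratio' : operands[0] / operands[1]; zero denominators yield a
    missing value rather than raising.
    """

    name: str
    kind: Literal["sum", "ratio"]
    operands: tuple[str, ...]
    weights: tuple[float, ...] | None = None


def derived_traits(
    means: pd.DataFrame,
    recipes: Sequence[TraitRecipe],
) -> pd.DataFrame:
    """Append derived sum/ratio traits to an accession-by-trait table.

    Recipes are applied in order and may reference earlier derived traits;
    cyclic or unknown references raise ``ValueError``.
    """
    out = means.copy()
    for r in recipes:
        if r.name in out.columns:
            raise ValueError(f"derived trait {r.name!r} already exists")
        unknown = [t for t in r.operands if t not in out.columns]
        if unknown:
            raise ValueError(
                f"recipe {r.name!r} references unknown traits {unknown}")
        if r.kind == "sum":
            w = r.weights or tuple(1.0 for _ in r.operands)
            if len(w) != len(r.operands):
                raise ValueError(f"recipe {r.name!r}: weight/operand mismatch")
            vals = sum(wi * out[t] for wi, t in zip(w, r.operands))
        elif r.kind == "ratio":
            if len(r.operands) != 2:
                raise ValueError(
                    f"ratio recipe {r.name!r} needs exactly 2 operands")
            num, den = out[r.operands[0]], out[r.operands[1]]
            zero = den == 0
            if zero.any():
                logger.warning("recipe %s: %d zero denominators -> missing",
                               r.name, int(zero.sum()))
            vals = num / den.where(~zero)
        else:  # pragma: no cover - dataclass Literal guards this
            raise ValueError(f"unknown recipe kind {r.kind!r}")
        out[r.name] = vals
    return out


# ---------------------------------------------------------------------------
# trait trees
# ---------------------------------------------------------------------------


def trait_distance_matrix(means: pd.DataFrame) -> pd.DataFrame:
    """Trait-by-trait distance d = 1 - Spearman rho across accessions.

    Pairwise-complete observations; constant traits (undefined rho) are
    excluded with a warning.
    """
    keep = []
    for t in means.columns:
        vals = means[t].dropna()
        if vals.nunique() <= 1:
            logger.warning("trait %s is constant; excluded from tree", t)
        else:
            keep.append(t)
    sub = means[keep]
    rho = sub.corr(method="spearman")  # pairwise-complete
    d = 1.0 - rho
    np.fill_diagonal(d.values, 0.0)
    return d


def nj_tree(d: pd.DataFrame):
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths are clamped to zero with the length
    transferred to the adjacent branch (standard NJ adjustment).
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(d.to_numpy(), ids=list(d.columns))
    return nj(dm, neg_as_zero=True)


def trait_tree(means: pd.DataFrame, min_traits: int = 4):
    """Neighbor-joining tree over traits from Spearman-correlation distances.

    Distances are ``1 - rho`` (rank correlations across accessions), so
    the tree depends only on trait orderings: any monotone transform of a
    trait leaves it unchanged. Negative NJ branch lengths are set to zero
    (with the length transferred to the adjacent branch, the standard NJ
    adjustment). Returns an unrooted ``skbio.TreeNode`` serializable to
    Newick via ``str(tree)`` or ``tree.write``.
    """
    d = trait_distance_matrix(means)
    if len(d) < min_traits:
        raise ValueError(
            f"need >= {min_traits} usable traits, got {len(d)}")
    return nj_tree(d)


def tree_to_newick(tree) -> str:
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
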