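"""Mutual-rank co-expression networks and network-distance candidate tests.

The mutual rank (MR) of a gene pair is the geometric mean of their two
reciprocal correlation ranks: rank_a(b) is the rank of b among a's
partners by descending correlation (self excluded, average ranks on
ties), and MR(a, b) = sqrt(rank_a(b) * rank_b(a)). Low MR means strong
mutual co-expression; an edge is drawn when MR is at or below a
threshold (15 by default).

Candidate networks are the connected components of the MR graph
restricted to the GWA candidates plus "bait" genes of known pathway
function, ranked by size. The distance test asks whether candidates sit
closer to baits than random control genes inside the full (all-gene) MR
network, comparing shortest-path distributions by a rank-sum (location)
and an Ansari-Bradley (dispersion) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["mutual_rank", "build_network", "CoexpressionNetwork",
           "distance_test", "DistanceDistributionResult",
           "export_pajek", "read_pajek"]


# ---------------------------------------------------------------------------
# mutual rank
# ---------------------------------------------------------------------------


def mutual_rank(corr: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    """Mutual-rank matrix of a symmetric correlation matrix.

    For each row, partners are ranked by descending correlation with self
    excluded and ties given average ranks; MR is the geometric mean of
    the two directed ranks. The minimum possible MR is 1 (a mutually
    top-ranked pair). The diagonal is 0 by convention (no self-edges).
    """
    A = corr.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("correlation matrix must be square")
    if np.nanmax(np.abs(A - A.T)) > tol:
        raise ValueError("correlation matrix is not symmetric")
    p = A.shape[0]
    ranks = np.empty_like(A)
    for i in range(p):
        row = -A[i].copy()
        row[i] = np.inf  # self ranks last and is never used
        r = stats.rankdata(row, method="average")
        ranks[i] = r
    mr = np.sqrt(ranks * ranks.T)
    np.fill_diagonal(mr, 0.0)
    return pd.DataFrame(mr, index=corr.index, columns=corr.columns)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


@dataclass
class CoexpressionNetwork:
    """Undirected MR-thresholded co-expression graph with provenance."""

    graph: nx.Graph
    threshold: float
    node_rule: str = "seeds"
    components: list[list[str]] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def build_network(
    mr: pd.DataFrame,
    threshold: float = 15.0,
    seeds: set[str] | list[str] | None = None,
    dataset_labels: dict[str, set[str]] | None = None,
) -> CoexpressionNetwork:
    """Build the MR graph on a node set and enumerate its components.

    Nodes are restricted to ``seeds`` (typically GWA candidates plus bait
    genes); with ``seeds=None`` the full gene set is used — this is the
    "full co-expression network" the distance test runs on. An edge
    (a, b) exists iff MR(a, b) <= threshold, weighted by the MR value.
    Connected components are sorted by node count descending, ties broken
    by their lexicographically smallest member; the relative size of a
    component is the primary interest signal. ``dataset_labels`` attaches
    to each node the datasets that called it (display semantics).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if seeds is not None:
        seeds = set(seeds)
        if not seeds:
            raise ValueError("seed set is empty")
        missing = seeds - set(mr.index)
        if missing:
            raise ValueError(f"seed genes absent from MR matrix: "
                             f"{sorted(missing)[:5]}...")
        nodes = sorted(seeds)
        rule = "seeds"
    else:
        nodes = list(mr.index)
        rule = "all-genes"
    sub = mr.loc[nodes, nodes].to_numpy()
    G = nx.Graph()
    G.add_nodes_from(nodes)
    iu, ju = np.triu_indices(len(nodes), k=1)
    hit = sub[iu, ju] <= threshold
    for i, j in zip(iu[hit], ju[hit]):
        G.add_edge(nodes[i], nodes[j], weight=float(sub[i, j]))
    if dataset_labels:
        for node in G.nodes:
            G.nodes[node]["datasets"] = sorted(
                name for name, s in dataset_labels.items() if node in s)
    comps = [sorted(c) for c in nx.connected_components(G)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return CoexpressionNetwork(graph=G, threshold=threshold,
                               node_rule=rule, components=comps)


# ---------------------------------------------------------------------------
# distance test
# ---------------------------------------------------------------------------


@dataclass
class DistanceDistributionResult:
    """Candidate-vs-control shortest-path distance comparison."""

    candidate_distances: np.ndarray
    control_distances: np.ndarray
    unreachable_frac_candidates: float
    unreachable_frac_controls: float
    rank_sum_stat: float
    rank_sum_p: float
    ansari_stat: float
    ansari_p: float
    n_controls: int
    per_pathway: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        rows = [
            ("candidate", len(self.candidate_distances),
             float(np.median(self.candidate_distances))
             if len(self.candidate_distances) else np.nan,
             self.unreachable_frac_candidates),
            ("control", len(self.control_distances),
             float(np.median(self.control_distances))
             if len(self.control_distances) else np.nan,
             self.unreachable_frac_controls),
        ]
        out = pd.DataFrame(
            rows, columns=["group", "n_pairs", "median", "unreachable_frac"])
        out["rank_sum_p"] = self.rank_sum_p
        out["ansari_p"] = self.ansari_p
        return out


def _pair_distances(
    G: nx.Graph, sources: list[str], baits: list[str]
) -> tuple[np.ndarray, float]:
    """All source-bait unweighted shortest-path lengths; unreachable pairs
    and zero-length self pairs are excluded, their fraction returned."""
    dist = []
    total = 0
    for b in baits:
        lengths = nx.single_source_shortest_path_length(G, b)
        for s in sources:
            if s == b:
                continue
            total += 1
            if s in lengths:
                dist.append(lengths[s])
    arr = np.array(dist, dtype=float)
    unreachable = 1.0 - len(arr) / total if total else np.nan
    return arr, unreachable


def distance_test(
    network: CoexpressionNetwork,
    candidates: set[str] | list[str],
    baits: pd.DataFrame | set[str],
    n_controls: int | None = None,
    seed: int = 0,
    pathways: dict[str, set[str]] | None = None,
) -> DistanceDistributionResult:
    """Do candidates sit closer to bait genes than random controls?

    Computes unweighted (BFS) shortest paths from every candidate and
    every control gene to every bait gene inside the full network.
    Controls are drawn uniformly without replacement from nodes that are
    neither candidates nor baits, size-matched to the candidates by
    default. Unreachable pairs are excluded from both distributions
    (rank tests on mixed finite/infinite values are ill-defined) and
    their fraction reported. A two-sided Wilcoxon rank-sum test assesses
    a location shift; an Ansari-Bradley test assesses a dispersion
    difference. With ``pathways`` given (pathway label -> bait subset),
    the comparison is repeated per pathway.
    """
    G = network.graph
    bait_ids = set(baits["gene"]) if isinstance(baits, pd.DataFrame) \
        else set(baits)
    candidates = set(candidates)
    cand_in = sorted(candidates & set(G.nodes))
    baits_in = sorted(bait_ids & set(G.nodes))
    if not cand_in or not baits_in:
        raise ValueError("candidates and baits must be present in network")
    pool = sorted(set(G.nodes) - candidates - bait_ids)
    if n_controls is None:
        n_controls = len(cand_in)
    if n_controls > len(pool):
        logger.warning("control pool smaller than requested (%d < %d)",
                       len(pool), n_controls)
        n_controls = len(pool)
    rng = np.random.default_rng(seed)
    controls = sorted(rng.choice(pool, size=n_controls, replace=False))

    d_cand, u_cand = _pair_distances(G, cand_in, baits_in)
    d_ctrl, u_ctrl = _pair_distances(G, controls, baits_in)
    if len(d_cand) == 0 and len(d_ctrl) == 0:
        raise ValueError("no reachable candidate-bait or control-bait pairs")

    def _tests(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float, float]:
        if len(a) == 0 or len(b) == 0:
            return np.nan, np.nan, np.nan, np.nan
        rs = stats.ranksums(a, b)
        try:
            ab = stats.ansari(a, b)
            ab_stat, ab_p = float(ab.statistic), float(ab.pvalue)
        except ValueError:
            ab_stat, ab_p = np.nan, np.nan
        return float(rs.statistic), float(rs.pvalue), ab_stat, ab_p

    rs_stat, rs_p, ab_stat, ab_p = _tests(d_cand, d_ctrl)

    per_pathway = None
    if pathways:
        rows = []
        for label, genes in sorted(pathways.items()):
            sub_baits = sorted(set(genes) & set(baits_in))
            if not sub_baits:
                continue
            dc, uc = _pair_distances(G, cand_in, sub_baits)
            dn, un = _pair_distances(G, controls, sub_baits)
            s, p, s2, p2 = _tests(dc, dn)
            rows.append((label, len(dc), len(dn),
                         float(np.median(dc)) if len(dc) else np.nan,
                         float(np.median(dn)) if len(dn) else np.nan,
                         p, p2))
        per_pathway = pd.DataFrame(rows, columns=[
            "pathway", "n_candidate_pairs", "n_control_pairs",
            "candidate_median", "control_median", "rank_sum_p", "ansari_p"])

    return DistanceDistributionResult(
        candidate_distances=d_cand, control_distances=d_ctrl,
        unreachable_frac_candidates=u_cand,
        unreachable_frac_controls=u_ctrl,
        rank_sum_stat=rs_stat, rank_sum_p=rs_p,
        ansari_stat=ab_stat, ansari_p=ab_p,
        n_controls=n_controls, per_pathway=per_pathway)


# ---------------------------------------------------------------------------
# Pajek export
# ---------------------------------------------------------------------------


def export_pajek(net: CoexpressionNetwork, path) -> None:
    """Write the network in the Pajek .net dialect.

    ``*Vertices n`` with 1-based ids and quoted labels, then ``*Edges``
    with unordered vertex-id pairs and the MR edge weight. Round-trips
    exactly through :func:`read_pajek`.
    """
    nodes = sorted(net.graph.nodes)
    if not nodes:
        raise ValueError("cannot export an empty network")
    idx = {n: i + 1 for i, n in enumerate(nodes)}
    with open(path, "w") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for n in nodes:
            fh.write(f'{idx[n]} "{n}"\n')
        fh.write("*Edges\n")
        for a, b, data in sorted(net.graph.edges(data=True)):
            i, j = sorted((idx[a], idx[b]))
            fh.write(f"{i} {j} {data.get('weight', 1.0):.6g}\n")


def read_pajek(path) -> CoexpressionNetwork:
    """Read a Pajek .net file written by :func:`export_pajek`."""
    G = nx.Graph()
    labels: dict[int, str] = {}
    mode = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                mode = "vertices"
                continue
            if low.startswith("*edges") or low.startswith("*arcs"):
                mode = "edges"
                continue
            if mode == "vertices":
                vid, label = line.split(maxsplit=1)
                labels[int(vid)] = label.strip().strip('"')
                G.add_node(labels[int(vid)])
            elif mode == "edges":
                parts = line.split()
                i, j = int(parts[0]), int(parts[1])
                w = float(parts[2]) if len(parts) > 2 else 1.0
                G.add_edge(labels[i], labels[j], weight=w)
    comps = [sorted(c) for c in nx.connected_components(G)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return CoexpressionNetwork(graph=G, threshold=float("nan"),
                               node_rule="file", components=comps)
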