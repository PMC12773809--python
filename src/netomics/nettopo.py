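"""Interactome seed expansion and network-stability analysis.

Two complementary prioritizations expand a seed gene set (the
multi-omics signature) over a protein-interaction network:

* **Hidden Nodes (HN)** — local over-connectivity: each non-seed node is
  scored by the upper-tail hypergeometric probability of observing at
  least its number of seed neighbours given its degree.
* **Network propagation (NP)** — global diffusion: seed mass is spread
  by a random walk with restart; significance comes from degree-matched
  permuted seed sets.

Both report Benjamini-Hochberg adjusted p-values and scores on the
-log10 scale. A four-pillar stability suite characterizes the result:
robustness under random node removal, node criticality via global
efficiency, structural metrics (path length, clustering, modularity Q,
degree/betweenness centralization), and regulator statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._utils import adjust_pvalues

_MIN_LOG_P = 1e-300  # floor before -log10 so scores stay finite


@dataclass
class InteractionNetwork:
    """Undirected weighted interaction graph with optional regulator flags."""

    graph: nx.Graph
    regulators: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        g = self.graph
        loops = list(nx.selfloop_edges(g))
        if loops:
            raise ValueError(f"self-loop on node {loops[0][0]!r}")
        for u, v, w in g.edges(data="weight", default=1.0):
            if not (w > 0):
                raise ValueError(f"non-positive weight on edge ({u!r}, {v!r})")

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


_STRING_ALIASES = {"protein1": "node1", "protein2": "node2", "combined_score": "weight"}


def read_edge_list(path: str | Path, score_threshold: float = 0.0) -> InteractionNetwork:
    """Read a tab-delimited ``node1 node2 weight`` edge list.

    STRING-export headers (``protein1 protein2 combined_score``) are
    recognized; a missing weight column defaults to 1. Edges with
    weight below ``score_threshold`` are dropped.
    """
    path = Path(path)
    first = path.open().readline().rstrip("\n").split("\t")
    has_header = any(tok in _STRING_ALIASES or tok in ("node1", "node2", "weight")
                     for tok in first)
    if has_header:
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        df = df.rename(columns=_STRING_ALIASES)
    else:
        ncol = len(first)
        names = ["node1", "node2", "weight"][:ncol]
        df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={0: str, 1: str})
    if "weight" not in df.columns:
        df["weight"] = 1.0
    df["weight"] = df["weight"].astype(float)
    df = df[df["weight"] >= score_threshold]
    g = nx.Graph()
    for u, v, w in df[["node1", "node2", "weight"]].itertuples(index=False):
        if u == v:
            continue
        g.add_edge(str(u), str(v), weight=float(w))
    return InteractionNetwork(g)


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    rows = [(u, v, g.get("weight", 1.0)) for u, v, g in
            ((u, v, d) for u, v, d in net.graph.edges(data=True))]
    pd.DataFrame(rows, columns=["node1", "node2", "weight"]).to_csv(
        path, sep="\t", index=False)


def _scores_frame(nodes, raw_p, method: str, alpha_mask) -> pd.DataFrame:
    adj = adjust_pvalues(np.asarray(raw_p))
    score = -np.log10(np.maximum(adj, _MIN_LOG_P))
    df = pd.DataFrame({
        "node": nodes, "raw_p": raw_p, "adj_p": adj,
        "score": score, "method": method, "significant": alpha_mask(adj, score),
    })
    return df.sort_values(["score", "node"], ascending=[False, True]).reset_index(drop=True)


def hidden_nodes(net: InteractionNetwork, seeds: set, alpha: float = 0.05,
                 adjust: str = "bh", include_seeds: bool = False) -> pd.DataFrame:
    """Hypergeometric over-connectivity of candidate nodes to the seed set.

    For candidate v with degree k and x seed neighbours the raw p-value
    is P(X >= x) with X ~ Hypergeom(N=|nodes|-1, K=|seeds| (minus one if
    v is itself a seed), n=k): the chance a random neighbourhood of v's
    size captures at least as many seeds. Adjusted p-values (BH by
    default) below ``alpha`` mark significant nodes; scores are
    -log10(adjusted p). Returns every evaluated candidate.
    """
    g = net.graph
    seed_set = set(seeds) & set(g.nodes())
    if not seed_set:
        raise ValueError("no seed overlaps the network node set")
    candidates = [v for v in g.nodes() if include_seeds or v not in seed_set]
    N = g.number_of_nodes() - 1
    raw = np.empty(len(candidates))
    for i, v in enumerate(candidates):
        k = g.degree(v)
        K = len(seed_set) - (1 if v in seed_set else 0)
        x = sum(1 for u in g.neighbors(v) if u in seed_set)
        raw[i] = 1.0 if x == 0 else float(hypergeom.sf(x - 1, N, K, k))
    adj = adjust_pvalues(raw, method=adjust)
    score = -np.log10(np.maximum(adj, _MIN_LOG_P))
    df = pd.DataFrame({"node": candidates, "raw_p": raw, "adj_p": adj,
                       "score": score, "method": "HN",
                       "significant": adj < alpha})
    return df.sort_values(["score", "node"], ascending=[False, True]).reset_index(drop=True)


def _column_stochastic(g: nx.Graph, nodes: list) -> np.ndarray:
    A = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    colsum = A.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return A / colsum


def propagate(net: InteractionNetwork, seeds: set, restart: float = 0.5,
              tol: float = 1e-6, max_iter: int = 10_000) -> pd.Series:
    """Random walk with restart from a uniform seed distribution.

    Iterates F <- (1-restart) W F + restart F0 with W the
    column-stochastic (degree-normalized) adjacency; total mass is
    conserved at every step.
    """
    if not (0 < restart <= 1):
        raise ValueError("restart must lie in (0, 1]")
    nodes = list(net.graph.nodes())
    seed_set = set(seeds) & set(nodes)
    if not seed_set:
        raise ValueError("seeds empty after intersection with node set")
    W = _column_stochastic(net.graph, nodes)
    F0 = np.array([1.0 / len(seed_set) if v in seed_set else 0.0 for v in nodes])
    F = F0.copy()
    for _ in range(max_iter):
        F_new = (1 - restart) * (W @ F) + restart * F0
        if np.abs(F_new - F).sum() < tol:
            F = F_new
            break
        F = F_new
    return pd.Series(F, index=nodes, name="propagation")


def propagate_exact(net: InteractionNetwork, seeds: set, restart: float = 0.5) -> pd.Series:
    """Closed-form stationary solution restart (I - (1-restart) W)^-1 F0."""
    nodes = list(net.graph.nodes())
    seed_set = set(seeds) & set(nodes)
    W = _column_stochastic(net.graph, nodes)
    F0 = np.array([1.0 / len(seed_set) if v in seed_set else 0.0 for v in nodes])
    F = restart * np.linalg.solve(np.eye(len(nodes)) - (1 - restart) * W, F0)
    return pd.Series(F, index=nodes, name="propagation")


def _degree_bins(degrees: np.ndarray, n_bins: int = 10) -> np.ndarray:
    edges = np.quantile(degrees, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    return np.clip(np.searchsorted(edges, degrees, side="right") - 1, 0, len(edges) - 2)


def network_propagation(net: InteractionNetwork, seeds: set, restart: float = 0.5,
                        tol: float = 1e-6, n_perm: int = 1000, top_frac: float = 0.01,
                        seed: int | None = None, adjust: str = "bh") -> pd.DataFrame:
    """Diffusion scores with degree-aware permutation significance.

    Null seed sets of matching size are drawn within 10 degree-quantile
    bins (matching the real seeds' bin composition) to control hub
    bias. Empirical p = (1 + #{F_null >= F_obs}) / (n_perm + 1), BH
    adjusted; score = -log10(adjusted p). The ``significant`` column
    marks the ceil(top_frac * |nodes|) top-scoring non-seed nodes.
    """
    rng = np.random.default_rng(seed)
    nodes = list(net.graph.nodes())
    seed_set = set(seeds) & set(nodes)
    F_obs = propagate(net, seed_set, restart=restart, tol=tol).to_numpy()

    degrees = np.array([net.graph.degree(v) for v in nodes])
    bins = _degree_bins(degrees)
    by_bin: dict[int, np.ndarray] = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    node_pos = {v: i for i, v in enumerate(nodes)}
    seed_bins = [bins[node_pos[s]] for s in sorted(seed_set)]

    W = _column_stochastic(net.graph, nodes)
    I_minus = np.eye(len(nodes)) - (1 - restart) * W
    solve = np.linalg.inv(I_minus)  # reused across permutations
    exceed = np.zeros(len(nodes))
    for _ in range(n_perm):
        idx = [by_bin[b][rng.integers(len(by_bin[b]))] for b in seed_bins]
        idx = np.unique(idx)
        F0 = np.zeros(len(nodes))
        F0[idx] = 1.0 / len(idx)
        F_null = restart * (solve @ F0)
        exceed += F_null >= F_obs - 1e-15
    raw = (1.0 + exceed) / (n_perm + 1.0)
    adj = adjust_pvalues(raw, method=adjust)
    score = -np.log10(np.maximum(adj, _MIN_LOG_P))

    df = pd.DataFrame({"node": nodes, "diffusion": F_obs, "raw_p": raw,
                       "adj_p": adj, "score": score, "method": "NP"})
    df["is_seed"] = df["node"].isin(seed_set)
    non_seed = df[~df["is_seed"]]
    n_keep = math.ceil(top_frac * len(nodes))
    top = non_seed.sort_values(["score", "diffusion", "node"],
                               ascending=[False, False, True]).head(n_keep)["node"]
    df["significant"] = df["node"].isin(set(top))
    return df.sort_values(["score", "diffusion", "node"],
                          ascending=[False, False, True]).reset_index(drop=True)


def robustness(net: InteractionNetwork, fractions: np.ndarray | None = None,
               reps: int = 20, seed: int | None = None) -> tuple[pd.DataFrame, float]:
    """LCC survival under uniform random node removal.

    Per removal fraction f: ``reps`` draws of floor(f*N) nodes are
    deleted and the ratio LCC(after)/LCC(original) recorded. Returns
    the mean curve and the overall score (unweighted mean over
    fractions).
    """
    if fractions is None:
        fractions = np.arange(0.05, 0.501, 0.05)
    fractions = np.asarray(fractions, dtype=float)
    if (fractions >= 1).any():
        raise ValueError("removal fractions must be < 1")
    g = net.graph
    nodes = np.array(list(g.nodes()), dtype=object)
    if len(nodes) < 20:
        raise ValueError("robustness needs at least 20 nodes")
    lcc0 = len(max(nx.connected_components(g), key=len))
    rng = np.random.default_rng(seed)
    means = []
    for f in fractions:
        n_remove = int(math.floor(f * len(nodes)))
        ratios = []
        for _ in range(reps):
            drop = set(rng.choice(nodes, size=n_remove, replace=False))
            h = g.subgraph([v for v in nodes if v not in drop])
            lcc = len(max(nx.connected_components(h), key=len)) if h.number_of_nodes() else 0
            ratios.append(lcc / lcc0)
        means.append(float(np.mean(ratios)))
    curve = pd.DataFrame({"fraction": fractions, "lcc_ratio": means})
    return curve, float(np.mean(means))


def global_efficiency(net: InteractionNetwork) -> float:
    """Mean inverse shortest-path length over ordered node pairs (1/inf = 0)."""
    if net.n_nodes < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return nx.global_efficiency(net.graph)


def node_criticality(net: InteractionNetwork, nodes=None) -> pd.Series:
    """Relative drop in global efficiency when each node is deleted.

    criticality(v) = (E(G) - E(G without v)) / E(G), with the reduced
    efficiency computed on the N-1 remaining nodes; negative values mean
    removal raises efficiency (peripheral nodes). ``nodes`` restricts
    the evaluation to a subset (each deletion costs an all-pairs BFS).
    """
    E0 = global_efficiency(net)
    if E0 == 0:
        raise ValueError("global efficiency is zero (empty edge set); criticality undefined")
    g = net.graph
    out = {}
    for v in (g.nodes() if nodes is None else nodes):
        h = g.subgraph([u for u in g.nodes() if u != v])
        Ev = nx.global_efficiency(h) if h.number_of_nodes() >= 2 else 0.0
        out[v] = (E0 - Ev) / E0
    return pd.Series(out, name="criticality")


def degree_centralization(g: nx.Graph) -> float:
    """Freeman degree centralization, 1 for a star and 0 for a regular graph."""
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("centralization needs at least 3 nodes")
    deg = np.array([d for _, d in g.degree()])
    return float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))


def betweenness_centralization(g: nx.Graph) -> float:
    """Freeman centralization of normalized betweenness (1 for a star)."""
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("centralization needs at least 3 nodes")
    bc = np.array(list(nx.betweenness_centrality(g, normalized=True).values()))
    return float((bc.max() - bc).sum() / (n - 1))


def structural_metrics(net: InteractionNetwork, modularity_method: str = "greedy",
                       seed: int | None = None) -> dict:
    """Average path length (on the LCC), clustering, modularity Q, centralizations.

    Modularity uses deterministic greedy (CNM) agglomeration by default
    so Q is reproducible; ``modularity_method="louvain"`` uses seeded
    Louvain.
    """
    g = net.graph
    if g.number_of_nodes() < 3:
        raise ValueError("structural metrics need at least 3 nodes")
    lcc = g.subgraph(max(nx.connected_components(g), key=len))
    apl = nx.average_shortest_path_length(lcc) if lcc.number_of_nodes() > 1 else 0.0
    clustering = nx.average_clustering(g, count_zeros=True)
    if modularity_method == "louvain":
        parts = nx.algorithms.community.louvain_communities(g, seed=seed)
    else:
        parts = list(nx.algorithms.community.greedy_modularity_communities(g))
    Q = nx.algorithms.community.modularity(g, parts)
    return {
        "avg_path_length": float(apl),
        "clustering_coefficient": float(clustering),
        "modularity_Q": float(Q),
        "communities": [sorted(c) for c in parts],
        "degree_centralization": degree_centralization(g),
        "betweenness_centralization": betweenness_centralization(g),
    }


def regulator_stats(net: InteractionNetwork, regulators: set | None = None) -> dict:
    """Degree ratio and mean normalized betweenness of regulators vs the rest."""
    regs = set(net.regulators if regulators is None else regulators) & set(net.graph.nodes())
    others = set(net.graph.nodes()) - regs
    if not regs or not others:
        raise ValueError("both regulator and non-regulator sets must be nonempty")
    deg = dict(net.graph.degree())
    mean_reg = np.mean([deg[v] for v in regs])
    mean_other = np.mean([deg[v] for v in others])
    if mean_other == 0:
        raise ValueError("non-regulator mean degree is zero; ratio undefined")
    bc = nx.betweenness_centrality(net.graph, normalized=True)
    return {
        "degree_ratio": float(mean_reg / mean_other),
        "regulator_mean_betweenness": float(np.mean([bc[v] for v in regs])),
        "non_regulator_mean_betweenness": float(np.mean([bc[v] for v in others])),
    }


def stability_report(net: InteractionNetwork, regulators: set | None = None,
                     reps: int = 20, seed: int | None = None,
                     criticality_nodes=None) -> dict:
    """Four-pillar stability suite bundled into one JSON-serializable dict.

    ``criticality_nodes`` limits the per-node efficiency sweep (e.g. to
    the top-degree hubs) on large networks.
    """
    curve, overall = robustness(net, reps=reps, seed=seed)
    crit = node_criticality(net, nodes=criticality_nodes)
    struct = structural_metrics(net)
    report = {
        "robustness_curve": curve.to_dict(orient="list"),
        "robustness_score": overall,
        "criticality": crit.to_dict(),
        **{k: v for k, v in struct.items() if k != "communities"},
        "n_communities": len(struct["communities"]),
    }
    regs = set(net.regulators if regulators is None else regulators)
    if regs:
        report.update(regulator_stats(net, regs))
    return report
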