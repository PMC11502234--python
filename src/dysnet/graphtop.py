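"""Protein-interaction-network topology: filtering, hubs, fragmentation,
seeded growth, and gene-set enrichment.

Interaction files follow the STRING edge-list dialect: one row per protein
pair with per-channel evidence scores (experimental, database, fusion,
textmining, coexpression, neighborhood, cooccurence) as integers 0-1000 and
a precomputed combined score. Filtering recomputes the combined score from
the *selected* channels only, so evidence from excluded channels (e.g. text
mining) cannot carry an edge over the confidence threshold.

Hub detection uses maximal clique centrality (MCC): each node scores the
sum of (|C| - 1)! over the maximal cliques C that contain it. A node whose
neighbors share no edges has only size-<=2 maximal cliques through it, so
its MCC reduces to its degree — the conventional special case falls out of
the definition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FragmentationStats",
    "load_interactions",
    "string_combined_score",
    "mcc_scores",
    "topological_coefficients",
    "delete_nodes_stats",
    "grow_seeded_network",
    "hypergeom_enrichment",
    "read_gmt",
]

#: STRING's prior probability that a random protein pair interacts.
STRING_PRIOR = 0.041

#: Synonyms accepted for channel selection -> file column name.
CHANNEL_ALIASES = {
    "experiments": "experimental",
    "experimental": "experimental",
    "databases": "database",
    "database": "database",
    "fusion": "fusion",
    "textmining": "textmining",
    "coexpression": "coexpression",
    "neighborhood": "neighborhood",
    "cooccurence": "cooccurence",
    "cooccurrence": "cooccurence",
}

DEFAULT_CHANNELS = ("experiments", "databases", "fusion")


@dataclass(frozen=True)
class FragmentationStats:
    """Summary topology of a graph snapshot."""

    n_nodes: int
    n_edges: int
    n_components: int
    avg_degree: float
    removed_disconnected: tuple[str, ...] = ()

    @classmethod
    def of(cls, g: nx.Graph, removed: tuple[str, ...] = ()) -> "FragmentationStats":
        n = g.number_of_nodes()
        return cls(
            n_nodes=n,
            n_edges=g.number_of_edges(),
            n_components=nx.number_connected_components(g) if n else 0,
            avg_degree=(2.0 * g.number_of_edges() / n) if n else 0.0,
            removed_disconnected=removed,
        )


def string_combined_score(scores: dict[str, float], prior: float = STRING_PRIOR) -> float:
    """STRING-style combined confidence from per-channel scores in [0, 1].

    Each channel score is stripped of the prior, the de-priored
    probabilities are combined as 1 - prod(1 - s_i), and the prior is added
    back: a single channel passes through unchanged.
    """
    noprior = 1.0
    for s in scores.values():
        s_adj = max(0.0, (s - prior) / (1.0 - prior))
        noprior *= 1.0 - s_adj
    return prior + (1.0 - prior) * (1.0 - noprior)


def load_interactions(
    path: str | Path,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    min_combined: float = 0.9,
) -> nx.Graph:
    """Read a STRING-dialect edge list, filter by channel-recomputed score.

    Only the named evidence channels contribute; edges whose recomputed
    combined score falls below ``min_combined`` (0-1 scale) are dropped, and
    nodes left without edges are removed. Self-loops and duplicate pairs are
    collapsed.
    """
    try:
        cols = [CHANNEL_ALIASES[c] for c in channels]
    except KeyError as e:
        raise ValueError(f"unknown channel name: {e.args[0]!r}") from None
    table = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in ("protein1", "protein2", *cols) if c not in table.columns]
    if missing:
        raise ValueError(f"interaction file missing columns: {missing}")
    g = nx.Graph()
    for row in table.itertuples(index=False):
        r = row._asdict()
        u, v = str(r["protein1"]), str(r["protein2"])
        if u == v:
            continue
        per_channel = {}
        for c in cols:
            s = float(r[c])
            if not 0 <= s <= 1000:
                raise ValueError(f"malformed score {s} for channel {c!r} on {u}-{v}")
            per_channel[c] = s / 1000.0
        combined = string_combined_score(per_channel)
        if combined >= min_combined:
            g.add_edge(u, v, combined_score=int(round(combined * 1000)), **{
                c: int(round(s * 1000)) for c, s in per_channel.items()
            })
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


def _check_simple(graph: nx.Graph) -> None:
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("an undirected simple graph is required")
    if any(u == v for u, v in graph.edges):
        raise ValueError("graph has self-loops")


def mcc_scores(graph: nx.Graph, max_cliques: int = 1_000_000) -> pd.DataFrame:
    """Maximal clique centrality per node, with dense ranks.

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!, with
    cliques enumerated exactly by Bron-Kerbosch with pivoting. Enumeration
    aborts with an error if it exceeds ``max_cliques`` — worst-case clique
    counts are exponential, though interactomes at high confidence are far
    below the guard.

    Returns a frame indexed by node with columns ``mcc``, ``rank`` (dense:
    tied scores share a rank) and ``degree``, sorted by rank.
    """
    _check_simple(graph)
    score = dict.fromkeys(graph.nodes, 0)
    for i, clique in enumerate(nx.find_cliques(graph)):
        if i >= max_cliques:
            raise RuntimeError(
                f"maximal clique enumeration exceeded the {max_cliques} guard"
            )
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            score[v] += contrib
    table = pd.DataFrame(
        {
            "mcc": pd.Series(score),
            "degree": pd.Series(dict(graph.degree)),
        }
    )
    table["rank"] = table["mcc"].rank(method="dense", ascending=False).astype(int)
    return table.sort_values(["rank", "mcc"], ascending=[True, False])


def top_hubs(ranking: pd.DataFrame, top: int = 10) -> list[str]:
    """Top-``top`` nodes by MCC dense rank; ties at the boundary retained."""
    ordered = ranking.sort_values("mcc", ascending=False)
    if len(ordered) <= top:
        return list(ordered.index)
    cutoff = ordered["mcc"].iloc[top - 1]
    return list(ordered.index[ordered["mcc"] >= cutoff])


def topological_coefficients(graph: nx.Graph) -> pd.Series:
    """Topological coefficient TC(v) per node.

    TC(v) averages J(v, u)/k(v) over all nodes u != v that share at least
    one neighbor with v, where J(v, u) is the number of shared neighbors
    plus one if u and v are adjacent, and k(v) is v's degree. Nodes with
    degree <= 1 or no qualifying partner score 0. In hub-and-spoke networks
    TC falls with degree.
    """
    _check_simple(graph)
    neighbors = {v: set(graph[v]) for v in graph.nodes}
    tc = {}
    for v in graph.nodes:
        k = len(neighbors[v])
        if k <= 1:
            tc[v] = 0.0
            continue
        partners = set()
        for w in neighbors[v]:
            partners.update(neighbors[w])
        partners.discard(v)
        js = []
        for u in partners:
            shared = len(neighbors[v] & neighbors[u])
            if shared == 0:
                continue
            js.append(shared + (1 if u in neighbors[v] else 0))
        tc[v] = (np.mean(js) / k) if js else 0.0
    return pd.Series(tc, name="tc")


def delete_nodes_stats(
    graph: nx.Graph, nodes: list[str]
) -> tuple[nx.Graph, FragmentationStats, FragmentationStats]:
    """Remove nodes (plus any nodes thereby disconnected) and compare topology.

    Returns the pruned graph and (before, after) fragmentation statistics;
    the "after" record lists the nodes that were removed because the
    deletion left them without edges.
    """
    unknown = [v for v in nodes if v not in graph]
    if unknown:
        raise ValueError(f"unknown node id(s): {unknown}")
    before = FragmentationStats.of(graph)
    pruned = graph.copy()
    pruned.remove_nodes_from(nodes)
    stranded = tuple(sorted(nx.isolates(pruned)))
    pruned.remove_nodes_from(stranded)
    after = FragmentationStats.of(pruned, removed=stranded)
    return pruned, before, after


def grow_seeded_network(
    seeds: list[str],
    candidates: list[str],
    interactome: nx.Graph,
) -> nx.Graph:
    """Grow a network from seed genes by direct interactions only.

    Starting from the seeds (and the interactome edges among them),
    candidates joining the network must have a direct edge to a node already
    included; admission repeats to a fixpoint, so candidate chains reach in
    only through a connection to the seeded core — candidate-only islands
    are never admitted. The result is the interactome subgraph induced on
    the included nodes.
    """
    if not seeds:
        raise ValueError("at least one seed gene is required")
    present = [s for s in seeds if s in interactome]
    if not present:
        warnings.warn("no seed gene found in the interactome", stacklevel=2)
        return nx.Graph()
    included = set(present)
    pool = {c for c in candidates if c in interactome} - included
    changed = True
    while changed:
        changed = False
        for c in sorted(pool):
            if any(nb in included for nb in interactome[c]):
                included.add(c)
                pool.remove(c)
                changed = True
    return interactome.subgraph(included).copy()


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene-set file: set id, description, then member genes, tab-split."""
    collection = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        collection[parts[0]] = parts[2:]
    return collection


def hypergeom_enrichment(
    query: list[str],
    collection: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Over-representation of the query in each gene set.

    One-sided hypergeometric upper-tail p per set, odds ratio from the 2x2
    table (Haldane 0.5 correction when any cell is zero), and BH-adjusted q
    across the collection. Sets are intersected with the universe; the query
    must be a subset of the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    stray = set(query) - uni
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    q = set(query)
    n_uni, n_query = len(uni), len(q)
    rows = []
    for set_id, genes in collection.items():
        members = set(genes) & uni
        k = len(q & members)
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, n_uni, K, n_query))
        a, b = k, n_query - k
        c, d = K - k, n_uni - n_query - K + k
        if min(a, b, c, d) == 0:
            a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        rows.append(
            {
                "set": set_id,
                "overlap": k,
                "set_size": K,
                "expected": n_query * K / n_uni,
                "odds_ratio": (a * d) / (b * c),
                "p": min(max(p, np.finfo(float).tiny), 1.0),
            }
        )
    result = pd.DataFrame(rows).set_index("set")
    if len(result):
        result["q"] = multipletests(result["p"], method="fdr_bh")[1]
    return result.sort_values("p")
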