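"""Static graph-centrality indices and per-link flexibility scores.

These provide the static-topology counterpoint to the dynamic
(leave-one-out) flexibility indices: the bipartite meta-network is treated
as a single undirected, unweighted simple graph of N vertices, and the
classical centralities are computed on it with the normalizations below.

* degree: incident edge count divided by N - 1;
* betweenness: shortest-path vertex betweenness normalized by
  2 / ((N - 1)(N - 2)) so it lies in [0, 1];
* eigenvector: principal adjacency eigenvector scaled to maximum 1
  (computed on the largest connected component; other components get 0);
* closeness: reciprocal of the total graph distance to reachable vertices,
  divided by (size of own component) - 1;
* edge betweenness: shortest-path betweenness of each edge divided by the
  number of unordered vertex pairs N(N - 1) / 2.

The per-link *flexibility* score contrasts this static view with the
dynamic one: each edge scores the product of its two endpoints'
min-max-scaled coordinator indices (max delta_RW), so the most flexible
links join the top coordinator of each guild.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .network import BipartiteNetwork


def _graph(net: BipartiteNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.consumers, guild="consumer")
    g.add_nodes_from(net.resources, guild="resource")
    g.add_edges_from(net.edges)
    return g


def vertex_centralities(net: BipartiteNetwork) -> pd.DataFrame:
    """Normalized degree, betweenness, eigenvector and closeness per vertex.

    Returns a DataFrame indexed by species with a ``guild`` column and the
    four centralities.  On networks with fewer than three vertices
    betweenness is reported as 0 with ``degenerate=True``.
    """
    if net.is_empty:
        raise ValueError("cannot compute centralities on an empty network")
    g = _graph(net)
    n = g.number_of_nodes()
    degree_norm = {v: d / (n - 1) for v, d in g.degree()} if n > 1 else {v: 0.0 for v in g}
    degenerate = n < 3
    if degenerate:
        betweenness = {v: 0.0 for v in g}
    else:
        betweenness = nx.betweenness_centrality(g, normalized=True)
    eigen = {v: 0.0 for v in g}
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(components[0])
    if giant.number_of_nodes() > 2:
        ev = nx.eigenvector_centrality_numpy(giant)
        top = max(ev.values())
        eigen.update({v: x / top for v, x in ev.items()})
    else:  # a single edge: principal eigenvector is uniform
        eigen.update({v: 1.0 for v in giant})
    closeness = {}
    for comp in components:
        sub = g.subgraph(comp)
        nc = sub.number_of_nodes()
        for v in comp:
            total_dist = sum(nx.single_source_shortest_path_length(sub, v).values())
            closeness[v] = (1.0 / total_dist) / (nc - 1) if total_dist > 0 else 0.0
    rows = [
        {
            "species": v,
            "guild": g.nodes[v]["guild"],
            "degree_norm": degree_norm[v],
            "betweenness_norm": betweenness[v],
            "eigenvector_scaled": eigen[v],
            "closeness_norm": closeness[v],
            "degenerate": degenerate,
        }
        for v in sorted(g.nodes)
    ]
    df = pd.DataFrame(rows).set_index("species")
    df.attrs["n_vertices"] = n
    return df


def edge_betweenness(net: BipartiteNetwork) -> pd.DataFrame:
    """Standardized shortest-path edge betweenness per link.

    Each edge's betweenness (number of unordered vertex pairs whose shortest
    paths traverse it, with fractional credit for ties) is divided by the
    total number of unordered pairs N(N - 1) / 2.
    """
    if net.is_empty:
        raise ValueError("cannot compute edge betweenness on an empty network")
    g = _graph(net)
    n = g.number_of_nodes()
    raw = nx.edge_betweenness_centrality(g, normalized=False)
    n_pairs = n * (n - 1) / 2
    rows = []
    for (x, y), val in raw.items():
        c, r = (x, y) if x in net.consumers else (y, x)
        rows.append(
            {
                "consumer": c,
                "resource": r,
                "edge_betweenness_std": val / n_pairs,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["consumer", "resource"], kind="mergesort")
        .reset_index(drop=True)
    )


def _minmax(values: pd.Series) -> pd.Series:
    lo, hi = values.min(), values.max()
    if not np.isfinite(lo) or not np.isfinite(hi) or hi == lo:
        # constant (or all-NaN) guild: scaling is undefined, use 1 throughout
        return pd.Series(1.0, index=values.index)
    return (values - lo) / (hi - lo)


def link_flexibility(
    summary: pd.DataFrame,
    meta: BipartiteNetwork,
    *,
    min_count: int = 10,
    scale_consumers: bool = True,
    scale_resources: bool = True,
) -> pd.DataFrame:
    """Per-link flexibility scores on the meta-network.

    Each guild's ``max_delta_RW`` vector is min-max scaled to [0, 1]
    (per-guild scaling can be disabled to use raw deltas on one axis), and
    each edge scores the product of its endpoints' scaled values.  Edges
    with weight below ``min_count`` are dropped (default 10, the
    conventional detection-count threshold for well-observed links; 0
    disables the filter).  Edge betweenness of the *full* meta-network is
    attached for the static-vs-dynamic comparison.

    Raises
    ------
    KeyError
        If a meta-network species is missing from ``summary``.
    """
    scores = summary.set_index("species")["max_delta_RW"]
    missing = sorted(meta.species - set(scores.index))
    if missing:
        raise KeyError(f"species missing from contribution summary: {missing[:5]}")
    cons = sorted(meta.consumers)
    ress = sorted(meta.resources)
    c_scores = scores.loc[cons]
    r_scores = scores.loc[ress]
    c_scaled = _minmax(c_scores) if scale_consumers else c_scores
    r_scaled = _minmax(r_scores) if scale_resources else r_scores
    eb = edge_betweenness(meta).set_index(["consumer", "resource"])["edge_betweenness_std"]
    rows = []
    for (c, r), w in sorted(meta.edges.items()):
        if min_count and w < min_count:
            continue
        rows.append(
            {
                "consumer": c,
                "resource": r,
                "weight": w,
                "flexibility": float(c_scaled[c] * r_scaled[r]),
                "edge_betweenness_std": float(eb[(c, r)]),
            }
        )
    df = pd.DataFrame(
        rows, columns=["consumer", "resource", "weight", "flexibility", "edge_betweenness_std"]
    )
    df.attrs["min_count"] = min_count
    return df


def write_table(df: pd.DataFrame, path, *, delimiter: str = "\t", header_comments=()) -> None:
    """Write a centrality/flexibility table as tidy TSV."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=delimiter, index=not isinstance(df.index, pd.RangeIndex))
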