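"""Data model and I/O for temporal bipartite weighted interaction networks.

The central objects are :class:`BipartiteNetwork` (one realization of a
consumer-resource network, e.g. the spider-prey web observed in one month)
and :class:`NetworkSeries` (an ordered sequence of realizations together
with the derived *meta-network*, the union of all realizations with summed
edge weights).

Edge weights are interaction frequencies (e.g. prey-detection counts: the
number of predator individuals in which a prey taxon's DNA was detected).
Species occurrence in a realization is defined as having at least one
incident edge there; the data record interactions only, so there is no
notion of an interaction-free occurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, SchemaError

Edge = tuple[str, str]

#: edge-class labels used when two networks are aligned
SHARED = "shared"
UNIQUE_RW = "unique_rw"  # one-sided edge between species present in both networks
UNIQUE_ST = "unique_st"  # one-sided edge involving a species present in only one


class BipartiteNetwork:
    """A weighted bipartite network over two disjoint guilds.

    Parameters
    ----------
    edges
        Mapping from ``(consumer_id, resource_id)`` to a positive weight.
        An empty mapping yields a valid (degenerate) empty network; such
        networks arise when a species removal empties a realization and are
        flagged by downstream dissimilarity computations.

    Notes
    -----
    Vertex sets are implicit: every vertex has at least one incident edge.
    Consumer and resource ID spaces must be disjoint (bipartite semantics);
    the same label appearing in both roles is rejected.
    """

    __slots__ = ("_edges", "_consumers", "_resources")

    def __init__(self, edges: Mapping[Edge, float] | Iterable[tuple[Edge, float]] = ()):
        items = dict(edges)
        consumers: set[str] = set()
        resources: set[str] = set()
        for (c, r), w in items.items():
            if not (w > 0) or not math.isfinite(w):
                raise ValueError(
                    f"edge ({c!r}, {r!r}) has non-positive or non-finite weight {w!r}"
                )
            consumers.add(c)
            resources.add(r)
        overlap = consumers & resources
        if overlap:
            raise SchemaError(
                "consumer and resource namespaces overlap: "
                + ", ".join(sorted(overlap)[:5])
            )
        self._edges = items
        self._consumers = frozenset(consumers)
        self._resources = frozenset(resources)

    # -- basic accessors -------------------------------------------------
    @property
    def edges(self) -> dict[Edge, float]:
        return dict(self._edges)

    @property
    def consumers(self) -> frozenset[str]:
        return self._consumers

    @property
    def resources(self) -> frozenset[str]:
        return self._resources

    @property
    def species(self) -> frozenset[str]:
        """All vertices (both guilds) with at least one incident edge."""
        return self._consumers | self._resources

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def is_empty(self) -> bool:
        return not self._edges

    @property
    def total_weight(self) -> float:
        return sum(self._edges.values())

    def weight(self, edge: Edge) -> float:
        return self._edges.get(edge, 0.0)

    def __contains__(self, edge: Edge) -> bool:
        return edge in self._edges

    def __eq__(self, other) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return self._edges == other._edges

    def __hash__(self):  # pragma: no cover - networks are de facto immutable
        return hash(frozenset(self._edges.items()))

    def __repr__(self) -> str:
        return (
            f"<BipartiteNetwork {len(self._consumers)} consumers x "
            f"{len(self._resources)} resources, {len(self._edges)} edges>"
        )

    # -- transformations -------------------------------------------------
    def to_proportions(self) -> "BipartiteNetwork":
        """Rescale edge weights to proportions summing to one.

        Raises
        ------
        ValueError
            If the network has zero total weight (empty network).
        """
        total = self.total_weight
        if total <= 0:
            raise ValueError("cannot convert empty (zero-total) network to proportions")
        return BipartiteNetwork({e: w / total for e, w in self._edges.items()})

    def remove_species(self, species_id: str) -> "BipartiteNetwork":
        """Return a copy with all edges incident to *species_id* deleted.

        Removing an absent species is a no-op.  Vertices left without edges
        disappear (vertex sets are edge-implied), and the result may be
        empty.
        """
        if species_id not in self._consumers and species_id not in self._resources:
            return self
        return BipartiteNetwork(
            {(c, r): w for (c, r), w in self._edges.items() if species_id not in (c, r)}
        )

    def marginal_weights(self) -> dict[str, float]:
        """Total incident edge weight per species (both guilds)."""
        marg: dict[str, float] = {}
        for (c, r), w in self._edges.items():
            marg[c] = marg.get(c, 0.0) + w
            marg[r] = marg.get(r, 0.0) + w
        return marg


def build_meta_network(realizations: Sequence[BipartiteNetwork]) -> BipartiteNetwork:
    """Aggregate realizations into the meta-network.

    The meta-network's edge set is the union of the realization edge sets
    and each edge's weight is the sum of its weights across realizations.

    Raises
    ------
    EmptyInputError
        If *realizations* is empty.
    """
    if len(realizations) == 0:
        raise EmptyInputError("cannot build a meta-network from zero realizations")
    acc: dict[Edge, float] = {}
    for net in realizations:
        for e, w in net._edges.items():
            acc[e] = acc.get(e, 0.0) + w
    return BipartiteNetwork(acc)


class NetworkSeries:
    """An ordered sequence of network realizations plus the meta-network.

    Parameters
    ----------
    realizations
        Ordered ``(realization_id, BipartiteNetwork)`` pairs.  Realizations
        emptied by species removal are retained (with zero edges) so the
        series length stays stable across leave-one-out computations.
    """

    __slots__ = ("_ids", "_nets", "_meta")

    def __init__(self, realizations: Sequence[tuple[str, BipartiteNetwork]]):
        if len(realizations) == 0:
            raise EmptyInputError("a NetworkSeries needs at least one realization")
        ids = [str(rid) for rid, _ in realizations]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate realization labels in series")
        nets = [net for _, net in realizations]
        all_consumers = frozenset().union(*(n.consumers for n in nets))
        all_resources = frozenset().union(*(n.resources for n in nets))
        overlap = all_consumers & all_resources
        if overlap:
            raise SchemaError(
                "consumer and resource namespaces overlap across realizations: "
                + ", ".join(sorted(overlap)[:5])
            )
        self._ids = tuple(ids)
        self._nets = tuple(nets)
        self._meta = build_meta_network(nets)

    @property
    def realization_ids(self) -> tuple[str, ...]:
        return self._ids

    @property
    def networks(self) -> tuple[BipartiteNetwork, ...]:
        return self._nets

    @property
    def meta(self) -> BipartiteNetwork:
        return self._meta

    def __len__(self) -> int:
        return len(self._ids)

    def __iter__(self):
        return iter(zip(self._ids, self._nets))

    def __getitem__(self, key: int | str) -> BipartiteNetwork:
        if isinstance(key, str):
            try:
                key = self._ids.index(key)
            except ValueError:
                raise KeyError(key) from None
        return self._nets[key]

    def __eq__(self, other) -> bool:
        if not isinstance(other, NetworkSeries):
            return NotImplemented
        return self._ids == other._ids and self._nets == other._nets

    def __repr__(self) -> str:
        return (
            f"<NetworkSeries {len(self._ids)} realizations, meta "
            f"{len(self._meta.consumers)}x{len(self._meta.resources)} "
            f"({self._meta.n_edges} edges)>"
        )

    def remove_species(self, species_id: str) -> "NetworkSeries":
        """Leave-one-species-out copy of the whole series.

        The species is removed from every realization; the meta-network is
        rebuilt from the reduced realizations (equivalently: the species is
        removed from the dataset before any aggregation).  Realizations left
        with no edges are retained as empty networks.
        """
        return NetworkSeries(
            [(rid, net.remove_species(species_id)) for rid, net in self]
        )


# ---------------------------------------------------------------------------
# Edge alignment between two networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeAlignment:
    """Aligned edge union of two networks with rewiring/turnover classes.

    ``u`` and ``v`` are the two networks' weight vectors over ``edge_ids``
    (zero where an edge is absent).  Each edge carries one of three labels:
    ``shared`` (positive weight in both networks), ``unique_rw`` (one-sided,
    but both endpoints occur in both networks — a rewired interaction) or
    ``unique_st`` (one-sided with at least one endpoint missing from one
    network — attributable to species turnover).
    """

    edge_ids: tuple[Edge, ...]
    u: np.ndarray
    v: np.ndarray
    class_of: dict[Edge, str] = field(repr=False)

    # binary counts in the notation of pairwise beta-diversity partitioning
    @property
    def a(self) -> int:
        """Number of edges present in both networks."""
        return sum(1 for e in self.edge_ids if self.class_of[e] == SHARED)

    @property
    def b(self) -> int:
        """Number of edges unique to the first network."""
        return int(np.sum((self.u > 0) & (self.v == 0)))

    @property
    def c(self) -> int:
        """Number of edges unique to the second network."""
        return int(np.sum((self.v > 0) & (self.u == 0)))

    @property
    def b_rw(self) -> int:
        """Edges unique to the first network with both endpoints shared (b')."""
        return sum(
            1
            for i, e in enumerate(self.edge_ids)
            if self.class_of[e] == UNIQUE_RW and self.u[i] > 0
        )

    @property
    def c_rw(self) -> int:
        """Edges unique to the second network with both endpoints shared (c')."""
        return sum(
            1
            for i, e in enumerate(self.edge_ids)
            if self.class_of[e] == UNIQUE_RW and self.v[i] > 0
        )

    @property
    def b_st(self) -> int:
        """Edges unique to the first network lost to species turnover (b - b')."""
        return self.b - self.b_rw

    @property
    def c_st(self) -> int:
        """Edges unique to the second network lost to species turnover (c - c')."""
        return self.c - self.c_rw

    def mask(self, *classes: str) -> np.ndarray:
        """Boolean mask over ``edge_ids`` selecting the given classes."""
        return np.array([self.class_of[e] in classes for e in self.edge_ids], bool)


def align_edges(m: BipartiteNetwork, n: BipartiteNetwork) -> EdgeAlignment:
    """Align two networks over their edge union and classify every edge.

    The classification drives the rewiring/turnover partition: an edge
    observed in only one network is a *rewiring* difference if both its
    endpoint species occur in both networks, and a *turnover* difference
    otherwise.

    Raises
    ------
    SchemaError
        If a label is used as a consumer in one network and a resource in
        the other (the networks must share one bipartite ID space).
    """
    overlap = (m.consumers | n.consumers) & (m.resources | n.resources)
    if overlap:
        raise SchemaError(
            "consumer and resource namespaces overlap between networks: "
            + ", ".join(sorted(overlap)[:5])
        )
    shared_species = m.species & n.species
    edge_ids = tuple(sorted(set(m._edges) | set(n._edges)))
    u = np.array([m.weight(e) for e in edge_ids], float)
    v = np.array([n.weight(e) for e in edge_ids], float)
    class_of: dict[Edge, str] = {}
    for e in edge_ids:
        c, r = e
        if e in m and e in n:
            class_of[e] = SHARED
        elif c in shared_species and r in shared_species:
            class_of[e] = UNIQUE_RW
        else:
            class_of[e] = UNIQUE_ST
    return EdgeAlignment(edge_ids=edge_ids, u=u, v=v, class_of=class_of)


# ---------------------------------------------------------------------------
# I/O: long-format edge tables and wide incidence matrices
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {
    "realization": "realization",
    "consumer": "consumer",
    "resource": "resource",
    "count": "count",
}


def read_interaction_table(
    path,
    *,
    delimiter: str = "\t",
    columns: Mapping[str, str] | None = None,
    realization_order: Sequence[str] | None = None,
) -> NetworkSeries:
    """Read a long-format interaction table into a :class:`NetworkSeries`.

    The file is delimited text with a header; lines starting with ``#`` are
    treated as comments.  Each row binds one realization (e.g. a month) to
    one weighted consumer-resource edge.  Duplicate
    ``(realization, consumer, resource)`` rows are summed; zero-count rows
    are dropped.

    Parameters
    ----------
    path
        Input file path.
    delimiter
        Field separator (default: tab).
    columns
        Mapping from the roles ``realization``, ``consumer``, ``resource``,
        ``count`` to the actual column names in the file.
    realization_order
        Explicit ordering of realization labels.  Defaults to order of first
        appearance in the file.  Labels present in the data but missing from
        the list are rejected.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str)
    for role in ("realization", "consumer", "resource", "count"):
        if cols[role] not in df.columns:
            raise SchemaError(
                f"required column {cols[role]!r} (role: {role}) not found; "
                f"file has columns {list(df.columns)}"
            )
    counts = pd.to_numeric(df[cols["count"]], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
        raise ValueError(
            f"weight {df[cols['count']].iloc[int(np.flatnonzero(bad.to_numpy())[0])]!r} "
            f"at line {row} is not a nonnegative integer"
        )
    df = df.assign(_count=counts.astype(np.int64))
    df = df[df["_count"] > 0]
    if df.empty:
        raise EmptyInputError("no positive-count interaction records in input")
    grouped = (
        df.groupby([cols["realization"], cols["consumer"], cols["resource"]], sort=False)[
            "_count"
        ]
        .sum()
        .reset_index()
    )
    observed = list(dict.fromkeys(grouped[cols["realization"]]))
    if realization_order is None:
        order = observed
    else:
        order = [str(x) for x in realization_order]
        unknown = set(observed) - set(order)
        if unknown:
            raise SchemaError(
                "realizations present in data but missing from realization_order: "
                + ", ".join(sorted(unknown))
            )
        order = [rid for rid in order if rid in set(observed)]
    realizations = []
    for rid in order:
        sub = grouped[grouped[cols["realization"]] == rid]
        edges = {
            (c, r): float(w)
            for c, r, w in zip(sub[cols["consumer"]], sub[cols["resource"]], sub["_count"])
        }
        realizations.append((rid, BipartiteNetwork(edges)))
    return NetworkSeries(realizations)


def write_interaction_table(
    series: NetworkSeries,
    path,
    *,
    delimiter: str = "\t",
    columns: Mapping[str, str] | None = None,
    header_comments: Sequence[str] = (),
) -> None:
    """Write a series back to the long-format edge table the reader consumes."""
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    rows = []
    for rid, net in series:
        for (c, r), w in sorted(net.edges.items()):
            rows.append((rid, c, r, int(w) if float(w).is_integer() else w))
    df = pd.DataFrame(
        rows, columns=[cols["realization"], cols["consumer"], cols["resource"], cols["count"]]
    )
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=delimiter, index=False)


def write_incidence_matrix(net: BipartiteNetwork, path, *, delimiter: str = "\t") -> None:
    """Write one network as a wide consumers x resources count matrix."""
    consumers = sorted(net.consumers)
    resources = sorted(net.resources)
    mat = pd.DataFrame(0.0, index=consumers, columns=resources)
    for (c, r), w in net.edges.items():
        mat.loc[c, r] = w
    mat.index.name = "consumer"
    mat.to_csv(path, sep=delimiter)
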