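"""Graph data model, edge-list I/O, preprocessing and descriptive statistics.

Networks are simple undirected graphs with stable node labels.  Input files
follow the KONECT edge-list dialect: whitespace-separated columns, ``%`` (or
``#``) comment lines, optional weight/timestamp columns which are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import networkx as nx
import numpy as np


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass(frozen=True)
class EdgeRecords:
    """Raw edge records as read from a file, before any cleaning.

    Duplicate records and self-loops are preserved so that
    :func:`preprocess` can report them.  ``labels`` is in first-appearance
    order and defines the provisional node indexing.
    """

    labels: tuple[str, ...]
    records: tuple[tuple[int, int], ...]

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def m(self) -> int:
        return len(self.records)


class Network:
    """A simple undirected, optionally edge-weighted network.

    Parameters
    ----------
    labels
        Node labels in internal-index order (index ``i`` <-> ``labels[i]``).
    edges
        Mapping from unordered index pairs ``(i, j)`` with ``i < j`` to a
        strictly positive weight.  Unweighted networks carry weight 1 on
        every edge.
    """

    def __init__(self, labels: Sequence[str], edges: dict[tuple[int, int], float]):
        labels = tuple(str(x) for x in labels)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate node labels")
        clean: dict[tuple[int, int], float] = {}
        for (i, j), w in edges.items():
            if i == j:
                raise ValueError(f"self-loop on node index {i}")
            if not (0 <= i < len(labels) and 0 <= j < len(labels)):
                raise ValueError(f"edge ({i},{j}) references unknown node index")
            key = (i, j) if i < j else (j, i)
            if key in clean:
                raise ValueError(f"duplicate edge {key}")
            if not w > 0:
                raise ValueError(f"non-positive weight on edge {key}")
            clean[key] = float(w)
        self.labels = labels
        self.edges = clean

    # -- basic properties -------------------------------------------------
    @property
    def n(self) -> int:
        """Number of nodes."""
        return len(self.labels)

    @property
    def m(self) -> int:
        """Number of edges."""
        return len(self.edges)

    @property
    def is_weighted(self) -> bool:
        return any(w != 1.0 for w in self.edges.values())

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(str(label))
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    def adjacency(self) -> np.ndarray:
        """Dense symmetric adjacency matrix (weights as entries)."""
        A = np.zeros((self.n, self.n))
        for (i, j), w in self.edges.items():
            A[i, j] = A[j, i] = w
        return A

    def degrees(self) -> np.ndarray:
        """Unweighted degree (neighbour count) per node."""
        k = np.zeros(self.n, dtype=int)
        for i, j in self.edges:
            k[i] += 1
            k[j] += 1
        return k

    def neighbours(self, i: int) -> set[int]:
        out = set()
        for a, b in self.edges:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return out

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self.edges)

    def non_edges(self) -> list[tuple[int, int]]:
        """All unordered node pairs not joined by an edge."""
        present = self.edge_set()
        return [
            (i, j)
            for i in range(self.n)
            for j in range(i + 1, self.n)
            if (i, j) not in present
        ]

    def with_edges(self, keep: Iterable[tuple[int, int]]) -> "Network":
        """Subnetwork on the same nodes restricted to ``keep`` edges."""
        keep = {(min(i, j), max(i, j)) for i, j in keep}
        missing = keep - set(self.edges)
        if missing:
            raise ValueError(f"edges not in network: {sorted(missing)[:3]}")
        return Network(self.labels, {e: self.edges[e] for e in keep})

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for (i, j), w in self.edges.items():
            g.add_edge(i, j, weight=w)
        return g

    def is_connected(self) -> bool:
        if self.n == 0:
            return False
        seen = {0}
        stack = [0]
        adj: dict[int, list[int]] = {i: [] for i in range(self.n)}
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "weighted" if self.is_weighted else "unweighted"
        return f"<Network n={self.n} m={self.m} {kind}>"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.labels == other.labels and self.edges == other.edges


@dataclass(frozen=True)
class PreprocessReport:
    """What :func:`preprocess` removed to reach a simple connected graph."""

    loops_removed: int = 0
    duplicates_removed: int = 0
    components_dropped: int = 0
    nodes_dropped: int = 0
    weights_dropped: bool = False
    singleton: bool = False

    @property
    def empty(self) -> bool:
        return (
            self.loops_removed == 0
            and self.duplicates_removed == 0
            and self.components_dropped == 0
            and not self.weights_dropped
        )


@dataclass(frozen=True)
class NetworkStats:
    """Descriptive statistics of a connected simple network."""

    n: int
    m: int
    clustering: float
    mean_degree: float
    density: float
    heterogeneity: float
    mean_path_length: float


def read_edge_list(source: IO[str] | str | Iterable[str]) -> EdgeRecords:
    """Read a KONECT-dialect edge list into raw :class:`EdgeRecords`.

    Lines beginning with ``%`` or ``#`` are comments; remaining lines must
    carry at least two whitespace-separated tokens (extra columns such as
    weights or timestamps are ignored).  Duplicates and loops are preserved
    for :func:`preprocess` to report.
    """
    if isinstance(source, str):
        lines: Iterable[str] = source.splitlines()
    else:
        lines = source
    labels: list[str] = []
    index: dict[str, int] = {}
    records: list[tuple[int, int]] = []

    def idx(tok: str) -> int:
        if tok not in index:
            index[tok] = len(labels)
            labels.append(tok)
        return index[tok]

    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("%", "#")):
            continue
        tokens = stripped.split()
        if len(tokens) < 2:
            raise EdgeListError(f"line {lineno}: expected at least 2 tokens, got {len(tokens)}")
        records.append((idx(tokens[0]), idx(tokens[1])))
    if not records:
        raise EdgeListError("no edges")
    return EdgeRecords(tuple(labels), tuple(records))


def write_edge_list(network: Network, stream: IO[str]) -> None:
    """Write a network as a two-column (three with weights) edge list."""
    stream.write("% linkdiffuse edge list\n")
    for (i, j), w in sorted(network.edges.items()):
        if network.is_weighted:
            stream.write(f"{network.labels[i]}\t{network.labels[j]}\t{w:g}\n")
        else:
            stream.write(f"{network.labels[i]}\t{network.labels[j]}\n")


def preprocess(raw: EdgeRecords | Network) -> tuple[Network, PreprocessReport]:
    """Reduce raw records (or any network) to a simple, unweighted,
    connected network.

    Drops self-loops, duplicate edges and edge weights, then keeps only the
    largest connected component (ties broken by the component containing
    the lowest first-appearing label).  Node labels keep their
    first-appearance order.
    """
    if isinstance(raw, Network):
        labels = list(raw.labels)
        pairs = list(raw.edges)
        weights_dropped = raw.is_weighted
        loops = 0
        dupes = 0
        uniq = set(pairs)
    else:
        labels = list(raw.labels)
        loops = 0
        dupes = 0
        uniq: set[tuple[int, int]] = set()
        weights_dropped = False
        for i, j in raw.records:
            if i == j:
                loops += 1
                continue
            key = (min(i, j), max(i, j))
            if key in uniq:
                dupes += 1
            else:
                uniq.add(key)

    # connected components over nodes that appear in at least one edge,
    # plus isolated nodes (their own singleton components)
    adj: dict[int, list[int]] = {i: [] for i in range(len(labels))}
    for i, j in uniq:
        adj[i].append(j)
        adj[j].append(i)
    seen: set[int] = set()
    components: list[list[int]] = []
    for start in range(len(labels)):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.append(v)
                    stack.append(v)
        components.append(sorted(comp))
    # largest component; tie-break = lowest first-appearing node index
    components.sort(key=lambda c: (-len(c), c[0]))
    keep = components[0]
    keep_set = set(keep)
    dropped_nodes = len(labels) - len(keep)

    remap = {old: new for new, old in enumerate(keep)}
    new_labels = [labels[old] for old in keep]
    new_edges = {
        (remap[i], remap[j]): 1.0
        for i, j in uniq
        if i in keep_set and j in keep_set
    }
    report = PreprocessReport(
        loops_removed=loops,
        duplicates_removed=dupes,
        components_dropped=len(components) - 1,
        nodes_dropped=dropped_nodes,
        weights_dropped=weights_dropped,
        singleton=len(keep) == 1,
    )
    return Network(new_labels, new_edges), report


def network_stats(network: Network) -> NetworkStats:
    """Topological summary: clustering C, <k>, density rho, heterogeneity
    H = <k^2>/<k>^2, and mean shortest-path length.

    Mean path length averages over all unordered reachable pairs; the
    clustering coefficient is the mean local clustering coefficient with
    degree-<2 nodes contributing 0.
    """
    n, m = network.n, network.m
    if n < 2:
        raise ValueError("network statistics require at least 2 nodes")
    g = network.to_networkx()
    k = network.degrees().astype(float)
    mean_k = 2.0 * m / n
    density = 2.0 * m / (n * (n - 1))
    heterogeneity = float(np.mean(k**2) / mean_k**2)
    clustering = float(nx.average_clustering(g, count_zeros=True))
    # average over reachable unordered pairs (equals the usual definition
    # on connected graphs, stays defined on disconnected library inputs)
    total = 0.0
    pairs = 0
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            if dst > src:
                total += d
                pairs += 1
    mean_path = total / pairs if pairs else float("nan")
    return NetworkStats(
        n=n,
        m=m,
        clustering=clustering,
        mean_degree=mean_k,
        density=density,
        heterogeneity=heterogeneity,
        mean_path_length=mean_path,
    )
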