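"""Deterministic example graphs and a seeded two-community generator.

These fixtures make every module testable without downloads: the two
four-node diffusion-demo cycles, a nine-node neighbourhood whose
transform-and-preweight arithmetic is known in closed form, and a planted
two-community generator for community-ordering properties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import Network


@dataclass(frozen=True)
class FixtureSpec:
    """Provenance of a fixture: which parts are forced, which are chosen."""

    name: str
    parameters: dict
    provenance: str


def four_cycle(weighted: bool = False) -> Network:
    """The four-node cycle u1-u2-u3-u4-u1 used to demonstrate diffusion.

    In the weighted variant edge (u1, u2) carries weight 2 and the rest
    weight 1, so heat injected at u1 prefers the u2 channel; unweighted,
    u2 and u4 receive identical amounts and u3 (two hops away) less.
    """
    w12 = 2.0 if weighted else 1.0
    edges = {(0, 1): w12, (1, 2): 1.0, (2, 3): 1.0, (0, 3): 1.0}
    return Network(["u1", "u2", "u3", "u4"], edges)


#: edges of the nine-node local-neighbourhood fixture, by label
_WORKED_EXAMPLE_EDGES = [
    ("a", "b"),
    ("b", "c"),
    ("b", "d"),
    ("c", "d"),
    ("c", "e"),
    ("e", "f"),
    ("e", "g"),
    ("f", "h"),
    ("g", "i"),
]


def worked_example_network() -> Network:
    """Nine nodes, nine links, with a fully determined neighbourhood of c.

    Forced structure: c is adjacent to b, d and e; d's only neighbours
    are b and c (degree 2); b has degree 3 (a third neighbour a outside
    c's neighbourhood); c and e share no common neighbour.  Under
    resource-allocation pre-weighting this pins the transformed weights
    at c: w(c,e) = 1, w(c,b) = 1 + 1/2 = 3/2, w(c,d) = 1 + 1/3 = 4/3.

    The placement of the remaining four links (e-f, e-g, f-h, g-i) is a
    chosen completion — kept outside c's two-hop ball so the weights
    above are unaffected — arranged so the graph has exactly nine two-hop
    pairs and the transform therefore doubles the link count to 18.
    """
    labels = sorted({x for e in _WORKED_EXAMPLE_EDGES for x in e})
    idx = {lab: k for k, lab in enumerate(labels)}
    edges = {(min(idx[u], idx[v]), max(idx[u], idx[v])): 1.0 for u, v in _WORKED_EXAMPLE_EDGES}
    return Network(labels, edges)


WORKED_EXAMPLE_SPEC = FixtureSpec(
    name="worked_example_network",
    parameters={"edges": _WORKED_EXAMPLE_EDGES},
    provenance=(
        "forced: c~{b,d,e}; Gamma(d)={b,c}; deg(b)=3 via outside node a; "
        "c,e share no common neighbour. chosen: the four links e-f, e-g, "
        "f-h, g-i completing 9 nodes / 9 links with exactly 9 two-hop pairs."
    ),
)


def random_connected_network(n: int, m: int, seed: int = 0) -> Network:
    """Seeded uniform-ish random connected graph with ``n`` nodes, ``m`` edges.

    A random recursive tree guarantees connectivity; the remaining
    ``m - (n-1)`` edges are drawn uniformly without replacement from the
    absent pairs.
    """
    if m < n - 1:
        raise ValueError("connected graph needs m >= n-1")
    if m > n * (n - 1) // 2:
        raise ValueError("too many edges for a simple graph")
    rng = np.random.default_rng(seed)
    edges: set[tuple[int, int]] = set()
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edges.add((u, v))
    absent = [
        (i, j) for i in range(n) for j in range(i + 1, n) if (i, j) not in edges
    ]
    extra = m - (n - 1)
    if extra:
        for k in rng.choice(len(absent), size=extra, replace=False):
            edges.add(absent[k])
    return Network([f"n{i}" for i in range(n)], {e: 1.0 for e in edges})


def two_community_network(
    size_per_community: int = 20,
    p_in: float = 0.25,
    p_out: float = 0.02,
    seed: int = 0,
    n_bridges: int | None = None,
) -> tuple[Network, dict[int, int]]:
    """Seeded planted-partition graph with two communities.

    Within-community pairs connect with probability ``p_in``,
    between-community pairs with ``p_out``; if ``n_bridges`` is given,
    exactly that many between-community links are drawn instead of
    Bernoulli sampling.  The result is reduced to its largest connected
    component.  Returns the network and a node-index -> community map.

    Defaults model the qualitative regime used throughout: dense blocks
    (``p_in = 0.25``) with sparse inter-community contact
    (``p_out = 0.02``), about the density contrast of small social
    networks with clear modular structure.
    """
    if not p_in > p_out >= 0:
        raise ValueError("requires p_in > p_out >= 0")
    s = size_per_community
    rng = np.random.default_rng(seed)
    for _attempt in range(10):
        edges: dict[tuple[int, int], float] = {}
        labels = [f"v{i}" for i in range(2 * s)]
        community = {i: i // s for i in range(2 * s)}
        for i in range(2 * s):
            for j in range(i + 1, 2 * s):
                if community[i] == community[j]:
                    if rng.random() < p_in:
                        edges[(i, j)] = 1.0
                elif n_bridges is None and rng.random() < p_out:
                    edges[(i, j)] = 1.0
        if n_bridges is not None:
            cross = [(i, j) for i in range(s) for j in range(s, 2 * s)]
            chosen = rng.choice(len(cross), size=n_bridges, replace=False)
            for c in chosen:
                edges[cross[c]] = 1.0
        if not edges:
            import warnings

            warnings.warn("degenerate empty graph; resampling", stacklevel=2)
            continue
        net = Network(labels, edges)
        from .netio import preprocess

        net, _ = preprocess(net)
        if net.n >= 2:
            comm = {net.index_of(lab): community[int(lab[1:])] for lab in net.labels}
            return net, comm
    raise RuntimeError("could not generate a non-degenerate graph in 10 attempts")
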