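"""Train/probe splitting, AUC estimation, and benchmark protocols.

Evaluation follows the standard missing-link protocol: the observed links
``E`` are partitioned into a training set ``E^T`` and a probe set ``E^P``
such that the training network stays connected (a random spanning tree is
retained, the probe is drawn from the off-tree links).  Indices are
computed on the training network only and judged by

    AUC = (sigma_1 + 0.5 sigma_2) / sigma

over comparisons between probe links and never-observed pairs
``E' = U \\ E``: ``sigma_1`` wins (probe scored strictly higher),
``sigma_2`` ties, ``sigma`` total comparisons.  Random scores give 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .netio import Network
from .indices import INDEX_REGISTRY, IndexParams, ScoreMatrix, compute_index
from . import wpmfi as _wpmfi  # ensures pmfi/wpmfi are registered

Pair = tuple[int, int]


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitResult:
    """A connectivity-preserving partition of observed links."""

    training: Network
    probe: frozenset[Pair]
    tree_edges: frozenset[Pair]
    probe_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if self.probe & self.training.edge_set():
            raise ValueError("probe and training sets overlap")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def random_spanning_tree(network: Network, rng_seed: int) -> frozenset[Pair]:
    """A seeded uniform-edge-order spanning tree (randomised Kruskal).

    On an unweighted network every spanning tree is minimum, so drawing
    the tree from a shuffled edge order avoids a fixed-tree bias across
    repeated trials while keeping the run reproducible.
    """
    if not network.is_connected():
        raise ValueError("spanning tree requires a connected network")
    rng = np.random.default_rng(rng_seed)
    edges = sorted(network.edges)
    order = rng.permutation(len(edges))
    uf = _UnionFind(network.n)
    tree: set[Pair] = set()
    for idx in order:
        i, j = edges[idx]
        if uf.union(i, j):
            tree.add((i, j))
            if len(tree) == network.n - 1:
                break
    return frozenset(tree)


def split_train_probe(
    network: Network, probe_fraction: float, rng_seed: int
) -> SplitResult:
    """Partition links into connected training set and probe set.

    The probe holds ``round(probe_fraction * |E|)`` links sampled
    uniformly without replacement from the off-tree links, so the
    training network (which keeps the whole spanning tree) stays
    connected by construction.
    """
    if not 0 <= probe_fraction < 1:
        raise ValueError("probe_fraction must lie in [0, 1)")
    m = network.m
    n_probe = int(round(probe_fraction * m))
    max_probe = m - (network.n - 1)
    if n_probe > max_probe:
        raise ValueError(
            f"infeasible probe fraction {probe_fraction}: needs {n_probe} links "
            f"but only {max_probe} off-tree links exist "
            f"(max feasible fraction {max_probe / m:.4f})"
        )
    tree = random_spanning_tree(network, rng_seed)
    off_tree = sorted(set(network.edges) - tree)
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 1]))
    chosen = rng.choice(len(off_tree), size=n_probe, replace=False) if n_probe else []
    probe = frozenset(off_tree[i] for i in chosen)
    training = network.with_edges(set(network.edges) - probe)
    return SplitResult(
        training=training,
        probe=probe,
        tree_edges=tree,
        probe_fraction=probe_fraction,
        seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# AUC


@dataclass(frozen=True)
class AUCEstimate:
    """AUC with its comparison counts.

    ``auc = (sigma1 + 0.5 sigma2) / sigma`` exactly; ``mode`` records
    whether every probe-vs-nonexistent comparison was made
    (``exhaustive``) or ``sigma`` independent uniform draws (``sampled``).
    """

    auc: float
    sigma: int
    sigma1: int
    sigma2: int
    mode: str

    def __post_init__(self) -> None:
        assert self.sigma1 + self.sigma2 <= self.sigma
        assert abs(self.auc - (self.sigma1 + 0.5 * self.sigma2) / self.sigma) < 1e-12


def auc(
    scores: ScoreMatrix | np.ndarray,
    probe: Iterable[Pair],
    nonexistent: Iterable[Pair],
    mode: str = "exhaustive",
    n_samples: int = 100_000,
    rng_seed: int = 0,
) -> AUCEstimate:
    """AUC of a score matrix over probe links vs never-observed pairs.

    ``nonexistent`` must be the complement set ``E' = U \\ E`` of the
    *full* network's links (training links are excluded from both sides).
    Exhaustive mode counts all ``|E^P| * |E'|`` comparisons; sampled mode
    draws ``n_samples`` independent uniform (probe, nonexistent) pairs.
    Ties are exact score equality.
    """
    values = scores.values if isinstance(scores, ScoreMatrix) else np.asarray(scores)
    probe = list(probe)
    nonexistent = list(nonexistent)
    if not probe or not nonexistent:
        raise ValueError("probe and nonexistent sets must both be non-empty")
    if set(probe) & set(nonexistent):
        raise ValueError("probe and nonexistent sets overlap")
    p = np.array([values[i, j] for i, j in probe])
    q = np.array([values[i, j] for i, j in nonexistent])

    if mode == "exhaustive":
        q_sorted = np.sort(q)
        below = np.searchsorted(q_sorted, p, side="left")
        upto = np.searchsorted(q_sorted, p, side="right")
        sigma1 = int(below.sum())          # negatives strictly below each probe
        sigma2 = int((upto - below).sum())  # exact ties
        sigma = len(p) * len(q)
    elif mode == "sampled":
        rng = np.random.default_rng(rng_seed)
        ps = p[rng.integers(0, len(p), size=n_samples)]
        qs = q[rng.integers(0, len(q), size=n_samples)]
        sigma1 = int(np.count_nonzero(ps > qs))
        sigma2 = int(np.count_nonzero(ps == qs))
        sigma = n_samples
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AUCEstimate(
        auc=(sigma1 + 0.5 * sigma2) / sigma,
        sigma=sigma,
        sigma1=sigma1,
        sigma2=sigma2,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# benchmark protocols


@dataclass
class BenchmarkResult:
    """Per-(index, repeat) AUC table with mean +/- std summaries."""

    raw: pd.DataFrame  # columns: index, repeat, auc, sigma, sigma1, sigma2

    @property
    def summary(self) -> pd.DataFrame:
        g = self.raw.groupby("index", sort=False)["auc"]
        out = pd.DataFrame({"mean": g.mean(), "std": g.std(ddof=1).fillna(0.0), "repeats": g.size()})
        return out.reset_index()

    def mean_auc(self, index: str) -> float:
        sel = self.raw.loc[self.raw["index"] == index, "auc"]
        if sel.empty:
            raise KeyError(f"index {index!r} not in benchmark")
        return float(sel.mean())


def _derive_seed(master_seed: int, *parts: int) -> int:
    """Deterministic per-repeat seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, parts)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


ScoreFn = Callable[[Network], ScoreMatrix]


def _resolve_scorers(
    index_names: Sequence[str], params: IndexParams
) -> dict[str, ScoreFn]:
    scorers: dict[str, ScoreFn] = {}
    for name in index_names:
        if name not in INDEX_REGISTRY:
            raise ValueError(f"unknown index {name!r}")
        scorers[name] = lambda net, _n=name: compute_index(net, _n, params)
    return scorers


def run_benchmark(
    network: Network,
    index_names: Sequence[str],
    probe_fraction: float = 0.1,
    repeats: int = 10,
    master_seed: int = 0,
    params: IndexParams | None = None,
    scorers: dict[str, ScoreFn] | None = None,
) -> BenchmarkResult:
    """Repeated split-score-evaluate protocol over a list of indices.

    Per repeat one connectivity-preserving split is drawn (seed derived
    deterministically from ``master_seed`` and the repeat number) and
    shared by every index; each index scores the *training* network only
    and is evaluated exhaustively against ``E' = U \\ E``.
    """
    params = params or IndexParams()
    if scorers is None:
        scorers = _resolve_scorers(index_names, params)
    nonexistent = network.non_edges()
    rows = []
    for rep in range(repeats):
        split = split_train_probe(
            network, probe_fraction, _derive_seed(master_seed, rep)
        )
        for name, fn in scorers.items():
            sm = fn(split.training)
            est = auc(sm, split.probe, nonexistent)
            rows.append(
                {
                    "index": name,
                    "repeat": rep,
                    "auc": est.auc,
                    "sigma": est.sigma,
                    "sigma1": est.sigma1,
                    "sigma2": est.sigma2,
                }
            )
    return BenchmarkResult(raw=pd.DataFrame(rows))


def fraction_sweep(
    network: Network,
    index_names: Sequence[str],
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    repeats: int = 10,
    master_seed: int = 0,
    params: IndexParams | None = None,
) -> dict[float, BenchmarkResult]:
    """Probe-fraction sweep: one benchmark per probe fraction.

    Infeasible fractions (probe larger than the off-tree link budget) are
    skipped with a warning rather than aborting the sweep.
    """
    import warnings

    out: dict[float, BenchmarkResult] = {}
    for frac in fractions:
        try:
            out[frac] = run_benchmark(
                network, index_names, frac, repeats,
                _derive_seed(master_seed, int(round(frac * 1000))), params,
            )
        except ValueError as exc:
            warnings.warn(f"fraction {frac} skipped: {exc}", stacklevel=2)
    return out


def beta_sweep(
    network: Network,
    betas: Sequence[float] = (0.0001, 0.001, 0.05, 0.1, 0.2, 0.5, 1.0),
    probe_fraction: float = 0.1,
    repeats: int = 10,
    master_seed: int = 0,
    weighting: str = "ra",
) -> pd.DataFrame:
    """WPMFI forest-parameter sweep on shared splits.

    Every beta value is evaluated on the identical per-repeat splits so
    differences are attributable to beta alone.  Returns a summary frame
    indexed by beta with mean/std AUC.
    """
    nonexistent = network.non_edges()
    rows = []
    for rep in range(repeats):
        split = split_train_probe(
            network, probe_fraction, _derive_seed(master_seed, rep)
        )
        for beta in betas:
            sm = _wpmfi.wpmfi_scores(split.training, beta=beta, weighting=weighting)
            est = auc(sm, split.probe, nonexistent)
            rows.append({"beta": beta, "repeat": rep, "auc": est.auc})
    raw = pd.DataFrame(rows)
    g = raw.groupby("beta", sort=False)["auc"]
    return pd.DataFrame(
        {"mean": g.mean(), "std": g.std(ddof=1).fillna(0.0)}
    ).reset_index()


def preweight_comparison(
    network: Network,
    weightings: Sequence[str] = ("none", "cn", "aa", "ra"),
    beta: float = 0.05,
    probe_fraction: float = 0.1,
    repeats: int = 10,
    master_seed: int = 0,
) -> BenchmarkResult:
    """Ablation of the pre-weighting step on shared splits.

    ``"none"`` is plain PMFI on the untransformed training network; the
    others are WPMFI with the named local index as pre-weighting.
    """
    scorers: dict[str, ScoreFn] = {}
    for w in weightings:
        if w == "none":
            scorers["none"] = lambda net, _b=beta: _wpmfi.pmfi_scores(net, beta=_b)
        else:
            scorers[w] = lambda net, _w=w, _b=beta: _wpmfi.wpmfi_scores(
                net, beta=_b, weighting=_w
            )
    return run_benchmark(
        network,
        list(scorers),
        probe_fraction,
        repeats,
        master_seed,
        scorers=scorers,
    )


def ra_threshold_counts(
    network: Network, thresholds: Sequence[float] = (0.25, 0.2, 0.15)
) -> pd.DataFrame:
    """Count disconnected pairs whose RA score reaches each threshold.

    Thresholds must be descending; the ``band`` column counts the pairs
    newly admitted by each successive (lower) threshold and ``cumulative``
    the total admitted so far.  This reproduces, on any input network,
    the thresholded link-addition census used to visualise how many new
    links an RA cut-off would draw.
    """
    from .indices import resource_allocation_scores

    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be strictly descending")
    ra = resource_allocation_scores(network).values
    vals = np.array([ra[i, j] for i, j in network.non_edges()])
    rows = []
    prev = 0
    for thr in thresholds:
        cum = int(np.count_nonzero(vals >= thr))
        rows.append({"threshold": thr, "band": cum - prev, "cumulative": cum})
        prev = cum
    return pd.DataFrame(rows)
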