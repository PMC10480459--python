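"""Classical link-prediction similarity indices.

Each index maps a simple network to a symmetric matrix of pair scores; a
higher score means the pair is judged more likely to be (or become) a
link.  The local indices (CN, AA, RA, PA) read only the immediate
neighbourhoods; the global indices (MFI, LO, CND, Katz) see the whole
topology; SRW, RWR and LP are walk/path based quasi-local indices.

Diagonal entries are defined for convenience but never take part in
ranking, and all matrices are guaranteed finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

from .netio import Network
from .spectral import laplacian, pmfi_kernel


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric node-pair score table produced by a similarity index."""

    values: np.ndarray
    index_name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("score matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.index_name}: non-finite scores")
        if not np.allclose(v, v.T, atol=1e-10, rtol=0.0):
            raise ValueError(f"{self.index_name}: score matrix not symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def score(self, i: int, j: int) -> float:
        return float(self.values[i, j])


@dataclass(frozen=True)
class IndexParams:
    """Tunable parameters of the parametric indices.

    The benchmark literature sets these per the methods' original papers;
    the defaults here follow those conventions: a small Katz/LP damping
    well inside the convergence radius for typical benchmark graphs, the
    PageRank-style restart ``c = 0.85``, three superposed walk steps, and
    a small linear-optimisation regulariser.
    """

    beta_katz: float = 0.01
    beta_lp: float = 0.01
    c_rwr: float = 0.85
    t_srw: int = 3
    alpha_lo: float = 0.1
    beta_pmfi: float = 0.05

    def __post_init__(self) -> None:
        for name in ("beta_katz", "beta_lp", "c_rwr", "alpha_lo", "beta_pmfi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.t_srw < 1:
            raise ValueError("t_srw must be >= 1")


def _transition_matrix(network: Network) -> np.ndarray:
    """Row-stochastic random-walk matrix ``P = D^{-1} A``."""
    A = network.adjacency()
    k = A.sum(axis=1)
    k[k == 0] = 1.0  # isolated nodes keep a zero row rather than NaN
    return A / k[:, None]


# ---------------------------------------------------------------------------
# local indices


def common_neighbour_scores(network: Network) -> ScoreMatrix:
    """Common neighbours: ``CN(i,j) = |Gamma_i ∩ Gamma_j| = [A^2]_ij``."""
    A = network.adjacency()
    return ScoreMatrix(A @ A, "cn")


def adamic_adar_scores(network: Network) -> ScoreMatrix:
    """Adamic-Adar: common neighbours weighted by ``1 / log(degree)``.

    Natural logarithm.  On a simple graph a common neighbour of two
    distinct nodes has degree >= 2, so ``1/log 1`` never arises off the
    diagonal; degree-<2 nodes get coefficient 0, which only touches the
    (unranked) diagonal.
    """
    A = network.adjacency()
    k = A.sum(axis=1)
    coef = np.zeros_like(k)
    mask = k >= 2
    coef[mask] = 1.0 / np.log(k[mask])
    return ScoreMatrix((A * coef) @ A, "aa")


def resource_allocation_scores(network: Network) -> ScoreMatrix:
    """Resource allocation: sum of reciprocal common-neighbour degrees.

    Computed as ``A D^{-1} A`` with the diagonal zeroed — each common
    neighbour ``k`` forwards ``1/|Gamma_k|`` of a unit resource.
    """
    A = network.adjacency()
    k = A.sum(axis=1)
    inv = np.divide(1.0, k, out=np.zeros_like(k), where=k > 0)
    S = (A * inv) @ A
    np.fill_diagonal(S, 0.0)
    return ScoreMatrix(S, "ra")


def preferential_attachment_scores(network: Network) -> ScoreMatrix:
    """Preferential attachment: degree product ``|Gamma_i| * |Gamma_j|``."""
    k = network.degrees().astype(float)
    return ScoreMatrix(np.outer(k, k), "pa")


# ---------------------------------------------------------------------------
# global indices


def mfi_scores(network: Network) -> ScoreMatrix:
    """Matrix forest index ``(I + L)^{-1}``.

    Entry ``(i, j)`` is the fraction of spanning rooted forests in which
    ``i`` and ``j`` share a tree; identical to the PMFI kernel at beta=1.
    """
    kern = pmfi_kernel(laplacian(network), 1.0)
    return ScoreMatrix(kern.values, "mfi", {"beta": 1.0})


def lo_scores(network: Network, alpha_lo: float = 0.1) -> ScoreMatrix:
    """Linear optimisation index ``A (alpha (alpha A^T A + I)^{-1} A^T A)``.

    The printed composition is not symmetric in general, so the result is
    symmetrised as ``(S + S^T) / 2`` before ranking.
    """
    if alpha_lo <= 0:
        raise ValueError("alpha_lo must be positive")
    A = network.adjacency()
    G = A.T @ A
    inner = scipy.linalg.solve(alpha_lo * G + np.eye(network.n), G, assume_a="pos")
    S = A @ (alpha_lo * inner)
    return ScoreMatrix((S + S.T) / 2.0, "lo", {"alpha": alpha_lo})


def cnd_scores(network: Network) -> ScoreMatrix:
    """Common neighbours and distance:
    ``CND(i,j) = |Gamma_i ∩ Gamma_j| / 2 + (1 - A(i,j)) / d_ij``.

    ``d_ij`` is the unweighted shortest-path length; adjacent pairs take
    nothing from the distance term.  On disconnected inputs unreachable
    pairs contribute a distance term of 0 (the ``1/d -> 0`` limit).
    """
    A = network.adjacency()
    cn = A @ A
    d = scipy.sparse.csgraph.shortest_path((A != 0).astype(float), unweighted=True)
    inv_d = np.zeros_like(d)
    reachable = np.isfinite(d) & (d > 0)
    inv_d[reachable] = 1.0 / d[reachable]
    S = cn / 2.0 + (1.0 - (A != 0).astype(float)) * inv_d
    np.fill_diagonal(S, 0.0)
    return ScoreMatrix(S, "cnd")


def katz_scores(network: Network, beta_katz: float = 0.01) -> ScoreMatrix:
    """Katz index ``(I - beta A)^{-1} - I``: damped count of all walks.

    Requires ``beta < 1 / rho(A)`` for the defining series to converge.
    """
    if beta_katz <= 0:
        raise ValueError("beta_katz must be positive")
    A = network.adjacency()
    rho = float(np.max(np.abs(scipy.linalg.eigvalsh(A)))) if network.n else 0.0
    if rho > 0 and beta_katz >= 1.0 / rho:
        raise ValueError(
            f"beta_katz = {beta_katz} outside convergence radius: "
            f"spectral radius rho(A) = {rho:.6g} requires beta < {1.0 / rho:.6g}"
        )
    S = scipy.linalg.solve(np.eye(network.n) - beta_katz * A, np.eye(network.n)) - np.eye(network.n)
    return ScoreMatrix((S + S.T) / 2.0, "katz", {"beta": beta_katz})


# ---------------------------------------------------------------------------
# quasi-local indices


def srw_scores(network: Network, t_srw: int = 3) -> ScoreMatrix:
    """Superposed random walk over walk lengths ``1..t``.

    Each step superposes the degree-weighted walker distributions:
    ``sum_{l=1}^{t} (|Gamma_i| pi_ij(l) + |Gamma_j| pi_ji(l)) / (2|E|)``
    with ``pi_i(l) = P^T pi_i(l-1)`` and ``pi_i(0) = e_i``.
    """
    if t_srw < 1:
        raise ValueError("t_srw must be >= 1")
    P = _transition_matrix(network)
    k = network.degrees().astype(float)
    m = network.m
    S = np.zeros((network.n, network.n))
    Pl = np.eye(network.n)
    for _ in range(t_srw):
        Pl = Pl @ P  # Pl[i, j] = pi_ij at this walk length
        contrib = k[:, None] * Pl
        S += (contrib + contrib.T) / (2.0 * m)
    return ScoreMatrix(S, "srw", {"t": t_srw})


def rwr_scores(network: Network, c_rwr: float = 0.85) -> ScoreMatrix:
    """Random walk with restart: ``RWR(x,y) = q_xy + q_yx`` with
    ``q_x = (1-c) (I - c P^T)^{-1} e_x``.

    All ``q_x`` vectors come from one factorisation with ``n`` right-hand
    sides; each is a probability vector (sums to 1).
    """
    if not 0 < c_rwr < 1:
        raise ValueError(f"c_rwr must lie in (0, 1), got {c_rwr}")
    P = _transition_matrix(network)
    Q = (1.0 - c_rwr) * scipy.linalg.solve(
        np.eye(network.n) - c_rwr * P.T, np.eye(network.n)
    )
    # column x of Q is q_x; score(x, y) = q_x[y] + q_y[x]
    S = Q + Q.T
    return ScoreMatrix(S, "rwr", {"c": c_rwr})


def lp_scores(network: Network, beta_lp: float = 0.01) -> ScoreMatrix:
    """Local path index ``A^2 + beta A^3``: CN extended to length-3 paths."""
    if beta_lp <= 0:
        raise ValueError("beta_lp must be positive")
    A = network.adjacency()
    A2 = A @ A
    return ScoreMatrix(A2 + beta_lp * (A2 @ A), "lp", {"beta": beta_lp})


# ---------------------------------------------------------------------------
# registry

IndexFn = Callable[..., ScoreMatrix]

#: name -> (function, parameter names drawn from IndexParams)
INDEX_REGISTRY: dict[str, tuple[IndexFn, tuple[str, ...]]] = {
    "cn": (common_neighbour_scores, ()),
    "aa": (adamic_adar_scores, ()),
    "ra": (resource_allocation_scores, ()),
    "pa": (preferential_attachment_scores, ()),
    "mfi": (mfi_scores, ()),
    "lo": (lo_scores, ("alpha_lo",)),
    "cnd": (cnd_scores, ()),
    "katz": (katz_scores, ("beta_katz",)),
    "srw": (srw_scores, ("t_srw",)),
    "rwr": (rwr_scores, ("c_rwr",)),
    "lp": (lp_scores, ("beta_lp",)),
}


def compute_index(
    network: Network, name: str, params: IndexParams | None = None
) -> ScoreMatrix:
    """Compute any registered index by name (see also ``wpmfi`` module for
    the ``pmfi`` and ``wpmfi`` entries added at import time)."""
    params = params or IndexParams()
    try:
        fn, par_names = INDEX_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown index {name!r}; choose from {sorted(INDEX_REGISTRY)}"
        ) from None
    kwargs = {p: getattr(params, p) for p in par_names if hasattr(params, p)}
    if name in ("pmfi", "wpmfi"):
        kwargs = {"beta": params.beta_pmfi}
    return fn(network, **kwargs)
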