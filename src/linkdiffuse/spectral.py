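"""Laplacian, heat kernel, and the parametrised matrix forest kernel family.

The heat kernel ``H_t = exp(-t L)`` describes diffusion of heat on a graph:
entry ``(i, j)`` is the amount of heat at node ``j`` after time ``t`` given
a unit source at ``i``.  The parametrised matrix forest index
``PMFI_beta = (I + beta L)^{-1}`` (also known as the regularised Laplacian
kernel) approximates the same diffusion for small ``beta``; at ``beta = 1``
it is the classical matrix forest index.

Both kernels are doubly stochastic-like on any graph: symmetric, entrywise
nonnegative, with every row summing to 1 (because ``L 1 = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .netio import Network

#: entries in (-CLIP_TOL, 0) are floating-point dust and snapped to zero
CLIP_TOL = 1e-12


@dataclass(frozen=True)
class KernelMatrix:
    """A diffusion kernel with its parameter and invariant checks."""

    values: np.ndarray
    parameter: float
    kind: str  # "heat" | "pmfi" | "mfi"

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_invariants(self, sym_tol: float = 1e-10, row_tol: float = 1e-8) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=sym_tol, rtol=0.0):
            raise AssertionError("kernel not symmetric")
        if not np.allclose(v.sum(axis=1), 1.0, atol=row_tol, rtol=0.0):
            raise AssertionError("kernel rows do not sum to 1")
        if v.min() < -CLIP_TOL:
            raise AssertionError(f"negative kernel entry {v.min()}")


def _clip(values: np.ndarray) -> np.ndarray:
    """Snap floating-point dust in (-CLIP_TOL, 0) to exact zero."""
    values[(values > -CLIP_TOL) & (values < 0.0)] = 0.0
    return values


def laplacian(network: Network) -> np.ndarray:
    """Weighted graph Laplacian ``L = D - A`` as a dense symmetric array.

    Off-diagonal ``(i, j)`` is ``-w_ij`` for edges, the diagonal holds the
    weighted degree, and rows sum to zero exactly in exact arithmetic.
    """
    A = network.adjacency()
    return np.diag(A.sum(axis=1)) - A


def heat_kernel(
    lap: np.ndarray,
    t: float,
    route: str = "exponential",
) -> KernelMatrix:
    """Heat kernel ``H_t = exp(-t L)``.

    Three numerically independent routes are provided and agree to 1e-8:

    - ``"exponential"`` — scipy's Pade-based ``expm`` (default);
    - ``"spectral"`` — ``sum_k exp(-lambda_k t) phi_k phi_k^T`` from the
      eigendecomposition of the symmetric Laplacian;
    - ``"series"`` — the truncated Taylor series of ``exp(-t L)``.
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    lap = np.asarray(lap, dtype=float)
    if route == "exponential":
        H = scipy.linalg.expm(-t * lap)
    elif route == "spectral":
        lam, phi = scipy.linalg.eigh(lap)
        H = (phi * np.exp(-lam * t)) @ phi.T
    elif route == "series":
        H = _expm_series(-t * lap)
    else:
        raise ValueError(f"unknown route {route!r}")
    H = _clip((H + H.T) / 2.0)
    return KernelMatrix(values=H, parameter=float(t), kind="heat")


def _expm_series(M: np.ndarray, rtol: float = 1e-14, max_terms: int = 200) -> np.ndarray:
    """Taylor series for expm with scaling-and-squaring for convergence."""
    norm = np.linalg.norm(M, ord=np.inf)
    squarings = max(0, int(np.ceil(np.log2(norm))) + 1) if norm > 0 else 0
    Ms = M / (2**squarings)
    out = np.eye(M.shape[0])
    term = np.eye(M.shape[0])
    for k in range(1, max_terms):
        term = term @ Ms / k
        out = out + term
        if np.linalg.norm(term, ord=np.inf) < rtol:
            break
    for _ in range(squarings):
        out = out @ out
    return out


def pmfi_kernel(lap: np.ndarray, beta: float) -> KernelMatrix:
    """Parametrised matrix forest kernel ``(I + beta L)^{-1}``.

    Solved as the symmetric positive-definite system
    ``(I + beta L) X = I`` via a Cholesky factorisation with ``n``
    right-hand sides — no explicit inverse is formed.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    lap = np.asarray(lap, dtype=float)
    n = lap.shape[0]
    M = np.eye(n) + beta * lap
    c, low = scipy.linalg.cho_factor(M)
    X = scipy.linalg.cho_solve((c, low), np.eye(n))
    X = _clip((X + X.T) / 2.0)
    kind = "mfi" if beta == 1.0 else "pmfi"
    return KernelMatrix(values=X, parameter=float(beta), kind=kind)


def pmfi_series(lap: np.ndarray, beta: float, terms: int) -> np.ndarray:
    """Partial Neumann series ``sum_{i=0}^{terms} (-beta)^i L^i``.

    Converges to :func:`pmfi_kernel` only inside the geometric-series
    regime ``beta * rho(L) < 1``; outside it an error names the bound.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if terms < 0:
        raise ValueError("terms must be >= 0")
    lap = np.asarray(lap, dtype=float)
    rho = float(np.max(np.abs(scipy.linalg.eigvalsh(lap))))
    if terms >= 1 and beta * rho >= 1.0:
        raise ValueError(
            f"series diverges: beta*rho(L) = {beta * rho:.6g} >= 1 "
            f"(requires beta < {1.0 / rho:.6g})"
        )
    n = lap.shape[0]
    out = np.eye(n)
    term = np.eye(n)
    for _ in range(terms):
        term = term @ (-beta * lap)
        out = out + term
    return out


def diffusion_profile(
    network: Network,
    source: str | int,
    times: list[float] | np.ndarray,
) -> dict[float, np.ndarray]:
    """Heat vectors from a unit source, per ``PMFI_beta`` time value.

    Interprets ``PMFI_beta(source, j)`` as the heat at node ``j`` after
    time ``t = beta`` given a unit injection at ``source`` (a small-beta
    approximation of the true heat kernel).  Each returned vector sums
    to 1.  ``beta = 0`` returns the initial unit mass at the source.
    """
    if isinstance(source, str):
        src = network.index_of(source)
    else:
        src = int(source)
        if not 0 <= src < network.n:
            raise KeyError(f"unknown source index {source}")
    lap = laplacian(network)
    out: dict[float, np.ndarray] = {}
    for t in times:
        t = float(t)
        if t < 0:
            raise ValueError(f"negative time {t}")
        if t == 0.0:
            vec = np.zeros(network.n)
            vec[src] = 1.0
        else:
            vec = pmfi_kernel(lap, t).values[src].copy()
        out[t] = vec
    return out
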