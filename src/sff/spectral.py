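"""Column-similarity graphs of pixel patches and their Fiedler value.

A small grayscale patch ``X = [x_1 ... x_N]`` (one node per *column* of the
patch) is turned into an unweighted undirected graph: the radial-basis kernel

    omega_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))

scores the similarity of two columns, and an edge joins nodes ``i != j``
whenever ``omega_ij <= r`` — i.e. whenever the columns are *dissimilar*.  The
algebraic connectivity of that graph, read off the normalized Laplacian

    L = D^(-1/2) (D - S) D^(-1/2),

is the "Fiedler value" used as a per-patch texture-contrast score: the more
the pixel intensities vary across the patch, the more edges appear and the
larger the smallest non-zero eigenvalue of ``L`` becomes.

Conventions for degenerate graphs (uniform patches are the common case in
flat image regions):

* isolated nodes (degree 0) are excluded from the Laplacian, so ``1/sqrt(d)``
  is always defined; the spectrum returned is that of the non-isolated
  subgraph;
* an edgeless graph has Fiedler value 0 (zero contrast);
* eigenvalues at or below ``zero_tol`` count as zero when selecting the
  smallest non-zero eigenvalue, so a disconnected graph reports the smallest
  eigenvalue above tolerance rather than the textbook 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, DimensionError, ParameterError

DEFAULT_ZERO_TOL = 1e-8


@dataclass(frozen=True)
class KernelParams:
    """Free parameters of the similarity graph.

    sigma
        Bandwidth of the radial-basis kernel, on the [0, 1] intensity scale.
    r
        Connection threshold in (0, 1): columns with kernel similarity at or
        below ``r`` are joined by an edge.
    """

    sigma: float = 0.25
    r: float = 0.3

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ParameterError(f"sigma must be a positive real, got {self.sigma}")
        if not (0.0 < self.r < 1.0):
            raise ParameterError(f"r must lie strictly in (0, 1), got {self.r}")


@dataclass
class PixelPatch:
    """A small patch of [0, 1]-normalized pixel intensities (columns = nodes)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise DimensionError(f"patch must be 2-D, got ndim={v.ndim}")
        if v.shape[1] < 2:
            raise DegenerateInputError("patch needs at least 2 columns to form a graph")
        if not np.all(np.isfinite(v)):
            raise ValueError("patch contains non-finite values")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError("patch intensities must be normalized to [0, 1]")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass
class SimilarityGraph:
    """Kernel weights and the thresholded binary adjacency of a patch graph."""

    weights: np.ndarray
    adjacency: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def is_complete(self, on_subgraph: bool = False) -> bool:
        """Whether every node pair is joined; optionally restricted to the
        non-isolated subgraph (the part the Laplacian is built on)."""
        a = np.asarray(self.adjacency, dtype=bool)
        if on_subgraph:
            keep = a.any(axis=0)
            if keep.sum() < 2:
                return False
            a = a[np.ix_(keep, keep)]
        n = a.shape[0]
        return bool(n >= 2 and a.sum() == n * (n - 1))


@dataclass
class SpectralResult:
    """Spectrum of the normalized Laplacian on the non-isolated subgraph.

    ``eigenvalues`` is sorted nondecreasing; ``degrees`` covers all nodes of
    the original graph (isolated nodes keep degree 0).
    """

    eigenvalues: np.ndarray
    fiedler_value: float
    degrees: np.ndarray


def has_only_clique_components(adjacency: np.ndarray) -> bool:
    """Whether every connected component of the non-isolated subgraph is a
    complete graph (a disjoint union of cliques).

    These are exactly the graphs whose Fiedler value (smallest non-zero
    normalized-Laplacian eigenvalue) exceeds 1: a connected non-complete
    component always contributes an eigenvalue <= 1, while a clique K_m
    contributes m/(m-1) > 1 — the "pathological scenarios" of the bound
    0 < lambda_2 < 1.
    """
    a = np.asarray(adjacency, dtype=bool)
    keep = a.any(axis=0)
    if not keep.any():
        return False
    a = a[np.ix_(keep, keep)]
    n = a.shape[0]
    # label components by repeated neighborhood expansion
    seen = np.zeros(n, dtype=bool)
    for start in range(n):
        if seen[start]:
            continue
        comp = np.zeros(n, dtype=bool)
        comp[start] = True
        while True:
            grown = comp | (a[comp].any(axis=0))
            if (grown == comp).all():
                break
            comp = grown
        m = int(comp.sum())
        sub = a[np.ix_(comp, comp)]
        if sub.sum() != m * (m - 1):
            return False
        seen |= comp
    return True


def kernel_weight(x_i: np.ndarray, x_j: np.ndarray, sigma: float) -> float:
    """Radial-basis similarity of two intensity column vectors."""
    x_i = np.asarray(x_i, dtype=float).ravel()
    x_j = np.asarray(x_j, dtype=float).ravel()
    if x_i.shape != x_j.shape:
        raise DimensionError(f"vector lengths differ: {x_i.size} vs {x_j.size}")
    if not np.isfinite(sigma) or sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    k = float(np.sum((x_i - x_j) ** 2))
    return float(np.exp(-k / (2.0 * sigma**2)))


def pairwise_weights(values: np.ndarray, sigma: float) -> np.ndarray:
    """Kernel weight matrix over the columns of ``values`` (exact unit diagonal)."""
    if not np.isfinite(sigma) or sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    x = np.asarray(values, dtype=float)
    sq = np.sum(x * x, axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x.T @ x)
    np.maximum(d2, 0.0, out=d2)
    w = np.exp(-d2 / (2.0 * sigma**2))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 1.0)
    return w


def build_graph(patch: PixelPatch | np.ndarray, params: KernelParams) -> SimilarityGraph:
    """Threshold the kernel weights of a patch into a binary similarity graph.

    An edge joins ``i != j`` iff ``omega_ij <= r``: the kernel decreases with
    column distance, so edges connect *dissimilar* columns and a uniform patch
    yields an edgeless graph.
    """
    if not isinstance(patch, PixelPatch):
        patch = PixelPatch(np.asarray(patch))
    w = pairwise_weights(patch.values, params.sigma)
    s = (w <= params.r)
    np.fill_diagonal(s, False)
    return SimilarityGraph(weights=w, adjacency=s.astype(np.uint8))


def fiedler_value(
    graph: SimilarityGraph | np.ndarray, zero_tol: float = DEFAULT_ZERO_TOL
) -> SpectralResult:
    """Smallest above-tolerance eigenvalue of the normalized Laplacian.

    Accepts a :class:`SimilarityGraph` or a bare binary adjacency matrix.
    Isolated nodes are dropped before forming ``D^(-1/2)``; an edgeless graph
    returns 0 by convention.
    """
    adj = graph.adjacency if isinstance(graph, SimilarityGraph) else graph
    s = np.asarray(adj, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise DimensionError("adjacency must be a square matrix")
    if not np.array_equal(s, s.T):
        raise ValueError("adjacency must be symmetric")
    degrees = s.sum(axis=1)
    keep = degrees > 0
    if not keep.any():
        return SpectralResult(
            eigenvalues=np.zeros(0),
            fiedler_value=0.0,
            degrees=degrees.astype(int),
        )
    a = s[np.ix_(keep, keep)]
    d = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    lap = np.eye(a.shape[0]) - (inv_sqrt[:, None] * a * inv_sqrt[None, :])
    eig = np.linalg.eigvalsh(lap)
    above = eig[eig > zero_tol]
    lam2 = float(above[0]) if above.size else 0.0
    return SpectralResult(eigenvalues=eig, fiedler_value=lam2, degrees=degrees.astype(int))


def fiedler_values_batched(
    adjacency: np.ndarray, zero_tol: float = DEFAULT_ZERO_TOL
) -> np.ndarray:
    """Fiedler values of a stack of binary adjacency matrices, vectorized.

    ``adjacency`` has shape (B, N, N).  Isolated nodes are handled by zeroing
    their Laplacian row/column, which only adds eigenvalues at 0 — below the
    zero tolerance — so the result matches the per-graph routine that drops
    them explicitly.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 3 or a.shape[1] != a.shape[2]:
        raise DimensionError("adjacency stack must have shape (B, N, N)")
    d = a.sum(axis=2)
    inv_sqrt = np.where(d > 0, d, 1.0) ** -0.5
    inv_sqrt = np.where(d > 0, inv_sqrt, 0.0)
    lap = -(inv_sqrt[:, :, None] * a * inv_sqrt[:, None, :])
    diag = np.arange(a.shape[1])
    lap[:, diag, diag] = (d > 0).astype(float)
    eig = np.linalg.eigvalsh(lap)
    masked = np.where(eig > zero_tol, eig, np.inf)
    lam2 = masked.min(axis=1)
    return np.where(np.isfinite(lam2), lam2, 0.0)
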