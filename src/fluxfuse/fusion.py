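"""Weighted similarity-network fusion (SNF) over multiplex condition layers.

Each omic layer is a symmetric condition-by-condition similarity matrix W.
Fusion initializes a status matrix P per layer (a row-normalized form of W),
builds a sparse local kernel S per layer (similarity restricted to each
node's K nearest neighbours, row-normalized), and iterates the
cross-diffusion update

    P(v)  <-  S(v) . mean_of_other_layers(P) . S(v)^T

until the layers agree.  The weighted variant replaces the plain mean by a
bias-weighted mean, sum_k(P(k) b_k) / sum_k(b_k) over k != v, so that more
trusted layers (e.g. the fluxomic layer of a well-validated model) pull the
others harder.  With two layers this weighted mean has a single term and
the bias cancels algebraically inside the update; the bias therefore also
enters the final aggregation sum_v(b_v P(v)) / sum_v(b_v), which is where a
2:1 phenotype:transcriptome weighting takes effect in the two-layer case
(controllable via ``bias_mode``).

Convergence is detected from the first and second discrete derivatives of
the per-iteration change scalar: the mean relative Frobenius change across
layers must be small and must have stopped changing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SimilarityLayer",
    "LocalAffinity",
    "MultiplexNetwork",
    "FusionResult",
    "distance_matrix",
    "similarity_exp",
    "similarity_scaled_kernel",
    "normalize_native",
    "layer_from_features",
    "normalize_p0",
    "local_affinity",
    "weighted_update",
    "fuse",
    "SimilarityNetworkFusion",
    "read_layer",
    "write_layer",
]

SYMMETRY_TOL = 1e-12


@dataclass
class SimilarityLayer:
    """A square, symmetric, non-negative condition-similarity matrix."""

    matrix: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.node_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != ({n}, {n}) node ids"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("similarity matrix must be finite")
        if np.any(self.matrix < 0):
            raise ValueError("similarity matrix must be non-negative")
        asym = np.abs(self.matrix - self.matrix.T).max(initial=0.0)
        if asym > 1e-9:
            raise ValueError(f"similarity matrix asymmetric (max dev {asym:.2e})")
        # tolerate tiny float asymmetry
        self.matrix = (self.matrix + self.matrix.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.node_ids)


@dataclass
class LocalAffinity:
    """Row-stochastic similarity restricted to K nearest neighbours per row."""

    matrix: np.ndarray
    K: int


@dataclass
class MultiplexNetwork:
    """Ordered similarity layers over one shared node set, plus fusion knobs."""

    layers: list[SimilarityLayer]
    bias: np.ndarray
    K: int
    max_iter: int = 20
    tol_change: float = 1e-6
    tol_slope: float = 1e-6

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("a multiplex needs >= 2 layers")
        ids = self.layers[0].node_ids
        for lay in self.layers[1:]:
            if lay.node_ids != ids:
                raise ValueError("all layers must share node ids and ordering")
        self.bias = np.asarray(self.bias, dtype=float)
        if self.bias.shape != (len(self.layers),):
            raise ValueError("bias length must equal layer count")
        if np.any(self.bias <= 0):
            raise ValueError("biases must be > 0")
        if not 1 <= self.K < self.layers[0].n:
            raise ValueError("K must satisfy 1 <= K < number of nodes")


@dataclass
class FusionResult:
    fused: SimilarityLayer
    iterations: int
    trace: list[float] = field(default_factory=list)
    converged: bool = True
    diverged: bool = False


def distance_matrix(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between rows (conditions)."""
    arr = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("distance_matrix requires finite input (impute first)")
    return squareform(pdist(arr, metric="euclidean"))


def similarity_exp(d: np.ndarray, node_ids: Sequence[str] | None = None) -> SimilarityLayer:
    """Similarity by exponential negative squared distance, exp(-d^2)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    W = np.exp(-(d ** 2))
    ids = list(node_ids) if node_ids is not None else [str(i) for i in range(d.shape[0])]
    return SimilarityLayer(W, ids)


def similarity_scaled_kernel(
    d: np.ndarray,
    mu: float = 0.5,
    K: int = 20,
    node_ids: Sequence[str] | None = None,
) -> SimilarityLayer:
    """Scaled exponential kernel exp(-d_ij^2 / (mu * eps_ij)).

    ``eps_ij`` is the local scale ``(mean_i + mean_j + d_ij^2) / 3`` where
    ``mean_i`` is the mean *squared* distance from i to its K nearest
    neighbours (self excluded); numerator and scale live on the same
    squared-distance scale, so the exponent is dimensionless and the kernel
    is invariant to a global rescaling of the distances.  Zero eps
    (coincident points) yields similarity 1 by continuity.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    K = min(K, n - 1)
    d2 = d ** 2
    sorted_d2 = np.sort(d2, axis=1)
    # column 0 is the self-distance 0; neighbours start at column 1
    means = sorted_d2[:, 1 : K + 1].mean(axis=1)
    eps = (means[:, None] + means[None, :] + d2) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.exp(-d2 / (mu * eps))
    W[eps == 0] = 1.0
    ids = list(node_ids) if node_ids is not None else [str(i) for i in range(n)]
    return SimilarityLayer(W, ids)


def layer_from_features(
    matrix: pd.DataFrame | np.ndarray,
    node_ids: Sequence[str] | None = None,
    kernel: str = "exp",
    rescale: str | float | None = "median",
    mu: float = 0.5,
    K: int = 20,
) -> SimilarityLayer:
    """Build a condition-similarity layer from a conditions x features matrix.

    Euclidean distances are computed between rows and passed through either
    the plain exponential kernel exp(-d^2) (``kernel="exp"``) or the locally
    scaled kernel (``kernel="scaled"``).  For the plain kernel, raw
    distances on high-dimensional data make exp(-d^2) underflow to an
    all-zero (disconnected) similarity row, so distances are first divided
    by a scale: the median positive pairwise distance (``rescale="median"``),
    a number, or ``None`` to disable.
    """
    if isinstance(matrix, pd.DataFrame) and node_ids is None:
        node_ids = [str(i) for i in matrix.index]
    d = distance_matrix(matrix)
    if kernel == "scaled":
        return similarity_scaled_kernel(d, mu=mu, K=K, node_ids=node_ids)
    if kernel != "exp":
        raise ValueError(f"unknown kernel {kernel!r}")
    if rescale == "median":
        pos = d[np.triu_indices_from(d, k=1)]
        pos = pos[pos > 0]
        scale = float(np.median(pos)) if pos.size else 1.0
    elif rescale is None:
        scale = 1.0
    else:
        scale = float(rescale)
    return similarity_exp(d / scale, node_ids)


def normalize_native(layer: SimilarityLayer) -> SimilarityLayer:
    """Normalize native similarities into [0, 1]: square, divide by the max."""
    W = layer.matrix ** 2
    mx = W.max()
    if mx == 0:
        raise ValueError("cannot normalize an all-zero similarity matrix")
    return SimilarityLayer(W / mx, list(layer.node_ids))


def normalize_p0(layer: SimilarityLayer, method: str = "robust") -> np.ndarray:
    """Initial status matrix P0 from W; rows sum to 1 in both variants.

    ``row_stochastic``: D^-1 W.  ``robust``: off-diagonal entries are
    W(i,j) / (2 * sum_{k != i} W(i,k)) and the diagonal is fixed at 1/2,
    which decouples the diagonal from the (often dominant) self-similarity
    and is less prone to numerical instability.
    """
    W = layer.matrix
    n = W.shape[0]
    if method == "row_stochastic":
        sums = W.sum(axis=1)
        bad = np.flatnonzero(sums <= 0)
        if bad.size:
            raise ValueError(f"zero row sum at node {layer.node_ids[bad[0]]!r}")
        return W / sums[:, None]
    if method == "robust":
        off = W.sum(axis=1) - np.diag(W)
        bad = np.flatnonzero(off <= 0)
        if bad.size:
            raise ValueError(f"zero off-diagonal row sum at node {layer.node_ids[bad[0]]!r}")
        P = W / (2.0 * off[:, None])
        np.fill_diagonal(P, 0.5)
        return P
    raise ValueError(f"unknown normalization {method!r}")


def local_affinity(layer: SimilarityLayer, K: int) -> LocalAffinity:
    """Row-stochastic similarity restricted to each node's K nearest neighbours.

    The neighbourhood N_i holds the K nodes with the largest W(i, .), the
    node itself competing like any other (with a dominant diagonal, self is
    always included; K = 1 then keeps only self).  Entries outside N_i are
    exactly zero; surviving rows are normalized to sum 1.
    """
    n = layer.n
    if not 1 <= K < n:
        raise ValueError(f"K must satisfy 1 <= K < {n}")
    W = layer.matrix
    S = np.zeros_like(W)
    for i in range(n):
        # stable top-K: sort descending by similarity, ties by index
        order = np.lexsort((np.arange(n), -W[i]))
        nbr = order[:K]
        S[i, nbr] = W[i, nbr]
    sums = S.sum(axis=1)
    sums[sums == 0] = 1.0
    return LocalAffinity(S / sums[:, None], K)


def weighted_update(
    P_list: Sequence[np.ndarray],
    S_list: Sequence[np.ndarray],
    bias: Sequence[float] | None = None,
) -> list[np.ndarray]:
    """One cross-diffusion step for every layer, from pre-update state.

    Layer v becomes ``S_v . M_v . S_v^T`` where ``M_v`` is the bias-weighted
    mean of the other layers' P (plain mean when biases are equal or
    absent).  Each result is regularized by re-adding the identity —
    without this self-similarity anchor the diffusion's stationary state is
    the uninformative uniform matrix — then symmetrized and row-normalized.
    All layers read only the pre-update P's, so the per-layer updates are
    order-independent (parallelizable).
    """
    m = len(P_list)
    if m < 2 or len(S_list) != m:
        raise ValueError("need matched P and S lists with >= 2 layers")
    shape = P_list[0].shape
    for M in list(P_list) + list(S_list):
        if M.shape != shape:
            raise ValueError("all matrices must share one shape")
    b = np.ones(m) if bias is None else np.asarray(bias, dtype=float)
    if b.shape != (m,) or np.any(b <= 0):
        raise ValueError("bias must be positive with one entry per layer")
    eye = np.eye(shape[0])
    out = []
    for v in range(m):
        others = [k for k in range(m) if k != v]
        if len(others) == 1:
            # single-term weighted mean: the bias cancels algebraically
            Mv = P_list[others[0]]
        elif np.all(b[others] == b[others[0]]):
            Mv = sum(P_list[k] for k in others) / len(others)
        else:
            denom = sum(b[k] for k in others)
            Mv = sum(P_list[k] * b[k] for k in others) / denom
        P_new = S_list[v] @ Mv @ S_list[v].T
        P_new = (P_new + P_new.T) / 2.0 + eye
        out.append(_sym_row_normalize(P_new))
    return out


def _sym_row_normalize(P: np.ndarray, tol: float = 1e-10, max_pass: int = 200) -> np.ndarray:
    """Project a non-negative matrix to (near-)symmetric row-stochastic form.

    Alternates row normalization with symmetrization (a symmetric Sinkhorn
    scaling); at the fixed point the matrix is symmetric and doubly
    stochastic.  Stops when row sums are within ``tol`` of 1.
    """
    for _ in range(max_pass):
        sums = P.sum(axis=1)
        sums[sums == 0] = 1.0
        P = P / sums[:, None]
        P = (P + P.T) / 2.0
        if np.abs(P.sum(axis=1) - 1.0).max() < tol:
            break
    return P


def fuse(network: MultiplexNetwork, p0_method: str = "robust",
         bias_mode: str = "both") -> FusionResult:
    """Iterate the weighted update until the layers agree; aggregate them.

    ``bias_mode``: ``"update"`` applies the bias only inside the
    cross-diffusion mean, ``"aggregate"`` only in the final combination
    ``sum_v b_v P(v) / sum_v b_v``, ``"both"`` (default) in both places.
    Convergence requires the mean relative Frobenius change c_n across
    layers to fall below ``tol_change`` with its discrete slope
    |c_n - c_{n-1}| below ``tol_slope``.  A change scalar that increases
    for five consecutive iterations flags divergence and returns the
    partial result.
    """
    if bias_mode not in ("update", "aggregate", "both"):
        raise ValueError(f"unknown bias_mode {bias_mode!r}")
    P_list = [normalize_p0(lay, p0_method) for lay in network.layers]
    S_list = [local_affinity(lay, network.K).matrix for lay in network.layers]
    update_bias = network.bias if bias_mode in ("update", "both") else None
    agg_bias = network.bias if bias_mode in ("aggregate", "both") else np.ones(len(P_list))

    trace: list[float] = []
    converged = False
    diverged = False
    rising = 0
    iterations = 0
    for it in range(network.max_iter):
        P_next = weighted_update(P_list, S_list, update_bias)
        changes = [
            np.linalg.norm(Pn - Po, "fro") / max(np.linalg.norm(Po, "fro"), 1e-300)
            for Pn, Po in zip(P_next, P_list)
        ]
        c = float(np.mean(changes))
        P_list = P_next
        iterations = it + 1
        if trace and c > trace[-1]:
            rising += 1
            if rising >= 5:
                trace.append(c)
                diverged = True
                break
        else:
            rising = 0
        prev = trace[-1] if trace else None
        trace.append(c)
        if c < network.tol_change and prev is not None and abs(c - prev) < network.tol_slope:
            converged = True
            break

    agg = np.asarray(agg_bias, dtype=float)
    fused = sum(P * w for P, w in zip(P_list, agg)) / agg.sum()
    fused = (fused + fused.T) / 2.0
    return FusionResult(
        fused=SimilarityLayer(fused, list(network.layers[0].node_ids)),
        iterations=iterations,
        trace=trace,
        converged=converged or network.max_iter == 0,
        diverged=diverged,
    )


class SimilarityNetworkFusion(BaseEstimator, TransformerMixin):
    """Sklearn-style front end for weighted SNF.

    ``fit(X)`` accepts either a list of per-layer feature matrices
    (conditions x features; similarities are built with exp(-d^2) on
    Euclidean distances) or a list of :class:`SimilarityLayer` /
    square ndarrays already holding similarities.

    Parameters
    ----------
    K : int or None
        Neighbourhood size; ``None`` picks ``max(2, n_nodes // 3)``.
    bias : sequence of float or None
        Per-layer confidence weights (``None`` = unbiased).
    bias_mode : {"both", "update", "aggregate"}
        Where the bias enters (see :func:`fuse`).
    max_iter, tol_change, tol_slope
        Iteration cap and the first/second-derivative convergence
        tolerances on the change scalar.
    p0_method : {"robust", "row_stochastic"}
        Initial normalization of each layer.

    Attributes
    ----------
    fused_ : ndarray
        The fused similarity matrix.
    n_iter_ : int
    trace_ : list of float
    converged_, diverged_ : bool
    node_ids_ : list of str
    """

    def __init__(
        self,
        K: int | None = None,
        bias: Sequence[float] | None = None,
        bias_mode: str = "both",
        max_iter: int = 20,
        tol_change: float = 1e-6,
        tol_slope: float = 1e-6,
        p0_method: str = "robust",
    ):
        self.K = K
        self.bias = bias
        self.bias_mode = bias_mode
        self.max_iter = max_iter
        self.tol_change = tol_change
        self.tol_slope = tol_slope
        self.p0_method = p0_method

    def _to_layers(self, X) -> list[SimilarityLayer]:
        layers = []
        node_ids = None
        for item in X:
            if isinstance(item, SimilarityLayer):
                layers.append(item)
                continue
            if isinstance(item, pd.DataFrame):
                ids = [str(i) for i in item.index]
                arr = item.to_numpy(dtype=float)
            else:
                arr = np.asarray(item, dtype=float)
                ids = None
            square = arr.ndim == 2 and arr.shape[0] == arr.shape[1] and np.allclose(arr, arr.T, atol=1e-9)
            if square and np.all(arr >= 0) and np.all(arr <= 1 + 1e-12):
                layers.append(SimilarityLayer(arr, ids or [str(i) for i in range(arr.shape[0])]))
            else:
                layers.append(layer_from_features(arr, ids))
            node_ids = node_ids or layers[-1].node_ids
        return layers

    def fit(self, X, y=None):
        layers = self._to_layers(X)
        n = layers[0].n
        K = self.K if self.K is not None else max(2, n // 3)
        bias = np.ones(len(layers)) if self.bias is None else np.asarray(self.bias, float)
        net = MultiplexNetwork(
            layers=layers,
            bias=bias,
            K=K,
            max_iter=self.max_iter,
            tol_change=self.tol_change,
            tol_slope=self.tol_slope,
        )
        res = fuse(net, p0_method=self.p0_method, bias_mode=self.bias_mode)
        self.fused_ = res.fused.matrix
        self.node_ids_ = res.fused.node_ids
        self.n_iter_ = res.iterations
        self.trace_ = res.trace
        self.converged_ = res.converged
        self.diverged_ = res.diverged
        return self

    def transform(self, X=None):
        check_is_fitted(self, "fused_")
        return self.fused_

    def fit_transform(self, X, y=None):
        return self.fit(X).transform()


def read_layer(path: str | Path, sep: str = "\t") -> SimilarityLayer:
    """Read a square similarity matrix with node-id header row and column."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("row and column node ids differ")
    return SimilarityLayer(df.to_numpy(dtype=float), [str(i) for i in df.index])


def write_layer(layer: SimilarityLayer, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(layer.matrix, index=layer.node_ids, columns=layer.node_ids).to_csv(
        path, sep=sep
    )
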