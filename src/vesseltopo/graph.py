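"""Topology-preserving pixel-grid graph construction.

Every pixel of a P x Q raster is a node (row-major, 0-based).  An undirected
edge joins two pixels iff they are 8-neighbors and both belong to the
(optionally disk-dilated) foreground mask; background pixels remain as
isolated nodes.  Node features concatenate the pixel's backbone features
with its image channels.  The propagation matrix adds self-loops and applies
the symmetric degree normalization D_hat^(-1/2) (A + I) D_hat^(-1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import ndimage

from .backbone import FeatureMap, ProbabilityMap
from .synth import BACKGROUND

FEATURE_MODES = ("cnn+rgb", "cnn", "rgb")


@dataclass
class VesselGraph:
    """Pixel graph: N nodes, features X, undirected edges, sparse adjacency."""

    shape: tuple[int, int]  # (P, Q) of the source raster
    X: np.ndarray  # (N, C) node features
    edges: np.ndarray  # (M, 2) int array, each row i < j
    A: sp.csr_matrix  # symmetric 0/1 adjacency, zero diagonal
    y: np.ndarray | None = None  # optional (N,) node labels
    node_ids: np.ndarray | None = None  # original pixel ids when reindexed

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def M(self) -> int:
        return self.edges.shape[0]

    def pixel_to_node(self, row: int, col: int) -> int:
        return row * self.shape[1] + col

    def node_to_pixel(self, node: int) -> tuple[int, int]:
        return divmod(node, self.shape[1])


@dataclass
class NormalizedAdjacency:
    """Self-looped, symmetrically normalized propagation matrix."""

    A_hat: sp.csr_matrix
    D_hat: np.ndarray  # diagonal of the degree matrix of A_hat
    S: sp.csr_matrix  # D_hat^(-1/2) A_hat D_hat^(-1/2)


def binarize(probs: ProbabilityMap | np.ndarray) -> np.ndarray:
    """Foreground mask: pixels whose argmax class is any vessel class.

    Argmax ties break toward the lowest class index, so an exact tie with
    background stays background.
    """
    arr = probs.probs if isinstance(probs, ProbabilityMap) else np.asarray(probs)
    return arr.argmax(axis=-1) != BACKGROUND


def dilate(mask: np.ndarray, r: int) -> np.ndarray:
    """Morphological dilation with the disk {(di, dj): di^2 + dj^2 <= r^2}."""
    if r < 0:
        raise ValueError(f"dilation radius must be >= 0, got {r}")
    mask = np.asarray(mask, dtype=bool)
    if r == 0:
        return mask.copy()
    rng = np.arange(-r, r + 1)
    di, dj = np.meshgrid(rng, rng, indexing="ij")
    footprint = di * di + dj * dj <= r * r
    return ndimage.binary_dilation(mask, structure=footprint)


# 8-neighborhood: the four unique offsets (the other four are symmetric)
_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def build_edges(mask: np.ndarray) -> tuple[np.ndarray, sp.csr_matrix]:
    """Edges between 8-adjacent foreground pixel pairs; all pixels are nodes.

    Returns (edges, A): edges is an (M, 2) array of node-id pairs (i < j,
    row-major pixel ids); A is the symmetric 0/1 CSR adjacency over all
    P*Q nodes with zero diagonal.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a non-empty 2-D raster")
    P, Q = mask.shape
    ids = np.arange(P * Q).reshape(P, Q)
    src_list, dst_list = [], []
    for di, dj in _OFFSETS:
        if di >= 0:
            a = mask[: P - di if di else P, :]
            b = mask[di:, :]
            ia = ids[: P - di if di else P, :]
            ib = ids[di:, :]
        if dj > 0:
            a, b = a[:, : Q - dj], b[:, dj:]
            ia, ib = ia[:, : Q - dj], ib[:, dj:]
        elif dj < 0:
            a, b = a[:, -dj:], b[:, : Q + dj]
            ia, ib = ia[:, -dj:], ib[:, : Q + dj]
        both = a & b
        src_list.append(ia[both])
        dst_list.append(ib[both])
    src = np.concatenate(src_list)
    dst = np.concatenate(dst_list)
    lo, hi = np.minimum(src, dst), np.maximum(src, dst)
    order = np.lexsort((hi, lo))
    edges = np.stack([lo[order], hi[order]], axis=1)
    n = P * Q
    data = np.ones(2 * len(src), dtype=np.float64)
    A = sp.csr_matrix(
        (data, (np.concatenate([src, dst]), np.concatenate([dst, src]))),
        shape=(n, n),
    )
    A.sum_duplicates()
    return edges, A


def assemble_features(
    feats: FeatureMap | np.ndarray, image: np.ndarray, mode: str = "cnn+rgb"
) -> np.ndarray:
    """Node-feature matrix X (row-major pixel order).

    mode 'cnn+rgb' concatenates backbone features then image channels
    (C = H + CH); 'cnn' and 'rgb' select the respective subset.
    """
    f = feats.feats if isinstance(feats, FeatureMap) else np.asarray(feats)
    image = np.asarray(image)
    if mode not in FEATURE_MODES:
        raise ValueError(f"mode must be one of {FEATURE_MODES}, got {mode!r}")
    if f.shape[:2] != image.shape[:2]:
        raise ValueError(
            f"feature map {f.shape[:2]} and image {image.shape[:2]} disagree"
        )
    p, q = image.shape[:2]
    if mode == "cnn":
        stacked = f
    elif mode == "rgb":
        stacked = image
    else:
        stacked = np.concatenate([f, image], axis=-1)
    return stacked.reshape(p * q, -1).astype(np.float64)


def normalize(A: sp.spmatrix) -> NormalizedAdjacency:
    """Self-loop + symmetric degree normalization of an adjacency matrix."""
    A = sp.csr_matrix(A)
    if (abs(A - A.T)).nnz != 0:
        raise ValueError("adjacency must be symmetric")
    if A.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    n = A.shape[0]
    A_hat = (A + sp.identity(n, format="csr", dtype=np.float64)).tocsr()
    d_hat = np.asarray(A_hat.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(d_hat)
    Dinv = sp.diags(inv_sqrt)
    S = (Dinv @ A_hat @ Dinv).tocsr()
    return NormalizedAdjacency(A_hat=A_hat, D_hat=d_hat, S=S)


def build_graph(
    mask: np.ndarray,
    feats: FeatureMap | np.ndarray,
    image: np.ndarray,
    labels: np.ndarray | None = None,
    dilation_r: int = 0,
    feature_mode: str = "cnn+rgb",
    keep_isolated: bool = True,
) -> VesselGraph:
    """Assemble the full graph representation from a foreground mask.

    ``keep_isolated=False`` drops background (non-mask) pixels and
    reindexes the remaining nodes, recording original pixel ids in
    ``node_ids`` (the isolated-node ablation).
    """
    mask = dilate(mask, dilation_r)
    edges, A = build_edges(mask)
    X = assemble_features(feats, image, mode=feature_mode)
    y = None if labels is None else np.asarray(labels).reshape(-1).copy()
    if keep_isolated:
        return VesselGraph(shape=mask.shape, X=X, edges=edges, A=A, y=y)
    keep = np.flatnonzero(mask.reshape(-1))
    remap = -np.ones(mask.size, dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    edges = remap[edges]
    A = A[keep][:, keep].tocsr()
    return VesselGraph(
        shape=mask.shape,
        X=X[keep],
        edges=edges,
        A=A,
        y=None if y is None else y[keep],
        node_ids=keep,
    )
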