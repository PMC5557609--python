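"""Temporal/spatial decimation, interleaved grids, ZOH upsampling, compression.

Decimation is plain local averaging: blocks of ``k`` frames in time, blocks of
``ly x lx`` pixels in space.  The spatial operator is a sparse linear map on
flattened images, which makes the identity behind two-phase imaging exact:
``decimate(A @ C) == decimate(A) @ C`` to machine precision.

The block tiling may be shifted by an ``offset`` (row, col), the mechanism
behind interleaved acquisition: even frames use offset ``(0, 0)``, odd frames
a half-block shift.  Border blocks clipped by the grid average only the
pixels they cover, so constant images stay constant under any offset.

Truncated-SVD and Gaussian random-sketch compressions are provided as the
comparison baselines for decimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh, qr

from .io_model import VideoStack, flatten, unflatten

__all__ = [
    "DecimationSpec",
    "CompressedBasis",
    "decimate_temporal",
    "decimate_spatial",
    "decimated_grid_shape",
    "decimation_matrix",
    "upsample_zoh",
    "compress_svd",
    "compress_random",
]


@dataclass(frozen=True)
class DecimationSpec:
    """Decimation factors: ``k`` frames per temporal block, ``ly x lx`` pixels
    per spatial block, and a (row, col) grid shift for interleaving."""

    k: int = 1
    ly: int = 1
    lx: int = 1
    offset: Tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.k < 1 or self.ly < 1 or self.lx < 1:
            raise ValueError("decimation factors must be >= 1")
        oy, ox = self.offset
        if not (0 <= oy < self.ly and 0 <= ox < self.lx):
            raise ValueError("offset must lie in [0, block size)")

    @staticmethod
    def half_shift(ly: int, lx: int, k: int = 1) -> "DecimationSpec":
        """The half-block-shifted grid used on alternate interleaved frames."""
        return DecimationSpec(k=k, ly=ly, lx=lx, offset=(ly // 2, lx // 2))


# ---------------------------------------------------------------------------
# temporal decimation
# ---------------------------------------------------------------------------


def decimate_temporal(Y: np.ndarray, k: int, method: str = "mean") -> np.ndarray:
    """Aggregate each block of ``k`` frames of a ``D x T`` matrix (or 1-D
    trace) into one frame.  ``method`` is ``mean`` (default), ``median``, or
    ``subsample`` (first frame of each block).  A trailing partial block is
    aggregated over its actual length."""
    if k < 1:
        raise ValueError("temporal decimation factor k must be >= 1")
    Y = np.asarray(Y, dtype=np.float64)
    squeeze = Y.ndim == 1
    Y2 = np.atleast_2d(Y)
    D, T = Y2.shape
    if k == 1:
        out = Y2.copy()
    else:
        nblocks = -(-T // k)
        if method == "subsample":
            out = Y2[:, ::k].copy()
        else:
            agg = np.mean if method == "mean" else np.median
            if method not in ("mean", "median"):
                raise ValueError(f"unknown temporal decimation method {method!r}")
            full = (T // k) * k
            out = np.empty((D, nblocks))
            if full:
                out[:, : T // k] = agg(Y2[:, :full].reshape(D, T // k, k), axis=2)
            if full < T:
                out[:, -1] = agg(Y2[:, full:], axis=1)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# spatial decimation
# ---------------------------------------------------------------------------


def decimated_grid_shape(H: int, W: int, ly: int, lx: int,
                         offset: Tuple[int, int] = (0, 0)) -> Tuple[int, int]:
    """Output grid dims for block tiling anchored at ``-offset``."""
    oy, ox = offset
    return (-(-(H + oy) // ly), -(-(W + ox) // lx))


def decimation_matrix(H: int, W: int, ly: int, lx: int,
                      offset: Tuple[int, int] = (0, 0)) -> sp.csr_matrix:
    """Sparse ``D' x D`` averaging map for ``ly x lx`` block decimation.

    Each row averages the pixels of one block; rows sum to 1 (partial border
    blocks renormalize over the pixels they cover).
    """
    if ly < 1 or lx < 1:
        raise ValueError("spatial decimation factors must be >= 1")
    oy, ox = offset
    if ly > H + oy or lx > W + ox:
        raise ValueError("decimation block exceeds grid size")
    if not (0 <= oy < ly and 0 <= ox < lx):
        raise ValueError("offset must lie in [0, block size)")
    Hd, Wd = decimated_grid_shape(H, W, ly, lx, offset)
    rows = np.arange(H)
    cols = np.arange(W)
    block_r = (rows + oy) // ly
    block_c = (cols + ox) // lx
    # flat block index per input pixel
    dest = (block_r[:, None] * Wd + block_c[None, :]).ravel()
    src = np.arange(H * W)
    counts = np.bincount(dest, minlength=Hd * Wd).astype(np.float64)
    weights = 1.0 / counts[dest]
    return sp.csr_matrix((weights, (dest, src)), shape=(Hd * Wd, H * W))


def decimate_spatial(
    X: Union[VideoStack, np.ndarray],
    ly: int,
    lx: int,
    offset: Tuple[int, int] = (0, 0),
    grid: Optional[Tuple[int, int]] = None,
):
    """Spatially decimate a movie or a flat ``D x m`` matrix.

    For a :class:`VideoStack` input returns a decimated ``VideoStack``.  For a
    matrix input, ``grid=(H, W)`` must describe the pixel rows; returns
    ``(decimated matrix, (Hd, Wd))``.
    """
    if isinstance(X, VideoStack):
        mat = flatten(X)
        H, W = X.H, X.W
        M = decimation_matrix(H, W, ly, lx, offset)
        Hd, Wd = decimated_grid_shape(H, W, ly, lx, offset)
        return unflatten(M @ mat, Hd, Wd, rate=X.rate)
    if grid is None:
        raise ValueError("matrix input requires grid=(H, W) metadata")
    H, W = grid
    mat = np.atleast_2d(np.asarray(X, dtype=np.float64))
    one_d = np.asarray(X).ndim == 1
    if one_d:
        mat = mat.T
    if mat.shape[0] != H * W:
        raise ValueError(f"matrix has {mat.shape[0]} rows but grid implies {H * W}")
    M = decimation_matrix(H, W, ly, lx, offset)
    out = M @ mat
    if one_d:
        out = out.ravel()
    return out, decimated_grid_shape(H, W, ly, lx, offset)


def upsample_zoh(
    A_dec: np.ndarray,
    ly: int,
    lx: int,
    H: int,
    W: int,
    offset: Tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Zero-order-hold upsampling: every full-resolution pixel inherits the
    value of its covering block.  ``A_dec`` is ``D' x m`` (or length ``D'``)
    on the decimated grid; returns ``D x m`` (or length ``D``)."""
    Hd, Wd = decimated_grid_shape(H, W, ly, lx, offset)
    A_dec = np.asarray(A_dec, dtype=np.float64)
    one_d = A_dec.ndim == 1
    mat = np.atleast_2d(A_dec)
    if one_d:
        mat = mat.T
    if mat.shape[0] != Hd * Wd:
        raise ValueError(
            f"decimated input has {mat.shape[0]} rows, expected {Hd * Wd} for "
            f"grid ({H},{W}) with blocks ({ly},{lx}) offset {offset}")
    oy, ox = offset
    block_r = (np.arange(H) + oy) // ly
    block_c = (np.arange(W) + ox) // lx
    dest = (block_r[:, None] * Wd + block_c[None, :]).ravel()
    out = mat[dest, :]
    return out.ravel() if one_d else out


# ---------------------------------------------------------------------------
# compression baselines
# ---------------------------------------------------------------------------


@dataclass
class CompressedBasis:
    """Compressed representation of a ``D x T`` movie.

    SVD path: ``right_basis`` holds the ``M x T`` orthonormal eigenvector
    rows of ``Y^T Y``; compressed data is ``Y @ right_basis.T``.  Random path:
    ``left_sketch`` (``D x M``, orthonormal columns spanning range(Y Omega))
    and ``right_sketch`` (``M x T``, orthonormal rows for ``Y^T``).
    """

    M: int
    right_basis: Optional[np.ndarray] = None
    left_sketch: Optional[np.ndarray] = None
    right_sketch: Optional[np.ndarray] = None
    probe: Optional[np.ndarray] = None
    seed: Optional[int] = None


def compress_svd(Y: np.ndarray, M: int) -> Tuple[CompressedBasis, np.ndarray]:
    """Truncated SVD compression via the ``T x T`` covariance ``Y^T Y``.

    Returns the basis and the projected data ``Y @ V^T`` (``D x M``).
    """
    Y = np.asarray(Y, dtype=np.float64)
    D, T = Y.shape
    if not 1 <= M <= min(D, T):
        raise ValueError(f"M={M} out of range [1, {min(D, T)}]")
    cov = Y.T @ Y
    # eigh returns ascending order; take the top M
    _, vecs = eigh(cov, subset_by_index=(T - M, T - 1))
    V = vecs[:, ::-1].T  # M x T, descending eigenvalue order
    return CompressedBasis(M=M, right_basis=V), Y @ V.T


def compress_random(Y: np.ndarray, M: int, seed: int = 0) -> CompressedBasis:
    """Gaussian random-sketch compression: QR of ``Y @ Omega`` gives the
    orthonormal left basis ``L``; analogously for ``Y^T``.  Deterministic
    given ``seed``."""
    Y = np.asarray(Y, dtype=np.float64)
    D, T = Y.shape
    if not 1 <= M <= min(D, T):
        raise ValueError(f"M={M} out of range [1, {min(D, T)}]")
    rng = np.random.default_rng(seed)
    omega = rng.standard_normal((T, M))
    L, _ = qr(Y @ omega, mode="economic")
    omega2 = rng.standard_normal((D, M))
    R, _ = qr(Y.T @ omega2, mode="economic")
    return CompressedBasis(M=M, left_sketch=L, right_sketch=R.T, probe=omega, seed=seed)
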