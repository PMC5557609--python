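"""Noise estimation, greedy component detection, patches, initial factors.

The fitting pipeline needs four ingredients before any descent step runs:

* a per-pixel noise level ``sigma_d``, estimated from the high-frequency part
  of each pixel's power spectral density (slow calcium transients live at low
  frequencies, so the upper half of the spectrum is noise-dominated);
* component centers, found greedily: blur the movie with a Gaussian matched
  to the expected soma radius, repeatedly pick the pixel with the largest
  temporal energy, refine a local rank-1 (shape, trace) pair, subtract it;
* square patches ``P_n`` around the centers that confine each footprint,
  giving spatial locality by construction;
* initial factors: the spatial background as a low temporal percentile,
  Gaussian-bump shapes in their patches, traces read off the center pixels,
  and an all-ones temporal background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import periodogram

from .io_model import FactorModel, VideoStack, flatten

__all__ = [
    "NoiseMap",
    "CenterList",
    "PatchSet",
    "InitConfig",
    "estimate_pixel_noise",
    "greedy_initialize",
    "build_patches",
    "initialize_factors",
]


@dataclass
class InitConfig:
    """Initialization settings: component count, expected soma radius (px),
    patch half-width (px), background percentile, and PSD noise band."""

    n_components: int = 10
    expected_radius: float = 2.0
    patch_half_width: int = 6
    background_percentile: float = 20.0
    noise_band: Tuple[float, float] = (0.5, 1.0)


@dataclass
class NoiseMap:
    """Per-pixel noise standard deviation and the PSD band that produced it."""

    sigma: np.ndarray
    band: Tuple[float, float] = (0.5, 1.0)

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=np.float64).ravel()
        lo, hi = self.band
        if not (0 < lo < hi <= 1):
            raise ValueError("band must lie within (0, 1] as fractions of Nyquist")
        if np.any(self.sigma < 0):
            raise ValueError("noise levels must be non-negative")


@dataclass
class CenterList:
    """Ordered (row, col) coordinates of suspected somata."""

    centers: np.ndarray
    expected_radius: float = 2.0

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=int))

    def __len__(self):
        return len(self.centers)


@dataclass
class PatchSet:
    """Per-component admissible pixel supports (flat indices); the background
    patch is implicitly all pixels."""

    indices: List[np.ndarray]
    H: int
    W: int

    def __post_init__(self):
        D = self.H * self.W
        for n, idx in enumerate(self.indices):
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                raise ValueError(f"patch {n} is empty")
            if idx.min() < 0 or idx.max() >= D:
                raise ValueError(f"patch {n} indices out of [0, {D})")
            self.indices[n] = idx

    def __len__(self):
        return len(self.indices)

    def mask_matrix(self) -> np.ndarray:
        """Dense boolean ``D x N`` support mask."""
        D = self.H * self.W
        M = np.zeros((D, len(self.indices)), dtype=bool)
        for n, idx in enumerate(self.indices):
            M[idx, n] = True
        return M


# ---------------------------------------------------------------------------
# noise estimation
# ---------------------------------------------------------------------------


def estimate_pixel_noise(
    Y, rate: float = 1.0, band: Tuple[float, float] = (0.5, 1.0)
) -> NoiseMap:
    """Estimate per-pixel noise sigma from the mean periodogram power over a
    high-frequency band (fractions of Nyquist).

    Calibrated so i.i.d. Gaussian noise of std ``s`` yields ``sigma -> s``
    as ``T`` grows.  ``Y`` may be a movie, a ``D x T`` matrix, or one trace.
    """
    if isinstance(Y, VideoStack):
        Y = flatten(Y)
    Y = np.asarray(Y, dtype=np.float64)
    squeeze = Y.ndim == 1
    Y2 = np.atleast_2d(Y)
    T = Y2.shape[1]
    lo, hi = band
    if not (0 < lo < hi <= 1):
        raise ValueError("band must lie within (0, 1] as fractions of Nyquist")
    # fs=2 puts the Nyquist frequency at 1, so band limits are frequencies.
    freqs, pxx = periodogram(Y2, fs=2.0, axis=-1)
    sel = (freqs >= lo) & (freqs <= hi)
    if sel.sum() < 8:
        raise ValueError(
            f"only {int(sel.sum())} periodogram bins in band {band}; trace too "
            "short for noise estimation (need >= 8)")
    # One-sided periodogram integrates to the variance over f in [0, 1], so a
    # flat (white) spectrum sits at the variance itself; halve the doubled
    # interior bins' contribution by averaging power directly.
    sigma = np.sqrt(np.mean(pxx[:, sel], axis=1))
    sigma = np.nan_to_num(sigma)
    nm = NoiseMap(sigma=sigma, band=band)
    if squeeze:
        nm.sigma = nm.sigma[:1]
    return nm


# ---------------------------------------------------------------------------
# greedy center detection
# ---------------------------------------------------------------------------


def greedy_initialize(
    Y: VideoStack,
    N: int,
    expected_radius: float = 2.0,
    seed: int = 0,
    refine_iters: int = 3,
) -> CenterList:
    """Greedy detection of ``N`` component centers.

    Mean-subtracts the movie, Gaussian-blurs each frame (reflection padding)
    with width ``expected_radius``, and repeats ``N`` times: pick the pixel
    maximizing the temporal energy of the blurred movie (row-major index on
    ties), refine a local rank-1 (shape, trace) pair around it, subtract the
    explained signal, and continue.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if N > Y.D:
        raise ValueError(f"cannot place N={N} centers on D={Y.D} pixels")
    data = Y.data - Y.data.mean(axis=0, keepdims=True)
    if not np.any(data):
        raise ValueError("degenerate input: movie is constant in time")
    T, H, W = data.shape
    blurred = gaussian_filter(data, sigma=(0, expected_radius, expected_radius),
                              mode="reflect")
    energy = np.sum(blurred**2, axis=0)
    win = max(1, int(np.ceil(2 * expected_radius)))
    blur_pad = int(np.ceil(4 * expected_radius))
    centers = []
    for _ in range(N):
        d = int(np.argmax(energy))  # first max -> row-major tie rule
        r, c = divmod(d, W)
        centers.append((r, c))
        r0, r1 = max(0, r - win), min(H, r + win + 1)
        c0, c1 = max(0, c - win), min(W, c + win + 1)
        patch = data[:, r0:r1, c0:c1].reshape(T, -1)
        # rank-1 refinement: trace from the center pixel, then alternate
        trace = data[:, r, c].copy()
        shape = np.zeros(patch.shape[1])
        for _ in range(refine_iters):
            denom = trace @ trace
            if denom <= 0:
                break
            shape = np.maximum(0, patch.T @ trace / denom)
            denom = shape @ shape
            if denom <= 0:
                break
            trace = patch @ shape / denom
        data[:, r0:r1, c0:c1] -= np.outer(trace, shape).reshape(T, r1 - r0, c1 - c0)
        # refresh blurred energy near the modified window
        R0, R1 = max(0, r0 - blur_pad), min(H, r1 + blur_pad)
        C0, C1 = max(0, c0 - blur_pad), min(W, c1 + blur_pad)
        local = gaussian_filter(data[:, R0:R1, C0:C1],
                                sigma=(0, expected_radius, expected_radius),
                                mode="reflect")
        energy[R0:R1, C0:C1] = np.sum(local**2, axis=0)
    return CenterList(centers=np.array(centers), expected_radius=expected_radius)


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------


def build_patches(centers: CenterList, patch_half_width: int, H: int, W: int) -> PatchSet:
    """Square windows of side ``2 h + 1`` around each center, clipped at the
    grid borders."""
    if patch_half_width < 0:
        raise ValueError("patch_half_width must be >= 0")
    indices = []
    for r, c in centers.centers:
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"center ({r},{c}) outside the {H}x{W} grid")
        rows = np.arange(max(0, r - patch_half_width), min(H, r + patch_half_width + 1))
        cols = np.arange(max(0, c - patch_half_width), min(W, c + patch_half_width + 1))
        indices.append((rows[:, None] * W + cols[None, :]).ravel())
    return PatchSet(indices=indices, H=H, W=W)


# ---------------------------------------------------------------------------
# initial factors
# ---------------------------------------------------------------------------


def initialize_factors(
    Y: VideoStack,
    centers: CenterList,
    patches: PatchSet,
    percentile: float = 20.0,
) -> FactorModel:
    """Initial factor values: background from a low temporal percentile,
    Gaussian-bump shapes truncated to their patches, traces read off the
    center pixels (background-subtracted and clamped at 0), all-ones ``f``."""
    mat = flatten(Y)
    D, T = mat.shape
    H, W = Y.H, Y.W
    b = np.percentile(mat, percentile, axis=1)
    f = np.ones(T)
    N = len(centers)
    A = np.zeros((D, N))
    C = np.zeros((N, T))
    radius = max(centers.expected_radius, 1e-3)
    rows = np.arange(H)
    cols = np.arange(W)
    for n, (r, c) in enumerate(centers.centers):
        bump = np.exp(
            -((rows[:, None] - r) ** 2 + (cols[None, :] - c) ** 2) / (2 * radius**2)
        ).ravel()
        idx = patches.indices[n]
        A[idx, n] = bump[idx]
        d = r * W + c
        C[n] = np.maximum(0, mat[d] - b[d] * f)
    return FactorModel(A=A, C=C, b=b, f=f, H=H, W=W, rate=Y.rate,
                       patches=[idx.copy() for idx in patches.indices])
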