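"""Ground-truth fluorescence scene generator.

Builds movies with known factors so every stage of the pipeline can be
scored against truth: localized non-negative footprints (isotropic Gaussian
for cytosolic indicators, annular for nuclear-localized ones), calcium
traces generated by AR(2) recursion — or by convolving spike trains with a
measured response kernel — driven by Poisson spikes, a rank-1 background
(smooth spatial field times a slow temporal drift), and a choice of noise
models: i.i.d. Gaussian, offset Poisson (variance grows with the mean, as
photon counts do), or stratified reshuffling of a fitted model's residuals
(which keeps each pixel's residual marginal and its variance-vs-signal
coupling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.signal import lfilter

from .io_model import FactorModel, VideoStack, flatten, unflatten

__all__ = [
    "SceneSpec",
    "GroundTruthBundle",
    "make_scene",
    "reshuffle_residual",
    "fit_response_kernel",
    "standard_scene",
]


@dataclass
class SceneSpec:
    """Generative description of a synthetic scene.

    Defaults describe a moderate field at 20 frames/s with GCaMP6-like AR(2)
    dynamics and sparse firing (~0.4 spikes/s at 20 Hz).
    """

    H: int = 64
    W: int = 64
    N: int = 10
    T: int = 500
    rate: float = 20.0
    footprint: str = "gaussian"  # or "annular"
    radius: float = 3.0
    min_separation: float = 8.0
    spike_rate: float = 0.02  # spikes per frame
    gamma: Tuple[float, float] = (1.7, -0.712)
    kernel: Optional[np.ndarray] = None  # overrides AR dynamics when given
    amplitude: float = 1.0
    baseline: float = 1.0
    noise: str = "gaussian"  # "gaussian", "poisson", or "none"
    noise_sigma: float = 0.1
    poisson_offset: float = 10.0
    min_spikes: int = 0
    pair_fraction: float = 0.0  # fraction of N placed as close overlapping pairs
    pair_distance: Optional[float] = None
    centers: Optional[np.ndarray] = None  # explicit (row, col) placement
    seed: int = 0

    def __post_init__(self):
        if self.spike_rate < 0 or self.noise_sigma < 0 or self.poisson_offset < 0:
            raise ValueError("rates, noise levels and offsets must be >= 0")
        if self.kernel is None and not _stable(self.gamma):
            raise ValueError(f"AR coefficients {self.gamma} are not stable")


def _stable(gamma) -> bool:
    poly = np.concatenate([[1.0], -np.atleast_1d(gamma)])
    return bool(np.all(np.abs(np.roots(poly)) < 1.0)) if len(poly) > 1 else True


@dataclass
class GroundTruthBundle:
    """A scene with its generating factors; ``noiseless`` is exactly
    ``A_true C_true + b_true f_true^T``."""

    A_true: np.ndarray
    C_true: np.ndarray
    S_true: np.ndarray
    b_true: np.ndarray
    f_true: np.ndarray
    noiseless: VideoStack
    noisy: VideoStack
    centers: np.ndarray
    spec: SceneSpec

    def truth_model(self) -> FactorModel:
        return FactorModel(A=self.A_true.copy(), C=self.C_true.copy(),
                           b=self.b_true.copy(), f=self.f_true.copy(),
                           H=self.noiseless.H, W=self.noiseless.W,
                           rate=self.spec.rate)


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample centers at the requested separation; a fraction of
    components are added as deliberately close pairs."""
    H, W, N = spec.H, spec.W, spec.N
    margin = max(2, int(np.ceil(spec.radius)))
    n_pairs = int(round(spec.pair_fraction * N / 2))
    n_single = N - 2 * n_pairs
    pair_d = spec.pair_distance if spec.pair_distance is not None else 1.5 * spec.radius
    centers: list = []
    tries = 0
    while len(centers) < n_single:
        cand = rng.uniform([margin, margin], [H - margin, W - margin])
        if all(np.hypot(*(cand - c)) >= spec.min_separation for c in centers):
            centers.append(cand)
        tries += 1
        if tries > 2000 * N:
            raise RuntimeError(
                f"could not place {N} footprints at separation "
                f"{spec.min_separation} on a {H}x{W} grid")
    for _ in range(n_pairs):
        tries = 0
        while True:
            cand = rng.uniform([margin, margin], [H - margin, W - margin])
            if all(np.hypot(*(cand - c)) >= spec.min_separation for c in centers):
                theta = rng.uniform(0, 2 * np.pi)
                mate = cand + pair_d * np.array([np.cos(theta), np.sin(theta)])
                if (margin <= mate[0] < H - margin and margin <= mate[1] < W - margin
                        and all(np.hypot(*(mate - c)) >= spec.min_separation
                                for c in centers)):
                    centers.extend([cand, mate])
                    break
            tries += 1
            if tries > 2000 * N:
                raise RuntimeError("could not place overlapping pairs")
    return np.asarray(centers)


def _footprint(spec: SceneSpec, center: np.ndarray) -> np.ndarray:
    rows = np.arange(spec.H)[:, None]
    cols = np.arange(spec.W)[None, :]
    r2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    sig = spec.radius / 2.0
    if spec.footprint == "gaussian":
        a = np.exp(-r2 / (2 * (spec.radius / 1.5) ** 2))
    elif spec.footprint == "annular":
        r = np.sqrt(r2)
        a = np.exp(-((r - spec.radius * 0.7) ** 2) / (2 * sig**2))
    else:
        raise ValueError(f"unknown footprint family {spec.footprint!r}")
    a[a < 1e-3] = 0.0  # compact support
    return a.ravel()


def _spike_train(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    for _ in range(1000):
        s = rng.poisson(spec.spike_rate, size=spec.T).astype(np.float64)
        if s.sum() >= spec.min_spikes:
            return s
    raise RuntimeError("could not draw a spike train with the required count")


def make_scene(spec: SceneSpec) -> GroundTruthBundle:
    """Generate a scene; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    H, W, N, T = spec.H, spec.W, spec.N, spec.T
    D = H * W
    if spec.centers is not None:
        centers = np.atleast_2d(np.asarray(spec.centers, dtype=np.float64))
        if len(centers) != N:
            raise ValueError("explicit centers must match N")
    else:
        centers = _place_centers(spec, rng)
    A = np.column_stack([_footprint(spec, c) for c in centers]) if N else np.zeros((D, 0))
    S = np.vstack([_spike_train(spec, rng) for _ in range(N)]) if N else np.zeros((0, T))
    if spec.kernel is not None:
        k = np.asarray(spec.kernel, dtype=np.float64)
        C = np.vstack([np.convolve(s, k)[:T] for s in S]) if N else S.copy()
    else:
        g1, g2 = spec.gamma
        b_ar = [1.0]
        a_ar = [1.0, -g1, -g2]
        C = lfilter(b_ar, a_ar, S, axis=1) if N else S.copy()
    C *= spec.amplitude
    S = S * spec.amplitude
    # rank-1 background: broad smooth spatial field, slow positive drift
    rows = np.arange(H)[:, None] / max(H - 1, 1)
    cols = np.arange(W)[None, :] / max(W - 1, 1)
    b = spec.baseline * (0.75 + 0.25 * np.cos(np.pi * (rows - 0.4))
                         * np.cos(np.pi * (cols - 0.6))).ravel()
    t = np.arange(T) / max(T - 1, 1)
    f = 1.0 + 0.1 * np.sin(2 * np.pi * 0.5 * t) + 0.05 * t
    clean = A @ C + np.outer(b, f)
    if spec.noise == "none" or (spec.noise == "gaussian" and spec.noise_sigma == 0):
        noisy = clean.copy()
    elif spec.noise == "gaussian":
        noisy = clean + rng.normal(0, spec.noise_sigma, size=clean.shape)
    elif spec.noise == "poisson":
        nu = spec.poisson_offset
        lam = np.maximum(nu + clean, 0.0)
        noisy = rng.poisson(lam).astype(np.float64) - nu
    else:
        raise ValueError(f"unknown noise model {spec.noise!r}")
    return GroundTruthBundle(
        A_true=A, C_true=C, S_true=S, b_true=b, f_true=f,
        noiseless=unflatten(clean, H, W, rate=spec.rate),
        noisy=unflatten(noisy, H, W, rate=spec.rate),
        centers=np.round(centers).astype(int),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# surrogate movies from fitted models
# ---------------------------------------------------------------------------


def reshuffle_residual(Y, model: FactorModel, n_strata: int = 200,
                       seed: int = 0) -> VideoStack:
    """Semi-synthetic surrogate: per pixel, permute the fitted residuals
    within strata of similar reconstructed signal and add them back.

    Frames are ranked by the reconstruction ``A C + b f^T`` at that pixel and
    split into ``n_strata`` equal-count strata (ties broken by frame index);
    residuals are permuted within each stratum, preserving the per-pixel
    residual multiset exactly and the variance-vs-signal link up to stratum
    granularity.
    """
    movie = isinstance(Y, VideoStack)
    mat = flatten(Y) if movie else np.asarray(Y, dtype=np.float64)
    D, T = mat.shape
    if n_strata > T:
        n_strata = max(1, T // 5)
        warnings.warn(f"fewer frames than strata; reduced to {n_strata} strata",
                      RuntimeWarning)
    rng = np.random.default_rng(seed)
    recon = model.reconstruction()
    resid = mat - recon
    out = recon.copy()
    bounds = np.linspace(0, T, n_strata + 1).astype(int)
    stratum_id = np.repeat(np.arange(n_strata), np.diff(bounds)).astype(np.float64)
    for d in range(D):
        order = np.argsort(recon[d], kind="stable")  # ties -> frame index
        # sorting integer stratum ids + U(0,1) jitter randomizes order within
        # each stratum while keeping strata blocks intact
        perm = order[np.argsort(stratum_id + rng.random(T), kind="stable")]
        out[d, order] += resid[d, perm]
    if movie:
        return unflatten(out, Y.H, Y.W, rate=Y.rate)
    return unflatten(out, model.H, model.W, rate=model.rate)


def fit_response_kernel(y: np.ndarray, s: np.ndarray, L: int) -> np.ndarray:
    """Least-squares calcium response kernel: ``argmin_k || y - s * k ||^2``
    (``*`` is convolution) for a fluorescence trace ``y`` and spike counts
    ``s``.  Rank-deficient designs fall back to the minimum-norm solution
    with a warning."""
    y = np.asarray(y, dtype=np.float64).ravel()
    s = np.asarray(s, dtype=np.float64).ravel()
    T = len(y)
    if len(s) != T:
        raise ValueError("spike train and trace must have equal length")
    if L > T:
        raise ValueError(f"kernel length {L} exceeds trace length {T}")
    if not np.any(s):
        raise ValueError("spike train has no spikes")
    # design matrix: column j holds s shifted down by j
    X = np.zeros((T, L))
    for j in range(L):
        X[j:, j] = s[: T - j]
    rank = np.linalg.matrix_rank(X)
    if rank < L:
        warnings.warn("convolution design is rank-deficient; returning the "
                      "minimum-norm kernel", RuntimeWarning)
    k, *_ = np.linalg.lstsq(X, y, rcond=None)
    return k


# ---------------------------------------------------------------------------
# the standard benchmark scene
# ---------------------------------------------------------------------------

_STANDARD_SEED = 20170803


def standard_scene(seed: int = _STANDARD_SEED) -> GroundTruthBundle:
    """The fixed benchmark scene used across the package's own evaluations:
    128x128 grid, N=40 (including 4 deliberately overlapping pairs), T=1000
    frames at 20 frames/s, AR(2) dynamics, rank-1 background, Gaussian noise
    with sigma = 0.5 x the median peak pixel amplitude, and every neuron
    firing at least 3 spikes.  Soma radius (3 px) and packing (8 px minimum
    separation) emulate a densely packed cortical field at this grid scale."""
    spec = SceneSpec(
        H=128, W=128, N=40, T=1000, rate=20.0,
        footprint="gaussian", radius=3.0, min_separation=8.0,
        spike_rate=0.02, gamma=(1.7, -0.712), amplitude=1.0, baseline=1.0,
        noise="gaussian", noise_sigma=0.0,  # filled in below from peaks
        min_spikes=3, pair_fraction=0.2, pair_distance=4.0, seed=seed,
    )
    clean = make_scene(spec)
    peaks = np.max(clean.A_true, axis=0) * np.max(clean.C_true, axis=1)
    sigma = 0.5 * float(np.median(peaks))
    spec_noisy = SceneSpec(**{**spec.__dict__, "noise_sigma": sigma})
    return make_scene(spec_noisy)
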