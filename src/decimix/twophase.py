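"""Two-phase imaging: demix coarse movies with shapes learned at fine scale.

The protocol: (phase 1) image at standard resolution and fit footprints
``A_1`` with the multi-scale CNMF; (phase 2) acquire spatially decimated
movies ``Y_l`` and recover traces ``C_l`` by demixing with the *decimated*
shapes ``A_l`` held fixed.  Because spatial decimation is linear,
``decimate(A C) = decimate(A) C``, the coarse data remain a linear mixture
of the same traces — identifiability degrades only when decimated
footprints become collinear.  The one-phase baseline (footprints estimated
directly from coarse data, with sparse spatial updates and purging of
collapsed shapes) is the failure-prone alternative; interleaving two
half-shifted coarse grids on alternating frames restores separability of
neurons merged into a single coarse pixel.

Also here: the trivial compression decoder (reconstruct full-resolution
movies from coarse traces), component ranking, dF/F, and the recovery
metrics (per-neuron Pearson correlation, median/IQR, normalized MSE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .decimation import decimation_matrix, decimated_grid_shape
from .deconvolution import (ARModel, TraceNoise, deconvolve_interleaved,
                            update_spatial_constrained,
                            update_temporal_constrained)
from .hals import hals_activity
from .initialization import NoiseMap, estimate_pixel_noise
from .io_model import FactorModel, VideoStack, flatten, unflatten

__all__ = [
    "RecoveryReport",
    "DemixResult",
    "InterleavedMovie",
    "interleave_movie",
    "decimate_model",
    "demix_lowres",
    "run_one_phase",
    "demix_interleaved",
    "reconstruct",
    "rank_components",
    "compute_dff",
    "pearson",
    "evaluate_recovery",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class DemixResult:
    """Traces demixed from a coarse movie with shapes held fixed."""

    C: np.ndarray
    S: Optional[np.ndarray]
    f: np.ndarray
    zero_components: List[int] = field(default_factory=list)


@dataclass
class RecoveryReport:
    """Per-factor recovery metrics against a reference set of traces.

    ``correlations[factor]`` holds the per-neuron Pearson correlation of
    the denoised traces (purged components carry 0); deconvolved variants
    live in ``correlations_deconv``.  ``nmse[factor]`` is RSS(factor) /
    RSS(reference), so the reference configuration scores exactly 1.
    """

    factors: List
    correlations: Dict = field(default_factory=dict)
    correlations_deconv: Dict = field(default_factory=dict)
    median: Dict = field(default_factory=dict)
    iqr: Dict = field(default_factory=dict)
    median_deconv: Dict = field(default_factory=dict)
    nmse: Dict = field(default_factory=dict)
    purged: Dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# model decimation
# ---------------------------------------------------------------------------


def decimate_model(model: FactorModel, ly: int, lx: int,
                   offset: Tuple[int, int] = (0, 0)) -> FactorModel:
    """Decimate a model's shapes and background onto the coarse grid
    (``A_l = M A``, ``b_l = M b``); traces are untouched.  Patches map to
    the set of coarse pixels their fine pixels fall into."""
    if model.H is None or model.W is None:
        raise ValueError("model carries no grid metadata (H, W)")
    H, W = model.H, model.W
    M = decimation_matrix(H, W, ly, lx, offset)
    Hd, Wd = decimated_grid_shape(H, W, ly, lx, offset)
    oy, ox = offset
    patches = None
    if model.patches is not None:
        block_r = (np.arange(H) + oy) // ly
        block_c = (np.arange(W) + ox) // lx
        dest = (block_r[:, None] * Wd + block_c[None, :]).ravel()
        patches = [np.unique(dest[np.asarray(p, dtype=int)]) for p in model.patches]
    return FactorModel(
        A=M @ model.A, C=model.C.copy(), b=M @ model.b, f=model.f.copy(),
        H=Hd, W=Wd, rate=model.rate, patches=patches,
        gamma=None if model.gamma is None else np.array(model.gamma),
        meta=dict(model.meta),
    )


# ---------------------------------------------------------------------------
# two-phase demixing
# ---------------------------------------------------------------------------


def demix_lowres(
    Y_l,
    model_l: FactorModel,
    ar: Optional[ARModel] = None,
    sigma: Optional[np.ndarray] = None,
    max_sweeps: int = 200,
    tol: float = 1e-8,
    deconvolve: bool = True,
    warm_start: bool = False,
) -> DemixResult:
    """Demix a coarse movie with the decimated shapes held fixed.

    Phase A runs plain non-negative trace updates (HALS activity sweeps,
    shapes frozen, ``f`` free) to convergence; phase B applies the
    noise-constrained temporal update (per-neuron sparse deconvolution)
    unless ``deconvolve=False`` or no AR model is given.

    Traces start from zero (``f`` from ones) — phase-2 data carries no
    trace information of its own, and the phase-A problem is jointly convex
    in (C, f), so a warm start only matters for degenerate (collinear-shape)
    components, where using phase-1 traces would be cheating.  Pass
    ``warm_start=True`` to keep the model's current traces.

    ``Y_l`` is a :class:`VideoStack` or ``D_l x T`` matrix matching
    ``model_l``; ``model_l`` is modified in place (C, f, S).
    """
    Y = flatten(Y_l) if isinstance(Y_l, VideoStack) else np.asarray(Y_l, float)
    if not warm_start:
        model_l.C = np.zeros((model_l.N, Y.shape[1]))
        model_l.f = np.ones(Y.shape[1])
    elif model_l.T != Y.shape[1]:
        raise ValueError("warm start requires traces matching the data length")
    zero = [n for n in range(model_l.N) if np.linalg.norm(model_l.A[:, n]) == 0]
    if zero:
        warnings.warn(f"components {zero} have all-zero decimated shapes; "
                      "their traces are returned as zero", RuntimeWarning)
    prev = np.inf
    for _ in range(max_sweeps):
        C, f = hals_activity(Y, model_l, inner=1)
        model_l.C, model_l.f = C, f
        rss = float(np.sum((Y - model_l.reconstruction()) ** 2))
        if np.isfinite(prev) and prev - rss <= tol * max(prev, 1e-300):
            break
        prev = rss
    S = None
    if deconvolve and ar is not None:
        C, S, f = update_temporal_constrained(Y, model_l, ar, sigma=sigma)
    model_l.C[zero, :] = 0.0
    if S is not None:
        S[zero, :] = 0.0
    return DemixResult(C=model_l.C, S=S, f=model_l.f, zero_components=zero)


def run_one_phase(
    Y_l,
    model_init: FactorModel,
    ar: Optional[ARModel] = None,
    noise: Optional[NoiseMap] = None,
    purge_threshold: float = 1e-3,
) -> Tuple[FactorModel, List[int]]:
    """One-phase baseline: estimate footprints directly from coarse data.

    Starting from shapes/background decimated from a fine-scale fit and the
    fine-scale traces, runs the sparse spatial update on ``Y_l`` (shapes
    free), purges components whose shape l2-norm collapses below
    ``purge_threshold`` x its initial value, then runs the constrained
    temporal update with the survivors.  Returns the surviving model and the
    purged component indices (original numbering).
    """
    Y = flatten(Y_l) if isinstance(Y_l, VideoStack) else np.asarray(Y_l, float)
    model = model_init.copy()
    if noise is None:
        noise = estimate_pixel_noise(Y)
    init_norms = np.linalg.norm(model.A, axis=0)
    update_spatial_constrained(Y, model, noise)
    new_norms = np.linalg.norm(model.A, axis=0)
    purged = [n for n in range(model.N)
              if new_norms[n] < purge_threshold * max(init_norms[n], 1e-300)]
    survivors = np.setdiff1d(np.arange(model.N), purged)
    model.A = model.A[:, survivors]
    model.C = model.C[survivors, :]
    if model.patches is not None:
        model.patches = [model.patches[n] for n in survivors]
    if model.gamma is not None and np.ndim(model.gamma) == 2:
        model.gamma = model.gamma[survivors]
    model.meta["survivors"] = survivors.tolist()
    if purged:
        warnings.warn(f"purged components {purged} (shape collapsed)", RuntimeWarning)
    if model.N == 0:
        warnings.warn("all components purged; returning a background-only model",
                      RuntimeWarning)
        return model, purged
    if ar is not None:
        ar_surv = ARModel(ar.gamma if ar.gamma.ndim == 1 else ar.gamma[survivors])
        # refit traces with the new shapes before imposing dynamics
        demix_lowres(Y, model, ar_surv)
    else:
        demix_lowres(Y, model, None, deconvolve=False)
    return model, purged


# ---------------------------------------------------------------------------
# interleaved demixing
# ---------------------------------------------------------------------------


@dataclass
class InterleavedMovie:
    """Coarse movie acquired on alternating grids: frames 0, 2, ... on the
    unshifted grid (``Y0``), frames 1, 3, ... on the half-block-shifted grid
    (``Y1``).  Matrices are pixels x frames on their own coarse grids."""

    Y0: np.ndarray
    Y1: np.ndarray
    H: int
    W: int
    ly: int
    lx: int
    rate: float = 1.0

    @property
    def T(self) -> int:
        return self.Y0.shape[1] + self.Y1.shape[1]

    @property
    def offset1(self) -> Tuple[int, int]:
        return (self.ly // 2, self.lx // 2)


def interleave_movie(Y: VideoStack, ly: int, lx: int) -> InterleavedMovie:
    """Emulate interleaved acquisition from a fine-scale movie: decimate the
    even frames on the unshifted grid and the odd frames on the half-shifted
    grid."""
    mat = flatten(Y)
    M0 = decimation_matrix(Y.H, Y.W, ly, lx, (0, 0))
    M1 = decimation_matrix(Y.H, Y.W, ly, lx, (ly // 2, lx // 2))
    return InterleavedMovie(Y0=M0 @ mat[:, 0::2], Y1=M1 @ mat[:, 1::2],
                            H=Y.H, W=Y.W, ly=ly, lx=lx, rate=Y.rate)


def demix_interleaved(
    Y_pair: InterleavedMovie,
    model: FactorModel,
    ar: Optional[ARModel] = None,
    max_sweeps: int = 200,
    tol: float = 1e-8,
) -> DemixResult:
    """Demix an interleaved coarse movie with fine-scale shapes held fixed.

    Shapes are decimated separately per parity; phase A alternates
    non-negative trace updates against both parity grids; phase B runs the
    parity-weighted noise-constrained deconvolution per neuron.
    """
    if model.H is None:
        raise ValueError("model carries no grid metadata")
    ly, lx = Y_pair.ly, Y_pair.lx
    m0 = decimate_model(model, ly, lx, (0, 0))
    m1 = decimate_model(model, ly, lx, Y_pair.offset1)
    N = model.N
    T0, T1 = Y_pair.Y0.shape[1], Y_pair.Y1.shape[1]
    T = T0 + T1
    At0 = np.column_stack([m0.A, m0.b])
    At1 = np.column_stack([m1.A, m1.b])
    zero = [n for n in range(N)
            if np.linalg.norm(At0[:, n]) == 0 and np.linalg.norm(At1[:, n]) == 0]
    if zero:
        warnings.warn(f"components {zero} vanish on both parity grids",
                      RuntimeWarning)
    U0, V0 = At0.T @ Y_pair.Y0, At0.T @ At0
    U1, V1 = At1.T @ Y_pair.Y1, At1.T @ At1
    Ct0 = np.zeros((N + 1, T0))
    Ct1 = np.zeros((N + 1, T1))
    Ct0[N], Ct1[N] = 1.0, 1.0
    prev = np.inf
    for _ in range(max_sweeps):
        for n in range(N + 1):
            for U, V, Ct in ((U0, V0, Ct0), (U1, V1, Ct1)):
                if V[n, n] <= 0:
                    continue
                new = Ct[n] + (U[n] - V[n] @ Ct) / V[n, n]
                if n < N:
                    np.maximum(new, 0, out=new)
                Ct[n] = new
        rss = (float(np.sum((Y_pair.Y0 - At0 @ Ct0) ** 2))
               + float(np.sum((Y_pair.Y1 - At1 @ Ct1) ** 2)))
        if np.isfinite(prev) and prev - rss <= tol * max(prev, 1e-300):
            break
        prev = rss
    C = np.zeros((N, T))
    f = np.zeros(T)
    C[:, 0::2], C[:, 1::2] = Ct0[:N], Ct1[:N]
    f[0::2], f[1::2] = Ct0[N], Ct1[N]
    S = None
    if ar is not None:
        S = np.zeros((N, T))
        n0 = np.einsum("dn,dn->n", At0[:, :N], At0[:, :N])
        n1 = np.einsum("dn,dn->n", At1[:, :N], At1[:, :N])
        for n in range(N):
            if n in zero:
                continue
            # parity-specific projections of the residual without neuron n
            r0 = Y_pair.Y0 - At0 @ Ct0 + np.outer(At0[:, n], Ct0[n])
            r1 = Y_pair.Y1 - At1 @ Ct1 + np.outer(At1[:, n], Ct1[n])
            y0 = At0[:, n] @ r0 / n0[n] if n0[n] > 0 else np.zeros(T0)
            y1 = At1[:, n] @ r1 / n1[n] if n1[n] > 0 else np.zeros(T1)
            s0 = float(estimate_pixel_noise(y0).sigma[0]) if n0[n] > 0 else 0.0
            s1 = float(estimate_pixel_noise(y1).sigma[0]) if n1[n] > 0 else 0.0
            noise = TraceNoise(sigma_odd=s0, sigma_even=s1)
            dec = deconvolve_interleaved(y0, y1, noise, ARModel(ar.coeffs(n)))
            C[n] = dec.c
            S[n] = dec.s
            Ct0[n], Ct1[n] = dec.c[0::2], dec.c[1::2]
    return DemixResult(C=C, S=S, f=f, zero_components=zero)


# ---------------------------------------------------------------------------
# reconstruction, ranking, dF/F
# ---------------------------------------------------------------------------


def reconstruct(model: FactorModel, C_source: Optional[np.ndarray] = None,
                f_source: Optional[np.ndarray] = None) -> VideoStack:
    """Decode a movie from shapes and (possibly coarse-derived) traces:
    ``A C + b f^T`` on the model's grid.  This is the decompression step of
    the decimation-then-demix compression scheme (ratio ``l^2``)."""
    if model.H is None or model.W is None:
        raise ValueError("model carries no grid metadata")
    C = model.C if C_source is None else np.asarray(C_source, float)
    f = model.f if f_source is None else np.asarray(f_source, float)
    if C.shape[0] != model.N or len(f) != C.shape[1]:
        raise ValueError("trace dimensions do not match the model")
    mat = model.A @ C + np.outer(model.b, f)
    return unflatten(mat, model.H, model.W, rate=model.rate)


def rank_components(model: FactorModel) -> Tuple[np.ndarray, np.ndarray]:
    """Rank components by peak fluorescence x shape compactness.

    Shapes are first normalized to unit l2-norm (scale moved into the
    traces); the score is ``max_t C(n, t) * ||A(:, n)||_4``, which penalizes
    overly broad or noisy footprints.  Returns (descending order, scores);
    ties break by component index (stable sort).
    """
    m = model.copy().normalize()
    l4 = np.power(np.sum(m.A**4, axis=0), 0.25)
    peak = m.C.max(axis=1) if m.C.size else np.zeros(m.N)
    scores = peak * l4
    order = np.argsort(-scores, kind="stable")
    return order, scores


def compute_dff(model: FactorModel, n: int) -> Tuple[np.ndarray, np.ndarray]:
    """dF/F for component ``n``: fluorescence relative to the baseline from
    projecting the rank-1 background onto the footprint,

        (dF/F)_t = (A_n^T A_n) C(n, t) / (A_n^T b f(t)).

    Invariant to the (A, C) scale split.  Returns ``(dff, flagged)`` where
    flagged frames had a zero or negative baseline (dF/F set to NaN there).
    """
    a = model.A[:, n]
    num = float(a @ a) * model.C[n]
    ab = float(a @ model.b)
    den = ab * model.f
    flagged = den <= 0
    if flagged.all():
        warnings.warn(f"component {n}: baseline projection is never positive "
                      "(shape orthogonal to background?)", RuntimeWarning)
    dff = np.full_like(num, np.nan)
    np.divide(num, den, out=dff, where=~flagged)
    return dff, flagged


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with the convention that a constant trace (zero
    variance) scores 0 — needed for purged and degenerate components."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise ValueError("traces differ in length")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        return 0.0
    return float(np.clip(xc @ yc / denom, -1.0, 1.0))


def evaluate_recovery(
    reference_C: np.ndarray,
    candidates: Dict,
    reference_S: Optional[np.ndarray] = None,
    reference_rss: Optional[float] = None,
) -> RecoveryReport:
    """Score candidate trace sets against reference traces.

    ``candidates`` maps a label (e.g. the decimation factor) to a dict with
    keys ``C`` (required), ``S``, ``purged`` (indices, correlation forced to
    0), and ``rss``.  Component identities must already match the reference
    (they are inherited from the phase-1 model by construction).
    """
    reference_C = np.atleast_2d(np.asarray(reference_C, float))
    N = reference_C.shape[0]
    report = RecoveryReport(factors=list(candidates.keys()))
    for label, cand in candidates.items():
        C = np.atleast_2d(np.asarray(cand["C"], float))
        purged = list(cand.get("purged", []))
        if C.shape[1] != reference_C.shape[1]:
            raise ValueError(f"candidate {label!r}: trace length mismatch")
        survivors = cand.get("survivors")
        corr = np.zeros(N)
        row = 0
        for n in range(N):
            if n in purged:
                corr[n] = 0.0
                continue
            src = row if survivors is not None else n
            corr[n] = pearson(reference_C[n], C[src])
            row += 1
        report.correlations[label] = corr
        report.median[label] = float(np.median(corr))
        q1, q3 = np.percentile(corr, [25, 75])
        report.iqr[label] = (float(q1), float(q3))
        report.purged[label] = purged
        if "S" in cand and cand["S"] is not None and reference_S is not None:
            S = np.atleast_2d(np.asarray(cand["S"], float))
            corr_s = np.zeros(N)
            row = 0
            for n in range(N):
                if n in purged:
                    continue
                src = row if survivors is not None else n
                corr_s[n] = pearson(reference_S[n], S[src])
                row += 1
            report.correlations_deconv[label] = corr_s
            report.median_deconv[label] = float(np.median(corr_s))
        if "rss" in cand and cand["rss"] is not None and reference_rss:
            report.nmse[label] = float(cand["rss"]) / float(reference_rss)
    return report
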