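"""Patch-constrained fast HALS and the multi-scale fitting schedule.

The biconvex objective is

    minimize_{A, b, C, f}  || Y - A C - b f^T ||_F^2
    subject to             A, b, C >= 0,   A(d, n) = 0 for d outside P_n

solved by block-coordinate descent in the "fast HALS" ordering: update all
traces with shapes fixed, then all shapes with traces fixed.  Each row/column
update is the exact minimizer of the objective in that coordinate block, so
the residual sum of squares never increases.  The updates only touch the
small cross-products ``A^T Y`` / ``C Y^T`` and Gram matrices — the full
``D x T`` residual is never formed.

The multi-scale schedule runs most sweeps on temporally (factor ``k``) and
spatially (``ly x lx``) decimated data, where sweeps are cheap and the
coarse objective tends to sit near better local optima, then upsamples the
warm start (zero-order hold in both space and time) and polishes with a few
full-resolution sweeps using more inner iterations.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .decimation import decimate_spatial, decimate_temporal, upsample_zoh
from .initialization import (CenterList, InitConfig, PatchSet, build_patches,
                             greedy_initialize, initialize_factors)
from .io_model import FactorModel, VideoStack, flatten, unflatten

__all__ = [
    "FitSchedule",
    "ObjectiveTrace",
    "hals_activity",
    "hals_shape",
    "fit_multiscale",
    "fit_svd_compressed",
]


@dataclass
class FitSchedule:
    """Multi-scale fitting schedule.

    ``temporal_factor`` frames are averaged per decimated frame and spatial
    blocks are ``spatial_factors``; ``decimated_sweeps`` cheap alternating
    sweeps (one inner iteration each) run on the decimated data, then
    ``full_sweeps`` sweeps with ``inner_iterations`` run at full resolution,
    stopping early once the relative RSS improvement drops below ``tol``.
    """

    temporal_factor: int = 30
    spatial_factors: Tuple[int, int] = (3, 3)
    decimated_sweeps: int = 30
    full_sweeps: int = 5
    inner_iterations: int = 5
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if min(self.temporal_factor, self.decimated_sweeps, self.full_sweeps,
               self.inner_iterations, *self.spatial_factors) < 1:
            raise ValueError("all schedule counts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class ObjectiveTrace:
    """Per-sweep residual sum of squares for each phase (decimated-phase
    entries are measured on the decimated objective), plus wall-clock."""

    decimated_rss: List[float] = field(default_factory=list)
    full_rss: List[float] = field(default_factory=list)
    decimated_seconds: List[float] = field(default_factory=list)
    full_seconds: List[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# core updates (stacked form: Atil = [A b], Ctil = [C; f])
# ---------------------------------------------------------------------------


def _activity_sweeps(Y, Atil, Ctil, inner, clamp_last=False):
    """In-place fast-HALS trace updates; the last row is the background ``f``
    and is not clamped unless ``clamp_last``.  Returns skipped row indices."""
    U = Atil.T @ Y
    V = Atil.T @ Atil
    return _row_updates(U, V, Ctil, inner, n_clamped=Ctil.shape[0] - (0 if clamp_last else 1)), U, V


def _shape_sweeps(Y, Atil, Ctil, mask, inner):
    """In-place fast-HALS shape updates (columns of ``Atil``), masked to the
    patches; every column (background included) is clamped at 0."""
    U = Ctil @ Y.T
    V = Ctil @ Ctil.T
    At = Atil.T  # rows of At are components; views share memory with Atil
    skipped = _row_updates(U, V, At, inner, n_clamped=At.shape[0], mask=mask)
    return skipped, U, V


def _row_updates(U, V, X, inner, n_clamped, mask=None):
    """Gauss-Seidel row updates X[n] <- [X[n] + (U[n] - V[n] @ X) / V[n,n]]
    with optional non-negativity clamp (first ``n_clamped`` rows) and support
    mask.  Rows with V[n,n] == 0 are skipped and reported."""
    R = X.shape[0]
    skipped = []
    for _ in range(inner):
        for n in range(R):
            vnn = V[n, n]
            if vnn <= 0:
                if n not in skipped:
                    skipped.append(n)
                continue
            new = X[n] + (U[n] - V[n] @ X) / vnn
            if n < n_clamped:
                np.maximum(new, 0, out=new)
            if mask is not None:
                new *= mask[n]
            X[n] = new
    if skipped:
        warnings.warn(f"skipped zero-norm components {skipped} in HALS update",
                      RuntimeWarning, stacklevel=3)
    return skipped


def _stack(model: FactorModel):
    Atil = np.column_stack([model.A, model.b])
    Ctil = np.vstack([model.C, model.f[None, :]])
    return Atil, Ctil


def _mask_from_patches(patches: Optional[PatchSet], D: int, N: int) -> Optional[np.ndarray]:
    if patches is None:
        return None
    mask = np.zeros((N + 1, D))
    for n, idx in enumerate(patches.indices):
        mask[n, idx] = 1.0
    mask[N, :] = 1.0  # background patch: all pixels
    return mask


def hals_activity(Y: np.ndarray, model: FactorModel, inner: int = 1
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """One call of HALSactivity: update all traces (clamped at 0) and the
    background ``f`` (unclamped) with shapes fixed.  Returns new ``(C, f)``.

    ``Y`` is the ``D x T`` data matrix matching ``model``.
    """
    Atil, Ctil = _stack(model)
    _activity_sweeps(np.asarray(Y, dtype=np.float64), Atil, Ctil, inner)
    return Ctil[:-1].copy(), Ctil[-1].copy()


def hals_shape(Y: np.ndarray, model: FactorModel, patches: Optional[PatchSet] = None,
               inner: int = 1) -> Tuple[np.ndarray, np.ndarray]:
    """One call of HALSshape: update all footprints (masked to their patches
    and clamped at 0) and the background ``b`` (clamped) with traces fixed.
    Returns new ``(A, b)``."""
    Atil, Ctil = _stack(model)
    if patches is None and model.patches is not None and model.H is not None:
        patches = PatchSet([np.asarray(p) for p in model.patches], model.H, model.W)
    mask = _mask_from_patches(patches, Atil.shape[0], model.N)
    _shape_sweeps(np.asarray(Y, dtype=np.float64), Atil, Ctil, mask, inner)
    return Atil[:, :-1].copy(), Atil[:, -1].copy()


def _rss_from_products(Y_norm2, U, V, Ctil):
    """|| Y - Atil Ctil ||^2 via the activity-side cross products."""
    return float(Y_norm2 - 2 * np.sum(U * Ctil) + np.sum(V * (Ctil @ Ctil.T)))


def fit_svd_compressed(
    Y: np.ndarray,
    model: FactorModel,
    M: int,
    sweeps: int = 30,
    patches: Optional[PatchSet] = None,
    inner: int = 1,
) -> Tuple[FactorModel, list]:
    """Alternating HALS on truncated-SVD-compressed data.

    The movie is projected onto the top-``M`` right singular directions,
    ``Y_c = Y V^T``, and the alternating updates run against ``Y_c`` with
    compressed traces ``C_c = C V^T``.  Compressed traces and background may
    be negative, so no non-negativity is enforced on them (shapes keep their
    clamp and patch masks).  Returns the model with traces mapped back
    (``C = C_c V``) and the per-sweep full-data RSS.
    """
    from .decimation import compress_svd

    Y = np.asarray(Y, dtype=np.float64)
    basis, Yc = compress_svd(Y, M)
    V = basis.right_basis
    Atil = np.column_stack([model.A, model.b])
    Ctil_c = np.vstack([model.C, model.f[None, :]]) @ V.T
    if patches is None and model.patches is not None and model.H is not None:
        patches = PatchSet([np.asarray(p) for p in model.patches], model.H, model.W)
    mask = _mask_from_patches(patches, Atil.shape[0], model.N)
    Y_norm2 = float(np.sum(Y**2))
    rss_trace = []
    for _ in range(sweeps):
        _row_updates(Atil.T @ Yc, Atil.T @ Atil, Ctil_c, inner, n_clamped=0)
        U = Ctil_c @ Yc.T
        Vg = Ctil_c @ Ctil_c.T
        _row_updates(U, Vg, Atil.T, inner, n_clamped=Atil.shape[1], mask=mask)
        # full-data RSS: ||Y||^2 - ||Yc||-terms, exact because rows of V are
        # orthonormal and C = C_c V lives inside their span
        rss = (Y_norm2 - float(np.sum(Yc**2))
               + float(np.sum((Yc - Atil @ Ctil_c) ** 2)))
        rss_trace.append(rss)
    out = FactorModel(A=Atil[:, :-1].copy(), C=(Ctil_c @ V)[:-1],
                      b=Atil[:, -1].copy(), f=(Ctil_c @ V)[-1],
                      H=model.H, W=model.W, rate=model.rate,
                      patches=model.patches)
    return out, rss_trace


# ---------------------------------------------------------------------------
# the multi-scale schedule
# ---------------------------------------------------------------------------


def fit_multiscale(
    Y: VideoStack,
    schedule: FitSchedule = None,
    init: InitConfig = None,
    centers: Optional[CenterList] = None,
) -> Tuple[FactorModel, ObjectiveTrace]:
    """Fit the patch-constrained factorization with the multi-scale schedule.

    Runs: temporal decimation -> greedy centers (on the decimated movie) ->
    spatial decimation -> patches -> factor initialization -> cheap
    alternating sweeps on the decimated data -> zero-order-hold upsampling
    of shapes and traces -> full-resolution patches -> a few full-data sweeps
    with more inner iterations.  Returns the model (before deconvolution)
    and the per-sweep objective trace.

    ``centers`` may be supplied to skip greedy detection (e.g. when truth is
    known or detection ran elsewhere).
    """
    schedule = schedule or FitSchedule()
    init = init or InitConfig()
    k = schedule.temporal_factor
    ly, lx = schedule.spatial_factors
    H, W, T = Y.H, Y.W, Y.T
    trace = ObjectiveTrace()

    # --- decimated phase -------------------------------------------------
    Yt_mat = decimate_temporal(flatten(Y), k)  # D x Td
    Td = Yt_mat.shape[1]
    Yt = unflatten(Yt_mat, H, W, rate=Y.rate / k)
    if centers is None:
        centers = greedy_initialize(Yt, init.n_components, init.expected_radius,
                                    seed=schedule.seed)
    Yd_mat, (Hd, Wd) = decimate_spatial(Yt_mat, ly, lx, grid=(H, W))
    Yd = unflatten(Yd_mat, Hd, Wd, rate=Y.rate / k)
    ctr_dec = np.column_stack([centers.centers[:, 0] // ly, centers.centers[:, 1] // lx])
    l_max = max(ly, lx)
    radius_dec = max(1.0, init.expected_radius / l_max)
    half_dec = max(1, -(-init.patch_half_width // l_max))
    centers_dec = CenterList(ctr_dec, expected_radius=radius_dec)
    patches_dec = build_patches(centers_dec, half_dec, Hd, Wd)
    model_dec = initialize_factors(Yd, centers_dec, patches_dec,
                                   percentile=init.background_percentile)
    Atil = np.column_stack([model_dec.A, model_dec.b])
    Ctil = np.vstack([model_dec.C, model_dec.f[None, :]])
    mask_dec = _mask_from_patches(patches_dec, Hd * Wd, len(centers))
    Yd_norm2 = float(np.sum(Yd_mat**2))
    for _ in range(schedule.decimated_sweeps):
        t0 = time.perf_counter()
        _activity_sweeps(Yd_mat, Atil, Ctil, inner=1)
        _, U, V = _shape_sweeps(Yd_mat, Atil, Ctil, mask_dec, inner=1)
        # shape-side products give the same objective with roles swapped
        trace.decimated_rss.append(_rss_from_products(Yd_norm2, U, V, Atil.T))
        trace.decimated_seconds.append(time.perf_counter() - t0)

    # --- upsample the warm start -----------------------------------------
    A_full = upsample_zoh(Atil[:, :-1], ly, lx, H, W)
    b_full = upsample_zoh(Atil[:, -1], ly, lx, H, W)
    C_full = np.repeat(Ctil[:-1], k, axis=1)[:, :T]
    f_full = np.repeat(Ctil[-1], k)[:T]
    if C_full.shape[1] < T:  # T not divisible by k: hold the last value
        pad = T - C_full.shape[1]
        C_full = np.column_stack([C_full, np.tile(C_full[:, -1:], (1, pad))])
        f_full = np.concatenate([f_full, np.full(pad, f_full[-1])])
    patches_full = build_patches(centers, init.patch_half_width, H, W)
    # ZOH shapes bleed outside the full-resolution patches; clip immediately
    mask_full = _mask_from_patches(patches_full, H * W, len(centers))
    Atil = np.column_stack([A_full, b_full])
    Atil[:, :-1] *= mask_full[:-1].T
    Ctil = np.vstack([C_full, f_full[None, :]])

    # --- full-resolution polish ------------------------------------------
    Y_mat = flatten(Y)
    Y_norm2 = float(np.sum(Y_mat**2))
    prev = np.inf
    for _ in range(schedule.full_sweeps):
        t0 = time.perf_counter()
        _activity_sweeps(Y_mat, Atil, Ctil, inner=schedule.inner_iterations)
        _, U, V = _shape_sweeps(Y_mat, Atil, Ctil, mask_full,
                                inner=schedule.inner_iterations)
        rss = _rss_from_products(Y_norm2, U, V, Atil.T)
        trace.full_rss.append(rss)
        trace.full_seconds.append(time.perf_counter() - t0)
        if prev < np.inf and prev - rss < schedule.tol * max(prev, 1e-300):
            break
        prev = rss

    model = FactorModel(
        A=Atil[:, :-1].copy(), C=Ctil[:-1].copy(), b=Atil[:, -1].copy(),
        f=Ctil[-1].copy(), H=H, W=W, rate=Y.rate,
        patches=[idx.copy() for idx in patches_full.indices],
        meta={"centers": centers.centers.tolist()},
    )
    return model, trace
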