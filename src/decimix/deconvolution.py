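"""AR(2) dynamics estimation and noise-constrained sparse deconvolution.

Calcium traces are modeled as an autoregressive process driven by
non-negative spikes,

    c(t) = gamma_1 c(t-1) + gamma_2 c(t-2) + s(t),      s(t) >= 0,

written in matrix form as ``s = G c`` with ``G`` banded (unit diagonal,
``-gamma_1`` and ``-gamma_2`` on the first two subdiagonals).  Deconvolution
of a noisy trace ``y`` solves the parameter-free convex program

    minimize ||G c||_1   subject to   G c >= 0,  ||y - c||^2 <= sigma^2 T,

i.e. the sparsest spike train whose calcium trace fits the data down to the
noise floor.  In the spike domain (``c = H s`` with ``H = G^{-1}`` the
impulse-response filter) the penalized subproblem is a non-negative lasso,
solved here by a warm-startable active-set method whose restricted systems
use the impulse-response Gram; an outer bisection on the sparsity
multiplier enforces the hard noise constraint.  For interleaved acquisition
the residual is weighted per frame parity (Eq. with ``sigma_odd`` /
``sigma_even``) and the same machinery applies.

The matrix updates around a fitted model impose the analogous constraints
jointly: per-neuron temporal updates deconvolve the projected residual
trace; per-pixel spatial updates minimize ``||A||_1`` under the pixel's
noise constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.signal import lfilter

from .initialization import NoiseMap, PatchSet, estimate_pixel_noise
from .io_model import FactorModel

__all__ = [
    "ARModel",
    "TraceNoise",
    "DeconvolvedTrace",
    "ar_matrix",
    "impulse_response",
    "estimate_ar",
    "deconvolve_trace",
    "deconvolve_interleaved",
    "update_temporal_constrained",
    "update_spatial_constrained",
]


# ---------------------------------------------------------------------------
# AR dynamics
# ---------------------------------------------------------------------------


def ar_matrix(gamma: Sequence[float], T: int) -> sp.csc_matrix:
    """The banded ``T x T`` matrix ``G`` with unit diagonal and ``-gamma_i``
    on the i-th subdiagonal, so spikes are ``s = G c``."""
    gamma = np.atleast_1d(np.asarray(gamma, dtype=np.float64))
    diags = [np.ones(T)]
    offsets = [0]
    for i, g in enumerate(gamma, start=1):
        if i < T:
            diags.append(np.full(T - i, -g))
            offsets.append(-i)
    return sp.diags(diags, offsets, format="csc")


def impulse_response(gamma: Sequence[float], T: int) -> np.ndarray:
    """First ``T`` samples of the AR filter's impulse response ``h`` (the
    calcium transient shape for a unit spike); ``h = G^{-1} e_0``."""
    gamma = np.atleast_1d(np.asarray(gamma, dtype=np.float64))
    x = np.zeros(T)
    x[0] = 1.0
    return lfilter([1.0], np.concatenate([[1.0], -gamma]), x)


def _is_stable(gamma: np.ndarray) -> bool:
    poly = np.concatenate([[1.0], -np.atleast_1d(gamma)])
    if len(poly) == 1:
        return True
    roots = np.roots(poly)
    return bool(np.all(np.abs(roots) < 1.0))


def _clip_stable(gamma: np.ndarray, radius: float = 0.999) -> np.ndarray:
    """Shrink the AR poles radially until they lie inside the unit circle."""
    gamma = np.atleast_1d(np.asarray(gamma, dtype=np.float64))
    if _is_stable(gamma):
        return gamma
    roots = np.roots(np.concatenate([[1.0], -gamma]))
    mags = np.abs(roots)
    roots = np.where(mags >= radius, roots * (radius / np.maximum(mags, 1e-300)), roots)
    poly = np.real(np.poly(roots))
    return -poly[1:]


@dataclass
class ARModel:
    """Per-neuron AR dynamics: ``gamma`` is ``(p,)`` for one neuron or
    ``(N, p)`` for a population."""

    gamma: np.ndarray

    def __post_init__(self):
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=np.float64))

    @property
    def order(self) -> int:
        return self.gamma.shape[-1]

    def coeffs(self, n: int = 0) -> np.ndarray:
        return self.gamma if self.gamma.ndim == 1 else self.gamma[n]

    def G(self, T: int, n: int = 0) -> sp.csc_matrix:
        return ar_matrix(self.coeffs(n), T)


@dataclass
class TraceNoise:
    """Per-trace noise levels; parity-split levels for interleaved frames."""

    sigma: Optional[np.ndarray] = None
    sigma_odd: Optional[float] = None
    sigma_even: Optional[float] = None

    def __post_init__(self):
        if self.sigma is not None:
            self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=np.float64))
            if np.any(self.sigma < 0):
                raise ValueError("noise levels must be >= 0")
        for s in (self.sigma_odd, self.sigma_even):
            if s is not None and s < 0:
                raise ValueError("noise levels must be >= 0")


@dataclass
class DeconvolvedTrace:
    """Denoised calcium ``c >= 0`` and relaxed spike magnitudes ``s = G c``."""

    c: np.ndarray
    s: np.ndarray
    lam: float = 0.0
    constraint_met: bool = True


def estimate_ar(y: np.ndarray, p: int = 2, sigma: Optional[float] = None,
                n_lags: int = 5, band: Tuple[float, float] = (0.5, 1.0),
                n_debias: int = 8) -> np.ndarray:
    """Estimate AR(p) coefficients from empirical autocovariances.

    Observation noise inflates the lag-0 autocovariance, so the Yule-Walker
    system over lags ``1 .. p + n_lags`` is solved with the noise variance
    subtracted wherever lag 0 enters.  The noise level comes from the
    high-frequency PSD (or ``sigma`` when given); because the AR signal
    itself leaks some power into that band, the leakage implied by the
    current coefficient estimate is subtracted and the system re-solved a
    few times (``n_debias`` rounds, cheap and convergent in practice).

    Near-flat or white traces return all-zero coefficients with a warning.
    The result is clipped to the stable region.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    T = len(y)
    max_lag = p + n_lags
    if T < max_lag + 10:
        raise ValueError(f"trace too short (T={T}) for lag-{max_lag} autocovariances")
    yc = y - y.mean()
    acov = np.array([yc[: T - tau] @ yc[tau:] / T for tau in range(max_lag + 1)])
    if acov[0] <= 0 or np.max(np.abs(acov[1:])) < 4.0 * acov[0] / np.sqrt(T):
        warnings.warn("trace is near-flat or white; returning zero AR coefficients",
                      RuntimeWarning, stacklevel=2)
        return np.zeros(p)
    sn2_meas = (float(sigma) ** 2 if sigma is not None
                else float(estimate_pixel_noise(y, band=band).sigma[0]) ** 2)
    sn2 = sn2_meas
    omega = np.linspace(band[0] * np.pi, band[1] * np.pi, 200)
    gamma = np.zeros(p)
    for _ in range(max(1, n_debias)):
        rows = np.array([[acov[abs(tau - i)] for i in range(1, p + 1)]
                         for tau in range(1, max_lag + 1)], dtype=np.float64)
        rows -= sn2 * np.eye(max_lag, p)
        gamma, *_ = np.linalg.lstsq(rows, acov[1:], rcond=None)
        innov_var = (acov[0] - sn2) - gamma @ acov[1:p + 1]
        if innov_var <= 0 or sigma is not None:
            break
        resp = 1.0 - sum(gamma[i] * np.exp(-1j * omega * (i + 1)) for i in range(p))
        leak = innov_var * float(np.mean(1.0 / np.abs(resp) ** 2))
        sn2 = max(sn2_meas - leak, 1e-12 * acov[0])
    return _clip_stable(gamma)


# ---------------------------------------------------------------------------
# active-set solver in the spike domain
# ---------------------------------------------------------------------------

_H_TRUNC = 1e-17


class _SpikeSolver:
    """Warm-startable active-set solver for the non-negative lasso

        min_s 0.5 * sum_t w2_t (y_t - (H s)_t)^2 + lam * sum_t s_t,  s >= 0,

    with ``H`` the AR impulse-response (lower-triangular Toeplitz) matrix.
    Restricted normal equations are built incrementally from truncated
    impulse-response inner products; full KKT checks cost O(T) via filtering.
    State persists across calls so an outer search on ``lam`` is cheap.
    """

    def __init__(self, y: np.ndarray, gamma: Sequence[float],
                 w2: Optional[np.ndarray] = None):
        self.y = np.asarray(y, dtype=np.float64).ravel()
        self.T = len(self.y)
        self.gamma = np.atleast_1d(np.asarray(gamma, dtype=np.float64))
        self.poly = np.concatenate([[1.0], -self.gamma])
        h = impulse_response(self.gamma, self.T)
        nz = np.nonzero(np.abs(h) > _H_TRUNC)[0]
        self.h = h[: nz[-1] + 1] if len(nz) else h[:1]
        self.nh = len(self.h)
        self.w2 = None if w2 is None else np.asarray(w2, dtype=np.float64).ravel()
        self.idx: list = []
        self.G = np.zeros((0, 0))
        self.q0 = np.zeros(0)
        self.s_vals = np.zeros(0)
        hty = self._corr(self.y if self.w2 is None else self.w2 * self.y)
        self.lam_max = float(max(hty.max(), 0.0))
        self.scale = max(1.0, float(np.abs(hty).max()))

    # -- linear operators ---------------------------------------------------

    def _filt(self, x: np.ndarray) -> np.ndarray:
        """H @ x."""
        return lfilter([1.0], self.poly, x)

    def _corr(self, x: np.ndarray) -> np.ndarray:
        """H.T @ x."""
        return lfilter([1.0], self.poly, x[::-1])[::-1]

    def _gram_entry(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        k = j - i
        if k >= self.nh:
            return 0.0
        L = min(self.T - j, self.nh - k)
        if L <= 0:
            return 0.0
        prod = self.h[:L] * self.h[k:k + L]
        if self.w2 is not None:
            prod = prod * self.w2[j:j + L]
        return float(prod.sum())

    def _q_entry(self, j: int) -> float:
        L = min(self.T - j, self.nh)
        seg = self.y[j:j + L]
        if self.w2 is not None:
            seg = seg * self.w2[j:j + L]
        return float(self.h[:L] @ seg)

    # -- support management -------------------------------------------------

    def _add(self, j: int) -> None:
        m = len(self.idx)
        row = np.array([self._gram_entry(i, j) for i in self.idx])
        Gnew = np.empty((m + 1, m + 1))
        Gnew[:m, :m] = self.G
        Gnew[m, :m] = row
        Gnew[:m, m] = row
        Gnew[m, m] = self._gram_entry(j, j)
        self.G = Gnew
        self.q0 = np.append(self.q0, self._q_entry(j))
        self.s_vals = np.append(self.s_vals, 0.0)
        self.idx.append(j)

    def _drop(self, positions: np.ndarray) -> None:
        keep = np.setdiff1d(np.arange(len(self.idx)), positions)
        self.G = self.G[np.ix_(keep, keep)]
        self.q0 = self.q0[keep]
        self.s_vals = self.s_vals[keep]
        self.idx = [self.idx[i] for i in keep]

    # -- solve --------------------------------------------------------------

    def s_full(self) -> np.ndarray:
        s = np.zeros(self.T)
        if self.idx:
            s[np.asarray(self.idx)] = self.s_vals
        return s

    def solve(self, lam: float, tol: float = 1e-10, max_outer: Optional[int] = None
              ) -> np.ndarray:
        """Solve for the given multiplier, continuing from the current state.
        Returns the full spike vector."""
        max_outer = max_outer or 4 * self.T + 10
        tol_g = tol * (self.scale + lam)
        for _ in range(max_outer):
            self._restricted_solve(lam)
            s = self.s_full()
            r = self._filt(s) - self.y
            if self.w2 is not None:
                r = r * self.w2
            g = self._corr(r) + lam
            if self.idx:
                g[np.asarray(self.idx)] = np.inf
            j = int(np.argmin(g))
            if g[j] >= -tol_g:
                return s
            # admit a small batch of violators per pass; the inner loop
            # drops any that overshoot, and large supports build much faster
            viol = np.nonzero(g < -tol_g)[0]
            for jj in viol[np.argsort(g[viol])][:16]:
                self._add(int(jj))
        warnings.warn("active-set solver hit its iteration cap", RuntimeWarning)
        return self.s_full()

    def _restricted_solve(self, lam: float, eps: float = 1e-12) -> None:
        """Lawson-Hanson inner loop on the current support."""
        while self.idx:
            sol = np.linalg.solve(self.G, self.q0 - lam)
            if np.all(sol >= -eps * (1 + np.abs(sol).max())):
                self.s_vals = np.maximum(sol, 0.0)
                return
            neg = sol < 0
            denom = self.s_vals[neg] - sol[neg]
            with np.errstate(divide="ignore", invalid="ignore"):
                alphas = np.where(denom > 0, self.s_vals[neg] / denom, 0.0)
            alpha = float(alphas.min())
            self.s_vals = self.s_vals + alpha * (sol - self.s_vals)
            self.s_vals[self.s_vals < 0] = 0.0
            hit = np.nonzero(neg)[0][alphas <= alpha + 1e-15]
            zero = np.nonzero(self.s_vals <= 0)[0]
            drop = np.union1d(hit, np.intersect1d(zero, np.nonzero(neg)[0]))
            if drop.size == 0:
                drop = np.array([int(np.nonzero(neg)[0][np.argmin(alphas)])])
            self._drop(drop)

    def rss(self) -> float:
        r = self._filt(self.s_full()) - self.y
        if self.w2 is not None:
            return float(np.sum(self.w2 * r**2))
        return float(np.sum(r**2))


def _solve_constrained(y, gamma, target, w2=None, rtol=1e-9, max_bisect=120):
    """min ||s||_1 s.t. s >= 0 and weighted RSS <= target, by bisection on
    the sparsity multiplier around the penalized solver.

    Returns (s, lam, feasible)."""
    gamma_arr = np.atleast_1d(np.asarray(gamma, dtype=np.float64))
    if not np.any(gamma_arr):
        return _solve_constrained_identity(np.asarray(y, float).ravel(), target, w2, rtol)
    solver = _SpikeSolver(y, gamma, w2=w2)
    wy2 = float(np.sum((w2 if w2 is not None else 1.0) * np.asarray(y, float) ** 2))
    if wy2 <= target * (1 + 1e-12) or solver.lam_max <= 0:
        # s = 0 is feasible (or no descent direction exists at all)
        s = np.zeros(solver.T)
        feasible = wy2 <= target * (1 + 1e-12)
        if not feasible:
            warnings.warn("noise constraint infeasible: even the projection "
                          "cannot reach the target residual", RuntimeWarning)
        return s, solver.lam_max, feasible
    lo, hi = 0.0, solver.lam_max
    s_lo = None
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        s = solver.solve(mid)
        rss = solver.rss()
        if rss > target:
            hi = mid
        else:
            lo = mid
            s_lo = s
            if rss >= target * (1 - rtol):
                return s, mid, True
        if hi - lo <= 1e-15 * solver.lam_max:
            break
    if lo == 0.0:
        # even a vanishing multiplier overshoots: the answer is the plain
        # projection onto {G c >= 0}
        s = solver.solve(0.0)
        rss = solver.rss()
        feasible = rss <= target * (1 + rtol) + 1e-12
        if not feasible:
            warnings.warn("noise constraint infeasible at zero multiplier; "
                          "returning the projection", RuntimeWarning)
        return s, 0.0, feasible
    if s_lo is None:
        s_lo = solver.solve(lo)
    elif not np.array_equal(solver.s_full(), s_lo):
        s_lo = solver.solve(lo)
    return s_lo, lo, True


def _solve_constrained_identity(y, target, w2, rtol):
    """Closed-form constrained solve for G = I (no dynamics): the solution
    is the soft threshold c = max(y - lam / w2, 0), with lam bisected on the
    weighted residual."""
    w2v = np.ones_like(y) if w2 is None else np.asarray(w2, float).ravel()

    def fit(lam):
        return np.maximum(y - lam / w2v, 0.0)

    def rss(c):
        return float(np.sum(w2v * (y - c) ** 2))

    s0 = fit(0.0)
    if rss(s0) >= target * (1 - rtol):
        feasible = rss(s0) <= target * (1 + rtol) + 1e-12
        if not feasible:
            warnings.warn("noise constraint infeasible at zero multiplier; "
                          "returning the projection", RuntimeWarning)
        return s0, 0.0, feasible
    lo, hi = 0.0, float(np.max(y * w2v)) + 1e-12
    s = s0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        sm = fit(mid)
        r = rss(sm)
        if r > target:
            hi = mid
        else:
            lo, s = mid, sm
            if r >= target * (1 - rtol):
                break
        if hi - lo <= 1e-16 * hi:
            break
    return s, lo, True


def deconvolve_trace(y: np.ndarray, ar: ARModel, sigma: float = 0.0,
                     mode: str = "constrained", lam: float = 0.0
                     ) -> DeconvolvedTrace:
    """Sparse non-negative deconvolution of one fluorescence trace.

    ``constrained`` mode (default) minimizes ``||G c||_1`` subject to
    ``G c >= 0`` and ``||y - c||^2 <= sigma^2 T``; ``sigma = 0`` returns the
    projection of ``y`` onto the feasible cone.  ``penalized`` mode solves
    the lasso form with the given multiplier ``lam``.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    gamma = ar.coeffs() if isinstance(ar, ARModel) else np.atleast_1d(ar)
    if mode == "penalized":
        solver = _SpikeSolver(y, gamma)
        s = solver.solve(lam)
        feasible = True
    elif mode == "constrained":
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        s, lam, feasible = _solve_constrained(y, gamma, sigma**2 * len(y))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    c = lfilter([1.0], np.concatenate([[1.0], -np.atleast_1d(gamma)]), s)
    return DeconvolvedTrace(c=c, s=s, lam=lam, constraint_met=feasible)


def deconvolve_interleaved(y_odd: np.ndarray, y_even: np.ndarray,
                           noise: TraceNoise, ar: ARModel) -> DeconvolvedTrace:
    """Deconvolve one neuron's trace acquired on alternating pixel grids.

    ``y_odd`` holds frames 0, 2, 4, ... (the unshifted grid; odd frames in
    1-based counting) and ``y_even`` frames 1, 3, 5, ....  The residuals are
    weighted by the parity-specific noise levels:

        minimize ||G c||_1  s.t.  G c >= 0,
        ||y_odd - c_odd||^2 / sigma_odd^2 + ||y_even - c_even||^2 / sigma_even^2 <= T.
    """
    y_odd = np.asarray(y_odd, dtype=np.float64).ravel()
    y_even = np.asarray(y_even, dtype=np.float64).ravel()
    if not (len(y_odd) == len(y_even) or len(y_odd) == len(y_even) + 1):
        raise ValueError("parity streams must interleave: len(y_odd) must be "
                         "len(y_even) or len(y_even)+1")
    T = len(y_odd) + len(y_even)
    y = np.empty(T)
    y[0::2] = y_odd
    y[1::2] = y_even
    s_odd = noise.sigma_odd if noise.sigma_odd is not None else 0.0
    s_even = noise.sigma_even if noise.sigma_even is not None else 0.0
    tiny = 1e-12 * max(1.0, float(np.abs(y).max()))
    w2 = np.empty(T)
    w2[0::2] = 1.0 / max(s_odd, tiny) ** 2
    w2[1::2] = 1.0 / max(s_even, tiny) ** 2
    gamma = ar.coeffs() if isinstance(ar, ARModel) else np.atleast_1d(ar)
    s, lam, feasible = _solve_constrained(y, gamma, float(T), w2=w2)
    c = lfilter([1.0], np.concatenate([[1.0], -np.atleast_1d(gamma)]), s)
    return DeconvolvedTrace(c=c, s=s, lam=lam, constraint_met=feasible)


# ---------------------------------------------------------------------------
# constrained matrix updates
# ---------------------------------------------------------------------------


def update_temporal_constrained(
    Y: np.ndarray,
    model: FactorModel,
    ar: ARModel,
    sigma: Optional[np.ndarray] = None,
    noise_band: Tuple[float, float] = (0.5, 1.0),
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-constrained temporal update of all traces plus background.

    Shapes are l2-normalized internally (scale moved into C) so the noise
    constraint applies to unit-shape projections; the caller's scale split
    is restored on exit, so the returned traces stay in the units of the
    input shapes.  For each neuron the residual with all other components
    removed is projected onto its shape and deconvolved under that trace's
    noise constraint; per-neuron noise is estimated from the projected
    trace's PSD unless ``sigma`` is given (in unit-shape projection units).
    The background ``f`` is refit by unconstrained least squares.

    Returns ``(C, S, f)``; the model is updated in place (including ``S``
    and ``sigma``, both reported in the same units as ``C``).
    """
    Y = np.asarray(Y, dtype=np.float64)
    scale = np.linalg.norm(model.A, axis=0)
    model.normalize()
    A, b, C, f = model.A, model.b, model.C, model.f
    N, T = C.shape
    AY = A.T @ Y
    AA = A.T @ A
    Ab = A.T @ b
    S = np.zeros_like(C)
    sig_out = np.zeros(N)
    for n in range(N):
        if AA[n, n] <= 0:
            warnings.warn(f"component {n} has a zero-norm shape; skipped",
                          RuntimeWarning)
            continue
        y_n = (AY[n] - AA[n] @ C + AA[n, n] * C[n] - Ab[n] * f) / AA[n, n]
        sig_n = float(sigma[n]) if sigma is not None else float(
            estimate_pixel_noise(y_n, band=noise_band).sigma[0])
        dec = deconvolve_trace(y_n, ARModel(ar.coeffs(n)), sig_n)
        C[n] = dec.c
        S[n] = dec.s
        sig_out[n] = sig_n
    bb = b @ b
    if bb > 0:
        f[:] = b @ (Y - A @ C) / bb
    # restore the caller's scale split (traces back in input-shape units)
    nz = scale > 0
    A[:, nz] *= scale[nz]
    C[nz, :] /= scale[nz, None]
    S[nz, :] /= scale[nz, None]
    sig_out[nz] /= scale[nz]
    model.S = S
    model.sigma = sig_out
    return C, S, f


def _nnls_penalized_small(G, q, penalty, max_iter=500):
    """min 0.5 w'Gw - q'w + penalty'w, w >= 0 for a handful of variables."""
    m = len(q)
    active: list = []
    w = np.zeros(m)
    qeff = q - penalty
    for _ in range(max_iter):
        grad = G @ w - qeff
        cand = [j for j in range(m) if j not in active and grad[j] < -1e-12 * (1 + np.abs(qeff).max())]
        if not cand:
            return w
        active.append(cand[int(np.argmin([grad[j] for j in cand]))])
        while active:
            ai = np.asarray(active)
            sol = np.linalg.lstsq(G[np.ix_(ai, ai)], qeff[ai], rcond=None)[0]
            if np.all(sol >= -1e-12 * (1 + np.abs(sol).max())):
                w = np.zeros(m)
                w[ai] = np.maximum(sol, 0.0)
                break
            wa = w[ai]
            neg = sol < 0
            denom = wa[neg] - sol[neg]
            alphas = np.where(denom > 0, wa[neg] / denom, 0.0)
            alpha = float(alphas.min())
            wa = wa + alpha * (sol - wa)
            w = np.zeros(m)
            w[ai] = np.maximum(wa, 0.0)
            for pos in sorted(np.nonzero(neg)[0][alphas <= alpha + 1e-15], reverse=True):
                active.pop(pos)
    return w


def update_spatial_constrained(
    Y: np.ndarray,
    model: FactorModel,
    noise: NoiseMap,
    patches: Optional[PatchSet] = None,
    rtol: float = 1e-3,
    max_bisect: int = 60,
) -> Tuple[np.ndarray, np.ndarray]:
    """Sparse spatial update: per pixel, minimize the l1-norm of the shape
    weights over the components whose patch contains the pixel (background
    unpenalized), subject to the pixel's residual constraint
    ``||Y(d,:) - A(d,:) C - b(d) f^T|| <= sigma_d sqrt(T)``.

    The sparsity multiplier is bisected until the constraint is met within
    ``rtol`` (0.1% by default) or the multiplier reaches 0.  Pixels outside
    every patch get a background-only fit.  Returns ``(A, b)``; the model is
    updated in place.
    """
    Y = np.asarray(Y, dtype=np.float64)
    A, b, C, f = model.A, model.b, model.C, model.f
    D, N = A.shape
    T = C.shape[1]
    if patches is None and model.patches is not None:
        cand_lists = model.patches
    elif patches is not None:
        cand_lists = patches.indices
    else:
        cand_lists = [np.arange(D)] * N
    members = [[] for _ in range(D)]
    for n, idx in enumerate(cand_lists):
        for d in np.asarray(idx, dtype=int):
            members[d].append(n)
    CC = C @ C.T
    Cf = C @ f
    ff = float(f @ f)
    CY = C @ Y.T  # N x D
    fY = Y @ f    # D
    targets = noise.sigma**2 * T
    if len(noise.sigma) != D:
        raise ValueError("noise map length does not match pixel count")
    for d in range(D):
        cand = members[d]
        y2 = float(Y[d] @ Y[d])
        if not cand:
            A[d, :] = 0.0
            b[d] = max(0.0, fY[d] / ff) if ff > 0 else 0.0
            continue
        ci = np.asarray(cand)
        m = len(ci)
        G = np.empty((m + 1, m + 1))
        G[:m, :m] = CC[np.ix_(ci, ci)]
        G[:m, m] = Cf[ci]
        G[m, :m] = Cf[ci]
        G[m, m] = ff
        q = np.concatenate([CY[ci, d], [fY[d]]])
        pen = np.concatenate([np.ones(m), [0.0]])

        def rss_of(w):
            return y2 - 2 * float(q @ w) + float(w @ G @ w)

        w0 = _nnls_penalized_small(G, q, 0.0 * pen)
        target = targets[d]
        if rss_of(w0) >= target * (1 - rtol):
            w = w0
        else:
            lam_hi = max(float(np.max(q[:m])), 1e-12)
            lo, hi = 0.0, lam_hi
            w = w0
            for _ in range(max_bisect):
                mid = 0.5 * (lo + hi)
                wm = _nnls_penalized_small(G, q, mid * pen)
                r = rss_of(wm)
                if r > target:
                    hi = mid
                else:
                    lo = mid
                    w = wm
                    if r >= target * (1 - rtol):
                        break
        A[d, :] = 0.0
        A[d, ci] = w[:m]
        b[d] = w[m]
    return A, b
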