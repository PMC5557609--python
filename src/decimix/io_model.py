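"""Core data containers and movie/model I/O.

A fluorescence movie is a ``VideoStack`` — an ``H x W`` pixel grid observed
for ``T`` frames.  Throughout the package pixels are flattened row-major and
0-based, ``d = row * W + col``, so a movie becomes the ``D x T`` matrix ``Y``
(``D = H * W``) on which all factorizations operate.

A fitted source-extraction model is a ``FactorModel``::

    Y ~= A C + b f^T

with non-negative spatial footprints ``A`` (``D x N``), non-negative calcium
traces ``C`` (``N x T``) and a rank-1 background ``b f^T`` (``b >= 0``, ``f``
unconstrained).  Movies themselves may be negative (offset-subtracted
cameras); non-negativity is a model constraint, never a data constraint.

Movies load from multi-page TIFF, HDF5, or raw binary with a JSON sidecar
header.  Models round-trip losslessly through HDF5 or NPZ archives with a
fixed layout (``A`` stored as a CSC sparse triplet).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import scipy.sparse as sp
import tifffile

__all__ = [
    "VideoStack",
    "FactorModel",
    "ResidualMovie",
    "load_video",
    "flatten",
    "unflatten",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class VideoStack:
    """A fluorescence movie stored as a ``(T, H, W)`` float array.

    Parameters
    ----------
    data
        Frame stack, shape ``(T, H, W)``; converted to float without
        rescaling.  Values may be negative but must be finite.
    rate
        Frame rate in frames per second.
    """

    data: np.ndarray
    rate: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a (T, H, W) array, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ValueError("movie contains non-finite values")
        if min(self.data.shape) < 1:
            raise ValueError("H, W, T must all be >= 1")
        if self.rate <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def T(self) -> int:
        return self.data.shape[0]

    @property
    def H(self) -> int:
        return self.data.shape[1]

    @property
    def W(self) -> int:
        return self.data.shape[2]

    @property
    def D(self) -> int:
        return self.H * self.W

    def matrix(self) -> np.ndarray:
        """The ``D x T`` pixel-by-time matrix ``Y`` (row-major pixels)."""
        return flatten(self)


def flatten(stack: VideoStack) -> np.ndarray:
    """Flatten a movie to the ``D x T`` matrix with ``d = row * W + col``."""
    T = stack.T
    return np.ascontiguousarray(stack.data.reshape(T, stack.D).T)


def unflatten(matrix: np.ndarray, H: int, W: int, rate: float = 1.0) -> VideoStack:
    """Inverse of :func:`flatten`: a ``D x T`` matrix back to a movie."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D D x T matrix")
    D, T = matrix.shape
    if D != H * W:
        raise ValueError(f"matrix has D={D} rows but H*W={H * W}")
    return VideoStack(matrix.T.reshape(T, H, W).copy(), rate=rate)


@dataclass
class FactorModel:
    """Fitted factorization ``Y ~= A C + b f^T``.

    ``A`` is ``D x N`` (non-negative footprints), ``C`` is ``N x T``
    (non-negative traces), ``b`` length ``D`` (non-negative), ``f`` length
    ``T`` (unconstrained).  Optional attachments: grid shape, frame rate,
    per-component patches (pixel-index arrays), AR coefficients ``gamma``
    (``N x p``), per-trace noise ``sigma``, and deconvolved spikes ``S``.
    """

    A: np.ndarray
    C: np.ndarray
    b: np.ndarray
    f: np.ndarray
    H: Optional[int] = None
    W: Optional[int] = None
    rate: float = 1.0
    patches: Optional[list] = None  # list of int index arrays, one per component
    gamma: Optional[np.ndarray] = None
    sigma: Optional[np.ndarray] = None
    S: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=np.float64))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=np.float64))
        self.b = np.asarray(self.b, dtype=np.float64).ravel()
        self.f = np.asarray(self.f, dtype=np.float64).ravel()
        D, N = self.A.shape
        N2, T = self.C.shape if self.C.size else (self.C.shape[0], len(self.f))
        if self.C.shape[0] != N:
            raise ValueError(f"A has {N} components but C has {self.C.shape[0]}")
        if len(self.b) != D:
            raise ValueError("b length does not match A rows")
        if self.C.size and self.C.shape[1] != len(self.f):
            raise ValueError("C columns do not match f length")

    @property
    def D(self) -> int:
        return self.A.shape[0]

    @property
    def N(self) -> int:
        return self.A.shape[1]

    @property
    def T(self) -> int:
        return len(self.f)

    def copy(self) -> "FactorModel":
        return FactorModel(
            A=self.A.copy(),
            C=self.C.copy(),
            b=self.b.copy(),
            f=self.f.copy(),
            H=self.H,
            W=self.W,
            rate=self.rate,
            patches=None if self.patches is None else [np.array(p) for p in self.patches],
            gamma=None if self.gamma is None else np.array(self.gamma),
            sigma=None if self.sigma is None else np.array(self.sigma),
            S=None if self.S is None else np.array(self.S),
            meta=dict(self.meta),
        )

    def reconstruction(self) -> np.ndarray:
        """``A C + b f^T`` as a ``D x T`` matrix."""
        return self.A @ self.C + np.outer(self.b, self.f)

    def normalize(self) -> "FactorModel":
        """Rescale so every footprint has unit l2-norm, moving scale into C.

        Zero-norm components are left untouched.  Returns self.
        """
        norms = np.linalg.norm(self.A, axis=0)
        nz = norms > 0
        self.A[:, nz] /= norms[nz]
        self.C[nz, :] *= norms[nz, None]
        return self

    def residual(self, Y: np.ndarray) -> "ResidualMovie":
        return ResidualMovie(Y - self.reconstruction())


@dataclass
class ResidualMovie:
    """``Y - A C - b f^T`` as a ``D x T`` matrix."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))

    def rss(self) -> float:
        return float(np.sum(self.values**2))


# ---------------------------------------------------------------------------
# movie readers
# ---------------------------------------------------------------------------

_HEADER_FIELDS = ("H", "W", "T", "dtype")


def load_video(path, format: Optional[str] = None, dataset: Optional[str] = None,
               rate: Optional[float] = None) -> VideoStack:
    """Load a movie from TIFF, HDF5, or raw binary with a JSON sidecar.

    Parameters
    ----------
    path
        Movie file.  For raw binary a sidecar ``<path>.json`` (or a ``header``
        key inside a ``.json`` path) must name ``H``, ``W``, ``T``, ``dtype``
        and optionally ``rate`` and ``byteorder`` (``"<"``/``">"``).
    format
        One of ``{"tiff", "hdf5", "raw"}``; inferred from the suffix when
        omitted.
    dataset
        HDF5 dataset name; when omitted the file must contain exactly one
        3-D dataset.
    rate
        Frame rate override (frames per second).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such movie file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {".tif": "tiff", ".tiff": "tiff", ".h5": "hdf5", ".hdf5": "hdf5",
                  ".hdf": "hdf5"}.get(suffix, "raw")
    if format == "tiff":
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"TIFF is not a grayscale frame stack: shape {data.shape}")
        return VideoStack(np.asarray(data, dtype=np.float64), rate=rate or 1.0)
    if format == "hdf5":
        with h5py.File(path, "r") as fh:
            if dataset is None:
                names = [k for k in fh.keys() if isinstance(fh[k], h5py.Dataset)
                         and fh[k].ndim == 3]
                if len(names) != 1:
                    raise ValueError(
                        f"HDF5 file holds {len(names)} 3-D datasets; pass dataset=")
                dataset = names[0]
            if dataset not in fh:
                raise KeyError(f"dataset {dataset!r} not found in {path}")
            data = np.asarray(fh[dataset], dtype=np.float64)
            file_rate = fh[dataset].attrs.get("rate", None)
        return VideoStack(data, rate=rate or file_rate or 1.0)
    if format == "raw":
        return _load_raw(path, rate=rate)
    raise ValueError(f"unsupported movie format: {format!r}")


def _load_raw(path: Path, rate: Optional[float] = None) -> VideoStack:
    header_path = path.with_suffix(path.suffix + ".json")
    if not header_path.exists():
        header_path = path.with_suffix(".json")
    if not header_path.exists():
        raise FileNotFoundError(f"raw movie {path} has no sidecar header (.json)")
    header = json.loads(header_path.read_text())
    for key in _HEADER_FIELDS:
        if key not in header:
            raise KeyError(f"raw header {header_path} missing required field {key!r}")
    H, W, T = int(header["H"]), int(header["W"]), int(header["T"])
    byteorder = header.get("byteorder", "=")
    try:
        dtype = np.dtype(header["dtype"]).newbyteorder(byteorder)
    except TypeError as exc:
        raise ValueError(f"unsupported dtype in header: {header['dtype']!r}") from exc
    payload = np.fromfile(path, dtype=dtype)
    if payload.size != H * W * T:
        raise ValueError(
            f"raw payload holds {payload.size} values but header claims "
            f"H*W*T = {H * W * T} (H={H}, W={W}, T={T})")
    data = payload.astype(np.float64).reshape(T, H, W)
    return VideoStack(data, rate=rate or header.get("rate", 1.0))


# ---------------------------------------------------------------------------
# model archives
# ---------------------------------------------------------------------------

_REQUIRED_DATASETS = ("A_data", "A_indices", "A_indptr", "A_shape", "C", "b", "f")


def _model_payload(model: FactorModel) -> dict:
    A = sp.csc_matrix(model.A)
    payload = {
        "A_data": A.data,
        "A_indices": A.indices,
        "A_indptr": A.indptr,
        "A_shape": np.array(A.shape, dtype=np.int64),
        "C": model.C,
        "b": model.b,
        "f": model.f,
    }
    meta = {"rate": model.rate, **model.meta}
    if model.H is not None:
        meta["H"] = int(model.H)
        meta["W"] = int(model.W)
    payload["meta_json"] = np.bytes_(json.dumps(meta).encode())
    if model.patches is not None:
        payload["patch_indices"] = np.concatenate(
            [np.asarray(p, dtype=np.int64) for p in model.patches]
        ) if model.N else np.empty(0, dtype=np.int64)
        payload["patch_lengths"] = np.array([len(p) for p in model.patches], dtype=np.int64)
    for name in ("gamma", "sigma", "S"):
        value = getattr(model, name)
        if value is not None:
            payload[name] = np.asarray(value)
    return payload


def save_model(model: FactorModel, path) -> None:
    """Write a model archive (HDF5 for ``.h5``/``.hdf5``, else NPZ)."""
    path = Path(path)
    payload = _model_payload(model)
    if path.suffix.lower() in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "w") as fh:
            for key, value in payload.items():
                fh.create_dataset(key, data=value)
    else:
        np.savez(path, **payload)


def load_model(path) -> FactorModel:
    """Load a model archive written by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such model archive: {path}")
    if path.suffix.lower() in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "r") as fh:
            payload = {k: np.asarray(fh[k]) for k in fh.keys()}
    else:
        with np.load(path, allow_pickle=False) as npz:
            payload = {k: npz[k] for k in npz.files}
    for key in _REQUIRED_DATASETS:
        if key not in payload:
            raise KeyError(f"model archive {path} is missing dataset {key!r}")
    shape = tuple(int(x) for x in payload["A_shape"])
    A = sp.csc_matrix(
        (payload["A_data"], payload["A_indices"], payload["A_indptr"]), shape=shape
    ).toarray()
    meta = {}
    if "meta_json" in payload:
        raw = payload["meta_json"]
        meta = json.loads(bytes(raw).decode() if raw.dtype.kind == "S" else str(raw))
    patches = None
    if "patch_lengths" in payload:
        lengths = payload["patch_lengths"].astype(int)
        idx = payload["patch_indices"].astype(int)
        patches, start = [], 0
        for n in lengths:
            patches.append(idx[start:start + n])
            start += n
    model = FactorModel(
        A=A,
        C=payload["C"],
        b=payload["b"],
        f=payload["f"],
        H=meta.pop("H", None),
        W=meta.pop("W", None),
        rate=float(meta.pop("rate", 1.0)),
        patches=patches,
        gamma=payload.get("gamma"),
        sigma=payload.get("sigma"),
        S=payload.get("S"),
        meta=meta,
    )
    return model
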