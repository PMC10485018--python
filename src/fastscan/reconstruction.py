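"""Sparse-to-full image estimation and reconstruction quality metrics.

Inside the acquisition loop the image estimate comes from inverse
distance weighted (IDW, Shepard) interpolation over the k nearest
measured points, which is cheap enough to rerun every iteration.  Final
images use biharmonic inpainting, which is slower but markedly better at
smooth regions and edges.  Quality is scored against ground truth with
the squared-L2 distortion, NRMSE (range-normalized) and SSIM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.metrics import structural_similarity
from skimage.restoration import inpaint_biharmonic as _sk_inpaint

from .sample import SampleImage

__all__ = [
    "MeasurementSet",
    "ReconstructedImage",
    "idw_reconstruct",
    "biharmonic_inpaint",
    "distortion",
    "nrmse",
    "ssim",
]


@dataclass(frozen=True)
class MeasurementSet:
    """Ordered history of (location, value) measurement pairs.

    Locations are (row, col) pixels on the scan grid, unique, stored in
    acquisition order; values are non-negative intensities.
    """

    locations: np.ndarray  # (k, 2) int
    values: np.ndarray  # (k,) float
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        loc = np.asarray(self.locations, dtype=np.intp).reshape(-1, 2)
        val = np.asarray(self.values, dtype=np.float64).reshape(-1)
        if len(loc) != len(val):
            raise ValueError("locations and values length mismatch")
        rows, cols = self.grid_shape
        if len(loc):
            if loc[:, 0].min() < 0 or loc[:, 0].max() >= rows:
                raise ValueError("measurement row outside grid")
            if loc[:, 1].min() < 0 or loc[:, 1].max() >= cols:
                raise ValueError("measurement col outside grid")
            flat = loc[:, 0] * cols + loc[:, 1]
            if len(np.unique(flat)) != len(flat):
                raise ValueError("duplicate measurement locations")
        object.__setattr__(self, "locations", loc)
        object.__setattr__(self, "values", val)
        object.__setattr__(self, "grid_shape", (int(rows), int(cols)))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def coverage(self) -> float:
        rows, cols = self.grid_shape
        return len(self) / (rows * cols)

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where measured."""
        m = np.zeros(self.grid_shape, dtype=bool)
        m[self.locations[:, 0], self.locations[:, 1]] = True
        return m

    def extend(self, locations, values) -> "MeasurementSet":
        """New set with extra measurements appended (acquisition order kept)."""
        loc = np.asarray(locations, dtype=np.intp).reshape(-1, 2)
        val = np.asarray(values, dtype=np.float64).reshape(-1)
        return MeasurementSet(
            np.vstack([self.locations, loc]),
            np.concatenate([self.values, val]),
            self.grid_shape,
        )

    def head(self, n: int) -> "MeasurementSet":
        """First n measurements in acquisition order."""
        return MeasurementSet(self.locations[:n], self.values[:n], self.grid_shape)

    @classmethod
    def from_mask(cls, mask: np.ndarray, image: SampleImage) -> "MeasurementSet":
        """Noise-free measurements of ``image`` at every True mask cell."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise ValueError("mask shape must match the image")
        loc = np.argwhere(mask)
        return cls(loc, image.values[mask], image.shape)


@dataclass(frozen=True)
class ReconstructedImage:
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or not np.all(np.isfinite(v)):
            raise ValueError("reconstruction must be a finite 2-D array")
        if self.method not in ("idw", "biharmonic"):
            raise ValueError(f"unknown reconstruction method {self.method!r}")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _as_array(img) -> np.ndarray:
    if isinstance(img, (SampleImage, ReconstructedImage)):
        return img.values
    return np.asarray(img, dtype=np.float64)


# Neighbor sets use a closed k-NN rule: every point tied (to within a
# relative 1e-12) with the k-th smallest distance is included.  On integer
# grids such ties are common and bit-exact, and an open rule would leave
# the interpolant dependent on the search tree's arbitrary tie order.
_TIE_PAD = 16
_TIE_RTOL = 1.0 + 1e-12


def _knn_query(tree: cKDTree, pts: np.ndarray, k: int, n_points: int):
    """Neighbor distances/indices padded so distance ties are visible."""
    kq = min(k + _TIE_PAD, n_points)
    d, idx = tree.query(pts, k=kq, workers=-1)
    d = d.reshape(len(pts), kq)
    idx = idx.reshape(len(pts), kq)
    return d, idx


def _idw_weights(d: np.ndarray, k: int, power: float = 2.0) -> np.ndarray:
    """Closed-rule IDW weights; exact hits collapse to the hit point."""
    kk = min(k, d.shape[1])
    dk = d[:, kk - 1]
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[d > dk[:, None] * _TIE_RTOL] = 0.0
    hit = d[:, 0] == 0.0
    w[hit] = 0.0
    w[hit, 0] = 1.0
    return w


def idw_reconstruct(
    m: MeasurementSet,
    n_neighbors: int | None = 10,
    power: float = 2.0,
) -> ReconstructedImage:
    """Shepard interpolation onto the full grid.

    Each unmeasured pixel is the d^(-power)-weighted mean of its
    ``n_neighbors`` nearest measured values, with distance ties at the
    neighbor cutoff all included (``None`` uses every measurement).
    Measured pixels pass through exactly.  Neighbor search uses a k-d
    tree.
    """
    if len(m) == 0:
        raise ValueError("cannot reconstruct from an empty MeasurementSet")
    rows, cols = m.grid_shape
    k = len(m) if n_neighbors is None else min(n_neighbors, len(m))
    tree = cKDTree(m.locations.astype(np.float64))
    grid = np.stack(
        np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij"), axis=-1
    ).reshape(-1, 2)
    d, idx = _knn_query(tree, grid, k, len(m))
    vals = m.values[idx]
    w = _idw_weights(d, k, power)
    out = (w * vals).sum(axis=1) / w.sum(axis=1)
    out = out.reshape(rows, cols)
    out[m.locations[:, 0], m.locations[:, 1]] = m.values
    return ReconstructedImage(out, "idw")


def biharmonic_inpaint(m: MeasurementSet) -> ReconstructedImage:
    """Fill unmeasured pixels by solving the biharmonic equation.

    Measured pixels are the boundary data and pass through exactly.
    """
    if len(m) == 0:
        raise ValueError("cannot inpaint from an empty MeasurementSet")
    known = m.mask
    img = np.zeros(m.grid_shape, dtype=np.float64)
    img[m.locations[:, 0], m.locations[:, 1]] = m.values
    if known.all():
        return ReconstructedImage(img, "biharmonic")
    out = _sk_inpaint(img, ~known)
    out[known] = img[known]
    return ReconstructedImage(out, "biharmonic")


def distortion(a, b) -> float:
    """Squared L2 distance ||a - b||^2 summed over all pixels."""
    av, bv = _as_array(a), _as_array(b)
    if av.shape != bv.shape:
        raise ValueError(f"shape mismatch {av.shape} vs {bv.shape}")
    diff = av - bv
    return float(np.dot(diff.ravel(), diff.ravel()))


def nrmse(truth, est) -> float:
    """Root mean squared error normalized by the ground-truth range."""
    tv, ev = _as_array(truth), _as_array(est)
    if tv.shape != ev.shape:
        raise ValueError(f"shape mismatch {tv.shape} vs {ev.shape}")
    rng = tv.max() - tv.min()
    if rng == 0:
        raise ValueError("NRMSE undefined for a constant ground truth")
    return float(np.sqrt(np.mean((tv - ev) ** 2)) / rng)


def ssim(truth, est) -> float:
    """Mean structural similarity with 7x7 windows on the [0, 1] scale."""
    tv, ev = _as_array(truth), _as_array(est)
    if tv.shape != ev.shape:
        raise ValueError(f"shape mismatch {tv.shape} vs {ev.shape}")
    return float(structural_similarity(tv, ev, win_size=7, data_range=1.0))
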