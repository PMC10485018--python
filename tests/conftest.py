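"""Shared fixtures and brute-force oracle helpers.

The oracles here deliberately avoid the package's spatial-tree fast
paths: they sort all pairwise distances per pixel and enumerate discs
directly, so tree-based results can be checked against them exactly.
Neighbor sets use the same closed rule as the package (every point tied
with the k-th smallest distance is included).
"""

from __future__ import annotations

import numpy as np
import pytest

import fastscan as fs

_TIE_RTOL = 1.0 + 1e-12


def brute_idw(m: fs.MeasurementSet, n_neighbors: int = 10, power: float = 2.0):
    """Reference IDW: per-pixel full distance sort, no spatial tree."""
    rows, cols = m.grid_shape
    out = np.empty((rows, cols))
    loc = m.locations.astype(float)
    for r in range(rows):
        for c in range(cols):
            d = np.hypot(loc[:, 0] - r, loc[:, 1] - c)
            if d.min() == 0.0:
                out[r, c] = m.values[np.argmin(d)]
                continue
            k = min(n_neighbors, len(m))
            dk = np.sort(d)[k - 1]
            sel = d <= dk * _TIE_RTOL
            w = d[sel] ** (-power)
            out[r, c] = (w * m.values[sel]).sum() / w.sum()
    return out


def brute_features(
    m: fs.MeasurementSet,
    recon: fs.ReconstructedImage,
    pixel: tuple[int, int],
    cfg: fs.FeatureConfig,
):
    """Reference 6-vector computed with plain loops."""
    r, c = pixel
    rows, cols = m.grid_shape
    gy, gx = np.gradient(recon.values)
    loc = m.locations.astype(float)
    d = np.hypot(loc[:, 0] - r, loc[:, 1] - c)
    k = min(cfg.n_neighbors, len(m))
    order = np.argsort(d, kind="stable")
    dk = d[order[k - 1]]
    in_set = d <= dk * _TIE_RTOL
    radius = cfg.radius_for(m.grid_shape, len(m))
    inside = in_set & (d <= radius)
    use = inside if inside.any() else in_set
    w = d[use] ** -2.0
    dev = np.abs(m.values[use] - recon.values[r, c])
    sigma1 = (w * dev).sum() / w.sum()
    sigma2 = (w * dev**2).sum() / w.sum()
    L = d.min()
    # disc enumeration for the measured-density feature
    n_in, n_meas = 0, 0
    mask = m.mask
    rad_i = int(np.floor(radius))
    for dr in range(-rad_i, rad_i + 1):
        for dc in range(-rad_i, rad_i + 1):
            if dr * dr + dc * dc > radius * radius:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                n_in += 1
                n_meas += bool(mask[rr, cc])
    return np.array([gx[r, c], gy[r, c], sigma1, sigma2, L, n_meas / n_in])


def random_measurements(shape, n, seed, image=None):
    """Uniform measurement set over a grid, optionally of a given image."""
    rng = np.random.default_rng(seed)
    rows, cols = shape
    flat = rng.choice(rows * cols, size=n, replace=False)
    loc = np.column_stack([flat // cols, flat % cols])
    if image is None:
        values = rng.random(n)
    else:
        values = image.values[loc[:, 0], loc[:, 1]]
    return fs.MeasurementSet(loc, values, shape)


@pytest.fixture(scope="session")
def flake_config():
    return fs.SimulatorConfig(rows=80, cols=60, seed=7)


@pytest.fixture(scope="session")
def flake_image(flake_config):
    return fs.generate_flake_image(flake_config)


@pytest.fixture(scope="session")
def quick_model():
    """Small, fast ERD model for loop-mechanics tests (not the default model)."""
    image = fs.generic_training_image(48)
    pairs = fs.build_training_set(
        image,
        coverage_levels=[0.02, 0.1, 0.3, 0.6],
        masks_per_level=2,
        pairs_per_mask=300,
        rng=11,
    )
    return fs.train_erd_model(pairs, epochs=30, seed=11)
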