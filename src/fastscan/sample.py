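"""Synthetic samples and a simulated instrument.

Generates dark-field-like ground-truth images (flakes with discrete
thickness levels on a zero-intensity background, decorated with bubbles
whose rims appear dark), per-pixel diffraction stacks in which local film
curvature displaces a Bragg-like peak from its nominal detector position,
and noisy point measurements standing in for detector exposures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import h5py
import numpy as np
import tifffile
from skimage.draw import polygon as draw_polygon

__all__ = [
    "SampleImage",
    "SimulatorConfig",
    "NoiseModel",
    "DiffractionStack",
    "generate_flake_image",
    "generate_diffraction_stack",
    "measure_point",
]


@dataclass(frozen=True)
class SampleImage:
    """Ground-truth normalized intensity field on the scan grid.

    Values are the per-position integrated dark-field intensities,
    normalized to [0, 1]; background (no material) is exactly 0.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"sample must be 2-D, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("sample contains non-finite values")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("sample values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tiff(self, path) -> None:
        tifffile.imwrite(str(path), self.values.astype(np.float32))

    @classmethod
    def from_tiff(cls, path) -> "SampleImage":
        return cls(np.asarray(tifffile.imread(str(path)), dtype=np.float64))

    def to_png(self, path) -> None:
        """8-bit preview export (documentation use only; lossy)."""
        import imageio.v3 as iio

        iio.imwrite(str(path), (np.clip(self.values, 0, 1) * 255).astype(np.uint8))


@dataclass(frozen=True)
class SimulatorConfig:
    """Scene description for the flake-and-bubble test object.

    ``thickness_levels`` are the normalized intensities of flat flake
    regions (thicker material diffracts more into the detector ROI, so it
    is brighter).  Bubbles are surface bumps: their rims tilt the film,
    pushing intensity out of the ROI, so rim pixels are depressed by
    ``rim_contrast`` relative to the surrounding flake.
    """

    rows: int = 150
    cols: int = 100
    n_flakes: int = 3
    thickness_levels: tuple[float, ...] = (0.35, 0.6, 0.85)
    n_bubbles_per_flake: int = 2
    bubble_radius_range: tuple[float, float] = (5.0, 10.0)
    rim_contrast: float = 0.7
    background_level: float = 0.0
    seed: int = 0
    # Characteristic flake radius in pixels; None picks a scale giving a
    # sparse scene (roughly a quarter of the grid covered by material).
    flake_radius_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("rows and cols must be positive")
        if self.n_flakes < 0 or self.n_bubbles_per_flake < 0:
            raise ValueError("flake/bubble counts must be >= 0")
        levels = tuple(float(t) for t in self.thickness_levels)
        if not levels:
            raise ValueError("thickness_levels must be nonempty")
        if any(not (0 < t <= 1) for t in levels):
            raise ValueError("thickness_levels must lie in (0, 1]")
        if list(levels) != sorted(levels):
            raise ValueError("thickness_levels must be sorted ascending")
        object.__setattr__(self, "thickness_levels", levels)
        rmin, rmax = self.bubble_radius_range
        if rmin > rmax:
            raise ValueError("bubble_radius_range min must be <= max")
        if rmax > min(self.rows, self.cols) / 2:
            raise ValueError("bubble radius exceeds half the grid extent")
        if not (0 <= self.background_level < 1):
            raise ValueError("background_level must lie in [0, 1)")
        if not (0 < self.rim_contrast <= 1):
            raise ValueError("rim_contrast must lie in (0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied by the simulated detector.

    kind="gaussian": additive zero-mean noise with std ``parameter``.
    kind="poisson": ``parameter`` is the expected photon count at unit
    intensity; counts are drawn and rescaled back to intensity units.
    Results are clipped at 0 (intensities are non-negative).
    """

    kind: str = "none"
    parameter: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.parameter < 0:
            raise ValueError("noise parameter must be >= 0")


@dataclass(frozen=True)
class DiffractionStack:
    """Per-scan-position detector patterns (rows, cols, det_rows, det_cols)."""

    patterns: np.ndarray
    nominal_center: tuple[float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.patterns, dtype=np.float64)
        if p.ndim != 4:
            raise ValueError("patterns must be 4-D")
        if p.min() < 0:
            raise ValueError("pattern intensities must be >= 0")
        cr, cc = self.nominal_center
        if not (0 <= cr < p.shape[2] and 0 <= cc < p.shape[3]):
            raise ValueError("nominal_center outside detector bounds")
        object.__setattr__(self, "patterns", p)
        object.__setattr__(self, "nominal_center", (float(cr), float(cc)))

    @property
    def scan_shape(self) -> tuple[int, int]:
        return self.patterns.shape[:2]

    @property
    def detector_shape(self) -> tuple[int, int]:
        return self.patterns.shape[2:]

    def to_hdf5(self, path, config: SimulatorConfig | None = None) -> None:
        with h5py.File(str(path), "w") as f:
            f.create_dataset("patterns", data=self.patterns.astype(np.float32))
            f.create_dataset("nominal_center", data=np.asarray(self.nominal_center))
            meta = {}
            if config is not None:
                meta = {k: v for k, v in config.__dict__.items()}
            f.create_dataset("meta", data=json.dumps(meta))

    @classmethod
    def from_hdf5(cls, path) -> "DiffractionStack":
        with h5py.File(str(path), "r") as f:
            patterns = np.asarray(f["patterns"], dtype=np.float64)
            center = tuple(np.asarray(f["nominal_center"]))
        return cls(patterns, center)


def _scene_fields(config: SimulatorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Build the intensity image and the film-height field together.

    The height field carries the bubbles as spherical-cap bumps; its
    gradient drives the diffraction-peak shift in the stack simulator.
    Both fields are pure functions of the config (seeded).
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.rows, config.cols
    img = np.full((rows, cols), config.background_level, dtype=np.float64)
    height = np.zeros((rows, cols), dtype=np.float64)

    if config.flake_radius_range is None:
        scale = min(rows, cols)
        flake_rr = (0.18 * scale, 0.32 * scale)
    else:
        flake_rr = config.flake_radius_range

    rr_grid, cc_grid = np.mgrid[0:rows, 0:cols]
    flake_mask = np.zeros((rows, cols), dtype=bool)

    for _ in range(config.n_flakes):
        cr = rng.uniform(0.15 * rows, 0.85 * rows)
        cc = rng.uniform(0.15 * cols, 0.85 * cols)
        base_r = rng.uniform(*flake_rr)
        # irregular convex-ish polygon: perturbed radial profile
        n_vert = 14
        ang = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
        ang = ang + rng.uniform(0, 2 * np.pi / n_vert)
        radii = base_r * rng.uniform(0.65, 1.25, n_vert)
        vr = cr + radii * np.sin(ang)
        vc = cc + radii * np.cos(ang)
        pr, pc = draw_polygon(vr, vc, shape=(rows, cols))
        thickness = rng.choice(config.thickness_levels)
        img[pr, pc] = thickness
        flake_mask[pr, pc] = True

        # bubbles: spherical-cap height bumps; rim annulus appears dark
        for _ in range(config.n_bubbles_per_flake):
            if len(pr) == 0:
                break
            j = rng.integers(len(pr))
            br, bc = float(pr[j]), float(pc[j])
            brad = rng.uniform(*config.bubble_radius_range)
            d = np.hypot(rr_grid - br, cc_grid - bc)
            inside = d < brad
            cap_h = 0.5 * brad
            sphere_r = (brad**2 + cap_h**2) / (2 * cap_h)
            h = np.zeros_like(height)
            h[inside] = np.sqrt(sphere_r**2 - d[inside] ** 2) - np.sqrt(
                sphere_r**2 - brad**2
            )
            height += h
            rim_w = max(1.5, 0.2 * brad)
            rim = inside & (d >= brad - rim_w)
            img[rim] *= 1.0 - config.rim_contrast

    img = np.clip(img, 0.0, 1.0)
    # height only matters where there is material
    height[~flake_mask] = 0.0
    return img, height


def generate_flake_image(config: SimulatorConfig) -> SampleImage:
    """Generate the flake-and-bubble ground-truth image.

    Deterministic for a fixed config (the seed is part of the config).
    Background pixels equal ``background_level`` exactly; flake interiors
    take values from ``thickness_levels``; bubble rims are depressed by
    ``rim_contrast`` relative to the surrounding flake.
    """
    img, _ = _scene_fields(config)
    return SampleImage(img)


def generate_diffraction_stack(
    sample_config: SimulatorConfig,
    det_rows: int = 24,
    det_cols: int = 24,
    peak_sigma: float = 1.5,
    shift_gain: float = 2.0,
) -> DiffractionStack:
    """Simulate a per-pixel diffraction stack for the configured scene.

    Each scan position carries a 2-D Gaussian peak whose center is
    displaced from the nominal position by ``shift_gain`` times the local
    gradient of the film-height field (bubbles are height bumps); flat
    regions give an unshifted peak.  The total pattern intensity equals
    the dark-field value of the pixel, so ROI integration recovers the
    generating image.  Shifts that would push the peak off-detector are
    clipped with a warning.
    """
    if det_rows < 8 or det_cols < 8:
        raise ValueError("detector dimensions must be >= 8")
    if peak_sigma <= 0:
        raise ValueError("peak_sigma must be > 0")

    img, height = _scene_fields(sample_config)
    gr, gc = np.gradient(height)
    nominal = ((det_rows - 1) / 2.0, (det_cols - 1) / 2.0)

    center_r = nominal[0] + shift_gain * gr
    center_c = nominal[1] + shift_gain * gc
    lo_r, hi_r = 1.0, det_rows - 2.0
    lo_c, hi_c = 1.0, det_cols - 2.0
    if (
        center_r.min() < lo_r
        or center_r.max() > hi_r
        or center_c.min() < lo_c
        or center_c.max() > hi_c
    ):
        warnings.warn(
            "peak shift exceeds detector bounds; clipping peak centers",
            stacklevel=2,
        )
        center_r = np.clip(center_r, lo_r, hi_r)
        center_c = np.clip(center_c, lo_c, hi_c)

    det_r = np.arange(det_rows, dtype=np.float64)
    det_c = np.arange(det_cols, dtype=np.float64)
    rows, cols = img.shape
    patterns = np.zeros((rows, cols, det_rows, det_cols), dtype=np.float64)
    # row-chunked to bound the broadcast temporaries
    for r0 in range(0, rows, 32):
        r1 = min(r0 + 32, rows)
        dr = det_r[None, None, :, None] - center_r[r0:r1, :, None, None]
        dc = det_c[None, None, None, :] - center_c[r0:r1, :, None, None]
        g = np.exp(-(dr**2 + dc**2) / (2 * peak_sigma**2))
        g /= g.sum(axis=(2, 3), keepdims=True)
        patterns[r0:r1] = img[r0:r1, :, None, None] * g
    return DiffractionStack(patterns, nominal)


def measure_point(
    sample: SampleImage,
    point: tuple[int, int],
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | None = None,
) -> float:
    """Simulated detector exposure at one scan position.

    Out-of-grid points are an error (the motors never clamp).  Noisy
    results are clipped at 0.
    """
    r, c = int(point[0]), int(point[1])
    rows, cols = sample.shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValueError(f"point {point} outside {rows}x{cols} grid")
    value = float(sample.values[r, c])
    if noise.kind == "none":
        return value
    if rng is None:
        raise ValueError("a Generator is required for noisy measurements")
    if noise.kind == "gaussian":
        value = value + rng.normal(0.0, noise.parameter)
    elif noise.kind == "poisson":
        if noise.parameter == 0:
            return value
        value = rng.poisson(value * noise.parameter) / noise.parameter
    return max(value, 0.0)


def measure_points(
    sample: SampleImage,
    points: np.ndarray,
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorized form of :func:`measure_point` for a batch of positions."""
    pts = np.asarray(points, dtype=np.intp).reshape(-1, 2)
    rows, cols = sample.shape
    if pts.size and (
        pts[:, 0].min() < 0
        or pts[:, 0].max() >= rows
        or pts[:, 1].min() < 0
        or pts[:, 1].max() >= cols
    ):
        raise ValueError("measurement point outside the scan grid")
    values = sample.values[pts[:, 0], pts[:, 1]].astype(np.float64)
    if noise.kind == "none":
        return values
    if rng is None:
        raise ValueError("a Generator is required for noisy measurements")
    if noise.kind == "gaussian":
        values = values + rng.normal(0.0, noise.parameter, size=values.shape)
    elif noise.kind == "poisson":
        if noise.parameter > 0:
            values = rng.poisson(values * noise.parameter) / noise.parameter
    return np.clip(values, 0.0, None)
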