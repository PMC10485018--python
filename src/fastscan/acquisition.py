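"""The closed measurement loop and static sampling baselines.

A scan starts from a low-discrepancy (Hammersley) set covering ~1% of
the grid, then repeats: IDW-reconstruct, predict the ERD of every
unmeasured pixel, pick the highest-ERD batch, order it into a short
motor path, and measure.  Static masks (raster grid, uniform random,
low-discrepancy random) provide the comparison baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .erd import ERDMap, ERDModel, FeatureConfig, predict_erd
from .reconstruction import (
    MeasurementSet,
    ReconstructedImage,
    biharmonic_inpaint,
    idw_reconstruct,
    nrmse,
    ssim,
)
from .routing import optimize_route
from .sample import NoiseModel, SampleImage, measure_points

__all__ = [
    "ScanGrid",
    "ScanConfig",
    "StoppingRule",
    "ScanTrajectory",
    "IterationRecord",
    "CheckpointRecord",
    "hammersley_points",
    "raster_mask",
    "uniform_random_mask",
    "ldr_mask",
    "select_batch",
    "run_fast_scan",
    "check_stopping",
]


@dataclass(frozen=True)
class ScanGrid:
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("scan grid must be at least 2x2")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class StoppingRule:
    """When to end the scan.

    ``coverage_only`` runs until the configured maximum coverage.
    ``erd_plateau`` additionally stops once the summed ERD has changed
    by less than ``rel_tolerance`` (relatively) over the last ``window``
    iterations — the numerical analog of watching the ERD map go quiet.
    """

    kind: str = "coverage_only"
    window: int = 5
    rel_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("coverage_only", "erd_plateau"):
            raise ValueError(f"unknown stopping kind {self.kind!r}")
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.rel_tolerance <= 0:
            raise ValueError("rel_tolerance must be > 0")


@dataclass(frozen=True)
class ScanConfig:
    initial_fraction: float = 0.01
    batch_size: int = 50
    max_coverage: float = 0.35
    stopping: StoppingRule = StoppingRule()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.initial_fraction < self.max_coverage <= 1):
            raise ValueError(
                "require 0 < initial_fraction < max_coverage <= 1"
            )
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    points: tuple[tuple[int, int], ...]  # batch in visit order
    n_measured: int
    coverage: float
    nrmse: float
    ssim: float
    total_erd: float
    route_length: float
    erd_order_length: float  # length of the unoptimized (ERD-descending) visit order


@dataclass(frozen=True)
class CheckpointRecord:
    coverage_target: float
    n_measured: int
    nrmse: float
    ssim: float


@dataclass
class ScanTrajectory:
    """Everything an adaptive run produced, in order."""

    grid_shape: tuple[int, int]
    iterations: list[IterationRecord] = field(default_factory=list)
    checkpoints: list[CheckpointRecord] = field(default_factory=list)
    measurements: MeasurementSet | None = None
    final_idw: ReconstructedImage | None = None
    final_biharmonic: ReconstructedImage | None = None

    @property
    def coverage(self) -> float:
        return 0.0 if self.measurements is None else self.measurements.coverage

    @property
    def erd_totals(self) -> list[float]:
        return [
            r.total_erd for r in self.iterations if np.isfinite(r.total_erd)
        ]


# ---------------------------------------------------------------------------
# point-set generators


def _van_der_corput(i: np.ndarray) -> np.ndarray:
    """Base-2 radical inverse of the given indices."""
    i = np.asarray(i, dtype=np.uint64).copy()
    v = np.zeros(i.shape, dtype=np.float64)
    denom = 1.0
    while i.any():
        denom *= 2.0
        v += (i & np.uint64(1)) / denom
        i >>= np.uint64(1)
    return v


def _hammersley_exact(shape: tuple[int, int], n: int) -> np.ndarray:
    """Exactly n distinct grid pixels from the 2-D Hammersley set.

    Pixel collisions after rounding are discarded and the sequence is
    regenerated longer until the count is met; should collisions persist
    (near-full coverage), remaining pixels are appended in raster order.
    """
    rows, cols = shape
    n_pix = rows * cols
    if not (1 <= n <= n_pix):
        raise ValueError(f"point count {n} outside [1, {n_pix}]")
    m = n
    for _ in range(64):
        i = np.arange(m)
        r = np.minimum((i * rows) // m, rows - 1).astype(np.intp)
        c = np.minimum(
            np.floor(_van_der_corput(i) * cols).astype(np.intp), cols - 1
        )
        flat = r * cols + c
        _, first = np.unique(flat, return_index=True)
        keep = flat[np.sort(first)]
        if len(keep) >= n:
            keep = keep[:n]
            return np.column_stack([keep // cols, keep % cols])
        if m >= 64 * n_pix:
            break
        m = max(m + 1, int(m * 1.3))
    taken = np.zeros(n_pix, dtype=bool)
    taken[keep] = True
    fill = np.flatnonzero(~taken)[: n - len(keep)]
    keep = np.concatenate([keep, fill])
    return np.column_stack([keep // cols, keep % cols])


def hammersley_points(grid, fraction: float) -> np.ndarray:
    """Low-discrepancy (row, col) pixels covering ``fraction`` of the grid.

    Deterministic (the set carries no seed); a fraction that would round
    to zero points is promoted to a single point.
    """
    shape = grid.shape if isinstance(grid, ScanGrid) else tuple(grid)
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    rows, cols = shape
    n = max(1, round(fraction * rows * cols))
    return _hammersley_exact(shape, n)


def _points_to_mask(shape, points) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(points, dtype=np.intp).reshape(-1, 2)
    mask[pts[:, 0], pts[:, 1]] = True
    return mask


def raster_mask(grid, n: int) -> np.ndarray:
    """Equally spaced lattice mask with exactly n cells.

    The lattice aspect ratio follows the grid (row/col strides near
    sqrt(N/n) per axis); surplus lattice sites are trimmed in raster
    order to hit n exactly.
    """
    shape = grid.shape if isinstance(grid, ScanGrid) else tuple(grid)
    rows, cols = shape
    n_pix = rows * cols
    if not (1 <= n <= n_pix):
        raise ValueError(f"n={n} outside [1, {n_pix}]")
    rows_sel = int(np.clip(round(np.sqrt(n * rows / cols)), 1, rows))
    cols_sel = int(np.clip(int(np.ceil(n / rows_sel)), 1, cols))
    while rows_sel * cols_sel < n:
        if rows_sel < rows:
            rows_sel += 1
        else:
            cols_sel += 1
    r_idx = np.floor((np.arange(rows_sel) + 0.5) * rows / rows_sel).astype(np.intp)
    c_idx = np.floor((np.arange(cols_sel) + 0.5) * cols / cols_sel).astype(np.intp)
    rr, cc = np.meshgrid(r_idx, c_idx, indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()])[:n]
    return _points_to_mask(shape, pts)


def uniform_random_mask(grid, n: int, rng) -> np.ndarray:
    """n cells drawn uniformly without replacement."""
    shape = grid.shape if isinstance(grid, ScanGrid) else tuple(grid)
    rows, cols = shape
    n_pix = rows * cols
    if not (1 <= n <= n_pix):
        raise ValueError(f"n={n} outside [1, {n_pix}]")
    rng = np.random.default_rng(rng)
    flat = rng.choice(n_pix, size=n, replace=False)
    return _points_to_mask(shape, np.column_stack([flat // cols, flat % cols]))


def ldr_mask(grid, n: int) -> np.ndarray:
    """Low-discrepancy (Hammersley) mask with exactly n cells."""
    shape = grid.shape if isinstance(grid, ScanGrid) else tuple(grid)
    return _points_to_mask(shape, _hammersley_exact(shape, n))


# ---------------------------------------------------------------------------
# batch selection and the loop


def select_batch(erd: ERDMap, batch_size: int) -> list[tuple[int, int]]:
    """Unmeasured pixels with the highest ERD, descending.

    Ties break lexicographically by (row, col); never returns a measured
    pixel; returns fewer than ``batch_size`` only when candidates run out.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    pix = np.argwhere(erd.defined)
    if len(pix) == 0:
        raise ValueError("ERD map has no defined pixels")
    vals = erd.values[pix[:, 0], pix[:, 1]]
    order = np.lexsort((pix[:, 1], pix[:, 0], -vals))
    take = order[: min(batch_size, len(pix))]
    return [tuple(p) for p in pix[take]]


def check_stopping(traj, rule: StoppingRule, max_coverage: float = 1.0) -> bool:
    """Evaluate the stopping rule on a trajectory (or an ERD-total series)."""
    if isinstance(traj, ScanTrajectory):
        coverage = traj.coverage
        totals = traj.erd_totals
    else:
        coverage = None
        totals = [float(t) for t in traj]
    if rule.kind == "coverage_only":
        if coverage is None:
            raise ValueError("coverage_only needs a ScanTrajectory")
        return coverage >= max_coverage
    # erd_plateau
    if len(totals) < rule.window:
        return False
    ref = totals[-rule.window]
    change = abs(totals[-1] - ref) / max(abs(ref), 1e-300)
    return change < rule.rel_tolerance


def run_fast_scan(
    sample: SampleImage,
    model: ERDModel,
    cfg: ScanConfig = ScanConfig(),
    noise: NoiseModel = NoiseModel(),
    checkpoints: tuple[float, ...] = (),
    feature_cfg: FeatureConfig | None = None,
) -> ScanTrajectory:
    """Run the full adaptive scan loop against a (simulated) sample.

    Hammersley initialization at ``initial_fraction``, then repeated
    [IDW reconstruct -> ERD predict -> top-ERD batch -> route -> measure]
    until the stopping rule fires or ``max_coverage`` is reached.
    Per-iteration metrics are scored on the in-loop IDW estimate;
    ``checkpoints`` (coverage fractions) additionally get biharmonic
    metrics, and the final reconstruction is always biharmonic.
    """
    if feature_cfg is None:
        feature_cfg = model.feature_config
    rows, cols = sample.shape
    n_pix = rows * cols
    target_n = max(1, round(cfg.max_coverage * n_pix))
    noise_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    init_pts = hammersley_points(sample.shape, cfg.initial_fraction)
    values = measure_points(sample, init_pts, noise, noise_rng)
    m = MeasurementSet(init_pts, values, sample.shape)
    position = tuple(init_pts[-1])

    traj = ScanTrajectory(grid_shape=sample.shape)
    recon = idw_reconstruct(m, n_neighbors=feature_cfg.n_neighbors)
    traj.iterations.append(
        IterationRecord(
            0,
            tuple(map(tuple, init_pts)),
            len(m),
            m.coverage,
            nrmse(sample, recon),
            ssim(sample, recon),
            np.nan,
            0.0,
            0.0,
        )
    )

    iteration = 0
    pending = sorted(checkpoints)
    while len(m) < target_n and len(m) < n_pix:
        iteration += 1
        erd_map = predict_erd(model, m, recon, feature_cfg)
        batch_size = min(cfg.batch_size, target_n - len(m), n_pix - len(m))
        batch = select_batch(erd_map, batch_size)
        from .routing import route_length as _rl
        erd_order_length = _rl(batch, position)
        route = optimize_route(batch, position)
        pts = np.asarray(route.points, dtype=np.intp)
        vals = measure_points(sample, pts, noise, noise_rng)
        m = m.extend(pts, vals)
        position = route.points[-1]

        recon = idw_reconstruct(m, n_neighbors=feature_cfg.n_neighbors)
        traj.iterations.append(
            IterationRecord(
                iteration,
                route.points,
                len(m),
                m.coverage,
                nrmse(sample, recon),
                ssim(sample, recon),
                erd_map.total,
                route.total_length,
                erd_order_length,
            )
        )
        traj.measurements = m

        while pending and m.coverage >= pending[0]:
            cp = pending.pop(0)
            n_cp = max(1, round(cp * n_pix))
            m_cp = m.head(n_cp)
            recon_cp = biharmonic_inpaint(m_cp)
            traj.checkpoints.append(
                CheckpointRecord(
                    cp, n_cp, nrmse(sample, recon_cp), ssim(sample, recon_cp)
                )
            )

        if check_stopping(traj, cfg.stopping, cfg.max_coverage):
            break

    traj.measurements = m
    traj.final_idw = recon
    traj.final_biharmonic = biharmonic_inpaint(m)
    return traj
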