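"""SLADS-Net decision core: features, kernelization, RD targets, ERD model.

The selector scores every unmeasured pixel with its *expected reduction
in distortion* (ERD): the predicted drop in squared-L2 reconstruction
error if that pixel were measured next.  The predictor g(.) is a small
fully connected network applied to a random-Fourier-feature (RBF)
expansion of a 6-dimensional, sample-agnostic feature vector describing
the local measurement state.  Training pairs (features, actual RD) are
harvested from random measurement masks of a generic photographic image,
so the shipped model carries no prior about any particular specimen.

Feature vector for an unmeasured pixel P (in order):

==========  ==========================================================
grad_x      central-difference gradient of the interpolant at P, x/col
grad_y      same, y/row direction
sigma1      d^-2-weighted mean |a_i - recon(P)| over nearby measurements
sigma2      same with squared deviations
L           Euclidean distance from P to the nearest measured point
rho         fraction of pixels within radius r of P that are measured
==========  ==========================================================

sigma1/sigma2 use the measured points within radius r among the k
nearest, falling back to all k when none lie inside the disc.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree
from sklearn.exceptions import ConvergenceWarning
from sklearn.kernel_approximation import RBFSampler
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .reconstruction import (
    MeasurementSet,
    ReconstructedImage,
    _idw_weights,
    _knn_query,
    _TIE_RTOL,
)
from .sample import SampleImage

__all__ = [
    "FeatureConfig",
    "TrainingPair",
    "ERDModel",
    "ERDMap",
    "compute_features",
    "kernelize",
    "compute_rd",
    "build_training_set",
    "train_erd_model",
    "train_default_model",
    "predict_erd",
]

FEATURE_NAMES = ("grad_x", "grad_y", "sigma1", "sigma2", "nearest_dist", "density")

# RD locality: half-width of the square update window, in units of the
# candidate's nearest-measurement distance L, with absolute clamps.
_RD_WINDOW_FACTOR = 3.0
_RD_WINDOW_MIN = 3
_RD_WINDOW_MAX = 30


@dataclass(frozen=True)
class FeatureConfig:
    """Feature and kernelization settings.

    ``neighborhood_radius`` of None derives r each call from the current
    measurement density: r = 2 * sqrt(n_pixels / n_measured), twice the
    mean inter-measurement spacing, so the disc around a candidate holds
    about a dozen measurements and the density feature actually varies.

    ``rbf_gamma`` defaults to 1/12: features are standardized before
    kernelization, so typical squared pairwise distances are ~2x6, and
    the Gaussian kernel scale should sit at that magnitude (the median
    heuristic) rather than collapse to zero overlap.
    """

    n_neighbors: int = 10
    neighborhood_radius: float | None = None
    rbf_dim: int = 50
    rbf_gamma: float = 1.0 / 12.0
    rbf_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.neighborhood_radius is not None and self.neighborhood_radius <= 0:
            raise ValueError("neighborhood_radius must be > 0")
        if self.rbf_dim < 1:
            raise ValueError("rbf_dim must be >= 1")

    def radius_for(self, grid_shape: tuple[int, int], n_measured: int) -> float:
        if self.neighborhood_radius is not None:
            return float(self.neighborhood_radius)
        rows, cols = grid_shape
        return 2.0 * float(np.sqrt(rows * cols / max(n_measured, 1)))


@dataclass(frozen=True)
class TrainingPair:
    features: np.ndarray  # (6,)
    rd: float


@dataclass(frozen=True)
class ERDMap:
    """Per-pixel ERD, defined only at unmeasured pixels (NaN elsewhere)."""

    values: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        d = np.asarray(self.defined, dtype=bool)
        if v.shape != d.shape:
            raise ValueError("values/defined shape mismatch")
        if not np.all(np.isfinite(v[d])):
            raise ValueError("ERD must be finite at unmeasured pixels")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "defined", d)

    @property
    def total(self) -> float:
        return float(self.values[self.defined].sum())


# ---------------------------------------------------------------------------
# feature computation


def _idw_from_knn(values, d, idx, k: int, power: float = 2.0) -> np.ndarray:
    """IDW estimates given precomputed (tie-padded) neighbor arrays."""
    vals = values[idx]
    w = _idw_weights(d, k, power)
    return (w * vals).sum(axis=1) / w.sum(axis=1)


def _grid_coords(shape) -> np.ndarray:
    rows, cols = shape
    return np.stack(
        np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij"), axis=-1
    ).reshape(-1, 2)


def _disc_kernel(radius: float) -> np.ndarray:
    n = int(np.floor(radius))
    ax = np.arange(-n, n + 1)
    dr, dc = np.meshgrid(ax, ax, indexing="ij")
    return (dr**2 + dc**2 <= radius**2).astype(np.float64)


def _density_map(mask: np.ndarray, radius: float) -> np.ndarray:
    """Measured fraction within a disc of ``radius`` around every pixel.

    Counts are integers, so the FFT convolution is rounded back to make
    the result exact (identical to direct enumeration).
    """
    kernel = _disc_kernel(radius)
    counts = np.rint(fftconvolve(mask.astype(np.float64), kernel, mode="same"))
    totals = np.rint(fftconvolve(np.ones_like(mask, float), kernel, mode="same"))
    return counts / totals


def _features_batch(
    m: MeasurementSet,
    recon: ReconstructedImage,
    pixels: np.ndarray,
    cfg: FeatureConfig,
    knn: tuple[np.ndarray, np.ndarray] | None = None,
    density: np.ndarray | None = None,
) -> np.ndarray:
    """(n, 6) feature matrix for unmeasured ``pixels`` ((n, 2) ints)."""
    pixels = np.asarray(pixels, dtype=np.intp).reshape(-1, 2)
    k = min(cfg.n_neighbors, len(m))
    r = cfg.radius_for(m.grid_shape, len(m))

    if knn is None:
        tree = cKDTree(m.locations.astype(np.float64))
        d, idx = _knn_query(tree, pixels.astype(np.float64), k, len(m))
    else:
        d, idx = knn

    gy, gx = np.gradient(recon.values)
    pr, pc = pixels[:, 0], pixels[:, 1]
    est = recon.values[pr, pc]

    dev = np.abs(m.values[idx] - est[:, None])
    with np.errstate(divide="ignore"):
        w = d**-2.0
    w = np.where(np.isfinite(w), w, 0.0)
    # closed k-NN set (ties at the cutoff included), then the radius-r
    # restriction, falling back to the whole set when the disc is empty
    kk = min(k, d.shape[1])
    in_set = d <= d[:, kk - 1][:, None] * _TIE_RTOL
    inside = in_set & (d <= r)
    none_inside = ~inside.any(axis=1)
    use = inside | (none_inside[:, None] & in_set)
    w_eff = w * use
    wsum = w_eff.sum(axis=1)
    wsum = np.where(wsum == 0, 1.0, wsum)
    sigma1 = (w_eff * dev).sum(axis=1) / wsum
    sigma2 = (w_eff * dev**2).sum(axis=1) / wsum

    if density is None:
        density = _density_map(m.mask, r)

    feats = np.column_stack(
        [gx[pr, pc], gy[pr, pc], sigma1, sigma2, d[:, 0], density[pr, pc]]
    )
    return feats


def compute_features(
    m: MeasurementSet,
    recon: ReconstructedImage,
    pixel: tuple[int, int],
    cfg: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """6-vector describing the measurement state around one unmeasured pixel."""
    if len(m) == 0:
        raise ValueError("measurement set is empty")
    r, c = int(pixel[0]), int(pixel[1])
    if m.mask[r, c]:
        raise ValueError(f"pixel {pixel} is already measured")
    return _features_batch(m, recon, np.array([[r, c]]), cfg)[0]


# ---------------------------------------------------------------------------
# RBF kernelization


def _make_rbf(cfg: FeatureConfig) -> RBFSampler:
    rbf = RBFSampler(
        gamma=cfg.rbf_gamma, n_components=cfg.rbf_dim, random_state=cfg.rbf_seed
    )
    rbf.fit(np.zeros((1, len(FEATURE_NAMES))))
    return rbf


def kernelize(v: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Random-Fourier-feature map of one or more 6-dim feature vectors.

    Approximates the Gaussian kernel exp(-gamma ||u - v||^2) as a dot
    product of the mapped vectors; deterministic for a fixed rbf_seed.
    """
    v = np.asarray(v, dtype=np.float64)
    single = v.ndim == 1
    out = _make_rbf(cfg).transform(np.atleast_2d(v))
    return out[0] if single else out


# ---------------------------------------------------------------------------
# reduction-in-distortion targets


def _rd_single_windows(
    truth: np.ndarray,
    m: MeasurementSet,
    grid_d: np.ndarray,
    grid_idx: np.ndarray,
    recon_flat: np.ndarray,
    pixels: np.ndarray,
    window_halfwidth: int | None,
    n_neighbors: int = 10,
) -> np.ndarray:
    """RD for each candidate pixel via an exact one-point k-NN update.

    Adding one measurement s can only shrink a pixel's k-th-neighbor
    distance, and every point inside the new cutoff already sits in the
    cached (tie-padded) neighbor arrays, so the post-measurement IDW
    values inside the locality window follow without rebuilding the
    tree.  The same closed tie rule as the reconstructor applies.
    """
    rows, cols = m.grid_shape
    kk = min(n_neighbors, grid_d.shape[1])
    kk_new = min(n_neighbors, len(m) + 1)
    out = np.empty(len(pixels))
    for i, (sr, sc) in enumerate(pixels):
        L = grid_d[sr * cols + sc, 0]
        if window_halfwidth is None:
            hw = int(np.clip(np.ceil(_RD_WINDOW_FACTOR * L), _RD_WINDOW_MIN, _RD_WINDOW_MAX))
        else:
            hw = int(window_halfwidth)
        r0, r1 = max(sr - hw, 0), min(sr + hw + 1, rows)
        c0, c1 = max(sc - hw, 0), min(sc + hw + 1, cols)
        wr, wc = np.mgrid[r0:r1, c0:c1]
        flat = (wr * cols + wc).ravel()
        d = grid_d[flat]
        unmeas = d[:, 0] > 0.0  # measured pixels cancel in the difference
        flat = flat[unmeas]
        d = d[unmeas]
        idx = grid_idx[flat]
        a_s = truth[sr, sc]

        pr, pc = flat // cols, flat % cols
        d_s = np.hypot(pr - sr, pc - sc)
        d_old = np.where(d <= d[:, kk - 1][:, None] * _TIE_RTOL, d, np.inf)
        d_new = np.column_stack([d_old, d_s])
        v_new = np.column_stack([m.values[idx], np.full(len(flat), a_s)])
        dk_new = np.partition(d_new, kk_new - 1, axis=1)[:, kk_new - 1]
        with np.errstate(divide="ignore"):
            w = d_new**-2.0
        w[d_new > dk_new[:, None] * _TIE_RTOL] = 0.0
        hit = d_s == 0.0  # the candidate pixel itself
        w[hit] = 0.0
        w[hit, -1] = 1.0
        recon_after = (w * v_new).sum(axis=1) / w.sum(axis=1)

        t = truth[pr, pc]
        before = t - recon_flat[flat]
        after = t - recon_after
        out[i] = float(np.dot(before, before) - np.dot(after, after))
    return out


def compute_rd(
    truth: SampleImage,
    m: MeasurementSet,
    pixel: tuple[int, int],
    n_neighbors: int = 10,
    window_halfwidth: int | None = None,
) -> float:
    """Actual reduction in distortion from measuring ``pixel``.

    Returns D(A, recon_k) - D(A, recon_{k,s}) where the second
    reconstruction includes the true value at the pixel, evaluated
    within a square locality window (half-width 3L by default, L being
    the pixel's nearest-measurement distance).  A window at least as
    large as the grid makes this the exact full-image RD.
    """
    if len(m) == 0:
        raise ValueError("measurement set is empty")
    r, c = int(pixel[0]), int(pixel[1])
    if m.mask[r, c]:
        raise ValueError(f"pixel {pixel} is already measured")
    k = min(n_neighbors, len(m))
    tree = cKDTree(m.locations.astype(np.float64))
    grid = _grid_coords(m.grid_shape).astype(np.float64)
    d, idx = _knn_query(tree, grid, k, len(m))
    recon_flat = _idw_from_knn(m.values, d, idx, k)
    return float(
        _rd_single_windows(
            truth.values,
            m,
            d,
            idx,
            recon_flat,
            np.array([[r, c]]),
            window_halfwidth,
            n_neighbors=n_neighbors,
        )[0]
    )


def compute_rd_batch(
    truth: SampleImage,
    m: MeasurementSet,
    pixels: np.ndarray,
    n_neighbors: int = 10,
    window_halfwidth: int | None = None,
) -> np.ndarray:
    """Vectorized :func:`compute_rd` over many candidate pixels.

    Identical values to per-pixel calls; the measurement-state neighbor
    arrays are prepared once instead of per candidate.
    """
    if len(m) == 0:
        raise ValueError("measurement set is empty")
    pixels = np.asarray(pixels, dtype=np.intp).reshape(-1, 2)
    mask = m.mask
    if mask[pixels[:, 0], pixels[:, 1]].any():
        raise ValueError("candidate pixels must be unmeasured")
    k = min(n_neighbors, len(m))
    tree = cKDTree(m.locations.astype(np.float64))
    grid = _grid_coords(m.grid_shape).astype(np.float64)
    d, idx = _knn_query(tree, grid, k, len(m))
    recon_flat = _idw_from_knn(m.values, d, idx, k)
    return _rd_single_windows(
        truth.values, m, d, idx, recon_flat, pixels, window_halfwidth,
        n_neighbors=n_neighbors,
    )


# ---------------------------------------------------------------------------
# training


def default_coverage_levels(n_levels: int = 10) -> np.ndarray:
    """Ten coverage fractions spanning 1% to 80%."""
    return np.linspace(0.01, 0.80, n_levels)


def build_training_set(
    image: SampleImage,
    coverage_levels=None,
    masks_per_level: int = 10,
    pairs_per_mask: int = 2000,
    rng: np.random.Generator | int | None = 0,
    cfg: FeatureConfig = FeatureConfig(),
) -> list[TrainingPair]:
    """Harvest (feature, RD) pairs from random measurement masks.

    For each coverage level and mask, measurement locations are drawn
    uniformly without replacement, the image is IDW-reconstructed, and
    up to ``pairs_per_mask`` unmeasured pixels are sampled to record
    their feature vector and actual (windowed) reduction in distortion.
    Deterministic for a fixed rng seed.
    """
    if coverage_levels is None:
        coverage_levels = default_coverage_levels()
    coverage_levels = np.asarray(coverage_levels, dtype=np.float64)
    if np.any(coverage_levels <= 0) or np.any(coverage_levels >= 1):
        raise ValueError("coverage levels must lie strictly in (0, 1)")
    rng = np.random.default_rng(rng)

    rows, cols = image.shape
    n_pix = rows * cols
    grid = _grid_coords(image.shape).astype(np.float64)
    pairs: list[TrainingPair] = []

    for level in coverage_levels:
        n_meas = int(np.clip(round(level * n_pix), 1, n_pix - 1))
        for _ in range(masks_per_level):
            flat_meas = rng.choice(n_pix, size=n_meas, replace=False)
            loc = np.column_stack([flat_meas // cols, flat_meas % cols])
            m = MeasurementSet(loc, image.values[loc[:, 0], loc[:, 1]], image.shape)

            k = min(cfg.n_neighbors, n_meas)
            tree = cKDTree(m.locations.astype(np.float64))
            d, idx = _knn_query(tree, grid, k, n_meas)
            recon_flat = _idw_from_knn(m.values, d, idx, k)
            recon = ReconstructedImage(recon_flat.reshape(rows, cols), "idw")

            unmeasured = np.flatnonzero(d[:, 0] > 0.0)
            take = min(pairs_per_mask, len(unmeasured))
            sel = rng.choice(unmeasured, size=take, replace=False)
            pix = np.column_stack([sel // cols, sel % cols])

            feats = _features_batch(m, recon, pix, cfg, knn=(d[sel], idx[sel]))
            rds = _rd_single_windows(
                image.values, m, d, idx, recon_flat, pix, None,
                n_neighbors=cfg.n_neighbors,
            )
            pairs.extend(
                TrainingPair(f, float(rd)) for f, rd in zip(feats, rds)
            )
    return pairs


@dataclass
class ERDModel:
    """Trained ERD predictor: standardizer -> RBF map -> 5x50 ReLU network."""

    scaler: StandardScaler
    rbf: RBFSampler
    network: MLPRegressor
    feature_config: FeatureConfig
    training_meta: dict = field(default_factory=dict)

    def predict_features(self, feats: np.ndarray) -> np.ndarray:
        """Raw (unclipped) ERD predictions for an (n, 6) feature matrix."""
        feats = np.atleast_2d(np.asarray(feats, dtype=np.float64))
        return self.network.predict(self.rbf.transform(self.scaler.transform(feats)))

    @property
    def loss_history(self) -> list[float]:
        return list(self.training_meta.get("loss_curve", []))

    # -- serialization: JSON header + weight arrays in one npz archive --

    _FORMAT = "fastscan-erd-1"

    def save(self, path) -> None:
        header = {
            "format": self._FORMAT,
            "feature_config": self.feature_config.__dict__,
            "training_meta": {
                k: v for k, v in self.training_meta.items() if k != "loss_curve"
            },
            "loss_curve": [float(x) for x in self.training_meta.get("loss_curve", [])],
            "n_layers": len(self.network.coefs_),
        }
        arrays = {
            "scaler_mean": self.scaler.mean_,
            "scaler_scale": self.scaler.scale_,
            "rbf_weights": self.rbf.random_weights_,
            "rbf_offset": self.rbf.random_offset_,
        }
        for i, (w, b) in enumerate(zip(self.network.coefs_, self.network.intercepts_)):
            arrays[f"coef_{i}"] = w
            arrays[f"intercept_{i}"] = b
        with open(path, "wb") as f:
            np.savez(f, header=np.frombuffer(json.dumps(header).encode(), np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "ERDModel":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"]).decode())
            if header.get("format") != cls._FORMAT:
                raise ValueError(f"unrecognized model format {header.get('format')!r}")
            fc = FeatureConfig(**{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in header["feature_config"].items()
            })
            scaler = StandardScaler()
            scaler.mean_ = z["scaler_mean"]
            scaler.scale_ = z["scaler_scale"]
            scaler.var_ = scaler.scale_**2
            scaler.n_features_in_ = len(scaler.mean_)
            rbf = _make_rbf(fc)
            rbf.random_weights_ = z["rbf_weights"]
            rbf.random_offset_ = z["rbf_offset"]
            n_layers = header["n_layers"]
            coefs = [z[f"coef_{i}"] for i in range(n_layers)]
            intercepts = [z[f"intercept_{i}"] for i in range(n_layers)]
        mlp = MLPRegressor(
            hidden_layer_sizes=tuple(len(b) for b in intercepts[:-1]),
            activation="relu",
        )
        mlp.coefs_ = coefs
        mlp.intercepts_ = intercepts
        mlp.n_layers_ = n_layers + 1
        mlp.n_outputs_ = 1
        mlp.out_activation_ = "identity"
        mlp.n_features_in_ = coefs[0].shape[0]
        meta = dict(header["training_meta"])
        meta["loss_curve"] = header["loss_curve"]
        return cls(scaler, rbf, mlp, fc, meta)


def train_erd_model(
    pairs: list[TrainingPair],
    epochs: int = 100,
    learning_rate: float = 0.001,
    cfg: FeatureConfig = FeatureConfig(),
    seed: int = 0,
    batch_size: int = 1000,
) -> ERDModel:
    """Fit the ERD network on (feature, RD) pairs.

    Architecture and optimizer are fixed: 5 hidden layers of 50 ReLU
    units, Adam with the given learning rate, mean squared error, run
    for exactly ``epochs`` epochs (minibatches of ``batch_size``).
    Training targets keep their sign; clipping happens only at
    prediction time.
    """
    if not pairs:
        raise ValueError("no training pairs supplied")
    if len(pairs) < 100:
        raise ValueError("at least 100 training pairs are required")
    X = np.stack([p.features for p in pairs])
    y = np.array([p.rd for p in pairs], dtype=np.float64)

    scaler = StandardScaler().fit(X)
    rbf = _make_rbf(cfg)
    Xk = rbf.transform(scaler.transform(X))

    mlp = MLPRegressor(
        hidden_layer_sizes=(50,) * 5,
        activation="relu",
        solver="adam",
        learning_rate_init=learning_rate,
        batch_size=min(batch_size, len(pairs)),
        max_iter=epochs,
        n_iter_no_change=max(epochs, 10),
        tol=0.0,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(Xk, y)
    meta = {
        "epochs": epochs,
        "learning_rate": learning_rate,
        "n_pairs": len(pairs),
        "loss_curve": [float(x) for x in mlp.loss_curve_],
    }
    return ERDModel(scaler, rbf, mlp, cfg, meta)


def generic_training_image(size: int = 128) -> SampleImage:
    """The built-in photographic training image, resized and normalized.

    A 512x512 grayscale photograph bundled with scikit-image, unrelated
    to any microscopy sample; the shipped default model is trained on it
    so the selector stays sample-agnostic.
    """
    from skimage.data import camera
    from skimage.transform import resize

    img = camera().astype(np.float64) / 255.0
    if size != img.shape[0]:
        img = resize(img, (size, size), anti_aliasing=True)
    lo, hi = img.min(), img.max()
    return SampleImage((img - lo) / (hi - lo))


def train_default_model(
    seed: int = 0,
    image_size: int = 128,
    cfg: FeatureConfig = FeatureConfig(),
    **train_kwargs,
) -> ERDModel:
    """Build the sample-agnostic default model from the generic image."""
    ss = np.random.SeedSequence(seed)
    mask_seed, net_seed = ss.spawn(2)
    image = generic_training_image(image_size)
    pairs = build_training_set(
        image, rng=np.random.default_rng(mask_seed), cfg=cfg
    )
    return train_erd_model(
        pairs,
        cfg=cfg,
        seed=int(net_seed.generate_state(1)[0] % (2**31)),
        **train_kwargs,
    )


def predict_erd(
    model: ERDModel,
    m: MeasurementSet,
    recon: ReconstructedImage,
    cfg: FeatureConfig | None = None,
) -> ERDMap:
    """Predicted ERD for every unmeasured pixel (negatives clipped to 0)."""
    if cfg is None:
        cfg = model.feature_config
    mask = m.mask
    if mask.all():
        raise ValueError("grid is fully measured; no candidates remain")
    pixels = np.argwhere(~mask)
    feats = _features_batch(m, recon, pixels, cfg)
    preds = np.clip(model.predict_features(feats), 0.0, None)
    # Degenerate-input rule: a candidate whose local evidence is exactly
    # consistent (zero deviations from every nearby measurement and a
    # locally flat interpolant) carries no sign of reconstruction error;
    # the regression never sees such states on a photographic training
    # image, so its extrapolated output there is noise.  The consistent
    # state maps to the regression's own zero-deviation limit: ERD 0.
    consistent = (feats[:, :4] == 0.0).all(axis=1)
    preds[consistent] = 0.0
    values = np.full(m.grid_shape, np.nan)
    values[pixels[:, 0], pixels[:, 1]] = preds
    return ERDMap(values, ~mask)
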