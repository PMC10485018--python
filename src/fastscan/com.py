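"""Center-of-mass post-analysis of diffraction stacks.

The acquisition loop only ever sees one scalar per scan position — the
detector intensity integrated over a region of interest (ROI) around
the nominal Bragg-peak position.  The full patterns carry more: local
film curvature (bubble rims) shifts the peak, so the intensity-weighted
center of mass of each pattern, relative to the nominal center, maps
the curvature.  CoMx is the detector-column shift, CoMy the
detector-row shift (sign: measured minus nominal).  Sparse CoM maps are
filled by biharmonic inpainting, one scalar field per axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reconstruction import MeasurementSet, biharmonic_inpaint
from .sample import DiffractionStack

__all__ = ["ROI", "CoMMaps", "roi_integrate", "pattern_com", "com_maps_from_scan"]


@dataclass(frozen=True)
class ROI:
    """Half-open detector-pixel window [row_min, row_max) x [col_min, col_max)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min >= self.row_max or self.col_min >= self.col_max:
            raise ValueError("ROI must be nonempty")
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError("ROI must start inside the detector")

    def validate_for(self, det_shape: tuple[int, int]) -> None:
        if self.row_max > det_shape[0] or self.col_max > det_shape[1]:
            raise ValueError(f"ROI {self} outside detector {det_shape}")

    @classmethod
    def full(cls, det_shape: tuple[int, int]) -> "ROI":
        return cls(0, det_shape[0], 0, det_shape[1])


@dataclass(frozen=True)
class CoMMaps:
    """Per-scan-position peak shifts in detector pixels.

    Zero-ROI-intensity positions are flagged invalid (NaN in the maps),
    never reported as a zero shift.
    """

    comx: np.ndarray
    comy: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        cx = np.asarray(self.comx, dtype=np.float64)
        cy = np.asarray(self.comy, dtype=np.float64)
        va = np.asarray(self.valid, dtype=bool)
        if not (cx.shape == cy.shape == va.shape):
            raise ValueError("comx/comy/valid shape mismatch")
        if not (np.all(np.isfinite(cx[va])) and np.all(np.isfinite(cy[va]))):
            raise ValueError("CoM maps must be finite where valid")
        object.__setattr__(self, "comx", cx)
        object.__setattr__(self, "comy", cy)
        object.__setattr__(self, "valid", va)


def roi_integrate(pattern: np.ndarray, roi: ROI) -> float:
    """Total detector intensity inside the ROI."""
    pattern = np.asarray(pattern, dtype=np.float64)
    roi.validate_for(pattern.shape)
    return float(
        pattern[roi.row_min : roi.row_max, roi.col_min : roi.col_max].sum()
    )


def pattern_com(
    pattern: np.ndarray, roi: ROI, nominal_center: tuple[float, float]
) -> tuple[float, float]:
    """(comx, comy) peak shift of one pattern relative to the nominal center.

    comx is the column shift, comy the row shift.  A pattern with zero
    ROI intensity has no center of mass and raises.
    """
    pattern = np.asarray(pattern, dtype=np.float64)
    roi.validate_for(pattern.shape)
    sub = pattern[roi.row_min : roi.row_max, roi.col_min : roi.col_max]
    total = sub.sum()
    if total <= 0:
        raise ValueError("zero ROI intensity: center of mass undefined")
    r = np.arange(roi.row_min, roi.row_max, dtype=np.float64)
    c = np.arange(roi.col_min, roi.col_max, dtype=np.float64)
    com_r = (sub.sum(axis=1) * r).sum() / total
    com_c = (sub.sum(axis=0) * c).sum() / total
    return float(com_c - nominal_center[1]), float(com_r - nominal_center[0])


def _sparse_com(stack: DiffractionStack, mask: np.ndarray, roi: ROI) -> CoMMaps:
    rows, cols = stack.scan_shape
    comx = np.full((rows, cols), np.nan)
    comy = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)
    for r, c in np.argwhere(mask):
        pat = stack.patterns[r, c]
        if roi_integrate(pat, roi) > 0:
            cx, cy = pattern_com(pat, roi, stack.nominal_center)
            comx[r, c], comy[r, c] = cx, cy
            valid[r, c] = True
    return CoMMaps(comx, comy, valid)


def com_maps_from_scan(
    stack: DiffractionStack, mask: np.ndarray, roi: ROI
) -> tuple[CoMMaps, CoMMaps]:
    """Sparse and inpainted CoM maps from the measured positions only.

    Each axis is inpainted independently (biharmonic) using the valid
    measured positions as boundary data; zero-intensity positions never
    enter the boundary set.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.scan_shape:
        raise ValueError("mask shape must match the scan grid")
    if not mask.any():
        raise ValueError("empty measurement mask")
    sparse = _sparse_com(stack, mask, roi)
    if not sparse.valid.any():
        raise ValueError("no valid (nonzero-intensity) measured positions")

    loc = np.argwhere(sparse.valid)
    filled = []
    for channel in (sparse.comx, sparse.comy):
        m = MeasurementSet(loc, channel[sparse.valid], stack.scan_shape)
        filled.append(biharmonic_inpaint(m).values)
    inpainted = CoMMaps(
        filled[0], filled[1], np.ones(stack.scan_shape, dtype=bool)
    )
    return sparse, inpainted
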