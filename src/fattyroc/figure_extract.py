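"""Recover data points from raster scatter plots.

Published studies in this area rarely release individual-level data, so
comparison distributions have to be digitised from figures: a marker
template (a small patch cut from the plot) is slid over the image with
normalized cross-correlation, correlation peaks above a threshold are
kept after non-maximum suppression, peak positions are refined to
sub-pixel accuracy by a quadratic fit, and pixel centers are mapped to
data units through a two-anchor-per-axis affine calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template, peak_local_max

__all__ = [
    "AxisCalibration",
    "MarkerTemplate",
    "detect_markers",
    "pixels_to_data",
    "data_to_pixels",
    "render_scatter",
    "disc_template",
]


@dataclass
class AxisCalibration:
    """Two pixel<->data anchors per axis.

    Each anchor is ``(pixel_coordinate, data_value)``.  Image rows grow
    downward, so the y map typically has negative slope.
    """

    x_anchors: tuple[tuple[float, float], tuple[float, float]]
    y_anchors: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        for name, ((p0, _), (p1, _)) in (
            ("x", self.x_anchors),
            ("y", self.y_anchors),
        ):
            if p0 == p1:
                raise ValueError(f"degenerate {name}-axis anchors (same pixel)")

    def _maps(self):
        (px0, dx0), (px1, dx1) = self.x_anchors
        (py0, dy0), (py1, dy1) = self.y_anchors
        sx = (dx1 - dx0) / (px1 - px0)
        sy = (dy1 - dy0) / (py1 - py0)
        if not (np.isfinite(sx) and np.isfinite(sy)) or sx == 0 or sy == 0:
            raise ValueError("axis calibration implies a zero or non-finite scale")
        return (px0, dx0, sx), (py0, dy0, sy)


@dataclass
class MarkerTemplate:
    """Grayscale marker patch with detection parameters.

    ``threshold`` is the minimum normalized cross-correlation for a
    detection; ``suppression_radius`` (pixels; default half the template
    width) is the exclusion zone around an accepted peak.
    """

    patch: np.ndarray
    threshold: float = 0.8
    suppression_radius: float | None = None

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=float)
        if self.patch.ndim != 2:
            raise ValueError("template patch must be 2-d grayscale")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.suppression_radius is None:
            self.suppression_radius = max(self.patch.shape) / 2
        if self.patch.std() == 0:
            raise ValueError("template patch is constant; cross-correlation undefined")


def _subpixel_refine(corr: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Quadratic (parabolic) refinement of an interior correlation peak."""
    dr = dc = 0.0
    if 0 < r < corr.shape[0] - 1:
        num = corr[r - 1, c] - corr[r + 1, c]
        den = 2 * (corr[r - 1, c] - 2 * corr[r, c] + corr[r + 1, c])
        if den != 0:
            dr = np.clip(num / den, -0.5, 0.5)
    if 0 < c < corr.shape[1] - 1:
        num = corr[r, c - 1] - corr[r, c + 1]
        den = 2 * (corr[r, c - 1] - 2 * corr[r, c] + corr[r, c + 1])
        if den != 0:
            dc = np.clip(num / den, -0.5, 0.5)
    return r + dr, c + dc


def detect_markers(image, template: MarkerTemplate) -> np.ndarray:
    """Marker centers as an (n, 2) array of (row, col) pixel positions.

    Normalized cross-correlation of the template over the image; local
    maxima at or above the threshold survive greedy non-maximum
    suppression within the suppression radius (two true markers closer
    than that radius collapse to one detection).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-d grayscale")
    th, tw = template.patch.shape
    if th > image.shape[0] or tw > image.shape[1]:
        raise ValueError("template is larger than the image")
    corr = match_template(image, template.patch, pad_input=True)
    peaks = peak_local_max(
        corr,
        min_distance=max(1, int(round(template.suppression_radius))),
        threshold_abs=template.threshold,
        exclude_border=False,
    )
    centers = [_subpixel_refine(corr, r, c) for r, c in peaks]
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def pixels_to_data(centers, cal: AxisCalibration) -> np.ndarray:
    """Map (row, col) pixel centers to (x, y) data coordinates."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    (px0, dx0, sx), (py0, dy0, sy) = cal._maps()
    x = dx0 + (centers[:, 1] - px0) * sx
    y = dy0 + (centers[:, 0] - py0) * sy
    return np.column_stack([x, y])


def data_to_pixels(points, cal: AxisCalibration) -> np.ndarray:
    """Inverse of :func:`pixels_to_data`: (x, y) data -> (row, col)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    (px0, dx0, sx), (py0, dy0, sy) = cal._maps()
    col = px0 + (points[:, 0] - dx0) / sx
    row = py0 + (points[:, 1] - dy0) / sy
    return np.column_stack([row, col])


# ---------------------------------------------------------------------------
# Synthetic rendering (for validation without external figures)
# ---------------------------------------------------------------------------


def disc_template(radius: int = 4) -> np.ndarray:
    """Anti-aliased dark disc on white background, used as a marker."""
    size = 2 * radius + 1
    yy, xx = np.mgrid[:size, :size] - radius
    dist = np.hypot(yy, xx)
    return np.clip(dist - radius + 0.5, 0, 1)  # 0 = ink, 1 = paper


def render_scatter(
    points, cal: AxisCalibration, shape: tuple[int, int], radius: int = 4
) -> np.ndarray:
    """Render data points as dark discs on a white canvas.

    A minimal stand-in for a published scatter figure: the round-trip
    render -> detect -> calibrate validates the extraction machinery.
    """
    img = np.ones(shape, dtype=float)
    disc = disc_template(radius)
    size = disc.shape[0]
    for row, col in data_to_pixels(points, cal):
        r0, c0 = int(round(row)) - radius, int(round(col)) - radius
        if r0 < 0 or c0 < 0 or r0 + size > shape[0] or c0 + size > shape[1]:
            raise ValueError("point renders outside the canvas")
        img[r0 : r0 + size, c0 : c0 + size] = np.minimum(
            img[r0 : r0 + size, c0 : c0 + size], disc
        )
    return img
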