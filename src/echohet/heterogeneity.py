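"""Core heterogeneity quantification.

The heterogeneity score of a region of interest is its coefficient of
variation, in percent::

    score = SD(intensities) / mean(intensities) * 100

with the sample standard deviation (divisor n - 1).  For clinical ROIs of
thousands of pixels the n vs n-1 choice is numerically immaterial (< 0.1%
relative), and sample SD is the standard CV convention; all oracles in the
test suite use the same choice.

The per-pixel heterogeneity map redistributes that regional score over the
ROI: each pixel with intensity v > 0 gets ``score / v * 100``, so darker
pixels — the ones deviating most from a bright homogeneous parenchyma —
light up.  Pixels with v = 0 contribute to the score (they are real data)
but the map is undefined there (division by zero); they are tracked
explicitly and excluded from any map summary.

Rasterization contract: a pixel belongs to an ROI iff its center (integer
row, col) lies inside the closed polygon or exactly on its boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import DegenerateROIError, ROIValidationError, UndefinedScoreError
from .image_io import ROIPolygon, USImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROIMask:
    """Boolean raster of one ROI polygon, congruent with its image."""

    mask: np.ndarray
    source_polygon: ROIPolygon | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if int(m.sum()) < 2:
            raise DegenerateROIError(
                "ROI covers fewer than 2 pixel centers; no dispersion is defined"
            )
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def label(self) -> str:
        return self.source_polygon.label if self.source_polygon else "nodule"


@dataclass(frozen=True)
class HeterogeneityResult:
    """Heterogeneity score of one ROI on one image.

    ``score_pct`` is the percent coefficient of variation; the identity
    ``score_pct * mean_intensity == 100 * sd_intensity`` holds to floating
    tolerance.
    """

    score_pct: float
    mean_intensity: float
    sd_intensity: float
    n_pixels: int
    roi_label: str = "nodule"


@dataclass(frozen=True)
class HeterogeneityMap:
    """Per-pixel heterogeneity map over one ROI.

    ``values`` is a full-frame float array, NaN outside the ROI and at
    zero-intensity ROI pixels; ``undefined_pixels`` lists the (row, col) of
    the latter.  ``cv_pct`` is the ROI score used as the numerator.
    """

    values: np.ndarray
    undefined_pixels: np.ndarray  # (k, 2) int array of (row, col)
    cv_pct: float
    mask: np.ndarray

    @property
    def defined_mask(self) -> np.ndarray:
        return self.mask & np.isfinite(self.values)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def rasterize_polygon(
    polygon: ROIPolygon, image_shape: tuple[int, int]
) -> ROIMask:
    """Rasterize a polygon: pixel centers inside or on the boundary.

    Vertices are (row, col) with the origin at the top-left pixel center;
    the decision at each integer pixel center is made by an exact geometric
    point-in-polygon predicate, so boundary pixels are deterministically
    included.
    """
    polygon.validate_bounds(image_shape)
    # shapely works in (x, y) = (col, row)
    xy = [(c, r) for r, c in polygon.vertices]
    poly = ShapelyPolygon(xy)
    if shapely.MultiPoint(xy).convex_hull.area == 0.0:
        raise DegenerateROIError("polygon has zero area (collinear vertices)")
    if not poly.is_valid:
        raise ROIValidationError("polygon is self-intersecting")

    h, w = image_shape
    minx, miny, maxx, maxy = poly.bounds
    r0, r1 = max(0, math.ceil(miny - 1e-12)), min(h - 1, math.floor(maxy + 1e-12))
    c0, c1 = max(0, math.ceil(minx - 1e-12)), min(w - 1, math.floor(maxx + 1e-12))
    mask = np.zeros(image_shape, dtype=bool)
    if r1 >= r0 and c1 >= c0:
        rr, cc = np.meshgrid(
            np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
        )
        inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel())
        mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    if int(mask.sum()) < 2:
        raise DegenerateROIError("polygon rasterizes to fewer than 2 pixels")
    return ROIMask(mask=mask, source_polygon=polygon)


# ---------------------------------------------------------------------------
# Score and map
# ---------------------------------------------------------------------------


def _roi_values(image: USImage, roi: ROIMask) -> np.ndarray:
    if roi.mask.shape != image.shape:
        raise ValueError(
            f"mask shape {roi.mask.shape} does not match image shape {image.shape}"
        )
    return image.pixels[roi.mask].astype(np.float64)


def compute_score(image: USImage, roi: ROIMask) -> HeterogeneityResult:
    """Heterogeneity score (percent CV, sample SD) of the ROI pixels."""
    vals = _roi_values(image, roi)
    mean = float(vals.mean())
    if mean == 0.0:
        raise UndefinedScoreError(
            "ROI mean intensity is zero; the CV denominator is undefined"
        )
    sd = float(vals.std(ddof=1))
    return HeterogeneityResult(
        score_pct=sd / mean * 100.0,
        mean_intensity=mean,
        sd_intensity=sd,
        n_pixels=roi.n_pixels,
        roi_label=roi.label,
    )


def compute_map(image: USImage, roi: ROIMask) -> HeterogeneityMap:
    """Per-pixel heterogeneity map: ROI CV divided by each pixel value, x100.

    Zero-intensity pixels inside the ROI are recorded as undefined rather
    than mapped (they would divide by zero); they still participate in the
    CV itself.
    """
    result = compute_score(image, roi)
    values = np.full(image.shape, np.nan)
    px = image.pixels.astype(np.float64)
    defined = roi.mask & (px > 0)
    values[defined] = result.score_pct / px[defined] * 100.0
    undefined = np.argwhere(roi.mask & (px == 0))
    return HeterogeneityMap(
        values=values,
        undefined_pixels=undefined,
        cv_pct=result.score_pct,
        mask=roi.mask,
    )


def aggregate_patient(
    results: Sequence[HeterogeneityResult], roi_label: str
) -> float:
    """Patient-level score: unweighted arithmetic mean across measurements.

    Clinical practice is two or three frames per patient; other list lengths
    are accepted with a warning.  All inputs must carry the same ROI label.
    """
    if not results:
        raise ValueError("cannot aggregate an empty list of results")
    labels = {r.roi_label for r in results}
    if labels != {roi_label}:
        raise ValueError(
            f"mixed or mismatched ROI labels {sorted(labels)}; expected {roi_label!r}"
        )
    if len(results) not in (2, 3):
        logger.warning(
            "aggregating %d measurements; typical practice is 2-3 frames per patient",
            len(results),
        )
    return float(np.mean([r.score_pct for r in results]))
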