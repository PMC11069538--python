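"""Synthetic speckle images and score-level cohorts.

No patient images accompany the study conditions this package targets, so
two generators make every pipeline stage testable end to end:

* **Speckle ROIs** — i.i.d. pixel intensities with a prescribed population
  mean and coefficient of variation.  The default gamma model is
  non-negative and right-skewed like B-mode amplitude speckle, and its CV is
  fixed entirely by the shape parameter, ``k = (100 / CV%)**2``; a lognormal
  alternative is provided.  This emulates only the first two intensity
  moments that the heterogeneity score measures — no point-spread function,
  attenuation or log-compression physics, and no spatial correlation.

* **Score-level cohorts** — patient heterogeneity scores drawn per group
  from a normal distribution truncated at zero, parameterized by the group
  mean/SD.  Defaults are the published cohort conditions: normal parenchyma
  11.74 +/- 2.84 (n=32), II-B 25.02 +/- 5.82 (n=24), III-B 32.04 +/- 10.34
  (n=52), III-M 39.93 +/- 14.79 (n=54), V/VI-M 41.30 +/- 16.12 (n=58).

All generators are bit-reproducible for a fixed seed (NumPy PCG64).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import EchoHetError
from .heterogeneity import rasterize_polygon
from .image_io import Photometric, ROIPolygon, USImage
from .stats import make_cohort

import pandas as pd

logger = logging.getLogger(__name__)

#: Fraction of pixels clipped at the bit-depth ceiling above which the
#: generator warns that the requested moments are being distorted.
CLIP_WARN_FRACTION = 1e-3


@dataclass(frozen=True)
class SpeckleSpec:
    """Specification of one homogeneous speckle region.

    ``target_cv_pct`` is the population coefficient of variation in percent;
    ``mean_intensity`` the population mean on the image intensity scale.
    """

    target_cv_pct: float
    n_pixels: int | None = None
    shape: tuple[int, int] | None = None
    mean_intensity: float = 100.0
    seed: int = 0
    distribution: str = "gamma"
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.target_cv_pct < 0:
            raise EchoHetError("target_cv_pct must be non-negative")
        if self.mean_intensity <= 0:
            raise EchoHetError("mean_intensity must be positive")
        if self.distribution not in ("gamma", "lognormal"):
            raise EchoHetError(f"unknown distribution {self.distribution!r}")
        if (self.n_pixels is None) == (self.shape is None):
            raise EchoHetError("specify exactly one of n_pixels or shape")

    @property
    def size(self) -> int:
        if self.n_pixels is not None:
            return self.n_pixels
        h, w = self.shape  # type: ignore[misc]
        return h * w


@dataclass(frozen=True)
class GroupSpec:
    """Score-distribution parameters of one patient group."""

    group: str
    mean_score: float
    sd_score: float
    n_patients: int

    def __post_init__(self) -> None:
        if self.sd_score < 0:
            raise EchoHetError("sd_score must be non-negative")
        if self.n_patients < 1:
            raise EchoHetError("n_patients must be at least 1")


#: Published cohort conditions: group score mean/SD and group sizes.
DEFAULT_GROUP_SPECS: tuple[GroupSpec, ...] = (
    GroupSpec("normal", 11.74, 2.84, 32),
    GroupSpec("II-B", 25.02, 5.82, 24),
    GroupSpec("III-B", 32.04, 10.34, 52),
    GroupSpec("III-M", 39.93, 14.79, 54),
    GroupSpec("V/VI-M", 41.30, 16.12, 58),
)


def generate_speckle_roi(
    spec: SpeckleSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw i.i.d. speckle intensities with the prescribed mean and CV.

    Gamma: shape ``k = (100/CV)**2``, scale ``mean/k``.  Lognormal: sigma^2 =
    ln(1 + (CV/100)^2), mu chosen so the arithmetic mean is ``mean``.  Values
    are clipped to [0, 2**bit_depth - 1]; the clipped fraction is logged and
    a warning is raised when it exceeds 0.1%, since clipping biases the
    realized moments.  ``target_cv_pct == 0`` returns constant pixels.

    Returns a float array shaped per the spec (flat for ``n_pixels``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.size
    cv = spec.target_cv_pct / 100.0
    if cv == 0.0:
        out = np.full(n, float(spec.mean_intensity))
    elif spec.distribution == "gamma":
        k = 1.0 / cv**2  # == (100 / target_cv_pct) ** 2
        out = rng.gamma(shape=k, scale=spec.mean_intensity / k, size=n)
    else:  # lognormal
        sigma2 = np.log1p(cv**2)
        mu = np.log(spec.mean_intensity) - sigma2 / 2.0
        out = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)

    vmax = 2.0**spec.bit_depth - 1.0
    clipped = int(np.count_nonzero((out < 0) | (out > vmax)))
    frac = clipped / n
    if frac > 0:
        logger.info("clipped %d/%d pixels (%.4f%%)", clipped, n, 100 * frac)
    if frac >= CLIP_WARN_FRACTION:
        logger.warning(
            "clipping fraction %.3f%% exceeds 0.1%%; realized mean/CV will be "
            "biased below the spec",
            100 * frac,
        )
    out = np.clip(out, 0.0, vmax)
    if spec.shape is not None:
        out = out.reshape(spec.shape)
    return out


def _ellipse_polygon(
    center: tuple[float, float],
    axes: tuple[float, float],
    label: str,
    image_ref: str,
    n_vertices: int = 64,
) -> ROIPolygon:
    cr, cc = center
    ar, ac = axes
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    vertices = np.column_stack([cr + ar * np.sin(theta), cc + ac * np.cos(theta)])
    # snap to multiples of 1/256: dyadic coordinates are exact doubles, so a
    # whole-pixel translation of the polygon is bitwise-exact and the nodule
    # and normal masks rasterize to identical pixel counts
    vertices = np.round(vertices * 256.0) / 256.0
    return ROIPolygon(vertices=vertices, label=label, image_ref=image_ref)


def embed_nodule(
    background_spec: SpeckleSpec,
    nodule_spec: SpeckleSpec,
    center: tuple[float, float],
    axes: tuple[float, float],
    normal_center: tuple[float, float] | None = None,
    source_id: str = "synthetic:embed_nodule",
) -> tuple[USImage, tuple[ROIPolygon, ROIPolygon]]:
    """Build a frame with an elliptical "nodule" embedded in background
    speckle, plus the matched ROI pair.

    The elliptical interior (pixel centers inside the traced polygon)
    follows ``nodule_spec``, the exterior ``background_spec``.  The returned
    polygons are the nodule ellipse and a congruent "normal" ellipse placed
    in the background — translated by a whole number of pixels, so the two
    rasterized masks cover identical pixel counts, mirroring the practice of
    drawing an equal-sized reference region in normal parenchyma.

    ``background_spec.shape`` fixes the frame size; by default the normal
    ellipse is mirrored horizontally about the frame midline.
    """
    if background_spec.shape is None:
        raise EchoHetError("background_spec must carry the frame shape")
    h, w = background_spec.shape
    cr, cc = center
    ar, ac = axes
    if not (ar + 2 <= cr <= h - 1 - ar - 2 and ac + 2 <= cc <= w - 1 - ac - 2):
        raise EchoHetError("ellipse does not fit in the frame with a 2-px margin")
    if normal_center is None:
        normal_center = (cr, w - 1 - cc)
    # integer translation => congruent rasterization
    dr, dc = round(normal_center[0] - cr), round(normal_center[1] - cc)
    ncr, ncc = cr + dr, cc + dc
    if not (ar + 2 <= ncr <= h - 1 - ar - 2 and ac + 2 <= ncc <= w - 1 - ac - 2):
        raise EchoHetError("normal ROI ellipse does not fit in the frame")
    if abs(ncr - cr) < 2 * ar + 2 and abs(ncc - cc) < 2 * ac + 2:
        raise EchoHetError("normal ROI overlaps the nodule; move it")

    nodule_poly = _ellipse_polygon(center, axes, "nodule", source_id)
    normal_poly = ROIPolygon(
        vertices=nodule_poly.vertices + np.array([dr, dc], dtype=float),
        label="normal",
        image_ref=source_id,
    )

    background = generate_speckle_roi(background_spec)
    inner = rasterize_polygon(nodule_poly, (h, w)).mask
    nodule_pixels = generate_speckle_roi(
        replace(nodule_spec, n_pixels=int(inner.sum()), shape=None)
    )
    frame = background.copy()
    frame[inner] = nodule_pixels

    vmax = 2**background_spec.bit_depth - 1
    pixels = np.clip(np.rint(frame), 0, vmax).astype(
        np.uint8 if background_spec.bit_depth == 8 else np.uint16
    )
    image = USImage(
        pixels, background_spec.bit_depth, source_id, Photometric.MONOCHROME
    )
    return image, (nodule_poly, normal_poly)


def generate_cohort(
    group_specs: Sequence[GroupSpec] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw a patient-level score cohort.

    Scores are sampled per group from a normal distribution truncated at
    zero with the group's mean/SD (``sd == 0`` degenerates to the constant
    mean).  Group order and sample counts follow the specs; patient ids are
    sequential and unique across the cohort.
    """
    specs = tuple(group_specs) if group_specs is not None else DEFAULT_GROUP_SPECS
    rng = np.random.default_rng(seed)
    records = []
    pid = 0
    for spec in specs:
        if spec.sd_score == 0:
            scores = np.full(spec.n_patients, spec.mean_score)
        else:
            a = (0.0 - spec.mean_score) / spec.sd_score
            scores = sps.truncnorm.rvs(
                a,
                np.inf,
                loc=spec.mean_score,
                scale=spec.sd_score,
                size=spec.n_patients,
                random_state=rng,
            )
        for s in scores:
            pid += 1
            records.append(
                {
                    "patient_id": f"P{pid:04d}",
                    "group": spec.group,
                    "score_pct": float(s),
                }
            )
    return make_cohort(pd.DataFrame.from_records(records))
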