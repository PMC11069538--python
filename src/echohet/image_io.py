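"""Reading ultrasound frames and ROI definitions; writing score tables and
color-map overlays.

Images are single-frame grayscale B-mode ultrasound frames, read from DICOM
(the clinical source format) or from 8/16-bit PNG/TIFF (so synthetic and test
data need no DICOM encoder).  Pixel intensities are used exactly as stored:
no rescale slope/intercept, no windowing.  The heterogeneity score is a
coefficient of variation and therefore invariant under any linear rescale,
so such preprocessing could not change a result.

ROIs are closed polygons in 0-based (row, col) pixel coordinates with the
origin at the *center* of the top-left pixel; fractional vertices are
allowed.  They are persisted as a small JSON schema::

    {"image_ref": "<source id>",
     "rois": [{"label": "nodule"|"normal", "vertices": [[row, col], ...]}]}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import pydicom
from matplotlib import colormaps
from PIL import Image, UnidentifiedImageError

from .errors import FormatError, ROIValidationError, UnsupportedContentError

if TYPE_CHECKING:  # pragma: no cover
    from .heterogeneity import HeterogeneityMap

#: ITU-R BT.601 luma weights used to collapse RGB payloads to grayscale.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Column order of the score CSV emitted by the tool.
SCORE_COLUMNS = [
    "patient_id",
    "image_id",
    "roi_label",
    "n_pixels",
    "mean",
    "sd",
    "heterogeneity_pct",
]

ROI_LABELS = ("nodule", "normal")

#: Color reserved for zero-intensity ROI pixels, where the per-pixel map is
#: undefined.  Magenta does not occur in the default "jet" ramp.
SENTINEL_COLOR = (255, 0, 255)


class Photometric(str, Enum):
    MONOCHROME = "monochrome"
    RGB_CONVERTED = "rgb-converted"


@dataclass(frozen=True)
class USImage:
    """A single grayscale ultrasound frame.

    Parameters
    ----------
    pixels : ndarray of shape (height, width)
        Non-negative integer intensities, bounded by the bit depth.
    bit_depth : int
        8 or 16.
    source_id : str
        File path or synthetic tag; referenced by ROI files.
    photometric : Photometric
        Whether the frame was stored as grayscale or converted from RGB.
    """

    pixels: np.ndarray
    bit_depth: int
    source_id: str = ""
    photometric: Photometric = Photometric.MONOCHROME

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.size and (px.min() < 0 or px.max() > 2**self.bit_depth - 1):
            raise ValueError("pixel values outside the bit-depth range")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ROIPolygon:
    """A closed vertex chain delimiting a region of interest.

    ``vertices`` is an (n, 2) float array of (row, col) pairs; the polygon is
    implicitly closed from the last vertex back to the first.  ``label``
    distinguishes the nodule contour from the equal-sized reference region
    drawn in the surrounding normal parenchyma.
    """

    vertices: np.ndarray
    label: str = "nodule"
    image_ref: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ROIValidationError("vertices must be an (n, 2) array of (row, col)")
        if v.shape[0] < 3:
            raise ROIValidationError(
                f"a polygon needs at least 3 vertices, got {v.shape[0]}"
            )
        if not np.all(np.isfinite(v)):
            raise ROIValidationError("vertices must be finite")
        if self.label not in ROI_LABELS:
            raise ROIValidationError(
                f"label must be one of {ROI_LABELS}, got {self.label!r}"
            )
        object.__setattr__(self, "vertices", v)

    def validate_bounds(self, image_shape: tuple[int, int]) -> None:
        """Check every vertex lies within the pixel-center grid of an image.

        Raises :class:`ROIValidationError` naming the first offending vertex.
        """
        h, w = image_shape
        for i, (r, c) in enumerate(self.vertices):
            if not (0.0 <= r <= h - 1 and 0.0 <= c <= w - 1):
                raise ROIValidationError(
                    f"vertex {i} at (row={r}, col={c}) outside image bounds "
                    f"{h}x{w}"
                )


# ---------------------------------------------------------------------------
# Image reading
# ---------------------------------------------------------------------------


def _rgb_to_gray(rgb: np.ndarray, bit_depth: int) -> np.ndarray:
    """Collapse an (h, w, 3) array to grayscale with BT.601 luma weights,
    rounded to the nearest representable intensity at the source bit depth."""
    w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
    gray = np.tensordot(rgb.astype(np.float64), w, axes=([-1], [0]))
    gray = np.clip(np.rint(gray), 0, 2**bit_depth - 1)
    return gray.astype(np.uint8 if bit_depth == 8 else np.uint16)


def _read_dicom(path: Path) -> USImage:
    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:  # pydicom raises a zoo of parse errors
        raise FormatError(f"could not read DICOM file {path}: {exc}") from exc

    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames > 1:
        raise UnsupportedContentError(
            f"{path}: multi-frame DICOM ({n_frames} frames) is not supported"
        )
    bits = int(getattr(ds, "BitsAllocated", 8))
    if bits not in (8, 16):
        raise UnsupportedContentError(f"{path}: unsupported bit depth {bits}")

    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if photometric == "RGB":
        if arr.ndim != 3 or arr.shape[-1] != 3:
            raise UnsupportedContentError(f"{path}: malformed RGB payload")
        pixels = _rgb_to_gray(arr, bits)
        return USImage(pixels, bits, str(path), Photometric.RGB_CONVERTED)
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise UnsupportedContentError(
            f"{path}: unsupported photometric interpretation {photometric!r}"
        )
    if arr.ndim != 2:
        raise UnsupportedContentError(f"{path}: expected a single 2-D frame")
    pixels = np.asarray(arr)
    if photometric == "MONOCHROME1":
        # MONOCHROME1 stores inverted video; normalize to MONOCHROME2.
        pixels = (2**bits - 1) - pixels
    return USImage(pixels, bits, str(path), Photometric.MONOCHROME)


def _read_pil(path: Path) -> USImage:
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("RGB", "RGBA"):
                arr = np.asarray(im.convert("RGB"))
                return USImage(
                    _rgb_to_gray(arr, 8), 8, str(path), Photometric.RGB_CONVERTED
                )
            if mode == "L":
                return USImage(np.asarray(im), 8, str(path))
            if mode in ("I;16", "I;16B", "I"):
                arr = np.asarray(im).astype(np.int64)
                if arr.min() < 0 or arr.max() > 65535:
                    raise UnsupportedContentError(
                        f"{path}: integer image exceeds 16-bit range"
                    )
                return USImage(arr.astype(np.uint16), 16, str(path))
            raise UnsupportedContentError(f"{path}: unsupported PIL mode {mode!r}")
    except UnidentifiedImageError as exc:
        raise FormatError(f"could not identify image format of {path}") from exc


def read_image(path: str | Path) -> USImage:
    """Read a single-frame ultrasound image from DICOM, PNG or TIFF.

    RGB payloads are converted to grayscale with the BT.601 luma weights
    (0.299, 0.587, 0.114) and rounded back to the source bit depth.
    MONOCHROME1 DICOM frames are inverted to MONOCHROME2 convention.
    Multi-frame DICOM is rejected.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such file: {path}")
    if pydicom.misc.is_dicom(str(path)):
        return _read_dicom(path)
    return _read_pil(path)


# ---------------------------------------------------------------------------
# ROI files
# ---------------------------------------------------------------------------


def read_roi_file(
    path: str | Path, image_shape: tuple[int, int] | None = None
) -> list[ROIPolygon]:
    """Read all ROI polygons from one JSON file.

    Each polygon is validated against the ROI contract (>= 3 vertices, known
    label); if ``image_shape`` is given, every vertex is also checked against
    the image bounds and the first offending vertex index is reported.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"could not read ROI file {path}: {exc}") from exc

    if not isinstance(doc, dict) or "rois" not in doc:
        raise FormatError(f"{path}: not an ROI file (missing 'rois' key)")
    image_ref = str(doc.get("image_ref", ""))
    polygons = []
    for entry in doc["rois"]:
        poly = ROIPolygon(
            vertices=np.asarray(entry["vertices"], dtype=float),
            label=entry["label"],
            image_ref=image_ref,
        )
        if image_shape is not None:
            poly.validate_bounds(image_shape)
        polygons.append(poly)
    return polygons


def write_roi_file(
    polygons: Sequence[ROIPolygon], path: str | Path, image_ref: str | None = None
) -> None:
    """Persist polygons to the ROI JSON schema.

    Vertices are written at full float precision, so a write/read round trip
    is exact.
    """
    if image_ref is None:
        refs = {p.image_ref for p in polygons}
        if len(refs) != 1:
            raise ValueError("polygons reference multiple images; pass image_ref")
        image_ref = refs.pop()
    doc = {
        "image_ref": image_ref,
        "rois": [
            {"label": p.label, "vertices": [[float(r), float(c)] for r, c in p.vertices]}
            for p in polygons
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------


def scores_to_frame(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble score records into the canonical score table."""
    df = pd.DataFrame(list(rows))
    for col in SCORE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[SCORE_COLUMNS]


def write_scores_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Overlay rendering
# ---------------------------------------------------------------------------


def _background_rgb(image: USImage) -> np.ndarray:
    """Grayscale background as an 8-bit RGB array."""
    px = image.pixels.astype(np.float64)
    if image.bit_depth == 16:
        px = px / 65535.0 * 255.0
    bg = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    return np.repeat(bg[:, :, None], 3, axis=2)


def render_overlay(
    image: USImage,
    hmap: "HeterogeneityMap",
    cmap: str = "jet",
    colorbar: bool = True,
    colorbar_width: int = 12,
) -> np.ndarray:
    """Render a heterogeneity map as an 8-bit RGB overlay.

    The grayscale frame is the background; inside the ROI each defined map
    value is colored by its position on the ``cmap`` ramp, linearly scaled
    between the ROI's own min and max map value (a constant map renders as
    the ramp minimum).  Zero-intensity pixels, where the map is undefined,
    get the reserved sentinel color.  A vertical colorbar strip (ramp maximum
    at the top) is appended on the right unless ``colorbar`` is False.
    Pixels outside the ROI are never altered.
    """
    if hmap.values.shape != image.shape:
        raise ValueError("map was not computed on this image")
    ramp = colormaps[cmap]
    rgb = _background_rgb(image)

    defined = hmap.defined_mask
    if defined.any():
        vals = hmap.values[defined]
        vmin, vmax = float(vals.min()), float(vals.max())
        frac = np.zeros_like(vals) if vmax == vmin else (vals - vmin) / (vmax - vmin)
        colors = (np.asarray(ramp(frac))[:, :3] * 255).round().astype(np.uint8)
        rgb[defined] = colors
    for r, c in hmap.undefined_pixels:
        rgb[r, c] = SENTINEL_COLOR

    if colorbar:
        h = rgb.shape[0]
        gap = np.full((h, 2, 3), 255, dtype=np.uint8)
        ramp_frac = np.linspace(1.0, 0.0, h)
        strip_col = (np.asarray(ramp(ramp_frac))[:, :3] * 255).round().astype(np.uint8)
        strip = np.repeat(strip_col[:, None, :], colorbar_width, axis=1)
        rgb = np.concatenate([rgb, gap, strip], axis=1)
    return rgb


def write_overlay(
    image: USImage, hmap: "HeterogeneityMap", path: str | Path, cmap: str = "jet"
) -> None:
    """Write the rendered overlay (see :func:`render_overlay`) as an RGB PNG."""
    rgb = render_overlay(image, hmap, cmap=cmap)
    try:
        Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
    except OSError as exc:
        raise OSError(f"could not write overlay to {path}: {exc}") from exc
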