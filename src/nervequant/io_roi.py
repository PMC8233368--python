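"""Frames, regions of interest, and their file formats.

A :class:`Frame` is an 8-bit raster ultrasound still (grayscale B-mode or RGB
color Doppler) plus an optional pixel-area calibration in mm² per pixel.
Regions of interest are operator-drawn polygons, stored either as JSON
(``{"vertices": [[x, y], ...], "label": "..."}``) or as ImageJ ``.roi`` files
(polygon/freehand subtypes only).

Coordinate convention: x = column, y = row, origin at the top-left corner;
pixel (x, y) covers the unit square [x, x+1) × [y, y+1) and its center is
(x + 0.5, y + 0.5). Rasterization includes a pixel iff its center lies
strictly inside the polygon.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from shapely import contains_xy
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import FormatError, ValidationError

__all__ = [
    "Frame",
    "RoiPolygon",
    "BinaryMask",
    "read_image",
    "write_image",
    "read_roi",
    "write_roi_json",
    "write_imagej_roi",
    "rasterize_roi",
    "to_gray_8bit",
]

#: Default pixel-area calibration in mm² per pixel (probe/depth dependent;
#: this default matches a 5–16 MHz linear probe at typical nerve depth).
DEFAULT_PIXEL_AREA_MM2 = 0.004017

_MODALITIES = ("bmode", "doppler")


@dataclass(frozen=True)
class Frame:
    """An 8-bit ultrasound still frame.

    Parameters
    ----------
    pixels
        ``(H, W)`` uint8 array for grayscale, ``(H, W, 3)`` for RGB.
    pixel_area
        Calibration in mm² per pixel, ``None`` if unknown.
    modality
        ``"bmode"`` (grayscale anatomy) or ``"doppler"`` (RGB color overlay).
        Doppler frames must carry three channels.
    """

    pixels: np.ndarray
    pixel_area: float | None = None
    modality: str = "bmode"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            if px.size and (px.min() < 0 or px.max() > 255):
                raise ValidationError("frame intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if px.ndim == 3 and px.shape[2] != 3:
            raise FormatError(f"expected 3 channels, got {px.shape[2]}")
        if px.ndim not in (2, 3):
            raise FormatError(f"expected 2-D or 3-D pixel array, got {px.ndim}-D")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("frame must have H >= 1 and W >= 1")
        if self.modality not in _MODALITIES:
            raise ValidationError(f"modality must be one of {_MODALITIES}")
        if self.modality == "doppler" and px.ndim != 3:
            raise FormatError("doppler frames require 3 channels")
        if self.pixel_area is not None and not self.pixel_area > 0:
            raise ValidationError("pixel_area must be > 0 mm^2")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the raster."""
        return self.pixels.shape[:2]

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3


@dataclass(frozen=True)
class RoiPolygon:
    """Operator-drawn region of interest as an ordered vertex list."""

    vertices: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValidationError(
                f"a polygon ROI needs at least 3 vertices, got {len(verts)}"
            )
        object.__setattr__(self, "vertices", verts)

    def as_shapely(self) -> _ShapelyPolygon:
        poly = _ShapelyPolygon(self.vertices)
        if not poly.is_valid:
            raise ValidationError("ROI polygon is not simple (self-intersecting)")
        return poly


@dataclass(frozen=True)
class BinaryMask:
    """Boolean pixel mask sharing the shape of its source frame."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2:
            raise ValidationError("mask must be 2-D")
        object.__setattr__(self, "pixels", px)

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


# ---------------------------------------------------------------------------
# image I/O


def read_image(
    path: str | Path,
    pixel_area: float | None = None,
    modality: str | None = None,
) -> Frame:
    """Read an 8-bit PNG or TIFF into a :class:`Frame`, bit-exactly.

    16-bit and float inputs are rejected rather than rescaled: silent
    rescaling would shift every threshold downstream. If ``modality`` is not
    given, grayscale files are tagged ``bmode`` and RGB files ``doppler``.
    A sidecar ``<stem>.calib.json`` with ``{"pixel_area_mm2": x}`` supplies
    calibration when ``pixel_area`` is not passed.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("I", "I;16", "I;16B", "I;16L", "F"):
                raise FormatError(
                    f"{path.name}: unsupported bit depth ({mode}); only 8-bit "
                    "images are accepted"
                )
            if mode not in ("L", "RGB"):
                raise FormatError(
                    f"{path.name}: unsupported channel layout ({mode}); expected "
                    "8-bit grayscale (L) or RGB"
                )
            arr = np.asarray(im, dtype=np.uint8)
    except FormatError:
        raise
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc

    if pixel_area is None:
        sidecar = path.with_suffix(".calib.json")
        if sidecar.exists():
            pixel_area = json.loads(sidecar.read_text()).get("pixel_area_mm2")
    if modality is None:
        modality = "doppler" if arr.ndim == 3 else "bmode"
    return Frame(arr, pixel_area=pixel_area, modality=modality)


def write_image(path: str | Path, frame: Frame) -> None:
    """Write a frame as 8-bit PNG or TIFF (chosen by file suffix), losslessly."""
    path = Path(path)
    im = Image.fromarray(frame.pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        im.save(path, format="TIFF")
    else:
        im.save(path, format="PNG")


# ---------------------------------------------------------------------------
# ROI I/O

# ImageJ .roi binary layout constants (fixed 64-byte header, "Iout" magic).
_IJ_MAGIC = b"Iout"
_IJ_POLYGON = 0
_IJ_FREEHAND = 7
_IJ_SUBTYPE_NAMES = {
    1: "rectangle",
    2: "oval",
    3: "line",
    4: "freeline",
    5: "polyline",
    6: "no-roi",
    8: "traced",
    9: "angle",
    10: "point",
}


def read_roi(path: str | Path) -> RoiPolygon:
    """Read a JSON or ImageJ ``.roi`` polygon.

    JSON: ``{"vertices": [[x, y], ...], "label": "..."}``. ImageJ ``.roi``:
    polygon and freehand subtypes only; integer vertex coordinates are taken
    as-is in this package's x=column / y=row convention.
    """
    path = Path(path)
    if path.suffix.lower() == ".roi":
        return _read_imagej_roi(path)
    data = json.loads(path.read_text())
    if "vertices" not in data:
        raise ValidationError(f"{path.name}: JSON ROI must contain 'vertices'")
    return RoiPolygon(
        tuple((v[0], v[1]) for v in data["vertices"]),
        label=data.get("label", ""),
    )


def _read_imagej_roi(path: Path) -> RoiPolygon:
    raw = path.read_bytes()
    if len(raw) < 64 or raw[:4] != _IJ_MAGIC:
        raise FormatError(f"{path.name}: not an ImageJ .roi file")
    roi_type = raw[6]
    if roi_type not in (_IJ_POLYGON, _IJ_FREEHAND):
        name = _IJ_SUBTYPE_NAMES.get(roi_type, f"type {roi_type}")
        raise FormatError(
            f"{path.name}: unsupported ROI subtype ({name}); only polygon and "
            "freehand outlines are accepted"
        )
    top, left, _bottom, _right, n = struct.unpack(">hhhhh", raw[8:18])
    if n < 3:
        raise ValidationError(f"{path.name}: polygon ROI has {n} < 3 vertices")
    xs = struct.unpack(f">{n}h", raw[64 : 64 + 2 * n])
    ys = struct.unpack(f">{n}h", raw[64 + 2 * n : 64 + 4 * n])
    verts = tuple((float(x + left), float(y + top)) for x, y in zip(xs, ys))
    return RoiPolygon(verts, label=path.stem)


def write_imagej_roi(path: str | Path, roi: RoiPolygon) -> None:
    """Write a polygon as a minimal ImageJ ``.roi`` file (integer coordinates)."""
    xs = [int(round(x)) for x, _ in roi.vertices]
    ys = [int(round(y)) for _, y in roi.vertices]
    left, top = min(xs), min(ys)
    right, bottom = max(xs), max(ys)
    n = len(xs)
    header = bytearray(64)
    header[:4] = _IJ_MAGIC
    struct.pack_into(">h", header, 4, 227)  # version, as written by ImageJ 1.52
    header[6] = _IJ_POLYGON
    struct.pack_into(">hhhhh", header, 8, top, left, bottom, right, n)
    body = struct.pack(f">{n}h", *(x - left for x in xs)) + struct.pack(
        f">{n}h", *(y - top for y in ys)
    )
    Path(path).write_bytes(bytes(header) + body)


def write_roi_json(path: str | Path, roi: RoiPolygon) -> None:
    Path(path).write_text(
        json.dumps({"vertices": [list(v) for v in roi.vertices], "label": roi.label})
    )


# ---------------------------------------------------------------------------
# rasterization and grayscale conversion


def rasterize_roi(roi: RoiPolygon, shape: tuple[int, int]) -> BinaryMask:
    """Rasterize a polygon: pixel (x, y) is inside iff its center
    (x+0.5, y+0.5) lies strictly inside the polygon.

    A polygon entirely outside the frame yields an empty mask with a warning,
    not an error (the frame may simply be the wrong one of a batch).
    """
    h, w = int(shape[0]), int(shape[1])
    if h < 1 or w < 1:
        raise ValidationError("shape must be positive")
    poly = roi.as_shapely()
    mask = np.zeros((h, w), dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(int(np.floor(minx - 0.5)), 0)
    y0 = max(int(np.floor(miny - 0.5)), 0)
    x1 = min(int(np.ceil(maxx + 0.5)), w)
    y1 = min(int(np.ceil(maxy + 0.5)), h)
    if x0 < x1 and y0 < y1:
        xs = np.arange(x0, x1) + 0.5
        ys = np.arange(y0, y1) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        mask[y0:y1, x0:x1] = contains_xy(poly, gx, gy)
    result = BinaryMask(mask)
    if result.area_px == 0:
        warnings.warn(
            f"ROI '{roi.label}' rasterizes to an empty mask on a {h}x{w} frame",
            stacklevel=2,
        )
    return result


def to_gray_8bit(frame: Frame) -> Frame:
    """Collapse RGB to 8-bit grayscale by the unweighted channel mean,
    rounded half-up. Grayscale input is returned unchanged."""
    if not frame.is_color:
        return frame
    mean = frame.pixels.astype(np.float64).mean(axis=2)
    gray = np.clip(np.floor(mean + 0.5), 0, 255).astype(np.uint8)
    return Frame(gray, pixel_area=frame.pixel_area, modality="bmode")
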