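"""Reading plate scans and reading/writing per-plate colony-size text files.

A plate scan is an 8-bit RGB raster of a single round culture dish, usually
produced by a flatbed scanner. The scan resolution (dots per inch) is read
from the image metadata when present; it drives the resolution-dependent
defaults of the counting pipeline, and converts pixel areas to mm².

Colony sizes are exchanged as plain UTF-8 text: comment-prefixed header
lines (plate id, unit, parameter summary), then one area per line in
detection order. Bare one-number-per-line files are accepted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import InputError, ParseError, ValidationError

UNKNOWN_DPI = "unknown"

#: valid units for colony areas
UNITS = ("pixel^2", "mm^2")


@dataclass
class PlateImage:
    """One scanned dish: an H×W×3 uint8 raster plus resolution metadata.

    Parameters
    ----------
    pixels
        8-bit intensities, shape (H, W, 3). Grayscale sources are promoted
        to three identical channels on load.
    resolution_dpi
        Scan resolution in dots per inch, or ``"unknown"`` when the file
        carried no resolution tag.
    source_id
        Label for the plate, derived from the filename stem by default.
    """

    pixels: np.ndarray
    resolution_dpi: Union[float, str] = UNKNOWN_DPI
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"PlateImage requires an H×W×3 array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("PlateImage must have H ≥ 1 and W ≥ 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.resolution_dpi != UNKNOWN_DPI:
            dpi = float(self.resolution_dpi)
            if not np.isfinite(dpi) or dpi <= 0:
                raise ValidationError(f"resolution_dpi must be positive, got {dpi}")
            self.resolution_dpi = dpi

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def has_dpi(self) -> bool:
        return self.resolution_dpi != UNKNOWN_DPI


def load_plate_image(path) -> PlateImage:
    """Load a PNG/TIFF/JPEG plate scan into a :class:`PlateImage`.

    Grayscale and palette images are promoted to RGB; an alpha channel is
    dropped. DPI is taken from the standard resolution tags when present,
    otherwise recorded as ``"unknown"``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            dpi_info = im.info.get("dpi")
            rgb = im.convert("RGB")
            pixels = np.asarray(rgb, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot decode image file {path}: {exc}") from exc
    if pixels.size == 0:
        raise InputError(f"zero-sized image: {path}")

    resolution: Union[float, str] = UNKNOWN_DPI
    if dpi_info:
        try:
            x = float(dpi_info[0])
            if np.isfinite(x) and x > 0:
                # PNG stores pixels-per-metre, so a 600 DPI tag reads back
                # as 599.9988…; snap to the integer the scanner meant
                resolution = round(x) if abs(x - round(x)) < 0.05 else x
        except (TypeError, ValueError, IndexError):
            resolution = UNKNOWN_DPI

    return PlateImage(pixels=pixels, resolution_dpi=resolution, source_id=path.stem)


@dataclass
class ColonySizeFile:
    """Parsed per-plate colony-size list."""

    plate_id: str
    unit: str
    areas: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.unit not in UNITS:
            raise ValidationError(f"unit must be one of {UNITS}, got {self.unit!r}")
        areas = np.asarray(self.areas, dtype=float)
        if areas.ndim != 1:
            raise ValidationError("areas must be a flat list")
        if areas.size and areas.min() <= 0:
            raise ValidationError("all colony areas must be > 0")
        self.areas = areas


def write_colony_sizes(
    records: Iterable,
    unit: str,
    path,
    plate_id: str | None = None,
    params: Mapping | None = None,
) -> ColonySizeFile:
    """Write one area per line, preceded by a ``#``-prefixed header.

    ``records`` may be colony records (anything with an ``area`` attribute,
    ``area_mm2`` used when ``unit == "mm^2"``) or bare numbers. Areas are
    written with ``repr`` so the read-back values are bit-identical.
    """
    if unit not in UNITS:
        raise ValidationError(f"unit must be one of {UNITS}, got {unit!r}")
    path = Path(path)
    if plate_id is None:
        plate_id = path.stem

    areas = []
    for rec in records:
        if hasattr(rec, "area"):
            value = rec.area_mm2 if (unit == "mm^2" and getattr(rec, "area_mm2", None) is not None) else rec.area
        else:
            value = float(rec)
        if value is None or value <= 0:
            raise ValidationError(f"colony area must be > 0, got {value}")
        areas.append(float(value))

    lines = [f"# plate_id: {plate_id}", f"# unit: {unit}"]
    if params:
        summary = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        lines.append(f"# params: {summary}")
    lines.extend(repr(a) for a in areas)
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot write colony-size file {path}: {exc}") from exc
    return ColonySizeFile(plate_id=plate_id, unit=unit, areas=np.array(areas))


_HEADER_RE = re.compile(r"^#\s*(\w+)\s*:\s*(.*?)\s*$")


def read_colony_sizes(path) -> ColonySizeFile:
    """Parse a colony-size text file (our header format or bare numbers).

    Bare files get ``unit = "pixel^2"`` and a plate id from the filename.
    A non-numeric data line raises :class:`ParseError` with its line number;
    a non-positive area raises :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such colony-size file: {path}")
    text = path.read_text(encoding="utf-8")

    plate_id = path.stem
    unit = "pixel^2"
    metadata: dict = {}
    areas: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _HEADER_RE.match(line)
            if m:
                key, value = m.group(1), m.group(2)
                if key == "plate_id":
                    plate_id = value
                elif key == "unit":
                    unit = value
                else:
                    metadata[key] = value
            continue
        try:
            value = float(line)
        except ValueError:
            raise ParseError(f"non-numeric colony area {line!r}", lineno) from None
        if not np.isfinite(value) or value <= 0:
            raise ValidationError(f"line {lineno}: colony area must be > 0, got {value}")
        areas.append(value)

    return ColonySizeFile(plate_id=plate_id, unit=unit, areas=np.array(areas), metadata=metadata)


def save_plate_image(plate: PlateImage, path, dpi: float | None = None) -> None:
    """Write a PlateImage as PNG/TIFF, embedding DPI metadata when known."""
    path = Path(path)
    im = Image.fromarray(plate.pixels)
    if dpi is None and plate.has_dpi:
        dpi = float(plate.resolution_dpi)
    if dpi:
        im.save(path, dpi=(dpi, dpi))
    else:
        im.save(path)
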