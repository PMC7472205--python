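"""Raster, box-file and report I/O for two-channel fluorescence micrographs.

Micrographs are 8-bit RGB images in which the blue channel carries the DAPI
(nucleus) stain and the red channel the rhodamine-phalloidin (cytoskeleton)
stain.  The green channel carries no signal and is discarded.

Coordinate convention: 0-based ``(row, column) = (y, x)`` with pixel centers
at integer coordinates.  Detection boxes are stored as center + size in
pixels and converted to half-open ranges ``[x0, x1) x [y0, y1)`` when
rasterized.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

if TYPE_CHECKING:  # pragma: no cover
    from .regions import CountsReport

NUCLEUS = "nucleus"
CYTOSKELETON = "cytoskeleton"

__all__ = [
    "ChannelImage",
    "DetectionBox",
    "read_image",
    "write_image",
    "split_channels",
    "compose_channels",
    "read_boxes",
    "write_boxes",
    "write_report",
    "read_report",
]


@dataclass(frozen=True)
class ChannelImage:
    """A single-channel 8-bit intensity image with a stain-role tag.

    Parameters
    ----------
    intensity
        2-D ``uint8`` array of grayscale values.
    role
        ``"nucleus"`` (blue / DAPI) or ``"cytoskeleton"`` (red / phalloidin).
    """

    intensity: np.ndarray
    role: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("channel intensity must be a non-empty 2-D array")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("channel intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        object.__setattr__(self, "intensity", arr)
        if self.role not in (NUCLEUS, CYTOSKELETON):
            raise ValueError(f"unknown channel role {self.role!r}")

    @property
    def height(self) -> int:
        return self.intensity.shape[0]

    @property
    def width(self) -> int:
        return self.intensity.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass(frozen=True)
class DetectionBox:
    """A nucleus detection box (center + size, pixels) with a confidence."""

    center_x: float
    center_y: float
    box_width: float
    box_height: float
    score: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.box_width <= 0 or self.box_height <= 0:
            raise ValueError("box size must be positive")

    def clamped(self, width: int, height: int) -> "DetectionBox":
        """Return the box clipped to lie fully inside ``[0,width)x[0,height)``."""
        x0 = max(0.0, self.center_x - self.box_width / 2)
        x1 = min(float(width), self.center_x + self.box_width / 2)
        y0 = max(0.0, self.center_y - self.box_height / 2)
        y1 = min(float(height), self.center_y + self.box_height / 2)
        if x1 <= x0 or y1 <= y0:
            raise ValueError("box lies entirely outside the image")
        return DetectionBox((x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0, self.score)

    def pixel_bounds(self, width: int, height: int) -> tuple[int, int, int, int]:
        """Half-open integer pixel ranges ``(x0, x1, y0, y1)``, clipped."""
        x0 = max(0, int(math.floor(self.center_x - self.box_width / 2)))
        x1 = min(width, int(math.ceil(self.center_x + self.box_width / 2)))
        y0 = max(0, int(math.floor(self.center_y - self.box_height / 2)))
        y1 = min(height, int(math.ceil(self.center_y + self.box_height / 2)))
        return x0, x1, y0, y1


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an ``(h, w, 3) uint8`` RGB array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"), dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ValueError(f"{path} is not a decodable image") from exc


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write an RGB (or grayscale) uint8 array as PNG or TIFF."""
    arr = np.asarray(pixels, dtype=np.uint8)
    Image.fromarray(arr).save(Path(path))


def split_channels(img: np.ndarray) -> tuple[ChannelImage, ChannelImage]:
    """Split an RGB micrograph into (nucleus=blue, cytoskeleton=red) channels."""
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("expected an (h, w, 3) RGB array")
    nucleus = ChannelImage(arr[:, :, 2], NUCLEUS)
    cytoskeleton = ChannelImage(arr[:, :, 0], CYTOSKELETON)
    return nucleus, cytoskeleton


def compose_channels(nucleus: ChannelImage, cytoskeleton: ChannelImage) -> np.ndarray:
    """Recompose red/blue planes into an RGB array (green left at zero)."""
    if nucleus.shape != cytoskeleton.shape:
        raise ValueError("channel shapes differ")
    rgb = np.zeros(nucleus.shape + (3,), dtype=np.uint8)
    rgb[:, :, 0] = cytoskeleton.intensity
    rgb[:, :, 2] = nucleus.intensity
    return rgb


def _parse_darknet_line(line: str, lineno: int, width: int, height: int) -> DetectionBox:
    parts = line.split()
    if len(parts) not in (5, 6):
        raise ValueError(f"line {lineno}: expected 'class cx cy w h [score]', got {line!r}")
    try:
        vals = [float(p) for p in parts[1:]]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-numeric field in {line!r}") from exc
    cx, cy, w, h = vals[:4]
    score = vals[4] if len(vals) == 5 else 1.0
    for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"line {lineno}: normalized {name}={v} outside [0, 1]")
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"line {lineno}: score={score} outside [0, 1]")
    box = DetectionBox(cx * width, cy * height, max(w * width, 1e-9), max(h * height, 1e-9), score)
    return box.clamped(width, height)


def read_boxes(path: str | Path, width: int, height: int) -> list[DetectionBox]:
    """Read nucleus detection boxes, denormalized to pixels and clamped.

    Two dialects are accepted: the plain-text one-box-per-line format
    ``class cx cy w h [score]`` with coordinates normalized to [0, 1]
    (the common single-class detector output), and a CSV file with header
    ``cx,cy,w,h,score`` in pixel units.  Missing scores default to 1.0.
    """
    path = Path(path)
    text = path.read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    boxes: list[DetectionBox] = []
    if first.lower().replace(" ", "").startswith("cx,"):
        reader = csv.DictReader(text.splitlines())
        for lineno, row in enumerate(reader, start=2):
            try:
                box = DetectionBox(
                    float(row["cx"]),
                    float(row["cy"]),
                    float(row["w"]),
                    float(row["h"]),
                    float(row.get("score") or 1.0),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"line {lineno}: malformed CSV box row {row!r}") from exc
            boxes.append(box.clamped(width, height))
        return boxes
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        boxes.append(_parse_darknet_line(line, lineno, width, height))
    return boxes


def write_boxes(
    boxes: Sequence[DetectionBox],
    path: str | Path,
    width: int,
    height: int,
    fmt: str = "darknet",
) -> None:
    """Write boxes as darknet-style normalized text or pixel-unit CSV."""
    path = Path(path)
    if fmt == "darknet":
        lines = [
            f"0 {b.center_x / width:.6f} {b.center_y / height:.6f} "
            f"{b.box_width / width:.6f} {b.box_height / height:.6f} {b.score:.4f}"
            for b in boxes
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["cx", "cy", "w", "h", "score"])
            for b in boxes:
                writer.writerow([b.center_x, b.center_y, b.box_width, b.box_height, b.score])
    else:
        raise ValueError(f"unknown box format {fmt!r}")


_REPORT_FIELDS = [
    "total_regions",
    "detected",
    "free_regions",
    "within_image",
    "boundary",
    "invalid",
    "normal",
    "micronuclei",
    "mitotic_or_micro",
    "ratio_normal",
    "ratio_abnormal",
]


def write_report(report: "CountsReport", path: str | Path) -> None:
    """Write a counts report as JSON (``.json``) or a one-row CSV.

    Undefined ratios (no valid nuclei) are emitted as ``null`` / ``NA``
    rather than raising.
    """
    path = Path(path)
    d = asdict(report)
    row = {f: d[f] for f in _REPORT_FIELDS}
    if path.suffix.lower() == ".json":
        out = {
            f: (None if isinstance(v, float) and math.isnan(v) else v)
            for f, v in row.items()
        }
        path.write_text(json.dumps(out, indent=2) + "\n")
    else:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_REPORT_FIELDS)
            writer.writerow(
                ["NA" if isinstance(v, float) and math.isnan(v) else v for v in row.values()]
            )


def read_report(path: str | Path) -> "CountsReport":
    """Read back a report written by :func:`write_report`."""
    from .regions import CountsReport

    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
    else:
        with path.open() as fh:
            rows = list(csv.DictReader(fh))
        if len(rows) != 1:
            raise ValueError(f"{path}: expected exactly one report row")
        raw = rows[0]

    def _num(field: str, value):
        if value is None or value == "NA":
            return math.nan
        return float(value) if field.startswith("ratio_") else int(value)

    return CountsReport(**{f: _num(f, raw[f]) for f in _REPORT_FIELDS})
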