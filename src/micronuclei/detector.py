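"""Pluggable nucleus-localization stage.

The trained network that localizes normal-looking nuclei is a boundary of
this package: everything downstream consumes only its boxes (Y).  Two modes
are provided — ``file`` replays externally produced box files, ``blob``
emits the bounding boxes of quantization-foreground components as a
classical stand-in so the full pipeline runs end to end.  Nuclei withheld
from Y (via a box file or the blob exclusion list) are routed to the
abnormal-by-omission pool M by the region algebra, mirroring a detector
trained only on normal nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import ndimage as ndi

from .io_images import ChannelImage, DetectionBox, read_boxes
from .quantize import foreground_mask, quantize_channel
from .regions import label_components

__all__ = ["DetectorConfig", "detect_nuclei"]


@dataclass(frozen=True)
class DetectorConfig:
    mode: str = "blob"  # "file" | "blob"
    min_area: float = 50.0
    max_area: float = 1.0e6
    score_threshold: float = 0.0
    k: int = 15
    seed: int = 0
    # (y, x) points whose enclosing blob box is suppressed; lets tests and
    # simulations withhold chosen nuclei from Y
    exclude_centers: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("file", "blob"):
            raise ValueError(f"unknown detector mode {self.mode!r}")
        if not self.min_area < self.max_area:
            raise ValueError("min_area must be < max_area")


def detect_nuclei(
    ch: ChannelImage,
    cfg: DetectorConfig = DetectorConfig(),
    boxes_path=None,
) -> list[DetectionBox]:
    """Produce nucleus detection boxes from a file or the blob stand-in.

    ``file`` mode reads and score-filters an external box file.  ``blob``
    mode quantizes the nucleus channel, removes the background, labels the
    foreground and emits one box per component with area inside
    ``[min_area, max_area]`` (score 1.0), deterministically.
    """
    if cfg.mode == "file":
        if boxes_path is None:
            raise ValueError("file mode requires boxes_path")
        boxes = read_boxes(boxes_path, ch.width, ch.height)
        return [b for b in boxes if b.score >= cfg.score_threshold]

    q = quantize_channel(ch, cfg.k, cfg.seed)
    rm = label_components(foreground_mask(q), tag="N")
    areas = rm.areas()
    boxes = []
    for cid, sl in enumerate(ndi.find_objects(rm.labels), start=1):
        if sl is None or not (cfg.min_area <= areas[cid] <= cfg.max_area):
            continue
        y0, y1 = sl[0].start, sl[0].stop
        x0, x1 = sl[1].start, sl[1].stop
        if any(y0 <= ey < y1 and x0 <= ex < x1 for ey, ex in cfg.exclude_centers):
            continue
        boxes.append(
            DetectionBox((x0 + x1) / 2.0, (y0 + y1) / 2.0, x1 - x0, y1 - y0, 1.0)
        )
    return boxes
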