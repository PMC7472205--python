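"""Connected-component labeling and the region-set algebra.

The pipeline works with labeled pixel regions carrying one-letter tags:

======  ==========================================================
``Y``   rasterized detector boxes (normal-looking nuclei)
``N``   nucleus foreground after background removal
``C``   cytoskeleton foreground after background removal
``B``   nucleus components touching the image border (clipped)
``D``   nucleus components with no cytoskeleton overlap (invalid)
``P``   retained pool, N minus B minus D
``A``   components of P overlapping Y∩C — analyzed for micronuclei
``M``   components of P not overlapping Y∩C — mitotic defects or
        free micronuclei (abnormal by omission from the detector)
======  ==========================================================

Set operations are lifted from pixel level to component level: a nucleus
component is kept or removed whole, never shredded at cytoskeleton gaps.
B, D and the components of P partition the components of N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd

    from .clsa import MicronucleusCall
    from .io_images import DetectionBox

__all__ = [
    "RegionMask",
    "AlgebraResult",
    "CountsReport",
    "label_components",
    "rasterize_boxes",
    "border_component_ids",
    "boundary_regions",
    "region_algebra",
    "ratio_split",
    "count_report",
    "component_table",
]

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndi.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class RegionMask:
    """A labeled binary pixel set with a provenance tag."""

    mask: np.ndarray
    labels: np.ndarray
    component_count: int
    tag: str

    def component(self, cid: int) -> np.ndarray:
        """Boolean mask of one component (ids are 1-based)."""
        return self.labels == cid

    def areas(self) -> np.ndarray:
        """Pixel count per component id; index 0 is the off-region."""
        return np.bincount(self.labels.ravel(), minlength=self.component_count + 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return _STRUCT_8
    if connectivity == 4:
        return _STRUCT_4
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def label_components(mask: np.ndarray, connectivity: int = 8, tag: str = "N") -> RegionMask:
    """Label maximal connected components of a binary mask (8-conn default)."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=_structure(connectivity))
    return RegionMask(mask, labels.astype(np.int32), int(n), tag)


def rasterize_boxes(
    boxes: Sequence["DetectionBox"], shape: tuple[int, int], connectivity: int = 8
) -> RegionMask:
    """Union of filled detection rectangles as a labeled mask (tag Y)."""
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    for b in boxes:
        x0, x1, y0, y1 = b.pixel_bounds(w, h)
        mask[y0:y1, x0:x1] = True
    rm = label_components(mask, connectivity=connectivity, tag="Y")
    return rm


def border_component_ids(rm: RegionMask) -> np.ndarray:
    """Ids of components having at least one pixel on the image border."""
    edge = np.concatenate(
        [rm.labels[0, :], rm.labels[-1, :], rm.labels[:, 0], rm.labels[:, -1]]
    )
    ids = np.unique(edge)
    return ids[ids > 0]


def boundary_regions(rm: RegionMask) -> RegionMask:
    """Union of whole components touching the image border (tag B)."""
    ids = border_component_ids(rm)
    mask = np.isin(rm.labels, ids)
    return label_components(mask, tag="B")


def _whole_components(n: RegionMask, ids: Iterable[int], tag: str) -> RegionMask:
    mask = np.isin(n.labels, np.fromiter(ids, dtype=np.int32, count=-1))
    return label_components(mask, tag=tag)


@dataclass(frozen=True)
class AlgebraResult:
    """Outcome of the component-level region algebra on N, C, Y."""

    n: RegionMask
    d: RegionMask
    p: RegionMask
    m: RegionMask
    a: RegionMask
    b: RegionMask
    category: Mapping[int, str]  # component id of N -> one of {"B","D","A","M"}
    detected_ids: frozenset[int]  # components of N overlapping Y
    overlap_c: np.ndarray  # per-id pixel overlap with C (index 0 unused)
    overlap_y: np.ndarray  # per-id pixel overlap with Y

    def ids(self, cat: str) -> list[int]:
        return sorted(cid for cid, c in self.category.items() if c == cat)


def region_algebra(
    n: RegionMask,
    c: RegionMask,
    y: RegionMask,
    min_overlap_frac: float = 0.0,
) -> AlgebraResult:
    """Classify every component of N as B, D, A or M.

    A component goes to B if it touches the image border; otherwise to D if
    its overlap with the cytoskeleton C is absent (or below
    ``min_overlap_frac`` of its area); the remainder is the retained pool P.
    Within P, components overlapping Y∩C form the analysis pool A, the rest
    the abnormal-by-omission pool M.  Results are unions of whole components
    of N — no component is ever split.
    """
    if not (n.shape == c.shape == y.shape):
        raise ValueError("N, C and Y masks must share one shape")
    areas = n.areas()
    flat = n.labels.ravel()
    minlen = n.component_count + 1
    ov_c = np.bincount(flat[c.mask.ravel()], minlength=minlen)
    ov_y = np.bincount(flat[y.mask.ravel()], minlength=minlen)
    ov_yc = np.bincount(flat[(y.mask & c.mask).ravel()], minlength=minlen)
    border = set(border_component_ids(n).tolist())

    category: dict[int, str] = {}
    for cid in range(1, n.component_count + 1):
        if cid in border:
            category[cid] = "B"
        elif _uncovered(ov_c[cid], areas[cid], min_overlap_frac):
            category[cid] = "D"
        elif ov_yc[cid] > 0:
            category[cid] = "A"
        else:
            category[cid] = "M"

    b = _whole_components(n, (i for i, t in category.items() if t == "B"), "B")
    d = _whole_components(n, (i for i, t in category.items() if t == "D"), "D")
    p = _whole_components(n, (i for i, t in category.items() if t in ("A", "M")), "P")
    a = _whole_components(n, (i for i, t in category.items() if t == "A"), "A")
    m = _whole_components(n, (i for i, t in category.items() if t == "M"), "M")
    detected = frozenset(int(i) for i in range(1, minlen) if ov_y[i] > 0)
    return AlgebraResult(n, d, p, m, a, b, category, detected, ov_c, ov_y)


def _uncovered(overlap: int, area: int, min_frac: float) -> bool:
    if min_frac <= 0.0:
        return overlap == 0
    return overlap < min_frac * area


def ratio_split(normal: int, abnormal: int) -> tuple[float, float]:
    """Percentage split (1 decimal) of normal vs abnormal valid nuclei.

    Returns ``(nan, nan)`` when there are no valid nuclei rather than
    dividing by zero.
    """
    total = normal + abnormal
    if total == 0:
        return math.nan, math.nan
    return (
        round(100.0 * normal / total, 1),
        round(100.0 * abnormal / total, 1),
    )


@dataclass(frozen=True)
class CountsReport:
    """Per-image nucleus accounting and the normal:abnormal ratio.

    ``detected`` counts nucleus components overlapping a detector box;
    ``within_image = detected - boundary`` (boundary counted among the
    detected, matching the headline accounting); ``invalid`` collects
    cytoskeleton-uncovered components plus undetected border components.
    Ratios are computed over valid nuclei only
    (``normal + micronuclei + mitotic_or_micro``).
    """

    total_regions: int
    detected: int
    free_regions: int
    within_image: int
    boundary: int
    invalid: int
    normal: int
    micronuclei: int
    mitotic_or_micro: int
    ratio_normal: float
    ratio_abnormal: float

    @classmethod
    def build(
        cls,
        *,
        detected: int,
        free_regions: int,
        boundary: int,
        invalid: int,
        normal: int,
        micronuclei: int,
        mitotic_or_micro: int,
    ) -> "CountsReport":
        rn, ra = ratio_split(normal, micronuclei + mitotic_or_micro)
        return cls(
            total_regions=detected + free_regions,
            detected=detected,
            free_regions=free_regions,
            within_image=detected - boundary,
            boundary=boundary,
            invalid=invalid,
            normal=normal,
            micronuclei=micronuclei,
            mitotic_or_micro=mitotic_or_micro,
            ratio_normal=rn,
            ratio_abnormal=ra,
        )

    @property
    def abnormal(self) -> int:
        return self.micronuclei + self.mitotic_or_micro


def count_report(
    algebra: AlgebraResult, calls: Sequence["MicronucleusCall"]
) -> CountsReport:
    """Assemble the per-image report from the algebra and the CLSA calls.

    Every component of N lands in exactly one bucket: boundary (detected
    border components), invalid (D plus undetected border components),
    normal / micronuclei (A pool, by CLSA call), or mitotic_or_micro (M).
    """
    positive = {c.nucleus_id for c in calls if c.positive}
    det = algebra.detected_ids
    boundary = invalid = normal = micro = mitotic = 0
    for cid, cat in algebra.category.items():
        if cat == "B":
            if cid in det:
                boundary += 1
            else:
                invalid += 1
        elif cat == "D":
            invalid += 1
        elif cat == "A":
            if cid in positive:
                micro += 1
            else:
                normal += 1
        else:  # M
            mitotic += 1
    detected = len(det)
    return CountsReport.build(
        detected=detected,
        free_regions=algebra.n.component_count - detected,
        boundary=boundary,
        invalid=invalid,
        normal=normal,
        micronuclei=micro,
        mitotic_or_micro=mitotic,
    )


def component_table(
    algebra: AlgebraResult, calls: Sequence["MicronucleusCall"] = ()
) -> "pd.DataFrame":
    """Per-component debug table (id, tag, area, bbox, overlaps, call)."""
    import pandas as pd

    n = algebra.n
    areas = n.areas()
    slices = ndi.find_objects(n.labels)
    border = set(border_component_ids(n).tolist())
    call_by_id = {c.nucleus_id: c for c in calls}
    rows = []
    for cid in range(1, n.component_count + 1):
        sl = slices[cid - 1]
        call = call_by_id.get(cid)
        rows.append(
            {
                "id": cid,
                "tag": algebra.category[cid],
                "area": int(areas[cid]),
                "y0": sl[0].start,
                "y1": sl[0].stop,
                "x0": sl[1].start,
                "x1": sl[1].stop,
                "border_touching": cid in border,
                "overlaps_C": int(algebra.overlap_c[cid]),
                "overlaps_Y": int(algebra.overlap_y[cid]),
                "micronucleus": bool(call.positive) if call else False,
            }
        )
    return pd.DataFrame(rows)
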