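"""Synthetic two-channel micrograph generator with per-nucleus ground truth.

Scenes emulate the features the pipeline must cope with: disk-like nuclei
with intensity falling off toward the rim (uneven staining), small
low-contrast bumps on the rim (attached micronuclei), fragmented two-lobed
shapes (mitotic defects), single-layer texture bumps, nuclei clipped by the
image border, nuclei outside the cytoskeleton, and additive Gaussian noise.

Bump intensities are calibrated against the package's own quantizer: the
bump-free scene is quantized once and the bump is painted at the grayscale
centroid of a chosen color layer, so a micronucleus bump surfaces in at
least three consecutive analyzed layers while a texture bump surfaces in
only the last analyzed layer.  The noiseless intensity planes are archived
with the ground truth, so every stage of the pipeline can be checked
against what was actually planted.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .clsa import layer_window
from .io_images import ChannelImage, DetectionBox, NUCLEUS, write_boxes, write_image
from .quantize import quantize_channel

__all__ = [
    "NORMAL",
    "MICRONUCLEUS",
    "MITOTIC_DEFECT",
    "TEXTURE_SPIKE",
    "NucleusSpec",
    "SceneSpec",
    "NucleusTruth",
    "GroundTruth",
    "generate_scene",
    "random_scene",
    "single_nucleus_scene",
    "generate_suite",
]

NORMAL = "normal"
MICRONUCLEUS = "micronucleus"
MITOTIC_DEFECT = "mitotic_defect"
TEXTURE_SPIKE = "texture_spike"
PHENOTYPES = (NORMAL, MICRONUCLEUS, MITOTIC_DEFECT, TEXTURE_SPIKE)


@dataclass(frozen=True)
class NucleusSpec:
    """One planted nucleus: geometry, staining profile and phenotype."""

    center: tuple[float, float]  # (y, x), pixels
    radius: float = 40.0
    peak: float = 230.0  # center brightness, 8-bit grayscale
    rim: float = 35.0  # rim brightness; stained nuclei stay above background
    falloff: float = 2.5  # radial falloff exponent p in rim+(peak-rim)*(1-(r/R)^p)
    phenotype: str = NORMAL
    bump_angle: float | None = None  # radians; drawn from the scene rng if None
    bump_radius: float | None = None  # default 0.28 * radius (< radius/3)
    covered: bool = True  # inside the cytoskeleton channel
    border_clip: bool = False
    in_boxes: bool = True  # offered to the detector box list

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.bump_radius is not None and self.bump_radius >= self.radius / 3:
            raise ValueError("bump radius must be < nucleus radius / 3")


@dataclass(frozen=True)
class SceneSpec:
    """A full synthetic scene: image geometry, nuclei, noise and seed."""

    shape: tuple[int, int] = (256, 256)
    nuclei: tuple[NucleusSpec, ...] = ()
    noise_sigma: float = 3.0
    k: int = 15  # layer count used for bump calibration
    seed: int = 0
    cyto_intensity: float = 140.0
    cyto_scale: float = 1.8  # cytoskeleton blob radius / nucleus radius
    allow_overlap: bool = False


@dataclass(frozen=True)
class NucleusTruth:
    """Ground truth for one planted nucleus."""

    phenotype: str
    mask: np.ndarray
    box: DetectionBox | None  # None when withheld from the detector
    expected_tag: str  # A-positive | A-negative | M | B | D
    bump_angle: float
    center: tuple[float, float]


@dataclass(frozen=True)
class GroundTruth:
    """Scene-level truth archived alongside the rendered image."""

    nuclei: tuple[NucleusTruth, ...]
    nucleus_plane: np.ndarray  # noiseless uint8 blue plane
    cytoskeleton_plane: np.ndarray  # noiseless uint8 red plane
    boxes: tuple[DetectionBox, ...]
    spec: SceneSpec


def _disk_profile(shape, center, radius, peak, falloff, rim=0.0) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    r = np.hypot(yy - center[0], xx - center[1])
    prof = rim + (peak - rim) * (1.0 - (np.minimum(r, radius) / radius) ** falloff)
    prof[r > radius] = 0.0
    return prof


def _render_nucleus(shape, nuc: NucleusSpec, rng: np.random.Generator):
    """Noiseless intensity plane and support mask of one nucleus (no bump)."""
    if nuc.phenotype == MITOTIC_DEFECT:
        # two overlapping lobes along a random axis: lobed/fragmented shape
        theta = rng.uniform(0, 2 * math.pi)
        off = 0.45 * nuc.radius
        lobe_r = 0.62 * nuc.radius
        plane = np.zeros(shape)
        for sign in (-1, 1):
            c = (
                nuc.center[0] + sign * off * math.sin(theta),
                nuc.center[1] + sign * off * math.cos(theta),
            )
            plane = np.maximum(
                plane, _disk_profile(shape, c, lobe_r, nuc.peak, nuc.falloff, nuc.rim)
            )
    else:
        plane = _disk_profile(
            shape, nuc.center, nuc.radius, nuc.peak, nuc.falloff, nuc.rim
        )
    return plane, plane > 0


def _stadium_mask(shape, p0, p1, halfwidth) -> np.ndarray:
    """Pixels within ``halfwidth`` of the segment p0-p1 (a thick line)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    vy, vx = p1[0] - p0[0], p1[1] - p0[1]
    denom = vy * vy + vx * vx
    t = np.clip(((yy - p0[0]) * vy + (xx - p0[1]) * vx) / max(denom, 1e-12), 0.0, 1.0)
    return np.hypot(yy - (p0[0] + t * vy), xx - (p0[1] + t * vx)) <= halfwidth


def _bump_mask(shape, nuc: NucleusSpec, angle: float, value: float) -> np.ndarray:
    """An attached rim bump: a small lobe outside the rim plus a neck.

    The lobe center sits beyond the nuclear radius so the silhouette
    overhangs — the center-to-silhouette distance jumps at the lobe's
    tangent angles, which is the signature feature of an attached
    micronucleus.  The neck starts inside the radius where the radial
    profile equals the bump's grayscale, keeping the bump 8-connected to
    the nucleus in every color layer in which it is visible.
    """
    rb = nuc.bump_radius if nuc.bump_radius is not None else 0.28 * nuc.radius
    d = nuc.radius + 0.8 * rb
    dirv = (math.sin(angle), math.cos(angle))
    bc = (nuc.center[0] + d * dirv[0], nuc.center[1] + d * dirv[1])
    frac = min(max((value - nuc.rim) / (nuc.peak - nuc.rim), 0.0), 0.95)
    r0 = max(nuc.radius * (1.0 - frac) ** (1.0 / nuc.falloff) - 2.0, 0.0)
    p0 = (nuc.center[0] + r0 * dirv[0], nuc.center[1] + r0 * dirv[1])
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    lobe = np.hypot(yy - bc[0], xx - bc[1]) <= rb
    return lobe | _stadium_mask(shape, p0, bc, 0.45 * rb)


def _expected_tag(nuc: NucleusSpec) -> str:
    if nuc.border_clip:
        return "B"
    if not nuc.covered:
        return "D"
    if nuc.phenotype == MITOTIC_DEFECT:
        return "M"
    if nuc.phenotype == MICRONUCLEUS:
        return "A-positive"
    return "A-negative"


def _bbox_of(mask: np.ndarray) -> DetectionBox:
    ys, xs = np.nonzero(mask)
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    return DetectionBox((x0 + x1) / 2.0, (y0 + y1) / 2.0, x1 - x0, y1 - y0, 1.0)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene and its ground truth, deterministically in the seed.

    The blue plane sums the nucleus intensity profiles, the red plane holds
    a cytoskeleton blob around each covered nucleus; Gaussian noise is
    added to both after the ground truth is recorded.
    """
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)

    if not spec.allow_overlap:
        for i, a in enumerate(spec.nuclei):
            for b in spec.nuclei[i + 1 :]:
                d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise ValueError(
                        "overlapping nuclei without allow_overlap "
                        f"(centers {a.center} and {b.center})"
                    )

    # base (bump-free) composition, used both for output and calibration
    planes, masks, bump_angles = [], [], []
    for nuc in spec.nuclei:
        plane, mask = _render_nucleus((h, w), nuc, rng)
        planes.append(plane)
        masks.append(mask)
        bump_angles.append(
            nuc.bump_angle
            if nuc.bump_angle is not None
            else float(rng.uniform(0, 2 * math.pi))
        )
    base = np.maximum.reduce(planes) if planes else np.zeros((h, w))
    # shot-noise-like: Gaussian amplitude scaling with sqrt(signal), so the
    # unstained background stays quiet (as in real 8-bit exports) while
    # stained regions carry noise_sigma at the reference intensity of 100
    u_r = rng.standard_normal((h, w))
    u_b = rng.standard_normal((h, w))

    def _noisy(plane: np.ndarray, u: np.ndarray) -> np.ndarray:
        return plane + u * spec.noise_sigma * np.sqrt(plane / 100.0)

    # calibrate bump intensities against the quantizer on the bump-free scene,
    # under the same noise realization the analyzer will quantize
    bump_nuclei = [n for n in spec.nuclei if n.phenotype in (MICRONUCLEUS, TEXTURE_SPIKE)]
    if bump_nuclei:
        q = quantize_channel(
            ChannelImage(
                np.clip(np.rint(_noisy(base, u_b)), 0, 255).astype(np.uint8), NUCLEUS
            ),
            spec.k,
            spec.seed,
        )
        first, last = layer_window(q.k)
        # layers whose centroid sits in the stained intensity range; dimmer
        # layers belong to the background/noise floor and carry no contour
        min_rim = min(n.rim for n in bump_nuclei)
        usable = [
            lv for lv in range(first, last + 1)
            if q.level_values[lv - 1] >= 0.8 * min_rim
        ]
        if len(usable) < 4:
            raise ValueError(
                "cannot calibrate bumps: fewer than 4 analyzed layers fall in "
                "the stained intensity range"
            )
        last_use = max(usable)
        # micronucleus bump: surfaces 3 layers above the dimmest usable layer,
        # so it persists through >= 4 consecutive analyzed layers; texture
        # bump: surfaces only in the dimmest usable layer
        micro_level = max(first, last_use - 3)
        texture_level = last_use
        micro_val = float(q.level_values[micro_level - 1])
        texture_val = float(q.level_values[texture_level - 1])

    nucleus_plane = base.copy()
    truths = []
    for nuc, mask, angle in zip(spec.nuclei, masks, bump_angles):
        mask = mask.copy()
        if nuc.phenotype in (MICRONUCLEUS, TEXTURE_SPIKE):
            val = micro_val if nuc.phenotype == MICRONUCLEUS else texture_val
            bump = _bump_mask((h, w), nuc, angle, val)
            nucleus_plane[bump] = np.maximum(nucleus_plane[bump], val)
            mask |= bump
        box = _bbox_of(mask) if (nuc.in_boxes and nuc.phenotype != MITOTIC_DEFECT) else None
        truths.append(
            NucleusTruth(nuc.phenotype, mask, box, _expected_tag(nuc), angle, nuc.center)
        )

    cyto_plane = np.zeros((h, w))
    for nuc in spec.nuclei:
        if nuc.covered:
            blob = _disk_profile(
                (h, w), nuc.center, nuc.radius * spec.cyto_scale, spec.cyto_intensity, 4.0
            )
            cyto_plane = np.maximum(cyto_plane, blob)

    nucleus_u8 = np.clip(np.rint(nucleus_plane), 0, 255).astype(np.uint8)
    cyto_u8 = np.clip(np.rint(cyto_plane), 0, 255).astype(np.uint8)

    rgb = np.zeros((h, w, 3))
    rgb[:, :, 0] = _noisy(cyto_plane, u_r)
    rgb[:, :, 2] = _noisy(nucleus_plane, u_b)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    boxes = tuple(t.box for t in truths if t.box is not None)
    return rgb, GroundTruth(tuple(truths), nucleus_u8, cyto_u8, boxes, spec)


def single_nucleus_scene(
    phenotype: str,
    seed: int,
    shape: tuple[int, int] = (192, 192),
    radius: float = 40.0,
    noise_sigma: float = 3.0,
    k: int = 15,
    **nucleus_kwargs,
) -> tuple[np.ndarray, GroundTruth]:
    """One centered nucleus on a small canvas (benchmark unit)."""
    center = (shape[0] / 2.0, shape[1] / 2.0)
    spec = SceneSpec(
        shape=shape,
        nuclei=(NucleusSpec(center, radius=radius, phenotype=phenotype, **nucleus_kwargs),),
        noise_sigma=noise_sigma,
        k=k,
        seed=seed,
    )
    return generate_scene(spec)


def random_scene(
    seed: int,
    shape: tuple[int, int] = (512, 512),
    n_nuclei: int = 12,
    mix: dict[str, float] | None = None,
    p_border: float = 0.1,
    p_uncovered: float = 0.1,
    radius_range: tuple[float, float] = (28.0, 42.0),
    noise_sigma: float = 3.0,
    k: int = 15,
) -> SceneSpec:
    """Draw a non-overlapping random scene specification.

    ``mix`` maps phenotype to proportion (default 70% normal, 15%
    micronucleus, 10% mitotic defect, 5% texture spike); a fraction of
    nuclei is clipped by the border or left outside the cytoskeleton.
    """
    mix = mix or {NORMAL: 0.70, MICRONUCLEUS: 0.15, MITOTIC_DEFECT: 0.10, TEXTURE_SPIKE: 0.05}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("phenotype proportions must sum to 1")
    rng = np.random.default_rng(seed)
    h, w = shape
    phenos = rng.choice(list(mix), size=n_nuclei, p=list(mix.values()))
    nuclei: list[NucleusSpec] = []
    for pheno in phenos:
        radius = float(rng.uniform(*radius_range))
        clip = bool(rng.random() < p_border)
        uncovered = (not clip) and bool(rng.random() < p_uncovered)
        for _ in range(200):
            if clip:
                # center close enough to one edge that the disk is clipped
                edge = rng.integers(4)
                off = float(rng.uniform(0.1, 0.6) * radius)
                if edge == 0:
                    center = (off, float(rng.uniform(radius, w - radius)))
                elif edge == 1:
                    center = (h - 1 - off, float(rng.uniform(radius, w - radius)))
                elif edge == 2:
                    center = (float(rng.uniform(radius, h - radius)), off)
                else:
                    center = (float(rng.uniform(radius, h - radius)), w - 1 - off)
            else:
                margin = radius * 1.35 + 2
                center = (
                    float(rng.uniform(margin, h - margin)),
                    float(rng.uniform(margin, w - margin)),
                )
            if all(
                math.hypot(center[0] - o.center[0], center[1] - o.center[1])
                > radius + o.radius + 6
                for o in nuclei
            ):
                break
        else:
            continue  # canvas full; drop this nucleus
        nuclei.append(
            NucleusSpec(
                center,
                radius=radius,
                phenotype=str(pheno),
                covered=not uncovered,
                border_clip=clip,
            )
        )
    return SceneSpec(
        shape=shape,
        nuclei=tuple(nuclei),
        noise_sigma=noise_sigma,
        k=k,
        seed=int(rng.integers(2**31 - 1)),
    )


def generate_suite(
    out_dir: str | Path,
    n_scenes: int = 10,
    mix: dict[str, float] | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    n_nuclei: int = 12,
) -> Path:
    """Write a directory of scenes: PNGs, box files, truth JSON, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_scenes):
        spec = random_scene(seed + i, shape=shape, n_nuclei=n_nuclei, mix=mix)
        rgb, truth = generate_scene(spec)
        stem = f"scene_{i:03d}"
        write_image(rgb, out / f"{stem}.png")
        write_boxes(truth.boxes, out / f"{stem}.boxes.txt", shape[1], shape[0])
        payload = {
            "seed": spec.seed,
            "shape": list(spec.shape),
            "nuclei": [
                {
                    "phenotype": t.phenotype,
                    "expected_tag": t.expected_tag,
                    "center": list(t.center),
                    "bump_angle": t.bump_angle,
                    "in_boxes": t.box is not None,
                }
                for t in truth.nuclei
            ],
        }
        (out / f"{stem}.truth.json").write_text(json.dumps(payload, indent=2) + "\n")
        counts = {p: sum(t.phenotype == p for t in truth.nuclei) for p in PHENOTYPES}
        rows.append({"scene": stem, "n_nuclei": len(truth.nuclei), **counts})
    with (out / "manifest.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]) if rows else ["scene"])
        writer.writeheader()
        writer.writerows(rows)
    return out
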