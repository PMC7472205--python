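"""Color Layer Signature Analysis: micronucleus detection on one nucleus.

A micronucleus attached to a nucleus shows up as a low-contrast bump on the
nuclear rim.  For each color layer q the cumulative thresholded region of
the nucleus is traced (8-connected chain-code border following) and turned
into the circular *signature curve* ``S(m)``: the distance from the nucleus
center to the region silhouette as a function of angle.  The Haar high-pass kernel
``(1/2, -1/2)`` extracts high-frequency boundary detail ``psi(m)``, its
circular first difference ``psi'(m)`` is accumulated over a 10-sample
window into the *short-window energy* ``delta(m)``, and circular intervals
where ``|delta| > mean(|delta|)/2`` (the ``Ru`` regions) are screened
against the sensitivity ``mu``.  A bump that produces a passing peak at a
consistent angular position in enough consecutive color layers (the
persistence criterion, default 3) is called a micronucleus; a peak confined
to a single layer is treated as nuclear texture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi

from .quantize import LayerRegion

__all__ = [
    "RegionTooSmall",
    "SignatureCurve",
    "EnergyCurve",
    "Peak",
    "PeakRegions",
    "MicronucleusCall",
    "ClsaConfig",
    "trace_boundary",
    "trace_signature",
    "haar_highpass",
    "short_window_energy",
    "screen_peaks",
    "layer_window",
    "detect_micronucleus",
    "nucleus_traces",
]

_STRUCT_8 = np.ones((3, 3), dtype=bool)

# neighbour offsets (dy, dx), clockwise in array coordinates starting East
_NBRS = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)],
    dtype=int,
)
_DIR_OF = {(int(dy), int(dx)): i for i, (dy, dx) in enumerate(_NBRS)}


class RegionTooSmall(Exception):
    """Raised when a region is too small to carry a signature (skip signal)."""


@dataclass(frozen=True)
class SignatureCurve:
    """Circular centroid-to-contour distance function of one layer region."""

    values: np.ndarray  # S(m), pixels
    angles: np.ndarray  # polar angle of each boundary sample, radians
    layer: int = 0
    nucleus_id: int = 0
    center: tuple[float, float] = (math.nan, math.nan)  # (y, x)

    @property
    def length(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EnergyCurve:
    """Haar high-pass, its difference, and the short-window energy of S(m)."""

    psi: np.ndarray
    psi_prime: np.ndarray
    delta: np.ndarray
    mean_abs: float  # mean of |delta|
    window: int = 10

    @property
    def length(self) -> int:
        return len(self.delta)


@dataclass(frozen=True)
class Peak:
    """A candidate peak inside one Ru interval."""

    index: int
    amplitude: float
    angle: float = math.nan


@dataclass(frozen=True)
class PeakRegions:
    """Circular intervals above (Ru) and below (Rd) the mean/2 threshold.

    Intervals are ``(start, length)`` pairs with circular indexing; Ru and
    Rd together cover every index exactly once.
    """

    ru: tuple[tuple[int, int], ...]
    rd: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class MicronucleusCall:
    """Per-nucleus decision with the supporting layers and peak location."""

    nucleus_id: int
    positive: bool
    supporting_layers: tuple[int, ...]
    angular_position: float  # circular mean of supporting peak angles, radians
    mu: float


@dataclass(frozen=True)
class ClsaConfig:
    """Tunable parameters of the signature analysis.

    ``mu`` is in signature units (pixels of centroid distance accumulated
    over the energy window) and is therefore resolution dependent; the
    default matches the 40x / 1360x1024 acquisition scale.
    """

    mu: float = 4.0
    persistence: int = 3
    angle_tolerance: float = 15.0  # degrees
    window: int = 10
    layer_window: tuple[int, int] | None = None  # None -> derive from k
    min_component_area: int = 5
    min_boundary_len: int = 12


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Order the outer boundary pixels of a single 8-connected component.

    Moore-neighbour border following starting from the topmost-leftmost
    pixel, traversing clockwise in array coordinates (counterclockwise in
    conventional y-up orientation).  Returns an ``(L, 2)`` array of (y, x)
    boundary pixels in chain-code order.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise RegionTooSmall("empty mask")
    start_i = np.lexsort((xs, ys))[0]
    s = (int(ys[start_i]), int(xs[start_i]))
    h, w = mask.shape

    def fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    def next_on_boundary(cur: tuple[int, int], back: tuple[int, int]):
        start_dir = _DIR_OF[(back[0] - cur[0], back[1] - cur[1])]
        for j in range(1, 9):
            d = (start_dir + j) % 8
            cand = (cur[0] + int(_NBRS[d, 0]), cur[1] + int(_NBRS[d, 1]))
            if fg(cand):
                prev = (start_dir + j - 1) % 8
                new_back = (cur[0] + int(_NBRS[prev, 0]), cur[1] + int(_NBRS[prev, 1]))
                return cand, new_back
        return None, None  # isolated pixel

    chain = [s]
    cur, back = next_on_boundary(s, (s[0], s[1] - 1))  # west of start is background
    if cur is None:
        return np.array(chain, dtype=int)
    second = cur
    chain.append(cur)
    limit = 4 * (len(ys) + 1) * 8
    for _ in range(limit):
        nxt, back = next_on_boundary(cur, back)
        if nxt is None:
            break
        # Jacob's stopping criterion: back at the start heading for the
        # same second pixel the trace began with
        if cur == s and nxt == second:
            break
        chain.append(nxt)
        cur = nxt
    if chain[-1] == s:
        chain.pop()
    return np.array(chain, dtype=int)


def trace_signature(
    mask: np.ndarray,
    center: tuple[float, float] | None = None,
    layer: int = 0,
    nucleus_id: int = 0,
    min_boundary_len: int = 8,
) -> SignatureCurve:
    """Radial signature curve S(m) of a single-component region.

    The boundary is followed in chain-code order and converted into the
    classic shape signature: center-to-silhouette distance as a circular
    function of polar angle, one angular sample per boundary pixel
    (``L`` = boundary length, so the curve scales with the region).  Where
    a protrusion makes the boundary multivalued in angle the outermost
    distance is kept, so an attached bump appears as a step of its full
    protrusion height between adjacent samples — the feature the
    short-window energy responds to.  Angular bins the boundary skips are
    filled from the circularly nearest filled bin.

    ``center`` is the (y, x) reference point; by default the centroid of
    the mask itself, but callers analyzing one nucleus across layers should
    pass the fixed centroid of the full nucleus footprint so that peak
    angles stay comparable between layers.
    """
    mask = np.asarray(mask, dtype=bool)
    _, n = ndi.label(mask, structure=_STRUCT_8)
    if n != 1:
        raise ValueError(f"expected exactly one component, found {n}")
    boundary = trace_boundary(mask)
    if len(boundary) < min_boundary_len:
        raise RegionTooSmall(f"boundary has {len(boundary)} < {min_boundary_len} pixels")
    if center is None:
        ys, xs = np.nonzero(mask)
        center = (float(ys.mean()), float(xs.mean()))
    dy = boundary[:, 0] - center[0]
    dx = boundary[:, 1] - center[1]
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    L = len(boundary)
    bins = np.clip(((theta + math.pi) / (2 * math.pi) * L).astype(int), 0, L - 1)
    values = np.full(L, -np.inf)
    np.maximum.at(values, bins, dist)
    filled = np.isfinite(values)
    if not filled.all():
        # nearest-neighbour circular fill: keeps silhouette discontinuities
        # (the micronucleus cue) one sample wide instead of smearing them
        idx = np.nonzero(filled)[0]
        gaps = np.nonzero(~filled)[0]
        pos = np.searchsorted(idx, gaps)
        left = idx[(pos - 1) % len(idx)]
        right = idx[pos % len(idx)]
        d_left = (gaps - left) % L
        d_right = (right - gaps) % L
        values[gaps] = np.where(
            d_left <= d_right, values[left], values[right]
        )
    angles = -math.pi + 2 * math.pi * (np.arange(L) + 0.5) / L
    return SignatureCurve(
        values, angles, layer, nucleus_id, (float(center[0]), float(center[1]))
    )


def haar_highpass(s: SignatureCurve | np.ndarray) -> np.ndarray:
    """Circular convolution of S with the Haar detail kernel (1/2, -1/2).

    ``psi(m) = (S(m) - S(m+1)) / 2`` with circular indexing; the kernel
    sums to zero, so does psi over one full turn.
    """
    values = s.values if isinstance(s, SignatureCurve) else np.asarray(s, dtype=float)
    if len(values) < 2:
        raise RegionTooSmall("signature too short for the Haar kernel")
    return (values - np.roll(values, -1)) / 2.0


def short_window_energy(psi: np.ndarray, window: int = 10) -> EnergyCurve:
    """Short-window energy: 10-term circular cumulative sum of psi'.

    ``psi'(m) = psi(m+1) - psi(m)`` and
    ``delta(m) = sum_{t=1..window} psi'(m+t)`` with circular padding;
    ``mean_abs`` is the mean of ``|delta|`` used for peak screening.
    """
    psi = np.asarray(psi, dtype=float)
    L = len(psi)
    if L < window + 2:
        raise RegionTooSmall(f"curve of length {L} shorter than window {window}")
    psi_prime = np.roll(psi, -1) - psi
    delta = np.zeros(L)
    for t in range(1, window + 1):  # literal windowed sum, not the telescoped form
        delta += np.roll(psi_prime, -t)
    return EnergyCurve(psi, psi_prime, delta, float(np.mean(np.abs(delta))), window)


def _circular_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal circular runs of True as (start, length) pairs."""
    L = len(flags)
    if not flags.any():
        return []
    if flags.all():
        return [(0, L)]
    starts = np.nonzero(flags & ~np.roll(flags, 1))[0]
    runs = []
    for s in starts:
        length = 1
        while flags[(s + length) % L]:
            length += 1
        runs.append((int(s), length))
    return runs


def screen_peaks(
    e: EnergyCurve, mu: float, angles: np.ndarray | None = None
) -> tuple[PeakRegions, list[Peak]]:
    """Split the energy curve into Ru/Rd intervals and screen Ru against mu.

    Ru intervals are the maximal circular runs with ``|delta| > mean_abs/2``.
    Within each Ru interval the extremum passes if ``max |delta| > mu``
    (peaks and valleys are treated symmetrically).  Passing peaks carry the
    boundary angle of their extremum when ``angles`` is supplied.
    """
    mag = np.abs(e.delta)
    above = mag > e.mean_abs / 2.0
    ru = _circular_runs(above)
    rd = _circular_runs(~above)
    L = e.length
    peaks = []
    for start, length in ru:
        idx = (start + np.arange(length)) % L
        j = idx[int(np.argmax(mag[idx]))]
        amp = float(mag[j])
        if amp > mu:
            # delta(m) spans samples m+1..m+window+1, so the boundary feature
            # sits about half a window ahead of the delta extremum
            aj = (int(j) + 1 + e.window // 2) % L
            ang = float(angles[aj]) if angles is not None else math.nan
            peaks.append(Peak(int(j), amp, ang))
    return PeakRegions(tuple(ru), tuple(rd)), peaks


def layer_window(k: int, rule: str = "auto") -> tuple[int, int]:
    """Analyzed layer range: drop the brightest and darkest fifth of layers.

    The brightest fifth carries nuclear texture and the darkest fifth
    (including the background layer) merges with the surround, so analysis
    runs on the middle layers: ``first = floor(k/5) + 1``,
    ``last = k - ceil(k/5)``; k = 15 gives layers 4..12.
    """
    if rule != "auto":
        raise ValueError(f"unknown layer-window rule {rule!r}")
    if k < 5:
        raise ValueError(f"k={k} too small for a layer window")
    first = k // 5 + 1
    last = k - math.ceil(k / 5)
    if first > last:
        raise ValueError(f"empty layer window for k={k}")
    return first, last


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def _single_component(mask: np.ndarray, min_area: int) -> np.ndarray | None:
    """The unique component of the mask after dropping speckles, else None."""
    labels, n = ndi.label(mask, structure=_STRUCT_8)
    if n == 1:
        return mask
    areas = np.bincount(labels.ravel())[1:]
    keep = np.nonzero(areas >= min_area)[0] + 1
    if len(keep) != 1:
        return None  # nucleus genuinely split in this layer
    return labels == keep[0]


def _circular_diff(a: float, b: float) -> float:
    return abs(math.remainder(a - b, 2 * math.pi))


def _circular_mean(angles: Sequence[float]) -> float:
    return math.atan2(
        float(np.mean(np.sin(angles))), float(np.mean(np.cos(angles)))
    )


def _merge_peaks(peaks: list[Peak], tol: float) -> list[Peak]:
    """Fuse same-layer peaks within ``tol`` radians into single features.

    A protrusion wider than the energy window answers with separate peaks
    at each of its angular edges; single-linkage merging by angle restores
    one feature whose angle is the amplitude-weighted circular mean.
    """
    usable = [p for p in peaks if not math.isnan(p.angle)]
    if len(usable) < 2:
        return peaks
    order = sorted(usable, key=lambda p: p.angle)
    groups: list[list[Peak]] = [[order[0]]]
    for p in order[1:]:
        if p.angle - groups[-1][-1].angle <= tol:
            groups[-1].append(p)
        else:
            groups.append([p])
    if len(groups) > 1:
        wrap = (order[0].angle + 2 * math.pi) - order[-1].angle
        if wrap <= tol:  # circular closure
            groups[0] = groups.pop() + groups[0]
    merged = []
    for g in groups:
        w = np.array([p.amplitude for p in g])
        ang = np.array([p.angle for p in g])
        mean = math.atan2(float(np.sum(w * np.sin(ang))), float(np.sum(w * np.cos(ang))))
        best = max(g, key=lambda p: p.amplitude)
        merged.append(Peak(best.index, best.amplitude, mean))
    return merged


def nucleus_traces(
    nucleus_id: int,
    layers: Mapping[int, np.ndarray] | Sequence[LayerRegion],
    cfg: ClsaConfig = ClsaConfig(),
    center: tuple[float, float] | None = None,
) -> dict[int, tuple[SignatureCurve, EnergyCurve, list[Peak]]]:
    """Per-layer signature, energy and passing peaks for one nucleus.

    ``layers`` maps the color-layer level to the cumulative layer mask
    restricted to this nucleus.  Layers that are empty, touch the image
    border, split into several components, or are too small for the energy
    window are skipped.  The signature center defaults to the centroid of
    the largest supplied layer mask and is held fixed across layers.
    """
    if not isinstance(layers, Mapping):
        layers = {lr.layer: lr.mask for lr in layers}
    levels = sorted(layers)
    if center is None:
        biggest = max(levels, key=lambda lv: int(np.count_nonzero(layers[lv])))
        ys, xs = np.nonzero(layers[biggest])
        if len(ys) == 0:
            return {}
        center = (float(ys.mean()), float(xs.mean()))

    traces: dict[int, tuple[SignatureCurve, EnergyCurve, list[Peak]]] = {}
    for level in levels:
        mask = np.asarray(layers[level], dtype=bool)
        if not mask.any() or _touches_border(mask):
            continue
        single = _single_component(mask, cfg.min_component_area)
        if single is None:
            continue
        try:
            sig = trace_signature(
                single, center=center, layer=level, nucleus_id=nucleus_id,
                min_boundary_len=cfg.min_boundary_len,
            )
            energy = short_window_energy(haar_highpass(sig), cfg.window)
        except RegionTooSmall:
            continue
        _, peaks = screen_peaks(energy, cfg.mu, angles=sig.angles)
        traces[level] = (sig, energy, peaks)
    return traces


def detect_micronucleus(
    nucleus_id: int,
    layers: Mapping[int, np.ndarray] | Sequence[LayerRegion],
    cfg: ClsaConfig = ClsaConfig(),
    center: tuple[float, float] | None = None,
) -> MicronucleusCall:
    """Decide whether one nucleus carries a micronucleus.

    Passing peaks are associated across consecutive color layers by angular
    proximity (tolerance ``cfg.angle_tolerance`` degrees); a chain spanning
    at least ``cfg.persistence`` layers calls the nucleus positive.  A peak
    confined to a single layer is interpreted as nuclear texture and left
    negative.  Skipped layers (split/edge-connected/too small) bridge a
    chain without extending it.
    """
    if not isinstance(layers, Mapping):
        layers = {lr.layer: lr.mask for lr in layers}
    traces = nucleus_traces(nucleus_id, layers, cfg, center=center)
    tol = math.radians(cfg.angle_tolerance)

    chains: list[dict] = []  # each: {"layers": [...], "angles": [...]}
    active: list[dict] = []
    for level in sorted(layers):
        if level not in traces:
            continue  # skipped layer: bridge, neither extend nor reset
        peaks = _merge_peaks(traces[level][2], tol)
        matched: list[dict] = []
        used: set[int] = set()
        for ch in active:
            best, best_d = None, tol
            for i, pk in enumerate(peaks):
                if i in used or math.isnan(pk.angle):
                    continue
                d = _circular_diff(pk.angle, _circular_mean(ch["angles"]))
                if d <= best_d:
                    best, best_d = i, d
            if best is not None:
                used.add(best)
                ch["layers"].append(level)
                ch["angles"].append(peaks[best].angle)
                matched.append(ch)
            else:
                chains.append(ch)
        for i, pk in enumerate(peaks):
            if i not in used:
                matched.append({"layers": [level], "angles": [pk.angle]})
        active = matched
    chains.extend(active)

    best_chain = max(chains, key=lambda ch: len(ch["layers"]), default=None)
    if best_chain is None or len(best_chain["layers"]) < cfg.persistence:
        support = tuple(best_chain["layers"]) if best_chain else ()
        return MicronucleusCall(nucleus_id, False, support, math.nan, cfg.mu)
    return MicronucleusCall(
        nucleus_id,
        True,
        tuple(best_chain["layers"]),
        _circular_mean(best_chain["angles"]),
        cfg.mu,
    )
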