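# Methods

## Pipeline model

The package analyzes 8-bit RGB fluorescence micrographs with two informative
channels: blue = DAPI (nuclei), red = rhodamine phalloidin (cytoskeleton).
The green channel is discarded. Coordinates are 0-based `(row, column)`;
detection boxes are center + size in pixels and become half-open pixel
rectangles when rasterized.

Stages, in order: channel split → unsharp sharpening → k-means color-layer
quantization of both channels → background removal (darkest layer) →
connected-component labeling → rasterization of detector boxes (Y) →
component-level region algebra (B, D, P, M, A) → color-layer signature
analysis of the A pool → counts report and overlay.

Nucleus localization itself is a boundary of the package: any detector that
emits boxes around *normal-looking* nuclei can feed the pipeline through a
box file. A classical blob detector (quantization foreground components
filtered by area) is included so the pipeline runs without external input.
Because the upstream detector is assumed to be trained/configured on normal
nuclei only, a retained nucleus that no box claims is abnormal *by
omission* and lands in M.

## Quantization

1-D k-means runs on the intensity histogram (unique gray values weighted by
pixel counts), initialized at k evenly spaced count-weighted quantiles and
therefore deterministic for a fixed (image, k, seed). Levels are relabeled
so level 1 is the brightest centroid and level k the darkest; level k is
the background. The cumulative layer region at level q (`level_index <= q`)
is monotone in q, which is what lets dim, unevenly stained nuclear rims and
low-contrast micronuclei survive where a single global threshold would drop
them. Default k = 15; values outside 10–20 warn but run. If the image has
fewer than k distinct grays, k is reduced with a warning (a constant image
collapses to one level).

Sharpening is unsharp masking with a small (radius 1) Gaussian; amount 0 is
the identity. Both channels are sharpened by default; per-channel flags can
disable it.

## Region algebra

Set operations are lifted to whole components of N: a nucleus is kept or
removed as a unit, because pixel-literal subtraction would shred nuclei at
cytoskeleton gaps, and the counts are counts of nuclei. Classification
order per component: border-touching → B; else no cytoskeleton overlap
(≥ 1 shared pixel by default, `min_overlap_frac` configurable) → D; else in
P, where overlap with Y∩C → A and otherwise → M. B, D, P partition the
components of N; A and M partition P. `within_image = detected − boundary`,
where `detected` counts components overlapping Y and `boundary` the
detected border components; undetected border components are folded into
`invalid` together with D. Ratios are percentages over valid nuclei only
(normal + abnormal), rounded to one decimal, and reported as undefined
(NaN / `NA`) when there are no valid nuclei.

Foreground components smaller than `min_region_area` (default 25 px) are
discarded as noise speckle before the algebra; real nuclei at this
magnification are three orders of magnitude larger.

## Signature analysis

For one nucleus, the analysis runs on the cumulative layer masks restricted
to the nucleus's foreground footprint, over the middle color layers only:
`first = floor(k/5)+1`, `last = k − ceil(k/5)` (4–12 for k = 15). The
brightest fifth of layers carries nuclear texture and the darkest fifth
(background and near-background) carries no reliable contour. Layers whose
restricted mask touches the image border are excluded; layers where the
nucleus splits into several components (after dropping speckles below
`min_component_area`) are skipped.

The boundary is traced by Moore-neighbour (8-connected) border following in
chain-code order, then converted to the classic radial signature: S(m) =
distance from the nucleus center to the silhouette as a circular function
of polar angle, with L = (number of boundary pixels) angular samples, so
the curve length scales with the region. Where a protrusion makes the
boundary multivalued in angle, the outermost distance is kept; angular bins
the boundary skips are filled from the nearest filled bin (circularly).
Nearest-neighbour fill is deliberate: linear interpolation would smear a
silhouette discontinuity across two samples and halve its response. The
center is the centroid of the full footprint, held fixed across layers so
peak angles remain comparable (per-layer centroids drift as the
micronucleus surfaces).

The Haar detail kernel gives ψ(m) = (S(m) − S(m+1))/2 (circular; the sign
convention is irrelevant because decisions use |δ|). Its circular first
difference ψ′ is accumulated over a fixed 10-sample window into the
short-window energy δ(m) = Σ_{t=1..10} ψ′(m+t), which telescopes to
ψ(m+11) − ψ(m+1) — an identity the tests exploit as an independent oracle.
δ̄ is the mean of |δ|. Maximal circular runs with |δ| > δ̄/2 form the
candidate intervals (Ru); within each, the extremum passes if |δ| > μ
(default μ = 4, in pixels of centroid distance, hence resolution
dependent). The δ extremum leads the physical boundary feature by about
half a window, so the reported peak angle is read half a window ahead.

Because δ is a *lagged difference* of ψ, only near-discontinuities in S
reach μ: an attached micronucleus whose lobe overhangs the nuclear rim
produces a jump of its protrusion height; smooth lobes, digitization ripple
and moderate contour noise stay near |δ| ≈ 1. Peaks wider than the energy
window answer at both angular edges; same-layer peaks within the angular
tolerance are merged (single linkage, amplitude-weighted circular mean)
into one feature.

Passing peaks are associated across consecutive color layers by angular
proximity (default tolerance 15°). A chain spanning ≥ `persistence`
(default 3) layers calls the nucleus positive; skipped layers bridge a
chain without extending it. A single-layer peak is treated as texture. The
call records the supporting layers and the circular-mean angle of the best
chain.

## Synthetic scenes

The generator emulates what the pipeline must survive: disk nuclei with
radially falling staining (profile `rim + (peak − rim)(1 − (r/R)^p)`,
defaults peak 230, rim 35, p 2.5, R 40 px — sized to a 40× acquisition),
fragmented two-lobed mitotic-defect nuclei (withheld from the detector box
list, exercising the abnormal-by-omission route), nuclei clipped by the
border, nuclei outside the cytoskeleton, and noise. Noise is Gaussian with
amplitude proportional to √signal (shot-noise-like), σ = 3 at reference
intensity 100: stained regions are noisy, the unstained background stays
near-black, as in real 8-bit exports. Strictly iid background noise is not
used because on a dark 8-bit background it concentrates discrete mass at
gray values 0–2; histogram k-means then dedicates centroids to them and the
darkest-layer background rule fails by percolation — a regime the source
images evidently did not contain.

A micronucleus is rendered as a lobe of radius 0.28 R centered at
R + 0.8 r_b plus a connecting neck, so its silhouette overhangs — the jump
feature the analysis detects, and the actual morphology of an attached
micronucleus. Bump grayscale is calibrated per scene against the package's
own quantizer run on the bump-free scene *under the same noise
realization*: the micronucleus bump is painted at the centroid of the layer
three levels above the dimmest analyzed layer that still lies in the
stained intensity range (so it persists through ≥ 4 consecutive analyzed
layers), the texture bump at the centroid of that dimmest usable layer (so
it appears in exactly one). Generation fails loudly if fewer than four
analyzed layers are usable. Ground truth (per-nucleus masks, boxes,
expected region tag, bump angle, noiseless planes) is archived with every
scene.

What the generator does **not** emulate: optical point-spread blur,
chromatic aberration, touching/overlapping nuclei (the method itself is
limited to single separated nuclei), photobleaching gradients, and
real staining texture inside nuclei. Passing the recovery suite therefore
shows the algorithm does what it claims on its own feature model, not that
it matches human scoring on real micrographs.

## Problem sizes and numerical choices

The test and acceptance suites use 192² single-nucleus scenes (100 nuclei
for recovery), 384–512² composite scenes, 48² random layouts for the
algebra oracle, and 1,000 random signatures for the telescoping check;
a full 1360×1024 frame with 40 nuclei runs through the pipeline in a few
seconds. Ties in nearest-centroid assignment go to the brighter level;
k-means uses a deterministic quantile initialization so identical inputs
give identical quantizations; report ratios use round-half-even at one
decimal; empty foregrounds yield all-zero reports with NaN ratios rather
than errors.

## Known limitations

- One nucleus per connected component: clumps are not split (no watershed);
  a fused pair is analyzed as one region.
- μ is an absolute δ-amplitude in pixels and must be rescaled for very
  different magnifications or image resolutions.
- Micronuclei detached from their nucleus are only caught through the
  region algebra (M), never by the signature analysis.
- A nucleus overlapping several detector boxes is counted once.
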