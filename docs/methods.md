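# Methods

## Model

An image is a scalar field `f : {0..H-1} × {0..W-1} → [0,1]` (grayscale
intensity; RGB inputs pass through the linear luma converter
`(299R + 587G + 114B)/1000`, divided by 255). The sublevel filtration is the
nested family of pixel sets `{f ≤ t}` with 8-connectivity. Its 0-dimensional
persistent homology assigns each connected component a birth (the intensity
of its minimum) and a death (the intensity at which it merges into an older
component — the elder rule: of two merging components, the one with the later
birth dies). Components of long lifetime `d − b` are the image's objects;
exactly one component per image never dies, born at the global minimum.

The method rests on two generic assumptions: the objects of interest are
darker than their surroundings (for lighter objects the `polarity="light"`
option negates the image, equivalent to a superlevel filtration), and they do
not touch the image border whereas the background does.

## The pipeline and its parameters

| parameter | default | meaning |
|---|---|---|
| `sigma` | 0.1 | std. dev. of tie-breaking Gaussian noise, [0,1] scale (variance 0.01) |
| `k` | odd round of Δ(I)/25, ≥ 3 | smoothing window side, pixels |
| `l` | round of Δ(I)/100, ≥ 1 | border band width, pixels |
| `power` | 2 | inverse-distance-weighting exponent |
| `min_lifetime` | 1/255 | smallest lifetime entering threshold selection |

Δ(I) = √(H² + W²) is the image diagonal. Noise exists solely so every pixel
value is unique and each diagram point maps to a well-defined birth pixel; it
is applied before smoothing and is not clamped (the filtration only cares
about order, not range). Smoothing averages over the k×k window *restricted
to the image* — near an edge the divisor is the number of valid pixels, never
k². Border modification sets the l-pixel frame to `min(f) − 10⁻⁶`: placing
the band strictly below every pixel guarantees it is the earliest birth, so
the immortal component is the border by the elder rule rather than by a tie
break. Distance to the border is Chebyshev (the band is a square frame).

Threshold selection sorts the finite lifetimes in decreasing order and scans
consecutive differences; τ is the midpoint of the first largest gap
(deterministic, maximal margin on both sides). Lifetimes below one 8-bit
gray level (1/255) are excluded first: a feature of sub-quantization lifetime
is not displayable and only pads the gap statistics. Degenerate inputs are
defined explicitly: a single lifetime is selected with the gap ratio reported
infinite; all-equal lifetimes select everything with ratio 0 (flagged
unstable).

Object marking extracts every selected component at one common level — the
strict sublevel set just below the minimum selected death. Strictness makes
the masks exactly the components "right before their lowest death-time":
each selected birth pixel lies in its own 8-connected component of
`{f < level}`, and the masks are disjoint by construction. The selected set
is closed under the elder rule (a component's killer has an earlier birth and
a no-shorter lifetime), so no selected component can be missing at that
level. Should a selected point's birth nonetheless reach the common level
(possible only with duplicated values), that component falls back to
extraction just below its own death, with a warning.

The IDW fill gives each background pixel the weighted mean of, per marked
component, the value of its nearest component pixel (one Euclidean distance
transform per component, `O(cn)` total), with weights `dist^(−power)`;
marked pixels keep their values. With one component this is a plain
nearest-value fill; equidistant pixels average their sources for any power.

Runtime is `O(n(α(n) + log n + c))` for n pixels and c marked objects: the
union-find uses path compression and union by rank, threshold selection sorts
the diagram, and marking/filling are a constant number of labelling and
distance-transform passes per object.

## 1-dimensional persistence

Loops are needed only for diagram demonstrations, not for object detection.
They are computed by the standard digital-topology duality — a hole of the
8-connected sublevel set is a bounded 4-connected component of the strict
complement `{f > t}` — as union-find over complement pixels in decreasing
order, with a virtual node permanently joining all image-border pixels
(whose component, the unbounded background, is discarded). A hole's birth is
the intensity whose pixel completes the surrounding cycle; its death is the
intensity filling the pocket. This reproduces the annulus case exactly and
agrees with the brute-force Betti-curve oracle on random images; it avoids
building an explicit 2-complex, where the treatment of 4-cliques of the
8-neighbourhood graph would be ambiguous.

An independent oracle (`betti_curve_oracle`) recounts components per
threshold by BFS labelling and is used in tests to verify both engines
exactly; the bottleneck distance (binary search over candidate costs with a
bipartite matching feasibility test, diagonal matches at half-lifetime,
infinite points matched by birth) verifies the stability inequality
`d_b ≤ ‖f − g‖∞` on random perturbation pairs.

## Metrics

Accuracy, Dice `2TP/(2TP+FP+FN)` and inclusion (recall) `TP/(TP+FN)` follow
the usual definitions. MCC is computed with the square-root denominator
`sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))` — the standard form, and the only one
for which the range [−1, 1] holds; an unrooted variant is available behind
`rooted=False` for comparison. Zero denominators return 0.0 and are
reported by `is_degenerate`.

## Synthetic scenes: what they emulate and what they do not

The generators are deterministic given a seed and produce connected ground
truths marking the lesion only.

* `digits_scene`: a '1' (bar + serif foot) and an '8' (two overlapping
  annuli), dark (≈0.1) on light (≈0.9) with mild texture — two components,
  two holes, drawn procedurally so no font is involved.
* `lesion_scene` (128×128 default): elliptical lesion (intensity 0.25) on a
  textured background (0.85, σ = 0.02), four 1-px hairs (0.3), a half-disk
  distractor clipped by the border (0.3); options add a global illumination
  gradient, an inflammation-style radial ramp, or a two-lobed lesion whose
  lobes (two filtration components) are joined by a lighter scar so the
  ground truth stays connected.
* `low_contrast_scene`: a lesion of depth `contrast` (default 0.02) over
  smooth background mottling (fourteen Gaussian wells, depths 0.005–0.035).
  The mottling is deliberately smooth: the contrast diagnostic concerns
  structural lifetimes, and pixel-level texture would be removed by
  smoothing anyway.

These scenes reproduce the *topological* structure of dermoscopy images —
relative contrasts, border-touching clutter, thin curvilinear distractors —
but not their photometric statistics: no color, no specular highlights, no
camera vignetting, and piecewise-constant rather than natural texture.
Passing fixture-scale tests therefore demonstrates the mechanism (clutter
removal, correct object counts, directional segmentation improvement), not
performance figures transferable to any particular real corpus; the batch
evaluator exists for running real image sets.

## The contrast diagnostic and tie-breaking noise

The ratio of the largest lifetime gap to the mean gap is bounded above by
the number of gaps, and the mean gap shrinks roughly as 1/|D|. Tie-breaking
noise inflates |D| with hundreds of near-zero lifetimes, which drives the
ratio far above 4 regardless of contrast. The diagnostic is therefore
computed on diagrams free of injected noise: synthetic scenes are
continuous-valued and need no tie-breaking (σ = 0), and the 1/255 lifetime
floor removes sub-quantization features. On real 8-bit images the same
effect is obtained by the floor alone once smoothing has reduced the
injected noise below one gray level per the σ/k averaging law.

## Problem sizes

The shipped checks use 96–128 px scenes (persistence in well under a second
per image), 20-scene batches for segmentation comparisons, 16×16 images for
the exact oracle and bottleneck-stability sweeps, and 64–256 px scenes for
the near-linearity check of the runtime — sizes at which every quantity is
recomputed from scratch in seconds while exercising the full pipeline.

## Known limitations

* Objects lighter than the background require the polarity flag; objects
  both lighter and darker in one image need a different filtration function
  altogether.
* Prominent irrelevant objects that do not touch the border (e.g. a marker
  circle around a lesion) survive TIM by design.
* Death-times usually occur after the whole object plus a halo of its
  surrounding gradient is included, so marked masks systematically
  overestimate the object; the IDW fill and a downstream segmenter, not the
  mask itself, produce the final segmentation.
* The Chan–Vese wrapper orients its two phases toward the darker region;
  on images where the object is not the darker phase this convention fails.
* Transparent/excluded pixels are not supported; every pixel participates in
  the filtration.
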