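# topoimage

Unsupervised object detection and contrast enhancement for raster images via
persistent homology, with skin-lesion segmentation as the motivating
application.

Generic unsupervised segmenters (Chan–Vese, ISODATA thresholding, isocontour
filling, …) fail on real-world images because *irrelevant* objects — hairs,
rulers, a second lesion clipped by the frame, sensor texture — are just as
salient as the object of interest. `topoimage` addresses this without any
supervision, in three stages:

1. **Topological image modification (TIM).** The image is converted to
   grayscale, `gray(p) = (299R + 587G + 114B)/1000` rescaled to [0, 1], and a
   small Gaussian noise (σ = 0.1) is added so every pixel value is unique.
   Mean-filter smoothing over a k×k window (k ≈ Δ(I)/25, where Δ(I) is the
   image diagonal in pixels) destroys small-scale topological features.
   Border modification sets an l-pixel frame (l ≈ Δ(I)/100) to the lowest
   intensity, so by the elder rule the single infinite-persistence component
   of the sublevel filtration *is* the border, and every border-touching
   object is born through it.
2. **Topological image processing (TIP).** 0-dimensional persistent homology
   of the sublevel filtration {f ≤ t} (8-connected pixels) is computed with a
   union-find engine that tracks birth and death pixels. Sorting the finite
   lifetimes in decreasing order, the threshold τ is placed in the middle of
   the largest gap between consecutive lifetimes; the c components with
   lifetime above τ are marked as the 8-connected components of the strict
   sublevel set just below their lowest death-time. Background pixels are
   then filled by inverse distance weighting of, per marked component, its
   nearest pixel's value — yielding a clean, contrast-enhanced image.
3. **Segmentation.** Any off-the-shelf unsupervised segmenter is run on the
   processed image; wrappers for six methods and confusion-matrix metrics
   (accuracy, Dice, MCC, inclusion/recall) are included.

The ratio of the largest lifetime gap to the mean gap doubles as a contrast
diagnostic: ratios below 4 flag images where objects cannot be reliably
separated from the background.

## Worked example

`examples/03_process_and_segment.py` builds a synthetic 128×128 lesion scene
(dark elliptical lesion, four hair-like curves, a half-disk lesion clipped by
the border, background texture), processes it, and scores three segmenters
against the ground truth:

```
status: ok, objects: 1, stability ratio: 282.5
 Chan-Vese: Dice 0.732 raw -> 0.990 processed
   ISODATA: Dice 0.680 raw -> 0.986 processed
isocontour: Dice 0.000 raw -> 0.860 processed
```

Exactly one object is marked (the interior lesion — hairs are destroyed by
smoothing, the border lesion is absorbed into the immortal border component),
the stability ratio far above 4 says the threshold is trustworthy, and every
segmenter's Dice score against the true lesion improves on the processed
image. The raw isocontour score of 0.000 is real: hairs connect the lesion's
isocontour to the frame, so the filled polygons cover everything *but* the
lesion. The other examples demonstrate diagram computation on a two-digit
image (`01`), TIM and object marking step by step (`02`), and the
low-contrast flag (`04`).

A thin CLI mirrors the library:

```sh
tip demo --scene lesion --seed 0 --out demo/
tip process scene.png --out processed.png --masks-dir masks/ --auto
tip segment processed.png --method isodata --out mask.png
tip evaluate mask.png truth.png
```

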