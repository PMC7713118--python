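"""Generic unsupervised segmenters applied downstream of TIP.

Six established methods — Chan-Vese level sets, ISODATA thresholding,
isocontour filling, k-means superpixels, Roberts edge detection, and active
contours — wrapped behind a uniform interface.  These are published
algorithms delegated to scikit-image with standard settings; the point of the
package is what happens to the image *before* they run.

Each wrapper is a pure function of its inputs and returns a
:class:`SegmentationResult` recording the binary mask, the method name and
the exact parameters used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from skimage import draw, filters, measure, morphology, segmentation

from .images import validate_gray
from .tip import ObjectMarking

__all__ = [
    "SegmentationResult",
    "chan_vese",
    "isodata_threshold",
    "isocontour_segment",
    "superpixels",
    "roberts_edges",
    "active_contour_segment",
]


@dataclass
class SegmentationResult:
    mask: np.ndarray
    method: str
    params: dict = field(default_factory=dict)


def chan_vese(img: np.ndarray) -> SegmentationResult:
    """Chan-Vese level-set segmentation with standard settings.

    The evolved region may fail to converge within the default iteration
    budget (leaving checkerboard artefacts from the initial level set); that
    is reported as-is, never raised.  The darker of the two phases is taken
    as the segmentation.
    """
    arr = validate_gray(img)
    seg = segmentation.chan_vese(arr, mu=0.25, lambda1=1.0, lambda2=1.0)
    # orient the phase so that the mask marks the darker region
    if seg.any() and (~seg).any():
        if arr[seg].mean() > arr[~seg].mean():
            seg = ~seg
    return SegmentationResult(seg.astype(bool), "chan_vese", {"mu": 0.25})


def isodata_threshold(img: np.ndarray) -> SegmentationResult:
    """Pixels darker than the ISODATA threshold.

    A constant image has no threshold; the degenerate result is an empty mask.
    """
    arr = validate_gray(img)
    if np.ptp(arr) == 0:
        return SegmentationResult(
            np.zeros_like(arr, dtype=bool), "isodata", {"threshold": None}
        )
    t = float(filters.threshold_isodata(arr))
    return SegmentationResult(arr < t, "isodata", {"threshold": t})


def isocontour_segment(img: np.ndarray, level: float | None = None) -> SegmentationResult:
    """Fill the closed isovalued contours of the image at ``level``.

    Contours are extracted by marching squares and treated as polygons in the
    plane; their filled union is the mask, so lighter patches enclosed by a
    contour are filled in too.  The default level is the image mean.  A level
    outside the intensity range yields an empty mask.
    """
    arr = validate_gray(img)
    if level is None:
        level = float(arr.mean())
    mask = np.zeros_like(arr, dtype=bool)
    if np.ptp(arr) == 0 or not (arr.min() < level < arr.max()):
        return SegmentationResult(mask, "isocontour", {"level": level})
    for contour in measure.find_contours(arr, level):
        rr, cc = draw.polygon(contour[:, 0], contour[:, 1], shape=arr.shape)
        mask[rr, cc] = True
    return SegmentationResult(mask, "isocontour", {"level": level})


def superpixels(
    img: np.ndarray, n: int = 20, marking: ObjectMarking | None = None
) -> SegmentationResult:
    """k-means (SLIC) oversegmentation into ``n`` superpixels, reduced to binary.

    With a marking, the mask is the union of superpixels whose majority of
    pixels lie inside the marked objects.  Without one, superpixels darker
    than the image mean are kept (a documented convention; the oversegmentation
    itself carries no notion of foreground).
    """
    arr = validate_gray(img)
    # compactness tuned to the [0, 1] intensity scale (the library default
    # assumes byte-scaled values and would yield a pure spatial grid here)
    labels = segmentation.slic(
        arr,
        n_segments=n,
        channel_axis=None,
        start_label=1,
        compactness=1.0,
        enforce_connectivity=True,
    )
    mask = np.zeros_like(arr, dtype=bool)
    ids = np.unique(labels)
    if marking is not None and len(marking) > 0:
        marked = marking.union()
        for lab in ids:
            region = labels == lab
            if marked[region].mean() > 0.5:
                mask |= region
    else:
        mean = arr.mean()
        for lab in ids:
            region = labels == lab
            if arr[region].mean() < mean:
                mask |= region
    if len(ids) == 1:
        mask = np.ones_like(arr, dtype=bool)
    return SegmentationResult(mask, "superpixels", {"n_segments": n, "compactness": 1.0})


def roberts_edges(img: np.ndarray) -> SegmentationResult:
    """Roberts' cross edge magnitude, thresholded at its mean."""
    arr = validate_gray(img)
    edges = filters.roberts(arr)
    return SegmentationResult(edges > edges.mean(), "roberts", {"threshold": "mean"})


def _mask_init_snake(mask: np.ndarray, n_points: int = 200) -> np.ndarray:
    """Closed initial snake: the 1-px-dilated convex hull boundary of a mask."""
    hull = morphology.convex_hull_image(mask)
    hull = binary_dilation(hull, iterations=1)
    contours = measure.find_contours(hull.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary to initialize a contour")
    boundary = max(contours, key=len)
    idx = np.linspace(0, len(boundary) - 1, n_points).astype(int)
    return boundary[idx]


def active_contour_segment(
    img: np.ndarray, marking: ObjectMarking
) -> SegmentationResult:
    """Fit one closed snake per marked object, initialized at its convex hull.

    Active contours need an initial curve surrounding the object; the marked
    areas provide exactly that, which is why this method is unusable on
    unmodified images.  The snake shrinks inward from the slightly dilated
    hull; its interior is the segmentation.
    """
    arr = validate_gray(img)
    if marking is None or len(marking) == 0:
        raise ValueError(
            "active contour segmentation requires a non-empty object marking "
            "to initialize the snake"
        )
    mask = np.zeros_like(arr, dtype=bool)
    for obj in marking.masks:
        init = _mask_init_snake(obj)
        snake = segmentation.active_contour(
            filters.gaussian(arr, sigma=1.0, preserve_range=True), init
        )
        rr, cc = draw.polygon(snake[:, 0], snake[:, 1], shape=arr.shape)
        mask[rr, cc] = True
    return SegmentationResult(mask, "active_contour", {"init": "convex_hull+1px"})
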