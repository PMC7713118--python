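"""Procedural test scenes with ground truth.

Everything here is synthetic: deterministic, seed-driven generators that
emulate the situations the pipeline is designed for, without any dataset
download.

* :func:`digits_scene` renders a '1' and an '8' (procedural bars and annuli,
  no fonts) dark on light — an image with exactly two components and two
  loops, the classic persistent-homology demonstration.
* :func:`lesion_scene` renders a lesion-like scene: a dark elliptical blob
  (the object of interest, recorded in the ground-truth mask), thin dark
  hair-like polylines, a dark half-disk clipped by the image border (a
  distractor lesion), fine background texture, and optionally a global
  illumination gradient or a two-lobed lesion split by a lighter scar.
* :func:`low_contrast_scene` renders a lesion whose depth is comparable to
  the smooth background mottling — the pathological case where lifetime
  thresholding is unreliable and the stability-ratio flag should fire.

Ground-truth masks mark the lesion only (never hairs or the distractor) and
are always connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw

__all__ = ["SceneSpec", "digits_scene", "lesion_scene", "low_contrast_scene"]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a lesion-like scene.

    Intensities are on the [0, 1] scale; the lesion must be darker than the
    background base and must not touch the image border.
    """

    size: tuple[int, int] = (128, 128)
    lesion_center: tuple[float, float] | None = None  # default: image center
    lesion_radii: tuple[float, float] = (24.0, 18.0)
    lesion_intensity: float = 0.25
    inflammation_gradient: bool = False
    two_lobed: bool = False
    n_hairs: int = 4
    hair_thickness: int = 1
    hair_intensity: float = 0.3
    border_distractor: bool = True
    distractor_intensity: float = 0.3
    background: float = 0.85
    texture_sigma: float = 0.02
    background_gradient: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError("scene must be at least 32x32")
        if self.lesion_intensity >= self.background:
            raise ValueError("lesion must be darker than the background base")
        cy, cx = self.lesion_center or (h / 2, w / 2)
        ry, rx = self.lesion_radii
        if cy - ry < 4 or cy + ry > h - 4 or cx - rx < 4 or cx + rx > w - 4:
            raise ValueError("lesion must not approach the image border")


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = center
    ry, rx = radii
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def digits_scene(size: tuple[int, int] = (96, 96), seed: int = 0):
    """A '1' and an '8' dark on light, with mild background texture.

    The scene has exactly two dark components, and exactly two loops (the
    holes of the '8').  Returns ``(image, expected)`` where ``expected`` is
    ``{"h0_outliers": 2, "h1_outliers": 2}``.
    """
    h, w = size
    if h < 64 or w < 64:
        raise ValueError("digits scene needs at least 64x64")
    rng = np.random.default_rng(seed)
    img = np.full((h, w), 0.9)
    img += rng.normal(0.0, 0.01, size=img.shape)

    glyph = np.zeros((h, w), dtype=bool)
    # the '1': a vertical bar with a serif foot
    r0, r1 = int(0.2 * h), int(0.8 * h)
    c0 = int(0.28 * w)
    bar = max(2, int(0.05 * w))
    glyph[r0:r1, c0 : c0 + bar] = True
    glyph[r1 - bar : r1, c0 - bar : c0 + 2 * bar] = True  # foot
    # the '8': two slightly overlapping annuli
    cx = int(0.68 * w)
    router = 0.16 * h
    rinner = 0.08 * h
    for cy in (0.36 * h, 0.64 * h):
        outer = _ellipse_mask((h, w), (cy, cx), (router, router))
        inner = _ellipse_mask((h, w), (cy, cx), (rinner, rinner))
        glyph |= outer & ~inner

    img[glyph] = 0.1 + rng.normal(0.0, 0.01, size=int(glyph.sum()))
    return img, {"h0_outliers": 2, "h1_outliers": 2}


def lesion_scene(spec: SceneSpec | None = None, **overrides):
    """A lesion-like scene with clutter; returns ``(image, truth_mask)``.

    The truth mask marks the lesion only.  With ``two_lobed=True`` the lesion
    is two dark lobes joined by a lighter scar band; the truth mask covers
    lobes and scar (one connected lesion), while the sublevel filtration sees
    two components.
    """
    spec = replace(spec, **overrides) if spec is not None else SceneSpec(**overrides)
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    img = np.full((h, w), spec.background)
    if spec.background_gradient:
        # illumination darker toward the lesion, as in backlit dermoscopy
        yy = np.linspace(0.0, 1.0, h)[:, None]
        img -= 0.12 * (1.0 - np.abs(2 * yy - 1.0))
    img += rng.normal(0.0, spec.texture_sigma, size=img.shape)

    # hairs: thin dark polylines spanning the frame, drawn under the lesion
    for _ in range(spec.n_hairs):
        edge = rng.integers(0, 2)
        if edge == 0:
            r_start, c_start = 0, int(rng.integers(0, w))
            r_end, c_end = h - 1, int(rng.integers(0, w))
        else:
            r_start, c_start = int(rng.integers(0, h)), 0
            r_end, c_end = int(rng.integers(0, h)), w - 1
        rr, cc = draw.line(r_start, c_start, r_end, c_end)
        hair = np.zeros((h, w), dtype=bool)
        hair[rr, cc] = True
        for _ in range(spec.hair_thickness - 1):
            hair |= np.roll(hair, 1, axis=1)
        img[hair] = spec.hair_intensity

    if spec.border_distractor:
        # half-disk clipped by the left edge
        cy = int(0.2 * h)
        rad = 0.18 * min(h, w)
        dist = _ellipse_mask((h, w), (cy, 0), (rad, rad))
        img[dist] = spec.distractor_intensity

    center = spec.lesion_center or (h / 2, w / 2)
    if spec.two_lobed:
        ry, rx = spec.lesion_radii
        off = rx * 0.9
        lobe1 = _ellipse_mask((h, w), (center[0], center[1] - off), (ry, rx * 0.7))
        lobe2 = _ellipse_mask((h, w), (center[0], center[1] + off), (ry, rx * 0.7))
        scar = _ellipse_mask((h, w), center, (ry * 0.5, rx * 0.5)) & ~lobe1 & ~lobe2
        img[lobe1 | lobe2] = spec.lesion_intensity
        # the scar sits well above the lobes but below the background, so the
        # filtration sees two components while the ground truth stays connected
        img[scar] = spec.lesion_intensity + 0.75 * (spec.background - spec.lesion_intensity)
        truth = lobe1 | lobe2 | scar
    else:
        truth = _ellipse_mask((h, w), center, spec.lesion_radii)
        if spec.inflammation_gradient:
            yy, xx = np.mgrid[0:h, 0:w]
            ry, rx = spec.lesion_radii
            r = np.sqrt(((yy - center[0]) / ry) ** 2 + ((xx - center[1]) / rx) ** 2)
            ramp = spec.lesion_intensity + (spec.background - spec.lesion_intensity) * (
                r / 1.0
            )
            img[truth] = ramp[truth]
        else:
            img[truth] = spec.lesion_intensity
    img[truth] += rng.normal(0.0, spec.texture_sigma, size=int(truth.sum()))
    return img, truth


def low_contrast_scene(
    size: tuple[int, int] = (128, 128), seed: int = 0, contrast: float = 0.02
):
    """A lesion barely darker than a mottled background; returns the image.

    The background is smooth mottling — a dozen shallow Gaussian wells whose
    depths span the same range as ``contrast`` — so the lesion's lifetime sits
    inside the bulk of the lifetime distribution and the largest-gap/mean-gap
    stability ratio stays below 4.  Raising ``contrast`` tenfold (0.2)
    restores a clear outlying lifetime and clears the flag.  The mottling is
    deliberately smooth (no pixel-level texture): the contrast diagnostic
    concerns structural lifetimes, and fine texture would be removed by
    smoothing anyway.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    img = np.full((h, w), 0.8)
    yy, xx = np.mgrid[0:h, 0:w]
    # smooth background mottling: shallow Gaussian wells
    for _ in range(14):
        cy, cx = rng.uniform(0.1 * h, 0.9 * h), rng.uniform(0.1 * w, 0.9 * w)
        depth = rng.uniform(0.005, 0.035)
        s = rng.uniform(0.04, 0.08) * min(h, w)
        img -= depth * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)))
    lesion = _ellipse_mask((h, w), (h / 2, w / 2), (0.18 * h, 0.14 * w))
    img[lesion] -= contrast
    return img
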