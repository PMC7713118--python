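"""Topological image modification (TIM).

TIM alters an image so that its persistence diagram reflects only the objects
of interest:

* **Smoothing** (destructive) averages each pixel over a ``k x k`` window
  restricted to the image, destroying small-scale topological features such
  as hairs and sensor texture.
* **Border modification** (constructive) forces an ``l``-pixel frame to the
  lowest intensity, so that by the elder rule the single infinite-persistence
  component is the border itself and every object touching it is born through
  the border — all border-connected clutter collapses into one diagram point.

The window and band widths scale with the image diagonal Delta(I):
``k ~ Delta/25`` (rounded to the nearest odd integer, at least 3) and
``l ~ Delta/100`` (at least 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .images import add_noise, diagonal, validate_gray

__all__ = ["TimParams", "default_params", "smooth", "border_modify", "modify"]

#: Offset below the image minimum used for the border band, on the [0, 1]
#: scale.  Placing the band strictly below every pixel guarantees it is the
#: earliest birth even under noise ties, so the elder rule makes the band the
#: infinite component without relying on tie-breaking.
BORDER_DELTA = 1e-6


@dataclass(frozen=True)
class TimParams:
    """Parameters of the TIM pipeline.

    k: odd smoothing window side (pixels); l: border band width (pixels);
    sigma: tie-breaking noise standard deviation on the [0, 1] scale;
    polarity: 'dark' detects dark-on-light objects via the sublevel
    filtration, 'light' negates the image first (equivalent to a superlevel
    filtration).
    """

    k: int = 3
    l: int = 1
    sigma: float = 0.1
    seed: int = 0
    polarity: str = "dark"

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be a positive odd integer, got {self.k}")
        if self.l < 1:
            raise ValueError(f"l must be >= 1, got {self.l}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.polarity not in ("dark", "light"):
            raise ValueError(f"polarity must be 'dark' or 'light', got {self.polarity!r}")


def default_params(img: np.ndarray, seed: int = 0, polarity: str = "dark") -> TimParams:
    """Diagonal-scaled defaults: k ~ Delta/25 (odd, >= 3), l ~ Delta/100 (>= 1).

    The noise level sigma = 0.1 corresponds to a variance of 0.01 on the
    [0, 1] intensity scale.
    """
    arr = validate_gray(img)
    d = diagonal(arr)
    k = int(round(d / 25.0))
    if k % 2 == 0:
        k += 1
    k = max(3, k)
    l = max(1, int(round(d / 100.0)))
    if l >= min(arr.shape) / 2:
        raise ValueError(
            f"border band l={l} would cover the whole {arr.shape} image"
        )
    return TimParams(k=k, l=l, sigma=0.1, seed=seed, polarity=polarity)


def smooth(img: np.ndarray, k: int) -> np.ndarray:
    """Mean filter over a k x k window clipped to the image.

    The window is undefined beyond the image borders: near an edge the divisor
    is the number of in-image pixels, not k^2.  ``k = 1`` is the identity.
    """
    arr = validate_gray(img)
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be a positive odd integer, got {k}")
    if k == 1:
        return arr.copy()
    sums = uniform_filter(arr, size=k, mode="constant", cval=0.0) * (k * k)
    counts = uniform_filter(np.ones_like(arr), size=k, mode="constant", cval=0.0) * (
        k * k
    )
    return sums / counts


def border_modify(img: np.ndarray, l: int) -> np.ndarray:
    """Set the l-pixel frame (Chebyshev distance < l from the border) to the lowest value.

    The band value is the global minimum minus a small offset, so the band is
    strictly the earliest birth of the sublevel filtration: the infinite
    component is the border, and every object touching the band is born
    through it.
    """
    arr = validate_gray(img)
    h, w = arr.shape
    if not 1 <= l < min(h, w) / 2:
        raise ValueError(f"need 1 <= l < min(H, W)/2, got l={l} for shape {arr.shape}")
    out = arr.copy()
    band_value = arr.min() - BORDER_DELTA
    out[:l, :] = band_value
    out[-l:, :] = band_value
    out[:, :l] = band_value
    out[:, -l:] = band_value
    return out


def band_mask(shape: tuple[int, int], l: int) -> np.ndarray:
    """Boolean mask of the l-pixel border band."""
    m = np.zeros(shape, dtype=bool)
    m[:l, :] = True
    m[-l:, :] = True
    m[:, :l] = True
    m[:, -l:] = True
    return m


def modify(img: np.ndarray, params: TimParams) -> np.ndarray:
    """Full TIM pipeline: (negate if light polarity) -> noise -> smooth -> border band.

    Deterministic given ``params.seed``.
    """
    arr = validate_gray(img)
    if params.polarity == "light":
        arr = 1.0 - arr
    arr = add_noise(arr, params.sigma, params.seed)
    arr = smooth(arr, params.k)
    return border_modify(arr, params.l)
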