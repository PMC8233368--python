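"""Maximum-entropy (Kapur) automatic thresholding on 8-bit histograms.

The criterion: for a candidate threshold t, split the normalized histogram
into background bins [0..t] and foreground bins [t+1..255] and maximize the
sum of the two within-class Shannon entropies,

    H(t) = H_b(t) + H_f(t),
    H_b(t) = -sum_{v<=t} (p_v / P_b) ln(p_v / P_b),   P_b = sum_{v<=t} p_v,

with the foreground term defined symmetrically. Zero-probability bins
contribute nothing. Only candidates with both classes non-empty are admitted;
ties break toward the smallest t so results are platform-stable. Entropies use
the natural log (the base does not affect the argmax). Foreground is the set
of pixels with intensity strictly greater than t.

The same threshold serves both B-mode fascicle selection and Doppler signal
selection; both compute the histogram over ROI pixels only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateHistogramError, EmptyRegionError, ParameterError
from .io_roi import BinaryMask, Frame

__all__ = ["Histogram256", "histogram256", "max_entropy_threshold", "apply_threshold"]


@dataclass(frozen=True)
class Histogram256:
    """Intensity histogram with exactly 256 bins."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,):
            raise ParameterError("histogram must have exactly 256 bins")
        if (c < 0).any():
            raise ParameterError("histogram counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_occupied(self) -> int:
        return int((self.counts > 0).sum())


def _as_gray_array(image: Frame | np.ndarray) -> np.ndarray:
    arr = image.pixels if isinstance(image, Frame) else np.asarray(image)
    if arr.ndim != 2:
        raise ParameterError("expected a grayscale (2-D) image")
    return arr.astype(np.uint8, copy=False)


def histogram256(image: Frame | np.ndarray, mask: BinaryMask | np.ndarray) -> Histogram256:
    """Histogram of the masked pixels. Raises on an empty mask."""
    arr = _as_gray_array(image)
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if m.shape != arr.shape:
        raise ParameterError("mask shape does not match image shape")
    values = arr[m]
    if values.size == 0:
        raise EmptyRegionError("histogram over an empty region")
    return Histogram256(np.bincount(values, minlength=256))


def max_entropy_threshold(hist: Histogram256) -> int:
    """Kapur maximum-entropy threshold in [0, 254].

    Raises :class:`DegenerateHistogramError` when fewer than two bins are
    occupied (no split can separate two classes).
    """
    counts = hist.counts
    if hist.n_occupied < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than two occupied bins; no threshold separates "
            "two classes"
        )
    p = counts / counts.sum()
    plogp = np.where(p > 0, p * np.log(p, where=p > 0, out=np.zeros_like(p)), 0.0)
    cum_p = np.cumsum(p)
    cum_plogp = np.cumsum(plogp)
    p_b = cum_p[:255]
    p_f = 1.0 - p_b
    valid = (p_b > 0) & (p_f > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_b = np.log(p_b) - cum_plogp[:255] / p_b
        h_f = np.log(p_f) - (cum_plogp[255] - cum_plogp[:255]) / p_f
    criterion = np.where(valid, h_b + h_f, -np.inf)
    return int(np.argmax(criterion))  # argmax takes the first (smallest) maximizer


def apply_threshold(
    image: Frame | np.ndarray, t: int, mask: BinaryMask | np.ndarray
) -> BinaryMask:
    """Binarize: true exactly where the mask is true and intensity > t."""
    if not 0 <= int(t) <= 254:
        raise ParameterError(f"threshold must lie in [0, 254], got {t}")
    arr = _as_gray_array(image)
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if m.shape != arr.shape:
        raise ParameterError("mask shape does not match image shape")
    return BinaryMask(m & (arr > int(t)))
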