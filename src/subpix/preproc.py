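"""Image preprocessing: Hann amplitude filtering, gamma adjustment, and
automatic threshold selection (Otsu, intermodes).

The Hann amplitude filter is a radially windowed raised-cosine low-pass
kernel; it suppresses high-frequency noise (AWGN, optical side lobes) before
blob detection.  Thresholds are computed on a fixed 256-bin histogram over
``[0, 1]`` (equivalently, the 8-bit representation of the image), so they are
directly comparable across images and reportable on the 0-255 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "HannKernel",
    "ThresholdResult",
    "hann_kernel",
    "hann_filter",
    "gamma_adjust",
    "image_histogram",
    "otsu_threshold",
    "intermodes_threshold",
    "intermodes_from_histogram",
]

N_BINS = 256


@dataclass(frozen=True)
class HannKernel:
    """A 2-D Hann window kernel of size ``n x n``, normalized to unit sum.

    The raw weight at Euclidean distance r from the center is
    ``w(r) = 0.5 * (1 - cos(2 pi (r - (n-1)/2) / (n-1)))`` for
    ``r <= (n-1)/2`` and 0 beyond; normalization preserves the mean intensity
    under filtering, keeping thresholds on the same scale.
    """

    n: int
    weights: np.ndarray


@dataclass(frozen=True)
class ThresholdResult:
    """A selected intensity threshold with its provenance.

    ``threshold`` is on the image's ``[0, 1]`` scale; ``threshold_8bit`` is
    the equivalent 0-255 histogram bin.  Foreground is ``img > threshold``.
    """

    threshold: float
    threshold_8bit: int
    histogram: np.ndarray
    method: str


def hann_kernel(n: int) -> HannKernel:
    """Build the unit-sum ``n x n`` Hann window kernel (``n`` odd, >= 3)."""
    if n < 3 or n % 2 == 0:
        raise ValueError("n must be an odd integer >= 3")
    half = (n - 1) / 2.0
    ax = np.arange(n) - half
    r = np.hypot(ax[:, None], ax[None, :])
    w = np.where(r <= half, 0.5 * (1.0 - np.cos(2.0 * np.pi * (r - half) / (n - 1))), 0.0)
    return HannKernel(n=n, weights=w / w.sum())


def hann_filter(img: np.ndarray, n: int = 5) -> np.ndarray:
    """Correlate the image with the unit-sum Hann kernel (reflect padding).

    The kernel is symmetric, so correlation equals convolution.  Constant
    images are fixed points.
    """
    img = np.asarray(img, dtype=float)
    if min(img.shape) < n:
        raise ValueError("kernel larger than image")
    return ndimage.correlate(img, hann_kernel(n).weights, mode="reflect")


def gamma_adjust(img: np.ndarray, gamma: float) -> np.ndarray:
    """Raise every pixel to the power ``gamma`` (gamma > 1 boosts contrast of
    bright objects relative to dim ones); preserves ``[0, 1]`` and ordering."""
    if not gamma > 0:
        raise ValueError("gamma must be > 0")
    return np.power(np.asarray(img, dtype=float), gamma)


def image_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin histogram of the 8-bit representation ``round(v * 255)``."""
    img = np.asarray(img, dtype=float)
    levels = np.clip(np.floor(img * 255.0 + 0.5), 0, 255).astype(np.intp)
    return np.bincount(levels.ravel(), minlength=N_BINS).astype(np.int64)


def _otsu_bin(hist: np.ndarray) -> int:
    """Between-class-variance maximizing split of a 256-bin histogram.

    Threshold bin t separates classes {0..t} and {t+1..255}; ties break to
    the lowest t (classic cumulative-moment formulation).
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    bins = np.arange(hist.size)
    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    m0 = np.cumsum(hist * bins)[:-1]
    m1 = (hist * bins).sum() - m0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise ValueError("no bimodal structure: constant image")
    sigma_b = np.full(hist.size - 1, -np.inf)
    sigma_b[valid] = w0[valid] * w1[valid] * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    return int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer


def otsu_threshold(img: np.ndarray) -> ThresholdResult:
    """Automatic threshold maximizing between-class variance (Otsu).

    Only the threshold value is meant to feed blob detection; positions are
    then computed from the original gray values, not a binarized image.
    """
    hist = image_histogram(img)
    t = _otsu_bin(hist)
    return ThresholdResult(threshold=t / 255.0, threshold_8bit=t,
                           histogram=hist, method="otsu")


def _smooth3(hist: np.ndarray) -> np.ndarray:
    """One 3-bin running-average pass with reflected ends."""
    padded = np.concatenate(([hist[0]], hist, [hist[-1]]))
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _local_maxima(hist: np.ndarray) -> np.ndarray:
    """Indices of local maxima; plateaus collapse to their leftmost bin."""
    maxima = []
    i, n = 0, hist.size
    while i < n:
        j = i
        while j + 1 < n and hist[j + 1] == hist[i]:
            j += 1
        left_ok = i == 0 or hist[i - 1] < hist[i]
        right_ok = j == n - 1 or hist[j + 1] < hist[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            maxima.append(i)
        i = j + 1
    return np.asarray(maxima, dtype=int)


def intermodes_from_histogram(hist: np.ndarray, max_iter: int = 10_000
                              ) -> tuple[float, np.ndarray]:
    """Iterate 3-bin smoothing until exactly two local maxima survive.

    Returns ``(threshold_bin, smoothed_histogram)``; the threshold is the
    arithmetic mean of the two surviving maximum positions.
    """
    h = np.asarray(hist, dtype=float).copy()
    if (h > 0).sum() < 2:
        raise ValueError("no bimodal structure: constant image")
    for _ in range(max_iter):
        peaks = _local_maxima(h)
        if peaks.size == 2:
            return (peaks[0] + peaks[1]) / 2.0, h
        if peaks.size < 2:
            raise ValueError("histogram smoothed to fewer than two maxima")
        h = _smooth3(h)
    raise ValueError(f"no bimodality after {max_iter} smoothing passes")


def intermodes_threshold(img: np.ndarray, max_iter: int = 10_000) -> ThresholdResult:
    """Intermodes automatic threshold (Prewitt-Mendelsohn): smooth the
    histogram by 3-bin running averages until bimodal, then take the mean of
    the two mode positions.  Tends to pick a higher threshold than Otsu when
    one histogram peak is dominant."""
    hist = image_histogram(img)
    t, _ = intermodes_from_histogram(hist, max_iter=max_iter)
    return ThresholdResult(threshold=t / 255.0, threshold_8bit=int(round(t)),
                           histogram=hist, method="intermodes")
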