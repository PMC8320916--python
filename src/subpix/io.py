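"""Reading and writing images and tables.

Images travel as 8- or 16-bit grayscale PNG or TIFF on disk and as float
arrays in ``[0, 1]`` in memory.  Ground truth and detections are CSV tables.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synth import TRUTH_COLUMNS, quantize

__all__ = ["imread", "imwrite", "write_truth_csv", "read_truth_csv",
           "write_detections_csv", "read_detections_csv"]


def imread(path: str | Path) -> np.ndarray:
    """Load a grayscale image as floats in ``[0, 1]``.

    Integer images are divided by their dtype's full scale; RGB(A) inputs are
    reduced to luminance by channel averaging.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(float), 0.0, 1.0)


def imwrite(path: str | Path, img: np.ndarray, bits: int = 8) -> None:
    """Write a ``[0, 1]`` float image as 8- or 16-bit grayscale (PNG/TIFF,
    chosen by extension)."""
    iio.imwrite(Path(path), quantize(img, bits))


def write_truth_csv(path: str | Path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, index=False, columns=TRUTH_COLUMNS)


def read_truth_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_detections_csv(path: str | Path, detections: pd.DataFrame) -> None:
    detections.to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
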