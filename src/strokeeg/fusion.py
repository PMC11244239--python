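"""Fusion of connectivity and complexity into one feature image.

The cwPLI matrix carries pairwise information in its off-diagonal
entries while the diagonal is structurally zero, so the per-channel
sample-entropy vector (min-max rescaled to [0, 1]) is placed on the
diagonal: the fused C x C matrix stays symmetric, loses nothing, and
matches the display shape of the connectivity matrix. The matrix is then
quantized through a fixed blue-to-yellow colormap and upscaled
(nearest-neighbor) to a square RGB image for the classifier.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import CwPliMatrix
from .errors import ParameterError


def _build_lut() -> np.ndarray:
    """Fixed 256-entry blue-to-yellow RGB lookup table (uint8).

    Piecewise-linear interpolation through five anchors, dark blue at 0
    to bright yellow at 1, monotone in perceived lightness.
    """
    anchors = np.array([
        [13, 40, 120],
        [32, 96, 160],
        [40, 160, 130],
        [130, 205, 70],
        [250, 230, 35],
    ], dtype=np.float64)
    stops = np.linspace(0.0, 1.0, len(anchors))
    t = np.linspace(0.0, 1.0, 256)
    lut = np.round(np.column_stack(
        [np.interp(t, stops, anchors[:, c]) for c in range(3)]
    )).astype(np.int16)
    # rounding can collapse neighbors in flat segments; nudge the blue
    # channel so every entry is distinct (required for exact decoding)
    seen = {tuple(lut[0])}
    for i in range(1, 256):
        step = 1 if lut[i, 2] >= lut[i - 1, 2] else -1
        for delta in range(256):
            candidate = int(np.clip(lut[i, 2] + step * delta, 0, 255))
            if (lut[i, 0], lut[i, 1], candidate) not in seen:
                lut[i, 2] = candidate
                break
        seen.add(tuple(lut[i]))
    if len(seen) != 256:  # pragma: no cover - construction guarantee
        raise AssertionError("colormap entries are not unique")
    return lut.astype(np.uint8)


#: bit-exact colormap shared by every rendering in the package
BLUE_YELLOW_LUT: np.ndarray = _build_lut()

DEFAULT_IMAGE_SIZE = 224


@dataclass
class FusionFeatureImage:
    """A fused feature matrix with its RGB rendering and provenance."""

    matrix: np.ndarray
    rgb: np.ndarray
    bounds: tuple[float, float] = (0.0, 1.0)
    colormap: str = "blue_yellow"
    epoch_id: int | None = None
    subject_id: str | None = None
    label: int | None = None


def fuse(cwpli: CwPliMatrix | np.ndarray, saen: np.ndarray,
         saen_bounds: tuple[float, float] | None = None) -> np.ndarray:
    """Fuse a cwPLI matrix with a sample-entropy vector.

    Off-diagonal cells keep the (symmetric) cwPLI; the diagonal receives
    the SaEn vector min-max rescaled to [0, 1] using ``saen_bounds``
    (compute the bounds on training data only). Without explicit bounds,
    ``(0, max(saen))`` is used.
    """
    cw = cwpli.values if isinstance(cwpli, CwPliMatrix) else np.asarray(cwpli, dtype=np.float64)
    saen = np.asarray(saen, dtype=np.float64).ravel()
    if cw.shape[0] != cw.shape[1] or cw.shape[0] != saen.size:
        raise ParameterError(
            f"channel mismatch: matrix {cw.shape} vs SaEn vector of {saen.size}"
        )
    if saen_bounds is None:
        hi = saen.max() if saen.size and saen.max() > 0 else 1.0
        saen_bounds = (0.0, float(hi))
    lo, hi = saen_bounds
    span = hi - lo
    diag = np.clip((saen - lo) / span, 0.0, 1.0) if span > 0 else np.zeros_like(saen)
    fused = cw.astype(np.float64).copy()
    np.fill_diagonal(fused, diag)
    return fused


def to_rgb(matrix: np.ndarray, size: int = DEFAULT_IMAGE_SIZE,
           bounds: tuple[float, float] = (0.0, 1.0),
           lut: np.ndarray = BLUE_YELLOW_LUT) -> np.ndarray:
    """Render a feature matrix as a ``size x size x 3`` uint8 image.

    The matrix is min-max normalized with fixed global ``bounds``
    (default [0, 1], the cwPLI range), quantized to the 256-entry
    colormap, and upscaled nearest-neighbor so each cell becomes a
    uniform block.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if not np.all(np.isfinite(m)):
        i, j = np.argwhere(~np.isfinite(m))[0]
        raise ParameterError(f"non-finite feature value at cell ({i}, {j})")
    lo, hi = bounds
    if hi <= lo:
        raise ParameterError("bounds must satisfy lo < hi")
    norm = np.clip((m - lo) / (hi - lo), 0.0, 1.0)
    q = np.round(norm * 255).astype(np.intp)
    small = lut[q]
    C = m.shape[0]
    idx = (np.arange(size) * C) // size
    return small[idx][:, idx]


def decode_rgb(img: np.ndarray, n_channels: int,
               bounds: tuple[float, float] = (0.0, 1.0),
               lut: np.ndarray = BLUE_YELLOW_LUT) -> np.ndarray:
    """Invert :func:`to_rgb`: block-average the image and match each
    block color to its nearest colormap entry."""
    img = np.asarray(img, dtype=np.float64)
    size = img.shape[0]
    idx = (np.arange(size) * n_channels) // size
    means = np.zeros((n_channels, n_channels, 3))
    counts = np.zeros((n_channels, n_channels, 1))
    for r in range(size):
        for c in range(size):
            means[idx[r], idx[c]] += img[r, c]
            counts[idx[r], idx[c], 0] += 1
    means /= counts
    d = ((means[:, :, None, :] - lut[None, None, :, :].astype(np.float64)) ** 2).sum(-1)
    q = d.argmin(-1)
    lo, hi = bounds
    return lo + (q / 255.0) * (hi - lo)


def feature_image(cwpli: CwPliMatrix | np.ndarray, saen: np.ndarray,
                  saen_bounds: tuple[float, float] | None = None,
                  size: int = DEFAULT_IMAGE_SIZE) -> FusionFeatureImage:
    """Convenience: fuse and render in one step."""
    fused = fuse(cwpli, saen, saen_bounds)
    rgb = to_rgb(fused, size=size)
    return FusionFeatureImage(
        matrix=fused, rgb=rgb,
        epoch_id=getattr(cwpli, "epoch_id", None),
        subject_id=getattr(cwpli, "subject_id", None),
    )


def save_png(img: np.ndarray, path: str | os.PathLike) -> None:
    from PIL import Image

    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path)


def write_feature_index(path: str | os.PathLike, rows: Sequence[dict]) -> None:
    """Index CSV (path, subject_id, epoch_id, label) for rendered images."""
    pd.DataFrame(rows, columns=["path", "subject_id", "epoch_id", "label"]).to_csv(
        path, index=False
    )
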