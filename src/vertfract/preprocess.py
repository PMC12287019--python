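"""Intensity preprocessing: neighborhood spatial filtering and global
histogram equalization.

Equalization follows the classical CDF construction: with per-level counts
``h(j)`` over ``L`` gray levels and ``N`` pixels,

    CDF(i)      = sum_{j<=i} h(j)
    CDF_norm(i) = CDF(i) / N
    I_new(i)    = round(CDF_norm(i) * (L - 1))

with round-half-up so the mapping is deterministic at .5 boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["HistogramMap", "equalize_histogram", "spatial_filter", "preprocess_image"]


@dataclass
class HistogramMap:
    """The level-mapping produced by global histogram equalization."""

    h: np.ndarray          # per-level counts, length L
    cdf: np.ndarray        # cumulative counts
    cdf_norm: np.ndarray   # cdf / N, in [0, 1]
    mapping: np.ndarray    # level -> level, non-decreasing

    def to_dict(self) -> dict:
        return {
            "h": self.h.tolist(),
            "cdf": self.cdf.tolist(),
            "cdf_norm": self.cdf_norm.tolist(),
            "mapping": self.mapping.tolist(),
        }


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def equalize_histogram(img: np.ndarray, levels: int = 256) -> tuple[np.ndarray, HistogramMap]:
    """Globally equalize an integer gray image via its normalized CDF.

    Returns the equalized image and the :class:`HistogramMap` used, so the
    exact level mapping can be logged or inverted for inspection.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    h = np.bincount(img.ravel().astype(np.int64), minlength=levels).astype(np.int64)
    cdf = np.cumsum(h)
    n = cdf[-1]
    cdf_norm = cdf / n
    mapping = _round_half_up(cdf_norm * (levels - 1)).astype(img.dtype if img.dtype.kind == "u" else np.int64)
    out = mapping[img.astype(np.int64)]
    return out.astype(img.dtype), HistogramMap(h=h, cdf=cdf, cdf_norm=cdf_norm, mapping=mapping.astype(np.int64))


def spatial_filter(img: np.ndarray, op: str = "median3") -> np.ndarray:
    """Neighborhood operator g(x,y) = T[f(x,y)] over a k x k window.

    ``op`` is ``"identity"``, ``"median<k>"`` or ``"mean<k>"`` with odd k
    (e.g. ``"median3"``). Edges use reflect padding.
    """
    img = np.asarray(img)
    if op == "identity":
        return img.copy()
    for prefix in ("median", "mean"):
        if op.startswith(prefix):
            k = int(op[len(prefix):])
            if k % 2 == 0 or k < 1:
                raise ValueError(f"window size must be odd and positive, got {k}")
            if prefix == "median":
                return ndimage.median_filter(img, size=k, mode="reflect")
            out = ndimage.uniform_filter(img.astype(float), size=k, mode="reflect")
            return np.rint(out).astype(img.dtype)
    raise ValueError(f"unknown spatial filter {op!r}")


def preprocess_image(img: np.ndarray, smooth: str = "median3", equalize: bool = True,
                     levels: int = 256) -> tuple[np.ndarray, HistogramMap | None]:
    """Default preprocessing chain: smoothing then global equalization.

    Smoothing first keeps isolated noise spikes from distorting the CDF.
    """
    out = spatial_filter(img, smooth)
    hmap = None
    if equalize:
        out, hmap = equalize_histogram(out, levels=levels)
    return out, hmap
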