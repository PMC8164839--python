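"""Two-channel colocalization: thresholded masks, mask product, count-based
Manders M1/M2, Pearson Rr, and Li's intensity-correlation analysis.

The workflow mirrors routine confocal practice for junctional markers: each
channel is thresholded into a binary mask (a fixed visual threshold or Otsu;
a no-primary-antibody control image may be supplied, and must yield an
essentially empty mask at the same threshold), the mask product outlines the
overlapping regions, and coefficients quantify the overlap:

* ``M1 = |A and B| / |A|`` and ``M2 = |A and B| / |B|`` — *count-based*
  co-occurrence fractions of mask-positive pixels (M1: fraction of
  channel-A-positive pixels that are also B-positive, and vice versa).
* Pearson ``Rr`` over all ROI pixel intensities, in [-1, 1].
* Li's ICQ: with per-pixel PDM ``(A_i - mean_A)(B_i - mean_B)``,
  ``ICQ = #{PDM > 0} / #{PDM != 0} - 0.5``, in [-0.5, 0.5]; pixels with PDM
  exactly 0 are excluded from the denominator.  The ++PDM map marks pixels
  with both channels above their means.

An intensity-weighted Manders variant (the classical split coefficients) is
available behind ``intensity_weighted=True`` for comparison; the count-based
form is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from skimage.filters import threshold_otsu

__all__ = [
    "ChannelImage",
    "BinaryMask",
    "ColocResult",
    "make_mask",
    "mask_product",
    "manders_overlap",
    "pearson_r",
    "li_ica",
    "coloc_report",
    "roi_to_mask",
]

CONTROL_FOREGROUND_LIMIT = 1e-3  # control masks must stay below 0.1% foreground


@dataclass(frozen=True)
class ChannelImage:
    """One fluorescence channel: rectangular non-negative intensity grid."""

    pixels: np.ndarray
    channel_name: str = ""

    def __init__(self, pixels, channel_name: str = ""):
        arr = np.asarray(pixels, dtype=float)
        if arr.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if np.any(arr < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "pixels", arr)
        object.__setattr__(self, "channel_name", channel_name)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """Segmented image: True where there is real signal."""

    pixels: np.ndarray
    threshold_used: float = float("nan")

    def __init__(self, pixels, threshold_used: float = float("nan")):
        arr = np.asarray(pixels).astype(bool)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "pixels", arr)
        object.__setattr__(self, "threshold_used", float(threshold_used))

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class ColocResult:
    m1: float
    m2: float
    pearson_r: float
    li_icq: float
    n_a: int
    n_b: int
    n_overlap: int
    overlap_mask: BinaryMask
    pdm_pp_mask: BinaryMask


def make_mask(
    img: ChannelImage,
    threshold: float | str,
    control: ChannelImage | None = None,
    strict: bool = False,
) -> BinaryMask:
    """Threshold a channel into a binary mask (strictly ``intensity > T``).

    ``threshold="otsu"`` picks the threshold by Otsu's method.  If a
    no-primary-antibody ``control`` image is given, the same threshold is
    applied to it and a warning is raised unless the control mask is
    essentially empty (<= 0.1% foreground) — noise must not be segmented as
    signal.  ``strict=True`` turns an empty result mask into an error.
    """
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        thr = float(threshold_otsu(img.pixels))
    else:
        thr = float(threshold)
        if thr < 0:
            raise ValueError("threshold must be >= 0")
    mask = img.pixels > thr
    if control is not None:
        frac = float(np.mean(control.pixels > thr))
        if frac > CONTROL_FOREGROUND_LIMIT:
            warnings.warn(
                f"control image for {img.channel_name or 'channel'} keeps "
                f"{frac:.2%} foreground at threshold {thr:g}; "
                "threshold may be segmenting noise",
                stacklevel=2,
            )
    if strict and not mask.any():
        raise ValueError(
            f"threshold {thr:g} is above the image maximum: empty mask"
        )
    return BinaryMask(mask, threshold_used=thr)


def _check_same_shape(a: BinaryMask | ChannelImage, b: BinaryMask | ChannelImage) -> None:
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(f"dimension mismatch: {a.pixels.shape} vs {b.pixels.shape}")


def mask_product(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Pixelwise multiplication (logical AND): the overlap outline."""
    _check_same_shape(a, b)
    return BinaryMask(a.pixels & b.pixels)


def manders_overlap(a: BinaryMask, b: BinaryMask) -> tuple[float, float]:
    """Count-based Manders coefficients (M1, M2) from two masks."""
    _check_same_shape(a, b)
    n_a, n_b = a.count, b.count
    if n_a == 0 or n_b == 0:
        raise ValueError(
            f"Manders coefficients undefined on an empty mask (n_a={n_a}, n_b={n_b})"
        )
    n_ab = int((a.pixels & b.pixels).sum())
    return n_ab / n_a, n_ab / n_b


def manders_intensity(
    a: ChannelImage, b: ChannelImage, mask_a: BinaryMask, mask_b: BinaryMask
) -> tuple[float, float]:
    """Classical intensity-weighted Manders split coefficients.

    M1 = sum of A intensity over B-positive pixels / total A intensity (and
    vice versa).  Provided for comparison with the count-based default.
    """
    _check_same_shape(a, b)
    tot_a = float(a.pixels[mask_a.pixels].sum())
    tot_b = float(b.pixels[mask_b.pixels].sum())
    if tot_a == 0 or tot_b == 0:
        raise ValueError("intensity-weighted Manders undefined: zero total signal")
    m1 = float(a.pixels[mask_a.pixels & mask_b.pixels].sum()) / tot_a
    m2 = float(b.pixels[mask_a.pixels & mask_b.pixels].sum()) / tot_b
    return m1, m2


def roi_to_mask(
    roi: np.ndarray | BinaryMask | Sequence[tuple[float, float]] | None,
    shape: tuple[int, int],
) -> np.ndarray:
    """Resolve an ROI (mask, boolean array or polygon vertices) to boolean
    pixel selection; polygon ROIs select pixels whose centers fall inside."""
    if roi is None:
        return np.ones(shape, dtype=bool)
    if isinstance(roi, BinaryMask):
        if roi.pixels.shape != shape:
            raise ValueError("ROI mask shape mismatch")
        return roi.pixels
    arr = np.asarray(roi)
    if arr.ndim == 2 and arr.shape == shape and arr.dtype != float:
        return arr.astype(bool)
    if arr.ndim == 2 and arr.shape[1] == 2 and arr.shape != shape:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        centers = np.column_stack([xx.ravel(), yy.ravel()])
        inside = MplPath(arr).contains_points(centers)
        return inside.reshape(shape)
    if arr.shape == shape:
        return arr.astype(bool)
    raise ValueError("ROI must be a same-shape mask or an (n, 2) polygon")


def pearson_r(
    a: ChannelImage, b: ChannelImage, roi: np.ndarray | None = None
) -> float:
    """Sample Pearson correlation over all ROI pixels (not only
    mask-positive ones); constant channels are an error."""
    _check_same_shape(a, b)
    select = roi_to_mask(roi, a.shape)
    va, vb = a.pixels[select], b.pixels[select]
    if va.size < 2:
        raise ValueError("ROI must contain >= 2 pixels")
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        raise ValueError("Pearson correlation undefined for a constant channel")
    return float(np.corrcoef(va, vb)[0, 1])


def li_ica(
    a: ChannelImage, b: ChannelImage, roi: np.ndarray | None = None
) -> tuple[float, BinaryMask]:
    """Li's intensity correlation analysis: (ICQ, ++PDM map).

    PDM_i = (A_i - mean_A)(B_i - mean_B) over ROI pixels;
    ICQ = #{PDM > 0}/#{PDM != 0} - 0.5.  The ++PDM mask flags pixels with
    both channels above their ROI means (False outside the ROI).
    """
    _check_same_shape(a, b)
    select = roi_to_mask(roi, a.shape)
    va, vb = a.pixels[select], b.pixels[select]
    if va.size < 2:
        raise ValueError("ROI must contain >= 2 pixels")
    da, db = va - va.mean(), vb - vb.mean()
    pdm = da * db
    nonzero = pdm != 0
    if not nonzero.any():
        raise ValueError("all PDMs are zero (both channels constant)")
    icq = float(np.sum(pdm > 0) / np.sum(nonzero)) - 0.5
    pp = np.zeros(a.shape, dtype=bool)
    pp[select] = (da > 0) & (db > 0)
    return icq, BinaryMask(pp)


def coloc_report(
    a: ChannelImage,
    b: ChannelImage,
    threshold_a: float | str,
    threshold_b: float | str,
    roi: np.ndarray | None = None,
    control_a: ChannelImage | None = None,
    control_b: ChannelImage | None = None,
) -> ColocResult:
    """Run the full colocalization suite on one two-channel ROI."""
    _check_same_shape(a, b)
    select = roi_to_mask(roi, a.shape)
    mask_a = make_mask(a, threshold_a, control=control_a)
    mask_b = make_mask(b, threshold_b, control=control_b)
    mask_a = BinaryMask(mask_a.pixels & select, mask_a.threshold_used)
    mask_b = BinaryMask(mask_b.pixels & select, mask_b.threshold_used)
    if mask_a.count == 0 or mask_b.count == 0:
        raise ValueError(
            "empty mask after thresholding "
            f"(n_a={mask_a.count}, n_b={mask_b.count}); coefficients undefined"
        )
    overlap = mask_product(mask_a, mask_b)
    m1, m2 = manders_overlap(mask_a, mask_b)
    r = pearson_r(a, b, roi=select)
    icq, pp = li_ica(a, b, roi=select)
    return ColocResult(
        m1=m1,
        m2=m2,
        pearson_r=r,
        li_icq=icq,
        n_a=mask_a.count,
        n_b=mask_b.count,
        n_overlap=overlap.count,
        overlap_mask=overlap,
        pdm_pp_mask=pp,
    )
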