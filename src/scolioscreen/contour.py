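"""Bent-back image preprocessing, edge operators, and contour profiling.

The sagittal measurement works on a photo of the back bent forward 90
degrees, seen from behind: the two scapular prominences appear as bulges on
the upper silhouette.  This module turns an 8-bit grayscale image (or a
precomputed binary mask) into the 1-D *contour profile* — for every image
column, the height of the silhouette top above the image bottom — so the
bulges become local maxima of a uniformly sampled signal.

Edge extraction offers the three classic gradient/Laplacian operators:

* Roberts: two 2x2 difference kernels, ``S = sqrt(dx^2 + dy^2)``;
* Prewitt: the two standard 3x3 kernels (rows/columns of +-1),
  ``S = sqrt(dx^2 + dy^2)``;
* LOG: Gaussian smoothing, the 4-neighbour Laplacian
  ``f(i+1,j)+f(i-1,j)+f(i,j+1)+f(i,j-1)-4 f(i,j)``, and edges at the zero
  crossings of the result.

All operators use replicate-edge padding so the edge map keeps the input
dimensions and column indexing stays aligned with the profile.

Foreground/background separation itself (salient-object segmentation) is
out of scope here: the pipeline accepts a binary mask produced by any
segmenter, with Otsu thresholding available as a fallback for
high-contrast studio images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.exposure import equalize_adapthist
from skimage.filters import threshold_otsu

from .errors import DomainError, EmptyProfileError

PREWITT_DX = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=float)
PREWITT_DY = np.array([[-1, -1, -1], [0, 0, 0], [1, 1, 1]], dtype=float)
LAPLACIAN_4 = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)


def _as_gray(image) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise DomainError("expected a non-empty 2-D grayscale array")
    return img


@dataclass
class EdgeMap:
    """Per-pixel edge response of one operator.

    ``strength`` is the non-negative magnitude (for LOG, a 0/1 zero-crossing
    indicator); ``dx``/``dy`` the signed component responses (None for LOG).
    """

    strength: np.ndarray
    operator: str
    dx: np.ndarray | None = None
    dy: np.ndarray | None = None


@dataclass
class ContourProfile:
    """1-D back-height signal: ``heights[c]`` is the silhouette-top height of
    column c in pixels above the image bottom, valid where ``valid_mask``."""

    heights: np.ndarray
    valid_mask: np.ndarray
    source_operator: str = "mask"

    def __len__(self) -> int:
        return len(self.heights)


def preprocess(image, denoise: bool = True, clahe: bool = True) -> np.ndarray:
    """Optional 3x3 median denoising and CLAHE contrast enhancement.

    Returns an image of the same dimensions; with both flags off this is the
    identity.  A constant image passes through unchanged (nothing to
    enhance, and histogram equalisation is undefined on it).
    """
    img = _as_gray(image)
    out = img.copy()
    if denoise:
        out = ndimage.median_filter(out, size=3, mode="nearest")
    if clahe and out.max() > out.min():
        scaled = (out - out.min()) / (out.max() - out.min())
        out = equalize_adapthist(scaled) * 255.0
    return out


def binarize(image, threshold="otsu") -> np.ndarray:
    """Threshold to a {0, 255} mask: foreground where intensity >= threshold.

    ``threshold`` is a fixed intensity or ``"otsu"`` for the histogram-based
    automatic choice.
    """
    img = _as_gray(image)
    if threshold == "otsu":
        thr = float(threshold_otsu(img)) if img.max() > img.min() else np.inf
    else:
        thr = float(threshold)
    return np.where(img >= thr, 255, 0).astype(np.uint8)


def _roberts(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # kernels [[1,0],[0,-1]] and [[0,1],[-1,0]], anchored at the top-left
    # pixel of the 2x2 support, replicate padding on the far edges
    P = np.pad(img, ((0, 1), (0, 1)), mode="edge")
    dx = P[:-1, :-1] - P[1:, 1:]
    dy = P[:-1, 1:] - P[1:, :-1]
    return dx, dy


def edge_detect(image, operator: str = "prewitt", log_sigma: float = 1.4) -> EdgeMap:
    """Apply one of the Roberts / Prewitt / LOG operators.

    Roberts and Prewitt return ``S = sqrt(dx^2 + dy^2)``; LOG returns a
    binary zero-crossing map of the Gaussian-smoothed 4-neighbour Laplacian
    (``log_sigma`` is the smoothing scale in pixels).
    """
    img = _as_gray(image)
    if operator == "roberts":
        if min(img.shape) < 2:
            raise DomainError("image smaller than the 2x2 Roberts kernel")
        dx, dy = _roberts(img)
        return EdgeMap(strength=np.hypot(dx, dy), operator="roberts", dx=dx, dy=dy)
    if operator == "prewitt":
        if min(img.shape) < 3:
            raise DomainError("image smaller than the 3x3 Prewitt kernel")
        dx = ndimage.correlate(img, PREWITT_DX, mode="nearest")
        dy = ndimage.correlate(img, PREWITT_DY, mode="nearest")
        return EdgeMap(strength=np.hypot(dx, dy), operator="prewitt", dx=dx, dy=dy)
    if operator == "log":
        if min(img.shape) < 3:
            raise DomainError("image smaller than the 3x3 Laplacian kernel")
        smooth = ndimage.gaussian_filter(img, sigma=log_sigma, mode="nearest")
        lap = ndimage.correlate(smooth, LAPLACIAN_4, mode="nearest")
        zc = np.zeros_like(lap, dtype=bool)
        # a zero crossing is a sign change against the right or lower neighbour
        zc[:, :-1] |= lap[:, :-1] * lap[:, 1:] < 0
        zc[:-1, :] |= lap[:-1, :] * lap[1:, :] < 0
        return EdgeMap(strength=zc.astype(float), operator="log")
    raise DomainError(f"unknown edge operator {operator!r}")


def extract_profile(mask_or_edges, strength_frac: float = 0.5) -> ContourProfile:
    """Column-wise top-of-silhouette heights.

    For a binary mask, each column's height is ``H - r_top`` where ``r_top``
    is its topmost foreground row (so a full-width rectangle of height h
    gives a constant profile h).  For an :class:`EdgeMap`, the topmost pixel
    with strength >= ``strength_frac`` of the map maximum is used.  Columns
    with no foreground are marked invalid; a fully empty input raises.
    """
    if isinstance(mask_or_edges, EdgeMap):
        s = mask_or_edges.strength
        fg = s >= strength_frac * s.max() if s.max() > 0 else np.zeros_like(s, bool)
        op = mask_or_edges.operator
    else:
        mask = _as_gray(mask_or_edges)
        fg = mask >= 128
        op = "mask"
    H, W = fg.shape
    if not fg.any():
        raise EmptyProfileError("no foreground pixels to profile")
    any_fg = fg.any(axis=0)
    r_top = np.argmax(fg, axis=0)  # first True row per column
    heights = np.where(any_fg, H - r_top, 0.0).astype(float)
    return ContourProfile(heights=heights, valid_mask=any_fg, source_operator=op)


def profile_signal(profile: ContourProfile) -> tuple[np.ndarray, int]:
    """Gap-free uniform signal from a profile.

    Marginal invalid columns are trimmed, interior invalid columns linearly
    interpolated (a peak-detection signal must have no missing samples).
    Returns the signal and the column offset of its first sample.
    """
    valid = profile.valid_mask
    idx = np.nonzero(valid)[0]
    if len(idx) == 0:
        raise EmptyProfileError("profile has no valid columns")
    lo, hi = idx[0], idx[-1] + 1
    h = profile.heights[lo:hi].copy()
    v = valid[lo:hi]
    if not v.all():
        cols = np.arange(len(h))
        h[~v] = np.interp(cols[~v], cols[v], h[v])
    return h, int(lo)


def rasterize_profile(heights, image_height: int) -> np.ndarray:
    """Binary mask filled from the bottom row up to each column's height.

    The inverse of :func:`extract_profile` up to integer rounding: column c
    of the mask is foreground on rows ``H - round(heights[c]) .. H-1``.
    """
    h = np.rint(np.asarray(heights, float)).astype(int)
    H = int(image_height)
    if np.any(h < 0) or np.any(h > H):
        raise DomainError("profile heights must lie in [0, image_height]")
    rows = np.arange(H)[:, None]
    return np.where(rows >= H - h[None, :], 255, 0).astype(np.uint8)
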