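"""From raw photograph to per-zone integrated greyscale signals.

Pipeline order: detect the six fiducial marks, fit a projective correction
(homography; keystoning is projective, so an affine model would not do),
resample the card into its reference frame, white-balance against a neutral
colour standard, then measure the mean ``255 - greyscale`` over each zone's
indicator circle.

Conventions used throughout (and in calibration):
- greyscale is the unweighted channel mean (R + G + B) / 3;
- a pixel at array index (row i, col j) has coordinates (x=j, y=i);
- integration over an ROI is the *mean* over member pixels, so signals are
  independent of photograph resolution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure
from skimage.transform import ProjectiveTransform

from .layout import CardLayout

__all__ = [
    "DetectedFiducial",
    "GeometricCorrection",
    "RectifiedImage",
    "ZoneSignal",
    "UnreadableCardError",
    "load_image",
    "detect_fiducials",
    "fit_geometric_correction",
    "rectify",
    "correct_white_balance",
    "measure_rois",
    "DEFAULT_SCALE",
]

#: default rectification resolution, px per mm
DEFAULT_SCALE = 10.0

#: fiducial ink is near-black; anything darker than this grey is a candidate.
#: Kept well below the darkest developed indicator spot (grey ~80 before
#: illumination) and well above black ink under a dim cast (grey ~13).
_DARK_THRESHOLD = 50.0
_MIN_BLOB_AREA = 30  # px
_MIN_CIRCULARITY = 0.5
_MAX_CANDIDATES = 8

#: sentinel colour for rectified pixels with no source data
SENTINEL_RGB = (255.0, 0.0, 255.0)


class UnreadableCardError(RuntimeError):
    """The image cannot be carried through the pipeline; ``reason`` is a
    machine-readable tag (too_few_fiducials, neutral_patch_saturated, ...)."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class DetectedFiducial:
    id: int  # matched layout fiducial
    centroid: tuple[float, float]  # (x, y) image px
    quality: float  # isoperimetric circularity, clipped to [0, 1]


@dataclass(frozen=True)
class GeometricCorrection:
    matrix: np.ndarray  # 3x3, image px -> reference mm
    residual: float  # RMS reprojection error over matched marks, mm


@dataclass
class RectifiedImage:
    """Card resampled into the reference frame at ``scale`` px/mm; pixels
    with no source data hold a sentinel colour and are False in ``valid``."""

    rgb: np.ndarray  # float, (H, W, 3), 0..255
    valid: np.ndarray  # bool, (H, W)
    scale: float


@dataclass(frozen=True)
class ZoneSignal:
    zone_id: int
    integrated_signal: float  # mean of (255 - greyscale) over ROI pixels
    pixel_count: int
    signal_sd: float
    unreadable: bool = False


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG photograph as a uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def grey_of(rgb: np.ndarray) -> np.ndarray:
    return np.asarray(rgb, dtype=float).mean(axis=-1)


# ---------------------------------------------------------------------------
# fiducial detection

def _candidate_blobs(image: np.ndarray) -> list[dict]:
    grey = grey_of(image)
    mask = grey < _DARK_THRESHOLD
    if not mask.any():
        return []
    labels = measure.label(mask)
    cands = []
    for p in measure.regionprops(labels, intensity_image=255.0 - grey):
        if p.area < _MIN_BLOB_AREA:
            continue
        perim = p.perimeter
        circ = 4.0 * math.pi * p.area / (perim * perim) if perim > 0 else 0.0
        if circ < _MIN_CIRCULARITY:
            continue
        r, c = p.centroid_weighted
        cands.append({"xy": (float(c), float(r)), "area": int(p.area), "quality": min(circ, 1.0)})
    cands.sort(key=lambda d: -d["area"])
    return cands[:_MAX_CANDIDATES]


def _umeyama_rms(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """RMS residual of the best similarity transform X -> Y, batched.

    X: (k, 2) reference points; Y: (B, k, 2) candidate assignments.
    Reflections are excluded (cards are never mirrored).
    """
    k = X.shape[0]
    Xc = X - X.mean(axis=0)
    Ym = Y.mean(axis=1, keepdims=True)
    Yc = Y - Ym
    # cross-covariance per batch: (B, 2, 2)
    A = np.einsum("bki,kj->bij", Yc, Xc) / k
    U, S, Vt = np.linalg.svd(A)
    det = np.linalg.det(U @ Vt)
    D = np.ones((Y.shape[0], 2))
    D[:, 1] = np.sign(det)
    var_x = (Xc**2).sum() / k
    scale = (S * D).sum(axis=1) / var_x
    R = U * D[:, None, :] @ Vt
    fitted = scale[:, None, None] * np.einsum("bij,kj->bki", R, Xc) + Ym
    return np.sqrt(((fitted - Y) ** 2).sum(axis=(1, 2)) / k)


def _match_constellation(
    cand_xy: np.ndarray, ref_xy: np.ndarray
) -> list[tuple[int, int]]:
    """Match candidate blobs to layout marks by the similarity-invariant
    shape of the constellation; returns (ref index, candidate index) pairs.

    All injective assignments are scored by the residual of the best-fitting
    similarity transform; ties break by smallest total match distance, then
    lexicographically (deterministic).
    """
    k, m = len(cand_xy), len(ref_xy)
    if k < 3:
        return []
    if k >= m:
        # assignment maps each layout mark to a distinct candidate
        assignments = list(itertools.permutations(range(k), m))
        Y = cand_xy[np.array(assignments)]  # (B, m, 2)
        rms = _umeyama_rms(ref_xy, Y)
        best = int(np.argmin(rms))
        return [(j, assignments[best][j]) for j in range(m)]
    # fewer candidates than marks: assign each candidate to a distinct mark
    # and score the fit of the candidate constellation onto each ref subset
    assignments = list(itertools.permutations(range(m), k))
    Yref = ref_xy[np.array(assignments)]  # (B, k, 2)
    rms = _umeyama_rms(cand_xy, Yref)
    best = int(np.argmin(rms))
    return [(assignments[best][j], j) for j in range(k)]


def detect_fiducials(image: np.ndarray, layout: CardLayout) -> list[DetectedFiducial]:
    """Locate the printed registration disks and identify each one.

    Dark circular blobs (thresholding + connected components, centroid =
    intensity-weighted mean) are matched to the layout's six-mark
    constellation. Missing or occluded marks are simply absent from the
    result; the downstream fit decides whether enough remain.
    """
    if image.size == 0:
        return []
    cands = _candidate_blobs(image)
    if len(cands) < 3:
        return []
    ref = sorted(layout.fiducials, key=lambda f: f.id)
    ref_xy = np.array([f.center for f in ref], dtype=float)
    cand_xy = np.array([c["xy"] for c in cands], dtype=float)
    pairs = _match_constellation(cand_xy, ref_xy)
    out = [
        DetectedFiducial(id=ref[ri].id, centroid=cands[ci]["xy"], quality=cands[ci]["quality"])
        for ri, ci in pairs
    ]
    out.sort(key=lambda d: d.id)
    return out


# ---------------------------------------------------------------------------
# geometric correction

def _collinear(points: np.ndarray, tol: float = 1e-6) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[0] < tol or s[1] / s[0] < 1e-6


def fit_geometric_correction(
    detections: Sequence[DetectedFiducial], layout: CardLayout
) -> GeometricCorrection:
    """Least-squares projective fit (normalized DLT) of image px -> card mm.

    Requires at least four matched, non-collinear detections; with exactly
    four the fit is exact and the residual is ~0.
    """
    if len(detections) < 4:
        raise UnreadableCardError(
            "too_few_fiducials", f"{len(detections)} matched marks; need >= 4"
        )
    by_id = {f.id: f for f in layout.fiducials}
    src = np.array([d.centroid for d in detections], dtype=float)
    dst = np.array([by_id[d.id].center for d in detections], dtype=float)
    if _collinear(src):
        raise UnreadableCardError("too_few_fiducials", "detected marks are collinear")
    tf = ProjectiveTransform.from_estimate(src, dst)
    if not tf:
        raise UnreadableCardError("too_few_fiducials", "degenerate projective fit")
    resid = float(np.sqrt(np.mean(np.sum((tf(src) - dst) ** 2, axis=1))))
    return GeometricCorrection(matrix=np.asarray(tf.params), residual=resid)


def rectify(
    image: np.ndarray,
    correction: GeometricCorrection,
    layout: CardLayout,
    scale: float = DEFAULT_SCALE,
) -> RectifiedImage:
    """Resample the photograph into the reference frame (bilinear).

    Output pixel (i, j) samples the source at the image position of the
    reference point (j/scale, i/scale) mm; output size is card_size * scale.
    Out-of-source pixels get the sentinel colour and valid=False.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    M = np.asarray(correction.matrix, dtype=float)
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError("geometric correction is not invertible")
    Minv = np.linalg.inv(M)  # mm -> px
    w_mm, h_mm = layout.card_size
    W = int(round(w_mm * scale))
    Hh = int(round(h_mm * scale))
    yy, xx = np.mgrid[0:Hh, 0:W]
    uvw = Minv @ np.stack([xx.ravel() / scale, yy.ravel() / scale, np.ones(xx.size)])
    xs = (uvw[0] / uvw[2]).reshape(Hh, W)
    ys = (uvw[1] / uvw[2]).reshape(Hh, W)

    src = np.asarray(image, dtype=float)
    out = np.empty((Hh, W, 3), dtype=float)
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            src[..., c], [ys, xs], order=1, mode="constant", cval=0.0
        )
    cover = ndimage.map_coordinates(
        np.ones(src.shape[:2]), [ys, xs], order=1, mode="constant", cval=0.0
    )
    valid = cover > 0.999
    out[~valid] = SENTINEL_RGB
    return RectifiedImage(rgb=out, valid=valid, scale=scale)


# ---------------------------------------------------------------------------
# white balance

def _patch_slice(bounds, scale, inset_mm=1.0):
    x, y, w, h = bounds
    j0 = int(math.ceil((x + inset_mm) * scale))
    j1 = int(math.floor((x + w - inset_mm) * scale))
    i0 = int(math.ceil((y + inset_mm) * scale))
    i1 = int(math.floor((y + h - inset_mm) * scale))
    return slice(i0, i1 + 1), slice(j0, j1 + 1)


def correct_white_balance(
    rect: RectifiedImage, layout: CardLayout
) -> tuple[RectifiedImage, tuple[float, float, float]]:
    """Per-channel gain correction against a neutral colour standard.

    Gains are nominal/measured channel means of the brightest neutral patch
    that is fully sampled and unsaturated (no channel mean >= 250); a
    saturated channel carries no colour information, so such patches are
    skipped. If no neutral patch is usable the card is unreadable.
    Returns the corrected image and the applied gains.
    """
    candidates = layout.neutral_patches()
    if not candidates:
        raise UnreadableCardError("neutral_patch_saturated", "layout has no neutral patch")
    for patch in candidates:
        si, sj = _patch_slice(patch.bounds, rect.scale)
        region = rect.rgb[si, sj]
        if region.size == 0 or not rect.valid[si, sj].all():
            continue
        means = region.reshape(-1, 3).mean(axis=0)
        if (means >= 250.0).any():
            continue
        gains = tuple(255.0 * n / m for n, m in zip(patch.nominal_color, means))
        out = np.clip(rect.rgb * np.asarray(gains), 0.0, 255.0)
        out[~rect.valid] = SENTINEL_RGB
        return RectifiedImage(rgb=out, valid=rect.valid.copy(), scale=rect.scale), gains
    raise UnreadableCardError(
        "neutral_patch_saturated", "no neutral colour standard is usable"
    )


# ---------------------------------------------------------------------------
# ROI measurement

def roi_pixel_mask(
    zone_center: tuple[float, float], radius: float, scale: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (rows, cols) of pixels whose centres fall inside the circle."""
    cx, cy = zone_center
    j0 = max(0, int(math.floor((cx - radius) * scale)) - 1)
    j1 = min(shape[1] - 1, int(math.ceil((cx + radius) * scale)) + 1)
    i0 = max(0, int(math.floor((cy - radius) * scale)) - 1)
    i1 = min(shape[0] - 1, int(math.ceil((cy + radius) * scale)) + 1)
    jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
    inside = (jj / scale - cx) ** 2 + (ii / scale - cy) ** 2 <= radius**2
    return ii[inside], jj[inside]


def measure_rois(rect: RectifiedImage, layout: CardLayout) -> list[ZoneSignal]:
    """Integrated signal for each of the 12 zones, in zone-id order.

    A zone whose ROI touches any out-of-source pixel is flagged unreadable
    (its numbers are still reported for diagnostics).
    """
    out: list[ZoneSignal] = []
    shape = rect.rgb.shape[:2]
    for z in sorted(layout.zones, key=lambda z: z.id):
        ii, jj = roi_pixel_mask(z.roi_center, z.roi_radius, rect.scale, shape)
        if ii.size == 0:
            out.append(ZoneSignal(z.id, 0.0, 0, 0.0, unreadable=True))
            continue
        sig = 255.0 - grey_of(rect.rgb[ii, jj])
        out.append(
            ZoneSignal(
                zone_id=z.id,
                integrated_signal=float(np.clip(sig.mean(), 0.0, 255.0)),
                pixel_count=int(ii.size),
                signal_sd=float(sig.std()),
                unreadable=bool((~rect.valid[ii, jj]).any()),
            )
        )
    return out
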