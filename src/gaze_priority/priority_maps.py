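"""Priority-map constructors for fixation prediction.

A priority map assigns to each pixel a non-negative attention-attraction
strength.  This module builds every variant the package evaluates:

``UC``
    Object-recognition uncertainty.  After confidence filtering and NMS,
    each surviving proposal ``b`` contributes a Gaussian centered on its
    box, scaled by ``f_b / max_B f_b`` where ``f_b`` is the number of
    object categories competing for the box.  The more categories compete
    for a proposal, the less certain its recognition, and the stronger its
    pull on attention; overlapping contributions sum.
``UC_E``
    Label-entropy uncertainty: the per-box weight is instead the Shannon
    entropy of the above-threshold confidence vector (renormalized to a
    distribution), so a box with one dominant label contributes ~0 and a
    box with k equally plausible labels contributes log10(k).
``UC_P``
    Pixel-wise uncertainty: per pixel, the count of confidence-filtered
    boxes (no NMS) enclosing it, smoothed with a Gaussian kernel whose
    window is one quarter of the image height.
``CB``
    Center bias: an isotropic Gaussian at the image center,
    ``CB_p = exp(-||P - I_c||^2 / (2 sigma_c^2)) / (sigma_c sqrt(2 pi))``.
``Target``
    Target-feature maps for visual search: a Gaussian of sd one quarter of
    the image height, built on an image-height square and bilinearly
    resampled to each qualifying box, placed at the box center.  For
    target-present search only the high-confidence (>0.9) target detection
    qualifies; for target-absent search every box with target confidence
    >0.02 contributes.
``Sal``
    Bottom-up saliency, loaded from a precomputed raster; a simple
    multi-scale center-surround contrast stand-in is provided for tests.

The information-theoretic reading of the UC map is also exposed:
``unique_object_probability`` maps competing counts to the probability
``P_unique(b) = 1 - f_b / sum(f)`` that box ``b`` holds a single uniquely
recognized object, and ``self_information`` is ``-log10 P``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .detections import (
    BoundingBox,
    DetectionParams,
    DetectionSet,
    competing_count,
    filter_by_confidence,
    nms,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PriorityMap",
    "GaussianSpec",
    "gaussian_blob",
    "unique_object_probability",
    "self_information",
    "uncertainty_map",
    "label_entropy_map",
    "pixelwise_uncertainty_map",
    "center_bias_map",
    "target_map_tp",
    "target_map_ta",
    "minmax_normalize",
    "histogram_match",
    "load_saliency",
    "save_map",
    "standin_saliency",
]

SigmaRule = "Callable[[BoundingBox, tuple[int, int]], float] | float | str"


@dataclass
class PriorityMap:
    """A non-negative raster aligned to an image.

    values : float array of shape (height, width), finite and >= 0.
    variant : one of {"UC", "UC_E", "UC_P", "CB", "Target", "Sal", "other"}.
    meta : parameters the map was built with (for provenance/manifests).
    """

    values: np.ndarray
    variant: str = "other"
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("priority map must be a 2-D raster")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("priority map contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("priority map contains negative values")
        self.meta = dict(self.meta or {})

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class GaussianSpec:
    """A 2-D Gaussian: center (x, y) in pixel-center coordinates, sd in
    pixels (scalar isotropic or (sigma_x, sigma_y)), optional square
    truncation window in pixels (None = full image support)."""

    center: tuple[float, float]
    sigma: float | tuple[float, float]
    support: int | None = None

    def __post_init__(self) -> None:
        sx, sy = self.sigmas
        if sx <= 0 or sy <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.support is not None and self.support < 1:
            raise ValueError("window size must be >= 1")

    @property
    def sigmas(self) -> tuple[float, float]:
        if np.isscalar(self.sigma):
            return float(self.sigma), float(self.sigma)  # type: ignore[arg-type]
        sx, sy = self.sigma  # type: ignore[misc]
        return float(sx), float(sy)


def gaussian_blob(spec: GaussianSpec, shape: tuple[int, int]) -> PriorityMap:
    """Evaluate an unnormalized (peak 1 on its center) Gaussian at every
    pixel center of a ``(height, width)`` raster; zero outside the
    truncation window when one is given."""
    h, w = shape
    cx, cy = spec.center
    sx, sy = spec.sigmas
    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)
    g = np.exp(
        -((xs[None, :] - cx) ** 2 / (2 * sx**2) + (ys[:, None] - cy) ** 2 / (2 * sy**2))
    )
    if spec.support is not None:
        half = (spec.support - 1) / 2.0
        inside = (np.abs(xs[None, :] - cx) <= half) & (np.abs(ys[:, None] - cy) <= half)
        g = np.where(inside, g, 0.0)
    return PriorityMap(g, "other", {"center": (cx, cy), "sigma": (sx, sy)})


def unique_object_probability(f: Sequence[int]) -> np.ndarray:
    """Probability that each proposal holds a single uniquely recognized
    object, given per-box competing-category counts.

    ``P_unique(b) = 1 - f_b / sum(f)``: the more categories compete for a
    box relative to the scene total, the less likely the box resolves to
    one object.  With counts (3, 2, 1, 4) this yields (0.70, 0.80, 0.90,
    0.60).  The outputs sum to B - 1 over B boxes.
    """
    f = np.asarray(f, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one competing count")
    if np.any(f < 1):
        raise ValueError("competing counts must be >= 1")
    return 1.0 - f / f.sum()


def self_information(p, base: float = 10.0):
    """Self-information ``-log_base(p)`` of a probability (base 10 by
    default); strictly decreasing in p, zero at certainty."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("probability must be in (0, 1]")
    out = -np.log(p) / np.log(base)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# sigma rules

def _resolve_sigma(
    sigma_rule, box: BoundingBox, image_size: tuple[int, int]
) -> float:
    """Per-proposal Gaussian sd.  The default rule ``"box"`` uses one
    quarter of the box height, matching the target-map convention; a number
    fixes a global sd; a callable receives (box, image_size)."""
    if callable(sigma_rule):
        return float(sigma_rule(box, image_size))
    if isinstance(sigma_rule, str):
        if sigma_rule == "box":
            return box.h / 4.0
        raise ValueError(f"unknown sigma rule {sigma_rule!r}")
    return float(sigma_rule)


def _preprocess(
    ds: DetectionSet, params: DetectionParams | None, *, apply_nms: bool = True
) -> DetectionSet:
    if params is None:
        return ds
    out = filter_by_confidence(ds, params.th_conf)
    if apply_nms:
        out = nms(out, params.th_nms)
    logger.debug(
        "image %s: %d proposals -> %d after filtering%s",
        ds.image_id, len(ds), len(out), "+NMS" if apply_nms else "",
    )
    return out


def _weighted_gaussian_sum(
    ds: DetectionSet, weights: Sequence[float], sigma_rule
) -> np.ndarray:
    h, w = ds.image_size
    acc = np.zeros((h, w), dtype=float)
    for p, wt in zip(ds.proposals, weights):
        if wt == 0.0:
            continue
        sigma = _resolve_sigma(sigma_rule, p.box, ds.image_size)
        acc += wt * gaussian_blob(
            GaussianSpec(p.box.center, sigma), (h, w)
        ).values
    return acc


def uncertainty_map(
    ds: DetectionSet,
    params: DetectionParams | None = DetectionParams(),
    sigma_rule: SigmaRule = "box",
) -> PriorityMap:
    """Object-recognition-uncertainty priority map.

    Each proposal surviving confidence filtering and NMS adds a Gaussian at
    its box center weighted by ``f_b / max_B f_b``, the box's competing
    category count normalized by the scene maximum; the box with the most
    competing categories peaks at 1 (before overlap).  Pass ``params=None``
    if the detection set is already preprocessed.  Zero map (with a
    warning) if no proposal survives.
    """
    th = params.th_conf if params is not None else DetectionParams().th_conf
    dsf = _preprocess(ds, params)
    if len(dsf) == 0:
        logger.warning("image %s: no surviving proposals; UC map is zero", ds.image_id)
        return PriorityMap(np.zeros(ds.image_size), "UC", {"empty": True})
    f = np.array([competing_count(p, th) for p in dsf.proposals], dtype=float)
    weights = f / f.max()
    values = _weighted_gaussian_sum(dsf, weights, sigma_rule)
    return PriorityMap(values, "UC", {"th_conf": th, "sigma_rule": str(sigma_rule)})


def label_entropy_map(
    ds: DetectionSet,
    params: DetectionParams | None = DetectionParams(),
    sigma_rule: SigmaRule = "box",
    log_base: float = 10.0,
    renormalize: bool = True,
) -> PriorityMap:
    """Label-entropy uncertainty map.

    The per-proposal weight is the Shannon entropy ``-sum w log w`` of its
    above-threshold category confidences, renormalized to sum to 1 (raw
    detector scores need not form a distribution); log base 10 so that k
    uniform categories give weight log10(k).  Gaussian placement and
    summation are as in the UC map.
    """
    th = params.th_conf if params is not None else DetectionParams().th_conf
    dsf = _preprocess(ds, params)
    if len(dsf) == 0:
        logger.warning("image %s: no surviving proposals; UC_E map is zero", ds.image_id)
        return PriorityMap(np.zeros(ds.image_size), "UC_E", {"empty": True})
    weights = []
    for p in dsf.proposals:
        conf = np.array([s for s in p.scores.values() if s >= th], dtype=float)
        if conf.size == 0:
            raise ValueError("proposal with no above-threshold category")
        if renormalize:
            conf = conf / conf.sum()
        weights.append(float(-(conf * np.log(conf) / np.log(log_base)).sum()))
    values = _weighted_gaussian_sum(dsf, weights, sigma_rule)
    return PriorityMap(
        values, "UC_E", {"th_conf": th, "log_base": log_base}
    )


def _box_pixel_range(lo: float, hi: float, n: int) -> tuple[int, int]:
    """Integer pixel indices j with lo <= j < hi, clipped to [0, n)."""
    j0 = max(int(np.ceil(lo)), 0)
    j1 = min(int(np.ceil(hi)), n)
    return j0, j1


def smoothing_kernel(window: int, sigma: float | None = None) -> np.ndarray:
    """Truncated 2-D Gaussian kernel of odd side ``window``, normalized to
    sum 1; sd defaults to window/4."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        window += 1
    if sigma is None:
        sigma = window / 4.0
    half = (window - 1) // 2
    ax = np.arange(-half, half + 1, dtype=float)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(k1, k1)
    return k / k.sum()


def pixelwise_uncertainty_map(
    ds: DetectionSet,
    params: DetectionParams | None = DetectionParams(),
    smooth: bool = True,
) -> PriorityMap:
    """Pixel-wise uncertainty map: the per-pixel count of enclosing
    confidence-filtered boxes (NMS deliberately not applied — counting
    overlapping proposals is the point), smoothed with a normalized
    Gaussian kernel whose window is one quarter of the image height.
    ``smooth=False`` returns the raw counts.
    """
    th = params.th_conf if params is not None else None
    dsf = (
        filter_by_confidence(ds, params.th_conf) if params is not None else ds
    )
    h, w = ds.image_size
    counts = np.zeros((h, w), dtype=float)
    for p in dsf.proposals:
        x0, x1 = _box_pixel_range(p.box.x, p.box.x2, w)
        y0, y1 = _box_pixel_range(p.box.y, p.box.y2, h)
        counts[y0:y1, x0:x1] += 1.0
    if not smooth:
        return PriorityMap(counts, "UC_P", {"th_conf": th, "smoothed": False})
    window = int(round(h / 4))
    kernel = smoothing_kernel(max(window, 1))
    values = ndimage.convolve(counts, kernel, mode="constant", cval=0.0)
    values = np.clip(values, 0.0, None)  # guard tiny negative round-off
    return PriorityMap(values, "UC_P", {"th_conf": th, "window": kernel.shape[0]})


def center_bias_map(
    shape: tuple[int, int], sigma_c: float | None = None
) -> PriorityMap:
    """Center-bias map: isotropic Gaussian at the image center with the
    one-dimensional normal amplitude ``1/(sigma_c sqrt(2 pi))``.  The
    amplitude cancels under min-max normalization but is retained for
    fidelity to the printed form.  ``sigma_c`` defaults to height/3.
    """
    h, w = shape
    if sigma_c is None:
        sigma_c = h / 3.0
    if sigma_c <= 0:
        raise ValueError("sigma_c must be positive")
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)
    d2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
    values = np.exp(-d2 / (2 * sigma_c**2)) / (sigma_c * np.sqrt(2 * np.pi))
    return PriorityMap(values, "CB", {"sigma_c": sigma_c})


# ---------------------------------------------------------------------------
# target maps

def _bilinear_resample(src: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize with the half-pixel-center coordinate convention
    (dst pixel j samples src at (j + 0.5) * scale - 0.5, edges clamped)."""
    oh, ow = out_shape
    sh, sw = src.shape
    ys = np.clip((np.arange(oh) + 0.5) * (sh / oh) - 0.5, 0, sh - 1)
    xs = np.clip((np.arange(ow) + 0.5) * (sw / ow) - 0.5, 0, sw - 1)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(src, [yy, xx], order=1, mode="nearest")


def _target_patch(image_height: int, box: BoundingBox) -> np.ndarray:
    """The target-map Gaussian for one box: built at square side h_im with
    sd h_im/4 and bilinearly resampled to the box's pixel footprint, so its
    anisotropy follows the box aspect ratio."""
    side = int(image_height)
    c = (side - 1) / 2.0
    base = gaussian_blob(GaussianSpec((c, c), side / 4.0), (side, side)).values
    bh = max(int(round(box.h)), 1)
    bw = max(int(round(box.w)), 1)
    return _bilinear_resample(base, (bh, bw))


def _add_patch(acc: np.ndarray, patch: np.ndarray, top: int, left: int) -> None:
    h, w = acc.shape
    ph, pw = patch.shape
    y0, y1 = max(top, 0), min(top + ph, h)
    x0, x1 = max(left, 0), min(left + pw, w)
    if y1 <= y0 or x1 <= x0:
        return
    acc[y0:y1, x0:x1] += patch[y0 - top : y1 - top, x0 - left : x1 - left]


def _target_map(
    ds: DetectionSet, target_category: str, conf: float, variant: str
) -> PriorityMap:
    known = {c for p in ds.proposals for c in p.scores}
    if target_category not in known:
        raise ValueError(
            f"unknown target category {target_category!r}; detections carry "
            f"{sorted(known)}"
        )
    h, w = ds.image_size
    acc = np.zeros((h, w), dtype=float)
    n = 0
    for p in ds.proposals:
        if p.scores.get(target_category, 0.0) > conf:
            patch = _target_patch(h, p.box)
            _add_patch(acc, patch, int(round(p.box.y)), int(round(p.box.x)))
            n += 1
    if n == 0:
        logger.warning(
            "image %s: no proposal with %s confidence > %g; target map is zero",
            ds.image_id, target_category, conf,
        )
    return PriorityMap(
        acc, variant, {"target": target_category, "conf": conf, "n_boxes": n}
    )


def target_map_tp(
    ds: DetectionSet, target_category: str, conf: float = 0.9
) -> PriorityMap:
    """Target-present target map: a Gaussian bump (resampled to the box
    footprint) at the center of each box whose target-category confidence
    exceeds ``conf`` (default 0.9 — high enough that usually only the true
    target qualifies)."""
    return _target_map(ds, target_category, conf, "Target")


def target_map_ta(
    ds: DetectionSet, target_category: str, conf: float = 0.02
) -> PriorityMap:
    """Target-absent target map: the same construction applied at every
    box whose target-category confidence exceeds ``conf`` (default 0.02);
    contributions from multiple boxes sum."""
    return _target_map(ds, target_category, conf, "Target")


# ---------------------------------------------------------------------------
# post-processing

def minmax_normalize(m: PriorityMap) -> PriorityMap:
    """Rescale to [0, 1] by (m - min)/(max - min); a constant map becomes
    all-zero with a warning."""
    lo = float(m.values.min())
    hi = float(m.values.max())
    if hi - lo <= 0:
        logger.warning("constant map (variant %s): min-max normalizes to zero", m.variant)
        return PriorityMap(np.zeros_like(m.values), m.variant, {**m.meta, "normalized": True})
    return PriorityMap(
        (m.values - lo) / (hi - lo), m.variant, {**m.meta, "normalized": True}
    )


def histogram_match(m: PriorityMap, reference: PriorityMap) -> PriorityMap:
    """Monotone histogram specification: remap the values of ``m`` so their
    empirical distribution matches the reference's, preserving pixel rank
    order up to ties.  Used to make priority-map intensity distributions
    comparable to ground-truth fixation-density maps before patch
    averaging."""
    if m.shape != reference.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {reference.shape}")
    from skimage.exposure import match_histograms

    out = match_histograms(m.values, reference.values)
    out = np.clip(out, 0.0, None)
    return PriorityMap(out, m.variant, {**m.meta, "histogram_matched": True})


# ---------------------------------------------------------------------------
# saliency adapter

def save_map(m: PriorityMap, path: str | Path) -> None:
    """Write a map as 16-bit grayscale PNG (min-max scaled) plus a JSON
    sidecar recording the scale, or as a plain-text matrix for ``.txt``."""
    path = Path(path)
    if path.suffix == ".txt":
        np.savetxt(path, m.values)
        return
    import imageio.v3 as iio

    lo = float(m.values.min())
    hi = float(m.values.max())
    scale = hi - lo if hi > lo else 1.0
    raster = np.round((m.values - lo) / scale * 65535).astype(np.uint16)
    iio.imwrite(path, raster)
    sidecar = {"min": lo, "max": hi, "variant": m.variant, "meta": m.meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_saliency(path: str | Path, shape: tuple[int, int]) -> PriorityMap:
    """Load a precomputed saliency raster (16-bit PNG with optional JSON
    sidecar, or plain-text matrix), resample it to ``shape`` and tag it as
    the Sal variant."""
    path = Path(path)
    if path.suffix == ".txt":
        values = np.loadtxt(path, dtype=float, ndmin=2)
    else:
        import imageio.v3 as iio

        raster = np.asarray(iio.imread(path), dtype=float)
        if raster.ndim == 3:
            raster = raster.mean(axis=2)
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            values = meta["min"] + raster / 65535.0 * (meta["max"] - meta["min"])
        else:
            values = raster
    if values.shape != tuple(shape):
        values = _bilinear_resample(values, tuple(shape))
    return PriorityMap(np.clip(values, 0.0, None), "Sal", {"source": str(path)})


def standin_saliency(image: np.ndarray) -> PriorityMap:
    """A simple multi-scale center-surround contrast map used as a
    bottom-up-saliency stand-in in tests.

    This is not a reimplementation of any published saliency model: it sums
    |center - surround| differences of Gaussian-blurred intensity (and, for
    color images, two opponent channels) at two scales, then min-max
    normalizes.  It exists so the saliency adapter and evaluation code can
    be exercised without external rasters.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        channels = [img]
    elif img.ndim == 3 and img.shape[2] >= 3:
        r, g, b = img[..., 0], img[..., 1], img[..., 2]
        channels = [(r + g + b) / 3.0, r - g, b - (r + g) / 2.0]
    else:
        raise ValueError("expected a 2-D grayscale or H×W×3 color image")
    acc = np.zeros(img.shape[:2], dtype=float)
    for ch in channels:
        for c_sigma in (1.0, 2.0):
            center = ndimage.gaussian_filter(ch, c_sigma)
            surround = ndimage.gaussian_filter(ch, 4.0 * c_sigma)
            acc += np.abs(center - surround)
    lo, hi = acc.min(), acc.max()
    values = (acc - lo) / (hi - lo) if hi > lo else np.zeros_like(acc)
    return PriorityMap(values, "Sal", {"standin": True})
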