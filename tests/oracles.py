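"""Independent brute-force oracles used to validate the map constructors.

Everything here recomputes the defining formulas by direct per-pixel (and
where relevant per-box) summation, deliberately avoiding the vectorized
code paths of the package, so agreement is a genuine dual-route check.
"""

from __future__ import annotations

import math

import numpy as np

from gaze_priority.detections import (
    BoundingBox,
    DetectionSet,
    competing_count,
    filter_by_confidence,
    nms,
)


def iou_pixels(a: BoundingBox, b: BoundingBox) -> float:
    """IoU by counting integer pixels under the half-open convention
    (valid for integer-coordinate boxes)."""
    pa = {
        (x, y)
        for x in range(int(a.x), int(a.x2))
        for y in range(int(a.y), int(a.y2))
    }
    pb = {
        (x, y)
        for x in range(int(b.x), int(b.x2))
        for y in range(int(b.y), int(b.y2))
    }
    return len(pa & pb) / len(pa | pb)


def gauss(px: float, py: float, cx: float, cy: float, sx: float, sy: float) -> float:
    return math.exp(
        -((px - cx) ** 2 / (2 * sx * sx) + (py - cy) ** 2 / (2 * sy * sy))
    )


def _center(box: BoundingBox) -> tuple[float, float]:
    return box.x + box.w / 2 - 0.5, box.y + box.h / 2 - 0.5


def uncertainty_oracle(ds: DetectionSet, th_conf: float, th_nms: float) -> np.ndarray:
    """Direct evaluation of the recognition-uncertainty map: per surviving
    proposal, a Gaussian (sd = box height / 4) scaled by f_b / max f_b,
    summed pixel by pixel."""
    dsf = nms(filter_by_confidence(ds, th_conf), th_nms)
    h, w = ds.image_size
    out = np.zeros((h, w))
    if len(dsf) == 0:
        return out
    f = [competing_count(p, th_conf) for p in dsf.proposals]
    fmax = max(f)
    for i in range(h):
        for j in range(w):
            total = 0.0
            for p, fb in zip(dsf.proposals, f):
                cx, cy = _center(p.box)
                s = p.box.h / 4
                total += (fb / fmax) * gauss(j, i, cx, cy, s, s)
            out[i, j] = total
    return out


def entropy_oracle(ds: DetectionSet, th_conf: float, th_nms: float) -> np.ndarray:
    """Direct evaluation of the label-entropy map (base-10 entropy of the
    renormalized above-threshold confidences)."""
    dsf = nms(filter_by_confidence(ds, th_conf), th_nms)
    h, w = ds.image_size
    out = np.zeros((h, w))
    weights = []
    for p in dsf.proposals:
        conf = [s for s in p.scores.values() if s >= th_conf]
        tot = sum(conf)
        probs = [c / tot for c in conf]
        weights.append(-sum(q * math.log10(q) for q in probs))
    for i in range(h):
        for j in range(w):
            total = 0.0
            for p, wt in zip(dsf.proposals, weights):
                cx, cy = _center(p.box)
                s = p.box.h / 4
                total += wt * gauss(j, i, cx, cy, s, s)
            out[i, j] = total
    return out


def box_count_oracle(ds: DetectionSet, th_conf: float) -> np.ndarray:
    """Per-pixel count of enclosing confidence-filtered boxes: pixel j is
    inside [x, x+w) iff x <= j < x+w."""
    dsf = filter_by_confidence(ds, th_conf)
    h, w = ds.image_size
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            n = 0
            for p in dsf.proposals:
                if p.box.x <= j < p.box.x2 and p.box.y <= i < p.box.y2:
                    n += 1
            out[i, j] = n
    return out


def smooth_oracle(counts: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded correlation with a symmetric kernel, one output pixel at
    a time on a padded copy."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    padded = np.zeros((counts.shape[0] + 2 * ph, counts.shape[1] + 2 * pw))
    padded[ph : ph + counts.shape[0], pw : pw + counts.shape[1]] = counts
    out = np.empty_like(counts, dtype=float)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            out[i, j] = float((padded[i : i + kh, j : j + kw] * kernel).sum())
    return out


def center_bias_oracle(shape: tuple[int, int], sigma_c: float) -> np.ndarray:
    h, w = shape
    cx, cy = (w - 1) / 2, (h - 1) / 2
    out = np.empty((h, w))
    amp = 1.0 / (sigma_c * math.sqrt(2 * math.pi))
    for i in range(h):
        for j in range(w):
            d2 = (j - cx) ** 2 + (i - cy) ** 2
            out[i, j] = amp * math.exp(-d2 / (2 * sigma_c**2))
    return out


def bilinear_oracle(src: np.ndarray, oh: int, ow: int) -> np.ndarray:
    """Hand-rolled bilinear resize under the half-pixel-center convention,
    four-neighbour formula per output pixel."""
    sh, sw = src.shape
    out = np.empty((oh, ow))
    for i in range(oh):
        y = min(max((i + 0.5) * (sh / oh) - 0.5, 0.0), sh - 1)
        y0 = int(math.floor(y))
        y1 = min(y0 + 1, sh - 1)
        fy = y - y0
        for j in range(ow):
            x = min(max((j + 0.5) * (sw / ow) - 0.5, 0.0), sw - 1)
            x0 = int(math.floor(x))
            x1 = min(x0 + 1, sw - 1)
            fx = x - x0
            out[i, j] = (
                src[y0, x0] * (1 - fy) * (1 - fx)
                + src[y0, x1] * (1 - fy) * fx
                + src[y1, x0] * fy * (1 - fx)
                + src[y1, x1] * fy * fx
            )
    return out


def target_map_oracle(
    ds: DetectionSet, category: str, conf: float
) -> np.ndarray:
    """Direct construction of the target map: big square Gaussian
    (side h_im, sd h_im/4), hand-bilinear resample to each qualifying box
    footprint, accumulate at the box position with border clipping."""
    h, w = ds.image_size
    side = int(h)
    c = (side - 1) / 2
    base = np.empty((side, side))
    for i in range(side):
        for j in range(side):
            base[i, j] = gauss(j, i, c, c, side / 4, side / 4)
    out = np.zeros((h, w))
    for p in ds.proposals:
        if p.scores.get(category, 0.0) > conf:
            bh = max(int(round(p.box.h)), 1)
            bw = max(int(round(p.box.w)), 1)
            patch = bilinear_oracle(base, bh, bw)
            top, left = int(round(p.box.y)), int(round(p.box.x))
            for i in range(bh):
                for j in range(bw):
                    if 0 <= top + i < h and 0 <= left + j < w:
                        out[top + i, left + j] += patch[i, j]
    return out


def fdm_oracle(points, shape: tuple[int, int], sigma: float) -> np.ndarray:
    h, w = shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = sum(
                math.exp(-((j - fx) ** 2 + (i - fy) ** 2) / (2 * sigma**2))
                for fx, fy in points
            )
    return out / out.sum()


def logistic_mle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Maximum-likelihood logistic regression via direct NLL minimization
    (BFGS) — the oracle for the zero-random-variance limit of the mixed
    model."""
    from scipy.optimize import minimize

    Xd = np.column_stack([np.ones(len(X)), X])

    def nll(beta):
        eta = Xd @ beta
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    def grad(beta):
        mu = 1.0 / (1.0 + np.exp(-(Xd @ beta)))
        return Xd.T @ (mu - y)

    res = minimize(nll, np.zeros(Xd.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x
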