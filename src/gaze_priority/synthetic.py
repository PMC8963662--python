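"""Seeded generators for scenes, detector outputs, and simulated gaze.

Real inputs to this package are detector output files and eye-tracking
fixation tables; neither is needed for testing.  This module fabricates
both from known ground truth:

* scenes — bounding boxes with category labels, placed under a
  controllable overlap policy;
* detections — one multi-class proposal per object whose number of
  above-threshold competing categories is set exactly, so the
  recognition-uncertainty machinery can be inverted against the
  construction;
* fixations — multi-subject sequences sampled i.i.d. from a known convex
  mixture of priority maps plus a uniform floor, so the GLMM weighting
  analysis has a recoverable ground truth.

Fixations are sampled independently across scanpath positions: no
saccade-length prior or inhibition of return.  The patch-grid GLMM treats
fixation indices independently, so sequential structure is unnecessary for
testing it — but simulated scanpaths are not realistic scanpaths.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detections import (
    BoundingBox,
    DetectionParams,
    DetectionSet,
    ObjectProposal,
)
from .fixation_eval import (
    Fixation,
    FixationSequence,
    GlmmResult,
    WeightTable,
    build_fdm,
    build_observation_table,
    fit_glmm,
    patch_feature_means,
    select_fixation,
    weight_table,
)
from .priority_maps import (
    PriorityMap,
    center_bias_map,
    minmax_normalize,
    target_map_tp,
    uncertainty_map,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORY_POOL",
    "SceneSpec",
    "Scene",
    "MixtureSpec",
    "gen_scene",
    "gen_detections",
    "gen_fixations",
    "weight_recovery_experiment",
    "RecoveryResult",
]

#: default global category pool: the 18 everyday target-object categories
#: used in large-scale search experiments
CATEGORY_POOL: tuple[str, ...] = (
    "bottle", "bowl", "car", "chair", "clock", "cup", "fork", "keyboard",
    "knife", "laptop", "microwave", "mouse", "oven", "potted plant",
    "sink", "stop sign", "toilet", "tv",
)


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth scene layout parameters.

    image_size : (height, width) pixels; default 240 x 320, a scaled-down
        eye-tracking stimulus.
    n_objects : boxes to place.
    size_range : (min, max) box side length, pixels.
    overlap : "disjoint" (pairwise IoU 0), "any", or a float cap on
        pairwise IoU.
    region : optional fractional (x0, y0, x1, y1) window constraining box
        centers, for building spatially separated feature layouts.
    """

    image_size: tuple[int, int] = (240, 320)
    n_objects: int = 4
    size_range: tuple[int, int] = (24, 64)
    overlap: str | float = "disjoint"
    categories: tuple[str, ...] = CATEGORY_POOL
    region: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        lo, hi = self.size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid size range")


@dataclass
class Scene:
    image_size: tuple[int, int]
    boxes: list[BoundingBox]
    categories: list[str]
    scene_type: str = "scene0"


def _max_iou(spec: SceneSpec) -> float:
    if spec.overlap == "disjoint":
        return 0.0
    if spec.overlap == "any":
        return 1.0
    return float(spec.overlap)


def gen_scene(spec: SceneSpec, seed: int = 0) -> Scene:
    """Place ``n_objects`` boxes by rejection sampling under the overlap
    policy; raises if the layout is infeasible after bounded retries."""
    from .detections import iou

    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    cap = _max_iou(spec)
    x0f, y0f, x1f, y1f = spec.region or (0.0, 0.0, 1.0, 1.0)
    boxes: list[BoundingBox] = []
    tries = 0
    max_tries = 200 * max(spec.n_objects, 1)
    while len(boxes) < spec.n_objects:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {spec.n_objects} boxes under overlap policy "
                f"{spec.overlap!r} in {max_tries} tries"
            )
        tries += 1
        side_w = rng.integers(spec.size_range[0], spec.size_range[1] + 1)
        side_h = rng.integers(spec.size_range[0], spec.size_range[1] + 1)
        cx = rng.uniform(x0f * w, x1f * w)
        cy = rng.uniform(y0f * h, y1f * h)
        x = np.clip(cx - side_w / 2, 0, w - side_w)
        y = np.clip(cy - side_h / 2, 0, h - side_h)
        cand = BoundingBox(float(round(x)), float(round(y)), float(side_w), float(side_h))
        if all(iou(cand, b) <= cap for b in boxes):
            boxes.append(cand)
    cats = [spec.categories[i] for i in rng.integers(0, len(spec.categories), len(boxes))]
    return Scene(spec.image_size, boxes, cats)


def gen_detections(
    scene: Scene,
    competition: Sequence[int] | int,
    score_noise: float = 0.05,
    jitter: float = 0.0,
    seed: int = 0,
    th_conf: float = DetectionParams().th_conf,
    image_id: str = "synthetic",
) -> DetectionSet:
    """Emulate detector output for a scene with exact category competition.

    For each ground-truth object, one proposal is produced whose count of
    categories with confidence >= ``th_conf`` equals the requested
    competition level: the true category receives a dominant confidence
    (0.9 minus noise), the ``competition - 1`` distractor categories
    mid-range confidences in [0.05, 0.4], and every remaining pool
    category a sub-threshold residual, so confidence filtering has
    something to prune.  ``jitter`` shifts each box by up to that fraction
    of its size.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    comp = (
        [int(competition)] * len(scene.boxes)
        if np.isscalar(competition)
        else [int(c) for c in competition]
    )
    if len(comp) != len(scene.boxes):
        raise ValueError("one competition level per object required")
    pool = list(dict.fromkeys(scene.categories)) + [
        c for c in CATEGORY_POOL if c not in scene.categories
    ]
    h, w = scene.image_size
    proposals = []
    for box, cat, k in zip(scene.boxes, scene.categories, comp):
        if k < 1:
            raise ValueError("competition must be >= 1")
        distractors = [c for c in pool if c != cat]
        if k - 1 > len(distractors):
            raise ValueError(
                f"competition {k} exceeds category pool size {len(distractors) + 1}"
            )
        scores = {cat: float(np.clip(0.9 - score_noise * rng.uniform(), th_conf, 1.0))}
        chosen = rng.choice(len(distractors), size=k - 1, replace=False)
        for i in chosen:
            scores[distractors[i]] = float(rng.uniform(max(0.05, th_conf), 0.4))
        for i, c in enumerate(distractors):
            if i not in chosen and rng.uniform() < 0.5:
                scores[c] = float(rng.uniform(0.0, th_conf * 0.74))
        if jitter > 0:
            dx = rng.uniform(-jitter, jitter) * box.w
            dy = rng.uniform(-jitter, jitter) * box.h
            moved = BoundingBox(
                float(np.clip(box.x + dx, 0, w - box.w)),
                float(np.clip(box.y + dy, 0, h - box.h)),
                box.w,
                box.h,
            )
        else:
            moved = box
        proposals.append(ObjectProposal(moved, scores))
    return DetectionSet(image_id, scene.image_size, proposals)


@dataclass(frozen=True)
class MixtureSpec:
    """A known convex mixture of priority maps driving simulated gaze.

    weights : mixture weight per feature map, summing to 1.
    eps : uniform floor keeping the sampling density strictly positive
        (default 0.05), which also keeps the downstream logistic model
        away from separable data.
    n_subjects, n_fixations : cohort size and scanpath length per subject.
    """

    weights: tuple[float, ...]
    eps: float = 0.05
    n_subjects: int = 10
    n_fixations: int = 9
    seed: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be >= 0 and sum to 1")
        if not (0.0 <= self.eps <= 1.0):
            raise ValueError("eps must be in [0, 1]")


def mixture_density(mix: MixtureSpec, maps: Sequence[PriorityMap]) -> np.ndarray:
    """Sampling density ``(1 - eps) * sum_i w_i m_i / sum(m_i) + eps * uniform``."""
    if len(maps) != len(mix.weights):
        raise ValueError("one weight per map required")
    shape = maps[0].shape
    d = np.zeros(shape, dtype=float)
    for wt, m in zip(mix.weights, maps):
        if m.shape != shape:
            raise ValueError("all maps must share a shape")
        tot = m.values.sum()
        if tot > 0:
            d += wt * m.values / tot
    d = (1.0 - mix.eps) * d + mix.eps / (shape[0] * shape[1])
    if d.sum() <= 0:
        raise ValueError("all-zero mixture density")
    return d / d.sum()


def gen_fixations(
    mix: MixtureSpec,
    maps: Sequence[PriorityMap],
    image_id: str = "synthetic",
    seed: int | None = None,
) -> list[FixationSequence]:
    """Sample a cohort of fixation sequences i.i.d. from the mixture
    density; subject s, fixation n are drawn independently.  Deterministic
    given seed (falls back to ``mix.seed``)."""
    if seed is None:
        seed = mix.seed if mix.seed is not None else 0
    rng = np.random.default_rng(seed)
    d = mixture_density(mix, maps)
    h, w = d.shape
    flat = d.ravel()
    n_total = mix.n_subjects * mix.n_fixations
    idx = rng.choice(flat.size, size=n_total, p=flat)
    xs = (idx % w).astype(float)
    ys = (idx // w).astype(float)
    out = []
    k = 0
    for s in range(mix.n_subjects):
        fixations = []
        for n in range(1, mix.n_fixations + 1):
            fixations.append(Fixation(xs[k], ys[k], n))
            k += 1
        out.append(FixationSequence(f"s{s:02d}", image_id, fixations))
    return out


# ---------------------------------------------------------------------------
# end-to-end recovery harness

@dataclass
class RecoveryResult:
    """Output of the weight-recovery experiment: the recovered weight
    table, the per-index GLMM fits, the generating mixture, and the
    feature names in mixture order."""

    weights: WeightTable
    glmm_results: list[GlmmResult]
    mix: MixtureSpec
    features: list[str]


def _recovery_image(
    spec_size: tuple[int, int], rng: np.random.Generator, image_id: str
) -> tuple[dict[str, PriorityMap], Scene]:
    """One synthetic image with three spatially separated feature maps:
    recognition uncertainty from cluttered objects on one side, center
    bias, and a target map from a single high-confidence detection on the
    opposite side."""
    h, w = spec_size
    left = rng.uniform() < 0.5
    uc_region = (0.05, 0.1, 0.35, 0.9) if left else (0.65, 0.1, 0.95, 0.9)
    tgt_region = (0.72, 0.15, 0.9, 0.85) if left else (0.1, 0.15, 0.28, 0.85)
    clutter = gen_scene(
        SceneSpec(
            image_size=spec_size, n_objects=3, size_range=(28, 56),
            overlap=0.1, region=uc_region,
        ),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    comp = rng.integers(2, 5, size=len(clutter.boxes))
    det_clutter = gen_detections(
        clutter, comp, seed=int(rng.integers(0, 2**31 - 1)), image_id=image_id
    )
    target = gen_scene(
        SceneSpec(
            image_size=spec_size, n_objects=1, size_range=(36, 56),
            region=tgt_region,
        ),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    target.categories = ["cup"]
    det_target = gen_detections(
        target, 1, score_noise=0.02, seed=int(rng.integers(0, 2**31 - 1)),
        image_id=image_id,
    )
    # sigma_c = h/8: the three mixture components must be comparably
    # concentrated, else a GLMM z reflects a map's spatial discriminability
    # rather than its mixture weight and weight ordering is unrecoverable
    maps = {
        "uncertainty": minmax_normalize(uncertainty_map(det_clutter)),
        "center_bias": minmax_normalize(center_bias_map(spec_size, h / 8.0)),
        "target": minmax_normalize(target_map_tp(det_target, "cup", conf=0.5)),
    }
    clutter.scene_type = f"scene{int(rng.integers(0, 5))}"
    return maps, clutter


def weight_recovery_experiment(
    mix: MixtureSpec,
    n_images: int = 200,
    seed: int = 0,
    image_size: tuple[int, int] = (240, 320),
) -> RecoveryResult:
    """Run the full pipeline on simulated data with known mixture weights.

    Per image: build three well-separated feature maps (uncertainty,
    center bias, target), sample every subject's fixations from the
    weighted mixture, then per fixation index assemble the patch
    observation table and fit the logistic mixed model (scene type as a
    random intercept).  Returns the recovered weight table alongside the
    generating spec, so recovered z-orderings can be compared with the
    true weights.
    """
    features = ["uncertainty", "center_bias", "target"]
    if len(mix.weights) != len(features):
        raise ValueError(f"this harness mixes {len(features)} features")
    rng = np.random.default_rng(seed)
    maps: dict[str, dict[str, PriorityMap]] = {}
    scene_types: dict[str, str] = {}
    seqs: list[FixationSequence] = []
    for i in range(n_images):
        image_id = f"im{i:04d}"
        per_image, scene = _recovery_image(image_size, rng, image_id)
        maps[image_id] = per_image
        scene_types[image_id] = scene.scene_type
        seqs.extend(
            gen_fixations(
                mix, [per_image[f] for f in features], image_id,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    fdms = {
        img: build_fdm([s for s in seqs if s.image_id == img], image_size)
        for img in maps
    }
    pfeat = patch_feature_means(maps, fdms)
    results = []
    instances = []
    for n in range(1, mix.n_fixations + 1):
        table = build_observation_table(
            maps, seqs, n, fdms=fdms, group_labels={"scene_type": scene_types},
            patch_features=pfeat,
        )
        results.append(fit_glmm(table, features, random=["scene_type"]))
        _, count = select_fixation(seqs, n)
        instances.append(count)
    wt = weight_table(results, instances, features)
    return RecoveryResult(wt, results, mix, features)
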