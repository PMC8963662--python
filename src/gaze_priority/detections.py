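"""Multi-class object proposals: data model, IO, filtering, IoU and NMS.

A detector (e.g. an instance-segmentation network) emits, per image, a set
of proposal bounding boxes each carrying a confidence score for one or more
object categories.  Everything downstream — the recognition-uncertainty
maps, the label-entropy map, the target maps — operates on these proposals
after two preprocessing steps:

* confidence filtering: a proposal survives iff its best category score
  reaches ``th_conf`` (default 0.02), and sub-threshold category entries
  are pruned from survivors;
* class-agnostic non-maximum suppression (NMS) at IoU ``th_nms`` (default
  0.30), which enforces a one-to-one mapping between a surviving proposal
  and a physical object.

Coordinates are 0-based with origin at the top-left corner, x growing
rightward and y downward.  A box ``[x, y, w, h]`` covers the half-open
pixel range ``[x, x+w) × [y, y+h)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "BoundingBox",
    "ObjectProposal",
    "DetectionSet",
    "DetectionParams",
    "DetectionFormatError",
    "iou",
    "filter_by_confidence",
    "nms",
    "competing_count",
    "read_detections",
    "write_detections",
]


class DetectionFormatError(ValueError):
    """A detection file record could not be parsed."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box ``[x, x+w) × [y, y+h)`` in pixel units."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"degenerate box: w={self.w}, h={self.h}")
        for v in (self.x, self.y, self.w, self.h):
            if not math.isfinite(v):
                raise ValueError("box coordinates must be finite")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        """Box center ``(cx, cy)`` in pixel-center coordinates.

        Pixel ``(row i, col j)`` has its center at continuous coordinate
        ``(x=j, y=i)``, so a box [0, 10) is centered at 4.5.
        """
        return (self.x + self.w / 2 - 0.5, self.y + self.h / 2 - 0.5)

    def clip(self, image_size: tuple[int, int]) -> "BoundingBox | None":
        """Clip to ``(height, width)``; None if nothing remains inside."""
        h_im, w_im = image_size
        x1 = max(self.x, 0.0)
        y1 = max(self.y, 0.0)
        x2 = min(self.x2, float(w_im))
        y2 = min(self.y2, float(h_im))
        if x2 - x1 <= 0 or y2 - y1 <= 0:
            return None
        return BoundingBox(x1, y1, x2 - x1, y2 - y1)


@dataclass(frozen=True)
class ObjectProposal:
    """A bounding box plus per-category confidences in [0, 1]."""

    box: BoundingBox
    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError("proposal must carry at least one category score")
        for cat, s in self.scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"confidence for {cat!r} outside [0,1]: {s}")
        object.__setattr__(self, "scores", dict(self.scores))

    @property
    def max_score(self) -> float:
        return max(self.scores.values())


@dataclass
class DetectionSet:
    """All proposals for one image, in stable input order."""

    image_id: str
    image_size: tuple[int, int]  # (height, width)
    proposals: list[ObjectProposal] = field(default_factory=list)

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError(f"invalid image size {self.image_size}")
        self.image_id = str(self.image_id)
        self.proposals = list(self.proposals)

    def __len__(self) -> int:
        return len(self.proposals)

    def replace_proposals(self, proposals: Iterable[ObjectProposal]) -> "DetectionSet":
        return DetectionSet(self.image_id, self.image_size, list(proposals))


@dataclass(frozen=True)
class DetectionParams:
    """Detector post-processing thresholds.

    th_conf : minimum category confidence for a proposal (and for a
        category entry within it) to be retained; default 0.02.
    th_nms : IoU above which a lower-scoring box is suppressed; default 0.30.
    """

    th_conf: float = 0.02
    th_nms: float = 0.30

    def __post_init__(self) -> None:
        for name in ("th_conf", "th_nms"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes under the half-open convention.

    For integer-coordinate boxes this equals the ratio of overlapping to
    covered pixel counts.
    """
    iw = min(a.x2, b.x2) - max(a.x, b.x)
    ih = min(a.y2, b.y2) - max(a.y, b.y)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def filter_by_confidence(ds: DetectionSet, th_conf: float) -> DetectionSet:
    """Keep proposals whose best score reaches ``th_conf``; prune weak entries.

    Within a surviving proposal, category entries with confidence below the
    threshold are dropped, so the remaining entries are exactly the
    categories still competing for the box.  Input order is preserved.
    """
    if not (0.0 <= th_conf <= 1.0):
        raise ValueError(f"th_conf must be in [0,1], got {th_conf}")
    kept = []
    for p in ds.proposals:
        if p.max_score >= th_conf:
            scores = {c: s for c, s in p.scores.items() if s >= th_conf}
            kept.append(ObjectProposal(p.box, scores))
    return ds.replace_proposals(kept)


def nms(
    ds: DetectionSet, th_nms: float, *, class_agnostic: bool = True
) -> DetectionSet:
    """Greedy non-maximum suppression on a detection set.

    Proposals are visited in order of decreasing best category score (ties
    broken by input order); each kept box suppresses any later box whose
    IoU with it is strictly greater than ``th_nms``.  The default is
    class-agnostic — one surviving box per physical object regardless of
    its label; ``class_agnostic=False`` instead suppresses within each
    category independently (using that category's score) and keeps a
    proposal with the union of its surviving category entries.
    """
    if not (0.0 <= th_nms <= 1.0):
        raise ValueError(f"th_nms must be in [0,1], got {th_nms}")
    if class_agnostic:
        kept_idx = _greedy_nms(
            [(p.box, p.max_score) for p in ds.proposals], th_nms
        )
        return ds.replace_proposals(ds.proposals[i] for i in sorted(kept_idx))
    # per-class: run the same greedy pass inside each category
    surviving: dict[int, set[str]] = {}
    categories = sorted({c for p in ds.proposals for c in p.scores})
    for cat in categories:
        idx = [i for i, p in enumerate(ds.proposals) if cat in p.scores]
        kept = _greedy_nms(
            [(ds.proposals[i].box, ds.proposals[i].scores[cat]) for i in idx],
            th_nms,
        )
        for k in kept:
            surviving.setdefault(idx[k], set()).add(cat)
    out = []
    for i in sorted(surviving):
        p = ds.proposals[i]
        out.append(
            ObjectProposal(p.box, {c: p.scores[c] for c in sorted(surviving[i])})
        )
    return ds.replace_proposals(out)


def _greedy_nms(boxes_scores: list[tuple[BoundingBox, float]], th: float) -> list[int]:
    order = sorted(
        range(len(boxes_scores)), key=lambda i: (-boxes_scores[i][1], i)
    )
    kept: list[int] = []
    for i in order:
        if all(iou(boxes_scores[i][0], boxes_scores[k][0]) <= th for k in kept):
            kept.append(i)
    return kept


def competing_count(p: ObjectProposal, th_conf: float) -> int:
    """Number of categories competing for a proposal: entries with
    confidence >= ``th_conf``.

    This is the per-box quantity the recognition-uncertainty map is built
    from; it is at least 1 for any proposal that survived confidence
    filtering.  Raises if no category meets the threshold (such a proposal
    should have been filtered out upstream).
    """
    n = sum(1 for s in p.scores.values() if s >= th_conf)
    if n == 0:
        raise ValueError(
            f"no category reaches th_conf={th_conf}; proposal should have "
            "been removed by confidence filtering"
        )
    return n


# ---------------------------------------------------------------------------
# IO

def _proposal_record(image: DetectionSet, p: ObjectProposal) -> dict:
    return {
        "image_id": image.image_id,
        "image_height": image.image_size[0],
        "image_width": image.image_size[1],
        "bbox": [p.box.x, p.box.y, p.box.w, p.box.h],
        "scores": dict(p.scores),
    }


def write_detections(sets: Sequence[DetectionSet], path: str | Path) -> None:
    """Serialize detection sets as a flat JSON list of per-proposal records."""
    records = [_proposal_record(ds, p) for ds in sets for p in ds.proposals]
    # images with zero proposals still need a stanza so sizes round-trip
    seen = {r["image_id"] for r in records}
    for ds in sets:
        if ds.image_id not in seen:
            records.append(
                {
                    "image_id": ds.image_id,
                    "image_height": ds.image_size[0],
                    "image_width": ds.image_size[1],
                    "bbox": None,
                    "scores": {},
                }
            )
    Path(path).write_text(json.dumps(records, indent=1))


def read_detections(
    path: str | Path,
    image_sizes: Mapping[str, tuple[int, int]] | None = None,
) -> list[DetectionSet]:
    """Read a multi-class detection file (or a strict single-category
    results file) into a list of DetectionSet, one per image.

    Two dialects are accepted:

    * native: records ``{image_id, image_height, image_width, bbox:[x,y,w,h],
      scores:{category: confidence, ...}}``;
    * single-category results (``{image_id, category_id, score, bbox}``,
      the common detector-output exchange format): records sharing an
      identical bbox within an image are coalesced into one multi-class
      proposal.  Image sizes are then taken from ``image_sizes`` or, with a
      warning, inferred from the maximal box extents.

    Boxes are clipped to the image bounds on read; a proposal entirely
    outside its image is dropped with a warning.  Malformed records raise
    DetectionFormatError naming the image and record index.
    """
    raw = json.loads(Path(path).read_text())
    if raw == []:
        return []
    if not isinstance(raw, list):
        raise DetectionFormatError("detection file must contain a JSON list")

    per_image: dict[str, dict] = {}
    for i, rec in enumerate(raw):
        if not isinstance(rec, dict):
            raise DetectionFormatError(f"record {i}: not an object")
        image_id = str(rec.get("image_id", ""))
        if not image_id:
            raise DetectionFormatError(f"record {i}: missing image_id")
        try:
            if "scores" in rec:
                entry = per_image.setdefault(
                    image_id,
                    {"size": (int(rec["image_height"]), int(rec["image_width"])),
                     "proposals": []},
                )
                if rec.get("bbox") is not None:
                    x, y, w, h = (float(v) for v in rec["bbox"])
                    entry["proposals"].append(
                        (x, y, w, h, {str(c): float(s) for c, s in rec["scores"].items()})
                    )
            elif "category_id" in rec:
                entry = per_image.setdefault(
                    image_id, {"size": None, "proposals": []}
                )
                x, y, w, h = (float(v) for v in rec["bbox"])
                key = (x, y, w, h)
                for bx, by, bw, bh, scores in entry["proposals"]:
                    if (bx, by, bw, bh) == key:
                        scores[str(rec["category_id"])] = float(rec["score"])
                        break
                else:
                    entry["proposals"].append(
                        (x, y, w, h, {str(rec["category_id"]): float(rec["score"])})
                    )
            else:
                raise KeyError("scores")
        except DetectionFormatError:
            raise
        except (KeyError, TypeError, ValueError) as exc:
            raise DetectionFormatError(
                f"image {image_id!r}, record {i}: {exc}"
            ) from exc

    out = []
    for image_id, entry in per_image.items():
        size = entry["size"]
        if size is None:
            if image_sizes is not None and image_id in image_sizes:
                size = tuple(image_sizes[image_id])
            else:
                size = (
                    int(math.ceil(max(y + h for _, y, _, h, _ in entry["proposals"]))),
                    int(math.ceil(max(x + w for x, _, w, _, _ in entry["proposals"]))),
                )
                logger.warning(
                    "image %s: no image size in file; inferred %s from box "
                    "extents", image_id, size,
                )
        proposals = []
        for x, y, w, h, scores in entry["proposals"]:
            clipped = BoundingBox(x, y, w, h).clip(size)
            if clipped is None:
                logger.warning(
                    "image %s: dropping proposal fully outside image: %s",
                    image_id, (x, y, w, h),
                )
                continue
            proposals.append(ObjectProposal(clipped, scores))
        out.append(DetectionSet(image_id, size, proposals))
    return out
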