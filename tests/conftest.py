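import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from gaze_priority.detections import BoundingBox, DetectionSet, ObjectProposal

CATEGORIES = ["cup", "bowl", "fork", "clock", "car", "bottle"]


def random_detection_set(
    rng: np.random.Generator,
    image_size=(64, 64),
    n_proposals=5,
    image_id="img",
) -> DetectionSet:
    """A random multi-class detection set with integer boxes and a spread
    of above/below-threshold confidences."""
    h, w = image_size
    proposals = []
    for _ in range(n_proposals):
        bw = int(rng.integers(6, max(7, w // 2)))
        bh = int(rng.integers(6, max(7, h // 2)))
        x = int(rng.integers(0, w - bw + 1))
        y = int(rng.integers(0, h - bh + 1))
        k = int(rng.integers(1, 5))
        cats = rng.choice(len(CATEGORIES), size=k, replace=False)
        scores = {CATEGORIES[c]: float(rng.uniform(0.03, 0.95)) for c in cats}
        # sprinkle sub-threshold entries so filtering has work to do
        if rng.uniform() < 0.5:
            extra = CATEGORIES[int(rng.integers(0, len(CATEGORIES)))]
            scores.setdefault(extra, float(rng.uniform(0.0, 0.015)))
        proposals.append(ObjectProposal(BoundingBox(x, y, bw, bh), scores))
    return DetectionSet(image_id, image_size, proposals)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
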