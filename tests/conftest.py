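import numpy as np
import pytest

from fusedet import (
    Box,
    Dataset,
    Detection,
    DetectionSet,
    GroundTruthBox,
    ImageInfo,
)


def make_dataset(image_sizes, gt_specs, category_id=1):
    """Build a Dataset from [(img, w, h)] and [(img, x0, y0, x1, y1)]."""
    images = [ImageInfo(i, w, h) for i, w, h in image_sizes]
    gts = [
        GroundTruthBox(img, Box(x0, y0, x1, y1), category_id)
        for img, x0, y0, x1, y1 in gt_specs
    ]
    return Dataset(images=images, ground_truth=gts,
                   categories={category_id: "object"})


def make_dets(model_id, det_specs, category_id=1, normalized=False):
    """Build a DetectionSet from [(img, x0, y0, x1, y1, score)]."""
    return DetectionSet(
        model_id=model_id,
        detections=[
            Detection(img, Box(x0, y0, x1, y1, normalized=normalized),
                      score, category_id, model_id)
            for img, x0, y0, x1, y1, score in det_specs
        ],
    )


def random_fusion_instance(seed, max_models=4, max_boxes=8):
    """A small random multi-model detection scenario on the unit square."""
    rng = np.random.default_rng(seed)
    n_models = int(rng.integers(1, max_models + 1))
    n_images = int(rng.integers(1, 4))
    det_sets = []
    for m in range(n_models):
        dets = []
        for img in range(1, n_images + 1):
            for b in range(int(rng.integers(0, max_boxes + 1))):
                cx, cy = rng.uniform(0.15, 0.85, 2)
                w, h = rng.uniform(0.05, 0.25, 2)
                box = Box(
                    max(cx - w / 2, 0.0), max(cy - h / 2, 0.0),
                    min(cx + w / 2, 1.0), min(cy + h / 2, 1.0),
                    normalized=True,
                )
                cat = int(rng.integers(1, 3))
                dets.append(
                    Detection(img, box, float(rng.uniform(0.0, 1.0)),
                              cat, f"m{m}")
                )
        det_sets.append(DetectionSet(model_id=f"m{m}", detections=dets))
    weights = [int(w) for w in rng.integers(1, n_models + 1, size=n_models)]
    return det_sets, weights


def random_eval_scene(seed, n_images=3, max_gt=3, max_dets=6):
    """A random ground-truth + single-model detection scene in pixels."""
    rng = np.random.default_rng(seed)
    images = [(i, 100, 100) for i in range(1, n_images + 1)]
    gt_specs, det_specs = [], []
    for img in range(1, n_images + 1):
        for _ in range(int(rng.integers(0, max_gt + 1))):
            x0, y0 = rng.uniform(0, 60, 2)
            w, h = rng.uniform(10, 35, 2)
            gt_specs.append((img, x0, y0, x0 + w, y0 + h))
        for _ in range(int(rng.integers(0, max_dets + 1))):
            x0, y0 = rng.uniform(0, 60, 2)
            w, h = rng.uniform(10, 35, 2)
            det_specs.append(
                (img, x0, y0, x0 + w, y0 + h, float(rng.uniform(0, 1)))
            )
    return make_dataset(images, gt_specs), make_dets("m", det_specs)


def synth_xray(light_bg, seed, size=(300, 240)):
    """Radiograph-like test image: limb-shaped bright blob on a dark (or
    light, when inverted acquisition is emulated) background plus noise."""
    rng = np.random.default_rng(seed)
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    blob = 180 * np.exp(-(((yy - h / 2) / (h / 3)) ** 2
                          + ((xx - w / 2) / (w / 6)) ** 2))
    bg = 230 if light_bg else 15
    base = np.full(size, float(bg))
    mask = blob > 30
    base[mask] = np.clip(255 - blob[mask] if light_bg else blob[mask], 0, 255)
    return np.clip(base + rng.normal(0, 5, size), 0, 255).astype(np.uint8)


@pytest.fixture
def toy_dataset():
    return make_dataset(
        [(1, 100, 100), (2, 100, 100)],
        [(1, 10, 10, 40, 40), (1, 60, 60, 90, 90), (2, 20, 20, 50, 50)],
    )
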