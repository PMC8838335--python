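"""Seeded simulation of ground truth and detector outputs.

The generator emulates the shape of a clinical wrist-radiograph detection
benchmark — a few hundred images, roughly 1.05 boxes per image (one
fracture per image, occasionally two) — and two detector archetypes:

* ``single``-stage-like: many boxes, most of them low-confidence false
  positives, so the number of surviving boxes falls steeply as the score
  threshold rises;
* ``two``-stage-like: few boxes with high confidence, so the count falls
  gently with the threshold.

Scores are Beta-distributed; detection of each ground-truth box is a
Bernoulli draw; localization error is truncated corner-wise Gaussian
jitter; false positives arrive as a per-image Poisson process with
uniformly placed boxes.  Everything is bit-reproducible given (config,
seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .boxes_io import (
    Box,
    Dataset,
    Detection,
    DetectionSet,
    GroundTruthBox,
    ImageInfo,
    ValidationError,
)

logger = logging.getLogger("fusedet")

__all__ = [
    "SceneConfig",
    "DetectorProfile",
    "SplitSpec",
    "single_stage_profile",
    "two_stage_profile",
    "generate_scenes",
    "box_hardness",
    "simulate_detector",
    "plant_ensemble_optimum",
    "split",
]


@dataclass(frozen=True)
class SceneConfig:
    """Ground-truth generator settings.

    ``boxes_per_image`` maps a box count to its probability; the default
    {1: 0.95, 2: 0.05} reproduces ~1.05 boxes per image (569 fractures in
    542 images).
    """

    n_images: int = 542
    image_size: tuple[int, int] = (800, 800)  # (width, height)
    boxes_per_image: dict[int, float] = field(
        default_factory=lambda: {1: 0.95, 2: 0.05}
    )
    box_size_range: tuple[int, int] = (48, 160)
    category_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 0:
            raise ValidationError("n_images must be >= 0")
        if min(self.image_size) < 1:
            raise ValidationError("image dimensions must be positive")
        lo, hi = self.box_size_range
        if not 0 < lo <= hi:
            raise ValidationError("box_size_range must be positive, lo <= hi")
        if hi > min(self.image_size):
            raise ValidationError(
                f"boxes up to {hi}px cannot fit inside a "
                f"{self.image_size[0]}x{self.image_size[1]} image"
            )
        total = sum(self.boxes_per_image.values())
        if abs(total - 1.0) > 1e-9 or any(
            k < 0 or p < 0 for k, p in self.boxes_per_image.items()
        ):
            raise ValidationError("boxes_per_image must be a distribution")


@dataclass(frozen=True)
class DetectorProfile:
    """Generative operating characteristics of one simulated detector."""

    model_id: str
    stage: str  # "single" or "two"
    p_detect: float = 0.85
    loc_jitter_sd: float = 6.0
    fp_per_image: float = 1.0
    tp_score_ab: tuple[float, float] = (6.0, 2.0)  # Beta parameters
    fp_score_ab: tuple[float, float] = (1.2, 5.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_detect <= 1.0:
            raise ValidationError("p_detect must be in [0, 1]")
        if self.loc_jitter_sd < 0 or self.fp_per_image < 0:
            raise ValidationError("jitter sd and FP rate must be >= 0")
        if self.stage not in ("single", "two"):
            raise ValidationError("stage must be 'single' or 'two'")


def single_stage_profile(model_id: str, p_detect: float = 0.95,
                         loc_jitter_sd: float = 14.0,
                         fp_per_image: float = 6.0) -> DetectorProfile:
    """Many boxes, mostly low-confidence: counts drop steeply with the
    score threshold (thousands at 0.1 down to a handful at 0.7).

    ``p_detect`` is high because real detectors almost always emit *some*
    box near a lesion — quality shows up as localization error and false
    positives, not absence.  Together with shared per-box hardness (see
    :func:`box_hardness`) the defaults put one simulated model in the
    AP50 ~ 0.6-0.8 range typical of fracture detectors on radiographs.
    """
    return DetectorProfile(
        model_id=model_id, stage="single", p_detect=p_detect,
        loc_jitter_sd=loc_jitter_sd, fp_per_image=fp_per_image,
        tp_score_ab=(5.0, 2.5), fp_score_ab=(1.2, 6.0),
    )


def two_stage_profile(model_id: str, p_detect: float = 0.95,
                      loc_jitter_sd: float = 9.0,
                      fp_per_image: float = 0.5) -> DetectorProfile:
    """Few boxes with high confidence: counts decline gently with the
    threshold.  Same AP50 ~ 0.65-0.8 single-model calibration."""
    return DetectorProfile(
        model_id=model_id, stage="two", p_detect=p_detect,
        loc_jitter_sd=loc_jitter_sd, fp_per_image=fp_per_image,
        tp_score_ab=(9.0, 1.8), fp_score_ab=(2.5, 2.0),
    )


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    rounding: str = "nearest_then_fix_total"

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValidationError("fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValidationError("fractions must sum to 1")
        if self.rounding != "nearest_then_fix_total":
            raise ValidationError(f"unknown rounding {self.rounding!r}")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_scenes(cfg: SceneConfig) -> Dataset:
    """Draw images and in-bounds ground-truth boxes; seeded, reproducible."""
    rng = np.random.default_rng(cfg.seed)
    w_img, h_img = cfg.image_size
    counts = sorted(cfg.boxes_per_image.keys())
    probs = [cfg.boxes_per_image[k] for k in counts]
    lo, hi = cfg.box_size_range

    images, gts = [], []
    for i in range(cfg.n_images):
        image_id = i + 1
        images.append(ImageInfo(image_id, w_img, h_img))
        n_boxes = int(rng.choice(counts, p=probs))
        for _ in range(n_boxes):
            bw = float(rng.uniform(lo, hi))
            bh = float(rng.uniform(lo, hi))
            x0 = float(rng.uniform(0.0, w_img - bw))
            y0 = float(rng.uniform(0.0, h_img - bh))
            gts.append(
                GroundTruthBox(
                    image_id=image_id,
                    box=Box(x0, y0, x0 + bw, y0 + bh),
                    category_id=cfg.category_id,
                )
            )
    return Dataset(images=images, ground_truth=gts,
                   categories={cfg.category_id: "fracture"})


def _jitter_box(box: Box, sd: float, w_img: int, h_img: int,
                rng: np.random.Generator) -> Box:
    """Corner-wise Gaussian jitter, truncated so the box stays valid and
    inside the image (at least 2 px of extent is preserved)."""
    if sd == 0:
        return box
    dx0, dy0, dx1, dy1 = rng.normal(0.0, sd, size=4)
    x0 = min(max(box.x_min + dx0, 0.0), w_img - 2.0)
    y0 = min(max(box.y_min + dy0, 0.0), h_img - 2.0)
    x1 = min(max(box.x_max + dx1, x0 + 2.0), float(w_img))
    y1 = min(max(box.y_max + dy1, y0 + 2.0), float(h_img))
    return Box(x0, y0, x1, y1)


def _random_box(lo: float, hi: float, w_img: int, h_img: int,
                rng: np.random.Generator) -> Box:
    bw = float(rng.uniform(lo, hi))
    bh = float(rng.uniform(lo, hi))
    x0 = float(rng.uniform(0.0, w_img - bw))
    y0 = float(rng.uniform(0.0, h_img - bh))
    return Box(x0, y0, x0 + bw, y0 + bh)


def _beta_score(ab: tuple[float, float], rng: np.random.Generator) -> float:
    # keep scores strictly inside [0, 1] to respect the Detection invariant
    return float(min(max(rng.beta(*ab), 1e-9), 1.0 - 1e-9))


def box_hardness(dataset: Dataset, seed: int = 0,
                 ab: tuple[float, float] = (0.6, 1.8)) -> np.ndarray:
    """Per-ground-truth-box difficulty in [0, 1], shared across detectors.

    Real detectors' errors are correlated: a subtle fracture is hard for
    every model at once.  Passing one hardness vector to several
    :func:`simulate_detector` calls reproduces that correlation — a hard
    box is missed more often, localized more loosely and scored lower by
    *all* simulated models, instead of each model erring independently.
    """
    rng = np.random.default_rng(seed)
    return rng.beta(*ab, size=len(dataset.ground_truth))


def simulate_detector(dataset: Dataset, prof: DetectorProfile,
                      seed: int = 0,
                      fp_size_range: tuple[int, int] = (48, 160),
                      detect_mask: dict[int, bool] | None = None,
                      hardness: np.ndarray | None = None
                      ) -> DetectionSet:
    """Simulate one detector's output over a dataset.

    Each ground-truth box is found with probability ``p_detect`` (or per
    the optional ``detect_mask`` keyed by ground-truth index), localized
    with truncated Gaussian corner jitter and scored from the TP Beta
    distribution.  False positives are a Poisson process per image with
    uniformly placed boxes and FP-Beta scores.

    ``hardness`` (one value in [0, 1] per ground-truth box, typically from
    :func:`box_hardness` with a dataset-level seed) induces correlated
    difficulty across detectors: hardness h scales the localization
    jitter by (0.5 + 2 h) and the detection probability mildly by
    (1 - 0.3 h) — hard lesions are poorly localized by *every* model at
    once, and occasionally missed outright.  Confidence is left
    untouched: the low-score mass of an archetype is its false
    positives, not shaky true positives.
    """
    rng = np.random.default_rng(seed)
    sizes = dataset.sizes()
    if hardness is not None and len(hardness) != len(dataset.ground_truth):
        raise ValidationError("one hardness value per ground-truth box")
    dets: list[Detection] = []
    for gt_idx, gt in enumerate(dataset.ground_truth):
        w_img, h_img = sizes[gt.image_id]
        h = float(hardness[gt_idx]) if hardness is not None else 0.0
        p_eff = prof.p_detect * (1.0 - 0.3 * h)
        if detect_mask is not None and gt_idx in detect_mask:
            found = detect_mask[gt_idx] and rng.uniform() < p_eff
        else:
            found = rng.uniform() < p_eff
        if not found:
            continue
        dets.append(
            Detection(
                image_id=gt.image_id,
                box=_jitter_box(gt.box, prof.loc_jitter_sd * (0.5 + 2.0 * h),
                                w_img, h_img, rng),
                score=_beta_score(prof.tp_score_ab, rng),
                category_id=gt.category_id,
                model_id=prof.model_id,
            )
        )
    lo, hi = fp_size_range
    cat = next(iter(dataset.categories), 1)
    for im in dataset.images:
        for _ in range(int(rng.poisson(prof.fp_per_image))):
            dets.append(
                Detection(
                    image_id=im.image_id,
                    box=_random_box(lo, hi, im.width, im.height, rng),
                    score=_beta_score(prof.fp_score_ab, rng),
                    category_id=cat,
                    model_id=prof.model_id,
                )
            )
    return DetectionSet(model_id=prof.model_id, detections=dets)


def plant_ensemble_optimum(dataset: Dataset, n_models: int, seed: int = 0,
                           n_planted: int = 3
                           ) -> tuple[dict[str, DetectionSet], list[str]]:
    """Construct a pool with a known-good member subset.

    ``n_planted`` detectors get complementary error patterns: the
    ground-truth boxes are partitioned into ``n_planted`` disjoint shares
    and planted detector i misses share i entirely while finding the rest
    almost surely with tight localization and few false positives.  The
    remaining models are noise-dominated (low detection rate, loose boxes,
    many false positives).  Fusing all planted members therefore beats any
    single one, and a criterion-driven search should recover them.
    """
    if n_models < 3:
        raise ValidationError("plant_ensemble_optimum needs n_models >= 3")
    if not 2 <= n_planted <= n_models:
        raise ValidationError("need 2 <= n_planted <= n_models")
    rng = np.random.default_rng(seed)
    shares = rng.integers(0, n_planted, size=len(dataset.ground_truth))

    det_sets: dict[str, DetectionSet] = {}
    planted: list[str] = []
    for i in range(n_planted):
        model_id = f"planted_{i + 1}"
        planted.append(model_id)
        prof = DetectorProfile(
            model_id=model_id, stage="two", p_detect=0.98,
            loc_jitter_sd=2.0, fp_per_image=0.1,
            tp_score_ab=(12.0, 2.0), fp_score_ab=(2.0, 3.0),
        )
        mask = {j: (shares[j] != i) for j in range(len(shares))}
        det_sets[model_id] = simulate_detector(
            dataset, prof, seed=int(rng.integers(2**31)), detect_mask=mask
        )
    for i in range(n_models - n_planted):
        model_id = f"noise_{i + 1}"
        prof = DetectorProfile(
            model_id=model_id, stage="single", p_detect=0.25,
            loc_jitter_sd=18.0, fp_per_image=4.0,
            tp_score_ab=(3.0, 3.0), fp_score_ab=(2.0, 3.0),
        )
        det_sets[model_id] = simulate_detector(
            dataset, prof, seed=int(rng.integers(2**31))
        )
    return det_sets, planted


# ---------------------------------------------------------------------------
# Train/validation/test split
# ---------------------------------------------------------------------------

def _partition_sizes(n: int, fractions: tuple[float, ...]) -> list[int]:
    sizes = [round(n * f) for f in fractions]
    # fix the largest partition so the sizes sum exactly to n
    sizes[int(np.argmax(sizes))] += n - sum(sizes)
    return sizes


def split(dataset: Dataset, spec: SplitSpec | None = None, seed: int = 0,
          groups: dict | None = None) -> tuple[Dataset, Dataset, Dataset]:
    """Partition images into train/validation/test datasets.

    Sizes are each fraction rounded to the nearest integer, with the
    largest partition adjusted so the total is exact (542 images at
    80/10/10 gives 434/54/54).  When ``groups`` maps image ids to a
    patient tag, all images of one patient land in the same partition
    (group-level greedy filling; sizes then become approximate).
    """
    spec = spec or SplitSpec()
    n = len(dataset.images)
    sizes = _partition_sizes(n, spec.fractions)
    rng = np.random.default_rng(seed)

    if groups is None:
        units = [[im.image_id] for im in dataset.images]
    else:
        by_group: dict = {}
        for im in dataset.images:
            by_group.setdefault(groups.get(im.image_id, im.image_id),
                                []).append(im.image_id)
        units = list(by_group.values())
    rng.shuffle(units)

    assigned: list[list] = [[], [], []]
    part = 0
    for unit in units:
        while part < 2 and len(assigned[part]) >= sizes[part]:
            part += 1
        assigned[part].extend(unit)

    out = []
    gt_by_img = dataset.gt_by_image()
    for ids in assigned:
        idset = set(ids)
        images = [im for im in dataset.images if im.image_id in idset]
        gts = [g for im in images for g in gt_by_img[im.image_id]]
        out.append(Dataset(images=images, ground_truth=gts,
                           categories=dict(dataset.categories)))
    return tuple(out)


def subset_detections(dets: DetectionSet, dataset: Dataset) -> DetectionSet:
    """Restrict a detection set to the images of one split."""
    keep = set(dataset.image_ids)
    return DetectionSet(
        model_id=dets.model_id,
        detections=[d for d in dets.detections if d.image_id in keep],
    )
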