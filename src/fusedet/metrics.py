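"""Detection evaluation: greedy IoU matching, AP50, AR and the LRP family.

Matching follows the standard protocol: within each image and category,
detections are visited in descending confidence and matched to the
still-unmatched ground-truth box of highest IoU, provided that IoU reaches
the threshold ``tau`` (default 0.5).  Unmatched detections are false
positives, unmatched ground truths false negatives; true negatives are
undefined for detection.

AP50 is the area under the precision-recall curve at tau = 0.5 (101-point
interpolation by default, exact all-point area optionally).  AR is the mean
recall over the IoU grid 0.50:0.05:0.95 with at most ``max_dets_per_image``
detections per image — the discrete form of twice the area under the
recall-IoU curve on [0.5, 1.0].

The LRP (localization recall precision) error at a score threshold s is

    LRP = [ sum_TP (1 - IoU_i)/(1 - tau) + N_FP + N_FN ] / (N_TP + N_FP + N_FN)

with components LRP_Loc (mean normalized localization error over TPs),
LRP_FP = 1 - precision and LRP_FN = 1 - recall.  oLRP is the minimum LRP
over all score thresholds and the LRP-optimal threshold is the argmin (ties
resolved toward the larger threshold, i.e. fewer detections kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes_io import Dataset, DetectionSet, denormalize_boxes
from .wbf import _iou

__all__ = [
    "MetricsConfig",
    "MatchResult",
    "EvalReport",
    "match",
    "precision_recall",
    "ap50",
    "ar",
    "lrp",
    "olrp",
    "evaluate",
    "normalize_dataset",
]

_DEFAULT_GRID = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class MetricsConfig:
    iou_tau: float = 0.5
    ar_iou_grid: tuple[float, ...] = _DEFAULT_GRID
    max_dets_per_image: int = 100
    ap_interpolation: str = "coco_101_point"  # or "all_point"

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_tau < 1.0:
            raise ValueError("iou_tau must be in (0, 1)")
        grid = tuple(self.ar_iou_grid)
        if list(grid) != sorted(grid) or not all(0.5 <= t < 1.0 for t in grid):
            raise ValueError("ar_iou_grid must be ascending within [0.5, 1.0)")
        if self.ap_interpolation not in ("coco_101_point", "all_point"):
            raise ValueError(
                f"unknown interpolation {self.ap_interpolation!r}"
            )


@dataclass(frozen=True)
class DetectionRecord:
    """Evaluation outcome of one detection."""

    score: float
    matched: bool
    iou: float  # IoU with the matched ground truth; 0.0 when unmatched
    category_id: int


@dataclass
class MatchResult:
    records: list[DetectionRecord]  # descending score, input-order ties
    n_tp: int
    n_fp: int
    n_fn: int
    n_gt: int
    n_gt_per_cat: dict[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class EvalReport:
    """AP50, AR, the oLRP decomposition and the LRP-optimal threshold."""

    ap50: float
    ar: float
    olrp: float
    olrp_loc: float
    olrp_fp: float
    olrp_fn: float
    lrp_opt_threshold: float

    def to_dict(self) -> dict[str, float]:
        return {
            "AP50": self.ap50,
            "AR": self.ar,
            "oLRP": self.olrp,
            "oLRP_Loc": self.olrp_loc,
            "oLRP_FP": self.olrp_fp,
            "oLRP_FN": self.olrp_fn,
            "LRP_opt_threshold": self.lrp_opt_threshold,
        }


# ---------------------------------------------------------------------------
# Flattening and greedy matching
# ---------------------------------------------------------------------------

def normalize_dataset(dataset: Dataset) -> Dataset:
    """Return a Dataset whose ground-truth boxes live on the unit square."""
    from dataclasses import replace

    from .boxes_io import Box

    sizes = dataset.sizes()
    gts = []
    for gt in dataset.ground_truth:
        if gt.box.normalized:
            gts.append(gt)
            continue
        w, h = sizes[gt.image_id]
        b = gt.box
        gts.append(
            replace(
                gt,
                box=Box(b.x_min / w, b.y_min / h, b.x_max / w, b.y_max / h,
                        normalized=True),
            )
        )
    return Dataset(images=list(dataset.images), ground_truth=gts,
                   categories=dict(dataset.categories))


def _coerce_units(dets: DetectionSet, dataset: Dataset) -> DetectionSet:
    """Bring detections to the ground truth's coordinate units."""
    gt_norm = bool(dataset.ground_truth) and dataset.ground_truth[0].box.normalized
    det_norm = bool(dets.detections) and dets.detections[0].box.normalized
    if det_norm and not gt_norm:
        return denormalize_boxes(dets, dataset)
    if gt_norm and not det_norm and dets.detections:
        from .boxes_io import normalize_boxes

        return normalize_boxes(dets, dataset)
    return dets


def _flat_dets(dets: DetectionSet, cap: int | None = None) -> dict:
    """(image, cat) -> list of (score, x0, y0, x1, y1, seq), input order."""
    if cap is not None:
        by_img: dict = {}
        for seq, d in enumerate(dets.detections):
            by_img.setdefault(d.image_id, []).append((seq, d))
        kept = []
        for img, rows in by_img.items():
            rows.sort(key=lambda r: (-r[1].score, r[0]))
            kept.extend(rows[:cap])
        kept.sort(key=lambda r: r[0])
        pairs = kept
    else:
        pairs = list(enumerate(dets.detections))
    flat: dict = {}
    for seq, d in pairs:
        b = d.box
        flat.setdefault((d.image_id, d.category_id), []).append(
            (d.score, b.x_min, b.y_min, b.x_max, b.y_max, seq)
        )
    return flat


def _flat_gts(dataset: Dataset) -> tuple[dict, dict[int, int]]:
    flat: dict = {}
    per_cat: dict[int, int] = {}
    for gt in dataset.ground_truth:
        b = gt.box
        flat.setdefault((gt.image_id, gt.category_id), []).append(
            (b.x_min, b.y_min, b.x_max, b.y_max)
        )
        per_cat[gt.category_id] = per_cat.get(gt.category_id, 0) + 1
    return flat, per_cat


def _greedy_records(det_flat: dict, gt_flat: dict, thr: float) -> list[tuple]:
    """Per-group greedy matching; returns (score, seq, cat, matched, iou)."""
    out = []
    for (img, cat), rows in det_flat.items():
        gts = gt_flat.get((img, cat), [])
        free = list(range(len(gts)))
        for score, x0, y0, x1, y1, seq in sorted(
            rows, key=lambda r: (-r[0], r[5])
        ):
            best_iou, best_pos = 0.0, -1
            for pos, j in enumerate(free):
                g = gts[j]
                v = _iou(x0, y0, x1, y1, g[0], g[1], g[2], g[3])
                if v > best_iou:
                    best_iou, best_pos = v, pos
            if best_pos >= 0 and best_iou >= thr:
                free.pop(best_pos)
                out.append((score, seq, cat, True, best_iou))
            else:
                out.append((score, seq, cat, False, 0.0))
    out.sort(key=lambda r: (-r[0], r[1]))
    return out


def match(dets: DetectionSet, dataset: Dataset, iou_thr: float = 0.5) -> MatchResult:
    """Greedy score-descending matching of detections to ground truth."""
    dets = _coerce_units(dets, dataset)
    gt_flat, per_cat = _flat_gts(dataset)
    raw = _greedy_records(_flat_dets(dets), gt_flat, iou_thr)
    records = [
        DetectionRecord(score=s, matched=m, iou=v, category_id=c)
        for s, _, c, m, v in raw
    ]
    n_tp = sum(1 for r in records if r.matched)
    n_gt = len(dataset.ground_truth)
    return MatchResult(
        records=records,
        n_tp=n_tp,
        n_fp=len(records) - n_tp,
        n_fn=n_gt - n_tp,
        n_gt=n_gt,
        n_gt_per_cat=per_cat,
    )


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); empty denominators count as perfect."""
    p = m.n_tp / (m.n_tp + m.n_fp) if (m.n_tp + m.n_fp) else 1.0
    r = m.n_tp / (m.n_tp + m.n_fn) if (m.n_tp + m.n_fn) else 1.0
    return p, r


# ---------------------------------------------------------------------------
# AP50
# ---------------------------------------------------------------------------

def _ap_from_flags(tp_flags: np.ndarray, n_gt: int, interpolation: str) -> float:
    if n_gt == 0:
        return 0.0
    if tp_flags.size == 0:
        return 0.0
    cum_tp = np.cumsum(tp_flags)
    cum_fp = np.cumsum(~tp_flags)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "coco_101_point":
        rec_thrs = np.linspace(0.0, 1.0, 101)
        idx = np.searchsorted(recall, rec_thrs, side="left")
        q = np.zeros(101)
        valid = idx < len(envelope)
        q[valid] = envelope[idx[valid]]
        return float(q.mean())
    # exact area under the staircase PR curve
    prev_r = 0.0
    area = 0.0
    for r, p in zip(recall, envelope):
        area += (r - prev_r) * p
        prev_r = r
    return float(area)


def ap50(dets: DetectionSet, dataset: Dataset,
         cfg: MetricsConfig | None = None) -> float:
    """Area under the precision-recall curve at the configured IoU tau."""
    cfg = cfg or MetricsConfig()
    dets = _coerce_units(dets, dataset)
    gt_flat, per_cat = _flat_gts(dataset)
    if not per_cat:
        return 0.0
    raw = _greedy_records(_flat_dets(dets), gt_flat, cfg.iou_tau)
    aps = []
    for cat, n_gt in sorted(per_cat.items()):
        flags = np.array([m for _, _, c, m, _ in raw if c == cat], dtype=bool)
        aps.append(_ap_from_flags(flags, n_gt, cfg.ap_interpolation))
    return float(np.mean(aps))


# ---------------------------------------------------------------------------
# AR
# ---------------------------------------------------------------------------

def ar(dets: DetectionSet, dataset: Dataset,
       cfg: MetricsConfig | None = None) -> float:
    """Mean recall over the IoU grid, capped at max_dets_per_image."""
    cfg = cfg or MetricsConfig()
    dets = _coerce_units(dets, dataset)
    gt_flat, per_cat = _flat_gts(dataset)
    if not per_cat:
        return 0.0
    det_flat = _flat_dets(dets, cap=cfg.max_dets_per_image)
    recalls = []
    for thr in cfg.ar_iou_grid:
        raw = _greedy_records(det_flat, gt_flat, thr)
        per_cat_recall = []
        for cat, n_gt in sorted(per_cat.items()):
            tp = sum(1 for _, _, c, m, _ in raw if c == cat and m)
            per_cat_recall.append(tp / n_gt)
        recalls.append(float(np.mean(per_cat_recall)))
    return float(np.mean(recalls))


# ---------------------------------------------------------------------------
# LRP family
# ---------------------------------------------------------------------------

def lrp(dets: DetectionSet, dataset: Dataset, score_thr: float,
        tau: float = 0.5) -> tuple[float, float, float, float]:
    """(LRP, LRP_Loc, LRP_FP, LRP_FN) at one confidence threshold."""
    if not 0.0 <= score_thr <= 1.0:
        raise ValueError("score_thr must be in [0, 1]")
    dets = _coerce_units(dets, dataset)
    kept = DetectionSet(
        model_id=dets.model_id,
        detections=[d for d in dets.detections if d.score >= score_thr],
    )
    gt_flat, _ = _flat_gts(dataset)
    raw = _greedy_records(_flat_dets(kept), gt_flat, tau)
    n_gt = len(dataset.ground_truth)
    loc_sum = sum((1.0 - v) / (1.0 - tau) for _, _, _, m, v in raw if m)
    n_tp = sum(1 for r in raw if r[3])
    n_fp = len(raw) - n_tp
    n_fn = n_gt - n_tp
    return _lrp_terms(loc_sum, n_tp, n_fp, n_fn)


def _lrp_terms(loc_sum: float, n_tp: int, n_fp: int,
               n_fn: int) -> tuple[float, float, float, float]:
    lrp_loc = loc_sum / n_tp if n_tp else 0.0
    lrp_fp = n_fp / (n_tp + n_fp) if (n_tp + n_fp) else 0.0
    lrp_fn = n_fn / (n_tp + n_fn) if (n_tp + n_fn) else 0.0
    z = n_tp + n_fp + n_fn
    total = (loc_sum + n_fp + n_fn) / z if z else 0.0
    return total, lrp_loc, lrp_fp, lrp_fn


def olrp(dets: DetectionSet, dataset: Dataset,
         tau: float = 0.5) -> tuple[float, float, float, float, float]:
    """(oLRP, oLRP_Loc, oLRP_FP, oLRP_FN, LRP-optimal threshold).

    The candidate thresholds are the distinct detection scores plus 0 and 1.
    Greedy matching restricted to scores >= t is a prefix of the full greedy
    run, so a single matching pass suffices; the sweep then accumulates
    TP/FP counts and localization error cumulatively.
    """
    dets = _coerce_units(dets, dataset)
    gt_flat, _ = _flat_gts(dataset)
    raw = _greedy_records(_flat_dets(dets), gt_flat, tau)
    n_gt = len(dataset.ground_truth)

    candidates = sorted({r[0] for r in raw} | {0.0, 1.0}, reverse=True)
    best = None
    i = 0
    cum_tp, cum_fp, cum_loc = 0, 0, 0.0
    for t in candidates:
        while i < len(raw) and raw[i][0] >= t:
            if raw[i][3]:
                cum_tp += 1
                cum_loc += (1.0 - raw[i][4]) / (1.0 - tau)
            else:
                cum_fp += 1
            i += 1
        terms = _lrp_terms(cum_loc, cum_tp, cum_fp, n_gt - cum_tp)
        if best is None or terms[0] < best[0][0]:
            best = (terms, t)
    total, loc, fpv, fnv = best[0]
    return total, loc, fpv, fnv, best[1]


def evaluate(dets: DetectionSet, dataset: Dataset,
             cfg: MetricsConfig | None = None) -> EvalReport:
    """Full report: AP50, AR and the oLRP decomposition."""
    cfg = cfg or MetricsConfig()
    o, o_loc, o_fp, o_fn, thr = olrp(dets, dataset, cfg.iou_tau)
    return EvalReport(
        ap50=ap50(dets, dataset, cfg),
        ar=ar(dets, dataset, cfg),
        olrp=o,
        olrp_loc=o_loc,
        olrp_fp=o_fp,
        olrp_fn=o_fn,
        lrp_opt_threshold=thr,
    )
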