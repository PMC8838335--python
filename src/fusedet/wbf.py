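"""Weighted boxes fusion (WBF).

Boxes proposed by several weighted detectors are clustered by overlap, and
each cluster is replaced by a single box whose coordinates are the
confidence-weighted mean of its members and whose confidence reflects both
the members' scores and how many models supported the cluster.

Update rules, per image and category:

1. drop boxes whose raw score is below ``skip_box_thr``;
2. give each surviving box an effective score ``s * w_m * N / W`` where
   ``w_m`` is its model's weight, ``N`` the number of models and ``W`` the
   weight sum (i.e. weights are normalized to mean 1, which makes the output
   invariant to rescaling all weights by a constant);
3. visit boxes in descending effective score (ties broken by model index,
   then original detection order); a box joins the first existing cluster
   whose *current fused box* has IoU strictly greater than ``iou_thr``,
   otherwise it opens a new cluster; the fused box is recomputed after every
   insertion;
4. a cluster's fused coordinates are the effective-score-weighted mean of
   its members; its fused score is the mean of member effective scores;
5. the fused score is rescaled by ``min(T, N) / N`` (default mode) with
   ``T`` the member count, then clipped to 1;
6. fused boxes of an image are sorted by score descending and truncated to
   ``limit_boxes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxes_io import (
    Box,
    Dataset,
    Detection,
    DetectionSet,
    ValidationError,
    denormalize_boxes,
    normalize_boxes,
)

try:  # optional JIT acceleration of the clustering inner loop
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is optional
    _njit = None

__all__ = ["FusionParams", "FusedCluster", "iou", "fuse", "fuse_brute_force"]


@dataclass(frozen=True)
class FusionParams:
    """Fusion knobs; the defaults are the recommended operating point
    (skip-box threshold 0.3, IoU threshold 0.5, box limit 6000)."""

    iou_thr: float = 0.5
    skip_box_thr: float = 0.3
    limit_boxes: int = 6000
    conf_rescale_mode: str = "min_T_N_over_N"  # or "T_over_N", "none"

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_thr <= 1.0:
            raise ValueError("iou_thr must be in (0, 1]")
        if not 0.0 <= self.skip_box_thr < 1.0:
            raise ValueError("skip_box_thr must be in [0, 1)")
        if self.limit_boxes < 1:
            raise ValueError("limit_boxes must be positive")
        if self.conf_rescale_mode not in ("min_T_N_over_N", "T_over_N", "none"):
            raise ValueError(f"unknown rescale mode {self.conf_rescale_mode!r}")


@dataclass
class FusedCluster:
    """One cluster of mutually overlapping member detections."""

    members: list[Detection]
    effective_scores: list[float]
    fused_box: Box
    fused_score: float

    @property
    def T(self) -> int:
        return len(self.members)


def iou(a: Box, b: Box) -> float:
    """Intersection area over union area of two boxes; 0 when disjoint."""
    if a.normalized != b.normalized:
        raise ValidationError("cannot compute IoU across normalization states")
    return _iou(a.x_min, a.y_min, a.x_max, a.y_max,
                b.x_min, b.y_min, b.x_max, b.y_max)


def _iou(ax0: float, ay0: float, ax1: float, ay1: float,
         bx0: float, by0: float, bx1: float, by1: float) -> float:
    ix0, iy0 = max(ax0, bx0), max(ay0, by0)
    ix1, iy1 = min(ax1, bx1), min(ay1, by1)
    if ix1 <= ix0 or iy1 <= iy0:
        return 0.0
    inter = (ix1 - ix0) * (iy1 - iy0)
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def _validate(det_sets: list[DetectionSet], weights) -> list[float]:
    if not det_sets:
        raise ValidationError("fuse requires at least one DetectionSet")
    if len(weights) != len(det_sets):
        raise ValidationError(
            f"{len(weights)} weights for {len(det_sets)} detection sets"
        )
    for w in weights:
        if int(w) != w or w < 1:
            raise ValidationError(f"weights must be integers >= 1, got {w!r}")
    n = len(det_sets)
    wsum = float(sum(weights))
    return [w * n / wsum for w in weights]


def _rescale_factor(mode: str, t: int, n: int) -> float:
    if mode == "min_T_N_over_N":
        return min(t, n) / n
    if mode == "T_over_N":
        return t / n
    return 1.0


# One prefiltered, normalized box ready for clustering:
# (eff_score, x0, y0, x1, y1, model_index, original_index, Detection)
_Entry = tuple


def _prefilter(det_sets: list[DetectionSet], w_norm: list[float],
               skip_thr: float) -> dict:
    """Group surviving boxes by (image_id, category_id)."""
    grouped: dict = {}
    for m_idx, ds in enumerate(det_sets):
        for o_idx, d in enumerate(ds.detections):
            if d.score < skip_thr:
                continue
            b = d.box
            grouped.setdefault((d.image_id, d.category_id), []).append(
                (d.score * w_norm[m_idx], b.x_min, b.y_min, b.x_max, b.y_max,
                 m_idx, o_idx, d)
            )
    return grouped


class _Cluster:
    """Running effective-score-weighted sums; insertion order preserved."""

    __slots__ = ("entries", "sw", "sx0", "sy0", "sx1", "sy1",
                 "fx0", "fy0", "fx1", "fy1")

    def __init__(self, e: _Entry) -> None:
        self.entries = [e]
        self.sw = e[0]
        self.sx0 = e[0] * e[1]
        self.sy0 = e[0] * e[2]
        self.sx1 = e[0] * e[3]
        self.sy1 = e[0] * e[4]
        self._refresh()

    def add(self, e: _Entry) -> None:
        self.entries.append(e)
        self.sw += e[0]
        self.sx0 += e[0] * e[1]
        self.sy0 += e[0] * e[2]
        self.sx1 += e[0] * e[3]
        self.sy1 += e[0] * e[4]
        self._refresh()

    def _refresh(self) -> None:
        if len(self.entries) == 1:
            # a singleton cluster is exactly its member (no rounding)
            e = self.entries[0]
            self.fx0, self.fy0, self.fx1, self.fy1 = e[1], e[2], e[3], e[4]
            return
        self.fx0 = self.sx0 / self.sw
        self.fy0 = self.sy0 / self.sw
        self.fx1 = self.sx1 / self.sw
        self.fy1 = self.sy1 / self.sw


def _assign_python(order: list[_Entry], iou_thr: float) -> list[_Cluster]:
    clusters: list[_Cluster] = []
    for e in order:
        for c in clusters:
            if _iou(e[1], e[2], e[3], e[4], c.fx0, c.fy0, c.fx1, c.fy1) > iou_thr:
                c.add(e)
                break
        else:
            clusters.append(_Cluster(e))
    return clusters


if _njit is not None:

    @_njit(cache=True, nogil=True)
    def _assign_kernel(be, iou_thr, out):  # pragma: no cover - jitted
        # be[i] = (eff, x0, y0, x1, y1) in visiting order; arithmetic mirrors
        # _Cluster/_iou operation-for-operation so assignments are identical
        n = be.shape[0]
        sw = np.empty(n)
        sx0 = np.empty(n)
        sy0 = np.empty(n)
        sx1 = np.empty(n)
        sy1 = np.empty(n)
        cnt = np.empty(n, np.int64)
        fx0 = np.empty(n)
        fy0 = np.empty(n)
        fx1 = np.empty(n)
        fy1 = np.empty(n)
        ncl = 0
        for i in range(n):
            e0, ax0, ay0, ax1, ay1 = be[i, 0], be[i, 1], be[i, 2], be[i, 3], be[i, 4]
            placed = -1
            for c in range(ncl):
                ix0 = max(ax0, fx0[c])
                iy0 = max(ay0, fy0[c])
                ix1 = min(ax1, fx1[c])
                iy1 = min(ay1, fy1[c])
                if ix1 <= ix0 or iy1 <= iy0:
                    continue
                inter = (ix1 - ix0) * (iy1 - iy0)
                union = (ax1 - ax0) * (ay1 - ay0) + \
                    (fx1[c] - fx0[c]) * (fy1[c] - fy0[c]) - inter
                if inter / union > iou_thr:
                    placed = c
                    break
            if placed >= 0:
                sw[placed] += e0
                sx0[placed] += e0 * ax0
                sy0[placed] += e0 * ay0
                sx1[placed] += e0 * ax1
                sy1[placed] += e0 * ay1
                cnt[placed] += 1
                fx0[placed] = sx0[placed] / sw[placed]
                fy0[placed] = sy0[placed] / sw[placed]
                fx1[placed] = sx1[placed] / sw[placed]
                fy1[placed] = sy1[placed] / sw[placed]
                out[i] = placed
            else:
                sw[ncl] = e0
                sx0[ncl] = e0 * ax0
                sy0[ncl] = e0 * ay0
                sx1[ncl] = e0 * ax1
                sy1[ncl] = e0 * ay1
                cnt[ncl] = 1
                fx0[ncl] = ax0
                fy0[ncl] = ay0
                fx1[ncl] = ax1
                fy1[ncl] = ay1
                out[i] = ncl
                ncl += 1
        return out, sw, sx0, sy0, sx1, sy1, fx0, fy0, fx1, fy1, ncl

else:  # pragma: no cover - numba is optional
    _assign_kernel = None


def _cluster_group(entries: list[_Entry], iou_thr: float) -> list[_Cluster]:
    order = sorted(entries, key=lambda e: (-e[0], e[5], e[6]))
    if _assign_kernel is not None and len(order) > 1:
        be = np.array([e[:5] for e in order], dtype=np.float64)
        (assign, sw, sx0, sy0, sx1, sy1,
         fx0, fy0, fx1, fy1, ncl) = _assign_kernel(
            be, iou_thr, np.empty(len(order), np.int64)
        )
        # adopt the kernel's running sums (same accumulation order as the
        # pure-python path, hence identical values) instead of replaying
        clusters: list[_Cluster] = []
        for c in range(ncl):
            cl = _Cluster.__new__(_Cluster)
            cl.entries = []
            cl.sw = float(sw[c])
            cl.sx0 = float(sx0[c])
            cl.sy0 = float(sy0[c])
            cl.sx1 = float(sx1[c])
            cl.sy1 = float(sy1[c])
            cl.fx0 = float(fx0[c])
            cl.fy0 = float(fy0[c])
            cl.fx1 = float(fx1[c])
            cl.fy1 = float(fy1[c])
            clusters.append(cl)
        for e, c in zip(order, assign):
            clusters[c].entries.append(e)
        return clusters
    return _assign_python(order, iou_thr)


def _finalize_image(per_cat: list[tuple[int, list[_Cluster]]], n_models: int,
                    params: FusionParams) -> list[tuple[float, float, float,
                                                        float, float, int,
                                                        _Cluster]]:
    """Score each cluster, sort the image's boxes, apply the box limit."""
    fused = []
    for order_key, (cat, clusters) in enumerate(per_cat):
        for c_idx, c in enumerate(clusters):
            t = len(c.entries)
            score = (c.sw / t) * _rescale_factor(params.conf_rescale_mode,
                                                 t, n_models)
            if score > 1.0:
                score = 1.0
            fused.append((score, c.fx0, c.fy0, c.fx1, c.fy1, cat,
                          order_key, c_idx, c))
    fused.sort(key=lambda f: (-f[0], f[6], f[7]))
    return [(f[0], f[1], f[2], f[3], f[4], f[5], f[8])
            for f in fused[: params.limit_boxes]]


def fuse(
    det_sets: list[DetectionSet],
    weights,
    params: FusionParams | None = None,
    dataset: Dataset | None = None,
    ensemble_id: str | None = None,
    return_clusters: bool = False,
):
    """Fuse the outputs of several detectors into one DetectionSet.

    Boxes are normalized per image before clustering when ``dataset`` is
    given and the inputs are in pixel units; the fused output is returned in
    the units of the input.  ``weights`` is one positive integer per model.
    """
    params = params or FusionParams()
    w_norm = _validate(det_sets, weights)
    n_models = len(det_sets)

    was_pixel = any(
        not d.box.normalized for ds in det_sets for d in ds.detections
    )
    if was_pixel:
        if dataset is None:
            raise ValidationError(
                "pixel-unit boxes require a dataset for normalization"
            )
        det_sets = [normalize_boxes(ds, dataset) for ds in det_sets]

    grouped = _prefilter(det_sets, w_norm, params.skip_box_thr)
    by_image: dict = {}
    for (img, cat), entries in grouped.items():
        by_image.setdefault(img, []).append((cat, entries))

    if ensemble_id is None:
        ensemble_id = "wbf(" + "+".join(ds.model_id for ds in det_sets) + ")"

    image_order = sorted(by_image.keys(), key=_image_sort_key)
    out: list[Detection] = []
    clusters_out: list[FusedCluster] = []
    for img in image_order:
        per_cat = sorted(by_image[img], key=lambda ce: ce[0])
        clustered = [(cat, _cluster_group(entries, params.iou_thr))
                     for cat, entries in per_cat]
        for score, x0, y0, x1, y1, cat, cl in _finalize_image(
            clustered, n_models, params
        ):
            det = Detection(
                image_id=img,
                box=Box(x0, y0, x1, y1, normalized=True),
                score=score,
                category_id=cat,
                model_id=ensemble_id,
            )
            out.append(det)
            if return_clusters:
                clusters_out.append(
                    FusedCluster(
                        members=[e[7] for e in cl.entries],
                        effective_scores=[e[0] for e in cl.entries],
                        fused_box=det.box,
                        fused_score=score,
                    )
                )

    fused_set = DetectionSet(model_id=ensemble_id, detections=out)
    if was_pixel:
        fused_set = denormalize_boxes(fused_set, dataset)
        if return_clusters:
            for cluster, det in zip(clusters_out, fused_set.detections):
                cluster.fused_box = det.box
    if return_clusters:
        return fused_set, clusters_out
    return fused_set


def _image_sort_key(img) -> tuple:
    # numeric ids sort numerically, everything else lexicographically
    if isinstance(img, (int, float)) and not isinstance(img, bool):
        return (0, float(img), "")
    return (1, 0.0, str(img))


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def fuse_brute_force(
    det_sets: list[DetectionSet],
    weights,
    params: FusionParams | None = None,
    dataset: Dataset | None = None,
    ensemble_id: str | None = None,
) -> DetectionSet:
    """Naive O(n^2) re-implementation of :func:`fuse` for use as an oracle.

    Same contract and byte-identical output; no sorting of candidates (the
    next box is found by repeated full scans) and cluster statistics are
    recomputed from scratch after every insertion.  Limited to 200 boxes.
    """
    params = params or FusionParams()
    w_norm = _validate(det_sets, weights)
    n_models = len(det_sets)
    total = sum(len(ds.detections) for ds in det_sets)
    if total > 200:
        raise ValidationError(
            f"brute-force oracle limited to 200 boxes, got {total}"
        )

    was_pixel = any(
        not d.box.normalized for ds in det_sets for d in ds.detections
    )
    if was_pixel:
        if dataset is None:
            raise ValidationError(
                "pixel-unit boxes require a dataset for normalization"
            )
        det_sets = [normalize_boxes(ds, dataset) for ds in det_sets]

    if ensemble_id is None:
        ensemble_id = "wbf(" + "+".join(ds.model_id for ds in det_sets) + ")"

    grouped = _prefilter(det_sets, w_norm, params.skip_box_thr)
    by_image: dict = {}
    for (img, cat), entries in grouped.items():
        by_image.setdefault(img, []).append((cat, entries))

    out: list[Detection] = []
    for img in sorted(by_image.keys(), key=_image_sort_key):
        fused_rows = []
        for order_key, (cat, entries) in enumerate(
            sorted(by_image[img], key=lambda ce: ce[0])
        ):
            clusters: list[list[_Entry]] = []
            remaining = list(entries)
            while remaining:
                # repeated full scan for the next-highest effective score
                best = remaining[0]
                for e in remaining[1:]:
                    if (-e[0], e[5], e[6]) < (-best[0], best[5], best[6]):
                        best = e
                remaining.remove(best)
                placed = False
                for members in clusters:
                    fx0, fy0, fx1, fy1, _ = _mean_box(members)
                    if _iou(best[1], best[2], best[3], best[4],
                            fx0, fy0, fx1, fy1) > params.iou_thr:
                        members.append(best)
                        placed = True
                        break
                if not placed:
                    clusters.append([best])
            for c_idx, members in enumerate(clusters):
                fx0, fy0, fx1, fy1, sw = _mean_box(members)
                t = len(members)
                score = (sw / t) * _rescale_factor(
                    params.conf_rescale_mode, t, n_models
                )
                if score > 1.0:
                    score = 1.0
                fused_rows.append((score, fx0, fy0, fx1, fy1, cat,
                                   order_key, c_idx))
        fused_rows.sort(key=lambda f: (-f[0], f[6], f[7]))
        for score, x0, y0, x1, y1, cat, _, _ in fused_rows[: params.limit_boxes]:
            out.append(
                Detection(
                    image_id=img,
                    box=Box(x0, y0, x1, y1, normalized=True),
                    score=score,
                    category_id=cat,
                    model_id=ensemble_id,
                )
            )

    fused_set = DetectionSet(model_id=ensemble_id, detections=out)
    if was_pixel:
        fused_set = denormalize_boxes(fused_set, dataset)
    return fused_set


def _mean_box(members: list[_Entry]) -> tuple[float, float, float, float, float]:
    """Effective-score-weighted mean, accumulated in insertion order."""
    sw = 0.0
    sx0 = sy0 = sx1 = sy1 = 0.0
    for e in members:
        sw += e[0]
        sx0 += e[0] * e[1]
        sy0 += e[0] * e[2]
        sx1 += e[0] * e[3]
        sy1 += e[0] * e[4]
    if len(members) == 1:
        e = members[0]
        return e[1], e[2], e[3], e[4], sw
    return sx0 / sw, sy0 / sw, sx1 / sw, sy1 / sw, sw
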