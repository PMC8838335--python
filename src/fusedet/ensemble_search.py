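"""Exhaustive ensemble construction over detector subsets and integer weights.

The search space for a pool of m detectors is every subset of size
k = k_min..m combined with every integer weight vector in {1..k}^k, i.e.

    n_configs(m) = sum_{k=k_min}^{m} C(m, k) * k^k

which gives 388 configurations for m = 4 and 4715 for m = 5.  Subsets are
enumerated in lexicographic order of member indices and weight vectors
odometer-style (last entry fastest), so the search and its tie-breaking
(first best configuration in enumeration order wins) are deterministic.

Five first-level ensembles are built from criterion-defined pools:
two architecture pools (all single-stage models; all two-stage models) and
three performance pools (top-k by AP50, top-k by AR, top-k by lowest
LRP-optimal threshold), searched with criteria max-AP50, max-AP50,
max-AP50, max-AR and min-oLRP respectively.  A second-level "combo"
ensemble then treats the five fused outputs as a new pool and searches it
with the max-AP50 criterion.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .boxes_io import Dataset, DetectionSet, ValidationError, normalize_boxes
from .metrics import EvalReport, MetricsConfig, ap50, ar, evaluate, normalize_dataset, olrp
from .wbf import FusionParams, fuse

logger = logging.getLogger("fusedet")

__all__ = [
    "EnsembleConfig",
    "Criterion",
    "SearchResult",
    "SuiteEntry",
    "PUBLISHED_WFD_CONFIGS",
    "n_configs",
    "enumerate_configs",
    "score_config",
    "search",
    "build_wfd_suite",
    "build_combo",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """An ordered member subset with its integer weight vector."""

    member_ids: tuple[str, ...]
    weights: tuple[int, ...]
    fusion: FusionParams = field(default_factory=FusionParams)

    def __post_init__(self) -> None:
        k = len(self.member_ids)
        if k < 2:
            raise ValidationError("an ensemble needs at least two members")
        if len(self.weights) != k:
            raise ValidationError("one weight per member required")
        for w in self.weights:
            if not 1 <= w <= k:
                raise ValidationError(
                    f"weight {w} outside 1..{k} for a {k}-member ensemble"
                )


@dataclass(frozen=True)
class Criterion:
    """Selection objective; larger is better after sign normalization."""

    kind: str  # max_AP50 | max_AR | min_oLRP

    def __post_init__(self) -> None:
        if self.kind not in ("max_AP50", "max_AR", "min_oLRP"):
            raise ValidationError(f"unknown criterion {self.kind!r}")


MAX_AP50 = Criterion("max_AP50")
MAX_AR = Criterion("max_AR")
MIN_OLRP = Criterion("min_oLRP")


@dataclass
class SearchResult:
    best: EnsembleConfig
    best_score: float
    n_evaluated: int
    criterion: Criterion
    ranking: list[tuple[EnsembleConfig, float]] = field(default_factory=list)


@dataclass
class SuiteEntry:
    """One first-level ensemble: its pool, criterion, winner and output."""

    name: str
    pool: list[str]
    criterion: Criterion
    result: SearchResult
    fused: DetectionSet


#: Submodels and weight coefficients of the published wrist-fracture
#: ensembles, kept as a reference fixture (the clinical detections needed to
#: recompute them are not public).
PUBLISHED_WFD_CONFIGS: dict[str, tuple[tuple[str, ...], tuple[int, ...]]] = {
    "WFD-1": (("RegNet", "FSAF", "RetinaNet", "SABL RetinaNet", "PAA"),
              (1, 5, 5, 5, 5)),
    "WFD-2": (("DCN", "SABL Faster R-CNN"), (2, 2)),
    "WFD-3": (("RegNet", "PAA", "FSAF", "Libra RetinaNet"), (3, 3, 3, 4)),
    "WFD-4": (("RegNet", "PAA", "FSAF", "SABL RetinaNet"), (1, 3, 3, 1)),
    "WFD-5": (("FSAF", "Faster R-CNN", "DCN", "Libra RetinaNet", "RetinaNet"),
              (2, 1, 4, 2, 3)),
    "WFD-C": (("WFD-1", "WFD-3", "WFD-4", "WFD-5", "WFD-2"), (4, 4, 3, 5, 5)),
}


def n_configs(m: int, k_min: int = 2) -> int:
    """Closed-form size of the search space for an m-model pool."""
    return sum(math.comb(m, k) * k**k for k in range(k_min, m + 1))


def enumerate_configs(pool, k_min: int = 2,
                      fusion: FusionParams | None = None):
    """Yield every (subset, weight vector) configuration deterministically."""
    pool = list(pool)
    if len(pool) < 2:
        raise ValidationError("pool must contain at least two models")
    fusion = fusion or FusionParams()
    for k in range(k_min, len(pool) + 1):
        for subset in itertools.combinations(pool, k):
            for weights in itertools.product(range(1, k + 1), repeat=k):
                yield EnsembleConfig(member_ids=subset, weights=weights,
                                     fusion=fusion)


def score_config(cfg: EnsembleConfig, det_sets: dict[str, DetectionSet],
                 dataset: Dataset, criterion: Criterion,
                 metrics_cfg: MetricsConfig | None = None) -> float:
    """Fuse the config's members and return the criterion scalar
    (oLRP is negated so that larger is always better)."""
    metrics_cfg = metrics_cfg or MetricsConfig()
    try:
        members = [det_sets[m] for m in cfg.member_ids]
    except KeyError as exc:
        raise ValidationError(f"member {exc.args[0]!r} missing from det_sets")
    fused = fuse(members, list(cfg.weights), cfg.fusion, dataset)
    if criterion.kind == "max_AP50":
        return ap50(fused, dataset, metrics_cfg)
    if criterion.kind == "max_AR":
        return ar(fused, dataset, metrics_cfg)
    return -olrp(fused, dataset, metrics_cfg.iou_tau)[0]


def search(pool, det_sets: dict[str, DetectionSet], dataset: Dataset,
           criterion: Criterion, k_min: int = 2,
           fusion: FusionParams | None = None,
           metrics_cfg: MetricsConfig | None = None,
           max_configs: int | None = None, seed: int | None = None,
           keep_ranking: int = 0,
           progress_every: int | None = None) -> SearchResult:
    """Exhaustively score every configuration and return the argmax.

    Ties go to the first configuration in enumeration order.  When
    ``max_configs`` is smaller than the full space, a seeded random
    subsample of configurations (in enumeration order) is scored instead.
    """
    pool = list(pool)
    fusion = fusion or FusionParams()
    metrics_cfg = metrics_cfg or MetricsConfig()

    # normalize once; fuse() and the metrics then skip per-call rescaling
    norm_sets = {m: normalize_boxes(det_sets[m], dataset) for m in pool}
    norm_data = normalize_dataset(dataset)

    total = n_configs(len(pool), k_min)
    selected = None
    if max_configs is not None and max_configs < total:
        rng = np.random.default_rng(seed)
        selected = set(
            rng.choice(total, size=max_configs, replace=False).tolist()
        )

    best_cfg, best_score = None, -math.inf
    ranking: list[tuple[EnsembleConfig, float]] = []
    n_eval = 0
    for idx, cfg in enumerate(enumerate_configs(pool, k_min, fusion)):
        if selected is not None and idx not in selected:
            continue
        s = score_config(cfg, norm_sets, norm_data, criterion, metrics_cfg)
        n_eval += 1
        if s > best_score:
            best_cfg, best_score = cfg, s
        if keep_ranking:
            ranking.append((cfg, s))
        if progress_every and n_eval % progress_every == 0:
            logger.info("search: %d/%d configs evaluated, best %s = %.4f",
                        n_eval, total, criterion.kind, best_score)
    if keep_ranking:
        ranking.sort(key=lambda cs: -cs[1])
        ranking = ranking[:keep_ranking]
    return SearchResult(best=best_cfg, best_score=best_score,
                        n_evaluated=n_eval, criterion=criterion,
                        ranking=ranking)


# ---------------------------------------------------------------------------
# The five first-level ensembles and the combo
# ---------------------------------------------------------------------------

def _top_k(reports: dict[str, EvalReport], order, key, k: int,
           reverse: bool) -> list[str]:
    ranked = sorted(
        order, key=lambda m: (-key(reports[m]) if reverse else key(reports[m]))
    )
    return ranked[:k]


def build_wfd_suite(stage_map: dict[str, str],
                    det_sets: dict[str, DetectionSet],
                    val_dataset: Dataset, top_k: int = 5,
                    fusion: FusionParams | None = None,
                    metrics_cfg: MetricsConfig | None = None,
                    k_min: int = 2) -> dict[str, SuiteEntry]:
    """Build the five first-level ensembles on a validation split.

    Pools: all single-stage models; all two-stage models; top-k by AP50;
    top-k by AR; top-k by lowest LRP-optimal threshold.  The two
    architecture pools and the AP50 pool are searched for maximum AP50, the
    AR pool for maximum AR and the LRP pool for minimum oLRP.  Pools with
    fewer than two members are skipped with a warning.
    """
    fusion = fusion or FusionParams()
    metrics_cfg = metrics_cfg or MetricsConfig()
    order = list(det_sets.keys())
    for m in order:
        if stage_map.get(m) not in ("single", "two"):
            raise ValidationError(
                f"model {m!r} has no single/two stage label"
            )
    reports = {m: evaluate(det_sets[m], val_dataset, metrics_cfg)
               for m in order}
    for m in order:
        r = reports[m]
        logger.info("model %s: AP50=%.4f AR=%.4f oLRP=%.4f LRP_t=%.3f",
                    m, r.ap50, r.ar, r.olrp, r.lrp_opt_threshold)

    pools = {
        "WFD-1": ([m for m in order if stage_map[m] == "single"], MAX_AP50),
        "WFD-2": ([m for m in order if stage_map[m] == "two"], MAX_AP50),
        "WFD-3": (_top_k(reports, order, lambda r: r.ap50, top_k, True),
                  MAX_AP50),
        "WFD-4": (_top_k(reports, order, lambda r: r.ar, top_k, True),
                  MAX_AR),
        "WFD-5": (_top_k(reports, order, lambda r: r.lrp_opt_threshold,
                         top_k, False), MIN_OLRP),
    }

    suite: dict[str, SuiteEntry] = {}
    for name, (pool, criterion) in pools.items():
        if len(pool) < 2:
            logger.warning("%s pool has %d member(s); skipped", name, len(pool))
            continue
        result = search(pool, det_sets, val_dataset, criterion,
                        k_min=k_min, fusion=fusion, metrics_cfg=metrics_cfg)
        fused = fuse([det_sets[m] for m in result.best.member_ids],
                     list(result.best.weights), fusion, val_dataset,
                     ensemble_id=name)
        logger.info("%s: members=%s weights=%s %s=%.4f (%d configs)",
                    name, result.best.member_ids, result.best.weights,
                    criterion.kind, result.best_score, result.n_evaluated)
        suite[name] = SuiteEntry(name=name, pool=pool, criterion=criterion,
                                 result=result, fused=fused)
    return suite


def build_combo(first_level: dict[str, DetectionSet],
                val_dataset: Dataset,
                params: FusionParams | None = None,
                metrics_cfg: MetricsConfig | None = None,
                ensemble_id: str = "WFD-C",
                max_configs: int | None = None,
                seed: int | None = None) -> tuple[SearchResult, DetectionSet]:
    """Second-level fusion: search over the first-level outputs (max AP50).

    The default second-level fusion uses a skip-box threshold of 0: the
    0.3 threshold has already been applied to raw detector confidences at
    the first level, and first-level fused confidences live on a
    compressed scale (the min(T, N)/N support rescale), so re-applying a
    raw-score threshold would silently discard the recall tail the
    first-level ensembles deliberately keep.  With skip 0, near-degenerate
    configurations dominated by the best member keep that member's full
    recall (and whenever two first-level outputs coincide, fusing the pair
    reproduces them exactly), so the searched combo tracks the best first
    level from above instead of losing its tail.  Pass ``params`` to
    override.
    """
    params = params or FusionParams(skip_box_thr=0.0)
    result = search(list(first_level.keys()), first_level, val_dataset,
                    MAX_AP50, fusion=params, metrics_cfg=metrics_cfg,
                    max_configs=max_configs, seed=seed)
    fused = fuse([first_level[m] for m in result.best.member_ids],
                 list(result.best.weights), params, val_dataset,
                 ensemble_id=ensemble_id)
    return result, fused
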