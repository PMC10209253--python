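"""Statistical validation of auto-segmented lesions against reference contours.

Covers one-to-one lesion matching, voxel-wise confusion counts,
Dice similarity, Pearson concordance, a threshold sweep with ROC points,
optimum-threshold selection and the per-patient report, plus the audit of
lesions present on only one side (auto-only / reference-only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bone_mask import apply_bone_mask
from .core import (BinaryMask, GeometryError, LesionStats, ParameterError,
                   UndefinedResultError, VolumeImage)
from .lesion import quantify_lesions, segment_lesions

DEFAULT_THRESHOLDS = (2.0, 2.5, 3.0, 3.5, 4.0, 6.0)


@dataclass(frozen=True)
class MatchedPair:
    auto_label: int
    ref_label: int
    suvmax_diff: float
    centre_distance_mm: float
    cost: float


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    domain: str = "bone"

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else 1.0

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else 1.0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn,
                               self.domain)


@dataclass
class SweepResult:
    """Pooled validation metrics per SUV threshold."""

    thresholds: list[float]
    sensitivity: list[float]
    specificity: list[float]
    dsc: list[list[float]]          # per matched pair, per threshold
    volume_r: list[float]           # nan where undefined
    suvmean_r: list[float]

    def median_dsc(self, i: int) -> float:
        return float(np.median(self.dsc[i])) if self.dsc[i] else 0.0

    def roc_points(self) -> list[tuple[float, float]]:
        """(1 - specificity, sensitivity) per threshold."""
        return [(1.0 - sp, se)
                for sp, se in zip(self.specificity, self.sensitivity)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "suv_threshold": self.thresholds,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "median_dsc": [self.median_dsc(i)
                           for i in range(len(self.thresholds))],
            "dsc_iqr": [float(np.subtract(*np.percentile(d, [75, 25])))
                        if d else 0.0 for d in self.dsc],
            "n_matched": [len(d) for d in self.dsc],
            "volume_r": self.volume_r,
            "suvmean_r": self.suvmean_r,
        })


def match_lesions(auto: list[LesionStats], ref: list[LesionStats],
                  d_scale: float = 10.0, s_scale: float = 1.0,
                  max_distance_mm: float = 20.0,
                  ) -> tuple[list[MatchedPair], list[LesionStats],
                             list[LesionStats]]:
    """Greedy one-to-one matching of auto lesions to reference lesions.

    Candidate pairs are ranked by ``cost = distance_mm/d_scale +
    |dSUVmax|/s_scale`` (distance between SUVmax locations, in physical mm)
    and accepted in ascending cost while both sides are unused; pairs
    farther apart than ``max_distance_mm`` are never accepted. Cost ties
    break towards the lower reference label, then the lower auto label, so
    the result is independent of input list order.

    Returns (pairs, unmatched_auto, unmatched_ref); the unmatched lists
    feed the missed-lesion audit.
    """
    candidates = []
    for a in auto:
        for r in ref:
            d = math.dist(a.max_coord_mm, r.max_coord_mm)
            if d > max_distance_mm:
                continue
            ds = abs(a.suv_max - r.suv_max)
            cost = d / d_scale + ds / s_scale
            candidates.append((cost, r.label, a.label, a, r, ds, d))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    pairs: list[MatchedPair] = []
    used_auto: set[int] = set()
    used_ref: set[int] = set()
    for cost, _rl, _al, a, r, ds, d in candidates:
        if a.label in used_auto or r.label in used_ref:
            continue
        used_auto.add(a.label)
        used_ref.add(r.label)
        pairs.append(MatchedPair(a.label, r.label, ds, d, cost))
    unmatched_auto = [a for a in auto if a.label not in used_auto]
    unmatched_ref = [r for r in ref if r.label not in used_ref]
    return pairs, unmatched_auto, unmatched_ref


def voxel_confusion(auto_mask: BinaryMask, ref_mask: BinaryMask,
                    domain: BinaryMask,
                    domain_name: str = "bone") -> ConfusionCounts:
    """Voxel-by-voxel TP/TN/FP/FN over an evaluation domain.

    Both masks are intersected with the domain first, so
    tp+tn+fp+fn equals the domain's voxel count.
    """
    if not (auto_mask.same_grid(ref_mask) and auto_mask.same_grid(domain)):
        raise GeometryError("confusion masks are on different grids")
    a = auto_mask.data & domain.data
    r = ref_mask.data & domain.data
    tp = int(np.count_nonzero(a & r))
    fp = int(np.count_nonzero(a & ~r))
    fn = int(np.count_nonzero(~a & r))
    tn = int(domain.voxel_count) - tp - fp - fn
    return ConfusionCounts(tp, tn, fp, fn, domain_name)


def dice(auto_mask: BinaryMask, ref_mask: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); two empty masks → 1.0."""
    if not auto_mask.same_grid(ref_mask):
        raise GeometryError("dice masks are on different grids")
    a, b = auto_mask.data, ref_mask.data
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / denom


def concordance_r(x, y) -> float:
    """Pearson correlation coefficient; degenerate input raises."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    if len(x) < 2:
        raise UndefinedResultError("correlation needs at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResultError("correlation undefined: zero variance")
    return float(sps.pearsonr(x, y).statistic)


def _safe_r(x: list[float], y: list[float]) -> float:
    try:
        return concordance_r(x, y)
    except UndefinedResultError:
        return float("nan")


def _label_mask(labels: VolumeImage, lab: int) -> BinaryMask:
    return BinaryMask(labels.data == lab, labels.spacing, labels.origin)


def _union_mask(labels: VolumeImage) -> BinaryMask:
    return BinaryMask(labels.data > 0, labels.spacing, labels.origin)


@dataclass
class CaseResult:
    """Validation metrics of one patient/phantom at one threshold."""

    pairs: list[MatchedPair]
    unmatched_auto: list[LesionStats]
    unmatched_ref: list[LesionStats]
    auto_stats: list[LesionStats]
    ref_stats: list[LesionStats]
    confusion: ConfusionCounts
    dsc_values: list[float] = field(default_factory=list)
    pair_volumes: list[tuple[float, float]] = field(default_factory=list)
    pair_suvmeans: list[tuple[float, float]] = field(default_factory=list)


def evaluate_case(suv_map: VolumeImage, bone: BinaryMask,
                  ref_labels: VolumeImage, suv_threshold: float,
                  connectivity: int = 26, min_voxels: int = 1,
                  match_kwargs: dict | None = None) -> CaseResult:
    """Segment one case at one threshold and compare against references."""
    masked = apply_bone_mask(suv_map, bone)
    auto_labels = segment_lesions(masked, suv_threshold,
                                  connectivity=connectivity,
                                  min_voxels=min_voxels)
    auto_stats = quantify_lesions(auto_labels, suv_map)
    ref_stats = quantify_lesions(ref_labels, suv_map)
    pairs, un_auto, un_ref = match_lesions(auto_stats, ref_stats,
                                           **(match_kwargs or {}))
    confusion = voxel_confusion(_union_mask(auto_labels),
                                _union_mask(ref_labels), bone)
    result = CaseResult(pairs, un_auto, un_ref, auto_stats, ref_stats,
                        confusion)
    auto_by_label = {s.label: s for s in auto_stats}
    ref_by_label = {s.label: s for s in ref_stats}
    for pair in pairs:
        a, r = auto_by_label[pair.auto_label], ref_by_label[pair.ref_label]
        result.dsc_values.append(dice(_label_mask(auto_labels, a.label),
                                      _label_mask(ref_labels, r.label)))
        result.pair_volumes.append((a.volume_ml, r.volume_ml))
        result.pair_suvmeans.append((a.suv_mean, r.suv_mean))
    return result


def sweep_thresholds(cases: list[tuple[VolumeImage, BinaryMask, VolumeImage]],
                     thresholds=DEFAULT_THRESHOLDS,
                     **case_kwargs) -> SweepResult:
    """Run segment→quantify→match across all cases per threshold and pool.

    ``cases`` is a list of (suv_map, bone_mask, ref_label_map) triples.
    Pooled sensitivity/specificity sum confusion counts across cases;
    volume/SUVmean concordance pools matched pairs across cases. Where a
    pooled correlation is undefined (fewer than 2 pairs or zero variance)
    NaN is recorded rather than raising.
    """
    if not cases:
        raise ParameterError("need at least one case")
    thresholds = [float(t) for t in thresholds]
    if not thresholds:
        raise ParameterError("empty threshold list")
    if sorted(set(thresholds)) != thresholds:
        raise ParameterError("thresholds must be strictly increasing")

    sweep = SweepResult(thresholds, [], [], [], [], [])
    for th in thresholds:
        pooled: ConfusionCounts | None = None
        dscs: list[float] = []
        vols_a: list[float] = []
        vols_r: list[float] = []
        suvs_a: list[float] = []
        suvs_r: list[float] = []
        for suv_map, bone, ref_labels in cases:
            res = evaluate_case(suv_map, bone, ref_labels, th, **case_kwargs)
            pooled = res.confusion if pooled is None else pooled + res.confusion
            dscs.extend(res.dsc_values)
            for av, rv in res.pair_volumes:
                vols_a.append(av)
                vols_r.append(rv)
            for am, rm in res.pair_suvmeans:
                suvs_a.append(am)
                suvs_r.append(rm)
        assert pooled is not None
        sweep.sensitivity.append(pooled.sensitivity)
        sweep.specificity.append(pooled.specificity)
        sweep.dsc.append(dscs)
        sweep.volume_r.append(_safe_r(vols_a, vols_r))
        sweep.suvmean_r.append(_safe_r(suvs_a, suvs_r))
    return sweep


def select_optimum_threshold(sweep: SweepResult) -> tuple[float, dict]:
    """The threshold maximising sensitivity + specificity (Youden point).

    Ties break towards the higher median DSC, then the lower threshold.
    The report carries the per-threshold ROC points and median DSC.
    """
    if not sweep.thresholds:
        raise ParameterError("empty sweep")
    scores = []
    for i, th in enumerate(sweep.thresholds):
        scores.append((sweep.sensitivity[i] + sweep.specificity[i],
                       sweep.median_dsc(i), -th, i))
    _, _, _, best = max(scores)
    report = {
        "optimum_threshold": sweep.thresholds[best],
        "sensitivity": sweep.sensitivity[best],
        "specificity": sweep.specificity[best],
        "median_dsc": sweep.median_dsc(best),
        "roc_points": [
            {"suv_threshold": th, "fpr": fpr, "tpr": tpr,
             "median_dsc": sweep.median_dsc(i)}
            for i, (th, (fpr, tpr)) in enumerate(
                zip(sweep.thresholds, sweep.roc_points()))
        ],
    }
    return sweep.thresholds[best], report


def patient_report(case_results: list[CaseResult]
                   ) -> tuple[pd.DataFrame, float]:
    """Per-patient validation table plus pooled lesion-count correlation.

    Concordance columns are NaN where undefined (e.g. a single lesion),
    mirroring a dash in a printed table. Sensitivity/specificity are in
    percent; the DSC column is the per-patient median over matched pairs.
    """
    rows = []
    n_auto_all, n_ref_all = [], []
    for i, res in enumerate(case_results, start=1):
        rows.append({
            "patient": i,
            "volume_r": _safe_r(*zip(*res.pair_volumes))
            if res.pair_volumes else float("nan"),
            "suvmean_r": _safe_r(*zip(*res.pair_suvmeans))
            if res.pair_suvmeans else float("nan"),
            "sensitivity_pct": 100.0 * res.confusion.sensitivity,
            "specificity_pct": 100.0 * res.confusion.specificity,
            "dsc": float(np.median(res.dsc_values))
            if res.dsc_values else float("nan"),
            "n_ref_lesions": len(res.ref_stats),
            "n_auto_lesions": len(res.auto_stats),
        })
        n_auto_all.append(len(res.auto_stats))
        n_ref_all.append(len(res.ref_stats))
    table = pd.DataFrame(rows)
    count_r = _safe_r(n_auto_all, n_ref_all) if len(n_auto_all) >= 2 \
        else float("nan")
    return table, count_r


def unmatched_report(case_results: list[CaseResult]) -> pd.DataFrame:
    """Audit of lesions present on one side only (missed-lesion analysis)."""
    rows = []
    for i, res in enumerate(case_results, start=1):
        for side, lesions in (("auto_only", res.unmatched_auto),
                              ("ref_only", res.unmatched_ref)):
            for s in lesions:
                rows.append({"patient": i, "side": side, "label": s.label,
                             "volume_ml": s.volume_ml,
                             "suv_mean": s.suv_mean, "suv_max": s.suv_max})
    return pd.DataFrame(rows, columns=["patient", "side", "label",
                                       "volume_ml", "suv_mean", "suv_max"])
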