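"""FROC-based evaluation of nodule detection.

Candidates are extracted from probability maps by thresholding and
connected-component analysis; a candidate is a true positive for a ground
truth nodule when it lies within the nodule's radius (the public-challenge
hit criterion); extra candidates inside an already-hit nodule are neither
TP nor FP.  The FROC curve sweeps the candidate-score threshold and reports
sensitivity at the seven standard operating points {0.125, 0.25, 0.5, 1, 2,
4, 8} false positives per scan; the scalar AUC summary is the mean of the
seven sensitivities (a trapezoidal variant over log2 FP/scan is available
behind a flag).

Nodule size classes: small d < 5 mm, middle 5 <= d <= 15 mm, large
d > 15 mm (boundaries inclusive to 'middle').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "OPERATING_POINTS",
    "Candidate",
    "GroundTruthNodule",
    "FROCCurve",
    "ConfusionSummary",
    "MatchResult",
    "extract_candidates",
    "classify_size",
    "match_candidates",
    "froc",
    "confusion_summary",
    "kfold_split",
]

#: The seven standard FP/scan operating points.
OPERATING_POINTS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class Candidate:
    """A detection: world-mm position (x, y, z) and score p in [0, 1]."""

    series_id: str
    position: tuple  # (x, y, z) world mm
    score: float

    def __post_init__(self):
        self.position = tuple(float(v) for v in self.position)
        self.score = float(self.score)
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass
class GroundTruthNodule:
    series_id: str
    center: tuple  # (x, y, z) world mm
    diameter_mm: float
    size_class: str = ""

    def __post_init__(self):
        self.center = tuple(float(v) for v in self.center)
        self.diameter_mm = float(self.diameter_mm)
        cls = classify_size(self.diameter_mm)
        if self.size_class and self.size_class != cls:
            raise ValueError(
                f"size_class {self.size_class!r} inconsistent with d={self.diameter_mm}"
            )
        self.size_class = cls


@dataclass
class FROCCurve:
    operating_points: tuple
    sensitivities: tuple
    auc: float

    def __post_init__(self):
        s = np.asarray(self.sensitivities, dtype=float)
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("sensitivities must lie in [0, 1]")
        if np.any(np.diff(s) < -1e-12):
            raise ValueError("sensitivities must be non-decreasing in FP/scan")


@dataclass
class ConfusionSummary:
    ACC: float
    SN: float
    SP: float


@dataclass
class MatchResult:
    """Per-scan match bookkeeping used by the FROC sweep.

    truth_best_score[s] lists, per truth nodule of scan s, the best score of
    any candidate inside it (-inf when none); truth_classes[s] the parallel
    size classes; fp_scores[s] lists the scores of candidates outside every
    nodule of scan s.
    """

    scan_ids: list
    truth_best_score: dict  # series -> list[float]
    fp_scores: dict  # series -> list[float]
    truth_classes: dict = field(default_factory=dict)  # series -> list[str]

    @property
    def n_truths(self) -> int:
        return sum(len(v) for v in self.truth_best_score.values())

    def restricted_to(self, size_class: str) -> "MatchResult":
        """The same match with only the truths of one size class.

        False positives are shared across strata: a candidate inside no
        nodule is a false positive regardless of which stratum is scored.
        """
        best = {
            s: [b for b, c in zip(self.truth_best_score[s], self.truth_classes[s])
                if c == size_class]
            for s in self.scan_ids
        }
        classes = {
            s: [c for c in self.truth_classes[s] if c == size_class]
            for s in self.scan_ids
        }
        return MatchResult(
            scan_ids=list(self.scan_ids),
            truth_best_score=best,
            fp_scores={s: list(v) for s, v in self.fp_scores.items()},
            truth_classes=classes,
        )


# ---------------------------------------------------------------------------

def extract_candidates(
    scores: np.ndarray,
    threshold: float,
    spacing: tuple = (1.0, 1.0, 1.0),
    origin: tuple = (0.0, 0.0, 0.0),
    series_id: str = "",
) -> list:
    """One candidate per supra-threshold connected component.

    The candidate sits at the component's score-weighted centroid
    (converted to world mm, (x, y, z)); its score is the component maximum.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    s = np.asarray(scores, dtype=float)
    mask = s > threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    out = []
    for lab in range(1, n + 1):
        comp = labels == lab
        w = s * comp
        total = float(w.sum())
        idx = np.array(ndimage.center_of_mass(w))  # (z, y, x), score-weighted
        if total <= 0:  # degenerate: fall back to geometric centroid
            idx = np.array(ndimage.center_of_mass(comp))
        world_zyx = np.asarray(origin) + idx * np.asarray(spacing)
        out.append(
            Candidate(
                series_id=series_id,
                position=(world_zyx[2], world_zyx[1], world_zyx[0]),
                score=float(s[comp].max()),
            )
        )
    return out


def classify_size(d: float) -> str:
    """small: d < 5 mm; middle: 5 <= d <= 15 mm; large: d > 15 mm."""
    if d <= 0:
        raise ValueError(f"diameter must be > 0, got {d}")
    if d < 5.0:
        return "small"
    if d <= 15.0:
        return "middle"
    return "large"


def match_candidates(
    candidates: Sequence[Candidate],
    truths: Sequence[GroundTruthNodule],
    scan_ids: Optional[Sequence[str]] = None,
) -> MatchResult:
    """Assign candidates to ground-truth nodules per scan.

    A candidate hits a nodule when its distance to the centre is <= d/2.
    A nodule counts as detected at most once (at the best candidate score);
    additional candidates inside it are ignored.  Candidates inside no
    nodule are false positives of their scan.
    """
    if scan_ids is None:
        scan_ids = sorted(
            {c.series_id for c in candidates} | {t.series_id for t in truths}
        )
    scan_ids = list(scan_ids)
    truth_best: Dict[str, list] = {s: [] for s in scan_ids}
    fp_scores: Dict[str, list] = {s: [] for s in scan_ids}
    truths_by_scan: Dict[str, list] = {s: [] for s in scan_ids}
    for t in truths:
        truths_by_scan.setdefault(t.series_id, []).append(t)
    for s in scan_ids:
        truth_best[s] = [-np.inf] * len(truths_by_scan.get(s, []))
    truth_classes = {
        s: [t.size_class for t in truths_by_scan.get(s, [])] for s in scan_ids
    }
    for c in candidates:
        scan_truths = truths_by_scan.get(c.series_id, [])
        hit = False
        for j, t in enumerate(scan_truths):
            dist = float(np.linalg.norm(np.subtract(c.position, t.center)))
            if dist <= t.diameter_mm / 2.0:
                hit = True
                if c.score > truth_best[c.series_id][j]:
                    truth_best[c.series_id][j] = c.score
        if not hit:
            fp_scores.setdefault(c.series_id, []).append(c.score)
    return MatchResult(scan_ids=scan_ids, truth_best_score=truth_best,
                       fp_scores=fp_scores, truth_classes=truth_classes)


def froc_by_size(
    match: MatchResult,
    operating_points: Sequence[float] = OPERATING_POINTS,
) -> dict:
    """Size-stratified FROC: one curve per size class present in the match."""
    present = sorted({c for v in match.truth_classes.values() for c in v})
    return {
        cls: froc(match.restricted_to(cls), operating_points) for cls in present
    }


def froc(
    match: MatchResult,
    operating_points: Sequence[float] = OPERATING_POINTS,
    trapezoid_auc: bool = False,
) -> FROCCurve:
    """FROC curve from a match result.

    The candidate-score threshold is swept over all distinct scores; at
    each threshold the sensitivity and the FP count per scan are computed.
    Sensitivity at each operating point f is read off the resulting step
    function: the best sensitivity achievable with at most f FP/scan
    (last value carried forward along the FP/scan axis; 0 before the first
    step).  The scalar summary is the arithmetic mean of the sensitivities
    at the seven points, or the trapezoid over log2 FP/scan behind the flag.
    """
    n_truths = match.n_truths
    if n_truths == 0:
        raise ValueError("no ground-truth nodules: sensitivity undefined")
    n_scans = len(match.scan_ids)
    best = np.array(
        [v for s in match.scan_ids for v in match.truth_best_score[s]], dtype=float
    )
    fps = np.array(
        [v for s in match.scan_ids for v in match.fp_scores[s]], dtype=float
    )
    thresholds = np.unique(np.concatenate([best[np.isfinite(best)], fps]))
    curve = []  # (fp_per_scan, sensitivity)
    for thr in thresholds:
        sens = float((best >= thr).sum()) / n_truths
        fp_rate = float((fps >= thr).sum()) / n_scans
        curve.append((fp_rate, sens))
    sens_at = []
    for f in operating_points:
        ok = [s for r, s in curve if r <= f]
        sens_at.append(max(ok) if ok else 0.0)
    sens_at = tuple(sens_at)
    if trapezoid_auc:
        x = np.log2(np.asarray(operating_points, dtype=float))
        auc = float(np.trapezoid(sens_at, x) / (x[-1] - x[0]))
    else:
        auc = float(np.mean(sens_at))
    return FROCCurve(
        operating_points=tuple(operating_points), sensitivities=sens_at, auc=auc
    )


def confusion_summary(tp: int, fn: int, tn: int, fp: int) -> ConfusionSummary:
    """ACC/SN/SP from confusion counts."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be >= 0")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("degenerate denominators: need positives and negatives")
    return ConfusionSummary(
        ACC=(tp + tn) / (tp + tn + fp + fn),
        SN=tp / (tp + fn),
        SP=tn / (tn + fp),
    )


def kfold_split(series_ids: Sequence[str], k: int = 5, seed: int = 0) -> list:
    """Deterministic seeded partition into k near-equal folds.

    Returns a list of (train_ids, test_ids) pairs; every id appears in
    exactly one test fold.
    """
    ids = list(series_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"need at least k={k} series, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = np.array_split(order, k)
    out = []
    for f in folds:
        test = [ids[i] for i in f]
        train = [ids[i] for i in order if ids[i] not in set(test)]
        out.append((train, test))
    return out
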