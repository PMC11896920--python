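"""Segment bookkeeping, linear threshold classifiers and evaluation statistics.

Segments enter the analysis only if they are longer than 4 cm, unique
(the shorter of each duplicate pair is dropped) and were not flagged as
failed centerline extractions by either rater.  Two one-dimensional
linear classifiers then act in series: a threshold on the mean absolute
velocity separates motile from non-motile segments (the "<50% motile"
and "not motile" rater classes are merged into the negative class), and
two cut points on the mean velocity assign motile segments a direction
(backward / bidirectional / forward).  Thresholds are chosen by
exhaustive accuracy-maximising search and validated with five-fold
cross-validation grouped by subject, so no subject contributes to the
thresholds applied to its own segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from .errors import ConfigurationError
from .motility import SegmentMetrics

__all__ = [
    "MOTILITY_CLASSES",
    "DIRECTION_CLASSES",
    "PREDICTED_CLASSES",
    "SegmentRecord",
    "ClassifierThresholds",
    "apply_exclusion_filters",
    "fit_thresholds",
    "grouped_kfold",
    "predict",
    "cross_validate",
    "roc_auc",
    "cohens_kappa",
    "accuracy",
    "contingency_matrix",
    "cohort_summary",
]

MOTILITY_CLASSES = ("motile", "lt50_motile", "non_motile")
DIRECTION_CLASSES = ("forward", "backward", "bidirectional")
# four-class label used for prediction and contingency matrices
PREDICTED_CLASSES = ("non_motile", "backward", "bidirectional", "forward")


@dataclass
class SegmentRecord:
    """Bookkeeping for one intestinal segment."""

    segment_id: str
    subject_id: str
    cohort: str  # healthy | crohns | synthetic
    length_mm: float
    extraction_failed: bool = False
    duplicate_of: Optional[str] = None
    reference_motility: Optional[str] = None  # motile | lt50_motile | non_motile
    reference_direction: Optional[str] = None  # forward | backward | bidirectional
    mean_velocity: Optional[float] = None
    mean_absolute_velocity: Optional[float] = None
    predicted_class: Optional[str] = None

    def __post_init__(self):
        if self.reference_motility is not None and self.reference_motility not in MOTILITY_CLASSES:
            raise ConfigurationError(f"unknown motility class {self.reference_motility!r}")
        if self.reference_direction is not None and self.reference_direction not in DIRECTION_CLASSES:
            raise ConfigurationError(f"unknown direction class {self.reference_direction!r}")
        if (self.reference_direction is not None) != (self.reference_motility == "motile"):
            raise ConfigurationError(
                "reference_direction must be present exactly for reference-motile segments"
            )

    @property
    def reference_class(self) -> Optional[str]:
        """Four-class reference label (<50% motile merged into non_motile)."""
        if self.reference_motility is None:
            return None
        if self.reference_motility == "motile":
            return self.reference_direction
        return "non_motile"

    def with_metrics(self, metrics: SegmentMetrics) -> "SegmentRecord":
        return replace(
            self,
            mean_velocity=metrics.mean_velocity,
            mean_absolute_velocity=metrics.mean_absolute_velocity,
        )


@dataclass(frozen=True)
class ClassifierThresholds:
    """Fitted cut points of the two serial 1-D classifiers."""

    motility_threshold: float  # on mean absolute velocity, mm/s
    peristalsis_lower: float  # on mean velocity: below -> backward
    peristalsis_upper: float  # on mean velocity: above -> forward

    def __post_init__(self):
        if self.peristalsis_lower > self.peristalsis_upper:
            raise ConfigurationError("peristalsis lower cut must not exceed upper cut")
        if self.motility_threshold <= 0:
            raise ConfigurationError("motility threshold must be positive")


def apply_exclusion_filters(
    records: Sequence[SegmentRecord], min_length_mm: float = 40.0
) -> tuple[list[SegmentRecord], dict]:
    """Apply the inclusion rules; returns (included, exclusion tally).

    Order of application follows the reported tally: length first, then
    duplicates (keeping the longer of each pair), then rater-flagged
    extraction failures.
    """
    by_id = {r.segment_id: r for r in records}
    for r in records:
        if r.duplicate_of is not None and r.duplicate_of not in by_id:
            raise ConfigurationError(f"duplicate_of {r.duplicate_of!r} does not resolve")

    tally = {"generated": len(records)}
    remaining = [r for r in records]
    short = [r for r in remaining if r.length_mm <= min_length_mm]
    remaining = [r for r in remaining if r.length_mm > min_length_mm]
    tally["excluded_length"] = len(short)

    kept_ids = {r.segment_id for r in remaining}
    drop: set[str] = set()
    for r in remaining:
        other_id = r.duplicate_of
        if other_id is None or other_id not in kept_ids:
            continue
        other = by_id[other_id]
        if _dup_chain_cycle(r, by_id):
            raise ConfigurationError("circular duplicate_of references")
        # keep the longer of the pair; ties keep the lexicographically first id
        if (r.length_mm, other.segment_id) < (other.length_mm, r.segment_id):
            drop.add(r.segment_id)
        elif (other.length_mm, r.segment_id) < (r.length_mm, other.segment_id):
            drop.add(other.segment_id)
    remaining = [r for r in remaining if r.segment_id not in drop]
    tally["excluded_duplicate"] = len(drop)

    failed = [r for r in remaining if r.extraction_failed]
    remaining = [r for r in remaining if not r.extraction_failed]
    tally["excluded_failed"] = len(failed)
    tally["included"] = len(remaining)
    return remaining, tally


def _dup_chain_cycle(record: SegmentRecord, by_id: dict) -> bool:
    """True for circular duplicate chains; a direct mutual pair (a <-> b) is legal."""
    seen = [record.segment_id]
    cur = record
    while cur.duplicate_of is not None:
        if cur.duplicate_of in seen:
            return not (len(seen) == 2 and cur.duplicate_of == seen[0])
        seen.append(cur.duplicate_of)
        cur = by_id[cur.duplicate_of]
    return False


def _candidate_cuts(values: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive sorted unique values, plus outer sentinels."""
    v = np.unique(values)
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate([[v[0] - 1.0], mids, [v[-1] + 1.0]])


def fit_thresholds(train: Sequence[SegmentRecord]) -> ClassifierThresholds:
    """Accuracy-maximising exhaustive 1-D threshold search.

    The motility threshold separates reference-motile from merged
    non-motile records on mean absolute velocity; the two peristalsis
    cut points are fitted on reference-motile records only, maximising
    3-class accuracy on mean velocity.  Ties pick the lowest cuts.
    """
    mav = np.array([r.mean_absolute_velocity for r in train], dtype=float)
    motile = np.array([r.reference_motility == "motile" for r in train])
    if motile.all() or (~motile).all():
        raise ConfigurationError("motility training data must contain both classes")
    best = (-1.0, None)
    for cut in _candidate_cuts(mav):
        acc = ((mav > cut) == motile).mean()
        if acc > best[0] + 1e-12:
            best = (acc, cut)
    thr = best[1]
    if thr <= 0:  # threshold is a physical speed; clamp just above zero
        thr = min(c for c in _candidate_cuts(mav) if c > 0)

    sub = [r for r in train if r.reference_motility == "motile"]
    if not sub:
        raise ConfigurationError("no motile training records for the peristalsis classifier")
    mv = np.array([r.mean_velocity for r in sub], dtype=float)
    direction = np.array([r.reference_direction for r in sub])
    cuts = _candidate_cuts(mv)
    best3 = (-1.0, None, None)
    for i, lo in enumerate(cuts):
        pred_lo = np.where(mv < lo, "backward", "bidirectional")
        for hi in cuts[i:]:
            pred = np.where(mv > hi, "forward", pred_lo)
            acc = (pred == direction).mean()
            if acc > best3[0] + 1e-12:
                best3 = (acc, lo, hi)
    return ClassifierThresholds(thr, best3[1], best3[2])


def grouped_kfold(records: Sequence[SegmentRecord], k: int = 5, seed: int = 0) -> np.ndarray:
    """Subject-grouped fold assignment (one fold index per record).

    All segments from a subject share a fold; subjects are shuffled
    deterministically by ``seed`` and dealt round-robin so fold sizes
    are balanced by subject count.
    """
    subjects = sorted({r.subject_id for r in records})
    if len(subjects) < k:
        raise ConfigurationError(f"need at least {k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    fold_of = {subjects[idx]: pos % k for pos, idx in enumerate(order)}
    return np.array([fold_of[r.subject_id] for r in records])


def predict(
    records: Sequence[SegmentRecord], thresholds: ClassifierThresholds
) -> list[SegmentRecord]:
    """Serial prediction: motility first, direction only for motile segments."""
    out = []
    for r in records:
        if r.mean_absolute_velocity is None or r.mean_velocity is None:
            raise ConfigurationError(f"segment {r.segment_id} has no metrics")
        if r.mean_absolute_velocity <= thresholds.motility_threshold:
            label = "non_motile"
        elif r.mean_velocity < thresholds.peristalsis_lower:
            label = "backward"
        elif r.mean_velocity > thresholds.peristalsis_upper:
            label = "forward"
        else:
            label = "bidirectional"
        out.append(replace(r, predicted_class=label))
    return out


def cross_validate(
    records: Sequence[SegmentRecord], k: int = 5, seed: int = 0
) -> tuple[list[SegmentRecord], list[dict]]:
    """Subject-grouped k-fold cross-validated prediction.

    Every record is predicted exactly once, with thresholds fitted on
    the other folds.  Returns the predicted records (original order)
    and per-fold summaries (thresholds and the fold's motility AUC).
    """
    folds = grouped_kfold(records, k, seed)
    predicted: list[Optional[SegmentRecord]] = [None] * len(records)
    fold_info = []
    for f in range(k):
        train = [r for r, ff in zip(records, folds) if ff != f]
        test_ix = [i for i, ff in enumerate(folds) if ff == f]
        thr = fit_thresholds(train)
        for i, r in zip(test_ix, predict([records[i] for i in test_ix], thr)):
            predicted[i] = r
        test = [predicted[i] for i in test_ix]
        info = {"fold": f, "thresholds": thr, "n_test": len(test)}
        labels = [t.reference_motility == "motile" for t in test]
        if len(set(labels)) == 2:
            info["motility_auc"] = roc_auc(
                [t.mean_absolute_velocity for t in test], labels
            )
        fold_info.append(info)
    return predicted, fold_info  # type: ignore[return-value]


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve (Mann-Whitney concordance; ties count 0.5)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ConfigurationError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Unweighted Cohen's kappa; NaN when chance agreement is exactly 1."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ConfigurationError("label vectors must have equal length")
    if len(set(a)) == 1 and set(a) == set(b):
        return float("nan")  # p_e = 1: kappa undefined
    return float(cohen_kappa_score(a, b))


def accuracy(labels_a: Sequence, labels_b: Sequence) -> float:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ConfigurationError("label vectors must have equal length")
    return float((a == b).mean())


def contingency_matrix(
    reference: Sequence[str], predicted: Sequence[str], classes: Sequence[str] = PREDICTED_CLASSES
) -> np.ndarray:
    """Counts[i, j] = #(reference == classes[i] and predicted == classes[j])."""
    ref = np.asarray(reference)
    pred = np.asarray(predicted)
    out = np.zeros((len(classes), len(classes)), dtype=int)
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            out[i, j] = int(np.sum((ref == ci) & (pred == cj)))
    return out


def percent(count: int, total: int) -> int:
    """Integer percentage, rounded half-up (34.48% -> 34, 34.5% -> 35)."""
    if total <= 0:
        raise ConfigurationError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


def cohort_summary(
    records: Sequence[SegmentRecord],
    equal_var: bool = True,
    alpha: float = 0.001,
) -> dict:
    """Per-cohort descriptive statistics and the between-cohort t-test.

    Medians and 25th/75th percentiles of mean absolute velocity, class
    percentages rounded to integer percent, and (when exactly two
    cohorts are present) a two-sided Student's t-test on mean absolute
    velocity (Welch variant available via ``equal_var=False``).
    """
    cohorts = sorted({r.cohort for r in records})
    out: dict = {"cohorts": {}}
    for c in cohorts:
        sub = [r for r in records if r.cohort == c]
        if not sub:
            raise ConfigurationError(f"empty cohort {c}")
        mav = np.array([r.mean_absolute_velocity for r in sub], dtype=float)
        entry = {
            "n": len(sub),
            "median": float(np.median(mav)),
            "iqr": (float(np.percentile(mav, 25)), float(np.percentile(mav, 75))),
        }
        refs = [r.reference_class for r in sub if r.reference_class is not None]
        if refs:
            counts = {cls: refs.count(cls) for cls in PREDICTED_CLASSES}
            entry["class_counts"] = counts
            entry["class_percent"] = {cls: percent(n, len(refs)) for cls, n in counts.items()}
            n_peri = counts["forward"] + counts["backward"]
            entry["peristalsis_percent"] = percent(n_peri, len(refs))
        out["cohorts"][c] = entry
    if len(cohorts) == 2:
        g1 = [r.mean_absolute_velocity for r in records if r.cohort == cohorts[0]]
        g2 = [r.mean_absolute_velocity for r in records if r.cohort == cohorts[1]]
        if min(len(g1), len(g2)) < 2:
            raise ConfigurationError("need >= 2 records per cohort for the t-test")
        t, p = _scipy_stats.ttest_ind(g1, g2, equal_var=equal_var)
        out["t_test"] = {"t": float(t), "p": float(p), "significant": bool(p < alpha)}
    return out
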