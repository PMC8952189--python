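"""Soft-voting fusion, classification metrics, ROC/AUC and the CV harness.

Each analysis level yields one DR probability per subject (tile levels
are first averaged over the subject's tiles); the ensemble decision is
the unweighted mean of those per-level probabilities — soft voting —
thresholded at 0.5, ties resolved toward DR (screening favours
sensitivity).  Metrics follow the standard confusion-count definitions
with DR as the positive class and are reported as percentages; AUC is
the trapezoidal area under the empirical ROC with tied scores grouped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PredictionRecord",
    "ConfusionCounts",
    "MetricsReport",
    "aggregate_tiles",
    "soft_vote",
    "confusion_from_predictions",
    "compute_metrics",
    "roc_auc",
    "balanced_accuracy",
    "cohens_kappa",
    "stratified_kfold",
    "crossvalidate",
]

PHASES = ("full", "quarters", "sixteenths", "fovea")


@dataclass
class PredictionRecord:
    """One classifier output for one subject at one analysis level."""

    subject_id: str
    phase: str
    prob_dr: float
    prob_ndr: float

    def __post_init__(self):
        if abs(self.prob_dr + self.prob_ndr - 1.0) > 1e-6:
            raise ValueError(
                f"probabilities must sum to 1: {self.prob_dr} + {self.prob_ndr}"
            )


@dataclass
class ConfusionCounts:
    """DR-positive confusion counts."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Percentage-scale summary metrics; ``undefined`` lists any metric
    whose denominator was zero (never silently reported as 0)."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None
    auc: float | None = None
    balanced_accuracy: float | None = None
    kappa: float | None = None
    roc_points: list = field(default_factory=list)
    undefined: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "accuracy", "sensitivity", "specificity", "precision",
                "f1", "auc", "balanced_accuracy", "kappa",
            )
        }


def aggregate_tiles(records: list[PredictionRecord]) -> PredictionRecord:
    """Mean tile probability -> one image-level record (renormalized)."""
    if not records:
        raise ValueError("need at least one record")
    subjects = {r.subject_id for r in records}
    phases = {r.phase for r in records}
    if len(subjects) > 1 or len(phases) > 1:
        raise ValueError(f"mixed subjects/phases: {subjects} / {phases}")
    pd = float(np.mean([r.prob_dr for r in records]))
    pn = float(np.mean([r.prob_ndr for r in records]))
    s = pd + pn
    return PredictionRecord(records[0].subject_id, records[0].phase, pd / s, pn / s)


def soft_vote(phase_records: list[PredictionRecord]) -> tuple[PredictionRecord, str]:
    """Unweighted mean of per-phase DR probabilities; DR iff mean >= 0.5."""
    if not (1 <= len(phase_records) <= 4):
        raise ValueError(f"need 1-4 phase records, got {len(phase_records)}")
    subjects = {r.subject_id for r in phase_records}
    if len(subjects) > 1:
        raise ValueError(f"mixed subjects: {subjects}")
    pd = float(np.mean([r.prob_dr for r in phase_records]))
    fused = PredictionRecord(phase_records[0].subject_id, "fusion", pd, 1.0 - pd)
    label = "DR" if pd >= 0.5 else "NDR"
    return fused, label


def confusion_from_predictions(pred_labels, truth_labels) -> ConfusionCounts:
    c = ConfusionCounts()
    for p, t in zip(pred_labels, truth_labels, strict=True):
        if t == "DR":
            if p == "DR":
                c.tp += 1
            else:
                c.fn += 1
        else:
            if p == "DR":
                c.fp += 1
            else:
                c.tn += 1
    return c


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Percentage-scale accuracy/sensitivity/specificity/precision/F1.

    A metric with a zero denominator is listed in ``undefined``
    instead of being reported.
    """
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    r = MetricsReport()
    r.accuracy = 100.0 * (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fn > 0:
        r.sensitivity = 100.0 * counts.tp / (counts.tp + counts.fn)
    else:
        r.undefined.append("sensitivity")
    if counts.tn + counts.fp > 0:
        r.specificity = 100.0 * counts.tn / (counts.tn + counts.fp)
    else:
        r.undefined.append("specificity")
    if counts.tp + counts.fp > 0:
        r.precision = 100.0 * counts.tp / (counts.tp + counts.fp)
    else:
        r.undefined.append("precision")
    if r.precision is not None and r.sensitivity is not None and (r.precision + r.sensitivity) > 0:
        r.f1 = 2.0 * r.precision * r.sensitivity / (r.precision + r.sensitivity)
    else:
        r.undefined.append("f1")
    if r.sensitivity is not None and r.specificity is not None:
        r.balanced_accuracy = (r.sensitivity + r.specificity) / 2.0
    r.kappa = cohens_kappa(counts)
    return r


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity, in percent."""
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.tn + counts.fp)
    return 100.0 * (sens + spec) / 2.0


def cohens_kappa(counts: ConfusionCounts) -> float | None:
    """Chance-corrected agreement between prediction and truth."""
    n = counts.total
    po = (counts.tp + counts.tn) / n
    p_yes = ((counts.tp + counts.fp) / n) * ((counts.tp + counts.fn) / n)
    p_no = ((counts.tn + counts.fn) / n) * ((counts.tn + counts.fp) / n)
    pe = p_yes + p_no
    if abs(1.0 - pe) < 1e-12:
        return None
    return (po - pe) / (1.0 - pe)


def roc_auc(scores, truth_labels) -> tuple[float, list[tuple[float, float]]]:
    """Trapezoidal AUC over the empirical ROC (DR positive).

    The threshold sweeps the unique scores in decreasing order with
    ties grouped, so the curve runs monotonically from (0, 0) to
    (1, 1).  AUC is returned on the [0, 1] scale.
    """
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray([1 if lb == "DR" else 0 for lb in truth_labels])
    n1, n0 = int(t.sum()), int((1 - t).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present for a ROC curve")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < s_sorted.size:
        j = i
        while j < s_sorted.size and s_sorted[j] == s_sorted[i]:
            tp += int(t_sorted[j])
            fp += int(1 - t_sorted[j])
            j += 1
        points.append((fp / n0, tp / n1))
        i = j
    xs = np.asarray([p[0] for p in points])
    ys = np.asarray([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return auc, points


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1) per subject."""
    y = np.asarray(labels)
    folds = np.empty(y.size, dtype=np.int64)
    rng = np.random.default_rng(seed)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        if idx.size < k:
            raise ValueError(
                f"class {cls!r} has {idx.size} subjects < k={k}; use k <= {idx.size}"
            )
        for fold, chunk in enumerate(np.array_split(idx, k)):
            folds[chunk] = fold
    return folds


def crossvalidate(
    subject_ids,
    labels,
    phase_trainer,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Subject-level stratified k-fold CV of the fused classifier.

    ``phase_trainer(train_idx, test_idx)`` must train all phase
    classifiers on the training subjects and return
    ``{subject_id: {phase: PredictionRecord}}`` for the held-out
    subjects; this harness owns the partition (all tiles of a subject
    share its fold, and the same test set serves every phase), fuses
    the phase records, and pools predictions over folds.
    """
    sids = list(subject_ids)
    y = np.asarray(labels)
    folds = stratified_kfold(y, k=k, seed=seed)
    pooled = ConfusionCounts()
    fused_scores: dict[str, float] = {}
    truth: dict[str, str] = dict(zip(sids, (str(v) for v in y)))
    per_fold = []
    for f in range(k):
        test_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        phase_preds = phase_trainer(train_idx, test_idx)
        pred_labels, truth_labels = [], []
        for i in test_idx:
            sid = sids[i]
            fused, label = soft_vote(list(phase_preds[sid].values()))
            fused_scores[sid] = fused.prob_dr
            pred_labels.append(label)
            truth_labels.append(truth[sid])
        cf = confusion_from_predictions(pred_labels, truth_labels)
        per_fold.append(compute_metrics(cf))
        pooled.tp += cf.tp
        pooled.fp += cf.fp
        pooled.tn += cf.tn
        pooled.fn += cf.fn
    report = compute_metrics(pooled)
    scores = [fused_scores[s] for s in sids]
    truths = [truth[s] for s in sids]
    report.auc, report.roc_points = roc_auc(scores, truths)
    report.auc *= 100.0
    return {"pooled": report, "per_fold": per_fold, "folds": folds, "scores": fused_scores}
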