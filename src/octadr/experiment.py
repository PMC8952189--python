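"""End-to-end screening experiment on synthetic cohorts.

Wires the whole pipeline together: phantom generation -> local
equalization -> GGMRF denoising -> MGRF vessel segmentation ->
signed-distance channel -> multi-scale decomposition -> one CNN per
level -> soft-voting fusion -> metrics.  This is the harness behind
the CLI ``pipeline`` command and the reproduction script.

Valid 3x3 convolutions need at least a 46-pixel side to survive four
blocks; tiles smaller than that (e.g. the sixteenth-tiles of a
128-pixel desk-scale frame) drop trailing blocks until the plan fits,
keeping the rest of the recipe unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fusion as fu
from .channels import CompositeImage, make_composite, signed_distance
from .classifier import ArchitectureSpec, TrainConfig, TrainedPhase, train_phase
from .enhancement import GgmrfParams, equalize_local, ggmrf_smooth
from .multiscale import LEVELS, decompose
from .segmentation import MgrfParams, segment_vessels
from .synthetic import PhantomSample, generate_cohort

__all__ = [
    "ExperimentConfig",
    "preprocess_image",
    "fit_spec_for_side",
    "build_phase_datasets",
    "run_experiment",
]


@dataclass
class ExperimentConfig:
    n_per_class: int = 50
    image_size: int = 128
    epochs: int = 8
    batch_size: int = 32
    learning_rate: float = 0.001
    dropout_rate: float = 0.2
    augmentation: bool = True
    test_frac_folds: int = 5  # one fold of a stratified k-fold is the 20% test set
    levels: tuple[str, ...] = LEVELS
    equalize_window: int | None = None  # default: ~1/4 of the side, odd
    clip_limit: float = 0.02
    ggmrf: GgmrfParams = field(default_factory=GgmrfParams)
    mgrf: MgrfParams = field(default_factory=MgrfParams)
    seed: int = 0


def preprocess_image(
    img: np.ndarray,
    *,
    window_px: int | None = None,
    clip_limit: float = 0.02,
    ggmrf: GgmrfParams | None = None,
    mgrf: MgrfParams | None = None,
    subject_id: str = "",
    label: str | None = None,
) -> CompositeImage:
    """Raw grayscale angiogram -> 3-channel composite.

    Runs local equalization, GGMRF denoising, MGRF segmentation with
    connectivity filtering, and the interior distance map.
    """
    if window_px is None:
        window_px = max(3, (img.shape[0] // 8) * 2 + 1)
    enhanced = equalize_local(img, window_px=window_px, clip_limit=clip_limit)
    denoised = ggmrf_smooth(enhanced, ggmrf or GgmrfParams())
    mask = segment_vessels(denoised, mgrf or MgrfParams())
    phi = signed_distance(mask) if mask.any() and not mask.all() else None
    if phi is None:
        ch3_src = np.zeros_like(denoised)
        return make_composite(denoised, mask, ch3_src, subject_id=subject_id, label=label)
    return make_composite(denoised, mask, phi, subject_id=subject_id, label=label)


def fit_spec_for_side(
    side: int,
    base_filters: tuple[int, ...] = (16, 32, 64, 128),
    dropout_rate: float = 0.2,
) -> ArchitectureSpec:
    """Largest prefix of the block plan that leaves a positive side."""
    for n_blocks in range(len(base_filters), 0, -1):
        spec = ArchitectureSpec(
            input_side=side, conv_filters=base_filters[:n_blocks], dropout_rate=dropout_rate
        )
        try:
            spec.validate()
            from .classifier import build_architecture

            build_architecture(spec)
            return spec
        except ValueError:
            continue
    raise ValueError(f"no block plan fits a {side}-pixel input")


def build_phase_datasets(
    composites: list[CompositeImage], levels: tuple[str, ...] = LEVELS
) -> dict[str, dict]:
    """Per-level training arrays: X (N,H,W,3), labels, subject ids."""
    out: dict[str, dict] = {lv: {"x": [], "y": [], "sid": []} for lv in levels}
    for comp in composites:
        parts = decompose(comp, levels)
        for lv, patches in parts.items():
            for p in patches:
                out[lv]["x"].append(p.channels)
                out[lv]["y"].append(comp.label)
                out[lv]["sid"].append(comp.subject_id)
    for lv in levels:
        out[lv]["x"] = np.stack(out[lv]["x"])
        out[lv]["y"] = np.asarray(out[lv]["y"])
        out[lv]["sid"] = np.asarray(out[lv]["sid"])
    return out


def _phase_records(
    trained: TrainedPhase, x: np.ndarray, sids: np.ndarray, phase: str
) -> dict[str, fu.PredictionRecord]:
    """Predict tiles, average per subject, return one record per subject."""
    probs = trained.predict_proba(x)
    recs: dict[str, list[fu.PredictionRecord]] = {}
    for sid, p in zip(sids, probs):
        recs.setdefault(str(sid), []).append(
            fu.PredictionRecord(str(sid), phase, float(p[1]), float(p[0]))
        )
    return {sid: fu.aggregate_tiles(rs) for sid, rs in recs.items()}


def run_experiment(cfg: ExperimentConfig | None = None) -> dict:
    """One seeded train/test screening experiment on a synthetic cohort.

    The cohort is split 80/20 at subject level (one stratified fold
    held out); all four phase CNNs share that split, their per-subject
    probabilities are fused by soft voting, and pooled metrics plus
    the ROC/AUC of the fused score are reported.
    """
    cfg = cfg or ExperimentConfig()
    samples, _ = generate_cohort(
        cfg.n_per_class, None, image_size=cfg.image_size, seed=cfg.seed
    )
    composites = []
    for i, s in enumerate(samples):
        sid = f"{s.label.lower()}_{i:03d}"
        composites.append(
            preprocess_image(
                s.image,
                window_px=cfg.equalize_window,
                clip_limit=cfg.clip_limit,
                ggmrf=cfg.ggmrf,
                mgrf=cfg.mgrf,
                subject_id=sid,
                label=s.label,
            )
        )

    subj_ids = [c.subject_id for c in composites]
    subj_labels = np.asarray([c.label for c in composites])
    folds = fu.stratified_kfold(subj_labels, k=cfg.test_frac_folds, seed=cfg.seed)
    test_subjects = {subj_ids[i] for i in np.flatnonzero(folds == 0)}

    datasets = build_phase_datasets(composites, cfg.levels)
    phase_metrics: dict[str, fu.MetricsReport] = {}
    phase_records_test: dict[str, dict[str, fu.PredictionRecord]] = {}
    curves: dict[str, dict] = {}
    for lv in cfg.levels:
        d = datasets[lv]
        in_test = np.asarray([sid in test_subjects for sid in d["sid"]])
        spec = fit_spec_for_side(d["x"].shape[1], dropout_rate=cfg.dropout_rate)
        tcfg = TrainConfig(
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            dropout_rate=cfg.dropout_rate,
            seed=cfg.seed,
            augmentation=cfg.augmentation,
        )
        trained = train_phase(d["x"][~in_test], d["y"][~in_test], spec, tcfg)
        curves[lv] = trained.curves
        recs = _phase_records(trained, d["x"][in_test], d["sid"][in_test], lv)
        phase_records_test[lv] = recs
        truth = {sid: lbl for sid, lbl in zip(subj_ids, subj_labels)}
        pred_labels = ["DR" if r.prob_dr >= 0.5 else "NDR" for r in recs.values()]
        truth_labels = [truth[sid] for sid in recs]
        phase_metrics[lv] = fu.compute_metrics(
            fu.confusion_from_predictions(pred_labels, truth_labels)
        )

    fused_scores, pred_labels, truth_labels, fused_sids = [], [], [], []
    truth = {sid: lbl for sid, lbl in zip(subj_ids, subj_labels)}
    for sid in sorted(test_subjects):
        per_phase = [phase_records_test[lv][sid] for lv in cfg.levels]
        fused, label = fu.soft_vote(per_phase)
        fused_scores.append(fused.prob_dr)
        pred_labels.append(label)
        truth_labels.append(truth[sid])
        fused_sids.append(sid)
    fused_metrics = fu.compute_metrics(
        fu.confusion_from_predictions(pred_labels, truth_labels)
    )
    auc, roc_points = fu.roc_auc(fused_scores, truth_labels)
    fused_metrics.auc = 100.0 * auc
    fused_metrics.roc_points = roc_points

    return {
        "phase_metrics": phase_metrics,
        "fused_metrics": fused_metrics,
        "curves": curves,
        "test_subjects": sorted(test_subjects),
        "fused_scores": dict(zip(fused_sids, fused_scores)),
        "config": cfg,
    }
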