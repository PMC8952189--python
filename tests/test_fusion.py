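"""Soft voting, metrics, ROC/AUC and the cross-validation harness."""

import numpy as np
import pytest

from octadr.fusion import (
    ConfusionCounts,
    PredictionRecord,
    aggregate_tiles,
    balanced_accuracy,
    cohens_kappa,
    compute_metrics,
    confusion_from_predictions,
    crossvalidate,
    roc_auc,
    soft_vote,
    stratified_kfold,
)


def _rec(pd, phase="full", sid="s1"):
    return PredictionRecord(sid, phase, pd, 1.0 - pd)


def test_record_probabilities_must_sum_to_one():
    with pytest.raises(ValueError):
        PredictionRecord("s", "full", 0.7, 0.7)


def test_aggregate_tiles():
    assert aggregate_tiles([_rec(0.8)]).prob_dr == pytest.approx(0.8)
    assert aggregate_tiles([_rec(1.0), _rec(0.0)]).prob_dr == pytest.approx(0.5)
    sixteen = [_rec(k / 16) for k in range(16)]
    assert aggregate_tiles(sixteen).prob_dr == pytest.approx(0.46875)
    with pytest.raises(ValueError):
        aggregate_tiles([_rec(0.5, sid="a"), _rec(0.5, sid="b")])


def test_soft_vote_hand_values_and_tie_rule():
    fused, label = soft_vote([_rec(p, ph) for p, ph in
                              zip((0.9, 0.8, 0.6, 0.7), ("full", "quarters", "sixteenths", "fovea"))])
    assert fused.prob_dr == pytest.approx(0.75)
    assert label == "DR"
    fused, label = soft_vote([_rec(0.5)])
    assert label == "DR"  # documented tie rule: screening favours sensitivity
    _, label = soft_vote([_rec(0.2), _rec(0.3, "fovea")])
    assert label == "NDR"


def test_soft_vote_order_invariance(rng):
    ps = rng.random(4)
    recs = [_rec(p, ph) for p, ph in zip(ps, ("full", "quarters", "sixteenths", "fovea"))]
    a, _ = soft_vote(recs)
    b, _ = soft_vote(recs[::-1])
    assert a.prob_dr == pytest.approx(b.prob_dr)


def test_tile_then_phase_mean_equals_pooled_mean(rng):
    """Unweighted means commute: fusing tile averages = averaging everything."""
    tiles = {ph: rng.random(4) for ph in ("full", "quarters")}
    phase_recs = [aggregate_tiles([_rec(p, ph) for p in v]) for ph, v in tiles.items()]
    fused, _ = soft_vote(phase_recs)
    pooled = np.mean([v.mean() for v in tiles.values()])
    assert fused.prob_dr == pytest.approx(pooled)


def test_metrics_hand_arithmetic():
    r = compute_metrics(ConfusionCounts(tp=11, fn=1, tn=6, fp=0))
    assert r.accuracy == pytest.approx(94.4, abs=0.05)
    assert r.sensitivity == pytest.approx(91.7, abs=0.05)
    assert r.specificity == pytest.approx(100.0)
    assert r.f1 == pytest.approx(95.65, abs=0.01)
    r2 = compute_metrics(ConfusionCounts(tp=10, fn=1, tn=6, fp=1))
    assert r2.sensitivity == pytest.approx(90.9, abs=0.05)
    assert r2.specificity == pytest.approx(85.7, abs=0.05)
    assert r2.f1 == pytest.approx(90.9, abs=0.05)
    perfect = compute_metrics(ConfusionCounts(tp=1, fn=0, tn=1, fp=0))
    assert perfect.accuracy == perfect.sensitivity == perfect.specificity == 100.0


def test_metrics_undefined_flagged_not_zero():
    r = compute_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
    assert r.sensitivity is None and "sensitivity" in r.undefined
    assert r.precision is None and "precision" in r.undefined
    with pytest.raises(ValueError):
        compute_metrics(ConfusionCounts())


def test_metrics_match_brute_force_recount(rng):
    for _ in range(25):
        n = int(rng.integers(4, 60))
        truth = rng.choice(["DR", "NDR"], n)
        pred = rng.choice(["DR", "NDR"], n)
        c = confusion_from_predictions(pred, truth)
        tp = sum(p == t == "DR" for p, t in zip(pred, truth))
        tn = sum(p == t == "NDR" for p, t in zip(pred, truth))
        assert (c.tp, c.tn) == (tp, tn)
        assert c.total == n
        r = compute_metrics(c)
        assert r.accuracy == pytest.approx(100.0 * np.mean(pred == truth))


def test_balanced_accuracy_and_kappa():
    c = ConfusionCounts(tp=8, fn=2, tn=6, fp=4)
    assert balanced_accuracy(c) == pytest.approx(100.0 * (0.8 + 0.6) / 2)
    k = cohens_kappa(c)
    po = 14 / 20
    pe = (12 / 20) * (10 / 20) + (8 / 20) * (10 / 20)
    assert k == pytest.approx((po - pe) / (1 - pe))


def _pairwise_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == "DR"]
    neg = [s for s, l in zip(scores, labels) if l == "NDR"]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


def test_auc_trivial_cases():
    auc, pts = roc_auc([0.9, 0.8, 0.2, 0.1], ["DR", "DR", "NDR", "NDR"])
    assert auc == pytest.approx(1.0)
    assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
    auc, pts = roc_auc([0.5] * 6, ["DR", "NDR"] * 3)
    assert auc == pytest.approx(0.5)
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.9], ["DR", "DR"])


def test_auc_matches_pairwise_oracle_and_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    hand_scores = [0.9, 0.7, 0.7, 0.4, 0.3, 0.1]
    hand_labels = ["DR", "NDR", "DR", "DR", "NDR", "NDR"]
    auc, _ = roc_auc(hand_scores, hand_labels)
    assert auc == pytest.approx(_pairwise_auc(hand_scores, hand_labels))
    for _ in range(20):
        n = int(rng.integers(6, 100))
        labels = ["DR"] * (n // 2) or ["DR"]
        labels = ["DR" if rng.random() < 0.5 else "NDR" for _ in range(n)]
        if len(set(labels)) < 2:
            continue
        scores = np.round(rng.random(n), 2)  # rounded -> plenty of ties
        auc, pts = roc_auc(scores, labels)
        assert auc == pytest.approx(_pairwise_auc(scores, labels))
        assert auc == pytest.approx(
            roc_auc_score([1 if l == "DR" else 0 for l in labels], scores)
        )
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        assert all(a <= b + 1e-12 for a, b in zip(xs, xs[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(ys, ys[1:]))


def test_stratified_kfold_partition_and_determinism():
    labels = ["DR"] * 25 + ["NDR"] * 25
    f1 = stratified_kfold(labels, k=5, seed=9)
    f2 = stratified_kfold(labels, k=5, seed=9)
    np.testing.assert_array_equal(f1, f2)
    for f in range(5):
        assert (f1 == f).sum() == 10
        assert (f1[:25] == f).sum() == 5  # stratified within each class
    with pytest.raises(ValueError, match="k <= 3"):
        stratified_kfold(["DR"] * 3 + ["NDR"] * 10, k=5)


def test_crossvalidate_harness_partition_and_fusion():
    """Every subject is tested exactly once; phase records are fused."""
    sids = [f"s{i}" for i in range(20)]
    labels = ["DR"] * 10 + ["NDR"] * 10
    tested: list[int] = []
    seen_test_sets = []

    def trainer(train_idx, test_idx):
        tested.extend(test_idx.tolist())
        seen_test_sets.append(tuple(sorted(test_idx.tolist())))
        out = {}
        for i in test_idx:
            p = 0.9 if labels[i] == "DR" else 0.1
            out[sids[i]] = {
                ph: PredictionRecord(sids[i], ph, p, 1 - p)
                for ph in ("full", "quarters", "sixteenths", "fovea")
            }
        return out

    res = crossvalidate(sids, labels, trainer, k=5, seed=1)
    assert sorted(tested) == list(range(20))  # each subject in exactly one test fold
    assert len(seen_test_sets) == len(set(seen_test_sets)) == 5
    assert res["pooled"].accuracy == pytest.approx(100.0)
    assert res["pooled"].auc == pytest.approx(100.0)
    assert len(res["per_fold"]) == 5
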