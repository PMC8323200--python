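import numpy as np
import pytest

from capsicd.metrics import (
    FrequencyBins,
    compute_report,
    error_breakdown,
    label_auc,
    macro_auc_by_group,
    macro_f1,
    micro_f1,
    top10_recall,
)


def counting_f1_oracle(gold, pred):
    """Cell-by-cell confusion counting with plain loops."""
    n, L = gold.shape
    tp = fp = fn = 0
    per_label = []
    for j in range(L):
        tpj = fpj = fnj = 0
        for i in range(n):
            if gold[i][j] and pred[i][j]:
                tpj += 1
            elif pred[i][j] and not gold[i][j]:
                fpj += 1
            elif gold[i][j] and not pred[i][j]:
                fnj += 1
        tp, fp, fn = tp + tpj, fp + fpj, fn + fnj
        denom = 2 * tpj + fpj + fnj
        per_label.append(2 * tpj / denom if denom else 0.0)
    micro = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return micro, sum(per_label) / L


def pairwise_auc_oracle(scores, gold):
    """All-pairs comparison AUC (ties count half)."""
    pos = [s for s, g in zip(scores, gold) if g]
    neg = [s for s, g in zip(scores, gold) if not g]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# -- F1 ----------------------------------------------------------------------


def test_perfect_prediction_scores_one():
    gold = np.array([[1, 0], [0, 1]])
    assert micro_f1(gold, gold) == 1.0
    assert macro_f1(gold, gold) == 1.0


def test_half_overlap_micro():
    gold = np.array([[1, 1, 0, 0]])
    pred = np.array([[1, 0, 1, 0]])
    assert micro_f1(gold, pred) == pytest.approx(0.5)  # 2*1/(2*1+1+1)


def test_f1_shape_mismatch():
    with pytest.raises(ValueError):
        micro_f1(np.zeros((2, 3)), np.zeros((3, 2)))


def test_f1_matches_counting_oracle_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(50):
        gold = (rng.random((20, 10)) < 0.3).astype(float)
        pred = (rng.random((20, 10)) < 0.3).astype(float)
        mic, mac = counting_f1_oracle(gold, pred)
        assert micro_f1(gold, pred) == pytest.approx(mic, abs=1e-12)
        assert macro_f1(gold, pred) == pytest.approx(mac, abs=1e-12)


def test_micro_f1_row_permutation_invariance():
    rng = np.random.default_rng(1)
    gold = (rng.random((15, 6)) < 0.4).astype(float)
    pred = (rng.random((15, 6)) < 0.4).astype(float)
    perm = rng.permutation(15)
    assert micro_f1(gold[perm], pred[perm]) == pytest.approx(micro_f1(gold, pred))


def test_label_permutation_leaves_all_metrics_unchanged():
    rng = np.random.default_rng(2)
    gold = (rng.random((30, 8)) < 0.3).astype(float)
    scores = rng.random((30, 8))
    pred = (scores >= 0.5).astype(float)
    perm = rng.permutation(8)
    assert micro_f1(gold[:, perm], pred[:, perm]) == pytest.approx(micro_f1(gold, pred))
    assert macro_f1(gold[:, perm], pred[:, perm]) == pytest.approx(macro_f1(gold, pred))
    assert top10_recall(scores[:, perm], gold[:, perm], k=3) == pytest.approx(
        top10_recall(scores, gold, k=3)
    )


# -- top-10 recall -----------------------------------------------------------


def test_full_recall_note_contributes_one():
    scores = np.array([[0.9, 0.8, 0.7, 0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]])
    gold = np.zeros((1, 12))
    gold[0, :3] = 1
    assert top10_recall(scores, gold) == 1.0


def test_recall_uses_max_of_ten_and_gold_count():
    # |M| = 12 > 10: the cut is the top 12; exactly 6 gold codes inside it
    L = 24
    scores = np.linspace(1.0, 0.0, L)[None, :]
    gold = np.zeros((1, L))
    gold[0, :6] = 1  # inside top 12
    gold[0, 18:] = 1  # outside top 12
    assert top10_recall(scores, gold) == pytest.approx(0.5)


def test_constant_scores_follow_label_order_tie_break():
    L = 15
    scores = np.full((1, L), 0.4)
    gold = np.zeros((1, L))
    gold[0, [0, 5, 12]] = 1  # labels 0 and 5 fall in the top-10 by order
    assert top10_recall(scores, gold) == pytest.approx(2.0 / 3.0)


def test_recall_invariant_to_monotone_transforms():
    rng = np.random.default_rng(3)
    scores = rng.random((20, 15))
    gold = (rng.random((20, 15)) < 0.25).astype(float)
    gold[gold.sum(axis=1) == 0, 0] = 1
    base = top10_recall(scores, gold)
    for f in (lambda s: 2 * s + 1, lambda s: s**3, np.tanh):
        assert top10_recall(f(scores), gold) == pytest.approx(base, abs=1e-12)


def test_empty_gold_rows_are_excluded_with_warning(caplog):
    scores = np.array([[0.9, 0.1], [0.2, 0.8]])
    gold = np.array([[1.0, 0.0], [0.0, 0.0]])
    with caplog.at_level("WARNING"):
        val = top10_recall(scores, gold)
    assert val == 1.0
    assert "skipped 1" in caplog.text


# -- AUC ---------------------------------------------------------------------


def test_perfect_separation_auc_one():
    scores = np.array([[0.9], [0.8], [0.2], [0.1]])
    gold = np.array([[1], [1], [0], [0]], dtype=float)
    assert label_auc(scores, gold)[0] == pytest.approx(1.0)


def test_auc_matches_pairwise_oracle():
    rng = np.random.default_rng(4)
    scores = rng.random((40, 10))
    gold = (rng.random((40, 10)) < 0.4).astype(float)
    gold[0] = 1  # ensure both classes exist per label
    gold[1] = 0
    aucs = label_auc(scores, gold)
    for j in range(10):
        assert aucs[j] == pytest.approx(
            pairwise_auc_oracle(scores[:, j], gold[:, j]), abs=1e-12
        )


def test_random_scores_auc_near_half():
    rng = np.random.default_rng(5)
    scores = rng.random((4000, 1))
    gold = (rng.random((4000, 1)) < 0.5).astype(float)
    assert label_auc(scores, gold)[0] == pytest.approx(0.5, abs=0.03)


def test_complementing_scores_flips_auc():
    rng = np.random.default_rng(6)
    scores = rng.random((50, 3))
    gold = (rng.random((50, 3)) < 0.5).astype(float)
    gold[0] = 1
    gold[1] = 0
    np.testing.assert_allclose(
        label_auc(1 - scores, gold), 1 - label_auc(scores, gold), atol=1e-12
    )


def test_auc_monotone_transform_invariance():
    rng = np.random.default_rng(7)
    scores = rng.random((30, 2))
    gold = (rng.random((30, 2)) < 0.5).astype(float)
    gold[0] = 1
    gold[1] = 0
    np.testing.assert_allclose(label_auc(scores**3, gold), label_auc(scores, gold), atol=1e-12)


def test_macro_auc_by_group_binning_and_skips(caplog):
    rng = np.random.default_rng(8)
    scores = rng.random((30, 4))
    gold = (rng.random((30, 4)) < 0.5).astype(float)
    gold[0] = 1
    gold[1] = 0
    gold[:, 3] = 1.0  # constant column: skipped
    counts = [5, 60, 60, 200]
    with caplog.at_level("WARNING"):
        groups = macro_auc_by_group(scores, gold, counts)
    aucs = label_auc(scores, gold)
    assert groups["[1,10]"] == pytest.approx(aucs[0])
    assert groups["[51,100]"] == pytest.approx(np.mean(aucs[1:3]))
    assert "[101,inf]" not in groups  # its only label was skipped
    assert "[11,50]" not in groups  # empty group absent, not zero
    assert "skipped 1" in caplog.text


def test_frequency_bins_validation():
    with pytest.raises(ValueError):
        FrequencyBins(edges=((1, 10), (10, 50), (51, float("inf"))))  # overlap at 10
    with pytest.raises(ValueError):
        FrequencyBins(edges=((1, 10), (11, 50)))  # not open-ended
    bins = FrequencyBins()
    assert bins.assign(100) == "[51,100]"
    assert bins.assign(101) == "[101,inf]"


# -- error breakdown ---------------------------------------------------------


def test_error_breakdown_zero_when_perfect():
    gold = np.array([[1, 0], [0, 1]], dtype=float)
    out = error_breakdown(gold, gold, [10, 10], labels=["007", "008"])
    assert all(v["fp"] == 0 and v["fn"] == 0 for v in out["per_label"].values())
    assert out["confused_pairs"] == []


def test_error_breakdown_flags_similar_code_confusion():
    # gold 007 predicted as the similar, more frequent 008
    gold = np.array([[1, 0]], dtype=float)
    pred = np.array([[0, 1]], dtype=float)
    out = error_breakdown(gold, pred, [19, 579], labels=["007", "008"])
    assert out["per_label"]["008"]["fp"] == 1
    assert out["per_label"]["007"]["fn"] == 1
    assert out["confused_pairs"][0] == {"predicted": "008", "gold": "007", "count": 1}


def test_error_breakdown_matches_counting_oracle():
    rng = np.random.default_rng(9)
    gold = (rng.random((25, 6)) < 0.3).astype(float)
    pred = (rng.random((25, 6)) < 0.3).astype(float)
    labels = [f"{j:03d}" for j in range(6)]
    out = error_breakdown(gold, pred, [10] * 6, labels=labels)
    for j, lab in enumerate(labels):
        fp = sum(1 for i in range(25) if pred[i][j] and not gold[i][j])
        fn = sum(1 for i in range(25) if gold[i][j] and not pred[i][j])
        assert out["per_label"][lab] == {
            "fp": fp, "fn": fn, "train_count": 10, "group": "[1,10]",
        }


# -- full report -------------------------------------------------------------


def test_compute_report_is_serializable_and_consistent():
    rng = np.random.default_rng(10)
    scores = rng.random((20, 5))
    gold = (rng.random((20, 5)) < 0.4).astype(float)
    gold[gold.sum(axis=1) == 0, 0] = 1
    report = compute_report(scores, gold, [5, 20, 60, 120, 7], threshold=0.5,
                            labels=[f"{j:03d}" for j in range(5)])
    pred = (scores >= 0.5).astype(float)
    assert report.micro_f1 == pytest.approx(micro_f1(gold, pred))
    assert report.decision_policy == {"policy": "threshold", "tau": 0.5}
    import json

    parsed = json.loads(report.to_json())
    assert parsed["n_notes"] == 20
    assert "micro F1" in report.table()


def test_macro_equals_micro_under_identical_label_confusions():
    # every label: 2 TP, 1 FP, 1 FN
    gold = np.array([[1, 1], [1, 1], [1, 1], [0, 0]], dtype=float)
    pred = np.array([[1, 1], [1, 1], [0, 0], [1, 1]], dtype=float)
    assert macro_f1(gold, pred) == pytest.approx(micro_f1(gold, pred))
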