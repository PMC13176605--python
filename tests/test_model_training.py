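"""Fusion layout, classifier head, fold construction, early stopping, and
metric reporting."""

import numpy as np
import pytest

from pathddi import nn
from pathddi.config import RunConfig
from pathddi.io import DDITable
from pathddi.model import DDIModel, VARIANT_BLOCKS, fuse, fused_width
from pathddi.training import (EarlyStopper, make_folds, metric_report)


# -- fusion -------------------------------------------------------------------


def test_fused_width_formula():
    # the published configuration: d_model=128, K*d'=64, d_kg=20 -> D=424
    cfg = RunConfig(L=128, d_emb=128, d_model=128, n_layers=2, n_head=4,
                    d_ff=256, K_heads=4, d_prime=16, d_kg=20)
    assert fused_width(cfg) == 2 * (128 + 64 + 20) == 424
    assert fused_width(RunConfig()) == 2 * (32 + 16 + 20)
    assert fused_width(RunConfig(ablation="transformer")) == 2 * 32
    assert fused_width(RunConfig(ablation="kg-rw")) == 2 * 20 == 40
    assert VARIANT_BLOCKS["full"] == ("trans", "gat", "kg")


def test_fuse_order_and_swap_sensitivity():
    rng = np.random.default_rng(0)
    reps_a = {b: nn.Tensor(rng.normal(size=4)) for b in ("trans", "gat", "kg")}
    reps_b = {b: nn.Tensor(rng.normal(size=4)) for b in ("trans", "gat", "kg")}
    x_ab = fuse(reps_a, reps_b).data
    x_ba = fuse(reps_b, reps_a).data
    assert x_ab.shape == (24,)
    np.testing.assert_array_equal(x_ab[:12], np.concatenate(
        [reps_a["trans"].data, reps_a["gat"].data, reps_a["kg"].data]))
    assert not np.array_equal(x_ab, x_ba)
    np.testing.assert_array_equal(np.sort(x_ab), np.sort(x_ba))
    zeros = {b: nn.Tensor(np.zeros(4)) for b in ("trans", "gat", "kg")}
    np.testing.assert_array_equal(fuse(zeros, zeros).data, np.zeros(24))


def test_head_softmax_is_a_probability_vector(tiny_cfg):
    rng = np.random.default_rng(1)
    model = DDIModel(tiny_cfg, vocab_size=10, n_classes=5, rng=rng)
    model.eval()
    x = nn.Tensor(rng.normal(size=(7, fused_width(tiny_cfg))))
    p = nn.softmax(model.head(x), axis=-1).data
    assert (p >= 0).all()
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_binary_mode_two_logit_softmax(tiny_cfg):
    cfg = RunConfig(**{**tiny_cfg.to_dict(), "task_mode": "binary"})
    model = DDIModel(cfg, vocab_size=10, n_classes=7, rng=np.random.default_rng(2))
    assert model.n_classes == 2
    model.eval()
    p = nn.softmax(model.head(nn.Tensor(np.zeros((1, fused_width(cfg))))),
                   axis=-1).data
    assert p.shape == (1, 2)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)


# -- folds --------------------------------------------------------------------


def balanced_ddi(n_classes=5, per_class=20):
    records = []
    k = 0
    for c in range(n_classes):
        for _ in range(per_class):
            records.append((f"d{k}", f"d{k+1}", c))
            k += 1
    return DDITable(records)


def test_stratified_folds_preserve_class_counts():
    ddi = balanced_ddi(5, 20)     # 100 pairs, 5 classes x 20, k=5
    plan = make_folds(ddi, k=5, mode="pair-stratified", rng_seed=0)
    labels = ddi.labels
    seen = np.zeros(len(ddi), dtype=int)
    for _, test_idx in plan.folds:
        seen[test_idx] += 1
        counts = np.bincount(labels[test_idx], minlength=5)
        assert (counts == 4).all()
    assert (seen == 1).all()      # every pair in exactly one test fold


def test_stratified_folds_tolerate_rare_classes():
    records = balanced_ddi(3, 10).records + [("x1", "x2", 9), ("x2", "x3", 9)]
    plan = make_folds(DDITable(records), k=5, mode="pair-stratified",
                      rng_seed=1)
    assert plan.merged_classes == [9]
    labels = DDITable(records).labels
    for _, test_idx in plan.folds:
        counts = np.bincount(labels[test_idx], minlength=10)
        assert abs(counts[0] - 2) <= 1


def test_drug_disjoint_certificate_is_zero():
    rng = np.random.default_rng(3)
    drugs = [f"d{i}" for i in range(10)]
    records = []
    for _ in range(60):
        a, b = rng.choice(10, size=2, replace=False)
        records.append((drugs[a], drugs[b], int(rng.integers(2))))
    ddi = DDITable(records)
    plan = make_folds(ddi, k=3, mode="drug-disjoint", rng_seed=4)
    assert plan.overlap_certificate(ddi) == [0] * 3
    for train_idx, test_idx in plan.folds:
        train_drugs = {d for i in train_idx for d in ddi.records[i][:2]}
        test_drugs = {d for i in test_idx for d in ddi.records[i][:2]}
        assert not train_drugs & test_drugs


def test_fold_plans_are_seed_deterministic():
    ddi = balanced_ddi(4, 8)
    for mode in ("pair-stratified", "drug-disjoint"):
        p1 = make_folds(ddi, k=4, mode=mode, rng_seed=7)
        p2 = make_folds(ddi, k=4, mode=mode, rng_seed=7)
        for (a1, b1), (a2, b2) in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(a1, a2)
            np.testing.assert_array_equal(b1, b2)
    with pytest.raises(ValueError):
        make_folds(ddi, k=1)


# -- early stopping -----------------------------------------------------------


def test_early_stopping_halts_at_patience_10():
    stopper = EarlyStopper(patience=10)
    trace = [0.5, 0.6] + [0.6] * 10
    stops = [stopper.update(v) for v in trace]
    assert stops == [False] * 11 + [True]    # halt exactly at epoch 12
    assert stopper.best_epoch == 2
    assert stopper.epoch == 12


def test_early_stopping_never_fires_while_improving():
    stopper = EarlyStopper(patience=10)
    assert not any(stopper.update(v) for v in np.linspace(0.1, 0.9, 50))
    assert stopper.best_epoch == 50


# -- metric reporting ---------------------------------------------------------


def proba_from_predictions(pred, n_classes):
    p = np.full((len(pred), n_classes), 0.01)
    p[np.arange(len(pred)), pred] = 1.0
    return p / p.sum(axis=1, keepdims=True)


def test_metric_report_hand_computed_confusion():
    # confusion [[8, 2], [3, 7]]: acc 15/20, precision (8/11, 7/9)
    y_true = np.array([0] * 10 + [1] * 10)
    y_pred = np.array([0] * 8 + [1] * 2 + [0] * 3 + [1] * 7)
    report = metric_report(y_true, proba_from_predictions(y_pred, 2), 2)
    assert report["accuracy"] == pytest.approx(0.75)
    assert report["confusion"] == [[8, 2], [3, 7]]
    assert report["per_class"][0]["precision"] == pytest.approx(8 / 11)
    assert report["per_class"][1]["precision"] == pytest.approx(7 / 9)
    assert report["roc_auc"] is not None


def test_metric_report_perfect_predictions():
    y = np.array([0, 1, 2, 1, 0])
    report = metric_report(y, proba_from_predictions(y, 3), 3)
    assert report["accuracy"] == 1.0
    assert report["macro"]["f1"] == 1.0
    assert all(row["f1"] == 1.0 for row in report["per_class"])


def test_metric_report_flags_absent_classes():
    y_true = np.zeros(6, dtype=int)
    report = metric_report(y_true, proba_from_predictions(y_true, 3), 3)
    flags = [row["absent_from_test"] for row in report["per_class"]]
    assert flags == [False, True, True]
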