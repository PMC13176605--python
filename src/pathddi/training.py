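"""Cross-validation, early stopping, training, and metric reporting.

Two split modes:

* ``pair-stratified`` — stratified k-fold over interaction pairs, preserving
  per-class proportions (classes with fewer than k members are pooled into a
  reported remainder stratum for splitting purposes only);
* ``drug-disjoint`` — drugs are partitioned into k groups; fold i trains on
  pairs whose drugs both lie outside group i and tests exclusively on pairs
  whose drugs both lie inside it, so train and test share no drugs.  The
  zero-overlap certificate is recorded per fold.

Training minimizes cross-entropy with Adam and halts once validation
accuracy has not improved for ``patience`` consecutive epochs; the
checkpoint from the best validation epoch is retained.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)

from . import nn
from .config import RunConfig
from .io import DDITable
from .model import DDIModel, DrugBatch


# ---------------------------------------------------------------------------
# fold construction


@dataclass
class FoldPlan:
    mode: str
    folds: list[tuple[np.ndarray, np.ndarray]]   # (train_idx, test_idx)
    merged_classes: list[int] = field(default_factory=list)
    drug_partition: dict[str, int] | None = None

    def overlap_certificate(self, ddi: DDITable) -> list[int]:
        """Per fold, |train-pair drugs  ∩  test-pair drugs| (drug-disjoint
        mode must certify zero)."""
        out = []
        for train_idx, test_idx in self.folds:
            train_drugs = {d for i in train_idx
                           for d in ddi.records[i][:2]}
            test_drugs = {d for i in test_idx
                          for d in ddi.records[i][:2]}
            out.append(len(train_drugs & test_drugs))
        return out


def make_folds(ddi: DDITable, k: int = 5, mode: str = "pair-stratified",
               rng_seed: int = 0) -> FoldPlan:
    if k < 2:
        raise ValueError("fold count k must be >= 2")
    if mode == "pair-stratified":
        labels = ddi.labels.copy()
        uniq, counts = np.unique(labels, return_counts=True)
        rare = [int(c) for c, n in zip(uniq, counts) if n < k]
        strat = labels.copy()
        if rare:
            # pooled remainder stratum; the labels themselves are untouched
            sentinel = labels.max() + 1
            strat[np.isin(labels, rare)] = sentinel
            if (strat == sentinel).sum() < k:
                # remainder itself too small: merge into the largest class
                strat[strat == sentinel] = uniq[np.argmax(counts)]
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
        folds = [(tr.astype(int), te.astype(int))
                 for tr, te in skf.split(np.zeros(len(labels)), strat)]
        return FoldPlan(mode=mode, folds=folds, merged_classes=rare)
    if mode == "drug-disjoint":
        drugs = sorted(ddi.drugs())
        rng = np.random.default_rng(rng_seed)
        assignment = {d: int(g) for d, g in
                      zip(drugs, rng.integers(0, k, size=len(drugs)))}
        folds = []
        for g in range(k):
            test = np.array([i for i, (a, b, _) in enumerate(ddi.records)
                             if assignment[a] == g and assignment[b] == g],
                            dtype=int)
            train = np.array([i for i, (a, b, _) in enumerate(ddi.records)
                              if assignment[a] != g and assignment[b] != g],
                             dtype=int)
            folds.append((train, test))
        return FoldPlan(mode=mode, folds=folds, drug_partition=assignment)
    raise ValueError(f"unknown split mode {mode!r}")


# ---------------------------------------------------------------------------
# early stopping


class EarlyStopper:
    """Stop after `patience` consecutive epochs without a new best value."""

    def __init__(self, patience: int = 10):
        self.patience = patience
        self.best_value = -np.inf
        self.best_epoch = 0
        self.epoch = 0
        self._since_best = 0

    def update(self, value: float) -> bool:
        """Record one epoch's validation score; True means halt now."""
        self.epoch += 1
        if value > self.best_value:
            self.best_value = value
            self.best_epoch = self.epoch
            self._since_best = 0
            return False
        self._since_best += 1
        return self._since_best >= self.patience


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainResult:
    checkpoint: list[np.ndarray]
    history: list[dict]
    best_epoch: int
    stopped_early: bool

    def write_history_csv(self, path) -> None:
        if not self.history:
            return
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(self.history[0]))
            writer.writeheader()
            writer.writerows(self.history)


def _accuracy(model: DDIModel, batch: DrugBatch, pairs, labels) -> float:
    proba = model.predict_proba(batch, pairs[:, 0], pairs[:, 1])
    return float(accuracy_score(labels, proba.argmax(axis=1)))


def train_fold(model: DDIModel, batch: DrugBatch,
               train_pairs: np.ndarray, train_labels: np.ndarray,
               val_pairs: np.ndarray, val_labels: np.ndarray,
               cfg: RunConfig, rng: np.random.Generator) -> TrainResult:
    """Adam + cross-entropy with patience-based early stopping.

    ``train_pairs`` is (n, 2) drug-index pairs; the model encodes the drug
    batch afresh each step so encoder gradients flow from every pair.
    """
    if len(train_pairs) == 0:
        raise ValueError("empty training set")
    optimizer = nn.Adam(model.parameters(), lr=cfg.lr)
    stopper = EarlyStopper(patience=cfg.patience)
    best_state = model.get_state()
    history = []
    stopped = False
    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(len(train_pairs))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.logits(batch, train_pairs[idx, 0],
                                  train_pairs[idx, 1])
            loss = nn.cross_entropy(logits, train_labels[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        val_acc = _accuracy(model, batch, val_pairs, val_labels)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_acc": val_acc,
        })
        if val_acc > stopper.best_value:
            best_state = model.get_state()
        if stopper.update(val_acc):
            stopped = True
            break
    model.set_state(best_state)
    return TrainResult(checkpoint=best_state, history=history,
                       best_epoch=stopper.best_epoch, stopped_early=stopped)


# ---------------------------------------------------------------------------
# evaluation


def evaluate(model: DDIModel, batch: DrugBatch, test_pairs: np.ndarray,
             test_labels: np.ndarray, n_classes: int) -> dict:
    """Accuracy, weighted and macro precision/recall/F1, and a per-class
    table; binary mode adds ROC-AUC and PR-AUC.  Classes absent from the
    test set are flagged rather than silently scored 0."""
    if len(test_pairs) == 0:
        raise ValueError("empty test set")
    proba = model.predict_proba(batch, test_pairs[:, 0], test_pairs[:, 1])
    return metric_report(test_labels, proba, n_classes)


def metric_report(test_labels: np.ndarray, proba: np.ndarray,
                  n_classes: int) -> dict:
    pred = proba.argmax(axis=1)
    labels = np.arange(n_classes)
    report: dict = {"accuracy": float(accuracy_score(test_labels, pred))}
    for avg in ("weighted", "macro"):
        p, r, f, _ = precision_recall_fscore_support(
            test_labels, pred, average=avg, labels=labels, zero_division=0
        )
        report[avg] = {"precision": float(p), "recall": float(r),
                       "f1": float(f)}
    p, r, f, support = precision_recall_fscore_support(
        test_labels, pred, average=None, labels=labels, zero_division=0
    )
    report["per_class"] = [
        {"label": int(c), "precision": float(p[i]), "recall": float(r[i]),
         "f1": float(f[i]), "support": int(support[i]),
         "absent_from_test": bool(support[i] == 0)}
        for i, c in enumerate(labels)
    ]
    report["confusion"] = confusion_matrix(
        test_labels, pred, labels=labels
    ).tolist()
    if n_classes == 2:
        scores = proba[:, 1]
        if len(np.unique(test_labels)) == 2:
            report["roc_auc"] = float(roc_auc_score(test_labels, scores))
            report["pr_auc"] = float(
                average_precision_score(test_labels, scores)
            )
        else:
            report["roc_auc"] = report["pr_auc"] = None
    return report
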