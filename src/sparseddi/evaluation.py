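"""Ranking metrics and the stratified cross-validation protocol.

Hyperedges are split into ``k`` folds balanced per side effect; each fold
is held out in turn, a model is fitted on the remaining folds, and the
held-out positives are ranked against uniformly sampled non-edge
negatives (disjoint from *all* known positives) at ``eval_neg_ratio``
negatives per positive.  AUC (rank-based, ties averaged) and AUPR
(average precision) are pooled over all test triples within a fold
(micro); a per-side-effect macro average is available as an option.
The across-fold mean and standard deviation are reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .hypergraph import (DDIHypergraph, DrugFeatureMatrix, stratified_kfold)
from .objective import sample_negative_triples
from .training import TrainConfig, fit, predict_scores

__all__ = ["auc", "aupr", "cross_validate", "CrossValidationResult"]


def _check_two_classes(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("metrics need both positive and negative labels")


def auc(scores, labels) -> float:
    """Area under the ROC curve (probability a random positive outranks a
    random negative; ties count one half)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores, labels) -> float:
    """Area under the precision–recall curve (average precision)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, float)))


@dataclass
class CrossValidationResult:
    per_fold: pd.DataFrame  # columns: fold, n_test_pos, auc, aupr
    auc_mean: float
    auc_std: float
    aupr_mean: float
    aupr_std: float

    def summary(self) -> dict:
        return {"auc_mean": self.auc_mean, "auc_std": self.auc_std,
                "aupr_mean": self.aupr_mean, "aupr_std": self.aupr_std,
                "k": int(len(self.per_fold))}

    def save(self, csv_path, json_path=None) -> None:
        self.per_fold.to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


def cross_validate(G: DDIHypergraph, F_d: DrugFeatureMatrix,
                   config: TrainConfig, k: int = 20,
                   eval_neg_ratio: int = 1, seed: int = 0,
                   per_side_effect: bool = False) -> CrossValidationResult:
    """k-fold cross-validated AUC/AUPR of the configured model variant."""
    folds = stratified_kfold(G, k, seed)
    all_pos = G._edge_set
    rng_eval = np.random.default_rng(np.random.SeedSequence(
        entropy=(seed, 0xe7a1)))
    rows = []
    for fold_id, test_idx in enumerate(folds):
        train_mask = np.ones(G.n_edges, dtype=bool)
        train_mask[test_idx] = False
        G_train = G.restrict_edges(np.where(train_mask)[0])
        fold_cfg = TrainConfig(**{**config.__dict__,
                                  "seed": (config.seed * 100003 + 7919
                                           * fold_id) % (2 ** 31)})
        model = fit(G_train, F_d, fold_cfg)
        test_pos = G.hyperedges[test_idx]
        neg = sample_negative_triples(G.n_drugs, G.n_side_effects,
                                      eval_neg_ratio * len(test_pos),
                                      rng_eval, all_pos)
        triples = np.vstack([test_pos, neg])
        labels = np.concatenate([np.ones(len(test_pos)),
                                 np.zeros(len(neg))])
        scores = predict_scores(model, triples)
        rows.append({"fold": fold_id, "n_test_pos": int(len(test_pos)),
                     "auc": _fold_metric(auc, scores, labels, triples,
                                         per_side_effect),
                     "aupr": _fold_metric(aupr, scores, labels, triples,
                                          per_side_effect)})
    df = pd.DataFrame(rows)
    return CrossValidationResult(
        df,
        float(df["auc"].mean()), float(df["auc"].std(ddof=1)),
        float(df["aupr"].mean()), float(df["aupr"].std(ddof=1)))


def _fold_metric(metric, scores, labels, triples, per_side_effect) -> float:
    if not per_side_effect:
        return metric(scores, labels)
    vals = []
    for t in np.unique(triples[:, 2]):
        m = triples[:, 2] == t
        if np.unique(labels[m]).size < 2:
            warnings.warn(f"side effect {t} has a single class in this fold; "
                          "skipped in the macro average")
            continue
        vals.append(metric(scores[m], labels[m]))
    return float(np.mean(vals))
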