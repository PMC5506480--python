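"""Multilabel evaluation metrics for annotation completion.

Four headline measures, computed from a real-valued score matrix and a
binary truth matrix of the same shape:

* ``macro_avg_f1`` — F1 per term at a fixed score threshold, averaged
  (unweighted) over terms with at least one true positive.
* ``avg_auc`` — per-term ROC AUC as the Mann-Whitney pair statistic (ties
  count one half), averaged over terms with both classes present.
* ``one_minus_ranking_loss`` — per protein, the fraction of
  (true term, false term) pairs mis-ordered by the scores (ties one half),
  averaged over eligible proteins and subtracted from 1.
* ``fmax`` — the protein-centric CAFA measure: maximum over a threshold
  grid of the harmonic mean of protein-averaged precision and recall.

All functions accept an optional boolean ``mask`` selecting which entries
participate — this is how a temporal split evaluates only the zero-entries
of the training matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError

logger = logging.getLogger(__name__)

FMAX_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


def _check_shapes(scores, truth, mask):
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValidationError(
            f"score shape {scores.shape} != truth shape {truth.shape}"
        )
    if mask is None:
        mask = np.ones(scores.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != scores.shape:
            raise ValidationError("mask shape does not match scores")
    return scores, truth.astype(np.int8), mask


def macro_avg_f1(scores, truth, threshold: float = 0.5, mask=None) -> float:
    """Unweighted mean of per-term F1 at a fixed binarisation threshold.

    Terms with no true positive in *truth* are excluded from the average;
    a term with zero precision+recall contributes F1 = 0.
    """
    if not 0 <= threshold <= 1:
        raise ValidationError("threshold must lie in [0, 1]")
    scores, truth, mask = _check_shapes(scores, truth, mask)
    pred = scores >= threshold
    f1s = []
    for j in range(scores.shape[1]):
        m = mask[:, j]
        t = truth[m, j]
        p = pred[m, j]
        if t.sum() == 0:
            continue
        tp = int(np.sum(p & (t == 1)))
        fp = int(np.sum(p & (t == 0)))
        fn = int(np.sum(~p & (t == 1)))
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    if not f1s:
        raise ValidationError("no term has a positive annotation")
    return float(np.mean(f1s))


def _auc_mann_whitney(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Fraction of (pos, neg) pairs ranked correctly, ties counting half."""
    all_scores = np.concatenate([pos_scores, neg_scores])
    ranks = rankdata(all_scores)  # average ranks handle ties
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def avg_auc(scores, truth, mask=None) -> float:
    """Mean per-term ROC AUC over terms with both a positive and a negative."""
    scores, truth, mask = _check_shapes(scores, truth, mask)
    aucs = []
    skipped = 0
    for j in range(scores.shape[1]):
        m = mask[:, j]
        t = truth[m, j]
        s = scores[m, j]
        n_pos = int(t.sum())
        n_neg = int((t == 0).sum())
        if n_pos == 0 or n_neg == 0:
            skipped += 1
            continue
        aucs.append(_auc_mann_whitney(s[t == 1], s[t == 0]))
    if skipped:
        logger.debug("avg_auc: %d single-class terms excluded", skipped)
    if not aucs:
        raise ValidationError("no term has both classes present")
    return float(np.mean(aucs))


def one_minus_ranking_loss(scores, truth, mask=None) -> float:
    """1 minus the mean per-protein mis-ranking fraction.

    For each protein with at least one true and one false term, the loss is
    the fraction of (true, false) term pairs where the false term scores
    strictly higher (ties count one half).
    """
    scores, truth, mask = _check_shapes(scores, truth, mask)
    losses = []
    for i in range(scores.shape[0]):
        m = mask[i]
        t = truth[i, m]
        s = scores[i, m]
        n_pos = int(t.sum())
        n_neg = int((t == 0).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        # loss = P(neg > pos) + 0.5 P(tie) = 1 - AUC of this row
        losses.append(1.0 - _auc_mann_whitney(s[t == 1], s[t == 0]))
    if not losses:
        raise ValidationError("no protein has both a true and a false term")
    return float(1.0 - np.mean(losses))


def fmax(scores, truth, mask=None, grid=None) -> tuple[float, float]:
    """Protein-centric Fmax over a threshold grid (step 0.01 by default).

    At each threshold tau, precision is averaged over proteins predicting at
    least one term and recall over proteins with at least one true term;
    F(tau) is their harmonic mean.  Returns ``(fmax, threshold)`` with the
    smallest arg-max threshold on ties.
    """
    scores, truth, mask = _check_shapes(scores, truth, mask)
    if grid is None:
        grid = FMAX_GRID
    row_has_truth = [(truth[i, mask[i]] == 1).any() for i in range(scores.shape[0])]
    if not any(row_has_truth):
        raise ValidationError("truth matrix has no positive annotation")
    best_f, best_tau = 0.0, float(grid[0])
    for tau in grid:
        precisions, recalls = [], []
        for i in range(scores.shape[0]):
            m = mask[i]
            t = truth[i, m]
            p = scores[i, m] >= tau
            n_pred = int(p.sum())
            n_true = int(t.sum())
            tp = int(np.sum(p & (t == 1)))
            if n_pred > 0:
                precisions.append(tp / n_pred)
            if n_true > 0:
                recalls.append(tp / n_true)
        if not precisions or not recalls:
            continue
        pr = float(np.mean(precisions))
        rc = float(np.mean(recalls))
        f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
        if f > best_f + 1e-12:
            best_f, best_tau = f, float(tau)
    return best_f, best_tau


def term_frequency_baseline(train_matrix) -> np.ndarray:
    """Score every pair by the term's training prevalence (column mean)."""
    values = np.asarray(train_matrix.values, dtype=float)
    if values.size == 0:
        raise ValidationError("training matrix is empty")
    prevalence = values.mean(axis=0)
    return np.broadcast_to(prevalence, values.shape).copy()


@dataclass
class EvaluationReport:
    """The four headline metrics plus per-term detail for one run."""

    macro_avg_f1: float
    avg_auc: float
    one_minus_rankloss: float
    fmax: float
    threshold_at_fmax: float
    f1_threshold: float = 0.5
    per_term_f1: dict = field(default_factory=dict)
    per_term_auc: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("macro_avg_f1", "avg_auc", "one_minus_rankloss", "fmax"):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValidationError(f"{name} = {val} outside [0, 1]")

    def summary(self) -> dict:
        return {
            "MacroAvgF1": self.macro_avg_f1,
            "AvgAUC": self.avg_auc,
            "1-RankLoss": self.one_minus_rankloss,
            "Fmax": self.fmax,
            "threshold_at_fmax": self.threshold_at_fmax,
            "f1_threshold": self.f1_threshold,
        }

    def to_json(self, path) -> None:
        payload = dict(self.summary())
        payload["per_term_f1"] = self.per_term_f1
        payload["per_term_auc"] = self.per_term_auc
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_tsv(self, path) -> None:
        """Per-term metrics as TSV, headline values in '#' header lines."""
        with open(path, "w") as fh:
            for key, val in self.summary().items():
                fh.write(f"# {key}\t{val:.6f}\n")
            fh.write("term\tf1\tauc\n")
            for term in sorted(set(self.per_term_f1) | set(self.per_term_auc)):
                f1 = self.per_term_f1.get(term, float("nan"))
                auc = self.per_term_auc.get(term, float("nan"))
                fh.write(f"{term}\t{f1:.6f}\t{auc:.6f}\n")


def _per_term_details(scores, truth, mask, terms, threshold):
    pred = scores >= threshold
    per_f1, per_auc = {}, {}
    for j, term in enumerate(terms):
        m = mask[:, j]
        t = truth[m, j]
        s = scores[m, j]
        p = pred[m, j]
        if t.sum() > 0:
            tp = int(np.sum(p & (t == 1)))
            fp = int(np.sum(p & (t == 0)))
            fn = int(np.sum(~p & (t == 1)))
            denom = 2 * tp + fp + fn
            per_f1[term] = 2 * tp / denom if denom else 0.0
        if 0 < t.sum() < len(t):
            per_auc[term] = _auc_mann_whitney(s[t == 1], s[t == 0])
    return per_f1, per_auc


def evaluate(scores, truth, mask=None, terms=None, threshold: float = 0.5) -> EvaluationReport:
    """Compute all four metrics and per-term detail in one report."""
    scores_a, truth_a, mask_a = _check_shapes(scores, truth, mask)
    if terms is None:
        terms = [f"term_{j}" for j in range(scores_a.shape[1])]
    f_val, tau = fmax(scores_a, truth_a, mask_a)
    per_f1, per_auc = _per_term_details(scores_a, truth_a, mask_a, terms, threshold)
    return EvaluationReport(
        macro_avg_f1=macro_avg_f1(scores_a, truth_a, threshold, mask_a),
        avg_auc=avg_auc(scores_a, truth_a, mask_a),
        one_minus_rankloss=one_minus_ranking_loss(scores_a, truth_a, mask_a),
        fmax=f_val,
        threshold_at_fmax=tau,
        f1_threshold=threshold,
        per_term_f1=per_f1,
        per_term_auc=per_auc,
    )


def evaluate_split(scores, split, threshold: float = 0.5) -> EvaluationReport:
    """Evaluate a score matrix against a :class:`TemporalSplit`.

    Only the zero-entries of the training matrix participate: evaluation
    positives are the newly added annotations, everything else is negative.
    """
    truth, mask = split.truth_and_mask()
    return evaluate(scores, truth, mask, terms=split.train.terms, threshold=threshold)
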