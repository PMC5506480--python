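"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — repeated edge expansion, exhaustive
pair/state enumeration, per-entry loops — and shares no code path with the
package beyond basic data containers.
"""

import itertools

import numpy as np


# --- ontology ---------------------------------------------------------------


def reachable_by_expansion(parent_map: dict, start: str) -> set:
    """Transitive closure by repeated one-step edge expansion."""
    reached = set(parent_map.get(start, ()))
    while True:
        grown = set(reached)
        for node in reached:
            grown |= set(parent_map.get(node, ()))
        if grown == reached:
            return reached
        reached = grown


def closure_by_ancestor_union(values: np.ndarray, terms: list, parent_map: dict):
    """True-path closure: per annotation, union in all ancestors."""
    term_ix = {t: j for j, t in enumerate(terms)}
    out = values.copy()
    for i in range(values.shape[0]):
        for j in np.nonzero(values[i])[0]:
            for anc in reachable_by_expansion(parent_map, terms[j]):
                if anc in term_ix:
                    out[i, term_ix[anc]] = 1
    return out


# --- RBM: exhaustive state enumeration --------------------------------------


def enumerate_joint(W, a, b):
    """P(v, h) table over all binary states, by direct energy enumeration."""
    c, m = W.shape
    V = list(itertools.product((0, 1), repeat=c))
    H = list(itertools.product((0, 1), repeat=m))
    table = np.zeros((len(V), len(H)))
    for vi, v in enumerate(V):
        for hi, h in enumerate(H):
            e = 0.0
            for i in range(c):
                e -= a[i] * v[i]
            for j in range(m):
                e -= b[j] * h[j]
            for i in range(c):
                for j in range(m):
                    e -= v[i] * W[i, j] * h[j]
            table[vi, hi] = np.exp(-e)
    return np.array(V), np.array(H), table / table.sum()


def conditional_h_given_v(W, a, b, v):
    """P(h_j = 1 | v) from the enumerated joint."""
    V, H, P = enumerate_joint(W, a, b)
    row = np.all(V == np.asarray(v), axis=1)
    pv = P[row].sum()
    return np.array([(P[row][0] * H[:, j]).sum() / pv for j in range(H.shape[1])])


def conditional_v_given_h(W, a, b, h):
    V, H, P = enumerate_joint(W, a, b)
    col = np.all(H == np.asarray(h), axis=1)
    ph = P[:, col].sum()
    return np.array([(P[:, col][:, 0] * V[:, i]).sum() / ph for i in range(V.shape[1])])


# --- metrics: pair/threshold enumeration ------------------------------------


def pairwise_auc(pos, neg):
    """AUC by exhaustive (positive, negative) pair comparison."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_macro_f1(scores, truth, threshold):
    f1s = []
    for j in range(truth.shape[1]):
        t = truth[:, j]
        if t.sum() == 0:
            continue
        p = scores[:, j] >= threshold
        tp = sum(1 for i in range(len(t)) if p[i] and t[i] == 1)
        fp = sum(1 for i in range(len(t)) if p[i] and t[i] == 0)
        fn = sum(1 for i in range(len(t)) if not p[i] and t[i] == 1)
        f1s.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
    return float(np.mean(f1s))


def brute_avg_auc(scores, truth):
    aucs = []
    for j in range(truth.shape[1]):
        t = truth[:, j]
        if t.sum() == 0 or (t == 0).sum() == 0:
            continue
        aucs.append(pairwise_auc(scores[t == 1, j], scores[t == 0, j]))
    return float(np.mean(aucs))


def brute_one_minus_rankloss(scores, truth):
    losses = []
    for i in range(truth.shape[0]):
        t = truth[i]
        if t.sum() == 0 or (t == 0).sum() == 0:
            continue
        viol = 0.0
        for p_score in scores[i, t == 1]:
            for n_score in scores[i, t == 0]:
                if n_score > p_score:
                    viol += 1.0
                elif n_score == p_score:
                    viol += 0.5
        losses.append(viol / (t.sum() * (t == 0).sum()))
    return float(1.0 - np.mean(losses))


def brute_fmax(scores, truth, thresholds):
    """Protein-centric Fmax by direct sweep over the given thresholds."""
    best = 0.0
    best_tau = thresholds[0]
    for tau in thresholds:
        precisions, recalls = [], []
        for i in range(truth.shape[0]):
            pred = scores[i] >= tau
            tp = int(np.sum(pred & (truth[i] == 1)))
            if pred.sum() > 0:
                precisions.append(tp / pred.sum())
            if truth[i].sum() > 0:
                recalls.append(tp / truth[i].sum())
        if not precisions or not recalls:
            continue
        pr, rc = np.mean(precisions), np.mean(recalls)
        f = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
        if f > best + 1e-12:
            best, best_tau = f, tau
    return float(best), float(best_tau)
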