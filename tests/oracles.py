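"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: plain loops and first-principles formulas, sharing no
code path with the package.
"""

import math

import numpy as np


def pearson_bruteforce(x, y):
    """Pearson correlation from the definition; 0 for zero-variance input."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def phi_from_table(a, b, c, d):
    """Phi coefficient of the 2x2 table [[a, b], [c, d]]."""
    denom = math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    return (a * d - b * c) / denom


def majority_by_counting(labels):
    """Modal 0/1 label with ties going to 1."""
    ones = sum(1 for v in labels if v == 1)
    zeros = len(labels) - ones
    return 1 if ones >= zeros else 0


def confusion_by_loop(y_true, y_pred):
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def auc_by_concordance(y_true, y_score):
    """Mann-Whitney pairwise concordance: ties count one half."""
    pos = [s for t, s in zip(y_true, y_score) if t == 1]
    neg = [s for t, s in zip(y_true, y_score) if t == 0]
    if not pos or not neg:
        raise ValueError("need both classes")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def metrics_by_formula(y_true, y_pred):
    tp, fp, tn, fn = confusion_by_loop(y_true, y_pred)
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    prec = tp / (tp + fp) if tp + fp else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return acc, prec, sens, f1


def pair_frequencies(codes, labels):
    """Frequency of each (code, label) pair, by dict counting."""
    counts = {}
    for c, l in zip(codes, labels):
        counts[(c, l)] = counts.get((c, l), 0) + 1
    return counts
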