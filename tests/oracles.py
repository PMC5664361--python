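"""Independent brute-force oracles used across the test suite.

Every function here enumerates pairs/thresholds directly and must stay
independent of the vectorized implementations it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def ari_pair_counting(labels_a, labels_b) -> float:
    """Adjusted Rand index via direct pair counting over the contingency."""
    keys = sorted(labels_a)
    assert sorted(labels_b) == keys
    n = len(keys)
    same_a = same_b = same_both = 0
    for x, y in combinations(keys, 2):
        a_same = labels_a[x] == labels_a[y]
        b_same = labels_b[x] == labels_b[y]
        same_a += a_same
        same_b += b_same
        same_both += a_same and b_same
    n_pairs = n * (n - 1) // 2
    expected = same_a * same_b / n_pairs
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0 if same_both == expected else 0.0
    return (same_both - expected) / (max_index - expected)


def f_values_enumeration(inside, outside):
    """(F_pw, F_all) by explicit Kronecker-delta double loops.

    Profiles are any hashable-comparable sequences (tuples/strings).
    """
    inside = [tuple(p) for p in inside]
    outside = [tuple(p) for p in outside]
    n = len(inside)
    within_pairs = ident_within = 0
    for i in range(n):
        for j in range(i + 1, n):
            within_pairs += 1
            ident_within += inside[i] == inside[j]
    cross = ident_cross = 0
    for p in inside:
        for q in outside:
            cross += 1
            ident_cross += p == q
    f_pw = ident_within / within_pairs if within_pairs else None
    denom = within_pairs + cross
    f_all = (ident_within + ident_cross) / denom if denom else None
    return f_pw, f_all


def aucprc_threshold_sweep(scores, truth) -> float | None:
    """PR area by explicit sweep over every distinct score as threshold."""
    pairs = [(s, t) for s, t in zip(scores, truth) if not math.isnan(s)]
    pairs.sort(key=lambda p: -p[0])
    n_pos = sum(t for _, t in pairs)
    if n_pos == 0:
        return None
    thresholds = sorted({s for s, _ in pairs}, reverse=True)
    area = 0.0
    prev_recall = 0.0
    for thr in thresholds:
        predicted = [(s, t) for s, t in pairs if s >= thr]
        tp = sum(t for _, t in predicted)
        precision = tp / len(predicted)
        recall = tp / n_pos
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area


def jaccard_bits(p1, p2) -> float:
    inter = sum(1 for a, b in zip(p1, p2) if a and b)
    union = sum(1 for a, b in zip(p1, p2) if a or b)
    return inter / union


def bh_stepup(pvals):
    """Benjamini-Hochberg by the literal step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvals[i] * m / rank_from_top)
        adjusted[i] = min(running_min, 1.0)
    return adjusted
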