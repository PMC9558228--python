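"""Independent brute-force oracles used to pin expected values.

These deliberately share no code with the production paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_oracle(u, m: int, r: float, strict: bool = False):
    """Naive double loop over all template pairs with Chebyshev matching.

    Returns (a_count, b_count, value) using unordered pair counts over the
    template range that admits an (m+1)-point extension.
    """
    u = np.asarray(u, dtype=float)
    n = len(u)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            dm = max(abs(u[i + k] - u[j + k]) for k in range(m))
            match_m = dm < r if strict else dm <= r
            if match_m:
                b += 1
            dm1 = max(dm, abs(u[i + m] - u[j + m]))
            match_m1 = dm1 < r if strict else dm1 <= r
            if match_m1:
                a += 1
    value = -math.log(a / b) if (a > 0 and b > 0) else math.nan
    return a, b, value


def cross_product_or(table):
    """Closed-form odds ratio and Wald 95% CI from a 2x2 table
    [[unexposed_neg, unexposed_pos], [exposed_neg, exposed_pos]]."""
    (a, b), (c, d) = table  # a,b: unexposed neg/pos; c,d: exposed neg/pos
    or_ = (d / c) / (b / a)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return or_, math.exp(log_or - 1.959963984540054 * se), math.exp(log_or + 1.959963984540054 * se)


def auc_pair_count(scores, labels):
    """AUC by explicit enumeration of positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def mann_whitney_u_count(a, b):
    """U statistic of sample a by exhaustive pair counting with half-ties."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u
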