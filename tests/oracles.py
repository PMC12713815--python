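"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition with the
simplest possible code (double loops, explicit enumeration), sharing no
logic with the package implementation they check.
"""

import math
from itertools import combinations


def ppl_oracle(tokens, log_prob):
    """Direct exponentiated mean NLL, token by token over the full prefix."""
    nll = 0.0
    for i in range(len(tokens)):
        nll -= log_prob(tokens[i], tokens[:i])
    return math.exp(nll / len(tokens))


def strided_ppl_oracle(tokens, log_prob, max_length, stride):
    """Enumerate windows explicitly; score each token once, in the first
    window that reaches it, conditioned on the tokens before it inside that
    window."""
    n = len(tokens)
    starts = list(range(0, n, stride))
    scored = {}
    for begin in starts:
        end = min(begin + max_length, n)
        for i in range(begin, end):
            if i not in scored:
                scored[i] = -log_prob(tokens[i], tokens[begin:i])
        if end == n:
            break
    assert sorted(scored) == list(range(n))
    return math.exp(sum(scored.values()) / n)


def ks2d_oracle(s1, s2):
    """Quadrant double-loop 2D KS statistic; boundary points fall in the
    closed lower/left quadrants, as in the implementation's convention."""

    def frac(sample, cx, cy, qx, qy):
        count = 0
        for x, y in sample:
            in_x = (x <= cx) if qx else (x > cx)
            in_y = (y <= cy) if qy else (y > cy)
            count += in_x and in_y
        return count / len(sample)

    def dmax(centers):
        best = 0.0
        for cx, cy in centers:
            for qx in (True, False):
                for qy in (True, False):
                    diff = abs(frac(s1, cx, cy, qx, qy) - frac(s2, cx, cy, qx, qy))
                    best = max(best, diff)
        return best

    return 0.5 * (dmax(s1) + dmax(s2))


def exhaustive_perm_pvalue(a, b):
    """Exact permutation p for the |mean difference| statistic by
    enumerating every assignment of the pooled values to group sizes."""
    pooled = list(a) + list(b)
    n1 = len(a)
    obs = abs(sum(a) / len(a) - sum(b) / len(b))
    total = 0
    count = 0
    for combo in combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in combo]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in combo]
        stat = abs(sum(g1) / len(g1) - sum(g2) / len(g2))
        total += 1
        if stat >= obs - 1e-12:
            count += 1
    return count / total


def holm_oracle(p_values):
    """Step-down Holm from its textbook definition."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(indexed):
        running = max(running, min(1.0, (m - rank) * p_values[i]))
        adjusted[i] = running
    return adjusted


def average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of tie-averaged ranks, computed longhand."""
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
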