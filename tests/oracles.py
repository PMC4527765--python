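"""Independent brute-force oracles used by the test suite.

These re-derive expected values by enumeration or first-principles
formulas and deliberately share no code with the implementation paths
they check.
"""

from itertools import combinations

import numpy as np

from memdyn.masks import BACKGROUND, PROTRUSION, RETRACTION, SHORT_LIVED, STABLE


def region_label_lookup(prev, curr, nxt):
    """Per-pixel membership-triple lookup, explicit python loops."""
    h, w = curr.shape
    labels = np.zeros((h, w), dtype=np.uint8)
    for i in range(h):
        for j in range(w):
            if not curr[i, j]:
                labels[i, j] = BACKGROUND
            elif prev[i, j] and nxt[i, j]:
                labels[i, j] = STABLE
            elif not prev[i, j] and nxt[i, j]:
                labels[i, j] = PROTRUSION
            elif prev[i, j] and not nxt[i, j]:
                labels[i, j] = RETRACTION
            else:
                labels[i, j] = SHORT_LIVED
    return labels


def exact_ranksum_p(a, b):
    """Exact two-sided rank-sum p by enumerating all rank assignments.

    Requires tie-free pooled samples. Two-sided p is the probability,
    under random assignment of the pooled ranks, of a rank sum at least
    as far from its mean as the observed one.
    """
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n, m = len(a), len(b)
    obs = sum(ranks[v] for v in a)
    mean = n * (n + m + 1) / 2
    count = 0
    total = 0
    for combo in combinations(range(1, n + m + 1), n):
        total += 1
        if abs(sum(combo) - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def kruskal_h(groups):
    """Kruskal-Wallis H from first principles (tie-free data)."""
    pooled = sorted(v for g in groups for v in g)
    assert len(set(pooled)) == len(pooled)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n = len(pooled)
    h = 0.0
    for g in groups:
        r = sum(ranks[v] for v in g)
        h += r * r / len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def centroid_by_averaging(mask):
    """Foreground centroid via explicit pixel accumulation."""
    tot = 0
    sr = 0.0
    sc = 0.0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j]:
                tot += 1
                sr += i
                sc += j
    return sr / tot, sc / tot
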