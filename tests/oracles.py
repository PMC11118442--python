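"""Independent brute-force oracles, sharing no code with the package."""

from __future__ import annotations

import math
from collections import Counter


def brute_ibs(s1: str, s2: str, m: int) -> float:
    """Direct dictionary-enumeration IBS distance.

    Same conventions as the package states (union vocabulary, descending
    probability with lexicographic tie-break, absent words ranked last and
    lexicographically among themselves, natural-log entropy weights,
    normalization by vocabulary size minus one) but implemented from the
    definition with Counters and explicit sorting.
    """
    words1 = Counter(s1[i:i + m] for i in range(len(s1) - m + 1))
    words2 = Counter(s2[i:i + m] for i in range(len(s2) - m + 1))
    vocab = sorted(set(words1) | set(words2))
    if len(vocab) < 2:
        raise ValueError("degenerate vocabulary")

    def rank_map(counter: Counter) -> dict[str, int]:
        total = sum(counter.values())
        def sort_key(w):
            present = counter.get(w, 0) > 0
            freq = counter.get(w, 0) / total
            # present words first by descending freq then lexicographic;
            # absent words after, lexicographic
            return (0 if present else 1, -freq, w)
        ordered = sorted(vocab, key=sort_key)
        return {w: i + 1 for i, w in enumerate(ordered)}

    r1, r2 = rank_map(words1), rank_map(words2)
    t1, t2 = sum(words1.values()), sum(words2.values())
    ent = {}
    for w in vocab:
        h = 0.0
        for counter, total in ((words1, t1), (words2, t2)):
            p = counter.get(w, 0) / total
            if p > 0:
                h -= p * math.log(p)
        ent[w] = h
    z = sum(ent.values())
    total = 0.0
    for w in vocab:
        weight = ent[w] / z if z > 0 else 1.0 / len(vocab)
        total += abs(r1[w] - r2[w]) * weight
    return total / (len(vocab) - 1)


def exact_mann_whitney_p(x, y) -> float:
    """Two-sided p-value by exhaustive enumeration of group assignments."""
    from itertools import combinations

    import numpy as np
    from scipy.stats import rankdata

    x = list(x)
    y = list(y)
    pooled = np.array(x + y, float)
    n1 = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total
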