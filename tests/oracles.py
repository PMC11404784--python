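"""Independent brute-force oracles used to verify the statistical core.

These are deliberately naive implementations — exhaustive enumeration and
direct running sums — kept free of any code path they check.
"""

import itertools
from math import comb


def hypergeom_upper_tail_enum(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by counting all C(N, n) equally likely draws.

    The universe is 0..N-1 with 0..K-1 the marked elements.
    """
    total = comb(N, n)
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if sum(1 for x in draw if x < K) >= k
    )
    return hits / total


def hypergeom_upper_tail_sum(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by the closed-form tail sum (a second independent route)."""
    return sum(
        comb(K, j) * comb(N - K, n - j) / comb(N, n)
        for j in range(k, min(K, n) + 1)
    )


def gsea_running_sum(ranked_in_set: list[bool], stats: list[float], weight: float) -> float:
    """Enrichment score: signed max deviation of the running sum, naively."""
    n = len(ranked_in_set)
    nh = sum(ranked_in_set)
    wsum = sum(abs(s) ** weight for s, h in zip(stats, ranked_in_set) if h)
    running = 0.0
    best = 0.0
    for hit, s in zip(ranked_in_set, stats):
        if hit:
            running += (abs(s) ** weight) / wsum
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


def bh_adjust_naive(pvals: list[float]) -> list[float]:
    """BH step-up: sort, scale by m/i, enforce monotonicity from the top."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    scaled = [pvals[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = min(scaled[rank], 1.0)
    return out
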