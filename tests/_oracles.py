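"""Independent brute-force reference implementations used only by tests.

Deliberately plain loops, sharing no code path with the package.
"""

from __future__ import annotations


def brute_force_running_sum(ids, scores, members, p_exp):
    """O(N * |S|) literal walk of the weighted hit/miss running sum.

    Returns (es, running list). Raises on degenerate overlap, mirroring
    the contract of the fast implementation.
    """
    n = len(ids)
    hits = [i in members for i in ids]
    n_hits = sum(hits)
    assert 0 < n_hits < n, "improper overlap"
    denom = sum(abs(scores[i]) ** p_exp for i in range(n) if hits[i])
    running = []
    value = 0.0
    for i in range(n):
        if hits[i]:
            if denom > 0:
                value += abs(scores[i]) ** p_exp / denom
            else:
                value += 1.0 / n_hits
        else:
            value -= 1.0 / (n - n_hits)
        running.append(value)
    es = 0.0
    for v in running:
        if abs(v) > abs(es):
            es = v
    return es, running


def brute_force_leading_edge(ids, running, members, es):
    """Hits at/before the peak (es>0) or at/after the trough (es<0)."""
    if es == 0:
        return []
    if es > 0:
        peak = max(range(len(running)), key=lambda i: (running[i], -i))
        return [i for j, i in enumerate(ids) if i in members and j <= peak]
    trough = min(range(len(running)), key=lambda i: (running[i], i))
    return [i for j, i in enumerate(ids) if i in members and j >= trough]


def step_up_bh(pvalues):
    """Benjamini-Hochberg step-up by the textbook recursion."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvalues[i] * m / rank)
        q[i] = val
        prev = val
    return q
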