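"""Independent naive oracles used to cross-check the pipeline's statistics.

Everything here is deliberately brute-force (enumeration, O(n^3) loops,
closed forms) and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def manhattan(a, b) -> float:
    return float(np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)).sum())


def upgma_oracle(X) -> list[tuple[frozenset, float]]:
    """Naive UPGMA on Manhattan distances.

    Returns the merge list as (leaf set, height) pairs in merge order.
    Cluster-to-cluster distance is the unweighted average of all pairwise
    leaf distances, recomputed from scratch at every step (O(n^3) overall).
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    base = {
        (i, j): manhattan(X[i], X[j]) for i in range(n) for j in range(i + 1, n)
    }

    def leafdist(i, j):
        return base[(i, j)] if i < j else base[(j, i)]

    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges: list[tuple[frozenset, float]] = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean(
                [leafdist(i, j) for i in clusters[a] for j in clusters[b]]
            )
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((merged, float(d)))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def linkage_to_merges(Z, n: int) -> list[tuple[frozenset, float]]:
    """Convert a scipy linkage matrix into (leaf set, height) merge pairs."""
    sets: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    merges = []
    for k, (a, b, h, _) in enumerate(np.asarray(Z)):
        merged = sets[int(a)] | sets[int(b)]
        sets[n + k] = merged
        merges.append((merged, float(h)))
    return merges


def mann_whitney_enum_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of labelings."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_stat(group1):
        rest = list(pooled)
        g1 = []
        for v in group1:
            g1.append(v)
        # count pairs (a from g1, b from g2) with a > b (+0.5 ties)
        g2 = list(pooled)
        for v in group1:
            g2.remove(v)
        u = 0.0
        for a in g1:
            for b in g2:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    u_obs = u_stat(x)
    centre = n1 * (len(pooled) - n1) / 2.0
    dev = abs(u_obs - centre)
    total = 0
    extreme = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = u_stat([pooled[i] for i in comb])
        total += 1
        if abs(u - centre) >= dev - 1e-9:
            extreme += 1
    return extreme / total


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted values by the literal step-up definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def fisher_enum_p(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration (point-prob rule)."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-7))


def km_empirical(times) -> dict[float, float]:
    """Survivor function without censoring: S(t) = #(T > t) / n."""
    times = np.asarray(times, dtype=float)
    return {float(t): float((times > t).mean()) for t in np.unique(times)}


def logrank_oracle(times1, events1, times2, events2) -> float:
    """Two-group log-rank chi-square via hypergeometric moments at each
    distinct event time."""
    t1, e1 = np.asarray(times1, float), np.asarray(events1, bool)
    t2, e2 = np.asarray(times2, float), np.asarray(events2, bool)
    event_times = np.unique(np.concatenate([t1[e1], t2[e2]]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = (t1 >= t).sum()
        n2 = (t2 >= t).sum()
        d1 = ((t1 == t) & e1).sum()
        d2 = ((t2 == t) & e2).sum()
        n, d = n1 + n2, d1 + d2
        if n < 1 or d == 0:
            continue
        e = d * n1 / n
        o_minus_e += d1 - e
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var) if var > 0 else 0.0


def spearman_oracle(a, b) -> float:
    """Rank (average ties) then Pearson, all by hand."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ra, rb = avg_ranks(a), avg_ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / math.sqrt((ra**2).sum() * (rb**2).sum()))
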