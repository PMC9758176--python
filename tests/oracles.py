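"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately share no code with the package implementation: the
streak oracle enumerates all valid windows in O(n^2), and the rank-sum
oracle enumerates every group assignment.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def brute_force_streaks(a, b, pos, max_mismatches=0, min_markers=1, min_span_bp=0):
    """All maximal IBD-compatible windows between genotype vectors a and b.

    A window [i, j] is valid when both boundary sites are informative and
    compatible and it contains at most ``max_mismatches`` incompatible
    sites; it is maximal when no valid window strictly contains it.
    Returns sorted tuples (start_bp, end_bp, n_markers, n_mismatches)
    after the min-markers/min-span filters.
    """
    a, b, pos = np.asarray(a), np.asarray(b), np.asarray(pos)
    n = pos.size
    informative = (a >= 0) & (b >= 0)
    incomp = informative & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))
    compat = informative & ~incomp
    valid: set[tuple[int, int]] = set()
    for i in range(n):
        if not compat[i]:
            continue
        mis = 0
        for j in range(i, n):
            if incomp[j]:
                mis += 1
                if mis > max_mismatches:
                    break
            if compat[j]:
                valid.add((i, j))
    if not valid:
        return []
    # a window strictly contained in a valid superset is also extendable
    # while keeping one endpoint fixed, so maximality reduces to: i is the
    # smallest valid start for j, and j the largest valid end for i
    min_i: dict[int, int] = {}
    max_j: dict[int, int] = {}
    for i, j in valid:
        min_i[j] = min(min_i.get(j, i), i)
        max_j[i] = max(max_j.get(i, j), j)
    out = []
    for i, j in valid:
        if min_i[j] == i and max_j[i] == j:
            nm = int(compat[i : j + 1].sum())
            mm = int(incomp[i : j + 1].sum())
            if nm >= min_markers and pos[j] - pos[i] >= min_span_bp:
                out.append((int(pos[i]), int(pos[j]), nm, mm))
    return sorted(out)


def exact_ranksum_p(x, y) -> float:
    """Exhaustive-permutation two-sided rank-sum p-value.

    Enumerates every assignment of the pooled values into groups of the
    observed sizes and counts assignments whose group-1 rank sum deviates
    from its null mean at least as much as observed.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = x.size, pooled.size
    er = n1 * (n + 1) / 2.0
    dev = abs(ranks[:n1].sum() - er)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - er) >= dev - 1e-9:
            hits += 1
    return hits / total
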