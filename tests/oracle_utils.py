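"""Independent test oracles: brute-force enumeration of nested secondary
structures, reference hit grouping, and a permutation rank-sum test.

These deliberately avoid the package's own algorithms so that agreement is
meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np

WEIGHTS = {
    frozenset("GC"): 3,
    frozenset("AU"): 2,
    frozenset("GU"): 1,
}


def pair_weight(a: str, b: str) -> int:
    return WEIGHTS.get(frozenset((a, b)), 0)


def enumerate_nested(seq: str, min_loop: int = 3) -> list[frozenset]:
    """All pseudoknot-free pair sets of ``seq`` (pairable positions only),
    by exhaustive recursion. Exponential: keep sequences short (<= ~14)."""

    def rec(i: int, j: int) -> list[frozenset]:
        if i >= j:
            return [frozenset()]
        structures = list(rec(i + 1, j))  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if pair_weight(seq[i], seq[k]) > 0:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        structures.append(inner | outer | {(i, k)})
        return structures

    return rec(0, len(seq) - 1)


def best_weight_bruteforce(seq: str, min_loop: int = 3) -> int:
    """Maximum total pair weight over all nested structures."""
    return max(
        sum(pair_weight(seq[i], seq[j]) for i, j in s)
        for s in enumerate_nested(seq, min_loop)
    )


def group_hits_bruteforce(starts, scores, step, window, threshold):
    """Reference hit fusion: label each window, then group consecutive
    above-threshold windows whose starts differ by exactly ``step``."""
    runs = []
    current = []
    for s, sc in zip(starts, scores):
        if sc > threshold:
            if current and s - current[-1][0] == step:
                current.append((s, sc))
            else:
                if current:
                    runs.append(current)
                current = [(s, sc)]
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    out = []
    for run in runs:
        start = run[0][0]
        end = run[-1][0] + window
        out.append(
            (start, end, (start + end - 1) // 2, max(sc for _s, sc in run))
        )
    return out


def ranksum_permutation_p(a, b) -> float:
    """Exact two-sided rank-sum p-value (twice the smaller tail, capped at
    1) by enumerating group assignments and comparing Mann-Whitney U
    statistics computed from pairwise comparisons."""
    a = list(a)
    b = list(b)
    combined = a + b
    n, na = len(combined), len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_stat(a, b)
    n_le = 0
    n_ge = 0
    total = 0
    for idx in itertools.combinations(range(n), na):
        mask = set(idx)
        ga = [combined[i] for i in idx]
        gb = [combined[i] for i in range(n) if i not in mask]
        u = u_stat(ga, gb)
        if u <= u_obs + 1e-9:
            n_le += 1
        if u >= u_obs - 1e-9:
            n_ge += 1
        total += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)
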