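"""Independent brute-force dynamic-programming oracles for the test suite.

These deliberately share no code with the package: plain-Python DP matrices
and exhaustive enumeration over alignment placements.
"""

from __future__ import annotations


def levenshtein_dp(a: str, b: str) -> int:
    """Full-matrix Levenshtein distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            cost = 0 if ai == b[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[n]


def semiglobal_end_costs_brute(target: str, pattern: str) -> dict[int, int]:
    """min over start positions s of NW(pattern, target[s:e]), for every e.

    `N` in the target matches nothing.  Enumerates every start position and
    sweeps a full edit-distance column along the suffix, recording the cost
    of each end position.
    """
    n = len(target)
    m = len(pattern)
    best: dict[int, int] = {e: m for e in range(n + 1)}  # e == s: delete whole pattern
    for s in range(n + 1):
        col = list(range(m + 1))  # NW(pattern[:i], "")
        if col[m] < best[s]:
            best[s] = col[m]
        for e in range(s + 1, n + 1):
            tc = target[e - 1]
            new = [e - s]
            for i in range(1, m + 1):
                cost = 0 if (pattern[i - 1] == tc and tc != "N") else 1
                new.append(min(col[i - 1] + cost, col[i] + 1, new[i - 1] + 1))
            col = new
            if col[m] < best[e]:
                best[e] = col[m]
    return best


def pr_points_set_algebra(entries: dict[str, int], truth: set[str], thresholds) -> list:
    """(threshold, precision, recall) by literal set algebra per threshold."""
    points = []
    for t in thresholds:
        predicted = {bc for bc, c in entries.items() if c > t}
        tp = len(predicted & truth)
        precision = tp / len(predicted) if predicted else 1.0
        recall = tp / len(truth)
        points.append((float(t), precision, recall))
    return points
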