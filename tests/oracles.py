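"""Independent brute-force reference implementations used only by tests.

Deliberately naive: explicit loops, dictionaries and full-matrix scans, no
shared code with the package under test.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


def brute_pe(series, m: int, lag: int = 1, normalize: bool = True) -> float:
    """Permutation entropy by dictionary count over explicit windows."""
    x = list(map(float, series))
    counts: Counter = Counter()
    i = 0
    while i + (m - 1) * lag < len(x):
        window = [x[i + k * lag] for k in range(m)]
        # stable rank pattern: position of each element in the sorted order,
        # ties broken by original position
        order = sorted(range(m), key=lambda k: (window[k], k))
        counts[tuple(order)] += 1
        i += 1
    total = sum(counts.values())
    h = 0.0
    for c in counts.values():
        p = c / total
        h -= p * math.log(p)
    if normalize:
        h /= math.log(math.factorial(m))
    return h


def brute_coarse_grain(series, scale: int, offset: int = 0):
    x = list(map(float, series))
    out = []
    i = offset
    while i + scale <= len(x):
        out.append(sum(x[i : i + scale]) / scale)
        i += scale
    return out


def lehmer_code(perm) -> int:
    """Lexicographic index of a permutation given as a sequence of ints."""
    m = len(perm)
    code = 0
    for i in range(m):
        smaller = sum(1 for j in range(i + 1, m) if perm[j] < perm[i])
        code += smaller * math.factorial(m - 1 - i)
    return code


def negation_code_map(m: int) -> dict[int, int]:
    """Map pattern code of a (tie-free) window to the code of its negation."""
    mapping = {}
    for perm in itertools.permutations(range(m)):
        mapping[lehmer_code(perm)] = lehmer_code(perm[::-1])
    return mapping


# ---------------------------------------------------------------------------
# naive full-matrix chromatic RQA


def naive_matrix(states, targets, loi_excluded: bool):
    T = len(states)
    R = [[False] * T for _ in range(T)]
    for i in range(T):
        for j in range(T):
            if i == j and loi_excluded:
                continue
            if states[i] == states[j] and states[i] in targets:
                R[i][j] = True
    return R


def naive_rqa(states, targets, v_min: int = 3, loi_excluded: bool = True):
    """RR/LAM/TT/ENTb by materializing and scanning the full T x T matrix.

    Returns a dict; tt/entb are None when undefined. Blocks are found by
    scanning the sequence for runs with itertools.groupby and pairing them.
    """
    states = list(states)
    T = len(states)
    R = naive_matrix(states, targets, loi_excluded)
    total = sum(sum(row) for row in R)
    denom = T * T - T if loi_excluded else T * T
    rr = 100.0 * total / denom

    lines = []
    for col in range(T):
        run = 0
        for row in range(T):
            if R[row][col]:
                run += 1
            else:
                if run:
                    lines.append(run)
                run = 0
        if run:
            lines.append(run)

    laminar = sum(l for l in lines if l >= v_min)
    lam = 100.0 * laminar / total if total else 0.0
    qual = [l for l in lines if l >= v_min]
    tt = sum(qual) / len(qual) if qual else None

    bouts = [
        (state, len(list(grp)))
        for state, grp in itertools.groupby(states)
        if state in targets
    ]
    areas = []
    for si, a in bouts:
        for sj, b in bouts:
            if si == sj:
                areas.append(a * b)
    if areas:
        hist = Counter(areas)
        n = sum(hist.values())
        entb = -sum((c / n) * math.log2(c / n) for c in hist.values()) + 0.0
    else:
        entb = None
    return {"rr": rr, "lam": lam, "tt": tt, "entb": entb, "lines": lines}
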