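"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: plain dynamic
programming, per-base boolean masks, exhaustive enumeration.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def nw_identity_unit_cost(a: str, b: str) -> float:
    """Global alignment identity (%) under unit-cost edit distance.

    Full O(nm) DP; identity = matches / columns along one optimal
    traceback preferring diagonal moves.
    """
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1), dtype=np.int32)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    eq = (np.frombuffer(a.encode(), dtype=np.uint8)[:, None]
          == np.frombuffer(b.encode(), dtype=np.uint8)[None, :])
    for i in range(1, n + 1):
        row_prev = D[i - 1]
        row = D[i]
        row[0] = i
        sub = row_prev[:-1] + (~eq[i - 1]).astype(np.int32)
        for j in range(1, m + 1):
            row[j] = min(sub[j - 1], row_prev[j] + 1, row[j - 1] + 1)
    # traceback
    i, j = n, m
    matches = columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (0 if eq[i - 1, j - 1] else 1):
            matches += int(eq[i - 1, j - 1])
            columns += 1
            i, j = i - 1, j - 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return 100.0 * matches / columns


def sw_protein_identity(a: str, b: str, match: int = 2, mismatch: int = -1,
                        gap: int = -2) -> tuple[float, float, float]:
    """Best local alignment of two proteins under simple linear-gap scoring.

    Returns (identity_pct over alignment columns, aligned span fraction
    of a, aligned span fraction of b).  Independent of any alignment
    library.
    """
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        s = np.where(np.frombuffer(b.encode(), dtype=np.uint8) == ord(a[i - 1]),
                     match, mismatch)
        row_prev = H[i - 1]
        row = H[i]
        for j in range(1, m + 1):
            v = max(0, row_prev[j - 1] + s[j - 1], row_prev[j] + gap, row[j - 1] + gap)
            row[j] = v
            if v > best:
                best, bi, bj = v, i, j
    if best == 0:
        return 0.0, 0.0, 0.0
    i, j = bi, bj
    matches = columns = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        sc = match if a[i - 1] == b[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + sc:
            matches += int(a[i - 1] == b[j - 1])
            columns += 1
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            columns += 1
            i -= 1
        elif H[i, j] == H[i, j - 1] + gap:
            columns += 1
            j -= 1
        else:
            break
    return 100.0 * matches / columns, (bi - i) / n, (bj - j) / m


def coverage_fraction_mask(intervals, total_len: int) -> float:
    """Per-base boolean-mask union coverage of [0, total_len)."""
    mask = np.zeros(total_len, dtype=bool)
    for iv in intervals:
        mask[iv.start:iv.end] = True
    return mask.sum() / total_len


def repeat_fraction_mask(intervals, repeats, total_len: int) -> float:
    """Per-base oracle for the repetitive fraction of a footprint."""
    foot = np.zeros(total_len, dtype=bool)
    rep = np.zeros(total_len, dtype=bool)
    for iv in intervals:
        foot[iv.start:iv.end] = True
    for iv in repeats:
        rep[iv.start:iv.end] = True
    return (foot & rep).sum() / foot.sum()


def rank_sum_pvalues_bruteforce(x, y, alternative: str) -> float:
    """Exhaustive rank-sum p over all labelings (small n only)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    total = ge = le = 0
    for comb in combinations(range(len(pooled)), n1):
        w = ranks[list(comb)].sum()
        total += 1
        ge += w >= w_obs - 1e-9
        le += w <= w_obs + 1e-9
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge / total, le / total))


def subset_sharing_counts(clusters, groups):
    """Brute-force count of clusters whose species set contains each group."""
    out = {}
    for name, group in groups.items():
        out[name] = sum(1 for c in clusters if set(group) <= set(c.species_set))
    return out
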