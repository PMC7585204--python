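"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from its definition by exhaustive
enumeration, deliberately sharing no code path with the implementation
it checks.
"""

from __future__ import annotations

import numpy as np


def oracle_circular_distance(a: int, b: int, L: int) -> int:
    """Shortest arc by walking both ways."""
    return min((a - b) % L, (b - a) % L)


def oracle_direct_repeats(seq: str, min_len: int = 8, rate: float = 0.25):
    """Exhaustive per-diagonal window enumeration + containment maximality.

    Returns a set of (pos_a, pos_b, length, mismatches) tuples.
    """
    L = len(seq)
    arr = np.frombuffer(seq.encode(), np.uint8)
    found = {}
    for d in range(1, L // 2 + 1):
        cap = min(d, L - d)
        if cap < min_len:
            continue
        mis = (arr != np.roll(arr, -d)).astype(np.int64)
        xx = np.concatenate([mis, mis[:cap]])
        cs = np.concatenate([[0], np.cumsum(xx)])
        valid = []
        cap_limit = int(np.floor(cap * rate))
        for ln in range(min_len, cap + 1):
            S = cs[ln:] - cs[:-ln]
            lim = int(np.floor(ln * rate))
            hi = min(L, len(S))
            if S[:hi].min() > cap_limit:
                break  # min window sum is non-decreasing in ln
            for a in np.flatnonzero(S[:hi] <= lim):
                valid.append((int(a), ln, int(S[a])))
        keep = []
        for i, (a, ln, m) in enumerate(valid):
            contained = False
            for j, (a2, ln2, _) in enumerate(valid):
                if i == j:
                    continue
                for s in (-L, 0, L):
                    if a2 <= a + s and a + s + ln <= a2 + ln2 and (
                        ln2 > ln or a2 != a + s
                    ):
                        contained = True
                        break
                if contained:
                    break
            if not contained:
                keep.append((a, ln, m))
        for a, ln, m in keep:
            pa = a % L
            pb = (pa + d) % L
            key = (min(pa, pb), max(pa, pb), ln)
            if key not in found or m < found[key]:
                found[key] = m
    return {(k[0], k[1], k[2], v) for k, v in found.items()}


def oracle_best_alignment_score(a: str, b: str, gap_open: float = 10.0,
                                gap_extend: float = 0.5, match: float = 5.0,
                                mismatch: float = -4.0) -> float:
    """Max score over all global alignments by recursive enumeration.

    Terminal gap runs (a maximal run of gap columns in one sequence at
    either end of the alignment) cost nothing; an internal gap of length
    k costs gap_open + k * gap_extend.
    """
    best = [-float("inf")]

    def score(cols):
        n = len(cols)
        kinds = [
            0 if c[0] != "-" and c[1] != "-" else (1 if c[1] == "-" else 2)
            for c in cols
        ]
        lead = 0
        if n and kinds[0] != 0:
            k0 = kinds[0]
            while lead < n and kinds[lead] == k0:
                lead += 1
        trail = n
        if trail > lead and kinds[trail - 1] != 0:
            k1 = kinds[trail - 1]
            while trail > lead and kinds[trail - 1] == k1:
                trail -= 1
        s = 0.0
        run = None
        for i in range(lead, trail):
            k = kinds[i]
            if k == 0:
                s += match if cols[i][0] == cols[i][1] else mismatch
                run = None
            else:
                if run != k:
                    s -= gap_open
                    run = k
                s -= gap_extend
        return s

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            s = score(cols)
            if s > best[0]:
                best[0] = s
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best[0]


def oracle_breakpoint_repeat_distance(pos5: int, pos3: int, repeats,
                                      L: int) -> float:
    """Min over repeat pairs and copy assignments, scanning every base of
    every copy for the nearest-base distance."""

    def dist_to_copy(p, start, length):
        return min(
            oracle_circular_distance(p, (start + k) % L, L)
            for k in range(length)
        )

    best = float("inf")
    for r in repeats:
        dA5 = dist_to_copy(pos5, r.pos_a, r.length)
        dB5 = dist_to_copy(pos5, r.pos_b, r.length)
        dA3 = dist_to_copy(pos3, r.pos_a, r.length)
        dB3 = dist_to_copy(pos3, r.pos_b, r.length)
        best = min(best, (dA5 + dB3) / 2.0, (dB5 + dA3) / 2.0)
    return best


def oracle_nearest_snv_distance(p: int, snv_positions, L: int) -> int:
    return min(oracle_circular_distance(p, s, L) for s in snv_positions)
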