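"""Sequence identity between deletion-breakpoint neighbourhoods.

For each deletion the 20-bp windows centred on the 5' junction (last
retained base | first deleted base) and the 3' junction (at the first
retained base after the gap) are extracted from the circle and globally
aligned; high identity between the two windows is the signature of
microhomology- or repeat-mediated deletion formation.  The aligner is
Needleman-Wunsch with affine gaps (Gotoh) and penalty-free terminal gaps,
scoring +5 match, -4 mismatch, gap open 10, gap extend 0.5 per gap
column (a length-k gap costs ``open + k * extend``).  Identity is
``100 * matches / alignment_columns``.

Deterministic tie-breaks: diagonal (match/mismatch) is preferred over a
gap, and a gap in the second sequence over a gap in the first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circular import CircularGenome, extract_window, window_has_ambiguous

GAP_OPEN = 10.0
GAP_EXTEND = 0.5
MATCH = 5.0
MISMATCH = -4.0

NEG = -math.inf


@dataclass(frozen=True)
class Alignment:
    score: float
    aligned_a: str
    aligned_b: str

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    @property
    def matches(self) -> int:
        return sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


@dataclass(frozen=True)
class IdentityResult:
    pos5: int
    pos3: int
    length: int | None
    window5: str
    window3: str
    identity: float | None  # None when a window contains N
    aln_length: int


def global_align(a: str, b: str, gap_open: float = GAP_OPEN,
                 gap_extend: float = GAP_EXTEND, match: float = MATCH,
                 mismatch: float = MISMATCH) -> Alignment:
    """Optimal global alignment with affine, end-free gaps.

    Three-state Gotoh: ``M`` ends in an aligned pair, ``X`` in a gap
    consuming ``a``, ``Y`` in a gap consuming ``b``.  Leading and
    trailing gap runs cost nothing (EMBOSS needle's default global mode);
    the first residue of an internal gap costs ``gap_open + gap_extend``
    and each further residue ``gap_extend``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    for s in (a, b):
        if set(s) - set("ACGT"):
            raise ValueError(f"ambiguous bases in sequence {s!r}")
    n, m = len(a), len(b)
    go = gap_open + gap_extend
    ge = gap_extend

    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b, consumes a
    Y = np.full((n + 1, m + 1), NEG)  # gap in a, consumes b
    M[0, 0] = 0.0
    X[1:, 0] = 0.0  # leading gap free
    Y[0, 1:] = 0.0

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)

    # trailing gaps free: stop anywhere on the last row/column
    best = (NEG, None)
    for i in range(n + 1):
        for st, tab in (("M", M), ("X", X), ("Y", Y)):
            if tab[i, m] > best[0]:
                best = (tab[i, m], (i, m, st))
    for j in range(m + 1):
        for st, tab in (("M", M), ("X", X), ("Y", Y)):
            if tab[n, j] > best[0]:
                best = (tab[n, j], (n, j, st))
    score, (ei, ej, state) = best

    # traceback; free trailing gaps appended first
    out_a = list(a[ei:][::-1] if ej == m else "-" * (m - ej))
    out_b = list("-" * (n - ei) if ej == m else b[ej:][::-1])
    i, j = ei, ej
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                break
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            if abs(M[i, j] - prev) < eps:
                state = "M"
            elif abs(X[i, j] - prev) < eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            if i == 0:
                break
            out_a.append(a[i - 1])
            out_b.append("-")
            if j == 0:  # leading free gap region
                i -= 1
                continue
            val = X[i, j]
            i -= 1
            if abs(M[i, j] - go - val) < eps:
                state = "M"
            elif abs(X[i, j] - ge - val) < eps:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            if j == 0:
                break
            out_a.append("-")
            out_b.append(b[j - 1])
            if i == 0:
                j -= 1
                continue
            val = Y[i, j]
            j -= 1
            if abs(M[i, j] - go - val) < eps:
                state = "M"
            elif abs(X[i, j] - go - val) < eps:
                state = "X"
            else:
                state = "Y"
    # leading free gaps
    while i > 0:
        out_a.append(a[i - 1])
        out_b.append("-")
        i -= 1
    while j > 0:
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    return Alignment(score=float(score), aligned_a="".join(reversed(out_a)),
                     aligned_b="".join(reversed(out_b)))


def breakpoint_window_identity(deletions, g: CircularGenome,
                               flank: int = 10) -> list[IdentityResult]:
    """Identity between the two breakpoint windows of each deletion.

    ``deletions`` may be (pos5, pos3) pairs or objects with ``pos5``,
    ``pos3`` (and optionally ``length``) attributes.  Windows containing
    N are flagged (identity None) and skipped by downstream statistics.
    """
    results = []
    for d in deletions:
        if isinstance(d, tuple):
            pos5, pos3 = d[0], d[1]
            length = d[2] if len(d) > 2 else (pos3 - pos5) % g.L
        else:
            pos5, pos3 = d.pos5, d.pos3
            length = getattr(d, "length", None) or (pos3 - pos5) % g.L
        w5 = extract_window(g, pos5, flank)
        w3 = extract_window(g, pos3, flank)
        if window_has_ambiguous(w5) or window_has_ambiguous(w3):
            results.append(IdentityResult(pos5, pos3, length, w5, w3, None, 0))
            continue
        aln = global_align(w5, w3)
        results.append(
            IdentityResult(pos5, pos3, length, w5, w3, aln.identity,
                           aln.columns)
        )
    return results


def identity_length_relation(results, group_split: int = 100) -> dict:
    """Identity vs deletion length: Pearson r on log10(length) plus a
    gated two-group comparison (lengths <= split vs > split).

    Returns ``r``/``p`` (None when identity is constant or n < 3), group
    means, and the location test chosen by the normality gate.
    """
    from .stats import location_test_gated, pearson

    pts = [
        (r.length, r.identity) for r in results
        if r.identity is not None and r.length
    ]
    out = {
        "n": len(pts), "r": None, "p": None,
        "group_means": {}, "group_test": None,
    }
    if not pts:
        return out
    lengths = np.array([p[0] for p in pts], float)
    idents = np.array([p[1] for p in pts], float)
    if len(pts) >= 3 and np.ptp(idents) > 0 and np.ptp(lengths) > 0:
        res = pearson(np.log10(lengths), idents)
        out["r"], out["p"] = res["r"], res["p"]
    short = idents[lengths <= group_split]
    long_ = idents[lengths > group_split]
    out["group_means"] = {
        f"<={group_split}": float(short.mean()) if short.size else None,
        f">{group_split}": float(long_.mean()) if long_.size else None,
    }
    if short.size >= 2 and long_.size >= 2:
        out["group_test"] = location_test_gated(short, long_)
    return out


def dump_alignments(results, path) -> None:
    """Plain-text pairwise-alignment dump for audit."""
    with open(path, "w") as fh:
        for r in results:
            fh.write(f"# deletion pos5={r.pos5 + 1} pos3={r.pos3 + 1} "
                     f"length={r.length}\n")
            if r.identity is None:
                fh.write("ambiguous window skipped\n\n")
                continue
            aln = global_align(r.window5, r.window3)
            fh.write(aln.aligned_a + "\n")
            fh.write("".join("|" if x == y and x != "-" else " "
                             for x, y in zip(aln.aligned_a, aln.aligned_b)))
            fh.write("\n" + aln.aligned_b + "\n")
            fh.write(f"identity={aln.identity:.2f} score={aln.score:.1f}\n\n")


def write_identity_tsv(results, path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "pos5_1based": r.pos5 + 1,
                "pos3_1based": r.pos3 + 1,
                "length": r.length,
                "window5": r.window5,
                "window3": r.window3,
                "identity": "" if r.identity is None else round(r.identity, 2),
                "aln_length": r.aln_length,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
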