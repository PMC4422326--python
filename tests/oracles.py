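"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: the alignment oracle is
a full Gotoh dynamic program over the complete matrix, and the edit-distance
oracles use the textbook Levenshtein recurrence.
"""

from __future__ import annotations

import numpy as np

NEG = -1e9


def semiglobal_affine_score(
    ref: str,
    read: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Optimal semi-global affine-gap score: reference end gaps free, the
    read fully aligned.  A gap of length k costs open + (k-1)*extend.

    Full Gotoh DP over the (len(read)+1) x (len(ref)+1) matrix with states
    M (diagonal), Ix (gap in the reference / insertion in the read) and
    Iy (gap in the read / deletion).  Rows are vectorised over reference
    positions; the within-row Iy chain uses its running-maximum closed form
    Iy[j] = max_{k<j} M[j=k] + open + (j-1-k)*extend.
    """
    m = len(ref)
    n = len(read)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    js = np.arange(m + 1)
    M = np.zeros(m + 1)          # i = 0: alignment may start at any ref offset
    Ix = np.full(m + 1, NEG)
    Iy = np.full(m + 1, NEG)
    for i in range(n):
        base = read[i].encode()[0]
        s = np.where(ref_arr[: m] == base, match, mismatch)
        prev_best = np.maximum(np.maximum(M, Ix), Iy)
        new_Ix = np.maximum(M + gap_open, Ix + gap_extend)
        new_M = np.full(m + 1, NEG)
        new_M[1:] = prev_best[:-1] + s
        # Iy[j] = max_{k<j} new_M[k] + open + (j-1-k)*extend
        new_Iy = np.full(m + 1, NEG)
        if m:
            run = np.maximum.accumulate(new_M - gap_extend * js)
            new_Iy[1:] = gap_open + gap_extend * (js[1:] - 1) + run[:-1]
        M, Ix, Iy = new_M, new_Ix, new_Iy
    return float(max(M.max(), Ix.max(), Iy.max()))


def levenshtein(a: str, b: str) -> int:
    """Plain full-matrix Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def prefix_edit_distance(query: str, text: str) -> int:
    """Min edits to align all of ``query`` against some prefix of ``text``."""
    prev = list(range(len(query) + 1))   # distances for empty text prefix
    best = prev[-1]
    for cb in text:
        cur = [prev[0] + 1]
        for i, ca in enumerate(query, 1):
            cur.append(min(prev[i] + 1, cur[i - 1] + 1, prev[i - 1] + (ca != cb)))
        prev = cur
        best = min(best, prev[-1])
    return best
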