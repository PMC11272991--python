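"""Exact Smith-Waterman kernels (numba-jitted).

Two kernels compute the same quantity — the optimal local alignment score
under match/mismatch scoring with affine gaps costing ``open + k * extend``
for a gap of length k — plus the identities, column count and subject span
of one optimal path:

``sw_full``
    The classic O(mn) dynamic programme with full traceback.

``sw_banded``
    A banded variant for equal-length sequence pairs, exact by
    construction: if the two sequences mismatch (in the scoring sense) at
    h positions, any alignment path that touches a diagonal offset of
    d > ceil(2.5 h / match) either lies entirely on a far diagonal (at
    most ``match * (L - d)``) or pays gap penalties of at least
    ``open + extend * d``; with the default scheme both bounds fall below
    the main-diagonal path's score of ``match*L - (match - mismatch)*h``,
    so the optimum lives inside the band. The dispatcher picks the band
    from the observed Hamming distance and falls back to the full
    programme when the band would not be smaller.

Ambiguity codes (anything outside ACGT) score as mismatches everywhere,
including against themselves, and never count as identities.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["encode", "sw_align"]

_ENCODE_TABLE = np.full(256, 4, dtype=np.int8)
for _k, _c in enumerate(b"ACGT"):
    _ENCODE_TABLE[_c] = _k

_NEG = -(10**9)


def encode(seq: str) -> np.ndarray:
    """Map an uppercase IUPAC string to codes 0-3 (ACGT) / 4 (ambiguous)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def sw_full(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = q.size, s.size
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int32)  # gap in query
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int32)  # gap in subject
    TB = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    TE = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 = extension
    TF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    go = gap_open + gap_extend
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - go
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                TE[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - go
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                TF[i, j] = 1
            else:
                F[i, j] = f_open
            sj = s[j - 1]
            sub = match if (qi == sj and qi <= 3) else mismatch
            h = H[i - 1, j - 1] + sub
            tb = 1
            if E[i, j] > h:
                h = E[i, j]
                tb = 2
            if F[i, j] > h:
                h = F[i, j]
                tb = 3
            if h <= 0:
                h = 0
                tb = 0
            H[i, j] = h
            TB[i, j] = tb
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0
    i, j = bi, bj
    ident = 0
    length = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        if state == 0:
            tb = TB[i, j]
            if tb == 0:
                break
            if tb == 1:
                length += 1
                if q[i - 1] == s[j - 1] and q[i - 1] <= 3:
                    ident += 1
                i -= 1
                j -= 1
            elif tb == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            length += 1
            ext = TE[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            length += 1
            ext = TF[i, j]
            i -= 1
            if ext == 0:
                state = 0
    return best, ident, length, j, bj


@njit(cache=True)
def sw_banded(q, s, band, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    # equal lengths assumed; cell (i, j) stored at column j - i + band
    n = q.size
    width = 2 * band + 1
    H = np.full((n + 1, width), _NEG, dtype=np.int32)
    E = np.full((n + 1, width), _NEG, dtype=np.int32)
    F = np.full((n + 1, width), _NEG, dtype=np.int32)
    TB = np.zeros((n + 1, width), dtype=np.uint8)
    TE = np.zeros((n + 1, width), dtype=np.uint8)
    TF = np.zeros((n + 1, width), dtype=np.uint8)
    for i in range(0, n + 1):
        lo = i - band
        if lo < 0:
            lo = 0
        hi = i + band
        if hi > n:
            hi = n
        for j in range(lo, hi + 1):
            H[i, j - i + band] = 0
    best = 0
    bi = 0
    bj = 0
    go = gap_open + gap_extend
    for i in range(1, n + 1):
        qi = q[i - 1]
        lo = i - band
        if lo < 1:
            lo = 1
        hi = i + band
        if hi > n:
            hi = n
        for j in range(lo, hi + 1):
            c = j - i + band
            # left neighbour (i, j-1) -> c - 1
            if c - 1 >= 0:
                h_left = H[i, j - 1 - i + band]
                e_left = E[i, j - 1 - i + band]
                e_open = (h_left - go) if h_left > _NEG else _NEG
                e_ext = (e_left - gap_extend) if e_left > _NEG else _NEG
                if e_ext > e_open:
                    E[i, c] = e_ext
                    TE[i, c] = 1
                else:
                    E[i, c] = e_open
            # up neighbour (i-1, j) -> c + 1
            if c + 1 < width:
                h_up = H[i - 1, j - (i - 1) + band]
                f_up = F[i - 1, j - (i - 1) + band]
                f_open = (h_up - go) if h_up > _NEG else _NEG
                f_ext = (f_up - gap_extend) if f_up > _NEG else _NEG
                if f_ext > f_open:
                    F[i, c] = f_ext
                    TF[i, c] = 1
                else:
                    F[i, c] = f_open
            # diagonal neighbour (i-1, j-1) -> same c
            h_diag = H[i - 1, c]
            sj = s[j - 1]
            sub = match if (qi == sj and qi <= 3) else mismatch
            h = (h_diag + sub) if h_diag > _NEG else _NEG
            tb = 1
            if E[i, c] > h:
                h = E[i, c]
                tb = 2
            if F[i, c] > h:
                h = F[i, c]
                tb = 3
            if h <= 0:
                h = 0
                tb = 0
            H[i, c] = h
            TB[i, c] = tb
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0
    i, j = bi, bj
    ident = 0
    length = 0
    state = 0
    while i > 0 and j > 0:
        c = j - i + band
        if state == 0:
            tb = TB[i, c]
            if tb == 0:
                break
            if tb == 1:
                length += 1
                if q[i - 1] == s[j - 1] and q[i - 1] <= 3:
                    ident += 1
                i -= 1
                j -= 1
            elif tb == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            length += 1
            ext = TE[i, c]
            j -= 1
            if ext == 0:
                state = 0
        else:
            length += 1
            ext = TF[i, c]
            i -= 1
            if ext == 0:
                state = 0
    return best, ident, length, j, bj


def _min_exact_band(h: int, match: int, mismatch: int,
                    gap_open: int, gap_extend: int) -> int:
    """Smallest band provably containing the optimum for an equal-length
    pair with h scoring mismatches.

    Main-diagonal full path scores ``match*L - (match - mismatch)*h``;
    a path touching diagonal offset d scores at most
    ``match*L - min(match*d, gap_open + gap_extend*d)``. The band b is the
    smallest offset whose bound falls strictly below the diagonal score,
    i.e. ``min(match*(b+1), gap_open + gap_extend*(b+1))`` must exceed
    ``(match - mismatch) * h``.
    """
    need = (match - mismatch) * h  # penalty budget of the diagonal path
    b = 0
    while min(match * (b + 1), gap_open + gap_extend * (b + 1)) <= need:
        b += 1
    return b


def sw_align(
    q: np.ndarray,
    s: np.ndarray,
    match: int,
    mismatch: int,
    gap_open: int,
    gap_extend: int,
) -> tuple[int, int, int, int, int]:
    """Dispatch to the banded kernel when it is provably exact and smaller.

    Returns ``(raw_score, identities, aln_length, sstart, send)``.
    """
    if q.size == s.size:
        h = int(np.count_nonzero((q != s) | (q > 3) | (s > 3)))
        if h == 0:
            n = q.size
            return match * n, n, n, 0, n
        band = _min_exact_band(h, match, mismatch, gap_open, gap_extend)
        if 2 * band + 1 < s.size:
            return sw_banded(q, s, band, match, mismatch, gap_open, gap_extend)
    return sw_full(q, s, match, mismatch, gap_open, gap_extend)
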