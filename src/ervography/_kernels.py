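"""Numba-jitted alignment kernels and sequence encoding shared across stages.

Encoding: A=0, C=1, G=2, T=3, N=4. With this code, ``base ^ 2`` is the
transition partner and ``base ^ 1`` / ``base ^ 3`` are the two transversions,
which the mutation model and the K2P counters both exploit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (N and anything else -> 4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer codes and their start positions; windows with N dropped."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    vals = codes.astype(np.int64)
    out = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for i in range(k):
        window = vals[i:i + n]
        out = (out << 2) | (window & 3)
        ok &= window < 4
    pos = np.nonzero(ok)[0]
    return out[pos], pos


# ---------------------------------------------------------------------------
# banded local alignment (affine gaps), seed-chain extension
# ---------------------------------------------------------------------------

@njit(cache=False)
def banded_local_align(q, t, diag_lo, diag_hi,
                       match, mismatch, gap_open, gap_ext):  # pragma: no cover - jitted
    """Smith-Waterman restricted to diagonals d = j - i in [diag_lo, diag_hi].

    Returns (score, q_start, q_end, t_start, t_end, matches, aligned_cols);
    ends are exclusive. Ties broken toward the smallest (i, then band column),
    i.e. leftmost-longest.
    """
    lq = q.shape[0]
    lt = t.shape[0]
    width = diag_hi - diag_lo + 1
    NEG = np.float32(-1e9)
    H = np.full((lq + 1, width), NEG, dtype=np.float32)
    E = np.full((lq + 1, width), NEG, dtype=np.float32)  # gap in query (consumes t)
    F = np.full((lq + 1, width), NEG, dtype=np.float32)  # gap in target (consumes q)
    ptr = np.zeros((lq + 1, width), dtype=np.uint8)  # 0 stop, 1 diag, 2 from E, 3 from F
    best = np.float32(0.0)
    bi = 0
    bw = 0
    for i in range(0, lq + 1):
        for w in range(width):
            j = i + diag_lo + w
            if j < 0 or j > lt:
                continue
            if i == 0 or j == 0:
                H[i, w] = 0.0
                ptr[i, w] = 0
                continue
            # E: gap in query, from (i, j-1) = (i, w-1)
            e = NEG
            if w - 1 >= 0:
                prev_h = H[i, w - 1]
                prev_e = E[i, w - 1]
                a = prev_h + gap_open
                b = prev_e + gap_ext
                e = a if a >= b else b
            E[i, w] = e
            # F: gap in target, from (i-1, j) = (i-1, w+1)
            f = NEG
            if w + 1 < width:
                prev_h = H[i - 1, w + 1]
                prev_f = F[i - 1, w + 1]
                a = prev_h + gap_open
                b = prev_f + gap_ext
                f = a if a >= b else b
            F[i, w] = f
            qa = q[i - 1]
            tb = t[j - 1]
            if qa < 4 and qa == tb:
                s = match
            else:
                s = mismatch
            diag = H[i - 1, w] + s
            h = np.float32(0.0)
            p = np.uint8(0)
            if diag > h:
                h = diag
                p = np.uint8(1)
            if e > h:
                h = e
                p = np.uint8(2)
            if f > h:
                h = f
                p = np.uint8(3)
            H[i, w] = h
            ptr[i, w] = p
            if h > best:
                best = h
                bi = i
                bw = w
    # traceback
    i = bi
    w = bw
    q_end = i
    t_end = i + diag_lo + w
    matches = 0
    cols = 0
    state = 0  # 0 in H, 1 in E, 2 in F
    while i > 0:
        j = i + diag_lo + w
        if j <= 0:
            break
        if state == 0:
            p = ptr[i, w]
            if p == 0:
                break
            if p == 1:
                cols += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # E cell at (i, w): came from (i, w-1)
            cols += 1
            from_h = H[i, w - 1] + gap_open
            if E[i, w] == from_h:
                state = 0
            w -= 1
        else:  # F cell: came from (i-1, w+1)
            cols += 1
            from_h = H[i - 1, w + 1] + gap_open
            if F[i, w] == from_h:
                state = 0
            i -= 1
            w += 1
    q_start = i
    t_start = i + diag_lo + w
    return best, q_start, q_end, t_start, t_end, matches, cols


@njit(cache=False)
def profile_align_path(sab, gap_open, gap_ext):  # pragma: no cover - jitted
    """Global affine alignment over a precomputed column-score matrix.

    sab[i, j] is the score of aligning profile-A column i with profile-B
    column j. Returns an int8 path array (0 = both, 1 = gap in B, 2 = gap in A)
    in alignment order. Gap opens only from the match state (deterministic,
    no gap-to-gap switching); ties prefer match > gap-in-B > gap-in-A.
    """
    la, lb = sab.shape
    NEG = np.float32(-1e9)
    M = np.full((la + 1, lb + 1), NEG, dtype=np.float32)
    X = np.full((la + 1, lb + 1), NEG, dtype=np.float32)  # gap in B (consumes A)
    Y = np.full((la + 1, lb + 1), NEG, dtype=np.float32)  # gap in A (consumes B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        x1 = M[i - 1, 0] + gap_open
        x2 = X[i - 1, 0] + gap_ext
        X[i, 0] = x1 if x1 >= x2 else x2
    for j in range(1, lb + 1):
        y1 = M[0, j - 1] + gap_open
        y2 = Y[0, j - 1] + gap_ext
        Y[0, j] = y1 if y1 >= y2 else y2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            prev_best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > prev_best:
                prev_best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > prev_best:
                prev_best = Y[i - 1, j - 1]
            M[i, j] = prev_best + sab[i - 1, j - 1]
            mx = M[i - 1, j] + gap_open
            xx = X[i - 1, j] + gap_ext
            yx = Y[i - 1, j] + gap_open
            best_x = mx
            if xx > best_x:
                best_x = xx
            if yx > best_x:
                best_x = yx
            X[i, j] = best_x
            my = M[i, j - 1] + gap_open
            yy = Y[i, j - 1] + gap_ext
            xy = X[i, j - 1] + gap_open
            best_y = my
            if yy > best_y:
                best_y = yy
            if xy > best_y:
                best_y = xy
            Y[i, j] = best_y
    # traceback
    path = np.empty(la + lb, dtype=np.int8)
    n = 0
    i = la
    j = lb
    # pick final state
    state = 0
    bv = M[la, lb]
    if X[la, lb] > bv:
        bv = X[la, lb]
        state = 1
    if Y[la, lb] > bv:
        bv = Y[la, lb]
        state = 2
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            path[n] = 0
            n += 1
            pb = M[i - 1, j - 1]
            ns = 0
            if X[i - 1, j - 1] > pb:
                pb = X[i - 1, j - 1]
                ns = 1
            if Y[i - 1, j - 1] > pb:
                pb = Y[i - 1, j - 1]
                ns = 2
            i -= 1
            j -= 1
            state = ns
        elif state == 1 and i > 0:
            path[n] = 1
            n += 1
            v = X[i, j]
            if v == M[i - 1, j] + gap_open:
                ns = 0
            elif v == X[i - 1, j] + gap_ext:
                ns = 1
            else:
                ns = 2
            i -= 1
            state = ns
        elif state == 2 and j > 0:
            path[n] = 2
            n += 1
            v = Y[i, j]
            if v == M[i, j - 1] + gap_open:
                ns = 0
            elif v == Y[i, j - 1] + gap_ext:
                ns = 2
            else:
                ns = 1
            j -= 1
            state = ns
        elif i > 0:
            path[n] = 1
            n += 1
            i -= 1
        else:
            path[n] = 2
            n += 1
            j -= 1
    return path[:n][::-1].copy()
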