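"""Pairwise alignment kernels over a small DNA alphabet with meta-symbols.

Two dynamic programs are implemented here:

* a global (Needleman-Wunsch) aligner with a linear gap penalty over an
  extended alphabet that includes a "sticky" intron meta-symbol, used to
  transfer intron positions between orthologous transcripts; and
* a local (Smith-Waterman) aligner with affine gaps, used to detect
  conserved sequence within orthologous introns.

Sequences are encoded as ``int8`` arrays: A=0, C=1, G=2, T=3, N=4,
META=5, MASK=6.  MASK is a sentinel used to blank out previously
reported local alignments; it scores ``FORBID`` against everything so a
masked region can never be re-used.  META may only pair with META.

The inner loops are compiled with numba; tracebacks are done in Python
on the stored score matrices (path lengths are short relative to the
matrix fill).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

A, C, G, T, N = 0, 1, 2, 3, 4
META = 5
MASK = 6
N_SYMBOLS = 7

#: large negative score standing in for -inf; chosen so that two of them
#: summed still fit comfortably in int32
FORBID = -(2**24)

_BASE_CODE = {"A": A, "C": C, "G": G, "T": T, "N": N, "|": META}
_CODE_BASE = np.array(list("ACGTN|#"))

_COMPLEMENT = np.array([T, G, C, A, N, META, MASK], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string (optionally containing ``|`` meta-symbols)."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        out[i] = _BASE_CODE.get(ch, N)
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(_CODE_BASE[codes])


def reverse_complement(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


@dataclass(frozen=True)
class StickyScoring:
    """Scoring scheme for the sticky global aligner.

    The meta-symbol bonus is large relative to base scores so aligned
    intron positions attract each other; meta-base pairing is forbidden
    outright (a gap is always preferred).
    """

    match: int = 1
    mismatch: int = -1
    gap: int = 2            # linear penalty per gapped symbol (positive)
    meta_bonus: int = 10

    def matrix(self) -> np.ndarray:
        S = np.full((N_SYMBOLS, N_SYMBOLS), self.mismatch, dtype=np.int32)
        for b in (A, C, G, T):
            S[b, b] = self.match
        # N never rewards a match
        S[N, :] = self.mismatch
        S[:, N] = self.mismatch
        S[META, :] = FORBID
        S[:, META] = FORBID
        S[META, META] = self.meta_bonus
        S[MASK, :] = FORBID
        S[:, MASK] = FORBID
        return S


@dataclass(frozen=True)
class LocalScoring:
    """Affine-gap Smith-Waterman scoring (first gap position pays
    ``gap_open``, each further position ``gap_extend``)."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = 4       # positive costs
    gap_extend: int = 1


@njit(cache=True)
def _nw_fill(a, b, S, gap):
    m = a.size
    n = b.size
    H = np.empty((m + 1, n + 1), dtype=np.int32)
    for j in range(n + 1):
        H[0, j] = -gap * j
    for i in range(1, m + 1):
        H[i, 0] = -gap * i
        ai = a[i - 1]
        for j in range(1, n + 1):
            v = H[i - 1, j - 1] + S[ai, b[j - 1]]
            u = H[i - 1, j] - gap
            if u > v:
                v = u
            l = H[i, j - 1] - gap
            if l > v:
                v = l
            H[i, j] = v
    return H


def nw_align(a: np.ndarray, b: np.ndarray, scoring: StickyScoring = StickyScoring()):
    """Global alignment; returns (score, aligned index pairs).

    ``pairs`` lists ``(i, j)`` positions placed in the same alignment
    column (matches and mismatches, not gaps).  Traceback prefers
    diagonal, then up, then left moves, which makes the reported path
    deterministic.
    """
    S = scoring.matrix()
    gap = scoring.gap
    H = _nw_fill(a, b, S, gap)
    pairs = []
    i, j = a.size, b.size
    while i > 0 and j > 0:
        h = H[i, j]
        if h == H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif h == H[i - 1, j] - gap:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return int(H[a.size, b.size]), pairs


@njit(cache=True)
def _sw_best(a, b, match, mismatch, gap_open, gap_extend):
    """Affine local alignment, score only; O(n) memory.

    Returns (best score, end_i, end_j) with the 0-based inclusive end
    positions of the best-scoring alignment; the first (row-major,
    then column) maximum is reported, making the result deterministic.
    """
    m = a.size
    n = b.size
    NEG = -(2**30)
    Hp = np.zeros(n + 1, dtype=np.int32)   # previous row H
    Fp = np.full(n + 1, NEG, dtype=np.int32)  # previous row F
    best = 0
    bi = -1
    bj = -1
    Hc = np.zeros(n + 1, dtype=np.int32)
    Ec = np.full(n + 1, NEG, dtype=np.int32)
    Fc = np.full(n + 1, NEG, dtype=np.int32)
    for i in range(1, m + 1):
        Hc[0] = 0
        Ec[0] = NEG
        ai = a[i - 1]
        for j in range(1, n + 1):
            # E: gap in b (move left); F: gap in a (move up)
            e = Hc[j - 1] - gap_open
            t = Ec[j - 1] - gap_extend
            if t > e:
                e = t
            f = Hp[j] - gap_open
            t = Fp[j] - gap_extend
            if t > f:
                f = t
            bj_sym = b[j - 1]
            if ai >= META or bj_sym >= META:
                s = FORBID
            elif ai == bj_sym and ai != N:
                s = match
            else:
                s = mismatch
            h = Hp[j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hc[j] = h
            Ec[j] = e
            Fc[j] = f
            if h > best:
                best = h
                bi = i - 1
                bj = j - 1
        # roll rows
        for j in range(n + 1):
            Hp[j] = Hc[j]
            Fp[j] = Fc[j]
    return best, bi, bj


def sw_best(a: np.ndarray, b: np.ndarray, scoring: LocalScoring = LocalScoring()):
    """Best local alignment score and end position (score-only kernel)."""
    s, i, j = _sw_best(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    return int(s), int(i), int(j)


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):
    m = a.size
    n = b.size
    NEG = -(2**30)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    best = 0
    bi = -1
    bj = -1
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] - gap_open
            t = E[i, j - 1] - gap_extend
            if t > e:
                e = t
            f = H[i - 1, j] - gap_open
            t = F[i - 1, j] - gap_extend
            if t > f:
                f = t
            bsym = b[j - 1]
            if ai >= META or bsym >= META:
                s = FORBID
            elif ai == bsym and ai != N:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def sw_align(a: np.ndarray, b: np.ndarray, scoring: LocalScoring = LocalScoring()):
    """Best local alignment with traceback.

    Returns ``(score, (a_start, a_end), (b_start, b_end))`` with 0-based
    half-open intervals, or ``(0, None, None)`` when no positive-scoring
    alignment exists.
    """
    H, E, F, best, bi, bj = _sw_fill(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if best <= 0:
        return 0, None, None
    go, ge = scoring.gap_open, scoring.gap_extend
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            if a[i - 1] < META and b[j - 1] < META:
                s = scoring.match if (a[i - 1] == b[j - 1] and a[i - 1] != N) else scoring.mismatch
            else:
                s = FORBID
            if h == H[i - 1, j - 1] + s:
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "E":
            if E[i, j] == E[i, j - 1] - ge:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            if F[i, j] == F[i - 1, j] - ge:
                i -= 1
            else:
                i -= 1
                state = "H"
    return int(best), (i, bi), (j, bj)


def warm_up() -> None:
    """Trigger numba compilation on tiny inputs (optional)."""
    a = encode("ACGT")
    b = encode("ACGT")
    nw_align(a, b)
    sw_best(a, b)
    sw_align(a, b)
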