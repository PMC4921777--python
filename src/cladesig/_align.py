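"""Low-level dynamic-programming alignment kernels.

All pairwise and profile alignments in the package go through the
numba-compiled routines in this module.  Scoring is BLOSUM62 with affine
gap penalties (gap open 11, gap extend 1): a gap of length *k* costs
``11 + (k - 1) * 1``, i.e. the open penalty is charged for the first
gapped position.  Terminal gaps are penalized in global alignments.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

#: Canonical amino-acid alphabet; ``X`` (unknown) is the last code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
GAP = "-"

_CODE = {aa: i for i, aa in enumerate(ALPHABET)}
N_AA = 20  # codes 0..19 are real residues, 20 is X

GAP_OPEN = 11.0
GAP_EXTEND = 1.0

NEG_INF = -1e30


def _load_blosum62() -> np.ndarray:
    """BLOSUM62 reindexed to :data:`ALPHABET` as a float64 matrix."""
    raw = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            m[i, j] = raw[a, b]
    return m


BLOSUM62 = _load_blosum62()


def encode(residues: str) -> np.ndarray:
    """Encode an ungapped amino-acid string as uint8 codes."""
    try:
        return np.fromiter((_CODE[c] for c in residues), dtype=np.uint8,
                           count=len(residues))
    except KeyError as exc:  # pragma: no cover - guarded by io validation
        raise ValueError(f"illegal residue {exc.args[0]!r}") from exc


# traceback codes
_DIAG, _UP, _LEFT = 0, 1, 2
# state codes
_M, _IX, _IY = 0, 1, 2


@njit(cache=True)
def _global_affine(a, b, sub, gap_open, gap_extend):
    """Global affine NW with rolling score rows and full pointer matrices.

    Returns (score, column type codes 0=diag/1=up/2=left in alignment order).
    """
    la, lb = a.shape[0], b.shape[0]
    # rolling rows of state scores for row i-1 / i
    M = np.full(lb + 1, NEG_INF, dtype=np.float64)
    Ix = np.full(lb + 1, NEG_INF, dtype=np.float64)  # gap in b
    Iy = np.full(lb + 1, NEG_INF, dtype=np.float64)  # gap in a
    pM = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    pX = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    pY = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    M[0] = 0.0
    for j in range(1, lb + 1):
        Iy[j] = -(gap_open + (j - 1) * gap_extend)
        pY[0, j] = _IY if j > 1 else _M
    for i in range(1, la + 1):
        subrow = sub[a[i - 1]]
        # cell (i, 0)
        m_diag = M[0]
        ix_diag = Ix[0]
        iy_diag = Iy[0]
        M[0] = NEG_INF
        Iy[0] = NEG_INF
        Ix[0] = -(gap_open + (i - 1) * gap_extend)
        pX[i, 0] = _IX if i > 1 else _M
        iy_left = NEG_INF
        m_left = NEG_INF
        ix_left = Ix[0]
        for j in range(1, lb + 1):
            s = subrow[b[j - 1]]
            m_up = M[j]
            ix_up = Ix[j]
            iy_up = Iy[j]
            # match state from diagonal of row i-1
            best = m_diag
            st = _M
            if ix_diag > best:
                best = ix_diag
                st = _IX
            if iy_diag > best:
                best = iy_diag
                st = _IY
            m_new = best + s
            pM[i, j] = st
            # gap in b (vertical, consume a[i-1]) from row i-1 same column
            best = m_up - gap_open
            st = _M
            if ix_up - gap_extend > best:
                best = ix_up - gap_extend
                st = _IX
            if iy_up - gap_open > best:
                best = iy_up - gap_open
                st = _IY
            ix_new = best
            pX[i, j] = st
            # gap in a (horizontal, consume b[j-1]) from column j-1 same row
            best = m_left - gap_open
            st = _M
            if iy_left - gap_extend > best:
                best = iy_left - gap_extend
                st = _IY
            if ix_left - gap_open > best:
                best = ix_left - gap_open
                st = _IX
            iy_new = best
            pY[i, j] = st
            m_diag = m_up
            ix_diag = ix_up
            iy_diag = iy_up
            M[j] = m_new
            Ix[j] = ix_new
            Iy[j] = iy_new
            m_left = m_new
            ix_left = ix_new
            iy_left = iy_new
    score = M[lb]
    state = _M
    if Ix[lb] > score:
        score = Ix[lb]
        state = _IX
    if Iy[lb] > score:
        score = Iy[lb]
        state = _IY
    cols = np.empty(la + lb, dtype=np.uint8)
    k = 0
    i, j = la, lb
    while i > 0 or j > 0:
        if state == _M:
            prev = pM[i, j]
            cols[k] = _DIAG
            i -= 1
            j -= 1
        elif state == _IX:
            prev = pX[i, j]
            cols[k] = _UP
            i -= 1
        else:
            prev = pY[i, j]
            cols[k] = _LEFT
            j -= 1
        state = prev
        k += 1
    return score, cols[:k][::-1].copy()


@njit(cache=True)
def _pairwise_stats(a, b, cols, n_aa):
    """Identity/coverage statistics from an alignment column-type path.

    Returns (n_identical, n_nonterminal_cols, a_res_nonterminal,
    b_res_nonterminal).  Terminal columns are the leading and trailing
    runs of gap-type columns; ``X`` never counts as identical.
    """
    n = cols.shape[0]
    first = 0
    while first < n and cols[first] != _DIAG:
        first += 1
    last = n - 1
    while last >= 0 and cols[last] != _DIAG:
        last -= 1
    n_ident = 0
    n_cols = 0
    a_res = 0
    b_res = 0
    i = 0
    j = 0
    for k in range(n):
        c = cols[k]
        inner = first <= k <= last
        if c == _DIAG:
            if inner:
                n_cols += 1
                a_res += 1
                b_res += 1
                if a[i] == b[j] and a[i] < n_aa:
                    n_ident += 1
            i += 1
            j += 1
        elif c == _UP:
            if inner:
                n_cols += 1
                a_res += 1
            i += 1
        else:
            if inner:
                n_cols += 1
                b_res += 1
            j += 1
    return n_ident, n_cols, a_res, b_res


def global_alignment_stats(a: np.ndarray, b: np.ndarray,
                           sub: np.ndarray = BLOSUM62,
                           gap_open: float = GAP_OPEN,
                           gap_extend: float = GAP_EXTEND):
    """Globally align two encoded sequences; return (score, identity,
    coverage_a, coverage_b).

    identity = identical columns / alignment columns, both counted over
    the non-terminal region of the alignment (terminal-gap runs at either
    end are excluded from the denominator).  coverage_x = residues of x
    falling in the non-terminal region / len(x).
    """
    score, cols = _global_affine(a, b, sub, gap_open, gap_extend)
    n_ident, n_cols, a_res, b_res = _pairwise_stats(a, b, cols, N_AA)
    identity = n_ident / n_cols if n_cols else 0.0
    return float(score), identity, a_res / len(a), b_res / len(b)


def global_alignment_path(a: np.ndarray, b: np.ndarray,
                          sub: np.ndarray = BLOSUM62,
                          gap_open: float = GAP_OPEN,
                          gap_extend: float = GAP_EXTEND):
    """Globally align and return (score, column type codes 0=diag/1=up/2=left)."""
    return _global_affine(a, b, sub, gap_open, gap_extend)


@njit(cache=True)
def profile_nw(S, gap_open, gap_extend):
    """Global affine alignment over a precomputed profile-profile score
    matrix ``S`` (L1 x L2).  Returns (score, column codes)."""
    la, lb = S.shape
    M = np.full((la + 1, lb + 1), NEG_INF, dtype=np.float64)
    Ix = np.full((la + 1, lb + 1), NEG_INF, dtype=np.float64)
    Iy = np.full((la + 1, lb + 1), NEG_INF, dtype=np.float64)
    pM = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    pX = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    pY = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
        pX[i, 0] = _IX if i > 1 else _M
    for j in range(1, lb + 1):
        Iy[0, j] = -(gap_open + (j - 1) * gap_extend)
        pY[0, j] = _IY if j > 1 else _M
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = S[i - 1, j - 1]
            best = M[i - 1, j - 1]
            st = _M
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                st = _IX
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                st = _IY
            M[i, j] = best + s
            pM[i, j] = st
            best = M[i - 1, j] - gap_open
            st = _M
            if Ix[i - 1, j] - gap_extend > best:
                best = Ix[i - 1, j] - gap_extend
                st = _IX
            if Iy[i - 1, j] - gap_open > best:
                best = Iy[i - 1, j] - gap_open
                st = _IY
            Ix[i, j] = best
            pX[i, j] = st
            best = M[i, j - 1] - gap_open
            st = _M
            if Iy[i, j - 1] - gap_extend > best:
                best = Iy[i, j - 1] - gap_extend
                st = _IY
            if Ix[i, j - 1] - gap_open > best:
                best = Ix[i, j - 1] - gap_open
                st = _IX
            Iy[i, j] = best
            pY[i, j] = st
    score = M[la, lb]
    state = _M
    if Ix[la, lb] > score:
        score = Ix[la, lb]
        state = _IX
    if Iy[la, lb] > score:
        score = Iy[la, lb]
        state = _IY
    cols = np.empty(la + lb, dtype=np.uint8)
    k = 0
    i, j = la, lb
    while i > 0 or j > 0:
        if state == _M:
            prev = pM[i, j]
            cols[k] = _DIAG
            i -= 1
            j -= 1
        elif state == _IX:
            prev = pX[i, j]
            cols[k] = _UP
            i -= 1
        else:
            prev = pY[i, j]
            cols[k] = _LEFT
            j -= 1
        state = prev
        k += 1
    return score, cols[:k][::-1].copy()


@njit(cache=True)
def smith_waterman_score(a, b, sub, gap_open, gap_extend):
    """Best local alignment score (affine gaps), linear memory."""
    la, lb = a.shape[0], b.shape[0]
    H = np.zeros(lb + 1, dtype=np.float64)    # row i-1, overwritten in place
    Ix = np.full(lb + 1, NEG_INF, dtype=np.float64)  # gap-in-b state, per column
    best = 0.0
    for i in range(1, la + 1):
        subrow = sub[a[i - 1]]
        diag = H[0]
        iy = NEG_INF  # gap-in-a state within the current row
        for j in range(1, lb + 1):
            ix = H[j] - gap_open          # H[j] still holds H[i-1, j]
            t = Ix[j] - gap_extend
            if t > ix:
                ix = t
            iy_new = H[j - 1] - gap_open  # H[j-1] already updated to H[i, j-1]
            t = iy - gap_extend
            if t > iy_new:
                iy_new = t
            hi = diag + subrow[b[j - 1]]
            if ix > hi:
                hi = ix
            if iy_new > hi:
                hi = iy_new
            if hi < 0.0:
                hi = 0.0
            diag = H[j]
            H[j] = hi
            Ix[j] = ix
            iy = iy_new
            if hi > best:
                best = hi
    return best


@njit(cache=True)
def smith_waterman_full(a, b, sub, gap_open, gap_extend):
    """Local alignment with traceback.

    Returns (score, a_start, a_end, b_start, b_end, n_identical,
    n_columns, n_mismatch, n_gap_opens); coordinates 1-based inclusive.
    """
    la, lb = a.shape[0], b.shape[0]
    H = np.zeros((la + 1, lb + 1), dtype=np.float64)
    Ix = np.full((la + 1, lb + 1), NEG_INF, dtype=np.float64)
    Iy = np.full((la + 1, lb + 1), NEG_INF, dtype=np.float64)
    ptr = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 0 stop 1 diag 2 up 3 left
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            ix = H[i - 1, j] - gap_open
            if Ix[i - 1, j] - gap_extend > ix:
                ix = Ix[i - 1, j] - gap_extend
            Ix[i, j] = ix
            iy = H[i, j - 1] - gap_open
            if Iy[i, j - 1] - gap_extend > iy:
                iy = Iy[i, j - 1] - gap_extend
            Iy[i, j] = iy
            m = H[i - 1, j - 1] + sub[ai, b[j - 1]]
            hi = 0.0
            p = 0
            if m > hi:
                hi = m
                p = 1
            if ix > hi:
                hi = ix
                p = 2
            if iy > hi:
                hi = iy
                p = 3
            H[i, j] = hi
            ptr[i, j] = p
            if hi > best:
                best = hi
                bi = i
                bj = j
    # traceback
    i, j = bi, bj
    n_id = 0
    n_cols = 0
    n_mm = 0
    n_go = 0
    prev_gap = 0
    while i > 0 and j > 0 and H[i, j] > 0.0:
        p = ptr[i, j]
        if p == 0:
            break
        n_cols += 1
        if p == 1:
            if a[i - 1] == b[j - 1] and a[i - 1] < 20:
                n_id += 1
            else:
                n_mm += 1
            prev_gap = 0
            i -= 1
            j -= 1
        elif p == 2:
            if prev_gap != 2:
                n_go += 1
            prev_gap = 2
            i -= 1
        else:
            if prev_gap != 3:
                n_go += 1
            prev_gap = 3
            j -= 1
    return best, i + 1, bi, j + 1, bj, n_id, n_cols, n_mm, n_go


def warmup() -> None:
    """Trigger compilation of all kernels on tiny inputs."""
    a = encode("ACDE")
    b = encode("ACE")
    global_alignment_stats(a, b)
    profile_nw(np.zeros((3, 3), dtype=np.float64), GAP_OPEN, GAP_EXTEND)
    smith_waterman_full(a, b, BLOSUM62, GAP_OPEN, GAP_EXTEND)
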