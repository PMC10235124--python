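"""Affine-gap local protein alignment engine.

Exact Smith-Waterman dynamic programming over encoded amino-acid
sequences, compiled with numba.  A gap of length ``k`` costs
``open + k * extend`` (BLAST convention), so the recurrence charges
``open + extend`` to open a gap and ``extend`` per additional residue.

Multiple high-scoring segment pairs (HSPs) per sequence pair are
recovered by masking the query residues of each reported alignment and
re-running the DP until the score drops below the reporting threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

#: Alignment alphabet; ``X`` absorbs ambiguous residues, ``*`` is a stop.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}
_X = _AA_INDEX["X"]

#: Sentinel index used to mask query residues between HSP iterations.
MASK = len(AA_ALPHABET)


def load_blosum62() -> np.ndarray:
    """BLOSUM62 as an int32 matrix over :data:`AA_ALPHABET` plus a mask row."""
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(AA_ALPHABET)
    mat = np.full((n + 1, n + 1), -4, dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            mat[i, j] = int(blosum[a][b])
    mat[MASK, :] = -10_000
    mat[:, MASK] = -10_000
    return mat


_BLOSUM62 = load_blosum62()


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string as indices into :data:`AA_ALPHABET`."""
    return np.array([_AA_INDEX.get(c, _X) for c in seq.upper()], dtype=np.int8)


@njit(cache=False)
def _sw_fill(q, s, mat, gap_open, gap_extend):  # pragma: no cover - numba
    m, n = len(q), len(s)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -(10**8), dtype=np.int32)
    F = np.full((m + 1, n + 1), -(10**8), dtype=np.int32)
    oe = gap_open + gap_extend
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - oe
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            E[i, j] = e
            f = H[i - 1, j] - oe
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=False)
def _sw_score_only(q, s, mat, gap_open, gap_extend):  # pragma: no cover - numba
    """Best local score with O(n) memory (used by the seed prefilter path)."""
    m, n = len(q), len(s)
    Hp = np.zeros(n + 1, dtype=np.int32)
    Ep = np.full(n + 1, -(10**8), dtype=np.int32)
    Fc = np.full(n + 1, -(10**8), dtype=np.int32)
    oe = gap_open + gap_extend
    best = 0
    for i in range(1, m + 1):
        h_diag = 0
        h_left = 0
        for j in range(1, n + 1):
            e = h_left - oe
            if Ep[j - 1] - gap_extend > e:
                e = Ep[j - 1] - gap_extend
            f = Hp[j] - oe
            if Fc[j] - gap_extend > f:
                f = Fc[j] - gap_extend
            Fc[j] = f
            h = h_diag + mat[q[i - 1], s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_diag = Hp[j]
            Hp[j] = h
            h_left = h
            Ep[j] = e
            if h > best:
                best = h
    return best


@dataclass(frozen=True)
class LocalAlignment:
    """One gapped local alignment between a query and a subject."""

    score: int
    #: 0-based half-open residue interval on the query.
    query_start: int
    query_end: int
    #: 0-based half-open residue interval on the subject.
    subject_start: int
    subject_end: int
    #: identical residue pairs among aligned columns
    matches: int
    #: total alignment columns including gap columns
    columns: int
    #: gapped query residues (columns with a gap in the query)
    query_gaps: int
    subject_gaps: int

    @property
    def identity(self) -> float:
        """Percent identity over all alignment columns (gaps count)."""
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def _traceback(q, s, mat, gap_open, gap_extend, H, E, F, bi, bj) -> LocalAlignment:
    oe = gap_open + gap_extend
    i, j = bi, bj
    matches = columns = qgaps = sgaps = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]
            if H[i, j] == diag:
                if q[i - 1] == s[j - 1]:
                    matches += 1
                columns += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in query, consume subject residue
            columns += 1
            qgaps += 1
            if E[i, j] == H[i, j - 1] - oe:
                state = "H"
            j -= 1
        else:  # gap in subject, consume query residue
            columns += 1
            sgaps += 1
            if F[i, j] == H[i - 1, j] - oe:
                state = "H"
            i -= 1
    return LocalAlignment(
        score=int(H[bi, bj]),
        query_start=i,
        query_end=bi,
        subject_start=j,
        subject_end=bj,
        matches=matches,
        columns=columns,
        query_gaps=qgaps,
        subject_gaps=sgaps,
    )


def smith_waterman(
    query: np.ndarray,
    subject: np.ndarray,
    matrix: np.ndarray | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
    min_score: int = 1,
    max_hsps: int = 1,
) -> list[LocalAlignment]:
    """All (up to ``max_hsps``) local alignments scoring >= ``min_score``.

    Ties during traceback prefer the diagonal, then a gap in the query,
    then a gap in the subject, making outputs deterministic.  Successive
    HSPs are found by masking the query span of each reported alignment.
    """
    if matrix is None:
        matrix = _BLOSUM62
    if len(query) == 0 or len(subject) == 0:
        return []
    q = query.astype(np.int8).copy()
    out: list[LocalAlignment] = []
    for _ in range(max_hsps):
        H, E, F, best, bi, bj = _sw_fill(q, subject, matrix, gap_open, gap_extend)
        if best < min_score:
            break
        aln = _traceback(q, subject, matrix, gap_open, gap_extend, H, E, F, bi, bj)
        out.append(aln)
        q[aln.query_start : aln.query_end] = MASK
    return out


@njit(cache=False)
def _nw_fill(a, b, match, mismatch, gap):  # pragma: no cover - numba
    m, n = len(a), len(b)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    for i in range(1, m + 1):
        H[i, 0] = H[i - 1, 0] + gap
    for j in range(1, n + 1):
        H[0, j] = H[0, j - 1] + gap
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if H[i - 1, j] + gap > h:
                h = H[i - 1, j] + gap
            if H[i, j - 1] + gap > h:
                h = H[i, j - 1] + gap
            H[i, j] = h
    return H


def needleman_wunsch_identity(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[int, int, int]:
    """Global alignment; returns (score, matches, columns).

    Linear gap penalty; traceback ties prefer diagonal, then a gap in
    ``b`` (consume ``a``), then a gap in ``a``, so identity is
    deterministic among co-optimal alignments.
    """
    av = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bv = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    H = _nw_fill(av, bv, match, mismatch, gap)
    i, j = len(av), len(bv)
    matches = columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if av[i - 1] == bv[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                if av[i - 1] == bv[j - 1]:
                    matches += 1
                columns += 1
                i -= 1
                j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + gap:
            columns += 1
            i -= 1
            continue
        columns += 1
        j -= 1
    return int(H[len(av), len(bv)]), matches, columns


def best_local_score(
    query: np.ndarray,
    subject: np.ndarray,
    matrix: np.ndarray | None = None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> int:
    if matrix is None:
        matrix = _BLOSUM62
    if len(query) == 0 or len(subject) == 0:
        return 0
    return int(_sw_score_only(query.astype(np.int8), subject, matrix, gap_open, gap_extend))
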