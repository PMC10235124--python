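"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the mathematical definition, without
touching the package's own engines, so agreement is meaningful.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

_BLOSUM = substitution_matrices.load("BLOSUM62")
_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)


def sw_best_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Affine-gap Smith-Waterman best local score, plain-Python DP.

    A gap of length k costs gap_open + k * gap_extend.
    """
    m, n = len(a), len(b)
    NEG = -(10**9)
    best = 0
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    oe = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - oe, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - oe, F[i - 1][j] - gap_extend)
            try:
                s = int(_BLOSUM[a[i - 1]][b[j - 1]])
            except (KeyError, IndexError):
                s = -4
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def needleman_wunsch_identity(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> float:
    """Percent identity of a global alignment; ties prefer diagonal,
    then gap in b, then gap in a (matching the package's convention)."""
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        H[i][0] = i * gap
    for j in range(1, n + 1):
        H[0][j] = j * gap
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
    i, j = m, n
    matches = columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i][j] == H[i - 1][j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            matches += a[i - 1] == b[j - 1]
            columns += 1
            i -= 1
            j -= 1
        elif i > 0 and H[i][j] == H[i - 1][j] + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return 100.0 * matches / columns


def stop_free_orfs(dna: str, min_len_aa: int):
    """All maximal stop-free segments >= min_len_aa across six frames,
    as (start, end, frame) forward-strand intervals."""
    out = set()
    L = len(dna)
    for frame in (1, 2, 3, -1, -2, -3):
        seq = dna if frame > 0 else str(Seq(dna).reverse_complement())
        off = abs(frame) - 1
        trimmed = seq[off : off + (len(seq) - off) - (len(seq) - off) % 3]
        aa = str(Seq(trimmed).translate(table=1)) if trimmed else ""
        i = 0
        while i < len(aa):
            if aa[i] == "*":
                i += 1
                continue
            j = i
            while j < len(aa) and aa[j] != "*":
                j += 1
            if j - i >= min_len_aa:
                lo, hi = off + 3 * i, off + 3 * j
                if frame > 0:
                    out.add((lo, hi, frame))
                else:
                    out.add((L - hi, L - lo, frame))
            i = j
    return out


def sl_scan_bruteforce(
    region: str, query: str, ambiguous: set[int], word: int, min_matches: int
):
    """All-positions comparison on both strands; (start, strand, matches)."""
    comp = str.maketrans("ACGTN", "TGCAN")
    hits = []
    for strand in "+-":
        if strand == "+":
            q, amb = query, ambiguous
        else:
            q = query.translate(comp)[::-1]
            amb = {len(query) - 1 - a for a in ambiguous}
        for p in range(len(region) - len(q) + 1):
            ok = [i in amb or region[p + i] == q[i] for i in range(len(q))]
            # seed: a run of `word` consecutive matched positions
            has_seed = any(all(ok[i : i + word]) for i in range(len(q) - word + 1))
            if has_seed and sum(ok) >= min_matches:
                hits.append((p, strand, sum(ok)))
    return hits


def ng86_codon_diffs(c1: str, c2: str):
    """(Sd, Nd) by explicit enumeration of all substitution orderings."""
    fwd = _TABLE.forward_table
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd = nd = 0.0
    paths = list(itertools.permutations(diff))
    for order in paths:
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa_cur = fwd.get(cur)
            aa_nxt = fwd.get(nxt)
            if aa_cur is not None and aa_cur == aa_nxt:
                sd += 1.0 / len(paths)
            else:
                nd += 1.0 / len(paths)
            cur = nxt
    return sd, nd
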