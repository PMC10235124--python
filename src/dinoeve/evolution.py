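"""Sequence comparison: identity, codon back-alignment, dN/dS, NJ trees.

The selection statistic is the Nei-Gojobori (1986) counting estimator:
synonymous (S) and nonsynonymous (N) sites are counted per codon
(mutations creating a stop codon count as nonsynonymous; every sense
codon contributes exactly three sites), observed differences are
averaged with equal weight over all mutational pathways for codons
differing at more than one position, and proportions are corrected for
multiple hits with Jukes-Cantor, ``d = -3/4 ln(1 - 4p/3)``.
``omega = dN/dS`` is reported with 1 indicating neutral evolution;
endogenized viral ORFs drifting at the host rate are expected near 1,
unlike exogenous coding sequence under purifying selection.

This is a deliberate estimator choice: counting methods are
self-contained and transparent at the scale of EVE ORF pairs, whereas
maximum-likelihood codon models add machinery without changing the
neutral-regime conclusion the statistic exists to support.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from ._align import needleman_wunsch_identity
from .core import InputError

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)  # sense codons only
_BASES = "ACGT"


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity from a global alignment (matches / columns)."""
    if not a or not b:
        raise InputError("pairwise_identity: empty sequence")
    _, matches, columns = needleman_wunsch_identity(a, b)
    return 100.0 * matches / columns


def identity_distance_matrix(seqs: dict[str, str]) -> pd.DataFrame:
    """Pairwise (1 - identity/100) distances, suitable for nj_tree."""
    ids = list(seqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dist = 1.0 - pairwise_identity(seqs[ids[i]], seqs[ids[j]]) / 100.0
        d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass(frozen=True)
class CodonAlignment:
    """Gapped in-frame CDS rows; gap columns come in whole codons."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    source_alignment_id: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows) or len(self.rows) < 1:
            raise InputError("codon alignment needs matching ids and rows")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise InputError("codon alignment rows differ in length")
        if ncol % 3 != 0:
            raise InputError("codon alignment column count not divisible by 3")

    @property
    def n_codon_columns(self) -> int:
        return len(self.rows[0]) // 3

    def codons(self, row: int) -> list[str]:
        r = self.rows[row]
        return [r[i : i + 3] for i in range(0, len(r), 3)]

    def has_internal_stop(self) -> bool:
        return any(
            c in _STOPS for k in range(len(self.rows)) for c in self.codons(k)[:-1]
        )


def codon_backalign(
    protein_ids: Sequence[str],
    protein_rows: Sequence[str],
    cds: dict[str, str],
    alignment_id: str = "",
) -> CodonAlignment:
    """Thread unaligned CDS through a gapped protein alignment.

    Every protein gap becomes a ``---`` codon gap and codons are
    preserved verbatim.  Each CDS must translate to its ungapped
    protein row (a trailing stop codon is tolerated).
    """
    out_rows = []
    for rid, prow in zip(protein_ids, protein_rows, strict=True):
        if rid not in cds:
            raise InputError(f"codon_backalign: no CDS for row {rid!r}")
        nt = cds[rid].upper().replace("U", "T")
        if len(nt) % 3 != 0:
            raise InputError(f"codon_backalign: CDS {rid!r} length not multiple of 3")
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        if codons and codons[-1] in _STOPS:
            codons = codons[:-1]
        ungapped = prow.replace("-", "")
        if len(codons) != len(ungapped):
            raise InputError(
                f"codon_backalign: CDS {rid!r} has {len(codons)} codons but "
                f"protein row has {len(ungapped)} residues"
            )
        for pos, (codon, aa) in enumerate(zip(codons, ungapped)):
            trans = str(Seq(codon).translate(table=1))
            if trans != aa.upper() and aa.upper() != "X":
                raise InputError(
                    f"codon_backalign: row {rid!r} position {pos}: codon "
                    f"{codon} translates to {trans}, protein has {aa}"
                )
        it = iter(codons)
        out_rows.append("".join("---" if c == "-" else next(it) for c in prow))
    return CodonAlignment(tuple(protein_ids), tuple(out_rows), alignment_id)


@dataclass(frozen=True)
class DnDsResult:
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    dn: float | None  # None when the JC correction is undefined (p >= 3/4)
    ds: float | None
    omega: float | None  # None when dS is 0 or undefined
    codons_compared: int
    internal_stops: bool = False


def _count_sites(codon: str) -> tuple[float, float]:
    """(S, N) site counts for one sense codon; stops count nonsynonymous."""
    aa = _AA[codon]
    s = n = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in _STOPS and _AA[alt] == aa:
                s += 1
            else:
                n += 1
    # normalize so every codon contributes exactly 3 sites
    total = s + n
    return 3.0 * s / total, 3.0 * n / total


def _count_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense-alphabet codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def step(ca: str, cb: str) -> tuple[int, int]:
        a, b = _AA.get(ca), _AA.get(cb)  # stops map to None
        return (1, 0) if a is not None and a == b else (0, 1)

    sd = nd = 0.0
    paths = list(itertools.permutations(diff))
    w = 1.0 / len(paths)
    for order in paths:
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            s, n = step(cur, nxt)
            sd += w * s
            nd += w * n
            cur = nxt
    return sd, nd


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return abs(-0.75 * math.log(1.0 - 4.0 * p / 3.0))


def ng86_dnds(ca: CodonAlignment, row_a: int = 0, row_b: int = 1) -> DnDsResult:
    """Pairwise NG86 dN/dS on two rows of a codon alignment.

    Codon columns containing a gap or an ambiguous base in either row
    are skipped; columns where either row holds a stop codon are
    skipped and flagged.
    """
    if len(ca.rows) < 2:
        raise InputError("ng86_dnds needs at least two rows")
    codons_a = ca.codons(row_a)
    codons_b = ca.codons(row_b)
    s_sites = n_sites = sd = nd = 0.0
    compared = 0
    saw_stop = False
    for c1, c2 in zip(codons_a, codons_b):
        if any(ch not in _BASES for ch in c1 + c2):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            saw_stop = True
            continue
        s1, n1 = _count_sites(c1)
        s2, n2 = _count_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        ds_, dn_ = _count_diffs(c1, c2)
        sd += ds_
        nd += dn_
        compared += 1
    if compared == 0:
        raise InputError("ng86_dnds: no comparable codon columns")
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    dS = _jc(ps)
    dN = _jc(pn)
    omega = None
    if dN is not None and dS is not None and dS > 0.0:
        omega = dN / dS
    return DnDsResult(
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        pn=pn,
        ps=ps,
        dn=dN,
        ds=dS,
        omega=omega,
        codons_compared=compared,
        internal_stops=saw_stop,
    )


def dnds_matrix(ca: CodonAlignment) -> tuple[pd.DataFrame, float | None]:
    """All-pairs omega matrix and the mean of the defined off-diagonals."""
    n = len(ca.rows)
    mat = pd.DataFrame(np.nan, index=ca.ids, columns=ca.ids, dtype=float)
    vals = []
    for i, j in itertools.combinations(range(n), 2):
        res = ng86_dnds(ca, i, j)
        if res.omega is not None:
            mat.iloc[i, j] = mat.iloc[j, i] = res.omega
            vals.append(res.omega)
    return mat, (float(np.mean(vals)) if vals else None)


def nj_tree(distances: pd.DataFrame | np.ndarray, ids: Sequence[str] | None = None) -> str:
    """Neighbor-joining tree (Newick) from a symmetric distance matrix."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if isinstance(distances, pd.DataFrame):
        ids = list(distances.index)
        data = distances.to_numpy(dtype=float)
    else:
        data = np.asarray(distances, dtype=float)
        if ids is None:
            ids = [f"t{i}" for i in range(len(data))]
    if data.shape[0] != data.shape[1] or not np.allclose(data, data.T):
        raise InputError("nj_tree requires a symmetric distance matrix")
    if not np.allclose(np.diag(data), 0.0):
        raise InputError("nj_tree requires a zero diagonal")
    tree = nj(DistanceMatrix(data, ids=list(ids)))
    return str(tree).strip()
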