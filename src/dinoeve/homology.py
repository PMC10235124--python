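"""Six-frame translated homology search against a viral protein panel.

The screen mirrors a BLASTx workflow: every scaffold is translated in
all six reading frames and aligned locally (affine-gap Smith-Waterman,
BLOSUM62, gap open 11 / extend 1) against each panel protein.  A shared
exact amino-acid word (default length 4) acts as a seed prefilter; an
``exhaustive`` switch disables it so tests can compare against pure
dynamic programming.  E-values follow the Karlin-Altschul form
``E = K * m * n * exp(-lambda * S)`` with the gapped BLOSUM62(11,1)
constants and a search space of total translated scaffold residues times
total panel residues.

Retention thresholds reproduce the published screen: E < 1e-5, bit
score >= 50, percent amino-acid identity >= 30, and — for whole-genome
(as opposed to metagenome) queries — alignment length >= 100 aa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from . import _align
from .core import InputError, Scaffold, reverse_complement

GENE_CLASSES = ("MCP", "RdRp", "other_viral", "retroelement", "cellular")

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class ProteinPanelEntry:
    """An annotated reference protein used as a search subject."""

    id: str
    seq: str
    gene_class: str
    panel_name: str = "panel"

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise InputError(
                f"panel entry {self.id!r}: unknown gene_class {self.gene_class!r}"
            )
        if not self.seq or any(c not in _align.AA_ALPHABET for c in self.seq.upper()):
            raise InputError(f"panel entry {self.id!r}: not a protein sequence")


@dataclass(frozen=True)
class FrameTranslation:
    """One reading frame with its forward-strand coordinate map."""

    frame: int  # +1,+2,+3,-1,-2,-3
    aa: str
    seq_len: int  # nt length of the source scaffold

    @property
    def offset(self) -> int:
        return abs(self.frame) - 1

    def aa_to_nt(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Forward-strand nt interval of aa slice [aa_start, aa_end)."""
        lo = self.offset + 3 * aa_start
        hi = self.offset + 3 * aa_end
        if self.frame > 0:
            return lo, hi
        return self.seq_len - hi, self.seq_len - lo

    def nt_to_aa(self, nt_pos: int) -> int:
        """Residue index covering forward-strand position ``nt_pos``."""
        if self.frame > 0:
            return (nt_pos - self.offset) // 3
        return (self.seq_len - 1 - nt_pos - self.offset) // 3


def translate_frame(dna: str, frame: int) -> str:
    """Translate one frame; N-containing codons give X, stops give ``*``."""
    seq = dna.upper() if frame > 0 else reverse_complement(dna.upper())
    seq = seq[abs(frame) - 1 :]
    seq = seq[: len(seq) - len(seq) % 3]
    if not seq:
        return ""
    return str(Seq(seq).translate(table=1))


def six_frame_translate(dna: str) -> list[FrameTranslation]:
    """All six frame translations with coordinate maps (empty input ok)."""
    return [FrameTranslation(f, translate_frame(dna, f), len(dna)) for f in FRAMES]


@dataclass(frozen=True)
class HomologyHit:
    """A translated local alignment between a scaffold region and a protein."""

    scaffold_id: str
    frame: int
    query_start: int  # forward-strand nt, 0-based half-open
    query_end: int
    subject_id: str
    subject_start: int  # aa, 0-based half-open
    subject_end: int
    raw_score: int
    bit_score: float
    evalue: float
    identity: float  # percent, 0-100
    align_len: int  # alignment columns (aa, gaps included)
    gene_class: str = "other_viral"

    @property
    def query_interval(self) -> tuple[int, int]:
        return self.query_start, self.query_end


@dataclass(frozen=True)
class SearchParams:
    """Scoring and statistics knobs of the translated search."""

    gap_open: int = 11
    gap_extend: int = 1
    word_size: int = 4
    #: gapped Karlin-Altschul constants for BLOSUM62 11/1
    lam: float = 0.267
    k: float = 0.041
    #: HSPs below this bit score are not reported at all
    min_report_bits: float = 30.0
    max_hsps: int = 8
    #: disable the shared-word seed prefilter (pure exhaustive DP)
    exhaustive: bool = False


@dataclass(frozen=True)
class FilterThresholds:
    """Retention rules applied after the translated search."""

    max_evalue: float = 1e-5
    min_bit: float = 50.0
    min_identity: float = 30.0
    min_align_len_aa: int = 100  # genome mode only


def bit_score(raw: float, params: SearchParams) -> float:
    return (params.lam * raw - math.log(params.k)) / math.log(2.0)


def evalue(raw: float, m: int, n: int, params: SearchParams) -> float:
    return params.k * m * n * math.exp(-params.lam * raw)


def _min_raw_score(params: SearchParams) -> int:
    s = (params.min_report_bits * math.log(2.0) + math.log(params.k)) / params.lam
    return max(1, math.ceil(s))


def _words(encoded: np.ndarray, w: int) -> set[bytes]:
    return {encoded[i : i + w].tobytes() for i in range(len(encoded) - w + 1)}


def translated_search(
    scaffold: Scaffold,
    panel: Sequence[ProteinPanelEntry],
    params: SearchParams = SearchParams(),
    search_space_n: int | None = None,
) -> list[HomologyHit]:
    """Six-frame local search of one scaffold against a protein panel.

    ``search_space_n`` overrides the subject search-space size (total
    panel residues) so multi-assembly runs can use a fixed database
    size; by default it is the summed length of ``panel``.
    """
    if not panel:
        raise InputError("translated_search: empty protein panel")
    frames = six_frame_translate(scaffold.seq)
    m = sum(len(f.aa) for f in frames)
    n = search_space_n if search_space_n is not None else sum(len(p.seq) for p in panel)
    min_raw = _min_raw_score(params)
    encoded_panel = [(p, _align.encode_protein(p.seq)) for p in panel]
    hits: list[HomologyHit] = []
    for ft in frames:
        if len(ft.aa) < 1:
            continue
        q = _align.encode_protein(ft.aa)
        qwords = None if params.exhaustive else _words(q, params.word_size)
        for entry, s in encoded_panel:
            if qwords is not None:
                if len(s) < params.word_size or not (
                    qwords & _words(s, params.word_size)
                ):
                    continue
            alns = _align.smith_waterman(
                q,
                s,
                gap_open=params.gap_open,
                gap_extend=params.gap_extend,
                min_score=min_raw,
                max_hsps=params.max_hsps,
            )
            for aln in alns:
                nt_start, nt_end = ft.aa_to_nt(aln.query_start, aln.query_end)
                hits.append(
                    HomologyHit(
                        scaffold_id=scaffold.id,
                        frame=ft.frame,
                        query_start=nt_start,
                        query_end=nt_end,
                        subject_id=entry.id,
                        subject_start=aln.subject_start,
                        subject_end=aln.subject_end,
                        raw_score=aln.score,
                        bit_score=bit_score(aln.score, params),
                        evalue=evalue(aln.score, m, n, params),
                        identity=aln.identity,
                        align_len=aln.columns,
                        gene_class=entry.gene_class,
                    )
                )
    hits.sort(
        key=lambda h: (-h.bit_score, -h.identity, h.subject_id, h.query_start, h.frame)
    )
    return hits


def filter_hits(
    hits: Iterable[HomologyHit],
    mode: Literal["metagenome", "genome"] = "genome",
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[HomologyHit]:
    """Apply the retention thresholds; genome mode adds the 100-aa rule."""
    if mode not in ("metagenome", "genome"):
        raise InputError(f"unknown filter mode {mode!r}")
    kept = []
    for h in hits:
        if h.evalue >= thresholds.max_evalue:
            continue
        if h.bit_score < thresholds.min_bit:
            continue
        if h.identity < thresholds.min_identity:
            continue
        if mode == "genome" and h.align_len < thresholds.min_align_len_aa:
            continue
        kept.append(h)
    return kept


def best_hit_per_locus(hits: Sequence[HomologyHit]) -> list[HomologyHit]:
    """Collapse overlapping same-scaffold hits to the best-scoring one.

    Ties break by higher identity, then lexicographic subject id, so the
    outcome does not depend on input order.
    """
    ordered = sorted(
        hits, key=lambda h: (-h.bit_score, -h.identity, h.subject_id, h.query_start)
    )
    chosen: list[HomologyHit] = []
    for h in ordered:
        clash = False
        for c in chosen:
            if (
                c.scaffold_id == h.scaffold_id
                and h.query_start < c.query_end
                and c.query_start < h.query_end
            ):
                clash = True
                break
        if not clash:
            chosen.append(h)
    chosen.sort(key=lambda h: (h.scaffold_id, h.query_start))
    return chosen


# ---------------------------------------------------------------------------
# panel and hit-table I/O


def read_panel(path: str | Path, panel_name: str | None = None) -> list[ProteinPanelEntry]:
    """Read a protein panel FASTA; headers carry ``gene_class=`` tokens."""
    path = Path(path)
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = dict(
            tok.partition("=")[::2] for tok in rec.description.split() if "=" in tok
        )
        gene_class = tags.get("gene_class")
        if gene_class is None:
            raise InputError(f"panel record {rec.id!r} lacks a gene_class= token")
        entries.append(
            ProteinPanelEntry(
                id=rec.id,
                seq=str(rec.seq),
                gene_class=gene_class,
                panel_name=panel_name or path.stem,
            )
        )
    if not entries:
        raise InputError(f"no panel entries in {path}")
    return entries


def write_panel(entries: Iterable[ProteinPanelEntry], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(e.seq), id=e.id, description=f"gene_class={e.gene_class}")
        for e in entries
    ]
    SeqIO.write(records, str(path), "fasta")


_HIT_COLUMNS = (
    "qseqid sseqid pident length qstart qend sstart send evalue bitscore "
    "raw frame gene_class"
).split()


def write_hits_tsv(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """BLAST outfmt-6-style table (1-based inclusive output coordinates)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.scaffold_id,
                        h.subject_id,
                        f"{h.identity:.2f}",
                        h.align_len,
                        h.query_start + 1,
                        h.query_end,
                        h.subject_start + 1,
                        h.subject_end,
                        f"{h.evalue:.3g}",
                        f"{h.bit_score:.1f}",
                        h.raw_score,
                        h.frame,
                        h.gene_class,
                    )
                )
                + "\n"
            )
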