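"""ORF calling, panel-based annotation, and flank-based verification.

ORFs are maximal stop-free runs in each of the six reading frames
(stop-to-stop), deliberately not requiring a start codon: endogenized
viral elements are typically fragmented, so insisting on ATG would
discard genuine relicts.  Annotation aligns each ORF translation against
a viral panel and a user-supplied cellular panel (standing in for a
general protein database) and keeps the best hit passing E < 1e-3 and
bit >= 50.

Candidates whose scaffold carries no complete ORF are re-checked by
aligning the hit region plus 300 nt of flanking sequence back to the
panels — the curation step for fragmented or degraded elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from . import _align
from .core import InputError, Scaffold
from .homology import (
    FilterThresholds,
    HomologyHit,
    ProteinPanelEntry,
    SearchParams,
    bit_score,
    evalue,
    six_frame_translate,
    translated_search,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_ORF_AA = 60


@dataclass(frozen=True)
class Annotation:
    subject_id: str
    gene_class: str
    bit: float
    evalue: float
    identity: float
    #: scaffold nt interval of the aligned (homologous) region; tighter
    #: than the stop-to-stop ORF extent, which runs on into background
    region_start: int = -1
    region_end: int = -1


@dataclass(frozen=True)
class OrfCall:
    """A stop-free reading-frame segment on a scaffold."""

    scaffold_id: str
    start: int  # forward-strand nt, 0-based half-open
    end: int
    strand: str  # '+' or '-'
    frame: int
    aa: str
    has_start: bool
    has_stop: bool
    annotation: Annotation | None = None

    def is_complete(self, min_len_aa: int = DEFAULT_MIN_ORF_AA) -> bool:
        """Complete = bounded by a stop downstream and long enough."""
        return self.has_stop and len(self.aa) >= min_len_aa

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass(frozen=True)
class ValidationResult:
    candidate: HomologyHit
    status: str  # confirmed_orf | confirmed_flank | rejected
    supporting: tuple[Annotation, ...] = ()


def find_orfs(scaffold: Scaffold, min_len_aa: int = DEFAULT_MIN_ORF_AA) -> list[OrfCall]:
    """All maximal stop-free segments of length >= ``min_len_aa`` aa."""
    if min_len_aa < 1:
        raise InputError("min_len_aa must be >= 1")
    calls: list[OrfCall] = []
    for ft in six_frame_translate(scaffold.seq):
        aa = ft.aa
        i = 0
        n = len(aa)
        while i < n:
            if aa[i] == "*":
                i += 1
                continue
            j = i
            while j < n and aa[j] != "*":
                j += 1
            seg = aa[i:j]
            if len(seg) >= min_len_aa:
                nt_start, nt_end = ft.aa_to_nt(i, j)
                calls.append(
                    OrfCall(
                        scaffold_id=scaffold.id,
                        start=nt_start,
                        end=nt_end,
                        strand="+" if ft.frame > 0 else "-",
                        frame=ft.frame,
                        aa=seg,
                        has_start=seg.startswith("M") or i == 0,
                        has_stop=j < n,
                    )
                )
            i = j
    calls.sort(key=lambda o: (o.start, o.end, o.frame))
    return calls


def _best_annotation(
    orf: OrfCall,
    panels: Sequence[ProteinPanelEntry],
    params: SearchParams,
    search_space_n: int,
) -> Annotation | None:
    q = _align.encode_protein(orf.aa)
    best: Annotation | None = None
    for entry in panels:
        s = _align.encode_protein(entry.seq)
        alns = _align.smith_waterman(
            q, s, gap_open=params.gap_open, gap_extend=params.gap_extend, min_score=20
        )
        if not alns:
            continue
        aln = alns[0]
        if orf.frame > 0:
            rs = orf.start + 3 * aln.query_start
            re_ = orf.start + 3 * aln.query_end
        else:
            rs = orf.end - 3 * aln.query_end
            re_ = orf.end - 3 * aln.query_start
        cand = Annotation(
            subject_id=entry.id,
            gene_class=entry.gene_class,
            bit=bit_score(aln.score, params),
            evalue=evalue(aln.score, len(orf.aa), search_space_n, params),
            identity=aln.identity,
            region_start=rs,
            region_end=re_,
        )
        if best is None or (cand.bit, cand.identity, best.subject_id) > (
            best.bit,
            best.identity,
            cand.subject_id,
        ):
            best = cand
    return best


def annotate_orfs(
    orfs: Sequence[OrfCall],
    viral_panel: Sequence[ProteinPanelEntry],
    cellular_panel: Sequence[ProteinPanelEntry] = (),
    params: SearchParams = SearchParams(),
    max_evalue: float = 1e-3,
    min_bit: float = 50.0,
) -> list[OrfCall]:
    """Attach the best qualifying panel annotation to each ORF."""
    panels = list(viral_panel) + list(cellular_panel)
    if not panels:
        logger.warning("annotate_orfs: no panel entries; all ORFs unannotated")
        return [replace(o, annotation=None) for o in orfs]
    n = sum(len(p.seq) for p in panels)
    out = []
    for orf in orfs:
        ann = _best_annotation(orf, panels, params, n)
        if ann is not None and (ann.evalue >= max_evalue or ann.bit < min_bit):
            ann = None
        out.append(replace(orf, annotation=ann))
    return out


@dataclass(frozen=True)
class FlankPair:
    upstream: str
    downstream: str
    upstream_truncated: bool
    downstream_truncated: bool
    upstream_interval: tuple[int, int]
    downstream_interval: tuple[int, int]


def extract_flanks(
    scaffold: Scaffold, interval: tuple[int, int], flank_nt: int = 300
) -> FlankPair:
    """Up to ``flank_nt`` of sequence each side, truncated at scaffold ends."""
    start, end = interval
    if start < 0 or end > len(scaffold.seq) or start > end:
        raise InputError(
            f"interval {interval} outside scaffold {scaffold.id!r} "
            f"(length {len(scaffold.seq)})"
        )
    up_lo = max(0, start - flank_nt)
    down_hi = min(len(scaffold.seq), end + flank_nt)
    return FlankPair(
        upstream=scaffold.seq[up_lo:start],
        downstream=scaffold.seq[end:down_hi],
        upstream_truncated=start - up_lo < flank_nt,
        downstream_truncated=down_hi - end < flank_nt,
        upstream_interval=(up_lo, start),
        downstream_interval=(end, down_hi),
    )


def verify_candidate(
    scaffold: Scaffold,
    hit: HomologyHit,
    orfs: Sequence[OrfCall],
    viral_panel: Sequence[ProteinPanelEntry],
    cellular_panel: Sequence[ProteinPanelEntry] = (),
    params: SearchParams = SearchParams(),
    min_len_aa: int = DEFAULT_MIN_ORF_AA,
    flank_nt: int = 300,
    reverify_max_evalue: float = 1e-3,
) -> ValidationResult:
    """Confirm a filtered hit via complete ORFs or, failing that, flanks.

    ``confirmed_orf``: a complete ORF (stop-bounded, >= ``min_len_aa``)
    overlapping the hit annotates to the same gene class.
    ``confirmed_flank``: no such ORF exists, but re-searching the hit
    region plus its flanks reproduces the viral annotation at
    E < ``reverify_max_evalue``.  Otherwise ``rejected``.
    """
    overlapping = [
        o for o in orfs if o.start < hit.query_end and hit.query_start < o.end
    ]
    supporting = tuple(o.annotation for o in overlapping if o.annotation is not None)
    complete = [
        o
        for o in overlapping
        if o.has_stop and len(o.aa) >= min_len_aa and o.annotation is not None
    ]
    for orf in complete:
        if orf.annotation.gene_class == hit.gene_class:
            return ValidationResult(hit, "confirmed_orf", supporting)

    flanks = extract_flanks(scaffold, (hit.query_start, hit.query_end), flank_nt)
    lo = flanks.upstream_interval[0]
    hi = flanks.downstream_interval[1]
    region = Scaffold(id=f"{scaffold.id}:{lo}-{hi}", seq=scaffold.seq[lo:hi])
    rehits = translated_search(region, list(viral_panel), params)
    for rh in rehits:
        if rh.gene_class == hit.gene_class and rh.evalue < reverify_max_evalue:
            return ValidationResult(hit, "confirmed_flank", supporting)
    return ValidationResult(hit, "rejected", supporting)


def write_orfs_gff3(orfs: Iterable[OrfCall], path: str | Path) -> None:
    """GFF3 (1-based inclusive) with annotation attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            attrs = [f"ID=orf_{o.scaffold_id}_{o.start}_{o.end}_{o.frame}"]
            if o.annotation:
                a = o.annotation
                attrs.append(f"gene_class={a.gene_class}")
                attrs.append(f"subject={a.subject_id}")
                attrs.append(f"identity={a.identity:.1f}")
                attrs.append(f"bit={a.bit:.1f}")
            fh.write(
                "\t".join(
                    (
                        o.scaffold_id,
                        "dinoeve",
                        "ORF",
                        str(o.start + 1),
                        str(o.end),
                        ".",
                        o.strand,
                        str((abs(o.frame) - 1) % 3),
                        ";".join(attrs),
                    )
                )
                + "\n"
            )
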