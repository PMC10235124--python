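"""EVE assembly: pairing, spliced-leader relict scan, context, coverage.

Validated MCP/RdRp members on a scaffold are combined into EVE calls.
Scaffolds carrying both a capsid (MCP) and a polymerase (RdRp) member
within a pairing distance (default 1.5 kb, measured between the facing
ends of the two regions) are called *genomic* integrations — candidate
whole-genome endogenizations; everything else is a single-ORF EVE.

The dinoflagellate spliced leader (dinoSL) is a 22-nt sequence
trans-spliced onto the 5' end of dinoflagellate mRNAs; a relict copy
just upstream of an endogenized RdRp is the signature of integration of
an mRNA intermediate through host retroelements.  The scanner uses
exact 9-mer seed words (ambiguous query positions wildcarded) followed
by full ungapped comparison of the 22-mer, on both strands, within a
window of the EVE.

The coverage-uniformity screen flags candidate EVEs sitting on chimeric
assemblies: a depth discontinuity across the EVE region (high
coefficient of variation, or inside/flank mean disagreement) fails the
candidate rather than letting a co-assembly artifact masquerade as an
integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import InputError, Scaffold, reverse_complement
from .orfs import OrfCall

DEFAULT_PAIRING_NT = 1500
DEFAULT_SL_WINDOW_NT = 500
DEFAULT_NEIGHBOR_WINDOW_NT = 20_000

#: Canonical dinoflagellate spliced leader (22 nt, DNA alphabet).  The
#: first base of the conserved core is degenerate across dinoflagellate
#: transcripts and the final base abuts the splice junction; those two
#: positions are treated as ambiguous (exempt from mismatch counting)
#: by default.  Both the sequence and the exempt positions are
#: configuration, not hard-coded biology.
DEFAULT_SL_SEQUENCE = "TCCGTAGCCATTTTGGCTCAAG"
DEFAULT_SL_AMBIGUOUS = (0, 21)


@dataclass(frozen=True)
class SLQuery:
    """The spliced-leader query: 22 nt with mismatch-exempt positions."""

    sequence: str = DEFAULT_SL_SEQUENCE
    ambiguous: tuple[int, ...] = DEFAULT_SL_AMBIGUOUS

    def __post_init__(self) -> None:
        if len(self.sequence) != 22:
            raise InputError("spliced-leader query must be 22 nt")
        if any(i < 0 or i >= 22 for i in self.ambiguous):
            raise InputError("ambiguous positions must index into the 22-mer")


@dataclass(frozen=True)
class SLHit:
    start: int  # forward-strand nt, 0-based half-open
    end: int
    strand: str
    matches: int  # matched positions (ambiguous count as matched)
    identity: float  # percent of query length
    offset: int  # signed nt distance to the EVE interval (0 = inside)


@dataclass(frozen=True)
class Neighbor:
    gene_class: str
    distance: int  # signed; + downstream of the EVE, - upstream
    side: str  # 'upstream' | 'downstream'
    subject_id: str


@dataclass(frozen=True)
class CoverageResult:
    contrast: float  # |mean inside - mean flank| / pooled mean
    cv: float  # coefficient of variation across inside+flanks
    status: str  # pass | fail
    reason: str = ""


@dataclass(frozen=True)
class EveMember:
    """A validated MCP or RdRp region contributing to an EVE call."""

    scaffold_id: str
    gene_class: str  # 'MCP' | 'RdRp'
    start: int
    end: int
    strand: str
    source_id: str  # best panel subject
    status: str = "confirmed_orf"  # validation outcome carried along

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class EveCall:
    scaffold_id: str
    type: str  # single_MCP | single_RdRp | genomic
    members: tuple[EveMember, ...]
    gap: int | None = None  # genomic only: nt between facing member ends
    sl_hits: tuple[SLHit, ...] = ()
    neighbors: tuple[Neighbor, ...] = ()
    coverage: CoverageResult | None = None
    coverage_status: str = "untested"  # pass | fail | untested
    validation_status: str = "confirmed"

    @property
    def start(self) -> int:
        return min(m.start for m in self.members)

    @property
    def end(self) -> int:
        return max(m.end for m in self.members)

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def has_retroelement_neighbor(self) -> bool:
        return any(n.gene_class == "retroelement" for n in self.neighbors)


def _gap(a: EveMember, b: EveMember) -> int:
    """Distance between the facing ends of two intervals (0 if touching)."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def call_eves(
    members: Sequence[EveMember],
    pairing_threshold_nt: int = DEFAULT_PAIRING_NT,
) -> list[EveCall]:
    """Greedy nearest-pair MCP/RdRp matching into genomic and single EVEs.

    Candidate MCP-RdRp pairs on the same scaffold are sorted by gap
    (ascending), ties broken by leftmost MCP then leftmost RdRp, and
    accepted greedily while the gap stays within the pairing threshold.
    Every member ends up in exactly one EVE.
    """
    if pairing_threshold_nt <= 0:
        raise InputError("pairing_threshold_nt must be positive")
    members = sorted(members, key=lambda m: (m.scaffold_id, m.start, m.end))
    mcps = [m for m in members if m.gene_class == "MCP"]
    rdrps = [m for m in members if m.gene_class == "RdRp"]
    other = [m for m in members if m.gene_class not in ("MCP", "RdRp")]
    if other:
        raise InputError(
            f"call_eves: members must be MCP or RdRp, got {other[0].gene_class!r}"
        )
    candidates = []
    for i, mc in enumerate(mcps):
        for j, rd in enumerate(rdrps):
            if mc.scaffold_id != rd.scaffold_id:
                continue
            g = _gap(mc, rd)
            if g <= pairing_threshold_nt:
                candidates.append((g, mc.start, rd.start, i, j))
    candidates.sort()
    used_m: set[int] = set()
    used_r: set[int] = set()
    calls: list[EveCall] = []
    for g, _, _, i, j in candidates:
        if i in used_m or j in used_r:
            continue
        used_m.add(i)
        used_r.add(j)
        calls.append(
            EveCall(
                scaffold_id=mcps[i].scaffold_id,
                type="genomic",
                members=(mcps[i], rdrps[j]),
                gap=g,
            )
        )
    for i, mc in enumerate(mcps):
        if i not in used_m:
            calls.append(EveCall(mc.scaffold_id, "single_MCP", (mc,)))
    for j, rd in enumerate(rdrps):
        if j not in used_r:
            calls.append(EveCall(rd.scaffold_id, "single_RdRp", (rd,)))
    calls.sort(key=lambda c: (c.scaffold_id, c.start, c.end))
    return calls


# ---------------------------------------------------------------------------
# spliced-leader scan

_COMP = str.maketrans("ACGTN", "TGCAN")


def _expand_wildcards(word: str, positions: list[int]) -> list[str]:
    words = [word]
    for p in positions:
        words = [w[:p] + b + w[p + 1 :] for w in words for b in "ACGT"]
    return words


def _match_count(region: str, p: int, query: str, ambiguous: set[int]) -> int:
    return sum(
        1
        for i in range(len(query))
        if i in ambiguous or region[p + i] == query[i]
    )


def _seed_positions(region: str, query: str, ambiguous: set[int], word: int) -> set[int]:
    """Candidate alignment starts sharing an exact seed word with the query."""
    index: dict[str, list[int]] = {}
    for r in range(len(region) - word + 1):
        index.setdefault(region[r : r + word], []).append(r)
    starts: set[int] = set()
    for i in range(len(query) - word + 1):
        wild = [a - i for a in ambiguous if i <= a < i + word]
        for w in _expand_wildcards(query[i : i + word], wild):
            for r in index.get(w, ()):
                p = r - i
                if 0 <= p <= len(region) - len(query):
                    starts.add(p)
    return starts


def scan_sl_region(
    region: str,
    query: SLQuery,
    word: int = 9,
    min_matches: int = 18,
) -> list[tuple[int, str, int]]:
    """Seeded both-strand scan of ``region``; (start, strand, matches)."""
    if word <= 0:
        raise InputError("seed word size must be positive")
    region = region.upper()
    q = query.sequence.upper()
    amb = set(query.ambiguous)
    hits: list[tuple[int, str, int]] = []
    for strand in "+-":
        if strand == "+":
            qq, aa = q, amb
        else:
            qq = q.translate(_COMP)[::-1]
            aa = {len(q) - 1 - a for a in amb}
        for p in sorted(_seed_positions(region, qq, aa, word)):
            m = _match_count(region, p, qq, aa)
            if m >= min_matches:
                hits.append((p, strand, m))
    return hits


def scan_dinoSL(
    scaffold: Scaffold,
    eve: EveCall,
    query: SLQuery = SLQuery(),
    window_nt: int = DEFAULT_SL_WINDOW_NT,
    word: int = 9,
    min_matches: int = 18,
) -> list[SLHit]:
    """Scan within ``window_nt`` of the EVE for spliced-leader relicts."""
    if window_nt <= 0:
        raise InputError("window_nt must be positive")
    lo = max(0, eve.start - window_nt)
    hi = min(len(scaffold.seq), eve.end + window_nt)
    region = scaffold.seq[lo:hi]
    qlen = len(query.sequence)
    out = []
    for p, strand, m in scan_sl_region(region, query, word, min_matches):
        start = lo + p
        end = start + qlen
        if end <= eve.start:
            offset = end - eve.start
        elif start >= eve.end:
            offset = start - eve.end
        else:
            offset = 0
        out.append(
            SLHit(
                start=start,
                end=end,
                strand=strand,
                matches=m,
                identity=100.0 * m / qlen,
                offset=offset,
            )
        )
    out.sort(key=lambda h: (h.start, h.strand))
    return out


# ---------------------------------------------------------------------------
# neighborhood annotation


def annotate_neighbors(
    eve: EveCall,
    annotated_orfs: Sequence[OrfCall],
    window_nt: int = DEFAULT_NEIGHBOR_WINDOW_NT,
) -> list[Neighbor]:
    """Annotated ORFs within ``window_nt`` of the EVE, with signed distance.

    Distance is measured between the facing ends of the EVE and the
    ORF's *annotated region* (the aligned part of the ORF, not the full
    stop-to-stop extent, which runs on into background sequence):
    positive for regions after the EVE (downstream on the forward
    strand), negative for regions before it.  Regions overlapping the
    EVE members themselves are not neighbors.
    """
    out = []
    for orf in annotated_orfs:
        if orf.scaffold_id != eve.scaffold_id or orf.annotation is None:
            continue
        start, end = orf.annotation.region_start, orf.annotation.region_end
        if start < 0:
            start, end = orf.start, orf.end
        if start < eve.end and eve.start < end:
            continue  # overlaps the EVE itself
        if start >= eve.end:
            dist = start - eve.end
            side = "downstream"
        else:
            dist = end - eve.start  # negative
            side = "upstream"
        if abs(dist) <= window_nt:
            out.append(
                Neighbor(
                    gene_class=orf.annotation.gene_class,
                    distance=dist,
                    side=side,
                    subject_id=orf.annotation.subject_id,
                )
            )
    out.sort(key=lambda n: (abs(n.distance), n.subject_id))
    return out


# ---------------------------------------------------------------------------
# coverage-uniformity screen


def coverage_uniformity(
    depth: np.ndarray,
    eve_interval: tuple[int, int],
    flank_nt: int = 500,
    cv_threshold: float = 0.5,
    contrast_threshold: float = 0.5,
) -> CoverageResult:
    """Depth-uniformity statistic over the EVE region and its flanks.

    ``contrast`` = |mean depth inside - mean depth in flanks| / pooled
    mean; ``cv`` = standard deviation / mean over the union.  Either
    exceeding its threshold fails the screen.
    """
    depth = np.asarray(depth, dtype=float)
    start, end = eve_interval
    if start < 0 or end > len(depth) or start >= end:
        raise InputError(f"eve interval {eve_interval} outside depth profile")
    inside = depth[start:end]
    flank = np.concatenate(
        [depth[max(0, start - flank_nt) : start], depth[end : end + flank_nt]]
    )
    union = np.concatenate([inside, flank]) if flank.size else inside
    pooled = float(union.mean())
    if pooled == 0.0:
        return CoverageResult(0.0, 0.0, "fail", "zero coverage across region")
    contrast = (
        abs(float(inside.mean()) - float(flank.mean())) / pooled if flank.size else 0.0
    )
    cv = float(union.std()) / pooled
    if contrast > contrast_threshold:
        return CoverageResult(contrast, cv, "fail", "inside/flank depth contrast")
    if cv > cv_threshold:
        return CoverageResult(contrast, cv, "fail", "depth dispersion")
    return CoverageResult(contrast, cv, "pass")


# ---------------------------------------------------------------------------
# depth input and call output


def read_depth_tsv(path: str | Path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """3-column (scaffold, 1-based position, depth) TSV to per-base arrays."""
    profiles = {sid: np.zeros(n, dtype=np.int32) for sid, n in lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sid, pos, d = line.split("\t")[:3]
            if sid not in profiles:
                raise InputError(f"depth TSV references unknown scaffold {sid!r}")
            profiles[sid][int(pos) - 1] = int(d)
    return profiles


def read_depth_sam(path: str | Path, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base depth from aligned reads in SAM/BAM."""
    import pysam

    profiles = {sid: np.zeros(n, dtype=np.int32) for sid, n in lengths.items()}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name not in profiles:
                continue
            prof = profiles[read.reference_name]
            lo = max(0, read.reference_start)
            hi = min(len(prof), read.reference_end or read.reference_start)
            prof[lo:hi] += 1
    return profiles


def write_eves_gff3(calls: Iterable[EveCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for idx, c in enumerate(calls):
            attrs = [
                f"ID=eve_{idx:04d}",
                f"class={c.type}",
                f"members={','.join(m.gene_class for m in c.members)}",
                f"coverage={c.coverage_status}",
                f"validation={c.validation_status}",
            ]
            if c.gap is not None:
                attrs.append(f"gap={c.gap}")
            if c.sl_hits:
                attrs.append("sl_offsets=" + ",".join(str(h.offset) for h in c.sl_hits))
            if c.neighbors:
                attrs.append(
                    "neighbors="
                    + ",".join(f"{n.gene_class}:{n.distance:+d}" for n in c.neighbors)
                )
            fh.write(
                "\t".join(
                    (
                        c.scaffold_id,
                        "dinoeve",
                        "EVE",
                        str(c.start + 1),
                        str(c.end),
                        ".",
                        c.members[0].strand,
                        ".",
                        ";".join(attrs),
                    )
                )
                + "\n"
            )


def write_eves_tsv(calls: Iterable[EveCall], path: str | Path) -> None:
    cols = (
        "scaffold type start end gap members sl_hits retro_neighbor "
        "coverage validation"
    ).split()
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        c.scaffold_id,
                        c.type,
                        c.start + 1,
                        c.end,
                        c.gap if c.gap is not None else ".",
                        ",".join(f"{m.gene_class}:{m.start + 1}-{m.end}" for m in c.members),
                        len(c.sl_hits),
                        int(c.has_retroelement_neighbor),
                        c.coverage_status,
                        c.validation_status,
                    )
                )
                + "\n"
            )
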