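"""Synthetic host assemblies with planted viral integrations.

The generator emulates the statistical structure the detection pipeline
assumes so that every stage can be verified against known ground truth:

* GC-biased host scaffolds carrying ordinary cellular ORFs,
* viral ORFs (MCP, RdRp) planted as degraded back-translations of
  named panel proteins — amino-acid substitutions at a tunable
  divergence, then indels (in-frame half the time, frameshifting
  otherwise), then optional internal stop codons, mimicking the
  fragmented state of real endogenized elements,
* 22-nt spliced-leader relicts at a known offset 5' of the RdRp,
* LINE-like retroelement neighbors at a known downstream offset,
* EVE-free negative-control scaffolds, and
* chimeric scaffolds joining two unrelated halves whose reads cover
  only one half, producing the depth discontinuity the coverage screen
  is meant to catch.

Everything is driven by one :class:`numpy.random.Generator`; a fixed
seed yields byte-identical FASTA, FASTQ, depth and manifest outputs.
All panel proteins are synthetic sequences generated from a fixed
internal seed — stand-ins for curated reference proteins, not real
viral sequences.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import InputError, Scaffold, reverse_complement
from .evecall import DEFAULT_SL_SEQUENCE
from .homology import ProteinPanelEntry, translate_frame

_PANEL_SEED = 230601  # fixed: the panel is part of the benchmark definition

# amino-acid background frequencies (rounded Robinson-Robinson style)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array(
    [7.8, 1.9, 5.4, 6.3, 3.9, 7.4, 2.2, 5.2, 5.7, 9.0,
     2.2, 4.4, 5.2, 4.3, 5.1, 7.1, 5.8, 6.4, 1.3, 3.4]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

_CODONS: dict[str, list[str]] = {}
from Bio.Data import CodonTable as _CT

for _codon, _aa in _CT.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
_STOP_CODONS = tuple(_CT.unambiguous_dna_by_id[1].stop_codons)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length, p=_AA_FREQ))


def default_viral_panel() -> list[ProteinPanelEntry]:
    """Synthetic stand-in for a curated viral reference-protein panel.

    Two major capsid proteins (~358 aa, the length reported for
    exogenous dinoRNAV capsids), two RNA-dependent RNA polymerases
    (~500 aa) and one other viral protein.  Sequences are random but
    fixed by an internal seed.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    entries = []
    for i in range(2):
        entries.append(
            ProteinPanelEntry(f"synthMCP_{i + 1:02d}", _random_protein(rng, 358), "MCP")
        )
    for i in range(2):
        entries.append(
            ProteinPanelEntry(f"synthRdRp_{i + 1:02d}", _random_protein(rng, 500), "RdRp")
        )
    entries.append(
        ProteinPanelEntry("synthViral_01", _random_protein(rng, 300), "other_viral")
    )
    return entries


def default_cellular_panel() -> list[ProteinPanelEntry]:
    """Synthetic decoy panel: host genes plus a LINE-like retroelement."""
    rng = np.random.default_rng(_PANEL_SEED + 1)
    return [
        ProteinPanelEntry("synthCollagen_01", _random_protein(rng, 320), "cellular"),
        ProteinPanelEntry("synthRnaBinding_01", _random_protein(rng, 280), "cellular"),
        ProteinPanelEntry("synthHostGene_01", _random_protein(rng, 350), "cellular"),
        ProteinPanelEntry("synthLineRT_01", _random_protein(rng, 150), "retroelement"),
    ]


# ---------------------------------------------------------------------------
# sequence construction primitives


def random_background(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def degrade_protein(
    aa: str, divergence: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Substitute each residue with probability ``divergence``."""
    out = list(aa)
    n_subs = 0
    for i, r in enumerate(out):
        if rng.random() < divergence:
            choices = [c for c in _AA20 if c != r]
            out[i] = choices[rng.integers(len(choices))]
            n_subs += 1
    return "".join(out), n_subs


def back_translate(aa: str, gc: float, rng: np.random.Generator) -> str:
    """Back-translate with codon choice weighted toward the target GC."""
    codons = []
    for r in aa:
        options = _CODONS[r]
        w = np.array(
            [
                np.prod([gc / 2 if b in "GC" else (1 - gc) / 2 for b in c])
                for c in options
            ]
        )
        codons.append(options[rng.choice(len(options), p=w / w.sum())])
    return "".join(codons)


def apply_indels(nt: str, indel_rate: float, rng: np.random.Generator) -> str:
    """Per-site indels; length 3 (in-frame) half the time, else 1-2."""
    if indel_rate <= 0:
        return nt
    out = []
    bases = "ACGT"
    i = 0
    while i < len(nt):
        if rng.random() < indel_rate:
            length = 3 if rng.random() < 0.5 else int(rng.integers(1, 3))
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            out.append("".join(bases[rng.integers(4)] for _ in range(length)))
        out.append(nt[i])
        i += 1
    return "".join(out)


def inject_stop(nt: str, rng: np.random.Generator) -> str:
    """Replace one random internal codon with a stop codon."""
    n_codons = len(nt) // 3
    if n_codons < 3:
        return nt
    pos = int(rng.integers(1, n_codons - 1)) * 3
    stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
    return nt[:pos] + stop + nt[pos + 3 :]


def mutate_sequence_neutral(
    nt: str, rate: float, rng: np.random.Generator
) -> str:
    """Uniform per-site nucleotide substitutions (no selective filter)."""
    out = list(nt)
    for i, b in enumerate(out):
        if rng.random() < rate:
            choices = [c for c in "ACGT" if c != b]
            out[i] = choices[rng.integers(3)]
    return "".join(out)


def mutate_cds_synonymous(nt: str, rate: float, rng: np.random.Generator) -> str:
    """Per-codon synonymous swaps only (dN = 0 by construction).

    Swaps are restricted to synonymous codons differing at exactly one
    position, so every mutational pathway between the two sequences is
    synonymous (two-position synonymous swaps, e.g. within the serine
    family, would pass through nonsynonymous intermediates).
    """
    fwd = _CT.unambiguous_dna_by_id[1].forward_table
    codons = [nt[i : i + 3] for i in range(0, len(nt) - len(nt) % 3, 3)]
    for i, c in enumerate(codons):
        if rng.random() < rate:
            aa = fwd.get(c)
            if aa is None:
                continue
            options = [
                x
                for x in _CODONS[aa]
                if sum(a != b for a, b in zip(x, c)) == 1
            ]
            if options:
                codons[i] = options[rng.integers(len(options))]
    return "".join(codons) + nt[len(codons) * 3 :]


# ---------------------------------------------------------------------------
# configuration and ground truth

_DEFAULT_DIVERGENCE_GRID = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.40, 0.50)
#: default genomic gaps straddle the published pairing rule (1.5 kb) and
#: the noncoding-gap range reported for real whole-genome integrations
_DEFAULT_GENOMIC_GAPS = (319, 400, 656, 800, 1500, 1501)


@dataclass(frozen=True)
class SimConfig:
    """Benchmark conditions; defaults define the standard desk-scale run."""

    seed: int = 0
    n_scaffolds: int = 30
    scaffold_len: int = 8000
    gc: float = 0.50
    n_single_eves: int = 24
    n_genomic_eves: int = 6
    divergence: float | tuple[float, ...] = _DEFAULT_DIVERGENCE_GRID
    stop_rate: float = 0.3
    indel_rate: float = 0.0
    sl_offset: int = 100
    line_offset: int = 95
    genomic_gap: int | tuple[int, ...] = _DEFAULT_GENOMIC_GAPS
    negatives: int = 10
    chimeras: int = 5
    read_len: int = 100
    read_depth: float = 30.0
    cellular_genes_per_scaffold: int = 1

    def __post_init__(self) -> None:
        for name in ("gc", "stop_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"SimConfig.{name} must be a fraction in [0, 1]")
        for d in self.divergences:
            if not 0.0 <= d <= 1.0:
                raise InputError("SimConfig.divergence values must lie in [0, 1]")
        for g in self.genomic_gaps:
            if g < 0:
                raise InputError("SimConfig.genomic_gap must be >= 0")
        for name in ("n_scaffolds", "scaffold_len", "negatives", "chimeras",
                     "n_single_eves", "n_genomic_eves", "sl_offset", "line_offset"):
            if getattr(self, name) < 0:
                raise InputError(f"SimConfig.{name} must be non-negative")

    @property
    def divergences(self) -> tuple[float, ...]:
        d = self.divergence
        return (d,) if isinstance(d, (int, float)) else tuple(d)

    @property
    def genomic_gaps(self) -> tuple[int, ...]:
        g = self.genomic_gap
        return (g,) if isinstance(g, (int, np.integer)) else tuple(g)


@dataclass(frozen=True)
class GroundTruthRecord:
    scaffold_id: str
    feature: str  # MCP|RdRp|genomic_pair|dinoSL|LINE|cellular_gene|chimera_junction
    start: int  # forward strand, 0-based half-open
    end: int
    strand: str
    source_id: str = ""
    divergence: float = 0.0  # realized aa substitution fraction
    stops: int = 0  # realized internal stop count
    gap: int | None = None  # genomic_pair only
    group: str = ""  # links members of one planted EVE


@dataclass
class GroundTruthManifest:
    records: list[GroundTruthRecord]
    config: dict

    def for_scaffold(self, scaffold_id: str) -> list[GroundTruthRecord]:
        return [r for r in self.records if r.scaffold_id == scaffold_id]

    def viral_members(self) -> list[GroundTruthRecord]:
        return [r for r in self.records if r.feature in ("MCP", "RdRp")]

    def genomic_pairs(self) -> list[GroundTruthRecord]:
        return [r for r in self.records if r.feature == "genomic_pair"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "records": [asdict(r) for r in self.records],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            records=[GroundTruthRecord(**r) for r in payload["records"]],
            config=payload.get("config", {}),
        )


@dataclass(frozen=True)
class EveSpec:
    """Per-EVE planting parameters."""

    kind: str  # single_MCP | single_RdRp | genomic
    divergence: float = 0.0
    stop_rate: float = 0.0
    indel_rate: float = 0.0
    sl_offset: int = 0
    line_offset: int = 0
    genomic_gap: int = 400
    strand: str | None = None  # None: random
    position: int | None = None  # block start; None: random
    mcp_source: str | None = None
    rdrp_source: str | None = None


@dataclass
class Read:
    id: str
    seq: str
    scaffold_id: str
    start: int


@dataclass
class Benchmark:
    scaffolds: list[Scaffold]
    reads: list[Read]
    depth: dict[str, np.ndarray]
    manifest: GroundTruthManifest


# ---------------------------------------------------------------------------
# planting


def _count_internal_stops(seq: str, interval: tuple[int, int], strand: str) -> int:
    sub = seq[interval[0] : interval[1]]
    if strand == "-":
        sub = reverse_complement(sub)
    return translate_frame(sub, 1).count("*")


def _overlaps(iv: tuple[int, int], occupied: list[tuple[int, int]], margin: int = 30) -> bool:
    return any(iv[0] < b + margin and a - margin < iv[1] for a, b in occupied)


class _FeatureWriter:
    """Overwrites feature blocks onto a mutable scaffold sequence."""

    def __init__(self, seq: str):
        self.chars = list(seq)
        self.occupied: list[tuple[int, int]] = []

    def write(self, pos: int, block: str) -> tuple[int, int]:
        if pos < 0 or pos + len(block) > len(self.chars):
            raise InputError(
                "planted feature exceeds scaffold bounds; increase "
                "scaffold_len or reduce feature sizes/offsets"
            )
        self.chars[pos : pos + len(block)] = list(block)
        iv = (pos, pos + len(block))
        self.occupied.append(iv)
        return iv

    def place(
        self,
        block: str,
        rng: np.random.Generator,
        lo: int = 0,
        hi: int | None = None,
        retries: int = 50,
        position: int | None = None,
    ) -> tuple[int, int]:
        hi = len(self.chars) if hi is None else hi
        if position is not None:
            if _overlaps((position, position + len(block)), self.occupied):
                raise InputError("requested feature position overlaps another feature")
            return self.write(position, block)
        span = hi - lo - len(block)
        if span < 0:
            raise InputError(
                "feature too long for scaffold: increase scaffold_len "
                f"(need {len(block)} nt in a {hi - lo} nt window)"
            )
        for _ in range(retries):
            pos = lo + int(rng.integers(span + 1))
            if not _overlaps((pos, pos + len(block)), self.occupied):
                return self.write(pos, block)
        raise InputError(
            "could not place feature without overlap after retries; "
            "reduce feature counts or increase scaffold_len"
        )

    def seq(self) -> str:
        return "".join(self.chars)


def _build_cds(
    entry: ProteinPanelEntry,
    divergence: float,
    stop_rate: float,
    indel_rate: float,
    gc: float,
    rng: np.random.Generator,
) -> tuple[str, float]:
    aa, n_subs = degrade_protein(entry.seq, divergence, rng)
    nt = back_translate(aa, gc, rng)
    nt = apply_indels(nt, indel_rate, rng)
    if rng.random() < stop_rate:
        nt = inject_stop(nt, rng)
    return nt, n_subs / len(entry.seq)


def plant_eve(
    scaffold: Scaffold,
    spec: EveSpec,
    rng: np.random.Generator,
    viral_panel: Sequence[ProteinPanelEntry] | None = None,
    cellular_panel: Sequence[ProteinPanelEntry] | None = None,
    gc: float = 0.5,
    occupied: list[tuple[int, int]] | None = None,
    group: str = "eve",
    margin_nt: int = 0,
) -> tuple[Scaffold, list[GroundTruthRecord]]:
    """Plant one EVE (plus optional spliced leader and LINE neighbor).

    The features are assembled as one block in virus orientation —
    optional spliced-leader pad, MCP, noncoding gap, RdRp, optional
    LINE pad and LINE ORF — reverse-complemented as a whole for
    minus-strand plants, and overwritten onto the scaffold.  Offsets
    (``sl_offset``, ``line_offset``, ``genomic_gap``) are therefore
    exact by construction.  Truth records carry forward-strand
    coordinates.
    """
    viral_panel = list(viral_panel) if viral_panel is not None else default_viral_panel()
    cellular_panel = (
        list(cellular_panel) if cellular_panel is not None else default_cellular_panel()
    )
    mcps = [p for p in viral_panel if p.gene_class == "MCP"]
    rdrps = [p for p in viral_panel if p.gene_class == "RdRp"]
    strand = spec.strand or ("+" if rng.random() < 0.5 else "-")

    def pick(entries, wanted_id):
        if wanted_id is None:
            return entries[rng.integers(len(entries))]
        match = [e for e in entries if e.id == wanted_id]
        if not match:
            raise InputError(f"no panel entry {wanted_id!r}")
        return match[0]

    parts: list[tuple[str, str, str, float]] = []  # (feature, seq, source, div)
    if spec.kind in ("single_MCP", "genomic"):
        entry = pick(mcps, spec.mcp_source)
        nt, div = _build_cds(
            entry, spec.divergence, spec.stop_rate, spec.indel_rate, gc, rng
        )
        parts.append(("MCP", nt, entry.id, div))
    if spec.kind in ("single_RdRp", "genomic"):
        entry = pick(rdrps, spec.rdrp_source)
        nt, div = _build_cds(
            entry, spec.divergence, spec.stop_rate, spec.indel_rate, gc, rng
        )
        parts.append(("RdRp", nt, entry.id, div))
    if not parts:
        raise InputError(f"unknown EVE kind {spec.kind!r}")

    sl_len = len(DEFAULT_SL_SEQUENCE)
    upstream_pad = 0
    if spec.sl_offset > 0:
        if spec.kind == "single_MCP":
            pass  # the leader marks the RdRp; no RdRp, no leader
        elif spec.kind == "genomic":
            if spec.genomic_gap < spec.sl_offset + sl_len:
                raise InputError(
                    "sl_offset + 22 must fit inside genomic_gap for genomic plants"
                )
        else:
            upstream_pad = spec.sl_offset + sl_len

    line_nt = line_source = None
    if spec.line_offset > 0:
        line_entries = [p for p in cellular_panel if p.gene_class == "retroelement"]
        if not line_entries:
            raise InputError("cellular panel has no retroelement entry for LINE plant")
        line_entry = line_entries[int(rng.integers(len(line_entries)))]
        line_nt, line_div = _build_cds(line_entry, 0.0, 0.0, 0.0, gc, rng)
        line_source = line_entry.id

    # assemble the block in virus orientation
    block_parts: list[str] = [random_background(rng, upstream_pad, gc)]
    offsets: dict[str, tuple[int, int]] = {}
    cursor = upstream_pad
    for idx, (feature, nt, source, div) in enumerate(parts):
        if idx > 0:
            gap_seq = random_background(rng, spec.genomic_gap, gc)
            block_parts.append(gap_seq)
            cursor += len(gap_seq)
        block_parts.append(nt)
        offsets[feature] = (cursor, cursor + len(nt))
        cursor += len(nt)
    if line_nt is not None:
        block_parts.append(random_background(rng, spec.line_offset, gc))
        cursor += spec.line_offset
        block_parts.append(line_nt)
        offsets["LINE"] = (cursor, cursor + len(line_nt))
        cursor += len(line_nt)
    block = "".join(block_parts)
    if spec.sl_offset > 0 and "RdRp" in offsets:
        r0 = offsets["RdRp"][0]
        sl_start = r0 - spec.sl_offset - sl_len
        block = block[:sl_start] + DEFAULT_SL_SEQUENCE + block[sl_start + sl_len :]
        offsets["dinoSL"] = (sl_start, sl_start + sl_len)
    if strand == "-":
        B = len(block)
        block = reverse_complement(block)
        offsets = {k: (B - b, B - a) for k, (a, b) in offsets.items()}

    writer = _FeatureWriter(scaffold.seq)
    writer.occupied = list(occupied or [])
    lo = margin_nt
    hi = len(scaffold.seq) - margin_nt
    pos, _ = writer.place(block, rng, lo=lo, hi=hi, position=spec.position)

    records: list[GroundTruthRecord] = []
    member_ivs: dict[str, tuple[int, int]] = {}
    for feature, nt, source, div in parts:
        a, b = offsets[feature]
        iv = (pos + a, pos + b)
        member_ivs[feature] = iv
        records.append(
            GroundTruthRecord(
                scaffold_id=scaffold.id,
                feature=feature,
                start=iv[0],
                end=iv[1],
                strand=strand,
                source_id=source,
                divergence=div,
                stops=_count_internal_stops(writer.seq(), iv, strand),
                group=group,
            )
        )
    if spec.kind == "genomic":
        mcp_iv = member_ivs["MCP"]
        rdrp_iv = member_ivs["RdRp"]
        gap = max(0, max(mcp_iv[0], rdrp_iv[0]) - min(mcp_iv[1], rdrp_iv[1]))
        records.append(
            GroundTruthRecord(
                scaffold_id=scaffold.id,
                feature="genomic_pair",
                start=min(mcp_iv[0], rdrp_iv[0]),
                end=max(mcp_iv[1], rdrp_iv[1]),
                strand=strand,
                gap=gap,
                group=group,
            )
        )
    if "dinoSL" in offsets:
        a, b = offsets["dinoSL"]
        records.append(
            GroundTruthRecord(
                scaffold_id=scaffold.id,
                feature="dinoSL",
                start=pos + a,
                end=pos + b,
                strand=strand,
                group=group,
            )
        )
    if "LINE" in offsets:
        a, b = offsets["LINE"]
        records.append(
            GroundTruthRecord(
                scaffold_id=scaffold.id,
                feature="LINE",
                start=pos + a,
                end=pos + b,
                strand=strand,
                source_id=line_source or "",
                divergence=line_div,
                group=group,
            )
        )
    out = Scaffold(
        id=scaffold.id,
        seq=writer.seq(),
        assembly=scaffold.assembly,
        genus=scaffold.genus,
        source=scaffold.source,
    )
    if occupied is not None:
        occupied[:] = writer.occupied
    return out, records


def _plant_cellular(
    writer: _FeatureWriter,
    scaffold_id: str,
    rng: np.random.Generator,
    cellular_panel: Sequence[ProteinPanelEntry],
    gc: float,
) -> GroundTruthRecord:
    host_genes = [p for p in cellular_panel if p.gene_class == "cellular"]
    entry = host_genes[int(rng.integers(len(host_genes)))]
    nt, div = _build_cds(entry, 0.0, 0.0, 0.0, gc, rng)
    iv = writer.place(nt, rng)
    return GroundTruthRecord(
        scaffold_id=scaffold_id,
        feature="cellular_gene",
        start=iv[0],
        end=iv[1],
        strand="+",
        source_id=entry.id,
        divergence=div,
    )


# ---------------------------------------------------------------------------
# whole-benchmark assembly


def _simulate_reads(
    rng: np.random.Generator,
    scaffold: Scaffold,
    read_len: int,
    depth: float,
    covered: tuple[int, int] | None = None,
) -> list[Read]:
    lo, hi = covered if covered is not None else (0, len(scaffold.seq))
    span = hi - lo
    if span < read_len:
        return []
    n_reads = int(round(depth * span / read_len))
    starts = np.sort(rng.integers(lo, hi - read_len + 1, size=n_reads))
    return [
        Read(
            id=f"{scaffold.id}_r{k:05d}",
            seq=scaffold.seq[s : s + read_len],
            scaffold_id=scaffold.id,
            start=int(s),
        )
        for k, s in enumerate(starts)
    ]


def _depth_from_reads(reads: Iterable[Read], lengths: dict[str, int]) -> dict[str, np.ndarray]:
    depth = {sid: np.zeros(n, dtype=np.int32) for sid, n in lengths.items()}
    for r in reads:
        depth[r.scaffold_id][r.start : r.start + len(r.seq)] += 1
    return depth


def make_benchmark(
    config: SimConfig = SimConfig(),
    outdir: str | Path | None = None,
) -> Benchmark:
    """Generate the full benchmark; optionally write it to ``outdir``."""
    rng = np.random.default_rng(config.seed)
    viral_panel = default_viral_panel()
    cellular_panel = default_cellular_panel()
    divs = config.divergences
    gaps = config.genomic_gaps

    scaffolds: list[Scaffold] = []
    records: list[GroundTruthRecord] = []
    reads: list[Read] = []

    # assign EVEs to scaffolds round-robin
    kinds = ["genomic"] * config.n_genomic_eves + ["single_MCP", "single_RdRp"] * (
        config.n_single_eves // 2 + 1
    )
    kinds = kinds[: config.n_genomic_eves + config.n_single_eves]
    per_scaffold: list[list[int]] = [[] for _ in range(max(config.n_scaffolds, 1))]
    for e, kind in enumerate(kinds):
        per_scaffold[e % len(per_scaffold)].append(e)

    eve_counter = 0
    gidx = 0
    for s in range(config.n_scaffolds):
        sid = f"sc_{s:04d}"
        bg = random_background(rng, config.scaffold_len, config.gc)
        sc = Scaffold(id=sid, seq=bg, assembly="synthetic_benchmark")
        sc_records: list[GroundTruthRecord] = []
        occupied: list[tuple[int, int]] = []
        for e in per_scaffold[s]:
            kind = kinds[e]
            div = divs[eve_counter % len(divs)]
            gap = gaps[gidx % len(gaps)] if kind == "genomic" else 0
            if kind == "genomic":
                gidx += 1
            spec = EveSpec(
                kind=kind,
                divergence=div,
                stop_rate=config.stop_rate,
                indel_rate=config.indel_rate,
                sl_offset=config.sl_offset if kind != "single_MCP" else 0,
                line_offset=config.line_offset,
                genomic_gap=gap,
                strand=None,
            )
            sc, eve_records = plant_eve(
                sc,
                spec,
                rng,
                viral_panel,
                cellular_panel,
                gc=config.gc,
                occupied=occupied,
                group=f"eve_{eve_counter:04d}",
                margin_nt=150,
            )
            sc_records.extend(eve_records)
            eve_counter += 1
        writer = _FeatureWriter(sc.seq)
        writer.occupied = occupied
        for _ in range(config.cellular_genes_per_scaffold):
            sc_records.append(
                _plant_cellular(writer, sid, rng, cellular_panel, config.gc)
            )
        sc = Scaffold(id=sid, seq=writer.seq(), assembly="synthetic_benchmark")
        scaffolds.append(sc)
        records.extend(sc_records)
        reads.extend(_simulate_reads(rng, sc, config.read_len, config.read_depth))

    for k in range(config.negatives):
        sid = f"neg_{k:04d}"
        bg = random_background(rng, config.scaffold_len, config.gc)
        writer = _FeatureWriter(bg)
        for _ in range(config.cellular_genes_per_scaffold):
            records.append(_plant_cellular(writer, sid, rng, cellular_panel, config.gc))
        sc = Scaffold(id=sid, seq=writer.seq(), assembly="synthetic_benchmark")
        scaffolds.append(sc)
        reads.extend(_simulate_reads(rng, sc, config.read_len, config.read_depth))

    for k in range(config.chimeras):
        sid = f"chi_{k:04d}"
        half = config.scaffold_len // 2
        # two unrelated halves with distinct composition
        bg = random_background(rng, half, config.gc) + random_background(
            rng, config.scaffold_len - half, min(1.0, max(0.0, config.gc - 0.15))
        )
        sc = Scaffold(id=sid, seq=bg, assembly="synthetic_benchmark")
        # the EVE straddles the junction so the depth break falls inside it
        block_guess = 1500  # single RdRp CDS length
        spec = EveSpec(
            kind="single_RdRp",
            divergence=0.10,
            stop_rate=0.0,
            indel_rate=0.0,
            strand="+",
            position=max(0, half - block_guess // 2),
        )
        sc, eve_records = plant_eve(
            sc,
            spec,
            rng,
            viral_panel,
            cellular_panel,
            gc=config.gc,
            group=f"chimera_{k:04d}",
        )
        records.extend(eve_records)
        records.append(
            GroundTruthRecord(
                scaffold_id=sid,
                feature="chimera_junction",
                start=half,
                end=half,
                strand="+",
                group=f"chimera_{k:04d}",
            )
        )
        scaffolds.append(sc)
        reads.extend(
            _simulate_reads(
                rng, sc, config.read_len, config.read_depth, covered=(0, half)
            )
        )

    depth = _depth_from_reads(reads, {sc.id: len(sc.seq) for sc in scaffolds})
    cfg_echo = asdict(config)
    cfg_echo["divergence"] = list(np.atleast_1d(config.divergence).astype(float))
    cfg_echo["genomic_gap"] = [int(g) for g in np.atleast_1d(config.genomic_gap)]
    manifest = GroundTruthManifest(records=records, config=cfg_echo)
    bench = Benchmark(scaffolds=scaffolds, reads=reads, depth=depth, manifest=manifest)
    if outdir is not None:
        write_benchmark(bench, outdir)
    return bench


def write_benchmark(bench: Benchmark, outdir: str | Path) -> None:
    from .core import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bench.scaffolds, outdir / "assembly.fasta")
    with open(outdir / "reads.fastq", "w") as fh:
        for r in bench.reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
    with open(outdir / "depth.tsv", "w") as fh:
        for sid, prof in bench.depth.items():
            for i, d in enumerate(prof):
                fh.write(f"{sid}\t{i + 1}\t{int(d)}\n")
    bench.manifest.to_json(outdir / "manifest.json")
    with open(outdir / "config.txt", "w") as fh:
        for key, value in sorted(bench.manifest.config.items()):
            fh.write(f"{key}: {value}\n")
    from .homology import write_panel

    write_panel(default_viral_panel(), outdir / "viral_panel.fasta")
    write_panel(default_cellular_panel(), outdir / "cellular_panel.fasta")
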