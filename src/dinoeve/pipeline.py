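"""End-to-end orchestration: homology -> ORFs -> validation -> EVE calls.

``scan_assembly`` is the library entry point; the command-line layer in
:mod:`dinoeve.cli` is a thin wrapper around it.  The stages follow the
published screen: translated search of every scaffold against the viral
panel, threshold filtering (genome or metagenome mode), ORF calling and
panel annotation on candidate scaffolds, ORF/flank validation of every
retained locus, pairing of MCP and RdRp members into genomic EVE calls,
spliced-leader scanning, neighborhood annotation, and the
coverage-uniformity chimera screen when read depth is supplied.

Hit regions validated on the same scaffold and gene class are merged
into one member locus, and the locus boundary is extrapolated to full
subject coverage (a hit covering subject residues [s0, s1) of a P-long
protein is widened by 3*s0 and 3*(P-s1) nt on the appropriate sides),
so the called member approximates the full endogenized CDS rather than
the trimmed high-scoring segment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .core import InputError, Scaffold, read_fasta
from .evecall import (
    CoverageResult,
    EveCall,
    EveMember,
    SLQuery,
    annotate_neighbors,
    call_eves,
    coverage_uniformity,
    read_depth_sam,
    read_depth_tsv,
    scan_dinoSL,
    write_eves_gff3,
    write_eves_tsv,
)
from .homology import (
    FilterThresholds,
    HomologyHit,
    ProteinPanelEntry,
    SearchParams,
    filter_hits,
    read_panel,
    translated_search,
    write_hits_tsv,
)
from .orfs import (
    DEFAULT_MIN_ORF_AA,
    OrfCall,
    ValidationResult,
    annotate_orfs,
    find_orfs,
    verify_candidate,
    write_orfs_gff3,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and thresholds of one scan run (CLI-facing)."""

    assembly: str
    viral_panel: str | None = None  # None: bundled synthetic panel
    cellular_panel: str | None = None
    depth: str | None = None
    metrics: str | None = None
    mode: str = "genome"  # genome | metagenome
    outdir: str = "dinoeve_out"
    seed: int = 0
    pairing_threshold_nt: int = 1500
    sl_window_nt: int = 500
    sl_word: int = 9
    sl_min_matches: int = 18
    neighbor_window_nt: int = 20_000
    min_orf_aa: int = DEFAULT_MIN_ORF_AA
    flank_nt: int = 300
    cv_threshold: float = 0.5
    contrast_threshold: float = 0.5
    merge_nt: int = 300
    log_level: str = "INFO"


@dataclass
class ScanResult:
    calls: list[EveCall]
    hits: list[HomologyHit]  # retained (post-filter) hits
    all_hits: list[HomologyHit]
    orfs: list[OrfCall]
    validations: list[ValidationResult]
    scaffolds: list[Scaffold]


def _cluster_hits(
    hits: Sequence[HomologyHit], merge_nt: int
) -> list[list[HomologyHit]]:
    """Group same-class hits whose intervals lie within ``merge_nt``."""
    clusters: list[list[HomologyHit]] = []
    for h in sorted(hits, key=lambda h: (h.query_start, h.query_end)):
        placed = False
        for cl in clusters:
            lo = min(c.query_start for c in cl)
            hi = max(c.query_end for c in cl)
            if h.query_start < hi + merge_nt and lo - merge_nt < h.query_end:
                cl.append(h)
                placed = True
                break
        if not placed:
            clusters.append([h])
    return clusters


def _member_interval(
    cluster: Sequence[HomologyHit],
    panel_len: Mapping[str, int],
    scaffold_len: int,
) -> tuple[int, int, HomologyHit]:
    best = max(cluster, key=lambda h: (h.bit_score, h.identity, h.subject_id))
    p = panel_len[best.subject_id]
    if best.frame > 0:
        start = best.query_start - 3 * best.subject_start
        end = best.query_end + 3 * (p - best.subject_end)
    else:
        start = best.query_start - 3 * (p - best.subject_end)
        end = best.query_end + 3 * best.subject_start
    start = min(start, min(h.query_start for h in cluster))
    end = max(end, max(h.query_end for h in cluster))
    return max(0, start), min(scaffold_len, end), best


def scan_assembly(
    scaffolds: Sequence[Scaffold],
    viral_panel: Sequence[ProteinPanelEntry],
    cellular_panel: Sequence[ProteinPanelEntry] = (),
    depth: Mapping[str, np.ndarray] | None = None,
    mode: str = "genome",
    params: SearchParams = SearchParams(),
    thresholds: FilterThresholds = FilterThresholds(),
    sl_query: SLQuery = SLQuery(),
    config: RunConfig | None = None,
) -> ScanResult:
    """Run the full detection pipeline over in-memory scaffolds."""
    cfg = config or RunConfig(assembly="<memory>", mode=mode)
    panel_len = {p.id: len(p.seq) for p in viral_panel}
    all_hits: list[HomologyHit] = []
    kept_hits: list[HomologyHit] = []
    all_orfs: list[OrfCall] = []
    validations: list[ValidationResult] = []
    calls: list[EveCall] = []

    for sc in scaffolds:
        hits = translated_search(sc, list(viral_panel), params)
        all_hits.extend(hits)
        kept = filter_hits(hits, mode, thresholds)
        kept_hits.extend(kept)
        if not kept:
            continue
        orfs = annotate_orfs(
            find_orfs(sc, cfg.min_orf_aa), viral_panel, cellular_panel, params
        )
        all_orfs.extend(orfs)

        members: list[EveMember] = []
        for gene_class in ("MCP", "RdRp"):
            class_hits = [h for h in kept if h.gene_class == gene_class]
            for cluster in _cluster_hits(class_hits, cfg.merge_nt):
                start, end, best = _member_interval(cluster, panel_len, len(sc.seq))
                verdict = verify_candidate(
                    sc,
                    best,
                    orfs,
                    viral_panel,
                    cellular_panel,
                    params,
                    min_len_aa=cfg.min_orf_aa,
                    flank_nt=cfg.flank_nt,
                )
                validations.append(verdict)
                if verdict.status == "rejected":
                    logger.info(
                        "rejected candidate %s:%d-%d (%s)",
                        sc.id, start, end, gene_class,
                    )
                    continue
                members.append(
                    EveMember(
                        scaffold_id=sc.id,
                        gene_class=gene_class,
                        start=start,
                        end=end,
                        strand="+" if best.frame > 0 else "-",
                        source_id=best.subject_id,
                        status=verdict.status,
                    )
                )
        if not members:
            continue
        sc_calls = call_eves(members, cfg.pairing_threshold_nt)
        for eve in sc_calls:
            eve.sl_hits = tuple(
                scan_dinoSL(
                    sc, eve, sl_query, cfg.sl_window_nt, cfg.sl_word, cfg.sl_min_matches
                )
            )
            eve.neighbors = tuple(
                annotate_neighbors(eve, orfs, cfg.neighbor_window_nt)
            )
            if any(m.status == "confirmed_flank" for m in eve.members):
                eve.validation_status = "confirmed_flank"
            else:
                eve.validation_status = "confirmed_orf"
            if depth is not None and sc.id in depth:
                cov = coverage_uniformity(
                    depth[sc.id],
                    eve.interval,
                    flank_nt=cfg.sl_window_nt,
                    cv_threshold=cfg.cv_threshold,
                    contrast_threshold=cfg.contrast_threshold,
                )
                eve.coverage = cov
                eve.coverage_status = cov.status
        calls.extend(sc_calls)

    calls.sort(key=lambda c: (c.scaffold_id, c.start))
    return ScanResult(
        calls=calls,
        hits=kept_hits,
        all_hits=all_hits,
        orfs=all_orfs,
        validations=validations,
        scaffolds=list(scaffolds),
    )


# ---------------------------------------------------------------------------
# file-level runs


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def calls_to_json(calls: Sequence[EveCall], path: str | Path) -> None:
    payload = []
    for c in calls:
        payload.append(
            {
                "scaffold_id": c.scaffold_id,
                "type": c.type,
                "gap": c.gap,
                "coverage_status": c.coverage_status,
                "validation_status": c.validation_status,
                "members": [asdict(m) for m in c.members],
                "sl_hits": [asdict(h) for h in c.sl_hits],
                "neighbors": [asdict(n) for n in c.neighbors],
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def calls_from_json(path: str | Path) -> list[EveCall]:
    from .evecall import Neighbor, SLHit

    with open(path) as fh:
        payload = json.load(fh)
    calls = []
    for c in payload:
        calls.append(
            EveCall(
                scaffold_id=c["scaffold_id"],
                type=c["type"],
                members=tuple(EveMember(**m) for m in c["members"]),
                gap=c["gap"],
                sl_hits=tuple(SLHit(**h) for h in c["sl_hits"]),
                neighbors=tuple(Neighbor(**n) for n in c["neighbors"]),
                coverage_status=c["coverage_status"],
                validation_status=c["validation_status"],
            )
        )
    return calls


def run_scan(config: RunConfig) -> ScanResult:
    """File-in, file-out scan; writes GFF3/TSV/JSON plus a run manifest."""
    from .synthio import default_cellular_panel, default_viral_panel

    scaffolds = read_fasta(config.assembly)
    viral = (
        read_panel(config.viral_panel)
        if config.viral_panel
        else default_viral_panel()
    )
    cellular = (
        read_panel(config.cellular_panel)
        if config.cellular_panel
        else default_cellular_panel()
    )
    lengths = {sc.id: len(sc.seq) for sc in scaffolds}
    depth = None
    if config.depth:
        if str(config.depth).endswith((".sam", ".bam")):
            depth = read_depth_sam(config.depth, lengths)
        else:
            depth = read_depth_tsv(config.depth, lengths)
    result = scan_assembly(
        scaffolds,
        viral,
        cellular,
        depth=depth,
        mode=config.mode,
        config=config,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_hits_tsv(result.hits, outdir / "hits.tsv")
    write_orfs_gff3(result.orfs, outdir / "orfs.gff3")
    write_eves_gff3(result.calls, outdir / "eves.gff3")
    write_eves_tsv(result.calls, outdir / "eves.tsv")
    calls_to_json(result.calls, outdir / "eves.json")
    inputs = {
        key: {"path": str(p), "sha256": _sha256(p)}
        for key, p in (
            ("assembly", config.assembly),
            ("viral_panel", config.viral_panel),
            ("cellular_panel", config.cellular_panel),
            ("depth", config.depth),
        )
        if p
    }
    manifest = {
        "tool": "dinoeve",
        "version": __version__,
        "config": asdict(config),
        "inputs": inputs,
        "n_scaffolds": len(scaffolds),
        "n_hits_kept": len(result.hits),
        "n_eves": len(result.calls),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return result


def run_simulate(seed: int, outdir: str | Path, **overrides) -> None:
    from .synthio import SimConfig, make_benchmark

    if "n_scaffolds" in overrides and "n_single_eves" not in overrides:
        # keep one EVE per scaffold (a fifth of them genomic) when only
        # the scaffold count is changed
        n = overrides["n_scaffolds"]
        n_genomic = n // 5
        overrides.setdefault("n_genomic_eves", n_genomic)
        overrides["n_single_eves"] = n - n_genomic
    config = SimConfig(seed=seed, **overrides)
    make_benchmark(config, outdir=outdir)


def run_evaluate(
    calls_json: str | Path, manifest_json: str | Path, out_tsv: str | Path | None = None
):
    from .report import benchmark_eval
    from .synthio import GroundTruthManifest

    calls = calls_from_json(calls_json)
    truth = GroundTruthManifest.from_json(manifest_json)
    metrics = benchmark_eval(calls, truth)
    if out_tsv is not None:
        metrics.to_csv(out_tsv, sep="\t", index=False)
    return metrics
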