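# Methods

This note records the models, parameter semantics, numerical choices and
known limits of `dinoeve`. It is the package's own account; every number
quoted here is computed by the test suite or `scripts/acceptance.py`,
not asserted from elsewhere.

## Translated homology screen

Scaffolds are translated in all six reading frames (ambiguous bases
become `X`, stops `*`; trailing partial codons are dropped). Each frame
carries a coordinate map between residue indices and forward-strand
nucleotide intervals, so hits are reported in genome coordinates
regardless of strand.

The aligner is an exact affine-gap Smith–Waterman (numba-compiled) over
BLOSUM62 with gap open 11 / extend 1 — a gap of length *k* costs
`11 + k`. A shared exact amino-acid word (default length 4) between a
frame and a panel protein gates the dynamic programming; an
`exhaustive` switch removes the gate so tests can compare the engine
against a pure-DP reference. Multiple HSPs per frame/protein pair are
recovered by masking the query span of each reported alignment and
re-running, up to `max_hsps` (8). Traceback ties prefer the diagonal,
then a gap in the query, then a gap in the subject, making outputs
order-independent.

E-values use the Karlin–Altschul form `E = K·m·n·exp(−λS)` with the
standard gapped BLOSUM62(11,1) constants λ = 0.267, K = 0.041, and a
search space of total translated scaffold residues × total panel
residues. Any internally consistent calibration serves the filters'
purpose; the constants and all thresholds are configurable
(`SearchParams`, `FilterThresholds`). The reporting floor is 30 bits —
far below the 50-bit retention threshold, so no retained hit is ever
lost to reporting, while random-sequence DP re-runs stay rare.

Retention reproduces the published screen exactly: `E < 1e-5`, bit ≥ 50,
percent identity ≥ 30 (identity counts matches over all alignment
columns, gaps included — the BLAST convention); *genome* mode adds
alignment length ≥ 100 aa, *metagenome* mode imposes no length penalty
(metagenome scaffolds are short; a length rule would discard real
fragments). These boundaries are tested bit-exactly at 49.9/50.0,
29/30, 1.1e-5/0.99e-5 and 99/100 aa.

## ORF calling and validation

ORFs are maximal stop-free runs per frame (stop-to-stop), default
minimum 60 aa, with no start-codon requirement — endogenized elements
are fragmented, and insisting on ATG discards genuine relicts.
`has_start` records whether the segment begins with Met or at a
scaffold edge; a "complete" ORF is stop-bounded and at least the
minimum length. Annotation aligns each ORF translation against the
viral and cellular panels and keeps the best hit passing `E < 1e-3`,
bit ≥ 50, recording both the ORF extent and the aligned subregion (the
subregion is what neighborhood distances are measured from, since
stop-to-stop ORFs overrun their genes into background sequence).

Candidate loci are confirmed three ways, in order: a complete
overlapping ORF annotating to the same gene class (`confirmed_orf`);
otherwise a re-search of the hit region ± 300 nt of flanks reproducing
the viral annotation at `E < 1e-3` (`confirmed_flank`); otherwise
`rejected`. On the default benchmark no planted element is rejected and
negative scaffolds produce no candidates at all.

## EVE calling

Validated hits of one gene class on one scaffold within 300 nt of each
other are merged into a member locus, and the locus boundary is
extrapolated to full subject coverage: a best hit covering subject
residues [s0, s1) of a P-residue protein is widened by 3·s0 and
3·(P−s1) nt on the appropriate sides (strand-aware), clipped to the
scaffold. Local alignments trim mismatched termini; the extrapolation
restores the full endogenized CDS span whenever the element carries no
net-length indels, which makes downstream gap measurements exact
rather than off by the trimmed margin.

MCP–RdRp pairing is greedy on the gap between facing interval ends,
ascending, ties broken by leftmost MCP then leftmost RdRp; pairs with
gap ≤ 1,500 nt become *genomic* EVEs, everything else single-ORF EVEs,
and each member belongs to exactly one call. The pairing threshold, the
1.5-kb rule, is applied uniformly to genome and metagenome inputs.

## Spliced-leader scan

The dinoSL query is a 22-nt sequence with a set of positions exempt
from mismatch counting. The bundled default is the canonical conserved
core in DNA alphabet (`TCCGTAGCCATTTTGGCTCAAG`) with exempt positions
(0, 21) — the degenerate 5' base and the splice-junction base. Both are
explicit configuration (`SLQuery`), not values this package claims from
the literature it reimplements.

The scan covers both strands of the region within 500 nt of the EVE:
exact 9-mer seed words (query words spanning an exempt position are
expanded over all bases there) locate candidate placements, which are
then scored by full ungapped comparison; a hit needs ≥ 18 of 22
positions matched, exempt positions counting as matched. Offsets are
signed distances to the EVE interval (negative = 5' side, 0 = inside).
The seeded scan is tested for exact agreement with an all-positions
brute-force comparison on 1,000 randomized cases.

## Coverage-uniformity screen

Per-base depth (from a depth TSV or SAM reads) over the EVE ± 500 nt
yields two statistics: `contrast` = |mean inside − mean flank| / pooled
mean, and `cv` = sd/mean over the union. Either exceeding 0.5 fails the
call; all-zero depth fails with an explicit reason. The thresholds
separate Poisson-like uniform coverage (cv ≈ 0.2 at 30×) from the
step-function profile of a chimeric join (cv ≈ 1) with a wide margin —
on mixed batches of simulated uniform and chimeric profiles the screen
classifies 50/50 correctly, and every simulated chimera in the default
benchmark is flagged.

## Evolution layer

Pairwise identity is a global (Needleman–Wunsch) alignment with match
+1 / mismatch −1 / linear gap −2, identity = matches / alignment
columns; traceback tie-breaks are fixed, and an independent DP oracle
checks the values. Codon back-alignment threads unaligned CDS through a
gapped protein alignment (every protein gap becomes `---`, codons
preserved verbatim, trailing stops tolerated, mismatches reported with
row and position).

dN/dS is the Nei–Gojobori (1986) counting estimator: per-codon
synonymous/nonsynonymous site counts (mutations creating stops count as
nonsynonymous; each sense codon contributes exactly 3 sites), observed
differences averaged with equal weight over all substitution orderings
for multi-hit codons, Jukes–Cantor correction `d = −(3/4)·ln(1−4p/3)`,
ω = dN/dS. Codon columns with gaps or ambiguity are dropped pairwise;
columns holding a stop are skipped and flagged. The correction is
undefined at p ≥ 3/4 and ω undefined at dS = 0; both are surfaced as
`None`, never silently clamped. A counting estimator replaces
likelihood codon models deliberately: it is transparent and
self-contained at the scale of EVE ORF pairs, and the scientific claim
it supports — neutral drift of endogenized ORFs — is a regime question,
not a parameter-precision question. Under a uniform neutral
substitution model the recovered median ω across 50 seeded replicates
sits in [0.8, 1.2]; skipping stop-gaining codon columns removes a small
amount of nonsynonymous signal, which is why the point value can sit
slightly below 1. Multi-sequence input yields the full pairwise ω
matrix and its mean, since a "single" dN/dS for a set of ORFs is
otherwise ambiguous.

The neighbor-joining utility (backed by scikit-bio, deterministic
tie-breaking, Newick output) is a lightweight exploration aid, not a
replacement for ML phylogenetics, which is out of scope.

## Count model

`fit_count_model` fits OLS of EVE-containing scaffold counts on genus
plus query length, N50 and completeness, with type-II F-tests per term.
All pairwise genus contrasts are computed from the fitted coefficient
covariance; p-values are Tukey-HSD adjusted via the studentized range
(Holm available). Rank-deficient designs and zero residual d.f. are
errors naming the offending columns; an all-constant response yields an
empty (flagged) F table rather than a 0/0. A planted genus effect of
20 scaffolds (σ = 5, n = 6 per genus) is detected at α = 0.05 in ≈ 99%
of 200 replicates.

Counting rule: a scaffold with both gene classes counts once, in
"both", so the three categories partition EVE-containing scaffolds and
the family rollup is additive. This is stated explicitly because
published per-category tables can otherwise be aggregated two ways.

## Synthetic benchmark

The generator emulates exactly the structure the detector assumes:

* **Host background** — i.i.d. nucleotides at a target GC (default
  0.50, typical of Symbiodiniaceae assemblies), plus one cellular decoy
  gene per scaffold.
* **Planted EVEs** — degraded back-translations of named panel
  proteins. Degradation order is fixed and layered: amino-acid
  substitutions at the per-EVE divergence, GC-matched codon choice on
  back-translation (synonymous codons weighted by the target base
  composition, so planted elements do not stand out compositionally),
  then per-site indels (length 3 half the time, else 1–2, i.e.
  frameshifting), then with probability `stop_rate` one internal stop
  codon. Realized substitution fractions and stop counts are recorded
  in the manifest and are reproducible from the emitted sequence.
* **Geometry** — genomic plants are `MCP — gap — RdRp` blocks; the
  spliced leader ends exactly `sl_offset` nt 5' of the RdRp start and a
  LINE-like ORF begins exactly `line_offset` nt downstream of the EVE
  (both in virus orientation; whole blocks are reverse-complemented for
  minus-strand plants, so offsets survive by construction).
* **Negatives** — background plus cellular genes only.
* **Chimeras** — two unrelated halves joined at the midpoint with an
  EVE straddling the junction; reads cover only the first half, so the
  depth profile steps from ~30× to 0 inside the EVE.
* **Reads** — error-free fixed-length fragments at uniform expected
  depth (default 100 nt, 30×). The coverage screen consumes depth
  uniformity, so read-error modelling would add nothing the pipeline
  reads.

Default conditions (the standard benchmark): 30 EVE scaffolds of 8 kb —
24 single-ORF and 6 genomic plants — over a divergence grid 0–0.5,
genomic gaps (319, 400, 656, 800, 1500, 1501) nt straddling the pairing
rule and covering the reported range for real whole-genome
integrations, `stop_rate` 0.3, `sl_offset` 100, `line_offset` 95, 10
negatives, 5 chimeras. The default `indel_rate` is 0: the benchmark
calibrates the sensitivity-versus-divergence curve, and frameshifting
indels would confound the divergence bins (a 5%-divergence plant with a
frameshift is no longer a 5% plant); indel degradation is fully
implemented, unit-tested, and a per-run knob. One `numpy` Generator
seeded from `SimConfig.seed` drives everything; identical configs give
byte-identical FASTA/FASTQ/depth/manifest output.

What the benchmark does **not** emulate: real genome composition
(repeats, introns, heterozygosity), homology between panel entries
(panel proteins are independent random sequences, so cross-class
confusions that a real panel could produce are not exercised),
sequencing error, or assembly artefacts beyond the depth-step chimera.
A pipeline passing here is verified as *internally correct at the
stated thresholds*; sensitivity on real assemblies additionally depends
on panel quality and assembly contiguity.

## Problem sizes and determinism

All shipped analyses are desk-scale by design: the default benchmark
(45 scaffolds × 8 kb against a 2,016-residue panel) scans in well under
a minute on one CPU, and the oracle comparisons (20 alignment
instances, 1,000 spliced-leader cases, 200 count-model replicates) are
sized to exercise the engines thoroughly while keeping the whole suite
fast. Every stochastic step takes an explicit seed; there is no global
random state.

## Known limitations

* The E-value calibration is internal; absolute E-values differ from
  BLAST/DIAMOND on the same data (thresholds were tuned for relative
  consistency, and remain configurable).
* The stop-to-stop ORF caller has no coding-potential model; in real
  GC-rich genomes it calls more spurious ORFs than a trained gene
  finder, which only affects the annotation workload, not hit
  retention.
* Member-boundary extrapolation assumes collinearity between query and
  subject; elements with large internal rearrangements will report
  envelope coordinates rather than exact ends.
* NG86 underestimates dN/dS slightly when many neutral changes create
  stops (those columns are skipped); likelihood codon models are
  explicitly out of scope.
* The chimera screen detects depth discontinuities only; chimeras with
  matched coverage on both halves are invisible to it.
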