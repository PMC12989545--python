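# Methods

This note documents the models, parameters and design choices behind
`strainmark`, and what its synthetic benchmarks do and do not show
about real data.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open; conversion to the
1-based inclusive convention happens only at the GFF3/BED/report
boundary. Nucleotide sequences are uppercased on load and every IUPAC
ambiguity code other than N collapses to N with a logged warning. An N
never matches a primer base — a deliberately conservative rule, since a
specificity claim should not rest on an ambiguous reference base.
"Hypothetical" annotation is detected by a configurable case-insensitive
term list (`hypothetical protein`, `uncharacterized protein`,
`domain of unknown function`, `DUF`).

## Singleton screen

**Alignment.** Pairwise comparison is local Smith–Waterman under
BLOSUM62 with affine gaps: a gap of length L costs 11 + L. X is scored
0 against every residue. Identity is matches divided by alignment
columns, with gap columns counted; coverage of a sequence is its
aligned span over its length. The engine is Biopython's
`PairwiseAligner`; the test suite verifies its scores against an
independent Gotoh dynamic program.

**Clustering.** Greedy incremental, CD-HIT style: proteins are sorted
by length descending (ties by id); each joins the earliest-founded
representative it matches at identity ≥ 0.80 **and** coverage ≥ 0.80
on *both* sequences, else founds a new cluster. The algorithm is a
deterministic reimplementation of the thresholds commonly used in
pan-proteome tools; representative-based greedy clustering with
bidirectional coverage is the standard reading of those thresholds. A
shared-5-mer prefilter skips representative comparisons that share no
5-mer; at these thresholds a qualifying pair without a shared 5-mer is
not realistically constructible, and the suite asserts partition
equality with and without the prefilter on all fixtures.

**Singletons.** A singleton is a cluster of exactly one protein
belonging to the focal strain — the standard reading of the term.

**Refinement.** Homologs in a background panel are counted at an
ungapped Karlin–Altschul e-value `E = K·m·n·e^{−λS}` (λ = 0.3176,
K = 0.134 for BLOSUM62), with m the query length and n the total panel
residues. Using the user's panel as the search space keeps significance
reproducible and independent of any external database size. Candidates
rank ascending by (homolog count, best identity, id); ties everywhere
break lexicographically by record id so any input permutation yields
the same list.

**Filters.** Genes strictly shorter than 300 bp are dropped (a 300-bp
gene is retained — the criterion is "shorter than"); hypothetical
products are dropped when `exclude_hypothetical` is set. Dropped
candidates carry machine-readable reason codes.

## Primer design

Criteria defaults: amplicon ≥ 301 bp (the strict "> 300 bp" on
integers), GC 40–60%, self-complementarity ≤ 4, primer length 18–24 nt,
Tm 57–63 °C, pair ΔTm ≤ 2 °C. All are configurable; the Tm window is a
ranking aid, not a published criterion.

**Self-complementarity** is the best contiguous window over all
ungapped antiparallel self-alignments (equivalently all offsets of the
sequence against its reverse complement), +1 per Watson–Crick pair and
−1 per non-pair, clamped at 0. The `end3` mode restricts windows to
those covering the 3′-terminal base. Gap-free ±1 scoring is the minimal
reproducible definition of the 0–4 criterion; both modes are computed,
and the "any" mode is the one checked against the published bound. Of
the six published assay primers, all score ≤ 4 under this scorer; one
(ubik_r) computes to 61.1% GC, just outside the stated 40–60% band — an
exception in the source assay set that the toolkit records but does not
resolve.

**Melting temperature** is nearest-neighbor with the SantaLucia 1998
unified parameter set: `Tm = ΔH/(ΔS + R·ln(C_T/4)) − 273.15 +
16.6·log₁₀[Na⁺]`, defaults 50 mM Na⁺ and 500 nM total oligo. The table
is authored in-package; the suite cross-checks every value against
Biopython's independent `MeltingTemp` implementation to 10⁻⁶ °C.

**Enumeration** considers every forward/reverse window pair in range,
keeps pairs whose primers individually pass GC/self-complementarity/Tm
and jointly pass ΔTm and amplicon length, and ranks by (|ΔTm|, combined
self-complementarity, |mean GC − 50|), ties by coordinates. Degenerate
bases disqualify a window. Design is exhaustive and deterministic.

## In-silico PCR

Binding uses a mismatch-count model: ≤ 2 total mismatches and an exact
3-base 3′ anchor by default. The anchor models polymerase extension
sensitivity; both knobs are assay-stringency parameters. No
thermodynamic duplex model is applied — the mismatch rule admits an
exact exhaustive oracle, which the suite runs on dozens of random
genomes. Amplicons pair a forward-strand site with a downstream
reverse-strand site in both orientations, lengths measured 5′-end to
5′-end inclusive, capped at 2 kb by default. An off-target genome is
flagged for mispriming when it yields a product within ±25% of a target
product length — the verbal requirement of "comparably long products
that would confound a melt assay" quantified once and made
configurable.

## Melt curves and classification

Amplicon melt temperature uses the empirical long-duplex formula
`Tm = 81.5 + 16.6·log₁₀[Na⁺] + 0.41·GC% − 675/N` (domain N ≥ 50).
Predicted Tm is **never** compared with an instrument's absolute peak
positions: SYBR-chemistry instruments shift peaks systematically, so
assays compare each well's Tm to a positive control measured on the
same instrument. The simulated derivative curve is the analytic
−dF/dT of a sum of abundance-weighted sigmoids (width 1 °C) on the
72–95 °C grid at 0.5 °C steps (the final grid point clamps at the end
temperature when the step does not divide the range); peaks are
per-connected-component argmaxes above half the global maximum.

The positivity rule is: positive iff Ct is present and ≤ 30 **and**
|Tm − control| ≤ 0.5 °C, both boundaries inclusive (0.5 °C being the
melt program's step and hence the measurement uncertainty). The rule is
monotone: lowering Ct or |ΔTm| never turns a positive negative.
Detection rates are 100·positives/total per (crop, timepoint, assay)
group at one decimal; groups requested but absent from the data report
"ND". A sample-level "colonized" verdict (positive with at least one
assay) is available as an OR-combination over a sample's calls.

## Novelty scan

Seed-and-extend: shared 15-mers on both strands, ungapped X-drop
extension (match +1, mismatch −2, X-drop 20), significance by ungapped
Karlin–Altschul with λ = 1.28, K = 0.46. Alignments at e ≤ 10⁻¹⁰ mark
covered query intervals; maximal uncovered intervals ≥ 10 bp are
reported with overlapping features. Coordinates are linear: rotate
circular replicons to a common start first, or the breakpoint surfaces
as one spurious region. The resolution limit at region boundaries is
seed_k − 1 per side (a flanking k-mer must fit to anchor coverage).
Counts produced by any particular aligner stack on real assemblies are
aligner-dependent; this scanner's guarantees are stated (and tested)
in terms of planted-insertion recovery, not any specific published
region count.

## Synthetic data

Generators are pure functions of (parameters, seed); the shipped
fixture seed is 42, and statistical properties sweep 20 seeds.

* **Pangenome** — default 4 background strains, 50 core families at
  95% identity, 5 planted focal-only genes of 150–900 bp (at least one
  forced below 300 bp so the length filter is exercised). Core families
  diverge by substitutions only, at family-wide interior positions,
  each non-focal strain receiving a *distinct* substitute residue, so
  every cross-strain pair of a family sits at the requested identity
  (±0.02 audited at generation time with `align_pair`). Planted genes
  are validated non-clusterable with any background protein. Real
  pan-proteomes additionally have indels, paralogy and phylogenetic
  correlation; recovery results here demonstrate correctness of the
  screen's logic, not robustness to those.
* **Off-target panel** — random genomes with decoys planted per
  scenario: none, a convergent site pair giving a product within ±10%
  of the target's, a 5× product, or one orphan forward site.
* **qPCR dataset** — per-group Bernoulli colonization; positives draw
  Ct ~ Normal(22, 3) truncated to (0, 40] and Tm ~ Normal(control,
  0.15 °C); negatives are absent, late (Ct ~ Normal(35, 2)) or
  off-peak (|ΔTm| ≥ 1.5 °C); untreated controls never colonized. These
  match routine assay behaviour for an established marker; crops and
  timepoints default to the five-crop, day-14/28 layout of a
  proof-of-concept colonization trial.
* **Planted insertions** — random-sequence insertions at uniform
  points kept ≥ 200 bp apart and ≥ 200 bp from the ends, so each maps
  to exactly one recoverable region.

## Problem sizes in the shipped benchmarks

The default suites run at desk scale, chosen to keep the feedback loop
tight while remaining statistically meaningful: 20-seed screens use 3
background strains × 20 core families; novelty sweeps use 20-kb
references with 3 insertions of 100–600 bp; oracle-equivalence checks
use 50 random genomes of 1–6 kb and 100 random protein pairs. All
sizes are ordinary function arguments and scale up directly.

## Known limitations

* The e-value model is ungapped Karlin–Altschul applied to gapped
  alignment scores — standard practice for quick significance, but not
  a calibrated gapped statistic.
* The binding model counts mismatches; it does not rank near-matches
  thermodynamically, so two sites with equal mismatch counts are
  treated alike regardless of base identity.
* Melt simulation uses a fixed 1 °C transition width and a two-state
  model; multi-domain amplicons with internal GC gradients can melt in
  stages this model does not produce.
* The clustering prefilter is heuristic; its partition-equivalence
  guarantee is empirical (asserted on all shipped fixtures), not
  proven.
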