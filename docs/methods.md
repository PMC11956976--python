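# Methods

This note documents the models, defaults and numerical choices behind
`nicrseq`, and what the synthetic-data generator does and does not emulate.

## Barcode model

A unit ("ICR") barcode is 14 nt: a 4-nt hardcoded sequence identifying the
gene cargo plus a 10-nt uniform-random sequence marking the clonal
replicate. Three unit barcodes — one per cargo set — are nested into a
54-nt barcode with two fixed 6-nt junctions:
`icr1 + junction1 + icr2 + junction2 + icr3`
(unit barcodes at 0-based half-open intervals [0,14), [20,34), [40,54)).
The genotype is read as a three-letter code in {Y,H,N}³ (yeast / human /
null, Set 1 letter first).

Choices where a real construct's sequences would be experiment-specific:

- **Junctions** default to `ACCGGT` (AgeI) and `GCTAGC` (NheI), the
  restriction enzymes whose sites would be regenerated by the nested
  cloning of Sets 2 and 3; configurable. They are a modeling choice, not a
  reconstruction of the real construct.
- **Flanking anchors** default to the M13 forward/reverse priming
  sequences (18 nt each) as generic stand-ins for the amplification
  primers.
- **Hardcodes** are experiment-specific; `design_codebook` draws codes greedily
  from a seeded permutation of the 4-mer space with all pairwise Hamming
  distances ≥ 2 (configurable), and decoding is exact (0 mismatches) by
  default: with minimum distance 2 a single sequencing error cannot be
  corrected unambiguously, and the read-count threshold in QC absorbs
  sequencing noise instead. Decoding with mismatch tolerance t is refused
  unless the codebook guarantees unambiguity (min distance ≥ 2t + 1).
- Random-part collisions across cargos are allowed; uniqueness is enforced
  at the full 14-nt (within a library) and 54-nt (within the pool) level.

## Synthetic data generator

The generator emulates the screen's study design so every stage is testable
without sequencing data. All randomness flows from explicit seeds and truth
tables are bit-for-bit reproducible.

**Single-cargo libraries.** Nine cargos (3 sets × {yeast gene, human
ortholog, null sequence}) with synthetic random reference sequences at
realistic amplicon lengths (1549–3957 nt; the real references are not
bundled, and short references can be injected for fast tests). Each library
has `n_barcodes_per_cargo` (default 500, the screen's cloning target)
barcodes, each assigned a cloning outcome:

- class rates default to 0.90 correct / 0.08 primer dimer / 0.015
  SNP-indel mutant / 0.005 misassociated — chosen once to echo the reported
  magnitudes of such screens (majority correct, primer dimers the dominant
  error, mutations ≈0.5%, misassociation rare but raised here so the class
  is exercised at n = 500); they are configuration, not claims;
- primer dimers are random inserts of 40–120 nt;
- mutants carry 1–3 substitutions or one 1–10-nt indel, placed with
  probability 0.7 inside the primer-derived ends (first/last 20 nt,
  emulating primer-synthesis errors) and otherwise ≥ 45 nt into the
  interior — deliberately clear of the 30-nt primer-region boundary used
  by QC, so the ground-truth "primer-region-only" flag is unambiguous even
  under alignment coordinate shifts in repeats;
- reads per barcode are Poisson (default mean 50, ≥ 1); each read is
  `anchor + barcode + anchor + insert` on a random strand with i.i.d.
  per-base substitution errors (default 5 × 10⁻⁴, a high-fidelity
  consensus-read regime).

**Nested pool.** For each of the 27 genotypes, `n_per_genotype` (default
500) component triples are sampled with replacement per component, unique
at the 54-nt level; component error classes are carried into the pool
truth.

**Growth time course.** Barcode b of genotype g grows as
`N_b(t) = N_b(0) · exp((r_g(c) + ε_b) t)` with `ε_b ~ N(0, σ_bc)` drawn
once per barcode — a persistent lineage effect, not per-observation noise,
because replicates are clonal lineages whose deviations persist. Observed
counts per sample are multinomial at `depth_per_sample` (default 5 × 10⁵)
over the latent abundances; the sample grid is 5 time points (0–48 h,
every 12 h) × 5 MMS concentrations (0–0.02%), with t = 0 samples drawn
from the common starting pool. Default rates fall with dose
(0.35 → 0.02 /h) and give only YYY a benefit at intermediate doses
(+0.05, +0.12, +0.04 /h at 0.005/0.01/0.015%, none at 0.02%), the
qualitative dose-response pattern the screen targets. `σ_bc` has no
empirical anchor (the screen does not report per-barcode fitness variance)
and defaults to 0.005/h as a small persistent effect; `N_b(0)` is
log-normal with σ = 0.25. Dilution steps do not change relative
frequencies and are not modeled.

**Not emulated:** raw long-read consensus error profiles, transformation
bottlenecks, plasmid copy-number variation, index hopping, read-pair
merging artifacts (reads are emitted pre-merged with flat Q30 qualities).
Passing tests therefore validate the analysis logic, not robustness to
these real-data phenomena.

## Long-read QC

Reads are searched for the upstream anchor on either strand
(substitution-only sliding-window match, ≤ 2 mismatches by default,
leftmost acceptable hit); the 14 nt that follow are the barcode, and the
cargo is everything after the downstream anchor. Inserts shorter than
150 nt (far below the shortest reference at 1549 nt) are primer dimers;
otherwise the insert is globally aligned (edlib, Needleman–Wunsch edit
distance) against all nine references and assigned to the best hit if
identity ≥ 0.9 (ties prefer the expected cargo), giving classes correct /
misassociated / mutant / unclassifiable. Only identity and edit positions
are consumed downstream, so edit distance is an adequate scoring model.
Variant positions come from the alignment CIGAR in reference coordinates;
a mutant is "primer-region-only" when all edits lie within the first/last
30 nt.

Per barcode (exact 14-nt identity; no error-clustering — the ≥ 10-read
threshold suppresses error-derived barcodes instead), reads vote:

- support for both the expected cargo (correct or mutant reads) **and** a
  wrong insert (misassociated, primer dimer, unclassifiable) marks the
  barcode *conflicting* and discards it;
- otherwise the majority read class wins, with ties resolved toward the
  more benign class.

The conflict rule is deliberately insert-level rather than read-level:
a read with one stray sequencing error in the cargo looks "mutant", so
treating any correct/mutant mixture as a conflict would discard nearly
every barcode at realistic error rates. Restricting conflicts to
right-cargo-vs-wrong-insert support keeps the intended discard behaviour
(a primer-dimer read against 12 correct reads still conflicts) while
letting majority voting absorb sequencing noise; at QC-scale read depth
(tens of reads per barcode) this holds per-barcode classification accuracy
above 99% at a per-base error of 10⁻³.

The whitelist is the correct barcodes plus mutants whose edits are all in
the primer regions (where gene function is untouched); interior-mutant
barcodes are excluded.

## Short-read counting

Merged reads are scanned for both anchors (≤ 2 substitutions each, either
strand); the sequence between them must be a structurally valid 54-nt
barcode with exact junctions. Counting is exact at the 54-nt level — no
error correction — and a nested barcode is kept iff all three components
are in their set's whitelist. Extraction failures are tallied by reason
(no anchor, wrong length, junction mismatch). Counting is order- and
shard-invariant, and the whitelist filter is idempotent and monotone.

## Growth analysis

Frequencies are normalized within sample, then to the matching 0-MMS
sample at the same time point. Zero-frequency barcodes (in reference or
target) are dropped from that condition and counted — no pseudocount by
default; values are analyzed on the log2 scale (ratios are multiplicative,
and the transform stabilizes variance; `log2=False` switches to the raw
scale). The per-condition model is a one-way fit of value on genotype:
genotype means, pooled residual variance, all pairwise contrasts on the
residual df (homoscedastic; no Satterthwaite variant), implemented in
closed form and cross-checked in the tests against statsmodels OLS and the
classical pooled t-test. Genotypes with fewer than two barcodes are
excluded from the fit and reported. BH adjustment is a single family over
all contrasts from all conditions; significance requires adjusted
p < 0.05 and |estimate / residual SD| > 0.2. Degenerate fits (zero
residual variance) give p = 1 and effect 0 when the estimate is 0.

## Power simulation

Downsampling uses the 0-MMS 48-h sample as the sampling frame: a barcode
must be observed there to be eligible, and sampled barcodes without a
normalized value at the target concentration simply contribute nothing.
Each replicate samples n unique barcodes per genotype (independent uniform
resampling across replicates), refits the model, BH-adjusts within that
downsample's own contrast family, and applies the detection rule to the
YYY–NNN pair; detection means adjusted p < 0.05 with |effect| > 0.2 (the
direction fixed by the analysis's aim of detecting significant
differences). One master seed spawns a substream per (concentration, n,
replicate), so results are identical regardless of execution order.
Clopper–Pearson intervals use Beta quantiles
(low = B⁻¹(α/2; k, n−k+1), high = B⁻¹(1−α/2; k+1, n−k)), verified against
direct binomial tail-sum inversion.

## Problem sizes used in the checks

The package defaults are study-scale (500 barcodes per cargo and per
genotype, 5 × 5 sample grid, 5 × 10⁵ reads per sample). The test-suite
simulations use deliberately smaller instances chosen to keep the checks
sharp: 60 barcodes/cargo and 40/genotype for truth-recovery (exact
assertions are scale-free), 27 × 40 barcodes at 2 × 10⁵ depth for the
null-error-rate check (500 downsamples), 100 simulation repeats for CI
coverage of the recovered rate difference, and the documented
strong-benefit regime (27 × 500 barcodes, +3.5 residual SDs for YYY,
500 replicates) for the detection-power benchmark.

## Known limitations

- Exact 54-nt matching cannot rescue reads with barcode-internal errors;
  deep sequencing compensates, but counts are conservative.
- The per-condition cross-sectional model ignores the longitudinal
  correlation of a lineage across time points; no mixed-effects or
  competition-coefficient fitness model is provided.
- The QC classifier has no chimeric-read detection beyond the conflict
  rule, and no consensus-building across reads.
- Synthetic references are random DNA: alignment-identity thresholds are
  easier to satisfy than for homologous real genes (the yeast/human
  ortholog pairs here share no sequence identity, unlike reality where the
  0.9 assignment floor still separates them comfortably).
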