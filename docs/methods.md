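# Methods

`smrtbs` analyses targeted amplicon bisulfite sequencing of long (CCS-level)
reads: molecules are bisulfite-converted, PCR-amplified with barcoded
universal primers, sequenced, and the per-CpG methylation level of each
sample × amplicon is estimated from retained-vs-converted cytosine counts.
This note records the models, parameters, and design decisions.

## Model and estimators

**Methylation level.** Bisulfite treatment deaminates unmethylated cytosine
to uracil (read as T after PCR); 5-methylcytosine is protected. For CpG site
*j* the level is estimated as

    beta_j = n_meth / (n_meth + n_unmeth)

where `n_meth` counts reads with a retained C (top strand; G on the bottom
strand) and `n_unmeth` reads with the converted base. Ambiguous observations
(any other base, or a deletion over the cytosine) count toward neither.
Under ideal chemistry the estimator is the binomial MLE with standard error
`sqrt(beta(1-beta)/depth)`. Sites with `depth < 10` are excluded from
exported profiles (the 10X depth gate): below that, the binomial noise
dominates any biological signal. Note that bisulfite methods cannot
distinguish 5hmC from 5mC; "methylation" here means their sum.

**Known chemistry bias.** With conversion efficiency *e* < 1, an
unmethylated cytosine is retained with probability 1−*e*, so the expected
observed level is `p + (1-p)(1-e)` (≈ p + 0.03(1−p) at e = 0.97), inflating
low levels. The package reports raw estimates and does not apply a
conversion correction; the tests assert unbiasedness against this analytic
expectation, not against the uncorrected truth.

**Per-read conversion rate.** Non-CpG cytosines are essentially
unmethylated in mammalian somatic DNA, so each read's fraction of converted
non-CpG cytosines measures its bisulfite chemistry. Reads with rate < 0.95
are removed (pass requires rate ≥ 0.95); reads with zero informative
non-CpG cytosines cannot be verified and fail by default (configurable).
With *k* informative sites the rate has SE `sqrt(e(1-e)/k)`; short
amplicons therefore lose more reads to this filter than long ones at the
same efficiency — with ~150 sites (700 bp) the 0.95 threshold sits only
~1.3 SD below a 0.97 mean.

**Clonal artifacts.** PCR copies of one template inflate apparent depth.
Clones are defined as reads with *identical* CpG and non-CpG call vectors
over the full amplicon site map, including UNCOVERED positions (so only
reads with the same aligned span can match). One representative per group
(first by read id) is retained; `drop_all_clones` removes entire groups.
Two caveats follow directly from the definition: (i) genuinely distinct
molecules can coincide by chance — at near-0 or near-1 methylation with
high conversion the fully converted pattern is common, so the filter is
only informative when the site pattern carries entropy; (ii) a clone pair
is detected only if *neither* copy acquired a sequencing error at any call
position, so at CCS error rates of a few per mille per base most true clone
pairs of a ~750 bp product escape detection. The filter is validated
against simulator truth in the error-free regime.

**Filter order.** Conversion filter first, clonal detection on its
survivors. Reports conserve reads exactly:
`n_input = n_low_conversion + n_clonal_removed + n_pass`.

## Demultiplexing and trimming

Reads carry `bc_fwd + primer_fwd + insert + rc(primer_rev) + rc(bc_rev)`
with 18 bp barcodes. Assignment tests the 5' end of both read orientations
against every sample's forward barcode and accepts the unique minimum at
Levenshtein distance ≤ 2 ("two mismatches including insertions/deletions"
is read as edit distance; the search window is the first
`barcode_length + max_edits` bases). Ties between distinct samples leave
the read unassigned — arbitrary assignment would cross-contaminate
samples. When the 3' barcode is locatable and strictly favours a different
sample within the same budget, the read is unassigned and the conflict
counted. Barcode + universal primer are trimmed at their best
sub-alignment on each end; if the primer cannot be located within its edit
budget the barcode alone is trimmed and the read flagged. After trimming,
reads not strictly longer than 50 bp are discarded (a `--min-len`/inclusive
switch exposes ≥).

## Bisulfite-aware alignment

Three-letter strategy: the reference is fully converted in silico (top
strand C→T, bottom strand G→A in forward coordinates) and the read is
collapsed the same way, so conversion state does not penalise placement;
methylation is read back from the original bases afterwards. Four
candidates per amplicon — {read, reverse complement} × {top, bottom} — are
scored with a semi-global affine alignment (reference end gaps free, read
fully aligned): match +2, mismatch −3, gap open −5, gap extend −2 (a gap of
length k costs open + (k−1)·extend), minimum identity 0.7 over aligned
columns. These scores are this package's own defaults — no published
parameterisation exists for this setting — and are exposed as parameters.
All candidates are scored exactly (no heuristic pre-screen); the best
placement wins and score ties between distinct amplicons discard the read
as ambiguous. The pairwise engine is Biopython's `PairwiseAligner`; the
test suite checks its scores against an independent full Gotoh dynamic
program. Insertions in the read contribute no methylation evidence
(no reference coordinate); deletions over a cytosine yield AMBIG.

Coordinates are 0-based half-open internally; all exported tables are
1-based and say so in their headers. A CpG site is always keyed by its
forward-strand C position, whichever strand the read came from.

## Replicate statistics, pooling, islands

Replicate reproducibility restricts to sites present in all replicates and
reports pairwise Pearson r (per amplicon, pooling that amplicon's common
sites) plus the per-site standard deviation across replicates (ddof = 1).
Zero-variance profiles make r undefined; such pairs are reported as NaN
with an explicit list, never coerced. Because r measures covariation
*across sites*, an amplicon whose sites share one truth level has little
across-site variance and cannot show high r however precise the data; the
statistic is informative in proportion to within-amplicon heterogeneity.
Cross-platform comparison intersects two site→level maps and reports r and
signed differences. The two correlation granularities (per-amplicon
mean ± SD of pairwise r, and pooled-sites r across all amplicons) are both
computed and labelled.

Equimolar pooling volumes follow

    V_i = M * L_i / (n * C_i * sum_j L_j)

(M total mass, L_i amplicon length, C_i concentration, n samples, m
amplicons); the implementation verifies V_i·C_i/L_i is constant across
amplicons and that pooled mass sums to M. CpG-island coverage is the
fraction of BED intervals with length ≤ the maximum amplicon size
(inclusive boundary; 1.5 kb amplicons are achievable with optimised
long-range bisulfite PCR).

## Simulator

The generator emulates the observed molecule pool, not the instrument: per
molecule, CpG states are independent coin flips at each site's true level;
every unmethylated cytosine (CpG or not) converts with probability
`conversion_efficiency` (methylated CpG cytosines never convert); the
template strand is uniform; reads get barcodes/primers, uniform
orientation, and per-base substitution/indel errors. PCR bias toward
unmethylated DNA is modelled as template sampling weight `w^u` (u =
unmethylated CpG count, w ≥ 1) — the simplest monotone mechanism with the
reported direction; for a single-CpG amplicon the expected observed level
is `p / (p + w(1-p))`. Sampling is *without* replacement from a 10×
oversized pool, because sampling with replacement would itself emit
duplicate molecules and confound the explicit `clonal_fraction` mechanism,
which copies a previously emitted molecule's converted sequence (errors are
then injected independently). `exact_sampling` replaces coin flips with
stratified assignment — each site methylated in exactly `round(level*n)` of
n molecules — so that with all noise off the pipeline recovers every level
exactly (pattern enumeration over 2^k haplotypes is infeasible at 20+ CpGs
and unnecessary for that purpose). A fixed seed makes the full output
byte-for-byte reproducible.

Defaults encode the study conditions the package targets: conversion
efficiency 0.97, 0.3% clonal reads, ~100X depth, 18 bp barcodes, 0.5%
substitution + 0.1% indel error (CCS-level), bias off (w = 1). The default
three-amplicon panel carries a mostly unmethylated island with a shore-like
gradient (0→0.25), a heterogeneous intermediate island cycling
{0, 0.25, 0.5, 0.75, 1}, and a highly methylated island (0.75→1) — real
islands are not flat, and across-site variation is what replicate
correlation measures.

What the simulator does *not* model: raw polymerase-read/ZMW behaviour and
CCS consensus formation (reads are generated at CCS level), chimeric PCR
products, bisulfite-induced fragmentation, co-methylation correlation along
a molecule (states are independent across sites; real haplotypes are
correlated), and context-dependent conversion resistance. Passing tests
therefore demonstrate correctness of the analysis given this generative
model, not performance on any particular instrument's error profile.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled study designs chosen as the
smallest sizes at which the statistical assertions have power: 3 × ~700 bp
amplicons × 3 replicates × 100X for the recovery/reproducibility study
(the multiplexing panel this mirrors used 702–866 bp amplicons at ~110X);
150 bp amplicons for the depth-scaling law (20–200X, tens of replicate
simulations); 100 alignment instances ≤ 300 bp for oracle equivalence.
Statistical assertions use 3-SE bands (with an explicit multiplicity
allowance when hundreds of sites are tested at once); algebraic identities
are checked to 1e-9 relative or better. Levels are written to 3 decimals
in TSVs; full precision is kept internally. Degenerate inputs (empty
profiles, zero informative sites, zero-variance correlations, empty BED)
return explicit statuses or warnings rather than silent zeros.

## Known limitations

* Conversion-rate filtering assumes non-CpG methylation is negligible; in
  tissues with appreciable CHG/CHH methylation the filter would discard
  valid reads.
* Pattern-identity clone detection under-detects at realistic error rates
  and over-merges when site patterns carry little entropy (see above).
* Alignment is to amplicon references only, not a genome; off-target reads
  are rejected by the identity floor rather than mapped elsewhere.
* No correction is applied for incomplete conversion or PCR bias; both are
  reported so a calibration (e.g. standard curves of methylation controls)
  can be applied downstream.
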