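# Methods

This note records the models, parameter choices, and numerical decisions
behind `clonotrace`, and what the simulator does and does not emulate.

## Assay model

A pooled library of double-barcoded lentiviral constructs (each carrying the
same 10-nt barcode distal to the 5′ LTR and proximal to the 3′ LTR, plus a
GFP marker) transduces primary cells at high MOI. Transduced founders seed a
tumour; each tumour cell inherits its founder's barcode combination. The
readout is targeted amplicon sequencing: per cell (three amplicons — 5′
barcode, 3′ barcode, GFP) and per microdissected region (bulk barcode
counts).

### Copies per cell

Copies per cell are modelled as Poisson(MOI), the canonical
independent-infection model: a single parameter, the transduced fraction is
1 − e^(−MOI), and the histogram-fitting estimator is its exact inverse. The
underlying copy-number distribution in this kind of assay is only known to
be unimodal and roughly symmetric at high MOI, which Poisson satisfies;
alternatives (e.g. negative binomial infection) are not implemented.
`estimate_moi` therefore fits a Poisson rate by maximum likelihood — the
sample mean, or for zero-truncated data (a single-cell assay that only
captures transduced cells) the root of λ/(1 − e^(−λ)) = m, solved by Brent's
method on [1e−9, m]. Confidence intervals are nonparametric bootstrap
(default 1,000 multinomial resamples of the histogram, seeded).

### Barcode design

Whitelists are generated by rejection sampling with pairwise Hamming
distance ≥ 3. Distance 3 is the smallest guarantee under which distance-1
correction can never be ambiguous, so the extraction contract (`exact` /
`corrected` / `ambiguous` / `nomatch`) is testable against a brute-force
scan. Generation fails explicitly when the design is too dense for the
requested count.

### Read depth and noise

Per (cell, amplicon), read depth follows a zero-truncated negative binomial
with mean `reads_per_cell_mean` (reads per amplicon per cell) and
overdispersion `reads_per_cell_dispersion` (variance m + αm²; α = 0 is the
Poisson limit). Zero-truncation is deliberate: absence of reads is governed
solely by the explicit `dropout_prob` knob (applied independently per
amplicon end), so the all-noise-zero configuration recovers truth exactly
rather than almost surely, and dropout rates in experiments compose
predictably. Other noise processes:

- substitution errors per base (`per_base_error`, default 1e-3);
- ambient contamination: each barcode read is, with probability
  `ambient_fraction` (default 0.02), replaced by a draw from the tumour-wide
  marginal construct distribution (free template in the lysate);
- doublets: with probability `doublet_rate` (default 0.05, a typical
  single-cell capture rate) a "cell" is two merged genotype draws;
- both read orientations are emitted with equal probability.

Defaults (error 1e-3, ambient 0.02, dropout 0.05, depth 50/amplicon) are the
study conditions used throughout the tests and the acceptance script.

### Cell identity

The vendor's raw single-cell format is proprietary; the simulator conveys
the cell identifier in the read name (`@cell:<id>:<serial>`), and extraction
consumes the same convention. This keeps the pipeline runnable end to end
without vendor software while exercising the same per-cell counting logic.

### Determinism

All randomness flows from one integer seed through counter-based Philox
substreams keyed by stage label (hash-stable, not salted), and gzip output
is written with a zeroed header mtime, so fixed-seed runs are byte-identical.

## Extraction

Reads are decoded by flank anchoring rather than general alignment: the
amplicons are short fixed templates, so the 10-mer between the two constant
flanks is the entire variable content. Flank matching tolerates
`max_flank_mismatch` = 2 substitutions per flank and positional shifts up to
`shift_window` = 3 (nearest shift first); both orientations are searched.
Candidates are corrected against the whitelist with Hamming budget 1 —
collision-free given the distance-3 design; ties at the minimal distance are
`ambiguous` and excluded from counts (tallied in QC), and candidates farther
than 1 from every entry are `nomatch` rather than novel barcodes, since only
designed constructs are meaningful. Non-ACGT symbols count as mismatches
wherever they fall. A per-sequence memo cache makes the common case (an
error-free template copy) a dictionary lookup; the cached path is tested
against the explicit per-read call stream.

5′/3′ concordance is reported per construct as the fraction of detected
(cell, construct) observations supported by both ends; constructs below a
configurable floor (default 0.9) are flagged as suspected recombinants,
because a recombined provirus pairs the 5′ barcode of one construct with the
3′ barcode of another and thus supports each on one end only.

## Clone calling

Cells with zero GFP amplicon reads are removed (untransduced cells or failed
captures). Counts are normalised per cell: the value of construct k in cell
c is count(k, c) divided by c's total construct counts, with GFP excluded
from the denominator (it is a retention marker, not a clonal marker), and by
default summing the 5′ and 3′ ends (a concordant-only mode is available). A
construct is present at normalised value ≥ 1% — inclusive, because a
*minimum* threshold names the smallest admitted value. The alternative
reading of the normalisation (per barcode across cells) does not yield a
per-cell decision rule and is not implemented.

Clones are the equivalence classes of exact presence-set equality, ordered
by descending cell count with lexicographic tie-break; retained cells with
empty sets form a residual class, so clone frequencies plus the residual
fraction sum to 1. Dominance is frequency ≥ 5% (no published numeric
criterion exists; the cutoff is exposed as a parameter and recorded in the
output provenance). A clone whose set equals the union of two distinct
dominant clones' sets is flagged as a possible doublet.

**A practical note on the 1% rule.** Its robustness scales with the per-cell
total: with k barcodes per clone at depth d per amplicon end, the presence
cut-off is ~0.02·k·d reads while an ambient contaminant construct expects
~0.04·k·d·p reads (p its tumour-wide marginal), so for multi-barcode clones
(the high-MOI regime) ambient reads sit far below threshold, but clones with
one or two barcodes at shallow depth can gain spurious presences from single
ambient reads. The recovery guarantees quoted by the tests are for clones
carrying several barcodes, as produced by high-MOI transduction.

## Region deconvolution

Bulk region counts are thresholded with the same inclusive 1% rule (no
separate published rule exists for bulk; mirroring the single-cell rule
keeps one interpretation). Each region is assigned the dominant clone with
the highest Jaccard index; containment (fraction of the clone's set detected
in the region) is reported alongside, since containment alone cannot
penalise extra barcodes from region impurity. Assignments whose Jaccard
margin over the runner-up is below 0.1 are flagged ambiguous (ties break
deterministically by clone order but remain flagged). The
genotype–histology table then partitions the whitelist: constructs in every
dominant clone are *common*, constructs in exactly one are *clone-specific*
(annotated with the histologies of that clone's unambiguous regions), and
all others — including constructs in some but not all dominant clones — are
*absent* from the dominant architecture.

## Library QC and rebalancing

ddCT operations are exact closed forms (copies = calibrator ×2^(−ddCT);
relative expression = 2^(−ddCT)); no amplification-efficiency correction is
applied. The representation report gives per-construct pool fractions,
fold-vs-uniform, class means and the shRNA:ORF ratio, and the coefficient of
variation. The rebalance plan weights each construct by 1/max(fraction,
floor), normalised; the floor (default 1e-4) keeps zero-read dropouts
finite. This inverse-proportional rule is this package's formalisation of
the empirical producer surface-area adjustment and is labelled as such: in a
noiseless world it is an exact one-round fix, and under multinomial
sequencing noise one round brings a tenfold class imbalance into ~[0.8,
1.25].

## What the simulator does not emulate

Genomic mutation amplicons, RNA expression, histology images, PCR chimera
formation, index hopping, quality-score structure (qualities are fixed), and
cell-to-cell amplification efficiency differences. Passing tests therefore
demonstrate correctness of the decoding and set logic under the stated
noise processes, not robustness to every artefact of real amplicon
sequencing.

## Problem sizes

The packaged worked example runs 3,000 cells at depth 50 per amplicon
(~2M reads, ~10 s); the end-to-end recovery suite uses tumours of 2–6
clones at a few hundred cells, which already separates the clone structure
cleanly; MOI recovery uses 10⁴–10⁵ cells (draws only). These sizes were
chosen to demonstrate each property at comfortable statistical margins.
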