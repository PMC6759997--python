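# Methods

## Scope and data model

The pipeline starts at a protein-level spectral-count table: the database
search, its peptide-level FDR filtering, and protein inference are upstream
and out of scope. The exchange format is a TSV with one row per protein
(accession, optional gene symbol) and one column per sample; a companion
table with the same layout may carry unique-peptide counts. A protein not
identified in a sample has zero spectra — empty cells are imputed as 0,
never treated as missing. When no unique-peptide table is supplied, peptide
counts default to the spectral counts themselves; this is an upper bound, so
the two-peptide gate is then only as stringent as the counts allow, and the
assumption is surfaced in the table's docstring. Whether shared (non-unique)
peptides contribute to the spectral counts is a property of the upstream
table that the package accepts as-is.

Bait and control samples are paired by replicate index, and the design must
be balanced: the enrichment rule is a per-replicate comparison, so every
bait replicate needs its control partner.

## Enrichment filter

Per replicate pair, the ratio is bait/control spectral counts. With the
default pseudocount of 0, a protein present in the bait but absent from the
control has ratio +∞ and passes any threshold — this is deliberate: many
genuine interactors never appear in the control IP at all (control NSAF
0.00), and a finite-ratio rule would discard exactly the cleanest cases. A
pseudocount option `(b + c)/(c + c)` is available for users who prefer
finite ratios; it defaults off.

A replicate passes when the ratio clears the fold threshold (default 5)
*and* the bait run has at least `min_unique` (default 2) unique peptides.
The threshold comparator is `≥` by default with `>` available in config:
source descriptions of this filter vary between "greater than 5" and "at
least 5", so both are exposed and the more inclusive one is the default.
The two-peptide identification gate is enforced per bait replicate rather
than on the pooled identification — the stricter of the two readings, and
the one consistent with requiring replicated evidence.

Categories: strict = all replicates pass; relaxed = exactly all-but-one
passes (so the relaxed set is *additional to*, and disjoint from, the
strict set); none otherwise. Raising the threshold can only shrink the
strict set (monotonicity), which the tests verify against a brute-force
re-statement of the rule text.

## NSAF

`NSAF_i = 100 · (SpC_i/L_i) / Σ_j (SpC_j/L_j)` per sample, with `L_i` the
residue count from the FASTA. Every NSAF vector sums to 100 (tolerance
1e−9) and is invariant under scaling all counts in a sample — both are
property-tested. An all-zero sample has no defined normalization and is an
error rather than a silent zero vector. Mean NSAF over bait and over
control replicates is the reported abundance; ranking is by descending mean
bait NSAF with ties broken lexicographically by accession (the ordering
must be total and deterministic; no scientific meaning is attached to the
tie-break).

## Phosphosite windows and position inference

A window is a peptide string with exactly one lowercase residue (the
phosphosite), which must uppercase to S, T or Y. Database windows are ±7
residues around the site, truncated at protein termini; tryptic peptides
from other repositories are accepted by the parser but can only be placed
if they overlap an anchor.

Position inference: a window with a declared position pins its residues to
absolute coordinates (window start = declared position − lowercase offset
+ 1; an N-terminally truncated window is thereby pinned at position 1
automatically). A query window is slid across the anchored stretch and
accepted where all overlapping residues match exactly, case-insensitively,
over at least 8 positions. The placement must be unique — zero or multiple
candidate offsets raise an error rather than guessing. The 8-residue
minimum is chosen so that a chance exact match is vanishingly unlikely
(20⁻⁸ per offset for random sequence) while still allowing the short
overlaps the reference windows actually have. Inference is symmetric:
anchoring on the inferred query position recovers the anchor's declared
position, and the tests assert this.

Species coordinates are never mixed: the mouse windows are placed in mouse
coordinates. When counting *human* sites, a row passes the species filter
if its species label matches **or** the site was experimentally identified
in this package's source study (the `identified_in` field), whose MS was
performed on the human protein — this is how a site first annotated on the
mouse orthologue legitimately enters the human count once confirmed.

## 14-3-3 motif scan

Only the two literal consensus contexts are scanned: mode I
`R(p−3) S(p−2) x pS/pT x P(p+2)` and mode II `R(p−4) x x x pS/pT x P(p+2)`.
A site too close to a terminus for a pattern cannot match it; one site may
match both modes. No trained site predictor is re-implemented — the scan is
a literal pattern check, and its output should be read as "has the
consensus context", not as a binding prediction.

## Colocalization statistics

Background is a per-image scalar supplied by the caller or estimated as a
low percentile of the image (default 5th — a conservative floor estimate
for images whose field is mostly non-cell); subtraction clamps at zero.
Pearson's r is computed over all paired pixels of the ROI (no intensity
thresholding; thresholded variants change r and are deliberately not
offered), and is undefined — an error — for a channel that is constant
after subtraction.

Group comparison uses the two-sided Mann–Whitney test: the exact null
distribution when both groups have ≤ 12 observations, the tie-corrected
normal approximation above that. The cutover at 12 keeps the typical
imaging design (10 ROIs per condition) in the exact regime while bounding
the enumeration cost. Stars: p ≤ 0.0001 `****`, ≤ 0.001 `***`, ≤ 0.01
`**`, ≤ 0.05 `*`, else `ns`.

## Synthetic data generator

The generator emulates the experimental design the filter targets, not the
mass spectrometer:

- **Baseline abundance**: protein-specific means drawn log-normally
  (σ = 0.8) with mean `base_mean` (default 10 spectra) — IP eluates span
  roughly two orders of magnitude in protein abundance.
- **Counts**: gamma-mixed Poisson (negative binomial) with variance
  μ + d·μ², dispersion d = 0.05 by default. Overdispersion is the harder
  model for a ratio filter, and spectral counts across IP replicates are
  empirically overdispersed; d = 0 degenerates to Poisson.
- **Planted truth**: `n_true` proteins (default 20 of 400) get bait means
  multiplied by `fold` (default 20); `fold = 1` is the null model.
- **Bait row**: the bait protein itself is added with high bait-only counts
  (mean 300, zero in the control), mimicking the dominant bait band; it is
  always part of the planted truth.
- **Unique peptides**: binomial thinning of the spectral counts
  (`peptide_ratio` = 0.3), floored at 1 whenever the count is positive.
- **Lengths**: uniform 100–1500 residues.
- **Determinism**: every draw derives from the config seed.

What the generator does **not** emulate: correlated backgrounds between
bait and control within a replicate (carry-over), protein-specific peptide
detectability, shared-peptide ambiguity, batch effects between replicates.
Passing recovery tests therefore demonstrate that the filter logic is
correct and well-calibrated under a realistic abundance/noise model — not
that the chosen thresholds are optimal for any particular instrument or
cell line.

The colocalization generator draws bivariate-normal pixel pairs with a
prescribed population correlation, shifted to mean 100 (sd 10) and clipped
at zero (clipping is negligible at that offset); per-ROI sample r converges
to the population value as pixel count grows.

## Evaluation

`evaluate_recovery` scores the strict set against the planted truth:
sensitivity |strict ∩ truth|/|truth|, specificity over non-truth proteins,
and empirical FDR |strict \ truth|/max(|strict|, 1) (the guard makes an
empty strict set yield FDR 0 rather than 0/0). An empty truth set is an
error, not a silent zero. Under the default recovery conditions (fold 20,
base mean 10, 20 of 400 planted, 3 replicates, 20 seeds) the filter's mean
sensitivity and FDR are exercised by the test suite; under the null
(fold 1) the strict-set size is compared with an independent Monte-Carlo
re-statement of the rule.

## Numerical and design notes

- Ratios are exact floating divisions of integers; +∞ is propagated, never
  replaced by a large sentinel.
- The interactome TSV report is formatted with fixed precision and a fixed
  line terminator so reruns are byte-identical.
- The packaged reference tables are SHA-256 checksum-guarded; a corrupted
  fixture raises rather than silently shifting downstream numbers.
- Problem sizes in the test suite (400-protein simulations, 20 seeds,
  1000 random sequences for the motif oracle) were chosen to make the
  statistical assertions stable while keeping the whole suite fast to run
  routinely.

## Known limitations

- No probabilistic interaction scoring (SAINT/CompPASS-style); the filter
  is the deterministic ratio rule.
- No protein inference or isoform collapsing; one row = one accession.
- Colocalization works from caller-supplied ROI pixel vectors (or masks
  applied upstream); cell segmentation is out of scope.
- The headline interactome sizes of the source study cannot be reproduced
  from the packaged tables: they require reprocessing the deposited raw
  spectra through a search engine, which is outside this package's scope.
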