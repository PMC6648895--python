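# Methods

## Scope and data model

The package analyses label-free TAP-MS purification panels (a protein ×
purification intensity matrix, e.g. a MaxQuant proteinGroups export), a
split-tag purification pair, and qRT-PCR N0 tables from a co-translational
binding assay. It consumes quantification output; peptide-level search,
protein inference and amplification-curve fitting (N0 estimation) are out
of scope. Missing matrix cells are explicit zeros ("not detected"), never
NaN, because the zero-replacement step operates on exact zeros.

## Panel co-enrichment screen

**Normalization.** Each purification column is scaled to percent of its
total intensity. Relative intensities are the unit of analysis throughout;
multiplying any raw column by a positive constant changes nothing
downstream (tested exactly).

**Zero replacement.** Exact zeros become 0.0001% so the subsequent log10
transform is defined; the matrix is deliberately *not* renormalized
afterwards, so a column with k zeros sums to 100 + 0.0001·k. Detected
intensities below the floor are left untouched. The floor also acts as the
pseudo-signal of an undetected protein in reference means, which is what
makes "detected only in one purification" the strongest possible
enrichment signature.

**Heat-map ordering.** Rows are sorted by functional group in a fixed
order (40S r-protein, 60S r-protein, ribosome AF, translation factor, cell
division, histone, transcription, other), then by descending mean log10
signal, with lexicographic tie-breaks — a deterministic total order.

**Reference mean and enrichment.** For focal purification s, each
protein's reference is the arithmetic mean of its (zero-replaced) relative
intensities over all purifications except designated outliers. Two
conventions needed fixing where the procedure is usually described only
loosely:

* the focal purification is *included* in its own reference mean (a
  leave-one-out variant is available behind a flag, off by default);
* an outlier purification is re-included in the reference for its *own*
  analysis, since otherwise its representation would be drawn against a
  mean it had no part in.

The mean is taken on the percent scale, not on log values, matching the
convention of plotting intensities against a mean intensity computed
before log scaling.

Including the focal column caps the attainable ratio at the panel size n:
a protein detected *only* in the focal purification has ratio
≈ n·R/(R + (n−1)·0.0001) < n. For n = 25 the ceiling is 25 (log10 ≈ 1.4).
Candidate calling therefore pairs the default 10-fold ratio threshold with
a 0.01% focal-intensity floor; in small panels (n ≲ 10) the 10-fold
default is unreachable by construction and a threshold matched to the
panel size (or the leave-one-out mode) should be used. Recovery of a
planted partner is assessed primarily by its *rank* among non-bait
proteins, which is threshold-free.

**Candidates.** Non-bait proteins with log10 ratio ≥ 1 and focal relative
intensity ≥ 0.01% by default, sorted by descending ratio; contaminant-
flagged proteins stay in the list but labeled. Bait proteins are excluded
from candidate lists but kept in all tables.

## Split-tag purification

The bait of a split purification is over-stoichiometric, so normalization
excludes it from the per-column denominator: non-bait proteins sum to
100%, and the bait's own share is expressed on the same bait-excluded
scale (exceeding 100% whenever the bait carries more than half of the raw
signal — both numbers are reported). Zero replacement and log transform
follow the screen conventions; the enriched/depleted comparison is
antisymmetric under swapping the two pools (tested exactly). All columns
of a split design are normalized with the same bait exclusion.

## Co-translational binding (qRT-PCR)

Per (purification, amplicon): ratio = mean(TEV N0 replicates) /
mean(total N0 replicates) — ratio of means, not mean of ratios, because
technical triplicates are averaged before any division. Plates with
missing wells use the mean of available replicates with a logged warning.

Two-way background correction: the purification background is the mean
ratio of a row excluding its cognate cell (the amplicon of that
purification's client); the amplicon background is the mean of a column
excluding the cell where it is cognate. Each ratio is divided by both, and
the matrix is rescaled so the mean over all non-cognate cells is exactly 1
(the global background mean; a per-row variant was considered and not
implemented). Cognate exclusion is cell-wise: in the intended design each
amplicon is cognate to exactly one purification.

Properties, established numerically and in tests:

* the unit background mean holds exactly (1e-9) for every valid input;
* global rescaling of the whole matrix is exactly neutral;
* a purification-efficiency factor cancels exactly in that purification's
  own corrected cognate cell, and moderate row/column factors (0.1–10×)
  do not displace a planted cognate from the top of the score ranking —
  but the correction is *not* exactly invariant to row/column factors in
  other cells, because subset arithmetic means do not factorize;
* under multiplicative log-normal cell noise the recovered cognate score
  is biased low by ≈ exp(σ_ln²/2) (the backgrounds are arithmetic means of
  log-normal variables), about −10% at σ_log10 = 0.2. Median recovery of
  an 8-fold planted enrichment stays within 15% of truth at that noise
  level; with all noise off, recovery is exact.

No significance model is attached to cognate scores; an optional
permutation p-value (shuffling the partner map) is available behind a
flag. Its attainable floor per purification is ≈ 1/n, since a shuffle
reassigns the original partner with probability 1/n.

## Synthetic data

`simulate_screen` generates a panel with planted structure: a shared
ribosome-like core (log10 abundance ≈ N(3, 0.35), arbitrary units)
carrying most of the signal, each bait boosted 2× in its own purification,
sporadic contaminants (presence probability 0.7, moderate abundance), a
low-abundance background continuum, a trace class near the detection
limit, and chaperone partners with base abundance ≈ 3 units — three
orders of magnitude below the core — multiplied by the planted fold only
in their bait's purification. Cell-wise multiplicative log-normal noise
(σ_log10 = 0.3 by default) is applied; dropout to zero follows a logistic
function of log10 *pre-noise* abundance (steepness 0.08 decades), with
location solved by bisection so the expected zero rate equals the
configured dropout rate (0.2 by default).

This geometry reproduces the hallmark of a dedicated chaperone: the
partner is detected reliably in its cognate purification (its boosted
abundance sits above the dropout shoulder) and only sporadically elsewhere
(its base abundance sits below it), exactly the pattern by which such
factors stand out from a panel. Defaults were chosen once to emulate that
structure — 25 purifications × 200 proteins, fold 10 — and the pipeline
recovers the planted partner as the top-ranked non-bait protein in ≥ 95%
of seeded replicates at σ_log10 ≤ 0.3 and ≤ 20% dropout, while matched
null panels (fold 1) yield empty default-threshold candidate lists in
≥ 95% of replicates.

What the generator does **not** model: peptide-level effects (shared
peptides, razor assignment), intensity-dependent quantification variance,
batch/run-order drift, correlated contamination, or compositional coupling
beyond the closed-sum constraint. Passing recovery tests therefore shows
the *statistic* behaves as designed under the stated noise model, not that
real panels are this clean; on real data the outlier mechanism and the
contaminant annotations carry more weight.

`simulate_cotrans` draws per-cell total-extract N0 values log-normally,
builds TEV values as total × capture efficiency × row (purification)
factor × column (amplicon) factor × planted cognate enrichment × cell
noise, and emits technical replicates with a configurable CV. Row/column
factor spreads default to σ_log10 = 0.2, a modest purification-efficiency
/ amplicon-efficiency variation.

`simulate_split` uses a purpose-built pool in which ribosomal and
chromatin/cell-division partners are comparably abundant (as for a bait
with both histone-chaperone and r-protein-chaperone roles), boosts
r-proteins/AFs 5× in the client-containing pool and histones/cell-division
proteins 5× in the client-free pool, and gives the bait 20% more signal
than the entire co-purifying pool.

## Numerical conventions

* Ties everywhere break lexicographically by protein identifier; ranks are
  a permutation of 1..n.
* TSV/CSV output uses 9 significant digits; readers parse floats in
  round-trip mode, so write-then-read is bit-identical.
* All-zero columns, non-positive denominators, duplicated identifiers,
  unknown group labels and missing qPCR fractions are hard errors, not
  warnings.
* Generators are pure functions of (config, seed); identical seeds give
  identical bytes.

## Problem sizes used in the shipped checks

Recovery and null specificity: 200 seeded replicates each of the default
25 × 200 panel. Oracle agreement: all matrix shapes up to 5×5 with dense
seeded sampling from small integer grids (1e-12 relative tolerance).
Cotrans noisy recovery: 500 seeded replicates of the 5×5 design at
σ_log10 = 0.2.

## Known limitations

* The ratio ceiling of the focal-inclusive reference mean makes the
  default 10-fold candidate threshold meaningless for panels much smaller
  than ~15 purifications (see above).
* The two-way qPCR correction removes row/column structure only
  approximately (exactly only in its own cognate cell), and its scores
  carry the arithmetic-mean log-normal bias noted above.
* Reproduction of the published screen's summary percentages requires the
  study's own supplementary intensity table, which cannot be shipped with
  the package; the corresponding acceptance test reports failure until
  that table is supplied under `data/`.
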