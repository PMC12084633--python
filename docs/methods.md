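# Methods

## Problem and model

`neurosplice` analyzes alternative splicing across many deeply sequenced
cell-type populations (the motivating system is the *C. elegans* nervous
system, where sorted isogenic populations yield deep per-neuron-type
transcriptomes with biological replicates). The quantity of interest is
percent spliced in (PSI): for each splicing event, each cell type and each
replicate,

    PSI = inclusion_reads / (inclusion_reads + exclusion_reads)

computed from junction-spanning read counts. Inclusion evidence is the
mean over the event's inclusion junctions (the two flanking junctions of a
cassette exon; the two exon–intron boundaries of a retained intron), and
exclusion evidence the mean over the remaining junctions. The mean — not
the sum — is used for multi-junction sides so the two-junction inclusion
side of a cassette exon is not double-weighted against its single skipping
junction; with no established convention for that weighting, the mean is
the symmetric choice and is isolated in one place (`quantify`).

PSI is stored as a fraction in [0, 1]. An entry is missing when combined
evidence is below the junction threshold (default 5 reads per biological
replicate); missing values propagate and are never imputed. An event is
*alternative* when any cell-type mean PSI lies in the inclusive 10–90%
band, *near-constitutive* otherwise. Inclusivity of the band boundaries is
a deliberate, conservative reading of "between 10 and 90%".

## Pairwise differential splicing

Every ordered pair of cell types is compared per event (46 cell types give
46x45 = 2070 ordered comparisons; a 4-label tissue mode gives 12). The
test is a stand-in for tool-specific models that are not re-implemented
here:

* **Welch test on arcsine-square-root transformed PSIs** when at least 8
  usable replicates are available in total and each group has ≥ 2. The
  transform stabilizes binomial variance; Welch avoids assuming equal
  replicate noise across cell types.
* **Exact two-sample permutation test** (statistic: |difference of
  transformed group means|, all C(n_a+n_b, n_a) splits) when fewer than 8
  total replicates are usable. At 3v3 the smallest attainable two-sided p
  is 2/20 = 0.1 — an honest statement that three replicates per side
  cannot clear a 0.05 bar; the threshold of 8 was chosen so the default
  4v4 design uses the calibrated parametric path, whose p-values are
  continuous and survive FDR adjustment. (A permutation floor of 2/70 at
  4v4 combined with per-family BH would make q < 0.05 structurally
  unattainable.)

A comparison requires each cell to retain at least n−1 usable replicates
(n = the cell's replicate count); otherwise the result row is absent, not
an error. Benjamini–Hochberg adjustment runs within each (pair, event
type) family, matching a per-run, per-type output structure; whether
families should instead be global is genuinely open, and per-type was
chosen because each pairwise run is an independent analysis unit.
Significance = p < 0.05 ∧ q < 0.05 ∧ |ΔPSI| > 0.10.

Differential expression uses the same skeleton: median-of-ratios size
factors, log2 fold change of normalized means with pseudocount 0.5, Welch
test on log2 normalized counts, thresholds p < 0.01 and |log2FC| > 2. It
is a documented stand-in; externally computed tables with the same columns
can be loaded in its place.

## Uniqueness index

For event *e* and focal cell *c*, the uniqueness index is the sum of
oriented ΔPSI(c, o) over all other cells *o* whose comparison is flagged
significant. Orientation makes "more upstream choice in transcript
coordinates" positive: raw deltas are expressed for the genomically-first
alternative, so A3S on the + strand and A5S on the − strand reverse sign;
cassette and IR keep sign (positive = more inclusion/retention); MXE keeps
sign (its genomically-first exon is the upstream exon after the same
strand logic); composite events orient through their primary,
cassette-like sub-choice (identity). Summing *fractions* bounds the index
by ±(N−1): 45 for a 46-cell dataset, attained exactly by 100% vs 0%
inclusion everywhere significant. Significance for summation applies all
three thresholds (p, q, |ΔPSI|), not q alone.

Note the orientation sign is an involution per (type, strand) but
composing it across a strand flip negates strand-sensitive types — that is
the intended algebra, verified by property test.

The expression uniqueness index sums significant log2 fold changes the
same way (the aggregation formula for expression is this package's
choice, stated prominently since only the splicing variant has a canonical
definition). The pan-neuronal view restricts to genes expressed in ≥ 123
of 126 cell types, scores each gene by the maximum |index| over its events
and cells, and ranks descending.

## Consequence classification

A retained intron (or inter-splice-site segment) of length L inserts
sequence into the transcript. Categories are mutually exclusive with
precedence frameshift > stop > neither: frameshift iff L mod 3 ≠ 0; stop
iff the phase-adjusted reading of the insertion contains TAA/TAG/TGA.
Codons straddling the *upstream* exon boundary are scanned (phase 1/2
needs 1/2 flanking exonic bases) because a phase-shifted insertion can
create a boundary stop; downstream read-through after a frameshift is not
scanned — the classification describes what the insertion itself
introduces. Both boolean flags are retained in output so alternative
tabulations remain possible. The classifier is verified exhaustively
against a translation oracle over all sequences of length ≤ 6 in all 3
phases.

Splice-site spacing for binary A3S/A5S choices is the absolute coordinate
difference of the two alternative sites; spacing mod 3 = 0 is
frame-preserving by construction.

## Global summaries

* **Type-count matrices**: significant events per unordered pair per type
  (the significance flag is symmetric, so ordered pairs are de-duplicated
  to avoid double counting); global summaries zero out (pair, type) cells
  below 5 events, per-pair heatmaps keep a floor of 1.
* **Cross-type correlation**: OLS of one type's per-pair counts on
  another's over unordered pairs; reported as adjusted R² =
  1 − (1−R²)(n−1)/(n−2). Zero variance on either axis is a typed error.
* **Outlier cells**: robust z = (total − median)/(1.4826·MAD) per type,
  flag z > 3.5. When the MAD collapses, IQR/1.349 substitutes; the scale
  never drops below 2 counts so nearly empty families (e.g. MXE at the
  default mix) cannot flag Poisson-level noise. The rule itself is a
  package choice — "outlier" has no canonical definition here — and k,
  the floor, and the fallback are exposed as parameters.
* **Introns per gene**: distinct significant IR events per gene,
  histogrammed.
* **PCA**: complete-case PSI usage (no imputation — imputing would
  fabricate structure), per-event standardization across cells (mean 0,
  sd 1, ddof 1), centered SVD; component variance = squared singular value
  / (n−1) and sums to the number of retained events. Composite events are
  excluded from the combined view so their count cannot dominate.

## Synthetic data

The generator defines the study conditions: 46 cell types x 4 replicates,
300 events, mean junction depth 100, event-type mix IR 0.51 / A5S 0.26 /
A3S 0.11 / cassette 0.069 / MXE 0.015 / composite 0.034 (the nominal
52/27/11-dominated mix renormalized to sum to one), baseline PSI ~
Beta(2, 2) (symmetric, mass in the alternative band), Poisson depth +
binomial inclusion reads, optional Beta-Binomial overdispersion (rho =
0.02 — a guess, exposed as config, since real between-replicate
variability has no stated magnitude).

Planted signals: 5 cell-unique events whose PSI moves by 0.6 toward the
farther bound in one cell (clamped to [0,1], so the realized effect is at
least 0.5 under Beta(2,2)); 3 unique genes at 2^3-fold expression in one
cell; one outlier cell in which *every* A3S event shifts by 0.3 in the
cell's PSI — 83% toward the upstream choice, the remainder downstream
(shifting the remainder downstream is what makes the planted 83% the
recoverable fraction among nonzero-index events; leaving them untouched
would push the recovered value to 1). The shift magnitude 0.3 clears the
0.10 ΔPSI threshold at depth 100 by a wide margin while keeping outlier
indices (≈ 13–16) well below planted-event indices (≈ 22–27), so the two
planted structures do not compete in rankings. Planted cells are drawn
from non-outlier cells so the outlier's other type counts stay at null
level. Composite events are simulated as a cassette choice whose skipping
reads split between two alternative acceptors. Everything is a pure
function of the seed; identical seeds produce byte-identical files.

What the generator does **not** emulate: alignment artifacts, 3' coverage
bias, rRNA-depletion effects, correlated event structure within genes,
realistic between-cell PSI correlation, or annotation errors. Passing
recovery benchmarks therefore shows the statistical machinery is sound
under the stated noise model, not that real data of this depth will yield
the same power.

## Problem sizes used in validation

The recovery and calibration suites run at the design scale: false
discovery control on 100 null seeds of 46 cells x 500 events; planted
recovery, outlier flagging and bias recovery on 20 seeds of the default
46-cell design; upstream-bias convergence on 20 seeds of an 8-cell,
250-event configuration weighted to ~200 A3S events. The brute-force
uniqueness oracle covers 200 random instances with ≤ 6 cells.

## Known limitations

* The differential tests are stand-ins; effect-size estimates are exact
  but p-values inherit small-sample Welch approximation error at 4
  replicates.
* With 3 replicates per side nothing can reach p < 0.05 (exact
  permutation floor 0.1); such pairs contribute zero to uniqueness
  indices rather than noise.
* The uniqueness index of a cell with absent (untested) comparisons has a
  silently smaller attainable bound; `n_significant` is reported alongside
  so consumers can see the support.
* A3S/A5S events with more than two alternative coordinates are rejected
  rather than decomposed.
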