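# Methods

This note documents the models and procedures implemented in `edufacsseq`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic generators do and do not emulate.

## Flow gating and EdU⁺ quantification

**Model.** An acquisition is a table of per-event intensities in four
channels: FITC (SybrGreen nucleic-acid stain — distinguishes cells from
debris), APC (the clicked EdU fluorophore — distinguishes replicating from
non-replicating cells), and forward/side scatter. A quadrant gate is a pair
of thresholds; events with FITC ≥ threshold are stained cells, and among
those, APC ≥ threshold defines Q2 (EdU⁺) versus Q3 (EdU⁻).

**Gate placement.** Thresholds are fitted exclusively on no-EdU control
acquisitions. The FITC threshold is the minimum of a Gaussian KDE of log10
FITC between the two dominant modes (debris and stained cells); when the
density is unimodal the fallback is a low quantile (default 0.01) of the
distribution. The APC threshold is the 0.999 quantile of APC among
FITC-positive control events, so by construction ~0.1% of unlabeled stained
cells land in Q2 of the control. Both quantiles are exposed as parameters.
Boundary events (intensity exactly at a threshold) fall in the higher
quadrant — a fixed, documented convention.

**Noise subtraction.** The background ("noise") is the mean Q2 count across
the no-EdU controls, rescaled by the ratio of stained (Q2+Q3) totals between
sample and control before subtraction, since spurious Q2 events scale with
acquisition depth. The EdU⁺ proportion is `max(0, Q2 − noise) / (Q2 + Q3)`;
negative noise-subtracted counts clamp to zero so that unlabeled samples
report 0 rather than a small negative number. Replicate +EdU acquisitions
are quantified individually and summarized as mean ± SD.

**Zero reporting for negative samples.** With the APC threshold at an
empirical control quantile, the expected bulk leakage into Q2 is the same
~0.1% of stained cells in control and sample alike, so for an unlabeled
sample the sign of `Q2 − noise` is near-symmetric at large acquisition
depths and the clamped proportion is a tiny positive value about half the
time (bounded by ~2/(Q2+Q3)). Exact zeros dominate at modest acquisition
depths, where the Poisson background spikes present only in the controls
make the noise estimate exceed the sample's leakage almost surely; the
negative-control property test therefore uses 2,000-event acquisitions,
typical of a quick isolate check, and asserts exact zeros in ≥95 of 100
runs. At any depth the residual is ≤ ~0.2%.

**Absolute counts.** Cell concentrations follow the counting-bead ratio
`(cell events / bead events) × beads added / acquired volume × dilution`,
with the bead gate supplied as a predicate on the event frame.

## Growth metrics

* **Max V** — the maximum over sliding windows (default 5 points) of the
  least-squares slope of OD against time, in OD/h. Computed on raw OD,
  matching plate-reader "Max V" semantics; a log-OD mode returning the
  specific growth rate (1/h) is available but not the default. The value is
  not clamped: a declining culture reports a negative slope.
* **Lag time** — the time at which the tangent through the max-slope window
  (at its midpoint) crosses the initial OD, clamped to [0, duration]. For a
  noiseless logistic curve `y = y0 + (K−y0)/(1+e^{−r(t−t0)})` the exact
  value of this construction is `t0 − ((K+y0)/2 − y(0)) / (r(K−y0)/4)` with
  `y(0)` the first observation; once the curve starts at its baseline
  (`y(0) ≈ y0`) this reduces to the familiar `t0 − 2/r`, and the tests use
  both forms as oracles in their respective regimes. When the maximum slope
  is ≤ 0 the lag is undefined and reported as the full duration with an
  explicit flag.
* **Total growth** — `max(OD) − OD[0]`, invariant to any constant offset.
* **AUC** — trapezoidal integral of blank-corrected OD with negative values
  floored at zero; exact for piecewise-linear input.
* **Correlation** — Pearson r (with r² and the two-sided t-based p, n−2 df)
  between Max V and EdU⁺ proportion across isolates.

No smoothing is applied by default; series from plate readers at 15-minute
cadence are clean enough for windowed regression, and a median filter can be
applied upstream if needed.

## Contamination filtering and rarefaction

A feature is flagged as sorter contamination iff it is present (count ≥
`min_count`, default 1 read) in the sheath-fluid sample, present in at least
one sorted sample (sorted initial, whole incubated, EdU⁺ or EdU⁻), and
absent from every unsorted initial sample. The rule is evaluated per
experiment, since each experiment has its own sheath and initial samples;
a feature flagged in any experiment is removed everywhere. The `min_count`
threshold is exposed because "present/absent" at 1–2 reads is a judgment
call on real data. The filter report records reads removed and the retained
fraction per sample (mean ± SD), and read counts are conserved:
retained + removed = original, per sample.

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric) to exactly the requested depth; samples below the depth are
dropped and listed, not padded, because subsampling without replacement is
undefined beyond the sample total. All subsampling is seeded.

## Diversity and group testing

* **Shannon index** in bits (log2), the convention of common amplicon
  pipelines; the base is a parameter.
* **Simpson evenness** = inverse-Simpson diversity / observed richness,
  1 at perfect evenness. This specific definition is documented because
  "Simpson" labels are ambiguous across tools.
* **Weighted UniFrac**, unnormalized: Σ over branches of b·|A−B| where A and
  B are the fractions of each sample's reads descending from the branch.
  Every feature with a nonzero count must be a tip of the supplied newick
  tree (missing features are reported by id). A normalized variant is a
  flag.
* **PCoA** by classical scaling of −½ D² double-centered; negative
  eigenvalues are reported, not silently truncated.
* **Pairwise PERMANOVA**: pseudo-F from total versus within-group sums of
  squared distances, permutation p-values with the +1 convention (p ≥
  1/(permutations+1); default 999 permutations), BH q-values across the
  pairwise family. Pairs with a singleton group are skipped with a warning.
  The implementation is vectorized over permutations and cross-checked in
  the tests against an independent library implementation of the statistic.
* **Kruskal–Wallis** with tie correction, Dunn's z post-hoc and BH
  adjustment across the pairwise family.

## Fraction enrichment (ANCOM-style W)

Counts are pseudocounted (+1) and log-transformed. For each feature i, every
pairwise log-ratio log(x_i/x_j) is tested across groups with Kruskal–Wallis;
W_i is the number of features j for which the test rejects at BH-adjusted α
(default 0.05). A feature is detected when W_i ≥ 0.7·(n_features − 1) —
the conventional W-quantile cutoff — or via the structural-zero shortcut: a
feature entirely absent from one group while present in ≥50% of the samples
of another is detected outright.

A blocking covariate (e.g. the experiment or the antibiotic treatment,
standing in for a random effect) is handled by rank alignment: log-ratios
are ranked within each block before the grouped test, removing block-level
location shifts. This is a deliberate simplification of full ANCOM-II
(no mixed-effects model, no iterative structural-zero taxonomy): the
question answered is *which features are directionally enriched in a sorted
fraction*, not effect-size estimation. The enrichment report joins detections
with mean ± SD relative abundance per fraction; sheath samples are excluded
from the comparison.

Calibration, verified by the test suite: type-I error of the pairwise
PERMANOVA within [0.02, 0.09] at nominal α = 0.05 over 200 null
simulations; no ANCOM detections in ≥90 of 100 null runs; ≥90% detection of
a 10-fold spiked feature in a 20-feature, 8-samples-per-group design.

## Pathway completeness

A pathway rule is an ordered list of OR-groups of KO ids; a genome completes
the rule when every group intersects its KO set, and the report carries the
satisfied-group fraction plus the missing groups with their alternatives.
Rules are packaged data (a small structured text file), not code, so users
can add modules. The three built-ins are the pyrimidine pathways relevant to
EdU labeling: salvage (thymidine kinase K00857, thymidylate kinase K00943,
nucleoside-diphosphate kinase K00940), de novo synthesis (KEGG module
M00051; eight groups, the dihydroorotate dehydrogenase group satisfied by
any of K00226/K00254/K17828) and deoxyribonucleoside biosynthesis (KEGG
module M00053; six KOs). K00940 and K00943 appear in both the salvage and
deoxyribonucleoside rules and are evaluated independently per rule.

## Synthetic data: what it emulates, and what it does not

* **Flow events** are per-population log-normal in each channel (log-decade
  axes are standard in cytometry): debris at low FITC, unlabeled cells at
  high FITC/low APC, labeled cells ≥2 log-decades higher in APC. The +EdU
  table draws a binomial share of stained cells from the labeled
  population; the no-EdU control carries Poisson background spikes
  (default rate 5 per acquisition) in the labeled region. Default events
  per acquisition: 50,000, with 10% debris. A mock-community variant gives
  each member its own FITC location and labeling status, and a perturbation
  helper re-jitters intensities in log10 space (default SD 0.1 decades) to
  emulate re-acquisition of sorted cells. Not emulated: spectral spillover,
  doublets, instrument drift, saturation.
* **Fraction tables** draw multinomial counts at fixed depth (default
  20,000 reads/sample, matching typical post-QC amplicon depths) from
  compositions linked by the experiment's logic: the unsorted initial
  community is a geometric rank-abundance profile; incubation drops each
  taxon rarer than 0.5% with probability 0.5 (reproducing the
  observed-richness loss of incubated fractions); the EdU⁺ composition is
  the incubated composition re-weighted by per-taxon replication weights
  (defaults: baseline 1, with one abundant and one rare taxon at weight 8 —
  the pattern of a dominant replicator plus a rare-but-active taxon); the
  EdU⁻ fraction matches the whole incubated community. Contaminant taxa
  appear only in the sheath sample (dominant there, with 10% community
  carryover) and as a 2% admixture in sorted samples — their sheath
  abundances are free parameters, since no quantitative description of
  sheath contamination exists to emulate. Not emulated: chimeras,
  taxonomy-assignment error, copy-number variation, overdispersion beyond
  multinomial sampling.
* **Growth curves** are logistic/Gompertz/linear/constant with i.i.d.
  Gaussian noise at 15-minute sampling.
* **Genome KO sets** complete exactly the requested modules (one random KO
  per OR-group) plus decoy KOs drawn outside every rule's KO universe.

All generators are bit-reproducible under a fixed seed; passing tests on
synthetic data demonstrate correctness of the analysis logic under the
stated generating models, not performance on real sequencing data.

## Numerical and design choices

* Every stochastic routine takes an explicit seed; nothing seeds from the
  wall clock.
* Permutation p-values never report zero (+1 convention).
* KDE valley-finding subsamples very large acquisitions (>20,000 events)
  for the FITC threshold; the valley is a bulk feature and is unaffected.
* Degenerate inputs fail loudly: empty control lists, samples with no
  stained events, empty samples in diversity, all-identical values in rank
  tests (p = 1), fewer than 3 features in ANCOM, unknown module names.
* Problem sizes in the test suite are desk-scale by design: 50,000-event
  acquisitions (100 simulations for parameter recovery), 200 PERMANOVA and
  100 ANCOM null simulations, 1,000-draw rarefaction Monte Carlo. The full
  suite runs in about half a minute.

## Known limitations

* Gate placement assumes a bimodal (debris/cell) FITC distribution or a
  clean unimodal stained population; heavily overlapping populations would
  need manual thresholds (both thresholds can be supplied directly).
* The lag-time definition is tangent-based; it differs from model-fit lag
  parameters (Gompertz/Baranyi), which are out of scope.
* The ANCOM variant here is intentionally reduced; on real data its
  detections may differ from full ANCOM-II with mixed effects.
* Weighted UniFrac requires a rooted tree; the synthetic tree generator
  always produces one.
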