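# Methods

`tapseries` scores candidate protein interactors from a tandem-affinity
purification (TAP) mass-spectrometry time course: a tagged bait protein
is pulled down at several Zeitgeber times (ZT, hours after lights-on)
in replicate, untagged control pulldowns capture the nonspecific
background, and label-free quantitation supplies peptide-level
intensities.  This note records the statistical model behind each
stage, the defaults and why, and what the synthetic benchmark does and
does not establish.

## Study design assumed by the defaults

The reference layout is six bait time points (ZT 7, 11, 15, 19, 23,
27 h) in biological quintuplicate plus a duplicated wrap-around point at
ZT 31 (one full cycle after ZT 7), against five singleton control
pulldowns spread over the series (omitting ZT 15 and 31): 32 bait runs,
5 control runs.  Controls are pooled across time points everywhere;
with one control per time point a per-time-point contrast has no
replication.

## Peptide-to-protein inference

Peptide rows are filtered on precursor charge (2-4 retained) and ion
score (default cutoff 20, the conventional export threshold of the
search engine behind this dialect).  Protein groups are formed by
parsimony: an accession whose peptide set is a subset of (or equal to)
another's merges into that accession's group, so shared peptides never
inflate the protein list.  Group abundance is the per-sample sum of
member-peptide abundances; a missing peptide value counts as zero
unless every member is missing, in which case the protein value stays
missing (label-free exports leave below-detection signals blank, not
zero).  Each peptide contributes to exactly one group (that of its
alphabetically first accession), making total signal conservation an
exact invariant.  `n_unique_peptides` counts peptide sequences mapping
only within the group.  Whether the original quantitation software
summed or averaged member peptides is not documented for this dialect;
summation is the common convention and is what the package does.

Analysis runs on raw abundances by default.  `normalized` mode rescales
every sample to the mean column total; on the synthetic benchmark tier
calls agree between the two modes in >= 95% of proteins, so the choice
is not load-bearing for candidate lists.

## Outlier QC

Two signals per bait sample: (i) its mean Pearson correlation with
same-time-point replicates, computed over proteins quantified in both
runs (raw scale by default, log scale optional); (ii) its position in
the first two principal components of the complete-protein abundance
matrix (proteins with any missing value are dropped from the PCA input
— the simplest treatment that introduces no imputation model).  A
sample is discarded only when both signals agree: mean r below 0.95
*and* PC1/PC2 distance from the sample centroid above 3 pooled standard
deviations.  The conjunction makes the decision deterministic and
conservative; on permutation fixtures it flags exactly the corrupted
sample, and raising the correlation threshold can only add flags
(monotonicity).  Time points with a single replicate yield an undefined
correlation and are never flagged.

## Background filtering

Two row-wise predicates, order-independent by construction:

* **Tag-binder exclusion** — protein groups intersecting a list of
  accessions known to co-purify with the affinity tag alone are
  removed.  Exclusion acts at group level (any member suffices), so a
  known contaminant cannot hide inside a shared-peptide group.
* **Compartment filter** — groups whose pooled location annotations are
  non-empty and lie entirely within {plastid, mitochondrion} are
  removed: the bait is cytosolic/nuclear, so purely organellar proteins
  are extraction artefacts.  Unannotated proteins are retained
  (only positive organellar evidence removes a protein).

A filter ledger records survivors per stage (total, >= 2 unique
peptides, rhythm-significant) and a removal audit attributes every
dropped group to its stage.

The qualitative presence/absence screen selects accessions detected by
at least one peptide in every bait sample and by none in any control
sample; it treats different extraction buffers as ordinary samples of
the design.

## Enrichment statistic

Per protein: the bait time point with the highest replicate-mean
abundance is located (the wrap-around ZT 31 point is excluded from the
argmax since it duplicates ZT 7; ties break to the earliest ZT; missing
values count as zero in means).  *Fold enrichment* is that maximum mean
divided by the mean over all control samples.  Significance is a
two-sided Welch (unequal-variance) t-test of the bait replicates at the
maximum time point against all control samples, using quantified values
only; fewer than two quantified values on either side makes the protein
*untestable*, excluded from multiplicity correction.  Welch rather than
pooled variance because the bait group's variance scales with its
(often much larger) mean.  Benjamini-Hochberg correction runs across
testable proteins; the step-up is implemented directly because the
multiplicity `m` must be settable above the number of computed
p-values.  Tiers: `high` (q < 0.05, fold >= 4), `weak` (q < 0.05,
2 <= fold < 4), `none`, `untestable`.

Note that the argmax over six time points biases background fold
enrichment slightly above 1 (median ~1.12 under default noise); the
t-test at the selected time point inherits a mild selection effect that
the benchmark shows does not break FDR control at these settings.

## Temporal change and rhythmicity

**ANOVA.** One-way fixed-effects ANOVA across bait time-point groups
(ZT 31 its own group) on arcsinh-transformed abundances,
`arcsinh(x) = ln(x + sqrt(x^2 + 1))` — variance-stabilizing and defined
at zero, applied without cofactor scaling.  Groups need >= 2 quantified
values; a protein needs >= 2 usable groups.

**JTK scan.** Rank-based rhythm detection in the Jonckheere-Terpstra-
Kendall family.  For each (period, lag) on a grid — integer periods
22-26 h, lags in [0, period) at 2-h steps (half the sampling interval)
— a cosine reference is evaluated at the bait sample times; replicates
share a reference value and are tied by construction.  The score is
`S = sum_{i<j} sign(x_i - x_j) sign(r_i - r_j)` over quantified pairs
(pairs tied in data or reference contribute zero), and
`tau = S / max attainable |S|` given both tie patterns.  The one-sided
p-value `P(S >= S_obs)` comes from the exact null distribution of S
under uniformly random orderings of distinct values, computed by
generating-function dynamic programming over the reference tie groups
(a product of Gaussian-binomial blocks, one per group merged into the
running pool; all polynomial arithmetic in exact integers).  The DP is
verified against brute-force enumeration for series lengths <= 8 over
random tie patterns.

Two numerical conventions matter:

* **Grid correction.** The minimum p over ~61 dependent references is
  strongly anti-conservative; feeding it to BH destroys FDR control
  (observed false-discovery proportion ~0.6 on planted mixtures).  The
  reported p is therefore the minimum Bonferroni-scaled by the grid
  size, matching the adjusted p-value convention of the rhythm tools
  this scan follows; BH across proteins then yields q.  With the
  correction, planted mixtures show full power on rhythmic interactors
  and zero observed false discoveries.  The uncorrected minimum remains
  available (`grid_correction=False`).
* **Tied optima.** Clean rhythms often tie several references at the
  minimal p (e.g. a 22-h reference with a late lag and a 26-h reference
  with an early lag can induce the same ordering).  The reported period
  is the mean of tied periods and the lag their circular mean on the
  24-h circle; S and tau come from the first tied reference.  On a
  noiseless 24-h cosine peaking at ZT 7 this recovers period 24 h and
  lag 7 h exactly, where a first-in-grid tie-break would report 22 h.

**Peak time** is the ZT of the maximal bait replicate mean with ZT 31
pooled into ZT 7; ties break early.  Missing-as-zero keeps the
convention aligned with the enrichment stage.

## Summaries

The phase histogram counts peak times of enriched (high/weak tier)
proteins with ANOVA q < 0.05 or JTK q < 0.05.  Profile correlations are
Pearson r between two proteins' bait time-point mean profiles (seven
points including ZT 31).  Term over-representation is a one-sided
hypergeometric test per annotation term with >= 3 background members,
BH-corrected — a deliberately plain replacement for graph-weighted
ontology methods, which are out of scope.  Heatmap rows are z-scored
time-point profiles clustered with 1 - Pearson distance and average
linkage; input rows are pre-sorted by accession so leaf order is
deterministic.

## Synthetic benchmark

The generator plants three prey classes: rhythmic interactors
(bait-over-control enrichment `phi`, raised-cosine interaction profile
with 24-h period, relative amplitude `A`, peak phase), constant
interactors (`phi`, flat), and background (`phi = 1`).  Observed
peptide intensity = expected profile x lognormal peptide response
factor (log-sd `peptide_cv`, normalized to sum to 1 per protein) x
lognormal noise (log-sd `sigma`); values below `dropout_threshold`
become missing (threshold censoring, not missing-at-random, reflecting
below-detection dropout).  The analyzer never assumes the cosine form —
rhythm detection is rank-based — so generator and pipeline stay
independent.

Defaults (chosen once): 5 rhythmic (`phi` 8, `A` 0.6), 20 constant
(`phi` 6), 200 background proteins; `sigma` 0.3; baselines lognormal
with median 1e4 intensity units and log-sd 1.0 (a typical label-free
dynamic range); `peptide_cv` 0.5; peptides per protein 1 + Poisson(2)
capped at 8 (a mix of single- and multi-peptide proteins, as real
candidate tables show); `dropout_threshold` 300, censoring the low
intensity tail.  Under these conditions the pipeline achieves ~94%
detection power on planted interactors, ~100% power and ~0 observed
false discoveries for rhythm calls, ~96% phase recovery within one
sampling interval, and a background fold-enrichment median of ~1.12.

What the benchmark does *not* establish: robustness to correlated
noise across samples (batch effects), peptide-level interference or
shared-peptide ambiguity at scale, non-sinusoidal interaction
waveforms, and informative missingness beyond simple threshold
censoring.  Passing tests on this generator therefore demonstrate
correctness of the statistical machinery under the stated model, not
performance guarantees on arbitrary real data.

## Problem sizes in the test suite

The suite and the acceptance script scale simulations to desk size as
the package's own verification budget: power and FDR properties use
10-20 seeds of the default 225-protein mixture, the global-null check
uses two 2500-protein background-only datasets, and exact-null
verification enumerates all orderings up to length 8.

## Known limitations

* The enrichment test ignores the time-point selection effect on its
  null distribution (as the max-vs-control design implies); the
  synthetic global null shows the realized false-discovery fraction
  stays at nominal level, but heavier-tailed noise could change that.
* Controls are modeled as exchangeable across time points.
* The JTK scan reports a single best (period, lag); uncertainty on
  phase is one lag-grid step at best.
* PCA-based QC drops proteins with any missing value, which can leave
  few proteins in very sparse datasets (the correlation signal then
  carries the decision; flagging still requires both signals).
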