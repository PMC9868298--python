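# Methods

`metapep` implements a peptide-centric quantitative-metaproteomics
analysis chain of the kind used to profile microbial communities in
solid-state food fermentations (the bundled generator emulates a starter
survey of three starter types sampled over three seasons).  This note
documents the models, the defaults and why they are what they are, and
what the synthetic benchmark does and does not demonstrate.

## Taxonomic inference

**Taxonomy.** A rooted tree with ranks
`root > domain > kingdom > phylum > class > order > family > genus >
species`.  "superkingdom" (NCBI dumps) is an alias for "domain".  Nodes
with unrecognized ranks are kept as `no-rank`: they are skipped in "at
rank r" reports but participate fully in LCA queries and rollups, so no
abundance is lost.  Children are ordered lexicographically, making every
traversal — and every file written — deterministic.

**Peptide assignment.** Database proteins are digested in silico with the
tryptic rule (cleave C-terminal to K or R, not before P; up to 2 missed
cleavages, matching common search-engine settings) and indexed after
replacing isoleucine by leucine, since the two are isobaric and
indistinguishable to standard MS/MS.  An observed peptide is matched by
exact equality against this index; the match set's taxa are reduced to
their lowest common ancestor, the most specific level the peptide's
sequence supports.  Peptides shorter than 5 residues are not indexed
(they match half of any database and carry no taxonomic information); the
threshold is configurable.  A substring-matching mode exists behind a
flag for semi-tryptic input.

**Rollup.** A taxon's abundance in a sample is the sum of the quantities
of all peptides assigned to it *or any descendant* (cumulative rollup),
expressed as percent of the root taxon's total — i.e. of all annotated
signal in that sample; the denominator is per-sample, so profiles are
compositional.  Cumulative abundance is used because percentages on a
cladogram then reach 100 % at the root, which a directly-assigned-only
definition cannot guarantee.  Missing intensities contribute zero; no
imputation happens at the taxon level.  A count mode (peptide observed =
1) is provided as a robustness check; it coincides exactly with
intensity mode when all observed intensities equal one.

**Singleton pruning.** A non-root taxon supported by exactly one peptide
across the whole dataset (not per sample) is treated as spurious: the
peptide is reassigned to the parent, bottom-up, iterated to a fixed
point.  The rule is a taxonomy-cleaning step, so it runs once before
rollup; it conserves total intensity by construction.

## Differential abundance

Two cascades:

* **Taxa** (on percent-of-root values): Kruskal–Wallis across the groups,
  raw p < 0.01, followed by pairwise Mann–Whitney U, raw p < 0.01.  No
  multiplicity adjustment — adjustment is reserved for the much larger
  protein-level family; this choice is deliberate and prominent.
* **Proteins**: a fold-change gate (group-mean ratio > 2 or < 0.5)
  combined with Benjamini–Hochberg-adjusted Kruskal–Wallis (across
  features) and BH-adjusted pairwise Mann–Whitney (across features,
  within each group pair), both at adjusted p < 0.05.  The per-pair BH
  family avoids pooling heterogeneous comparisons.

Mann–Whitney p-values are exact for samples of at most 8 (closed form
without ties, full permutation enumeration with ties); larger samples use
the tie-corrected normal approximation with continuity correction.  The
two-sided p is twice the smaller tail, the standard convention for rank
tests.  Kruskal–Wallis uses the tie-corrected H with a chi-squared
reference (k−1 df); completely tied data yields (H=0, p=1) rather than an
error, as zero-variance features are routine in sparse data.  Fold
changes are ratios of group means with missing values dropped; a zero
denominator with positive numerator is reported as +inf, 0/0 as
undefined.  Group medians are available by option.

**Pattern labels.** Each feature receives a seasonal pattern label: a
group is "+" when it is significantly higher than at least one other
group and never significantly lower than any ("Au+" = autumn-elevated,
"Sp+Au+" = spring and autumn both elevated over summer, "NS" = no
significant pair).  Contradictory inputs (a>b and b>a both flagged) are
rejected.

## Co-occurrence networks

Genus relative abundances within one sample group are screened at mean
relative abundance > 0.05 % (0.0005 as a fraction); Spearman correlations
are computed on pairwise-complete observations, with p from the
t-approximation (n−2 df) and Bonferroni multiplication by the number of
genus pairs actually tested after the abundance filter.  An edge requires
rho > 0.8 and Bonferroni-adjusted p < 0.05.  "Correlation > 0.8" is read
literally as positive-only edges (co-occurrence); an absolute-value mode
is available by flag.  Communities come from the Walktrap (Pons–Latapy)
random-walk agglomeration at step length t = 4 (the algorithm's canonical
default), cut at maximum modularity; disconnected components are never
merged because joining disconnected communities cannot raise modularity.
The summary's mean degree is 2E/N reported to one decimal.  No
compositionality-corrected correlation (SparCC and relatives) is
provided; spurious closure-induced correlations are a known limitation of
this estimator.

## PLS-DA and Q²

Protein matrices are preprocessed in the MetaboAnalyst style: drop
proteins missing in more than half the samples; impute remaining missing
values with one fifth of the protein's minimum positive value; normalize
each sample by its total; log10-transform; auto-scale each protein to
mean 0, unit variance (n−1).  Non-positive intensities are treated as
missing, since they carry no signal on a log scale.  Constant features
are dropped before scaling.

PLS-DA is PLS2 regression (NIPALS) of the one-hot class-indicator matrix
on the processed intensities.  For reproducibility the first nonzero
element of each weight vector is forced positive (scores, loadings and
y-loadings flip together, leaving predictions unchanged).  Predictive
ability is cumulative Q² = 1 − PRESS/TSS from leave-one-out
cross-validation: the filter and imputation are global, but
centering/scaling statistics are re-estimated inside every training fold
and applied to the held-out sample; the baseline (0-component) predictor
is the training-fold class mean, so Q²(0) = 0 by construction.

## Functional enrichment

Differential proteins are tallied per COG category (a protein with
several category letters counts once per category; unannotated proteins
land in a dedicated bucket) and broken down by taxon at a configurable
rank (default `class`), resolving each protein's lineage text against the
taxonomy by deepest matching name.  KO over-representation is a one-sided
hypergeometric test, P[X ≥ fg_hits] with X ~ Hypergeom(bg_size, bg_hits,
fg_size), BH-adjusted across terms, run separately per dominant taxon
against that taxon's own background.  Backgrounds are explicit input
tables (term → gene list per taxon) — the package never queries KEGG, so
runs are reproducible offline; a convenience builder derives backgrounds
from the full annotation table.  Proteins with several KOs contribute
each KO once (set semantics), avoiding double counting.

## Synthetic studies and ground truth

The generator produces a complete study from one seed: taxonomy, protein
database (random sequences, length 80–400, K/R-enriched so tryptic
fragments average ~8 residues; ambiguous letters B/Z/J excluded), peptide
and protein quantification matrices, sample metadata, annotations and
ground truth.  One root seed feeds independent per-stage streams, so
enabling one stage never perturbs another's draws.

The hierarchy of effects, all in natural-log space:

| level    | model | default |
|----------|-------|---------|
| genus baseline | N(0, base_sigma) per genus | sigma = 1.0 |
| starter-type effect | N(0, type_sigma) per genus and type | sigma = 0.5 |
| sample noise | N(0, noise_sigma) | sigma = 0.25 (CV ≈ 25 %) |
| planted fold change | + ln(fold) in the target group/type | — |
| protein weight | lognormal(0, weight_sigma), fixed | sigma = 0.5 |
| protein noise | N(0, protein_noise_sigma) per sample | sigma = 0.15 |
| peptide response | lognormal(0, response_sigma), fixed per peptide | sigma = 0.5 |

The default design is 3 types x 3 seasons x 10 replicates (90 samples),
32 genera, 6 proteins per genus, 5 detectable peptides per protein.

**Missingness** is missing-not-at-random by default, as in DIA data where
low-abundance peptides drop below the detection limit:
P(missing) = 1 / (1 + exp(slope·(log10 I − midpoint))), slope 2.0,
midpoint 5.0 on log10 intensity — about 25–30 % missing cells overall at
the default intensity scale, within the range typical of DIA
metaproteomics across heterogeneous samples.  A zero slope degenerates to
a constant rate of 0.5 (the logistic at zero); MCAR and no-missingness
modes are available.

**Co-abundance blocks.** A planted community module is a guild of minor
genera whose variation is mostly shared: members receive a common
per-sample factor (sigma 1.0) plus small independent noise (sigma 0.1),
and their mean abundance is depleted by 1.5 ln units.  This is the
generative definition of "co-abundant" rather than a tuned constant, and
the three parts matter: the shared/independent variance ratio puts the
latent within-block correlation near 0.99, so recovered edges reflect
community detection rather than luck against the rho > 0.8 threshold
after closure, peptide-level noise and missingness have eroded it; the
depletion keeps the guild's shared swings small relative to the
per-sample total, because large shared swings would propagate through the
compositional denominator, correlate all *other* genera above the edge
threshold, and inflate the variance of every percent-of-root value.

**Benchmark protocol.** Recovery benchmarks plant fourfold effects in the
black starter in autumn, on the lowest-abundance genera *outside* the
blocks (and, for proteins, on proteins of non-block genera): block
members inherit the guild's shared variance and would measure the block
factor rather than test power, and planting on large genera leaks
compositional shifts into the null taxa through the shared denominator.
Rank tests are scale-free, so sensitivity is unaffected by choosing small
targets.  Taxa and protein benchmarks run on separate studies so neither
planted truth distorts the other's composition.

**What the generator does not emulate:** sequence homology between
related taxa (random sequences make nearly every peptide genus-unique, so
LCA assignment is easier than with a real database, where conserved
peptides land at higher ranks); chromatographic or spectral artifacts;
correlated missingness across peptides of one protein beyond what shared
abundance induces; batch effects.  Passing benchmarks therefore
demonstrate the correctness and calibration of the statistical machinery
under the stated generative model, not performance on real spectra.

## Numerical and degenerate-input choices

* Zero-variance features test at p = 1 rather than erroring.
* Samples with no annotated signal get an undefined (missing)
  percent-of-root, with a warning.
* Fewer than 4 complete pairs leaves a Spearman correlation undefined.
* Percentages are stored as fractions internally and rendered as percent
  only in reports.
* All tables are UTF-8 TSV, header row, '.' decimal, missing as empty
  string; every writer/reader pair round-trips bit-identically.

## Problem sizes used in the shipped benchmarks

The test suite and `scripts/acceptance.py` run the full 90-sample design
with the 32-genus/192-protein database, 3–5 seeds per benchmark, 2,000
replicates for test calibration and 1,000 features for the
false-discovery check — sizes at which every quantity of interest is
stable to well within its acceptance margin while a complete run stays in
the tens of seconds on a laptop.
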