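# Methods

## The model

`karyoevolve` treats a genome as a set of chromosomes descended from a
fixed complement of ancestral linkage groups ("elements"), one element per
ancestral chromosome.  Along a rooted species tree, each branch of length
*t* receives Poisson(rate × *t*) fusion and fission events.  A fusion joins
two uniformly chosen chromosomes end-to-end, each in a uniformly chosen
orientation; a fission splits a uniformly chosen multi-gene chromosome at a
uniform internal gene boundary.  Gene content is conserved: no gains,
losses, or movement between elements, so every gene carries one immutable
element label.  These assumptions mirror the conservation that makes
ancestral-element reconstruction possible at all; the orientation choice in
fusions is arbitrary because only gene content, not gene order, feeds the
downstream assignment.

Sex linkage enters through read depth.  For a male-hemizygous region the
male sample carries one copy against the female's two, so with per-sample
normalization the expected female/male depth ratio is 1 on autosomes, 2 on
a fully degenerate X, and ≫ 1 (female depth ≈ 0) on the Y mirror-image.  A
neo-X still partially homologous to its neo-Y receives male reads from both
gametologs; the retained fraction θ ∈ [0, 1] of ancestral male depth gives
the neo-X an expected relative male depth of (1 + θ)/2 and an F/M ratio of
2/(1 + θ).  θ = 1 is indistinguishable from an autosome, θ = 0 from the
ancestral X; intermediate values reproduce the heterogeneous, modestly
male-reduced coverage of young neo-sex chromosomes.

Expression follows a log-normal FPKM model.  Hemizygous (X-stratum) genes
in males are scaled by a dosage factor: 1 under complete compensation, 0.5
under none, (1 + λ)/2 under partial compensation with λ the compensated
fraction.  Gonad-biased genes are planted at per-stratum fractions and
multiplied by a bias fold in their target gonad only.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `window_size` | 50 kb | depth-window tiling (10 kb appropriate for finer scans) |
| `mean_depth_f` / `mean_depth_m` | 20 / 30 reads/site | sexed sample depths |
| `dispersion` | 10 | negative-binomial size; var = m + m²/r, large r → Poisson |
| `theta` | 0 | neo-Y homology fraction retained on neo-X windows |
| `y_noise_frac` | 0.01 | female noise-floor depth on Y windows (repetitive cross-mapping), as a fraction of female depth |
| `x_threshold` | 1.6 (inclusive) | scaffold median F/M at or above which a scaffold is X-linked |
| `y_threshold` | 0.3 | scaffold median F/M at or below which a scaffold is Y-linked |
| `min_m_depth` | 2 reads | male-depth floor; windows below it are candidate female-specific and excluded from ratios |
| `min_orthologs` | 20 | minimum shared orthologs for a composition cell |
| `majority_frac` | 0.5 (strict >) | majority rule for promoting a linkage group to an element |
| `min_fpkm` | 1 (inclusive ≥) | expressed-gene filter, in either compared group |
| `fold` | 2 (strict >) | gonad-bias rule vs every other tissue |
| `alpha` | 0.05 | significance level after Bonferroni correction |

The X threshold of 1.6 sits deliberately below the theoretical 2.0; the gap
absorbs mapping noise and partial neo-Y homology.  The Y threshold and male
depth floor have no canonical literature value; 0.3 with a 2-read floor
separates Y from X and autosomes cleanly at ≥ 10× depth.  Both are
configurable.

## Normalization

Each sample is divided by its own genome-wide median window depth
(`genome_median`), which a single pass can always compute.  Because the
negative-binomial depth distribution is right-skewed and X windows
contaminate the genome median, a second pass re-normalizing on first-pass
autosomal calls (`autosomal_median`, iterate once) is provided and is what
the hemizygosity arithmetic check uses; with a realistic X fraction
(~10–15% of windows) the two modes differ by only a few percent.  All
ratios, calls and breakpoints are invariant to rescaling either sample by a
constant.

## Breakpoint estimation and its precision limit

The anc-X/neo-X boundary is the window boundary minimizing the total
within-segment squared error of log₂(F/M) over all single splits
(exhaustive scan, O(n) with prefix sums; verified in tests against a naive
O(n²) re-implementation).  A split is reported only when it reduces the
no-split cost by at least `min_gain` (default 10%); the confidence interval
is the set of boundaries within 1.0 summed-squared-log₂ unit of the
minimum.  Element labels left and right of the boundary (from the elements
module) corroborate the call but do not enter the optimization.

Localization precision is bounded by the signal-to-noise ratio of the step.
At the default simulation conditions (depths 20×/30×, dispersion 10) a
window's log₂ ratio has an SD of ≈ 0.8, while the θ = 0 vs θ = 0.8 step is
≈ 0.85 — about one noise SD — and the least-squares optimum then lands
within ±2 windows of the true boundary in only ~65–85% of replicates.
This is an information limit of single-window-resolution changepoint
estimation, not an estimator defect (the scan provably equals the global
brute-force minimum); the acceptance script reports the honestly measured
rate.  On real window-median tracks, where window-to-window scatter is
usually milder than dispersion 10, localization is correspondingly tighter.

## Element assignment choices

Elements are anchored to the focal species' linkage groups, with the focal
X labelled `X` first and autosomal elements lettered in linkage-group
order; no focal-free ancestral gene order is attempted.  A linkage group is
promoted when, in at least one target species, strictly more than
`majority_frac` of its placed orthologs (and at least `min_orthologs`) fall
on one chromosome; an exact tie is conservatively left unassigned, which
reproduces the behaviour expected for a non-conserved group scattered
across many chromosomes.  Event counts are star parsimony per species
against the one-element-one-chromosome ancestor — fissions count extra
chromosomes per element, fusions count extra elements per chromosome —
matching the composition-table presentation; tree-aware reconstruction is
out of scope.  Counts are exact whenever a lineage's events do not cancel
(e.g. a fission rejoined by a later fusion); the simulator's ground-truth
parsimony counts identify such lineages so tests compare like with like.

## Statistical conventions

Wilcoxon rank-sum tests use the exact null distribution when the smaller
sample has ≤ 8 observations and the pooled sample is tie-free, otherwise
the normal approximation with tie and continuity corrections; the reported
statistic is the rank-sum W of the first sample.  Hypergeometric tails are
P(X ≥ k) and P(X ≤ k) computed in stable log-space; both are checked
against full enumeration in the tests.  Bonferroni families are the
comparisons actually run in one invocation (all group pairs of a dosage
contrast; all stratum × bias-class × tail cells of an enrichment table),
and each output records its family size.  Significance letters group
strata by connected components of the not-significantly-different graph.
Zeros are kept in rank tests (no pseudocount), and stratum male/female
ratios are ratios of medians rather than medians of per-gene ratios,
matching the boxplot framing the statistics summarize.  The enrichment
background defaults to all genes present in the calls and the partition;
per-tissue expression values are medians over replicates throughout.

## What the generator does and does not emulate

The generator reproduces the statistical structure the inference relies
on: class-specific depth means with overdispersion, conserved element
content with within-segment shuffling only, 1:1 ortholog completeness, and
stratum-specific expression scaling.  It does not emulate mappability or GC
structure along real chromosomes, repeat-driven coverage artifacts beyond a
flat Y noise floor, assembly fragmentation or misjoins, ortholog-inference
errors, or tissue-specific expression covariance beyond log-normal noise.
Passing tests therefore demonstrate correctness of the inference chain
under the stated generative model, not robustness to every artifact of
real sequencing data.

## Problem sizes and determinism

Test and acceptance runs use deliberately desk-scale problems — 100
scaffolds × 20 windows for classification, 9 elements × 200 genes × 5
species for element recovery, 2 000–3 000 genes for expression analyses,
10–20 replicate seeds per stochastic check — chosen so the full suite and
the acceptance script each complete in well under a minute while leaving
Monte-Carlo error far smaller than the tested tolerances.  Every stochastic
operation takes an explicit seed; the pipeline derives stage seeds
deterministically from one global seed, and a fixed-seed run is
byte-identical across repetitions.

## Known limitations

Single changepoint only (a chromosome with two independent fusion
boundaries needs two passes); no gene gain/loss or inter-element
translocation in the simulator (v1 scope); star parsimony can under-count
cancelling event histories; the majority rule can leave a genuinely
conserved element unassigned if every sampled species happens to have
fissioned it near its middle; expression analyses consume FPKM-like values
as given and perform no cross-library renormalization.
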