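# Methods

This note documents the models, estimators and numerical choices behind
`wgdkit`, what the synthetic generator does and does not emulate, and the
known limitations.

## Coordinate and format conventions

Internally all gene intervals are 0-based half-open; GFF3 (1-based
inclusive) is converted exactly once at the file boundary, so internal
`end - start` equals gene length in bp. Gene *rank* is the 0-based order
index along a chromosome, assigned by ascending start with ties broken by
gene id; collinearity works entirely in rank space and ignores strand,
matching the anchor-level granularity of the downstream summaries. Hit
tables are the conventional 12-column tab-separated format; self-hits are
dropped, and when both (A,B) and (B,A) rows exist the higher bit-score row
is kept (ties: lexicographically smaller pair) so each gene pair enters the
graph once, deterministically.

## Bit-score normalization

Similarity bit-scores scale with alignment length, so longer genes get
larger scores at equal identity and length-heterogeneous families are
fragmented or glued. The correction uses the proxy length L = qlen × tlen
(amino acids). Hits sorted by L are split into `n_bins` equal-count bins
(default 100, clamped with a warning when there are fewer hits; remainder
hits spread over the leading bins, which is `numpy.array_split` behaviour).
In each bin the top `ceil(top_percent/100 × bin_size)` hits by bit-score
(default 5%, minimum one hit per bin) represent the "equally similar, longer
is bigger" frontier; ordinary least squares of log10(bitscore) on log10(L)
over those hits gives slope and intercept, and every hit's normalized score
is bitscore / 10^(intercept + slope·log10 L). Equal-count bins are used
because the per-bin percentile selection is defined on counts; equal-width
bins in log L behave similarly on the simulations. The procedure is
scale-equivariant: multiplying all bit-scores by a constant leaves the
normalized scores unchanged. If all hits share one proxy length there is
nothing to regress; scores are divided by their geometric mean and a
warning is emitted.

The generator's length-biased hit simulation (bitscore = L^0.8 × lognormal
noise) is the standing calibration: the slope is recovered within ±0.05 at
n = 10 000 and the post-normalization R² of log normalized score on log L
drops below 0.01 (from ≈ 0.88 before).

## Markov clustering

Families are read from the normalized-score graph with MCL: build the
symmetric weight matrix, set each node's self-loop to its maximum incident
weight, column-normalize, then iterate expansion (matrix squaring) and
inflation (entrywise power, default 2.0, then column renormalization),
pruning entries below 1e-8, until the largest entry change falls below 1e-6
or 100 iterations. Clusters are connected components of the converged
matrix; every input gene (including isolated ones) lands in exactly one
family, and output order is deterministic (size descending, then smallest
member id). Higher inflation fragments clusters; disconnected components
are never merged. The dense-matrix implementation is adequate for the
connected subgraphs that arise here (hits only exist between homologs);
genome-scale graphs would want a sparse implementation.

## Ks estimation (NG86)

Ks is estimated by the Nei–Gojobori (1986) counting method with
Jukes–Cantor correction. Per codon, each position contributes
(# synonymous single-nucleotide changes)/3 synonymous sites, with changes
to stop codons counted as nonsynonymous; site counts are averaged over the
two sequences. Differences between codons differing at k positions are
averaged over all k! substitution orderings, excluding orderings that pass
through a stop codon (unless all do). Codons containing ambiguous bases,
gaps, or stops are skipped entirely. Then ps = sd/S and
Ks = −(3/4)·ln(1 − (4/3)·ps); the estimate is flagged saturated when the
logarithm's argument is non-positive (ps ≥ 0.75). The estimator is exactly
symmetric and matches Biopython's independent NG86 implementation to 1e-6
on random diverged pairs.

Counting methods underestimate Ks relative to maximum-likelihood codon
models when codon usage is biased or transition/transversion rates differ;
for the synonymous-only, uniform-substitution sequences of the synthetic
generator NG86 is unbiased (median absolute error ≤ 0.05 at 300 codons for
targets up to 1.0), which is exactly why the generator evolves sequences
that way. An adapter to an external ML estimator can be slotted in at
`ksdist.ks_ng86`'s call sites; nothing downstream depends on the estimator
choice.

Pairwise comparison requires positionally matched CDS. Synthetic families
are gap-free by construction; real families need an external aligner, whose
protein MSA can be back-translated with `ksdist.backtranslate` (exact
translation check, gaps become `---`).

## Family trees and event-level weights

Raw pairwise Ks distributions over-count old duplications: a family of n
genes has n−1 duplication events but up to n(n−1)/2 pairs, most of which
trace back to the same deep node. Each family therefore gets an
average-linkage (UPGMA) tree built on its Ks matrix: at every step the two
clusters at minimal average Ks are merged, the new node's height being that
average; ties are broken by the lexicographically smallest pair of cluster
representatives, making the topology deterministic. Saturated or missing
entries are replaced by a cap (default 5.0). UPGMA self-roots, so no
separate midpoint rooting step exists. Heights match scipy's average
linkage to 1e-12; the tie-break and the pair-to-MRCA bookkeeping are why
the tree is built in-package.

Deduplication then assigns, for each internal node (duplication event),
either weight 1/(number of pairs whose MRCA it is) to each of those pairs
(node-weighted) or a single entry with the mean Ks and weight 1
(node-averaged). Per-node weights sum to 1 to machine precision, so total
weight equals the number of duplication events.

## Collinearity

Within each chromosome pair, homolog matches are chained in rank space:
match j can extend a chain ending at i when the rank step on the first axis
is in [1, max_gap] and the step on the second axis is in [1, max_gap]
(ascending) or [−max_gap, −1] (inverted blocks). Chains are extracted
longest-first from a longest-path table; chains with fewer than `min_genes`
anchors (default 3) or spanning less than `min_length_bp` (default 100 kb)
on either region are discarded. For intra-genome searches each unordered
relation is considered once, and same-chromosome pairs within `max_gap`
ranks (tandem arrays) are excluded before chaining — at anchor granularity
this is equivalent to collapsing the array to one representative.
Redundant chains (anchor-set overlap ≥ 50% of the smaller set) keep the
larger chain. This O(n²)-per-chromosome-pair chainer is deliberately
simple; tables from an external collinearity engine can be imported instead
(`collinearity.read_segments_table`).

Syndepth groups segments into homeologous groups: two region instances are
"the same region" when they share ≥ 50% rank overlap on one chromosome
(configurable — how segments aggregate into multiplication levels is a
modeling choice, not a given); regions linked by segments form a group, and
the group's level is its number of distinct regions, so a triplication's
three pairwise segments collapse into one level-3 group. DupStack projects
segments onto chromosomes as bp intervals packed into non-overlap lanes,
longest first. Dot-plot tables index genes cumulatively over chromosomes
sorted by descending length.

The anchor-Ks distribution applies the same event-level weighting within
connected components of the anchor-pair graph, then keeps only entries
that are anchor pairs, renormalizing per node so each retained duplication
event still carries total weight 1.

## KDE modes, bootstrap, and rate correction

The mode of an orthologous Ks distribution is read from a Gaussian KDE
(scipy, Silverman bandwidth, weighted when the distribution is
node-weighted) evaluated on a 512-point grid over [0, max·1.05]; the mode
is the grid argmax, left-most on ties — deterministic by construction.
Uncertainty comes from 200 bootstrap replicates (resampling with
replacement, probability proportional to weight).

For a trio (focal f, sister s, outgroup o), additivity of branch
contributions gives b_f = (d(f,s)+d(f,o)−d(s,o))/2. The rescaled
divergence mode Mean(f,o) − Mean(s,o) + Mean(f,s) equals 2·b_f, i.e. the
(f,s) divergence as if both lineages ran at the focal rate. With several
outgroups the estimate averages over trios. Replicates are paired by index
across the three distributions of a trio, and all trios share the single
(f,s) bootstrap stream; that sharing is what makes the across-trio
covariance estimable, and the reported standard deviation
(1/N)·sqrt(ΣVar_i + 2ΣΣCov_ij) is then *exactly* the empirical standard
deviation of the trio-averaged replicate vector (algebraic identity,
verified to 1e-9). With one trio it reduces to sqrt(Var). Under equal
simulated rates the correction moves the mode by less than 2·std; under a
2× focal rate it recovers twice the focal branch length.

## Mixture models

Both model families are fitted by weighted EM (per-point weights multiply
responsibilities in every sum), with n_init = 5 initializations
(quantile-spread means, jittered after the first), tolerance 1e-6 on the
log-likelihood, max 500 iterations, and a log-sd floor of 1e-3 against
variance collapse. The log-likelihood is non-decreasing every iteration
(asserted in tests); non-convergence returns the best-so-far fit flagged
`converged=False`.

* `gmm_log`: Gaussian mixture on ln(Ks); components are reported as
  lognormals on the Ks scale, peak = exp(log_mean − log_sd²). The reported
  likelihood includes the Jacobian of the log transform so criteria are
  comparable with the ELMM.
* `elmm`: exponential background plus m = 0..5 lognormals on the Ks scale.
  The exponential models the survivorship-decaying background of
  small-scale duplications; its rate M-step is the weighted MLE
  Σr₀/Σr₀x. The "log-transformed data" phrasing sometimes attached to this
  model is read as lognormal components (normals in log space) over an
  exponential on the Ks scale, which is the construction that makes the
  background proper.

Zero, negative, and non-finite Ks values are excluded before fitting and
counted (`n_excluded`). Model order is chosen by BIC (AIC optional), ties
to fewer components. At n ≥ 5000–8000, component log-means and weights are
recovered within ±0.05 on seeded simulations and BIC identifies the true
number of lognormals.

"95% confidence level" anchor filtering is implemented as the central 95%
quantile interval of the fitted component, exp(log_mean ± 1.95996·log_sd),
truncated above at a Ks saturation cutoff (default 3.0) — a quantile
interval of the component, not a confidence region of its parameters.
Retained fraction converges to the level on draws from the component.

## Synthetic data: what it emulates and what it does not

`sample_ks` draws from a specified exponential + lognormal mixture with
truncation at Ks = 5 (practical range limit; out-of-range draws are
resampled). Component-of-origin labels ride along for recovery tests and
never reach fitting code. `evolve_codon_pair` applies synonymous-only
single-nucleotide substitutions (uniform over current options, stop codons
never created) to one copy until the pair's NG86 expectation reaches the
target — the protein is provably unchanged. `build_genome` lays genes at a
fixed 12 kb spacing (so ≥ 10-gene blocks clear the 100 kb segment filter)
with random CDS of 150–300 codons (length variation exercises the
normalization), appends implanted copies as contiguous runs preserving
order, and records true families and all pairwise homeologous relations.
The implant's `ks` is each new copy's divergence from the source block, so
original-vs-copy anchors sit at the stated age.

Not emulated: indels and alignment uncertainty, codon-usage bias,
among-site rate variation, gene loss/fractionation inside duplicated
blocks, transposition-shuffled gene order, and background homology between
random genes. Passing tests therefore demonstrate correctness of the
estimators and algorithms under their own model assumptions, not robustness
to the full messiness of real genomes — in particular, real collinear
blocks are fragmented by loss and the chainer's recall there depends on
`max_gap`.

## Problem sizes and defaults

Test-suite and acceptance-script simulations use n = 6000–10 000 for
distribution-level checks (slope/parameter recovery, coverage), 100 pairs ×
300 codons for estimator recovery, 200 bootstrap replicates (the default
throughout), and a 640-gene genome for the end-to-end run — sizes at which
the stochastic tolerances above hold comfortably on a single CPU.

## Known limitations

* NG86 underestimates high Ks relative to ML codon models; saturated pairs
  (ps ≥ 0.75) are flagged and capped rather than estimated.
* The diagonal chainer has no statistical significance model for clusters
  of matches; on dense homology backgrounds it relies on `min_genes`,
  `min_length_bp` and redundancy removal rather than a cloud statistic.
* UPGMA trees assume rate constancy within a family (ultrametricity); rate
  asymmetry between paralogs biases node heights.
* Orthogroup assembly uses reciprocal best hits only, which breaks down for
  lineage-specific duplicates retained in the other species.
* External engines (aligners, ML Ks, collinearity search, molecular dating)
  are interfaced by file import/export, never executed.
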