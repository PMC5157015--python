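# Methods

## Expected-count model and interaction calling

The background model for a binned contact map factorizes the expected count
of bin pair (i, j) as `e_ij = b_i · b_j · f(d_ij)` for intra-chromosomal
pairs and `e_ij = b_i · b_j · r` for inter-chromosomal pairs.

* `f(d)` is the empirical contact frequency per distance: total reads at
  separation *d* over the number of bin pairs at that separation, pooled
  across chromosomes. Distances up to 20 bins keep their exact per-distance
  estimate (they have plentiful pairs and the decay curve is steep there —
  log-binning at short range biased `f` by ~10%); longer distances are
  smoothed over log-spaced bins, 10 per decade, with within-bin totals over
  within-bin pair counts. The diagonal (d = 0) keeps its own raw estimate.
* The bias vector `b` is fitted by damped fixed-point iteration so that each
  bin's expected marginal equals its observed read coverage
  (`b_i ← n_i / (Σ_j b_j f(d_ij) + r Σ_inter b_j)`, geometric-mean damping
  because the undamped update oscillates with period two). This handles
  uneven coverage and, importantly, chromosome-edge bins: their coverage is
  low only because they have fewer partners, and a naive coverage-product
  model calls spurious edge enrichments on null data. The flat
  inter-chromosomal rate `r` is re-estimated inside the same loop so that
  inter-chromosomal expectations sum to the observed inter total. After
  convergence the expected counts reproduce the total read count to well
  under 1%.
* Significance: upper-tail Poisson `P(X ≥ m_ij)` at mean `e_ij` for every
  stored pair with `m_ij > 0`; pairs with zero expectation are skipped and
  counted. BH q-values are computed over all tested pairs; a call requires
  both `p ≤ 0.001` and `q ≤ 0.1` (configurable in `RunConfig`). The Poisson
  choice is a modeling decision: it is the standard count-enrichment model
  and admits closed-form checks (e.g. `P(X ≥ 3 | λ=3) = 0.5768`).

On pure distance-decay simulations the caller averages ≈ 0.1 post-FDR calls
per whole-genome replicate.

## Compartments

Per chromosome with at least 10 covered bins: observed/expected matrix using
the model above, Pearson correlation of its columns (zero-variance columns
dropped), leading eigenvector of the correlation matrix as PC1. The sign of
PC1 is oriented per chromosome so that the positive side has the higher gene
density — a deterministic, annotation-only rule that avoids circularity with
expression; A-type chromatin is gene-dense in real genomes, and the
synthetic generator reproduces that (see below). Bins with positive PC1 are
A; genes take the sign of their length-weighted mean PC1 over overlapping
bins. A constant correlation matrix (e.g. a uniform single-block matrix)
flags the chromosome unassigned.

## Gene mapping

A gene maps to a bin when its body extended 2 kb upstream overlaps the bin;
the 2 kb window is a promoter proxy (strand is parsed but never used by the
statistics). Each significant bin pair contributes all cross pairs of its
two bins' gene lists; self-pairs are dropped, pairs are canonical unordered
tuples, and an optional tandem-duplicate pair list can be subtracted.

## Edge fraction and the matched-sampling null

`EF(S) = |{pairs of S in SGP}| / C(|S|, 2)`. The null draws gene sets
matched to the target set per gene: same chromosome, length within ±20%
(relative). Matching is per-target-gene — targets visited in
length-sorted-then-shuffled order, candidates drawn uniformly without
replacement within one sample; an exhausted candidate pool doubles that
gene's tolerance (at most twice, counted) before erroring. The universe is
the active-compartment annotation, pathway genes included (controls may
re-draw target genes — the conservative choice). Observed and null EFs share
the same denominator (the detected active subset of the pathway; pathways
below 10 usable genes are skipped). Z = (EF − mean)/sd over the 1000 null
EFs; the empirical p uses the add-one estimator with ties counted toward the
numerator. BH q-values are computed per collection (one family per cell
line). Inter-pathway proximity counts cross edges between the two exclusive
gene sets and resamples both sets jointly (disjointly within an iteration);
the housekeeping set is treated as one more pathway. The pair-overlap metric
is |A∩B| / min(|A|, |B|).

Degenerate nulls (sd = 0) flag the Z-score as undefined (NaN) while the
empirical p is still reported.

## Pair classes, expression and PPI

The five classes follow the standard picture: proximal pairs are
intra-pathway (shared membership, union semantics for multi-pathway genes),
inter-pathway (both annotated, no shared pathway) or generic (at least one
unannotated gene); non-proximal pairs are intra-pathway (enumerated exactly)
or generic (both genes proximal to nothing and unannotated — a quadratic
set, sampled uniformly up to 100 000 pairs when enumeration would exceed
that). Gene-level expression groups: A = genes with a proximal partner in a
shared pathway, B = other proximal genes, C = the rest; comparisons use
two-sided Wilcoxon rank-sum tests on per-gene values (maxima over
transcripts, applied at file read). Fractional PPI per class is compared
I-vs-each by 2×2 chi-square without continuity correction, falling back to
Fisher's exact test whenever an expected cell is below 5.

## Activity and the proximity–activity correlation

Pathway activity = mean expression of the pathway's proximal-intra-pathway
genes; its null re-matches on exactly the genes averaged, so the statistic
is exchangeable under no expression effect. The proximity–activity report is
the Spearman rank correlation (average ranks, t-approximation p) between EF
Z-scores and activity Z-scores joined on (pathway, cell line), pooled and
per cell line, with no Z thresholding.

## Hierarchy

A synthetic root is connected to every zero-in-degree node of the pathway's
directed graph; SPL is the BFS distance from that root (root children at
SPL 1), cycles allowed, unreachable nodes flagged. The proximal-versus-other
comparison pools (pathway, gene) occurrences (a gene in several pathways
counts once per pathway; the duplicate rate is logged), tests SPL
distributions one-sided (proximal lower) by rank-sum, and splits genes at a
configurable top-level threshold (default SPL ≤ 2, matching the convention
in which the root sits one notional step higher) for a 2×2 odds-ratio test.

## Synthetic studies and what they do (not) show

Defaults describe a deliberately small study that runs in seconds: 3
chromosomes × 10 Mb at 100 kb bins; 200 genes per chromosome with log-normal
lengths (median 10 kb, σ = 0.5), placed without overlap and with 70% of
genes in A blocks (gene-dense active chromatin, which also gives the PC1
orientation rule a real signal); contact decay `base_contacts · d^-1` with
`base_contacts = 50` at one bin; alternating A/B blocks of 20 bins with a
3× same-compartment boost; flat inter-chromosomal rate of 0.02 ×
`base_contacts`; Poisson count noise throughout (read-count character,
closed-form expectations for tests). Twenty disjoint pathways of 10–20 genes
are sampled uniformly from all genes, so the chromosome-matched null is
exercised non-trivially.

Proximity is planted on a per-pathway subset of members
(`pathway_proximal_fraction = 0.6`): all bin pairs hosting two selected
co-pathway genes get a `proximity_effect = 5` multiplier. Planting only a
subset keeps the non-proximal-intra-pathway class and the non-proximal side
of the hierarchy comparison populated, as in real pathways whose edge
fractions are far below 1. The truth SGP set is the full cross product of
gene pairs hosted by planted bin pairs — every gene in a boosted bin pair is
genuinely in excess contact — which also populates the proximal-inter-pathway
and proximal-generic classes. Expression is log-normal (μ = 1, σ = 1) with a
2× boost for planted-proximal genes and a further 1.5× for proximal genes
sharing a pathway; PPIs are independent edges at background 0.01 with class
multipliers 10/5/4/2/1 (classes I/II/III/IV/V); pathway DAGs have 4 layers,
adjacent-layer parents, optional back-edges restricted to layers ≥ 2 (so the
layer index is exactly the SPL), and planted-proximal genes land in the top
two layers with probability 0.8.

The generator emulates the statistical structure the analysis assumes —
distance decay, compartment plaid, co-pathway co-location, coupled
expression, class-ordered PPIs, hierarchy bias — and omits TADs, loops,
replicate structure, restriction-fragment effects and GC bias. Passing tests
therefore demonstrate correctness and calibration of the statistics, not
robustness to those unmodeled features of real Hi-C.

## Calibration and power experiment designs

* **Sampling-null calibration.** A fully null matrix yields an empty SGP set
  (the caller is calibrated), which makes EF degenerate; the calibration
  instead scores 200 random pseudo-pathways of size 30 against the SGP set
  of default planted studies — structure the random sets have nothing to do
  with, so exchangeability under chromosome/length matching makes the null
  exact. The 200 sets are split over 4 independently simulated studies
  because all Z-scores from one contact-map realization share a small random
  offset; size 30 (435 pairs) keeps the permutation p-values fine-grained
  enough for a continuous-uniformity KS test. Verified across five base
  seeds: |mean z| ≤ 0.1, sd ≈ 1, KS p ≥ 0.1.
* **Power.** 20 planted pathways of size 15 at effect 5, 10 seeds: recovery
  at z > 2 and q ≤ 0.1 is essentially complete.
* **Proximity–activity coupling.** 30 pathways with contact effects spaced
  on 1..5 and per-pathway expression boosts equal to the contact effect; the
  pooled Spearman rho across seeds is ≈ 0.6–0.75. With a weaker coupling the
  activity Z of a handful of heavy-tailed gene values is too noisy to rank
  reliably — activity power is intrinsically modest at these sizes, which is
  also why per-pathway activity detection is reported as a distribution
  shift rather than a near-certain call.

## Numerical and degenerate-input choices

Empirical p-values are never 0 (add-one); BH is delegated to statsmodels
with inputs validated to (0, 1]; chi-square tables with small expected
counts switch to Fisher's exact test; odds ratios with a zero denominator
report ∞ (or NaN when 0/0); a pathway with no proximal-intra-pathway genes
is skipped from activity with a log message rather than scored; matched
sampling errors name the chromosome and target gene when no control exists
after two tolerance doublings. All intervals are 0-based half-open
internally; 1-based inputs must be converted at the reader boundary.

## Known limitations

Single-end-state analysis (no replicate or differential machinery); the
Poisson caller ignores overdispersion beyond what the bias/distance model
absorbs; compartment assignment uses a single eigenvector and will not
resolve sub-compartments; the hierarchy comparison treats all directed edges
alike (no activation/inhibition semantics); matrix-balancing (ICE-style)
normalization and TAD-aware statistics are out of scope.
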