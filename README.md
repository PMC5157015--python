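# pathprox

Pathway-centric spatial-proximity analysis of binned Hi-C contact maps.

Chromosome-conformation capture (Hi-C) measures how often pairs of genomic
loci touch in the nucleus. Genes that work together — members of the same
signalling or metabolic pathway — tend to occupy neighbouring nuclear space,
and that co-location tracks the pathway's activity in a given cell type.
`pathprox` packages the full chain of analyses needed to ask such questions
quantitatively, starting from nothing more than a binned contact matrix, a
gene annotation and gene-set definitions:

1. **Background normalization and interaction calling.** Observed counts
   `m_ij` between bins *i* and *j* are compared with an expected count
   `e_ij = b_i · b_j · f(d_ij)`, where `f(d)` is the empirical contact
   frequency at genomic separation *d* (exact at short range, log-smoothed at
   long range) and the per-bin biases `b` are optimized so expected marginals
   match observed coverage. A bin pair is called interacting when the
   upper-tail Poisson probability `P(X ≥ m_ij | e_ij)` passes `p ≤ 0.001`
   and Benjamini–Hochberg `q ≤ 0.1`.
2. **A/B compartments.** PC1 of the per-chromosome observed/expected
   correlation matrix, oriented so the positive (A, active) side is the
   gene-dense one; genes are labelled by their length-weighted mean PC1.
   Downstream statistics use only A-compartment genes.
3. **The SGP set.** Significant bin pairs are mapped to genes (gene body
   plus a 2 kb promoter window), giving the set of spatially proximal gene
   pairs.
4. **Edge fraction and its null.** For a pathway with *N* usable genes, the
   edge fraction `EF = (# proximal pairs) / (N(N−1)/2)`. Its significance
   comes from 1000 random gene sets matched per-gene on chromosome and on
   length (±20%), yielding a Z-score, an add-one empirical p-value and a BH
   q-value. The same machinery scores inter-pathway proximity (cross edges
   after removing shared genes), housekeeping-versus-pathway proximity, and
   pathway activity (mean expression of proximal-intra-pathway genes).
5. **Pair classes, expression, PPI, hierarchy.** Gene pairs partition into
   five classes (proximal-intra-pathway, non-proximal-intra-pathway,
   proximal-inter-pathway, proximal-generic, non-proximal-generic) for
   expression and protein–protein-interaction comparisons; directed pathway
   graphs get per-gene hierarchy levels (shortest path length from a
   synthetic root above all zero-in-degree nodes) to test whether proximal
   genes sit higher in the regulatory hierarchy.

A synthetic-data module generates complete studies with planted ground truth
(distance-decay Poisson contact maps, compartment plaid, co-pathway contact
excess, coupled expression boosts, class-enriched PPIs, layered pathway
DAGs), so every stage can be validated against known answers.

## Worked example

```sh
python examples/02_pathway_proximity_zscores.py
```

```
pathway  n_genes  EF_obs  null_mean    z      q
    P01       15   0.152    0.0198    8.4 0.000999
    P02       15   0.219    0.0187   12.6 0.000999
    P03       15   0.190    0.0231    9.1 0.000999
    ...
significant pathways (z > 2, q <= 0.1): 20 / 20

inter-pathway P01 x P02: 0 cross edges, z = -1.79
```

Each planted pathway's observed edge fraction (e.g. 0.152: 16 of its 105
gene pairs are spatially proximal) sits roughly ten standard deviations
above its matched-sampling null (~0.02), so all 20 planted pathways are
recovered at the reporting thresholds, while two *different* pathways show
no cross-proximity beyond chance (z = −1.79). The other scripts in
`examples/` demonstrate interaction calling and compartments, the five-way
pair classification with expression/PPI orderings, activity and hierarchy
analyses, and the on-disk text formats.

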