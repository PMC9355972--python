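# Methods

## Model

A sample's somatic SNVs are reduced to the pyrimidine-strand 96-channel
representation: substitution class (C>A, C>G, C>T, T>A, T>C, T>G) plus
the 5' and 3' flanking bases, with purine-reference mutations
reverse-complemented before encoding. Channel indices follow the COSMIC
canonical order (class-major, then 5' flank, then 3' flank, each
A/C/G/T); any consistent order is statistically equivalent, this one is
fixed so indices are stable across files. The per-mutation indicator
matrix is never materialized — every computation uses per-segment
96-channel count vectors, its sufficient statistic.

Within a segment, mutations are i.i.d. `Mult(1; q)` draws. The MLE of
`q` is the count vector divided by its total, and the fit of a
partition is scored by a penalized deviance

    BIC(S) = sum_t [-2 sum_i c_ti ln q̂_ti] + lambda1 * T * ln N,

with the convention `0 * ln 0 = 0` (empty channels are harmless) and
natural logarithms throughout (the standard BIC convention; the penalty
form leaves the base as a pure scale choice absorbed by lambda).
Clustering uses the identical objective with `lambda2 * K * ln N` over
pooled cluster counts.

Independence along the genome and within segments is an idealization:
real catalogs contain doublet substitutions and localized events
(kataegis) that violate it. The segmentation is robust to small
violations because only count vectors enter the likelihood.

## Parameters

| parameter | default | role |
|---|---|---|
| lambda1 | 5 | per-segment penalty weight; larger = fewer segments |
| lambda2 | 5 | per-cluster penalty weight; larger = fewer clusters |
| min_bin_count | 30 mutations | initial bin size; also the resolution limit of boundary placement |
| min_mutations | 3000 / sample | cohort floor below which a sample is rejected |
| EM tol / max iter | 1e-8 / 10,000 | exposure refit stopping rule (max abs weight change) |
| permutations B | 10,000 | entropy null size; p has resolution 1/B |
| kataegis min_run / max_dist | 6 / 1000 bp | run length and strict inter-mutation distance |
| hypermutation cap | 30,000 | samples with >= this many SNVs are excluded from kataegis |
| min_per_signature | 10 | CCF sample-size floor per signature entering KS pairs |
| fdr alpha | 0.05 | BH threshold for discordant pairs |

The penalty weights, bin size, permutation count, kataegis rule,
hypermutation cap, sample floor and FDR level are the method's stated
operating point; they are defaults, not fitted quantities.

### The penalty and profile concentration

A 96-channel profile has 95 nominal degrees of freedom, so pooling two
segments with the *same* underlying profile raises the deviance by
roughly the profile's effective support (the number of channels with
expected count ≳ 1), up to 95 for diffuse profiles. The penalty
`lambda * ln N` is ≈ 35–70 for realistic N. The merge machinery
therefore presumes profiles whose effective support is well below the
penalty — a property real signature mixtures have (a handful of
dominant channels per active signature) and a diffuse profile does not.
With near-uniform profiles the method under-merges by design: that is a
property of the published operating point, not of this implementation,
and it is why the synthetic generator (below) draws concentrated
signatures.

## Greedy merging

* **Initial bins**: per (sample, chromosome), consecutive runs of
  exactly `min_bin_count` mutations; the trailing remainder joins the
  last bin; blocks smaller than one bin become a single flagged bin.
  Binning by mutation count (not genomic width) matches the model,
  which sees only the mutation sequence; a fixed-genomic-width variant
  is available (`bin_mode="width"`).
* **Local merge**: the adjacent pair with the smallest score is merged
  while that score is <= 0 (a zero-score merge is accepted: fewer
  segments at equal fit). Ties break to the leftmost pair. Only the
  two scores adjacent to a merged pair are recomputed; tests assert
  this equals full recomputation to 1e-9.
* **Distant merge**: genome-wide within a sample (clusters may span
  chromosomes; a per-chromosome mode exists). All unordered cluster
  pairs are scored; ties break to the lexicographically smallest id
  pair; final ids are renumbered by the genomic position of each
  cluster's first segment. `N` in the penalty is the sample's total
  mutation count.
* **Local optima**: greedy merging can stall one small segment short of
  the global optimum (a boundary-straddling or noise-selected remnant
  whose pooled deviance is pushed just past the penalty by the
  selection effect). On the reference synthetic genome this leaves
  K = 3 instead of K = 2 in a few percent of seeds. Exhaustive-
  enumeration tests confirm the greedy path's scores equal brute-force
  BIC differences; the stall is a property of greedy search, not a
  scoring bug.

## Exposures and posterior assignment

Exposures d solve the multinomial mixture likelihood with the signature
rows as fixed components, by EM from uniform initialization (monotone
log-likelihood, asserted per iteration in tests). NNLS on the
normalized count vector is a second, independent route used for
cross-checking; the two agree to total variation < 0.02 on
well-conditioned refits. Channels carrying counts that every signature
gives zero probability cannot be explained; their counts are excluded
from the fit and reported. No exposure-discard rule is applied by
default; `min_exposure=0.06` reproduces the common refitting-tool
behavior (discarded weights are renormalized).

The posterior of signature v for a mutation of channel i in region r is
`h_vi d_rv / sum_w h_wi d_rw`. Argmax ties break to the lowest
signature index. If the denominator underflows (below 1e-300) the
mutation is flagged unassigned rather than given a fabricated label.
Regions are clusters by default; `granularity="segment"` and
`"sample"` refit exposures per segment or per sample for comparison —
cluster-based assignment is the most accurate whenever regional
exposures differ from the genome average, because pooling same-profile
segments sharpens d without mixing regimes.

## Concordance, kataegis, CCF discordance

* **Levels**: a per-mutation signal is cut at its genome-wide empirical
  tertiles (ties at a cut fall to the lower level); the cut points are
  configurable. Mutations in track gaps are dropped from the test and
  counted.
* **Entropy test**: a cluster's statistic is the Shannon entropy of its
  three-level composition (0 = concordant, ln 3 = uniform). The null
  draws B same-size subsets of the genome's mutations without
  replacement; since only the level composition enters the entropy,
  compositions are drawn directly from the multivariate hypergeometric
  distribution — exact and O(B). The p-value is exactly
  `#(E_null <= E_obs) / B` with no pseudocount, matching the defining
  formula; a `(h+1)/(B+1)` variant exists for users needing p > 0.
  With ~100-mutation clusters the entropy support is rich enough that
  null p-values are uniform to a KS test; for very small clusters the
  discreteness of the entropy makes the test conservative.
* **Kataegis**: maximal runs of >= 6 mutations with every successive
  same-chromosome distance strictly below 1000 bp; chromosome changes
  break runs; samples at or above 30,000 mutations are excluded.
  Enrichment per signature present in an event is a one-sided
  (greater) Fisher exact test of event-vs-rest composition; one-sided
  because the question is enrichment. Events may carry several
  enriched signatures.
* **CCF pairs**: within a sample, signatures with >= 10 CCF-bearing
  assigned mutations are compared pairwise by the two-sided two-sample
  KS test; q-values are BH over the pooled list across samples (the
  discovery list is reported as one cohort-level table). In a
  discordant pair the signature with the higher median CCF is labelled
  the earlier one — a convention for orientation, not a causal claim.

## Synthetic data

The generator emulates exactly the structure the method assumes: a
genome is a list of regions, each with a mutation count, an exposure
vector, a latent signal band (three levels at 0.2/0.5/0.8 ± 0.05) and a
clonality mode (CCF ~ Beta(50, 2) clonal, Beta(5, 15) subclonal);
positions advance by geometric gaps (mean 1000 bp by default). Regions
sharing an exposure vector form the true clusters.

The bundled toy signatures mirror two properties of real catalogs:
concentration (geometric decay over a 4-channel own block — compare the
four NpCpG C>T channels carrying most of the clock-like signature) and
non-exclusivity (a 4-channel shared block carrying 45% of signature 1
and 20% of every other signature, making assignment genuinely
probabilistic: the analytic Bayes-optimal accuracy of the reference
two-mixture genome is 92.75%, not 100%).

What the generator does **not** emulate: real genomic position
structure (replication-timing gradients, hotspots), copy number and
purity effects on CCF, sequencing artifacts, doublet substitutions, or
COSMIC's actual signature shapes. Passing tests therefore demonstrate
correctness and calibration of the machinery under the model's own
assumptions, not performance on real tumors.

Problem sizes used by the tests and the acceptance script — chosen as
the smallest sizes at which the asymptotic behavior is visible: the
reference recovery genome has N = 20,000 (4 × 5,000, two chromosomes);
boundary recovery uses 100 replicates of a 2,000-mutation two-regime
chromosome (±30-index tolerance = one initial bin); the granularity
comparison uses 20 replicates of a 12-region × 300-mutation genome
(short segments are the regime where cluster pooling matters);
calibration uses 200 null clusters of ~100 mutations at B = 1,000 and
500 same-distribution CCF pairs.

## Known limitations

* Greedy search has no optimality guarantee (see local optima above);
  a dynamic-programming segmentation would be exact per chromosome but
  is deliberately out of scope — the greedy procedure is the method.
* The posterior conditions on the fitted cluster and its point-estimate
  exposures; uncertainty in d is not propagated.
* Exact zeros in signature rows can make observed channels
  unexplainable under a fitted cluster (flagged, not imputed).
* The entropy permutation test treats mutations as exchangeable across
  the genome; spatial autocorrelation of real signals makes the null
  anti-conservative for very large clusters.
* Indels, doublet substitutions and extended (1536-channel) contexts
  are out of scope.
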