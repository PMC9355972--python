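# sigsegment

Assigning individual somatic mutations to mutational signatures with
regional resolution.

Mutational signature analysis usually estimates, per cancer genome, how
much each mutational process (COSMIC SBS signatures) contributed to the
genome's mutation catalog. That sample-level view ignores that
mutational processes act non-uniformly along the genome, and it cannot
say which process produced a *particular* mutation — signatures share
trinucleotide channels (C>T at NpCpG is the hallmark of the clock-like
SBS1 yet is also produced by SBS6/7/10/14/15/20), so a mutation's
channel alone does not identify its cause. `sigsegment` implements a
multinomial framework that resolves both problems:

1. **Segmentation.** Each chromosome's coordinate-sorted mutations are
   modelled as draws from `Mult(1; q)` over the 96 trinucleotide
   channels, with `q` constant inside a segment. Starting from bins of
   30 mutations, neighboring segments are merged greedily under a
   penalized likelihood,

   `BIC(S) = -2 log L(S) + λ₁ · T · ln N`   (λ₁ = 5),

   merging whenever the score change `Sim(Sₜ, Sₜ₊₁) = BIC(merged) −
   BIC(current) ≤ 0`, until no merge lowers the BIC.

2. **Clustering.** Distant segments of the same genome that share a
   channel profile (the same process acting in non-adjacent regions)
   are pooled by the same greedy rule over all segment pairs, with
   penalty `λ₂ · K · ln N` (λ₂ = 5), yielding *mutation clusters*.

3. **Assignment.** Per cluster r, signature exposures `d_rv` are refit
   by maximum likelihood (EM over the multinomial mixture; NNLS is
   available as a cross-check), and each mutation of channel i is
   assigned to the signature maximizing the posterior

   `P(v | i, r) = h_vi · d_rv / Σ_w h_wi · d_rw`,

   where `h_vi` are the signature probabilities (COSMIC layout).

Downstream statistics operate on the per-mutation labels: Shannon-
entropy permutation tests for cluster concordance in an external signal
(replication timing, cancer cell fraction), kataegis detection (≥ 6
consecutive mutations, each pair < 1000 bp apart) with one-sided Fisher
enrichment per signature, and two-sample Kolmogorov–Smirnov tests for
evolutionary discordance of per-signature CCF distributions with
Benjamini–Hochberg FDR control.

The package is written for cancer-genomics analysts working with
somatic SNV call sets (VCF/MAF/TSV) who want mutation-level signature
labels rather than genome-level exposures, and for methodologists who
need a fully synthetic, ground-truth test bed for regional signature
assignment.

## Worked example

```python
import numpy as np
from sigsegment import SignatureAssigner
from sigsegment.simulate import default_study_genome

catalog, truth, regions, H = default_study_genome(seed=7)
assigner = SignatureAssigner(signatures=H).fit(catalog)

print(f"N = {catalog.n} mutations, T = {assigner.segmenter_.n_segments_} segments, "
      f"K = {assigner.clusterer_.n_clusters_} clusters")
for k, d in enumerate(assigner.exposures_):
    print(f"cluster {k}: exposures " + ", ".join(
        f"{s}={w:.3f}" for s, w in zip(H.signature_ids, d)))
acc = assigner.score(catalog, truth["true_signature"].to_numpy())
print(f"per-mutation assignment accuracy = {acc:.4f}")
```

prints

```
N = 20000 mutations, T = 4 segments, K = 2 clusters
cluster 0: exposures TOY1=0.701, TOY2=0.200, TOY3=0.099
cluster 1: exposures TOY1=0.098, TOY2=0.203, TOY3=0.699
per-mutation assignment accuracy = 0.9275
```

The reference genome has four regions on two chromosomes alternating
between true exposure vectors (0.7, 0.2, 0.1) and (0.1, 0.2, 0.7); the
segmenter finds all four regions, the clusterer pools the non-adjacent
same-profile regions into K = 2 clusters, the refit exposures match the
generating mixtures to ±0.003, and per-mutation accuracy (0.9275)
reaches the analytic Bayes-optimal rate for these mixtures (0.9275 —
mutations on channels shared between signatures cannot be assigned with
certainty by any method, which is the point of the posterior).

The same stages are available as scikit-learn-style estimators
(`BICSegmenter`, `BICClusterer`, `ExposureEstimator`,
`SignatureAssigner`) and from the command line:

```bash
sigsegment simulate --out-dir sim --seed 7
sigsegment run --input sim/catalog.tsv --signatures sim/signatures.tsv \
    --out-dir results --min-mutations 1 --signal signal
```

which writes `segments.bed`, `clusters.tsv`, `assignments.tsv` (per-
mutation posterior vectors and argmax labels), `concordance.tsv`,
`kataegis.tsv`, `ks_pairs.tsv` and a reproducibility manifest.

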