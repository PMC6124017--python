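# chromage

Integrative chromatin-aging analysis for developing B cells.

Aging alters the output of B lymphopoiesis, and in bone-marrow B cell
precursors (pro-B and pre-B cells) those changes are written at several
chromatin layers at once: accessibility and histone-mark enrichment over
regulatory elements, the chromatin-state composition of promoters, megabase
A/B compartmentalization, and the set of distal regions each promoter
physically contacts. `chromage` reimplements, as a tested and reusable
library, the analysis pipeline that integrates these layers between a young
and an aged condition:

- **Consensus peaks and differential enrichment** — base-pair-voting
  consensus over replicate peak calls ("peak in ≥3 of 4 samples", 100-bp
  merge), read-count and blacklist filtering (&lt;64 reads, &lt;32 for CTCF),
  and an in-house negative-binomial Wald test with median-of-ratios size
  factors and Benjamini–Hochberg correction.
- **Chromatin-state segmentation** — the genome tiled into 200-bp bins,
  binarized per mark (ATAC, H3K4me3, H3K27ac, H3K27me3, CTCF), and segmented
  with a multivariate Bernoulli hidden Markov model trained once on both
  conditions jointly (one emission matrix `p(mark m | state k)`, one
  transition matrix), then decoded separately per condition by posterior
  argmax and collapsed to six interpretable classes (polycomb, bivalent,
  active promoter, active regulatory, insulator, background).
- **Promoter occupancy change** — per-state base-pair coverage over 5-kb
  TSS-centred windows, dominant-state assignment with the
  background-only-if-nothing-else rule, selection of the promoters with the
  largest coverage changes, and complete-linkage clustering on the
  correlation-profile distance.
- **A/B compartments** — iterative correction (ICE) of 250-kb binned Hi-C
  maps, compartment score as the first principal component of the
  observed/expected correlation matrix with H3K4me3-based sign orientation,
  and per-bin switch calls (ANOVA p &lt; 0.05 plus a standardized mean change
  &gt; 3).
- **Promoter-capture interaction rewiring** — promoter:promoter vs
  promoter:PIR classification, gained/lost calls (significant at one age
  only, score difference ≥ 2 on a CHiCAGO-like score with significance at
  ≥ 5), feature enrichment at promoter-interacting regions against a
  distance-matched permutation null, six-way fragment chromatin-state
  priority rules, gene-category statistics (Fisher and ANOVA), and
  virtual 4C over five-fragment windows.

Every stage is exercised on a synthetic multi-omics generator
(`chromage.simdata`) that plants known truths — differentially expressed
genes, promoter state flips, compartment-switch bins, gained/lost
interactions — so the whole pipeline is testable without any external data.

## Worked example

```python
import numpy as np
from chromage.simdata import SimConfig, simulate_dataset
from chromage import chromstate, compartments, interactions, genome_io
from chromage.diffcounts import NBDifferentialTest

ds = simulate_dataset(SimConfig(seed=42))

deg = NBDifferentialTest().fit(ds.expression).results_
model = chromstate.fit_hmm(ds.tracks["young"], ds.tracks["aged"],
                           n_states=6, seed=0, tol=1e-7, n_restarts=3)
collapse = chromstate.default_collapse_mapping(model.emission_,
                                               ds.tracks["young"].marks)
seg_y = chromstate.segment(model, ds.tracks["young"], collapse)
seg_a = chromstate.segment(model, ds.tracks["aged"], collapse)
proms = genome_io.promoter_windows(ds.genes, 2500, ds.genome)
occ = chromstate.occupancy_change_clusters(seg_y, seg_a, proms,
                                           top_frac=0.04, k=9, expression=deg)
rew = interactions.call_rewiring(ds.interactions)
```

On this seed the run prints:

```
differential expression: 29 genes at padj<0.05 (50 planted)
emission matrix (states x ATAC/H3K4me3/H3K27ac/H3K27me3/CTCF):
[[0.8  0.1  0.8  0.05 0.1 ]
 [0.1  0.05 0.05 0.9  0.05]
 [0.3  0.8  0.1  0.8  0.05]
 [0.02 0.02 0.02 0.02 0.02]
 [0.9  0.9  0.5  0.05 0.1 ]
 [0.5  0.05 0.05 0.05 0.9 ]]
promoters selected for occupancy change: 109, clustered into 9 groups
compartment switches on chr1: 4 called, 4 of 5 planted recovered
interaction rewiring: {'stable-significant': 202, 'never-significant': 200,
                       'gained': 49, 'lost': 49}
```

The six recovered emission rows match the generator's planted states (active
regulatory, polycomb, bivalent, background, active promoter, insulator — EM
does not fix the state order); 29 of 50 planted expression changes clear
BH-adjusted significance at three replicates per condition; four of the five
planted compartment switches on chr1 are called with no false positives; and
the rewiring caller recovers the planted gained/lost interactions.

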