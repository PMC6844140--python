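# sigrank

Rank-based single-sample gene-set scoring and mutation-signature
classification for bulk and single-cell transcriptomics.

## The problem

Many driver mutations — NPM1c, *KMT2A*/*MLL* fusions and PTDs,
*PML-RARA* in AML — leave a characteristic transcriptional footprint. A
*gene signature* captures that footprint as a set of genes expected to
be up-regulated and a set expected down-regulated. Scoring each sample
against such a signature turns a whole transcriptome into one
interpretable number per sample, usable to predict mutation status, to
stratify cohorts, and to compare phenotypes across signatures.

`sigrank` scores a single sample using only the *ranks* of genes within
that sample. For an up-regulated set of `n` genes in a transcriptome of
`N` genes, with within-sample ranks `r_i` (rank `N` = highest
expression), the score is the normalised mean rank

```
u = ( mean(r_i) − (n+1)/2 ) / ( (2N−n+1)/2 − (n+1)/2 ),    score = u − 1/2
```

where `(n+1)/2` and `(2N−n+1)/2` are the theoretical minimum and
maximum mean rank for a set of size `n`. Down-regulated sets use
reflected ranks `N+1−r_i`; a paired signature's total score is the sum
of its centred up and down components, so its range is exactly
`[−1, 1]` (components `[−0.5, 0.5]`). Gene sets of unknown direction
are scored by the mean absolute deviation of ranks from the median
rank, normalised the same way to `[0, 1]`. Because everything happens
within one sample, scores need no between-sample normalisation and are
invariant to any monotone transform of expression (CPM, FPKM, log).
Each score comes with a *dispersion* — the scaled median absolute
deviation of the signature-gene ranks — measuring how coherently the
signature responds.

Around the scorer the package implements the complete workflow: CPM
filtering of low-count genes, TMM normalisation factors, logFPKM with
exon-union gene lengths from a GTF, GMT/MSigDB-XML signature IO with
`_UP`/`_DN` pairing, curated mutation-call parsing, logistic prediction
of mutation status with precision/recall/F1, unsupervised
stratification (Gaussian mixture, k-means, hierarchical) compared by
adjusted Rand index, and two-signature hexbin score landscapes with
sample projection. A synthetic-data generator plants a
signature-coherent mutant subpopulation in negative-binomial counts so
the whole pipeline is testable end to end without downloads.

## Worked example

```python
from sigrank import (GeneratorConfig, generate_dataset, rank_genes,
                     score_signature_pair)

counts, annot, signature, mutations = generate_dataset(GeneratorConfig(seed=1))
scores = score_signature_pair(rank_genes(counts.counts), signature)
print(scores.data.head().round(4))
```

```
                              TotalScore  ...  DownDispersion
TCGA-SY-0001-03A-01T-0001-13      0.2747  ...        252.7833
TCGA-SY-0002-03A-01T-0001-13     -0.0280  ...        200.8923
TCGA-SY-0003-03A-01T-0001-13     -0.0410  ...        146.0361
TCGA-SY-0004-03A-01T-0001-13     -0.0222  ...        241.6638
TCGA-SY-0005-03A-01T-0001-13     -0.0017  ...        266.1267
```

Sample 1 carries the planted lesion: its total score 0.27 says its
up-genes rank high and down-genes low, while the wild-type samples sit
near 0 (no enrichment). Feeding these scores to the logistic model
(`examples/03_predict_mutations.py`, weak effect `delta=0.3`) prints

```
           estimate  std_error  z_value  p_value
intercept   -0.3802     0.3944  -0.9641    0.335
score      140.1118    27.2704   5.1379    0.000

          score only: precision=0.949 recall=0.933 F1=0.941
  score + dispersion: precision=0.965 recall=0.917 F1=0.940
```

— a strongly positive score coefficient (higher score, higher odds of
the lesion) and high in-sample precision/recall even at a weak planted
effect. The scripts in `examples/` walk through each capability
(scoring, preprocessing, prediction, stratification and landscapes);
the `sigrank` command exposes the same stages as shell subcommands
(`sigrank all --outdir out --seed 1`).

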