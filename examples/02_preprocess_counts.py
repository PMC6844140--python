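"""Preprocess raw counts: filter low-expressed genes, TMM, logFPKM.

The scorer itself only needs within-sample ranks, so these transforms
do not change scores — but the low-count filter removes genes whose tied
ranks would dilute score resolution, and logFPKM gives interpretable
expression values for inspection.
"""

import tempfile
from pathlib import Path

from sigrank import (
    GeneratorConfig,
    exon_union_gene_lengths,
    filter_low_expression,
    generate_dataset,
    generate_gtf_fixture,
    log_fpkm,
    tmm_factors,
)

counts, annot, signature, _ = generate_dataset(GeneratorConfig(seed=1))
print(f"raw counts: {counts.counts.shape[0]} genes x {counts.counts.shape[1]} samples")

filtered = filter_low_expression(counts, cpm_threshold=1.0, prop_threshold=0.5)
print(f"after CPM > 1 in > 50% of samples: {filtered.counts.shape[0]} genes kept")

# gene lengths from a GTF via exon-interval union (here a generated toy GTF)
with tempfile.TemporaryDirectory() as d:
    gtf = Path(d) / "genes.gtf"
    generate_gtf_fixture(annot, exons_per_gene=2, path=gtf)
    lengths = exon_union_gene_lengths(gtf)
print(f"exon-union lengths recovered for {len(lengths.gene_lengths)} genes")

factors = tmm_factors(filtered)
print(f"TMM factors: min {factors.factors.min():.4f}, "
      f"max {factors.factors.max():.4f} (geometric mean 1 by construction)")

expr = log_fpkm(filtered, annot, factors)
print(f"logFPKM matrix: {expr.shape[0]} x {expr.shape[1]}, "
      f"range [{expr.min().min():.2f}, {expr.max().max():.2f}]")
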