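"""Count preprocessing: CPM filtering, TMM factors, logFPKM, gene lengths.

Turns a raw gene-by-sample read-count matrix into the filtered,
length-normalised expression matrix the scorer consumes.  Because the
scorer is rank-based and therefore invariant to monotone per-sample
transforms, these steps matter mainly for (a) removing low-count genes
that would produce heavily tied ranks and (b) producing expression
values comparable across genes for inspection; they do not change
scores beyond the gene filter itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GeneAnnotationTable",
    "NormalizationFactors",
    "compute_cpm",
    "filter_low_expression",
    "tmm_factors",
    "log_fpkm",
    "exon_union_gene_lengths",
    "strip_id_versions",
    "harmonize_ids",
    "read_counts_tsv",
    "read_counts_mtx",
]


@dataclass
class CountMatrix:
    """Non-negative integer read counts, genes x samples."""

    counts: pd.DataFrame

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample total read counts; recomputed after any subsetting."""
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)])

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class GeneAnnotationTable:
    """Gene annotation: exon-union length, biotype, optional secondary ID."""

    table: pd.DataFrame  # index gene_id; columns gene_length, gene_biotype[, secondary_id]

    def __post_init__(self):
        if self.table.index.duplicated().any():
            raise ValueError("duplicated gene IDs in annotation")
        if (self.table["gene_length"] < 1).any():
            raise ValueError("gene lengths must be >= 1")

    @property
    def gene_lengths(self) -> pd.Series:
        return self.table["gene_length"]

    def to_tsv(self, path) -> None:
        out = self.table.rename(
            columns={"gene_biotype": "gene_type"}
        )
        out.to_csv(path, sep="\t", index_label="ensembl_gene_id")

    @classmethod
    def from_tsv(cls, path) -> "GeneAnnotationTable":
        df = pd.read_csv(path, sep="\t", index_col="ensembl_gene_id")
        df = df.rename(columns={"gene_type": "gene_biotype"})
        df.index.name = "gene_id"
        return cls(df)


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors, geometric mean 1."""

    factors: pd.Series
    reference_sample: str

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        log_gm = np.log(self.factors.to_numpy()).mean()
        if abs(log_gm) > 1e-10:
            raise ValueError("factors do not have geometric mean 1")


def compute_cpm(
    counts: CountMatrix, log: bool = False, prior: float = 0.5
) -> pd.DataFrame:
    """Counts per million reads; optionally log2 with a prior count.

    The log variant follows the usual library-size-adjusted offset:
    ``log2((count + prior * L/mean(L)) / (L + 2 * prior * L/mean(L)) * 1e6)``
    where L is the library size, so that doubling a sample's depth
    leaves its logCPM essentially unchanged.
    """
    lib = counts.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.sample_ids[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    mat = counts.counts.to_numpy(dtype=float)
    if not log:
        cpm = mat * 1e6 / lib
    else:
        adj_prior = prior * lib / lib.mean()
        cpm = np.log2((mat + adj_prior) / (lib + 2 * adj_prior) * 1e6)
    return pd.DataFrame(cpm, index=counts.gene_ids, columns=counts.sample_ids)


def filter_low_expression(
    counts: CountMatrix,
    cpm_threshold: float = 1.0,
    prop_threshold: float = 0.5,
) -> CountMatrix:
    """Keep genes with CPM > ``cpm_threshold`` in more than
    ``prop_threshold`` of samples (both inequalities strict).

    Low-count genes produce duplicated ranks, which dilute the
    discriminative power of rank-based scores; filtering on CPM rather
    than raw counts accounts for library-size variation.  Library sizes
    of the result reflect the retained genes only.
    """
    cpm = compute_cpm(counts)
    prop_expressed = (cpm > cpm_threshold).mean(axis=1)
    keep = prop_expressed > prop_threshold
    if not keep.any():
        raise ValueError("filter removed every gene")
    return CountMatrix(counts.counts.loc[keep])


def _quantile75_ratio(mat: np.ndarray, lib: np.ndarray) -> np.ndarray:
    # per-sample 75th percentile of count/library-size, type-7 quantile
    return np.quantile(mat / lib, 0.75, axis=0)


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> NormalizationFactors:
    """Trimmed mean of M-values normalization factors.

    The reference sample is the one whose 75th percentile of
    count/library-size lies closest to the mean of those percentiles.
    For each sample, gene-wise log2 ratios to the reference (M) and
    average log2 abundances (A) are computed over genes expressed in
    both; the most extreme ``logratio_trim`` fraction by M and
    ``abs_trim`` fraction by A are discarded and the remaining M values
    averaged with inverse-asymptotic-variance weights.  Factors are
    rescaled so their geometric mean is exactly 1.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")

    q75 = _quantile75_ratio(mat, lib)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = mat[:, ref_idx]
    ref_lib = lib[ref_idx]

    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        obs = mat[:, j]
        both = (obs > 0) & (ref > 0)
        if not both.any():
            raise ValueError(
                f"sample {counts.sample_ids[j]!r} shares no expressed genes "
                "with the reference"
            )
        p_obs = obs[both] / lib[j]
        p_ref = ref[both] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # asymptotic (delta-method) variance of M
        w = (lib[j] - obs[both]) / (lib[j] * obs[both]) + (
            ref_lib - ref[both]
        ) / (ref_lib * ref[both])

        if np.max(np.abs(m)) < 1e-6:
            continue  # pure depth change: factor 1

        n = m.size
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_trim) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            continue
        log_factors[j] = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])

    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        factors=pd.Series(factors, index=counts.sample_ids),
        reference_sample=str(counts.sample_ids[ref_idx]),
    )


def log_fpkm(
    counts: CountMatrix,
    annot: GeneAnnotationTable,
    factors: NormalizationFactors | None = None,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 fragments per kilobase per million mapped reads.

    FPKM = count * 1e9 / (library_size * factor * gene_length); a small
    prior count (rescaled by effective library size, as for logCPM)
    keeps zero counts finite.  Gene-length normalisation makes values
    comparable between genes within a sample; it is cosmetic for the
    rank-based scorer beyond that.
    """
    missing = counts.gene_ids.difference(annot.table.index)
    if len(missing):
        raise ValueError(f"genes without annotated length: {missing.tolist()}")
    lengths = annot.gene_lengths.loc[counts.gene_ids].to_numpy(dtype=float)
    lib = counts.library_sizes.to_numpy(dtype=float)
    f = (
        factors.factors.loc[counts.sample_ids].to_numpy(dtype=float)
        if factors is not None
        else np.ones_like(lib)
    )
    if (f <= 0).any():
        raise ValueError("nonpositive normalization factor")
    eff_lib = lib * f
    mat = counts.counts.to_numpy(dtype=float)
    adj_prior = prior * eff_lib / eff_lib.mean()
    fpkm = (mat + adj_prior) * 1e9 / ((eff_lib + 2 * adj_prior) * lengths[:, None])
    return pd.DataFrame(
        np.log2(fpkm), index=counts.gene_ids, columns=counts.sample_ids
    )


def exon_union_gene_lengths(gtf_path, feature: str = "exon") -> GeneAnnotationTable:
    """Effective gene lengths from a GTF: union of exon intervals per gene.

    Overlapping or duplicated exons are merged before widths are summed,
    so each genomic base covered by any exon of the gene counts exactly
    once.  GTF coordinates are 1-based inclusive (width = end - start + 1).
    Genes with no exon records are absent from the output.
    """
    import pyranges as pr

    try:
        gr = pr.read_gtf(str(gtf_path))
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"malformed GTF {gtf_path}: {exc}") from exc
    df = gr.df
    required = {"Feature", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"GTF {gtf_path} lacks required attributes {required}")
    exons = df[df["Feature"] == feature]
    if exons.empty:
        raise ValueError(f"no {feature!r} records in {gtf_path}")
    biotype_col = "gene_type" if "gene_type" in exons.columns else (
        "gene_biotype" if "gene_biotype" in exons.columns else None
    )
    # pyranges stores 0-based half-open coordinates, so merged widths
    # (End - Start) already match the 1-based inclusive convention.
    merged = (
        pr.PyRanges(exons[["Chromosome", "Start", "End", "gene_id"]])
        .merge(by="gene_id", strand=False)
        .df
    )
    merged["width"] = merged["End"] - merged["Start"]
    lengths = merged.groupby("gene_id")["width"].sum()
    if biotype_col is not None:
        biotypes = exons.groupby("gene_id")[biotype_col].first()
    else:
        biotypes = pd.Series("unknown", index=lengths.index)
    table = pd.DataFrame(
        {"gene_length": lengths, "gene_biotype": biotypes.loc[lengths.index]}
    )
    table.index.name = "gene_id"
    return GeneAnnotationTable(table.sort_index())


_VERSION_RE = re.compile(r"\.\d+$")


def strip_id_versions(ids: Iterable[str]) -> list[str]:
    """Remove trailing ``.<digits>`` version suffixes from gene IDs."""
    return [_VERSION_RE.sub("", str(g)) for g in ids]


def harmonize_ids(
    data_ids: Iterable[str],
    mapping: Iterable[tuple[str, str]],
    annot: GeneAnnotationTable | None = None,
) -> tuple[list[str], dict[str, str], pd.Series | None]:
    """Keep only IDs with a one-to-one source/target mapping.

    Sources mapping to several targets are dropped, as are targets
    claimed by several sources, enforcing a unique bijection between the
    retained identifiers.  Returns the kept source IDs (in data order),
    their target mapping, and — when an annotation is supplied — the
    counts of discarded genes by biotype.
    """
    pairs = pd.DataFrame(list(mapping), columns=["source", "target"]).dropna()
    pairs = pairs.drop_duplicates()
    src_counts = pairs["source"].value_counts()
    tgt_counts = pairs["target"].value_counts()
    ok = pairs[
        pairs["source"].map(src_counts).eq(1)
        & pairs["target"].map(tgt_counts).eq(1)
    ]
    lut = dict(zip(ok["source"], ok["target"]))
    data_ids = list(data_ids)
    kept = [g for g in data_ids if g in lut]
    if not kept:
        raise ValueError("no gene IDs survived unique-mapping harmonization")
    discarded_by_biotype = None
    if annot is not None:
        discarded = [g for g in data_ids if g not in lut]
        present = [g for g in discarded if g in annot.table.index]
        discarded_by_biotype = (
            annot.table.loc[present, "gene_biotype"].value_counts()
            if present
            else pd.Series(dtype=int)
        )
    return kept, {g: lut[g] for g in kept}, discarded_by_biotype


def read_counts_tsv(path) -> CountMatrix:
    """Read a genes x samples count matrix from TSV (header row, gene IDs first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def read_counts_mtx(mtx_path, gene_ids_path, sample_ids_path) -> CountMatrix:
    """Read counts from MatrixMarket plus sidecar gene/sample ID lists."""
    from scipy.io import mmread
    from scipy.sparse import issparse

    raw = mmread(str(mtx_path))
    mat = np.asarray(raw.todense()) if issparse(raw) else np.asarray(raw)
    genes = pd.read_csv(gene_ids_path, header=None)[0].astype(str)
    samples = pd.read_csv(sample_ids_path, header=None)[0].astype(str)
    return CountMatrix(pd.DataFrame(mat, index=genes, columns=samples))
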