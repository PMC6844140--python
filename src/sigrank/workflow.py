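"""End-to-end workflow: simulate/preprocess/score/predict/cluster/landscape.

Each stage reads the TSV artifacts of its upstream stages from the
output directory and writes its own, logging input/output dimensions.
Partial stage selection reuses existing upstream artifacts; a missing
upstream artifact is an actionable error naming the stage to rerun.
All randomness flows from the explicit seeds in the config, so reruns
with the same config are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from . import prediction as pred
from . import landscape as ls
from .scoring import ScoreTable, rank_genes, score_signature
from .signatures import (
    MutationTable,
    join_samples_to_patients,
    pair_directional_sets,
    read_signatures,
    write_gmt,
)
from .synthetic import GeneratorConfig, generate_dataset, generate_gtf_fixture

__all__ = ["WorkflowConfig", "run_workflow", "STAGES"]

log = logging.getLogger("sigrank")

STAGES = ("simulate", "preprocess", "score", "predict", "cluster", "landscape")


@dataclass
class WorkflowConfig:
    """Declarative configuration for a workflow run."""

    outdir: str = "sigrank_out"
    counts: str | None = None  # defaults to <outdir>/counts.tsv
    gtf: str | None = None
    gene_lengths: str | None = None  # precomputed length table (TSV)
    signatures: str | None = None  # GMT; defaults to <outdir>/signatures.gmt
    mutations: str | None = None  # TSV; defaults to <outdir>/mutations.tsv
    cpm_threshold: float = 1.0
    prop_threshold: float = 0.5
    tie_method: str = "min"
    dispersion: str = "mad"
    mode: str = "auto"  # auto | paired | up | down | unknown
    mutation_column: str = "NPM1c.Mut"
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # GeneratorConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "WorkflowConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _artifact(outdir: Path, name: str, produced_by: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise FileNotFoundError(
            f"missing artifact {p}; run the {produced_by!r} stage first"
        )
    return p


def _signature_mode(cfg_mode: str) -> str:
    return {
        "auto": "unknown_direction",
        "unknown": "unknown_direction",
        "up": "single_directed_up",
        "down": "single_directed_down",
        "paired": "paired",
    }[cfg_mode]


def _load_signatures(cfg: WorkflowConfig, outdir: Path):
    gmt = Path(cfg.signatures) if cfg.signatures else _artifact(
        outdir, "signatures.gmt", "simulate"
    )
    collection = read_signatures(gmt, fmt="gmt")
    return pair_directional_sets(
        collection, unpaired_mode=_signature_mode(cfg.mode)
    )


def _stage_simulate(cfg: WorkflowConfig, outdir: Path) -> None:
    gen = GeneratorConfig(**{"seed": cfg.seed, **cfg.simulate})
    counts, annot, sig, muts = generate_dataset(gen)
    counts.to_tsv(outdir / "counts.tsv")
    annot.to_tsv(outdir / "gene_annotation.tsv")
    write_gmt(
        [(f"{sig.name}_UP", sig.up_ids), (f"{sig.name}_DN", sig.down_ids)],
        outdir / "signatures.gmt",
    )
    muts.to_tsv(outdir / "mutations.tsv")
    generate_gtf_fixture(annot, exons_per_gene=2, path=outdir / "genes.gtf")
    log.info(
        "simulate: %d genes x %d samples", counts.counts.shape[0], counts.counts.shape[1]
    )


def _stage_preprocess(cfg: WorkflowConfig, outdir: Path) -> None:
    counts_path = Path(cfg.counts) if cfg.counts else _artifact(
        outdir, "counts.tsv", "simulate"
    )
    counts = pp.read_counts_tsv(counts_path)
    log.info("preprocess: input %d genes x %d samples", *counts.counts.shape)
    filtered = pp.filter_low_expression(
        counts, cpm_threshold=cfg.cpm_threshold, prop_threshold=cfg.prop_threshold
    )
    if cfg.gene_lengths:
        annot = pp.GeneAnnotationTable.from_tsv(cfg.gene_lengths)
    elif cfg.gtf:
        annot = pp.exon_union_gene_lengths(cfg.gtf)
    else:
        annot_path = _artifact(outdir, "gene_annotation.tsv", "simulate")
        annot = pp.GeneAnnotationTable.from_tsv(annot_path)
    factors = pp.tmm_factors(filtered)
    expr = pp.log_fpkm(filtered, annot, factors)
    filtered.to_tsv(outdir / "filtered_counts.tsv")
    factors.factors.to_csv(outdir / "tmm_factors.tsv", sep="\t", header=["factor"])
    expr.to_csv(outdir / "logfpkm.tsv", sep="\t", index_label="gene_id")
    log.info("preprocess: retained %d genes x %d samples", *expr.shape)


def _score_tables(cfg: WorkflowConfig, outdir: Path) -> dict[str, ScoreTable]:
    expr = pd.read_csv(_artifact(outdir, "logfpkm.tsv", "preprocess"), sep="\t", index_col=0)
    ranks = rank_genes(expr, tie_method=cfg.tie_method, seed=cfg.seed)
    tables = {}
    for sig in _load_signatures(cfg, outdir):
        tables[sig.name] = score_signature(
            ranks, sig, dispersion_fun=cfg.dispersion
        )
    return tables


def _stage_score(cfg: WorkflowConfig, outdir: Path) -> None:
    for name, table in _score_tables(cfg, outdir).items():
        table.to_tsv(outdir / f"scores_{name}.tsv")
        log.info("score: %s -> %d samples (%s mode)", name, len(table.data), table.mode)


def _load_scores(outdir: Path) -> dict[str, pd.DataFrame]:
    paths = sorted(outdir.glob("scores_*.tsv"))
    if not paths:
        raise FileNotFoundError(
            f"no score tables in {outdir}; run the 'score' stage first"
        )
    return {
        p.stem.removeprefix("scores_"): pd.read_csv(p, sep="\t", index_col="sample_id")
        for p in paths
    }


def _load_labels(cfg: WorkflowConfig, outdir: Path, sample_ids) -> pd.Series:
    mut_path = Path(cfg.mutations) if cfg.mutations else _artifact(
        outdir, "mutations.tsv", "simulate"
    )
    muts = MutationTable.from_tsv(mut_path)
    joined = join_samples_to_patients(sample_ids, muts)
    return joined[cfg.mutation_column]


def _stage_predict(cfg: WorkflowConfig, outdir: Path) -> None:
    scores = _load_scores(outdir)
    rows, coef_rows = [], []
    for name, df in scores.items():
        y = _load_labels(cfg, outdir, df.index)
        for predictors, label in (
            (("TotalScore",), "score"),
            (("TotalScore", "TotalDispersion"), "score+dispersion"),
        ):
            fit = pred.fit_logistic(
                y,
                df[predictors[0]],
                df[predictors[1]] if len(predictors) > 1 else None,
            )
            perf = pred.classify_and_evaluate(fit, y)
            rows.append({"signature": name, "model": label, **perf})
            ct = fit.coefficient_table().reset_index(names="term")
            ct.insert(0, "model", label)
            ct.insert(0, "signature", name)
            coef_rows.append(ct)
    pd.DataFrame(rows).to_csv(outdir / "performance.tsv", sep="\t", index=False)
    pd.concat(coef_rows).to_csv(outdir / "coefficients.tsv", sep="\t", index=False)
    log.info("predict: %d models evaluated", len(rows))


def _stage_cluster(cfg: WorkflowConfig, outdir: Path) -> None:
    scores = _load_scores(outdir)
    out, ari_rows = [], []
    for name, df in scores.items():
        y = _load_labels(cfg, outdir, df.index).to_numpy()
        gmm = pred.gaussian_mixture_1d(df["TotalScore"], seed=cfg.seed)
        pts = df[["TotalScore", "TotalDispersion"]].to_numpy()
        km = pred.cluster_scores(pts, method="kmeans", seed=cfg.seed)
        hc = pred.cluster_scores(pts, method="hierarchical")
        assign = pd.DataFrame(
            {
                "gmm": gmm["assignments"],
                "gmm_uncertainty": gmm["uncertainty"],
                "kmeans": km,
                "hclust": hc,
            },
            index=df.index,
        )
        assign.insert(0, "signature", name)
        out.append(assign)
        for method, labels in (("gmm", gmm["assignments"]), ("kmeans", km), ("hclust", hc)):
            ari = pred.adjusted_rand_index(pred.PartitionPair.from_labels(labels, y))
            ari_rows.append({"signature": name, "method": method, "ari_vs_truth": ari})
    pd.concat(out).to_csv(outdir / "clusters.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(ari_rows).to_csv(outdir / "ari.tsv", sep="\t", index=False)
    log.info("cluster: %d stratifications", len(ari_rows))


def _stage_landscape(cfg: WorkflowConfig, outdir: Path) -> None:
    tables = _score_tables(cfg, outdir)
    names = list(tables)
    if len(names) < 2:
        # one paired signature: use its up/down components as the two axes
        name = names[0]
        t = tables[name]
        if "UpScore" not in t.data:
            raise ValueError("landscape needs two signatures or one paired signature")
        sx = ScoreTable(
            data=t.data[["UpScore", "TotalDispersion"]].rename(
                columns={"UpScore": "TotalScore"}
            ),
            mode=t.mode, centered=t.centered,
        )
        sy = ScoreTable(
            data=t.data[["DownScore", "TotalDispersion"]].rename(
                columns={"DownScore": "TotalScore"}
            ),
            mode=t.mode, centered=t.centered,
        )
        axis_names = (f"{name}_up", f"{name}_down")
    else:
        sx, sy = tables[names[0]], tables[names[1]]
        axis_names = (names[0], names[1])
    grid = ls.build_landscape(sx, sy, axis_names=axis_names)
    grid.to_tsv(outdir / "landscape.tsv")
    rho = ls.spearman_correlation(sx.total_score, sy.total_score)
    y = _load_labels(cfg, outdir, sx.data.index)
    gmm = pred.gaussian_mixture_1d(sx.total_score, seed=cfg.seed)
    overlay = ls.project_samples(
        grid, sx, sy,
        annotations=y.map({True: "mutant", False: "wild-type"}),
        uncertainty=pd.Series(gmm["uncertainty"], index=sx.data.index),
    )
    overlay.to_csv(outdir / "overlay.tsv", sep="\t")
    pd.DataFrame([{"spearman_rho": rho}]).to_csv(
        outdir / "landscape_stats.tsv", sep="\t", index=False
    )
    log.info("landscape: %d bins, Spearman rho %.3f", len(grid.bin_counts), rho)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "score": _stage_score,
    "predict": _stage_predict,
    "cluster": _stage_cluster,
    "landscape": _stage_landscape,
}


def run_workflow(cfg: WorkflowConfig, stages=("all",)) -> Path:
    """Run the selected stages in dependency order; returns the output dir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "all" in stages:
        stages = STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in STAGES:  # dependency order
        if stage in stages:
            _STAGE_FUNCS[stage](cfg, outdir)
    return outdir
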