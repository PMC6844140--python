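"""Rank-based single-sample gene-set scoring.

Each sample is reduced to the within-sample ranks of its genes; a
signature score is the mean rank of the signature genes normalised
against the theoretical minimum and maximum mean rank attainable by a
set of that size.  Because the statistic depends only on within-sample
ranks, scores are invariant to any monotone per-sample transformation
of expression (CPM, FPKM, log, ...) and no between-sample
normalisation is required at scoring time.

Three modes are supported:

* **paired** — separate up- and down-regulated gene sets; the total
  score is the sum of the two centred component scores, range [-1, 1]
  (components in [-0.5, 0.5]).
* **single directed** — one set, all up- (or all down-) regulated;
  centred range [-0.5, 0.5].
* **unknown direction** — one set of mixed or unknown direction,
  scored by mean absolute deviation of ranks from the median rank;
  range [0, 1], never centred.

Each score is accompanied by a dispersion of the signature-gene ranks
(default: scaled median absolute deviation), a per-sample measure of
signature coherence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankMatrix",
    "GeneSignature",
    "ScoreTable",
    "CoverageWarning",
    "rank_genes",
    "score_directed_set",
    "score_signature_pair",
    "score_undirected_set",
    "rank_dispersion",
    "check_signature_coverage",
    "combine_paired",
    "rank_density_data",
]

TieMethod = Literal["min", "max", "average", "first", "dense", "random"]

#: Consistency constant making the MAD of a normal sample estimate its
#: standard deviation; 1 / qnorm(0.75).
MAD_NORMAL_SCALE = 1.4826


class CoverageWarning(UserWarning):
    """Signature genes absent from the expression data."""


@dataclass(frozen=True)
class GeneSignature:
    """A named transcriptomic gene signature.

    Parameters
    ----------
    name:
        Signature name (e.g. the MSigDB base name without ``_UP``/``_DN``).
    up_ids:
        Genes expected up-regulated, or the full set for single /
        unknown-direction signatures.
    down_ids:
        Genes expected down-regulated; empty unless ``mode='paired'``.
    mode:
        One of ``paired``, ``single_directed_up``, ``single_directed_down``,
        ``unknown_direction``.
    """

    name: str
    up_ids: tuple[str, ...]
    down_ids: tuple[str, ...] = ()
    mode: str = "paired"

    def __post_init__(self):
        up = tuple(dict.fromkeys(self.up_ids))
        dn = tuple(dict.fromkeys(self.down_ids))
        object.__setattr__(self, "up_ids", up)
        object.__setattr__(self, "down_ids", dn)
        if self.mode not in (
            "paired",
            "single_directed_up",
            "single_directed_down",
            "unknown_direction",
        ):
            raise ValueError(f"unknown signature mode: {self.mode!r}")
        if set(up) & set(dn):
            raise ValueError(
                f"signature {self.name!r}: up and down sets overlap"
            )
        if self.mode == "paired" and (not up or not dn):
            raise ValueError(
                f"paired signature {self.name!r} requires non-empty up and down sets"
            )
        if not up and not dn:
            raise ValueError(f"signature {self.name!r} is empty")


@dataclass
class RankMatrix:
    """Per-sample integer ranks of genes (1 = lowest expression, N = highest)."""

    ranks: pd.DataFrame  # genes x samples, integer
    tie_method: str = "min"

    @property
    def gene_ids(self) -> pd.Index:
        return self.ranks.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.ranks.columns

    @property
    def n_genes(self) -> int:
        """Universe size N shared by every sample."""
        return self.ranks.shape[0]

    def to_tsv(self, path) -> None:
        self.ranks.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class ScoreTable:
    """Per-sample signature scores and rank dispersions.

    ``data`` carries one row per sample with columns ``TotalScore``,
    ``TotalDispersion`` and, for paired signatures, ``UpScore``,
    ``UpDispersion``, ``DownScore``, ``DownDispersion``.
    """

    data: pd.DataFrame
    mode: str
    centered: bool
    missing_up: int = 0
    missing_down: int = 0

    @property
    def total_score(self) -> pd.Series:
        return self.data["TotalScore"]

    @property
    def total_dispersion(self) -> pd.Series:
        return self.data["TotalDispersion"]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


def rank_genes(
    expr: pd.DataFrame,
    tie_method: TieMethod = "min",
    seed: int | None = None,
) -> RankMatrix:
    """Rank genes within each sample, ascending (highest expression -> rank N).

    Parameters
    ----------
    expr:
        Genes x samples expression matrix (any monotone scale: counts,
        CPM, logFPKM ...).  No missing values allowed.
    tie_method:
        Tie policy, one of ``min``, ``max``, ``average``, ``first``,
        ``dense``, ``random``.  ``min`` is the default and the
        recommended policy for RNA-seq.
    seed:
        Required when ``tie_method='random'``; breaks ties in a
        reproducible random order.
    """
    expr = pd.DataFrame(expr)
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes to rank")
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene IDs: {dups}")
    if expr.isna().any().any():
        bad = expr.index[expr.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in expression for genes: {bad}")

    values = expr.to_numpy(dtype=float)
    if tie_method == "random":
        if seed is None:
            raise ValueError("tie_method='random' requires a seed")
        rng = np.random.default_rng(seed)
        ranked = np.empty_like(values, dtype=np.int64)
        for j in range(values.shape[1]):
            perm = rng.permutation(values.shape[0])
            r = stats.rankdata(values[perm, j], method="ordinal")
            inv = np.empty_like(perm)
            inv[perm] = np.arange(perm.size)
            ranked[:, j] = r[inv]
    else:
        scipy_method = {"first": "ordinal"}.get(tie_method, tie_method)
        if scipy_method not in ("min", "max", "average", "dense", "ordinal"):
            raise ValueError(f"unknown tie method: {tie_method!r}")
        ranked = stats.rankdata(values, method=scipy_method, axis=0)
    ranks = pd.DataFrame(ranked, index=expr.index, columns=expr.columns)
    return RankMatrix(ranks=ranks, tie_method=tie_method)


def check_signature_coverage(
    ranks: RankMatrix, set_ids: Iterable[str], set_name: str = "gene set"
) -> tuple[list[str], list[str]]:
    """Partition ``set_ids`` into genes present in / absent from the universe.

    Emits a :class:`CoverageWarning` reporting the count and sorted IDs
    of any missing genes, mirroring the scorer's warn-and-proceed
    behaviour.
    """
    universe = set(map(str, ranks.gene_ids))
    ids = [str(g) for g in dict.fromkeys(set_ids)]
    present = [g for g in ids if g in universe]
    missing = sorted(g for g in ids if g not in universe)
    if missing:
        warnings.warn(
            f"{set_name}: {len(missing)} genes missing: {', '.join(missing)}",
            CoverageWarning,
            stacklevel=2,
        )
    return present, missing


def rank_dispersion(
    set_ranks: Sequence[float] | np.ndarray,
    fun: Literal["mad", "iqr"] = "mad",
    mad_scale: float = MAD_NORMAL_SCALE,
) -> float:
    """Dispersion of a signature's gene ranks within one sample.

    ``mad`` (default, recommended) is ``mad_scale * median(|r - median(r)|)``;
    ``iqr`` is the inter-quartile range.  Both are invariant under rank
    reversal ``r -> N + 1 - r``.
    """
    r = np.asarray(set_ranks, dtype=float)
    if r.size == 0:
        raise ValueError("cannot compute dispersion of an empty rank vector")
    if fun == "mad":
        return float(np.median(np.abs(r - np.median(r))) * mad_scale)
    if fun == "iqr":
        return float(stats.iqr(r))
    raise ValueError(f"unknown dispersion function: {fun!r}")


def _directed_bounds(n: int, n_universe: int) -> tuple[float, float]:
    # min/max mean rank of an n-subset of 1..N: the n smallest / largest ranks
    lo = (n + 1) / 2
    hi = (2 * n_universe - n + 1) / 2
    return lo, hi


def _resolve_set(
    ranks: RankMatrix, set_ids: Iterable[str], set_name: str
) -> tuple[np.ndarray, list[str]]:
    present, missing = check_signature_coverage(ranks, set_ids, set_name)
    if not present:
        raise ValueError(
            f"{set_name}: no signature genes found in the expression data"
        )
    idx = ranks.ranks.index.get_indexer(present)
    return ranks.ranks.to_numpy()[idx, :].astype(float), missing


def score_directed_set(
    ranks: RankMatrix,
    set_ids: Iterable[str],
    invert: bool = False,
    center: bool = True,
    dispersion_fun: Literal["mad", "iqr"] = "mad",
    mad_scale: float = MAD_NORMAL_SCALE,
    set_name: str = "gene set",
) -> pd.DataFrame:
    """Score one directed gene set for every sample.

    With effective ranks ``rho = r`` (``invert=False``) or
    ``rho = N + 1 - r`` (``invert=True``, for down-regulated sets), the
    mean effective rank is normalised to [0, 1] against the theoretical
    minimum ``(n+1)/2`` and maximum ``(2N-n+1)/2`` for a set of n genes;
    centring subtracts 0.5.  Dispersion is computed on the raw ranks.

    Returns a frame with columns ``Score`` and ``Dispersion`` indexed by
    sample.
    """
    sub, _missing = _resolve_set(ranks, set_ids, set_name)
    n_universe = ranks.n_genes
    n = sub.shape[0]
    eff = (n_universe + 1) - sub if invert else sub
    mean_rank = eff.mean(axis=0)
    lo, hi = _directed_bounds(n, n_universe)
    u = (mean_rank - lo) / (hi - lo)
    score = u - 0.5 if center else u
    disp = np.array(
        [rank_dispersion(sub[:, j], dispersion_fun, mad_scale) for j in range(sub.shape[1])]
    )
    return pd.DataFrame(
        {"Score": score, "Dispersion": disp}, index=ranks.sample_ids
    )


def _abs_deviation_bounds(n: int, n_universe: int) -> tuple[float, float]:
    # achievable min/max mean of n values from {|k - (N+1)/2| : k=1..N}
    med = (n_universe + 1) / 2
    devs = np.sort(np.abs(np.arange(1, n_universe + 1) - med))
    return float(devs[:n].mean()), float(devs[-n:].mean())


def score_undirected_set(
    ranks: RankMatrix,
    set_ids: Iterable[str],
    center: bool = False,
    dispersion_fun: Literal["mad", "iqr"] = "mad",
    mad_scale: float = MAD_NORMAL_SCALE,
    set_name: str = "gene set",
) -> pd.DataFrame:
    """Score a gene set whose direction of regulation is unknown.

    High scores arise when signature-gene ranks sit far from the median
    rank in either direction: the statistic is the mean absolute
    deviation of ranks from ``(N+1)/2``, normalised against the minimum
    and maximum achievable means for a set of that size.  Range [0, 1];
    these scores cannot be centred.
    """
    if center:
        raise ValueError("unknown-direction scores cannot be centered")
    sub, _missing = _resolve_set(ranks, set_ids, set_name)
    n_universe = ranks.n_genes
    n = sub.shape[0]
    dev = np.abs(sub - (n_universe + 1) / 2).mean(axis=0)
    lo, hi = _abs_deviation_bounds(n, n_universe)
    u = (dev - lo) / (hi - lo)
    disp = np.array(
        [rank_dispersion(sub[:, j], dispersion_fun, mad_scale) for j in range(sub.shape[1])]
    )
    return pd.DataFrame({"Score": u, "Dispersion": disp}, index=ranks.sample_ids)


def combine_paired(
    up_score, down_score, up_dispersion, down_dispersion, centered: bool = True
):
    """Combine up/down component scores and dispersions into totals.

    Centred totals add (range [-1, 1]); uncentred totals average to stay
    in [0, 1].  The total dispersion is always the mean of the two
    component dispersions.
    """
    up_score = np.asarray(up_score, dtype=float)
    down_score = np.asarray(down_score, dtype=float)
    total = up_score + down_score if centered else (up_score + down_score) / 2.0
    total_disp = (np.asarray(up_dispersion, dtype=float) + np.asarray(down_dispersion, dtype=float)) / 2.0
    return total, total_disp


def score_signature_pair(
    ranks: RankMatrix,
    sig: GeneSignature,
    center: bool = True,
    dispersion_fun: Literal["mad", "iqr"] = "mad",
    mad_scale: float = MAD_NORMAL_SCALE,
) -> ScoreTable:
    """Score a paired up/down signature; total = up + down (centred)."""
    if sig.mode != "paired":
        raise ValueError(f"signature {sig.name!r} is not paired (mode={sig.mode})")
    up = score_directed_set(
        ranks, sig.up_ids, invert=False, center=center,
        dispersion_fun=dispersion_fun, mad_scale=mad_scale,
        set_name=f"{sig.name} up set",
    )
    down = score_directed_set(
        ranks, sig.down_ids, invert=True, center=center,
        dispersion_fun=dispersion_fun, mad_scale=mad_scale,
        set_name=f"{sig.name} down set",
    )
    total, total_disp = combine_paired(
        up["Score"], down["Score"], up["Dispersion"], down["Dispersion"],
        centered=center,
    )
    n_up_missing = len(sig.up_ids) - int(
        pd.Index(sig.up_ids).isin(ranks.gene_ids).sum()
    )
    n_down_missing = len(sig.down_ids) - int(
        pd.Index(sig.down_ids).isin(ranks.gene_ids).sum()
    )
    data = pd.DataFrame(
        {
            "TotalScore": total,
            "TotalDispersion": total_disp,
            "UpScore": up["Score"],
            "UpDispersion": up["Dispersion"],
            "DownScore": down["Score"],
            "DownDispersion": down["Dispersion"],
        },
        index=ranks.sample_ids,
    )
    return ScoreTable(
        data=data, mode="paired", centered=center,
        missing_up=n_up_missing, missing_down=n_down_missing,
    )


def score_signature(
    ranks: RankMatrix,
    sig: GeneSignature,
    center: bool = True,
    dispersion_fun: Literal["mad", "iqr"] = "mad",
    mad_scale: float = MAD_NORMAL_SCALE,
) -> ScoreTable:
    """Score any signature, dispatching on its mode."""
    if sig.mode == "paired":
        return score_signature_pair(ranks, sig, center, dispersion_fun, mad_scale)
    if sig.mode in ("single_directed_up", "single_directed_down"):
        res = score_directed_set(
            ranks, sig.up_ids or sig.down_ids,
            invert=(sig.mode == "single_directed_down"),
            center=center, dispersion_fun=dispersion_fun, mad_scale=mad_scale,
            set_name=sig.name,
        )
        data = pd.DataFrame(
            {"TotalScore": res["Score"], "TotalDispersion": res["Dispersion"]},
            index=ranks.sample_ids,
        )
        return ScoreTable(data=data, mode=sig.mode, centered=center)
    res = score_undirected_set(
        ranks, sig.up_ids, dispersion_fun=dispersion_fun,
        mad_scale=mad_scale, set_name=sig.name,
    )
    data = pd.DataFrame(
        {"TotalScore": res["Score"], "TotalDispersion": res["Dispersion"]},
        index=ranks.sample_ids,
    )
    return ScoreTable(data=data, mode="unknown_direction", centered=False)


def rank_density_data(
    ranks: RankMatrix,
    sample: str,
    sig: GeneSignature,
    grid_size: int = 256,
) -> dict:
    """Barcode positions and rank densities of signature genes in one sample.

    Returns, per direction present in the signature, the normalised rank
    positions ``r/N`` of its genes plus a Gaussian kernel density
    estimate (Silverman bandwidth) evaluated on a grid over [0, 1].
    Rendering is left to the caller; this is diagnostics data only.
    """
    if sample not in ranks.sample_ids:
        raise KeyError(f"unknown sample: {sample!r}")
    col = ranks.ranks[sample]
    n_universe = ranks.n_genes
    grid = np.linspace(0.0, 1.0, grid_size)
    out: dict = {"grid": grid, "sample": sample}
    sets = {"up": sig.up_ids}
    if sig.down_ids:
        sets["down"] = sig.down_ids
    for direction, ids in sets.items():
        present = [g for g in ids if g in col.index]
        if not present:
            raise ValueError(f"no {direction} genes of {sig.name!r} in the data")
        pos = np.sort(col.loc[present].to_numpy(dtype=float) / n_universe)
        if pos.size > 1 and np.ptp(pos) > 0:
            kde = stats.gaussian_kde(pos, bw_method="silverman")
            density = kde(grid)
        else:
            density = np.zeros_like(grid)
        out[direction] = {"positions": pos, "density": density}
    return out
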