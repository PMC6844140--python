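"""Two-signature score landscapes.

Samples scored against two signatures form a 2-D distribution; a
hexagonal-bin density of that distribution is the "landscape", onto
which annotated sample subsets can be projected.  All functions here
return plain data (bin centres, counts, overlay coordinates); rendering
is a thin optional layer so analyses run headless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import ScoreTable

__all__ = [
    "LandscapeGrid",
    "build_landscape",
    "spearman_correlation",
    "project_samples",
    "render_landscape",
]


@dataclass
class LandscapeGrid:
    """Hexagonal-bin density of samples in two-signature score space."""

    bin_centers: np.ndarray  # (n_bins, 2)
    bin_counts: np.ndarray  # (n_bins,)
    axis_names: tuple[str, str]
    bins: int
    extent: tuple[float, float, float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.axis_names[0]: self.bin_centers[:, 0],
                self.axis_names[1]: self.bin_centers[:, 1],
                "count": self.bin_counts,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_alignment(scores_x: ScoreTable, scores_y: ScoreTable) -> None:
    ix, iy = scores_x.data.index, scores_y.data.index
    if not ix.equals(iy):
        only_x = ix.difference(iy).tolist()
        only_y = iy.difference(ix).tolist()
        raise ValueError(
            "score tables must cover the same samples in the same order; "
            f"only in x: {only_x[:5]}, only in y: {only_y[:5]}"
        )


def build_landscape(
    scores_x: ScoreTable,
    scores_y: ScoreTable,
    bins: int = 25,
    axis_names: tuple[str, str] = ("signature_x", "signature_y"),
) -> LandscapeGrid:
    """Bin samples on a hexagonal lattice spanning the observed score ranges.

    Both score tables must have been computed on the same samples with
    the order of samples retained.  Every sample falls in exactly one
    hexagon, so the bin counts sum to the number of samples.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _check_alignment(scores_x, scores_y)
    x = scores_x.total_score.to_numpy(dtype=float)
    y = scores_y.total_score.to_numpy(dtype=float)
    pad_x = (np.ptp(x) or 1.0) * 1e-3
    pad_y = (np.ptp(y) or 1.0) * 1e-3
    extent = (x.min() - pad_x, x.max() + pad_x, y.min() - pad_y, y.max() + pad_y)
    fig, ax = plt.subplots()
    try:
        coll = ax.hexbin(x, y, gridsize=bins, extent=extent, mincnt=1)
        centers = np.asarray(coll.get_offsets(), dtype=float)
        counts = np.asarray(coll.get_array(), dtype=float)
    finally:
        plt.close(fig)
    return LandscapeGrid(
        bin_centers=centers,
        bin_counts=counts,
        axis_names=tuple(axis_names),
        bins=bins,
        extent=extent,
    )


def spearman_correlation(x, y) -> float:
    """Spearman's rho: Pearson correlation of average-tie ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, _p = stats.spearmanr(x, y)
    return float(rho)


def project_samples(
    grid: LandscapeGrid,
    scores_x: ScoreTable,
    scores_y: ScoreTable,
    subset=None,
    annotations=None,
    uncertainty=None,
    uncertainty_threshold: float = 0.3,
) -> pd.DataFrame:
    """Overlay annotated samples on an existing landscape.

    Returns one row per projected sample with its two score coordinates,
    its categorical annotation, and a text ``label`` set only where the
    sample's classification uncertainty exceeds the threshold (uncertain
    calls are the ones worth inspecting by name).  Scores must come from
    the same two signatures that built the grid.
    """
    _check_alignment(scores_x, scores_y)
    samples = scores_x.data.index
    if subset is None:
        subset = samples
    subset = pd.Index(subset)
    missing = subset.difference(samples)
    if len(missing):
        raise ValueError(f"subset samples not scored: {missing.tolist()[:5]}")
    out = pd.DataFrame(
        {
            grid.axis_names[0]: scores_x.total_score.loc[subset],
            grid.axis_names[1]: scores_y.total_score.loc[subset],
        },
        index=subset,
    )
    if annotations is not None:
        out["annotation"] = pd.Series(annotations, index=subset) if not isinstance(
            annotations, pd.Series
        ) else annotations.loc[subset]
    if uncertainty is not None:
        unc = (
            uncertainty.loc[subset]
            if isinstance(uncertainty, pd.Series)
            else pd.Series(np.asarray(uncertainty), index=subset)
        )
        out["uncertainty"] = unc
        out["label"] = np.where(unc > uncertainty_threshold, subset, None)
    out.index.name = "sample_id"
    return out


def render_landscape(grid: LandscapeGrid, overlay: pd.DataFrame | None = None, path=None):
    """Optional rendering of a landscape (and overlay) to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    hb = ax.scatter(
        grid.bin_centers[:, 0], grid.bin_centers[:, 1],
        c=grid.bin_counts, marker="h", s=60, cmap="viridis",
    )
    fig.colorbar(hb, ax=ax, label="samples per bin")
    if overlay is not None:
        groups = overlay.groupby("annotation") if "annotation" in overlay else [("samples", overlay)]
        for name, grp in groups:
            ax.scatter(
                grp[grid.axis_names[0]], grp[grid.axis_names[1]],
                s=12, label=str(name),
            )
        ax.legend(fontsize="small")
    ax.set_xlabel(grid.axis_names[0])
    ax.set_ylabel(grid.axis_names[1])
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
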