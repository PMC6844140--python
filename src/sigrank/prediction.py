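"""Mutation-status prediction and stratification from signature scores.

Supervised: a binomial GLM (logit link) with the total score — and
optionally the rank dispersion — as predictors, evaluated in-sample by
precision, recall and F1 at the natural decision boundary (linear
predictor > 0, i.e. fitted probability > 0.5).

Unsupervised: one-dimensional Gaussian-mixture decomposition, k-means
and complete-linkage hierarchical clustering of (score, dispersion)
pairs, compared to each other and to the mutation labels with the
adjusted Rand index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

__all__ = [
    "LogisticFit",
    "PartitionPair",
    "fit_logistic",
    "classify_and_evaluate",
    "gaussian_mixture_1d",
    "cluster_scores",
    "adjusted_rand_index",
]


@dataclass
class LogisticFit:
    """Fitted binomial GLM: coefficient table and per-sample linear predictor."""

    coefficients: pd.Series
    standard_errors: pd.Series
    z_values: pd.Series
    p_values: pd.Series
    linear_predictor: pd.Series
    converged: bool

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "std_error": self.standard_errors,
                "z_value": self.z_values,
                "p_value": self.p_values,
            }
        )


@dataclass
class PartitionPair:
    """Two partitions of the same samples plus their contingency counts."""

    labels_a: np.ndarray
    labels_b: np.ndarray
    contingency: pd.DataFrame

    @classmethod
    def from_labels(cls, labels_a, labels_b) -> "PartitionPair":
        a = np.asarray(labels_a)
        b = np.asarray(labels_b)
        if a.shape != b.shape:
            raise ValueError(
                f"partition length mismatch: {a.shape} vs {b.shape}"
            )
        cont = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
        return cls(labels_a=a, labels_b=b, contingency=cont)


def fit_logistic(
    response,
    score,
    dispersion=None,
) -> LogisticFit:
    """Fit a logistic regression of mutation status on signature score.

    Maximum likelihood via iteratively reweighted least squares;
    standard errors from the inverse Fisher information and two-sided
    normal p-values.  Quasi-separated fits are flagged
    ``converged=False`` with a warning rather than raised.
    """
    y = np.asarray(response, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("response contains a single class")
    cols = {"score": np.asarray(score, dtype=float)}
    if dispersion is not None:
        cols["dispersion"] = np.asarray(dispersion, dtype=float)
    X = pd.DataFrame(cols)
    design = sm.add_constant(X, prepend=True).rename(columns={"const": "intercept"})

    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, design, family=sm.families.Binomial())
        res = model.fit(maxiter=100)
        if any("PerfectSeparation" in type(w.message).__name__ or
               "erfectly" in str(w.message) for w in caught):
            converged = False
    eta = res.predict(design, which="linear")
    # detect quasi-separation the way glm does: fitted probabilities
    # numerically at 0/1 for every sample of some class
    p = res.predict(design)
    if np.max(np.abs(eta)) > 25 and (np.minimum(p, 1 - p) < 1e-8).any():
        converged = False
    if not converged:
        warnings.warn(
            "quasi-separation detected: coefficients are unreliable",
            stacklevel=2,
        )
    names = design.columns
    return LogisticFit(
        coefficients=pd.Series(res.params.values, index=names),
        standard_errors=pd.Series(res.bse.values, index=names),
        z_values=pd.Series(res.tvalues.values, index=names),
        p_values=pd.Series(res.pvalues.values, index=names),
        linear_predictor=pd.Series(np.asarray(eta), index=X.index),
        converged=converged,
    )


def classify_and_evaluate(fit: LogisticFit, observed) -> dict[str, float]:
    """Precision, recall and F1 of the fit's natural classifier.

    A sample is predicted mutant when its linear predictor exceeds 0
    (fitted probability > 0.5).  Precision is NaN when nothing is
    predicted positive; F1 is 0 (not NaN) whenever there are no true
    positives, matching the convention F1 = 2TP / (2TP + FP + FN).
    """
    y = np.asarray(observed, dtype=bool)
    pred = fit.linear_predictor.to_numpy() > 0
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return {"precision": precision, "recall": recall, "f1": f1}


def gaussian_mixture_1d(
    values,
    k: int = 2,
    model: str = "unequal_var",
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> dict:
    """Two-component (by default) Gaussian mixture decomposition of scores.

    EM with ``n_restarts`` seeded initialisations, keeping the best
    log-likelihood.  ``model`` chooses equal (``equal_var``) or free
    (``unequal_var``) component variances.  The classification
    uncertainty of a sample is one minus its largest posterior
    probability; components are relabelled in order of increasing mean
    so that labels are stable across runs.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.shape[0] < 2 * k:
        raise ValueError(f"need at least {2 * k} values for a {k}-component mixture")
    cov = {"equal_var": "tied", "unequal_var": "full"}.get(model)
    if cov is None:
        raise ValueError(f"unknown mixture model: {model!r}")
    gm = GaussianMixture(
        n_components=k,
        covariance_type=cov,
        n_init=n_restarts,
        random_state=seed,
        tol=tol,
        max_iter=max_iter,
        reg_covar=1e-10,
    )
    gm.fit(x)
    if not gm.converged_:
        # component collapse is prevented by the covariance floor; hitting
        # the iteration cap just means a flat likelihood (e.g. null data)
        warnings.warn(
            "mixture EM stopped at the iteration cap before reaching "
            "tolerance; assignments may be unstable",
            stacklevel=2,
        )
    order = np.argsort(gm.means_.ravel())
    posteriors = gm.predict_proba(x)[:, order]
    assignments = np.argmax(posteriors, axis=1)
    uncertainty = 1.0 - posteriors.max(axis=1)
    return {
        "assignments": assignments,
        "posteriors": posteriors,
        "uncertainty": uncertainty,
        "means": gm.means_.ravel()[order],
        "log_likelihood": float(gm.score(x) * x.shape[0]),
    }


def cluster_scores(
    points,
    method: str = "kmeans",
    k: int = 2,
    restarts: int = 100,
    seed: int = 0,
    standardize: bool = False,
) -> np.ndarray:
    """Partition (score, dispersion) pairs into k clusters.

    ``kmeans`` keeps the best of ``restarts`` random initialisations by
    within-cluster sum of squares; ``hierarchical`` uses Euclidean
    distance with complete linkage cut at k clusters.  By default the
    two columns are used on their raw scales (they can differ by orders
    of magnitude, which then dominates the distances); ``standardize``
    rescales each column to unit variance first.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(-1, 1)
    if pts.shape[0] < k:
        raise ValueError(f"cannot form {k} clusters from {pts.shape[0]} points")
    if standardize:
        sd = pts.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        pts = (pts - pts.mean(axis=0)) / sd
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        return km.fit_predict(pts)
    if method == "hierarchical":
        link = hierarchy.linkage(pdist(pts, metric="euclidean"), method="complete")
        return hierarchy.fcluster(link, t=k, criterion="maxclust") - 1
    raise ValueError(f"unknown clustering method: {method!r}")


def adjusted_rand_index(pair: PartitionPair) -> float:
    """Chance-corrected agreement between two partitions (Hubert–Arabie).

    1 for identical partitions (up to relabelling), approximately 0 for
    independent ones; symmetric in its arguments.
    """
    return float(adjusted_rand_score(pair.labels_a, pair.labels_b))
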