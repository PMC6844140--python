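"""Core scoring: ranks, directed/undirected scores, dispersion, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sigrank import (
    CoverageWarning,
    GeneSignature,
    RankMatrix,
    check_signature_coverage,
    rank_density_data,
    rank_dispersion,
    rank_genes,
    score_directed_set,
    score_signature_pair,
    score_undirected_set,
)
from sigrank.scoring import combine_paired

from conftest import assign_ranks


# ---------------------------------------------------------------- ranking

@pytest.mark.parametrize(
    "column, tie_method, expected",
    [
        ([5.0, 1.0, 3.0], "min", [3, 1, 2]),
        ([2.0, 2.0, 1.0], "min", [2, 2, 1]),
        ([7.0, 7.0, 7.0], "min", [1, 1, 1]),
        ([2.0, 2.0, 1.0], "max", [3, 3, 1]),
        ([2.0, 2.0, 1.0], "average", [2.5, 2.5, 1]),
        ([2.0, 2.0, 1.0], "dense", [2, 2, 1]),
        ([2.0, 2.0, 1.0], "first", [2, 3, 1]),
    ],
)
def test_rank_genes_tie_policies(column, tie_method, expected):
    expr = pd.DataFrame({"s": column}, index=[f"g{i}" for i in range(len(column))])
    rm = rank_genes(expr, tie_method=tie_method)
    assert rm.ranks["s"].tolist() == expected


def test_rank_genes_columns_independent(small_expr):
    rm = rank_genes(small_expr)
    for col in small_expr:
        assert sorted(rm.ranks[col]) == list(range(1, 11))
        # highest expression gets rank N
        assert rm.ranks[col].idxmax() == small_expr[col].idxmax()


def test_rank_genes_random_ties_seeded():
    expr = pd.DataFrame({"s": [1.0] * 6 + [2.0]}, index=list("abcdefg"))
    r1 = rank_genes(expr, tie_method="random", seed=3).ranks["s"]
    r2 = rank_genes(expr, tie_method="random", seed=3).ranks["s"]
    assert (r1 == r2).all()
    assert sorted(r1) == list(range(1, 8))
    assert r1["g"] == 7
    with pytest.raises(ValueError, match="seed"):
        rank_genes(expr, tie_method="random")


def test_rank_genes_rejects_bad_input():
    expr = pd.DataFrame({"s": [1.0, np.nan, 3.0]}, index=["a", "b", "c"])
    with pytest.raises(ValueError, match="b"):
        rank_genes(expr)
    dup = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=["a", "a", "c"])
    with pytest.raises(ValueError, match="duplicated"):
        rank_genes(dup)
    with pytest.raises(ValueError, match="2 genes"):
        rank_genes(pd.DataFrame({"s": [1.0]}, index=["a"]))


# ---------------------------------------------------------- directed scores

@pytest.mark.parametrize(
    "rank_map, expected",
    [
        ({"a": 8, "b": 9, "c": 10}, 0.5),
        ({"a": 1, "b": 2, "c": 3}, -0.5),
        ({"a": 1, "b": 5, "c": 10}, (16 / 3 - 2) / 7 - 0.5),
    ],
)
def test_directed_score_known_configurations(rank_map, expected):
    rm = assign_ranks(None, rank_map, 10)
    res = score_directed_set(rm, list(rank_map))
    assert res["Score"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_directed_bounds_match_exhaustive_enumeration():
    """Normalization endpoints equal the min/max mean over all n-subsets."""
    for n_universe in range(5, 13):
        for n in range(1, 5):
            means = [
                np.mean(c)
                for c in itertools.combinations(range(1, n_universe + 1), n)
            ]
            lo, hi = (n + 1) / 2, (2 * n_universe - n + 1) / 2
            assert min(means) == pytest.approx(lo)
            assert max(means) == pytest.approx(hi)


def test_undirected_bounds_match_exhaustive_enumeration():
    for n_universe in (7, 10, 11, 12):
        med = (n_universe + 1) / 2
        for n in range(1, 5):
            means = [
                np.mean([abs(k - med) for k in c])
                for c in itertools.combinations(range(1, n_universe + 1), n)
            ]
            from sigrank.scoring import _abs_deviation_bounds

            lo, hi = _abs_deviation_bounds(n, n_universe)
            assert min(means) == pytest.approx(lo)
            assert max(means) == pytest.approx(hi)


def test_inverted_score_negates_centered_and_reflects_uncentered():
    rm = assign_ranks(None, {"a": 8, "b": 9, "c": 10}, 10)
    up = score_directed_set(rm, ["a", "b", "c"], invert=False)
    dn = score_directed_set(rm, ["a", "b", "c"], invert=True)
    assert dn["Score"].iloc[0] == pytest.approx(-up["Score"].iloc[0])
    up_u = score_directed_set(rm, ["a", "b", "c"], invert=False, center=False)
    dn_u = score_directed_set(rm, ["a", "b", "c"], invert=True, center=False)
    assert dn_u["Score"].iloc[0] == pytest.approx(1 - up_u["Score"].iloc[0])


def test_score_errors_on_empty_intersection(small_ranks):
    with pytest.raises(ValueError, match="no signature genes"):
        with pytest.warns(CoverageWarning):
            score_directed_set(small_ranks, ["nope1", "nope2"])


# -------------------------------------------------------- undirected scores

@pytest.mark.parametrize(
    "rank_map, expected",
    [
        ({"a": 1, "b": 11}, 1.0),
        ({"a": 5, "b": 6}, 0.0),
    ],
)
def test_undirected_score_extremes(rank_map, expected):
    rm = assign_ranks(None, rank_map, 11)
    res = score_undirected_set(rm, list(rank_map))
    assert res["Score"].iloc[0] == pytest.approx(expected)


def test_undirected_refuses_centering(small_ranks):
    with pytest.raises(ValueError, match="cannot be centered"):
        score_undirected_set(small_ranks, ["g0", "g1"], center=True)


# ------------------------------------------------------------- dispersion

def test_mad_of_consecutive_ranks():
    # median 3, |dev| {2,1,0,1,2}, median 1, scaled by 1.4826
    assert rank_dispersion([1, 2, 3, 4, 5]) == pytest.approx(1.4826)


def test_dispersion_degenerate_and_errors():
    assert rank_dispersion([7]) == 0.0
    with pytest.raises(ValueError):
        rank_dispersion([])
    with pytest.raises(ValueError):
        rank_dispersion([1, 2], fun="variance")


def test_iqr_dispersion():
    from scipy.stats import iqr

    assert rank_dispersion([1, 2, 3, 10], fun="iqr") == pytest.approx(
        iqr([1, 2, 3, 10])
    )


@given(
    ranks=st.lists(st.integers(1, 1000), min_size=1, max_size=50),
    n_universe=st.integers(1000, 2000),
)
@settings(deadline=None, max_examples=50)
def test_mad_invariant_under_rank_reversal(ranks, n_universe):
    r = np.array(ranks)
    assert rank_dispersion(r) == pytest.approx(rank_dispersion(n_universe + 1 - r))


# --------------------------------------------------------------- coverage

def test_coverage_warning_reports_missing(small_ranks):
    with pytest.warns(CoverageWarning, match=r"2 genes missing: x1, x2"):
        present, missing = check_signature_coverage(
            small_ranks, ["g0", "g1", "g2", "x2", "x1"]
        )
    assert present == ["g0", "g1", "g2"]
    assert missing == ["x1", "x2"]


def test_coverage_silent_when_complete(small_ranks, recwarn):
    present, missing = check_signature_coverage(small_ranks, ["g0", "g1"])
    assert missing == [] and present == ["g0", "g1"]
    assert not any(isinstance(w.message, CoverageWarning) for w in recwarn.list)


def test_missing_genes_shrink_n_but_keep_range(small_ranks):
    """With absent genes, bounds use the present-gene count: extremes still attained."""
    # g7, g8, g9 are not guaranteed extremes; build explicit ranks instead
    rm = assign_ranks(None, {"a": 9, "b": 10}, 10)
    with pytest.warns(CoverageWarning):
        res = score_directed_set(rm, ["a", "b", "ghost"])
    assert res["Score"].iloc[0] == pytest.approx(0.5)


# ----------------------------------------------------------- paired scores

def test_paired_extremes_and_additivity():
    rm = assign_ranks(None, {"u1": 9, "u2": 10, "d1": 1, "d2": 2}, 10)
    sig = GeneSignature("S", up_ids=("u1", "u2"), down_ids=("d1", "d2"))
    table = score_signature_pair(rm, sig)
    row = table.data.iloc[0]
    assert row["TotalScore"] == pytest.approx(1.0)
    assert row["TotalScore"] == pytest.approx(row["UpScore"] + row["DownScore"])
    assert row["TotalDispersion"] == pytest.approx(
        (row["UpDispersion"] + row["DownDispersion"]) / 2
    )
    # inverse enrichment: swap the sets
    swapped = GeneSignature("S", up_ids=("d1", "d2"), down_ids=("u1", "u2"))
    assert score_signature_pair(rm, swapped).data["TotalScore"].iloc[0] == pytest.approx(-1.0)


def test_component_combination_identities():
    """Total = up + down and total dispersion = mean of components."""
    total, disp = combine_paired(
        -0.0768291807, -0.01478324, 4513.034, 6000.823
    )
    assert total == pytest.approx(-0.09161242, abs=5e-9)
    assert disp == pytest.approx(5256.9285, abs=5e-5)


def test_paired_requires_paired_mode(small_ranks):
    sig = GeneSignature("U", up_ids=("g0",), mode="single_directed_up")
    with pytest.raises(ValueError, match="not paired"):
        score_signature_pair(small_ranks, sig)


# ---------------------------------------------------------- property suite

def _random_instance(seed, n_genes=60, n_samples=4):
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return rng, expr


@given(seed=st.integers(0, 10_000))
@settings(deadline=None, max_examples=25)
def test_scores_invariant_under_monotone_transforms(seed):
    """Any strictly increasing per-sample transform leaves scores unchanged."""
    rng, expr = _random_instance(seed)
    up = list(expr.index[rng.choice(60, 5, replace=False)])
    transformed = expr.copy()
    transforms = [np.exp, lambda x: 3 * x + 7, lambda x: x**3, np.arcsinh]
    for j, col in enumerate(transformed):
        transformed[col] = transforms[j % len(transforms)](transformed[col])
    a = score_directed_set(rank_genes(expr), up)
    b = score_directed_set(rank_genes(transformed), up)
    pd.testing.assert_frame_equal(a, b)
    ua = score_undirected_set(rank_genes(expr), up)
    ub = score_undirected_set(rank_genes(transformed), up)
    pd.testing.assert_frame_equal(ua, ub)


@given(seed=st.integers(0, 10_000))
@settings(deadline=None, max_examples=25)
def test_rank_reversal_negates_centered_scores(seed):
    rng, expr = _random_instance(seed)
    up = list(expr.index[rng.choice(60, 5, replace=False)])
    fwd = score_directed_set(rank_genes(expr), up)
    rev = score_directed_set(rank_genes(-expr), up)
    np.testing.assert_allclose(rev["Score"], -fwd["Score"], atol=1e-12)


def test_range_conservation_over_random_signatures():
    """Centered directed in [-0.5,0.5], paired in [-1,1], undirected in [0,1]."""
    rng = np.random.default_rng(0)
    n_genes, n_samples = 200, 3
    expr = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=list("abc"),
    )
    rm = rank_genes(expr)
    genes = np.array(expr.index)
    for _ in range(1000):
        size = rng.integers(2, 20)
        ids = genes[rng.choice(n_genes, size, replace=False)]
        split = max(1, size // 2)
        d = score_directed_set(rm, ids)["Score"]
        assert ((d >= -0.5) & (d <= 0.5)).all()
        u = score_undirected_set(rm, ids)["Score"]
        assert ((u >= 0) & (u <= 1)).all()
        sig = GeneSignature("r", tuple(ids[:split]), tuple(ids[split:]))
        t = score_signature_pair(rm, sig).data["TotalScore"]
        assert ((t >= -1) & (t <= 1)).all()


# -------------------------------------------------------------- diagnostics

def test_rank_density_reflects_planted_configuration():
    n_universe = 100
    rank_map = {f"u{i}": n_universe - i for i in range(5)}
    rank_map.update({f"d{i}": i + 1 for i in range(5)})
    rm = assign_ranks(None, rank_map, n_universe)
    sig = GeneSignature(
        "S", tuple(f"u{i}" for i in range(5)), tuple(f"d{i}" for i in range(5))
    )
    dens = rank_density_data(rm, "s", sig)
    assert (dens["up"]["positions"] > 0.9).all()
    assert (dens["down"]["positions"] < 0.1).all()
    grid = dens["grid"]
    up_peak = grid[np.argmax(dens["up"]["density"])]
    down_peak = grid[np.argmax(dens["down"]["density"])]
    assert up_peak > 0.8 and down_peak < 0.2


def test_rank_density_unknown_sample(small_ranks):
    sig = GeneSignature("S", ("g0", "g1"), mode="unknown_direction")
    with pytest.raises(KeyError, match="nope"):
        rank_density_data(small_ranks, "nope", sig)


def test_uniform_ranks_give_flat_density():
    rng = np.random.default_rng(5)
    n_universe = 2000
    ids = rng.choice(n_universe, 200, replace=False) + 1
    rank_map = {f"g{r}": int(r) for r in ids}
    rm = assign_ranks(None, rank_map, n_universe)
    sig = GeneSignature("S", tuple(rank_map), mode="unknown_direction")
    dens = rank_density_data(rm, "s", sig)
    interior = dens["up"]["density"][(dens["grid"] > 0.1) & (dens["grid"] < 0.9)]
    assert interior.std() / interior.mean() < 0.25
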