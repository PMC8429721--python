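"""Index construction: Z-scoring, averaging, thresholds, screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aridishift import indices
from aridishift.indices import (
    DegenerateColumnError,
    FunctionMatrix,
    averaging_index,
    classify_aridity,
    estimate_bnpp,
    multiple_threshold_analysis,
    site_level_aggregate,
    standardize,
    tradeoff_screen,
)
from aridishift.synthetic import FUNCTION_COLUMNS


@pytest.mark.parametrize(
    "veg, bare, cover, expected",
    [(10, 2, 0.3, 4.4), (7.5, 7.5, 0.42, 7.5), (5, 1, 1.0, 5.0)],
)
def test_site_level_aggregate(veg, bare, cover, expected):
    assert site_level_aggregate(veg, bare, cover) == pytest.approx(expected)


def test_site_level_aggregate_rejects_bad_cover():
    with pytest.raises(ValueError):
        site_level_aggregate(1.0, 1.0, 1.2)


def test_standardize_log10_two_sites():
    m = FunctionMatrix(np.array([[10.0], [1000.0]]), ["f"], [True])
    z = standardize(m).z_matrix
    np.testing.assert_allclose(z[:, 0], [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12)


def test_standardize_zero_variance_names_column():
    m = FunctionMatrix(
        np.column_stack([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]),
        ["flat", "ok"], [False, False],
    )
    with pytest.raises(DegenerateColumnError, match="flat"):
        standardize(m)


def test_standardize_contract(default_table):
    m = FunctionMatrix.from_table(default_table, FUNCTION_COLUMNS)
    res = standardize(m)
    assert np.all(np.abs(res.z_matrix.mean(axis=0)) < 1e-10)
    np.testing.assert_allclose(res.z_matrix.std(axis=0, ddof=1), 1.0)
    np.testing.assert_allclose(res.mf, res.z_matrix.mean(axis=1))


def test_averaging_index_examples():
    np.testing.assert_allclose(
        averaging_index(np.array([[1.0, -1.0], [-1.0, 1.0]])), [0.0, 0.0]
    )
    col = np.array([0.3, -0.7, 0.4])
    np.testing.assert_allclose(averaging_index(col.reshape(-1, 1)), col)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_averaging_index_mean_zero(seed):
    """The averaged index of standardized columns has site-mean zero."""
    r = np.random.default_rng(seed)
    raw = np.exp(r.standard_normal((12, 7)))
    res = standardize(FunctionMatrix(raw, [f"f{i}" for i in range(7)]))
    assert abs(res.mf.mean()) < 1e-10


def test_multifunctionality_affine_invariance(default_table):
    cols = list(FUNCTION_COLUMNS)
    m1 = FunctionMatrix.from_table(default_table, cols, log10=False)
    scaled = default_table.copy()
    scaled[cols[0]] = scaled[cols[0]] * 3.7
    scaled[cols[2]] = scaled[cols[2]] * 0.5 + 11.0
    m2 = FunctionMatrix.from_table(scaled, cols, log10=False)
    np.testing.assert_allclose(standardize(m1).mf, standardize(m2).mf, atol=1e-10)


def test_simplified_variant_matches_recomputation(default_table):
    simplified = indices.multifunctionality(default_table, "simplified5")
    assert simplified.included_functions == [
        "dna_conc", "org_C", "ammonium", "nitrate", "avail_P"
    ]
    manual = standardize(
        FunctionMatrix.from_table(default_table, simplified.included_functions)
    )
    np.testing.assert_allclose(simplified.mf, manual.mf)


def brute_force_counts(values, max_levels, thresholds):
    n, f = values.shape
    counts = np.zeros((n, len(thresholds)), dtype=int)
    for i in range(n):
        for ti, t in enumerate(thresholds):
            c = 0
            for j in range(f):
                if values[i, j] > (t / 100.0) * max_levels[j]:
                    c += 1
            counts[i, ti] = c
    return counts


def test_multiple_threshold_grid_and_oracle(rng):
    values = np.exp(rng.standard_normal((15, 4)))
    m = FunctionMatrix(values, list("abcd"), [False] * 4)
    div = rng.standard_normal(15)
    res = multiple_threshold_analysis(div, m)
    assert len(res.thresholds) == 99
    assert res.thresholds[0] == 1 and res.thresholds[-1] == 99
    top4 = np.sort(values, axis=0)[-4:].mean(axis=0)
    expected = brute_force_counts(values, top4, res.thresholds)
    np.testing.assert_array_equal(res.counts, expected)
    # per-site counts never increase with the threshold
    assert np.all(np.diff(res.counts, axis=1) <= 0)


def test_multiple_threshold_toy_recovery():
    div = np.arange(1.0, 7.0)
    values = np.column_stack([div * 2.0])
    m = FunctionMatrix(values, ["f"], [False])
    res = multiple_threshold_analysis(div, m)
    from scipy import stats

    sig = []
    slopes = np.empty(99)
    top4 = np.sort(values[:, 0])[-4:].mean()
    for ti, t in enumerate(range(1, 100)):
        y = (values[:, 0] > t / 100.0 * top4).astype(float)
        if y.std() == 0:
            slopes[ti] = 0.0
            continue
        fit = stats.linregress(div, y)
        slopes[ti] = fit.slope
        if fit.pvalue < 0.05:
            sig.append((t, fit.slope, fit.intercept))
    np.testing.assert_allclose(res.slopes, slopes, atol=1e-12)
    assert np.nanmax(res.slopes) > 0  # positive association at mid thresholds
    t_mde, s_mde, i_mde = max(sig, key=lambda r: abs(r[1]))
    assert res.Tmde == t_mde
    assert res.Mmde == pytest.approx(i_mde + s_mde * div.max())
    assert res.Tmin == sig[0][0] and res.Tmax == sig[-1][0]


def test_multiple_threshold_degenerate_inputs():
    m = FunctionMatrix(np.full((6, 3), 5.0), list("abc"), [False] * 3)
    res = multiple_threshold_analysis(np.arange(6.0), m)
    assert np.all(res.slopes[np.isfinite(res.slopes)] == 0)
    assert res.Tmin is None and "Tmin" in res.flags or "counts" in res.flags
    with pytest.raises(ValueError):
        multiple_threshold_analysis(
            np.arange(3.0), FunctionMatrix(np.ones((3, 2)) + np.eye(3)[:, :2],
                                           ["a", "b"], [False, False])
        )


@pytest.mark.parametrize(
    "agb, root, ndvi, expected",
    [(100.0, 200.0, 0.5, 1.0), (140.0, 140.0, 0.37, 0.37), (200.0, 100.0, 0.6, 0.3)],
)
def test_estimate_bnpp(agb, root, ndvi, expected):
    assert estimate_bnpp(agb, root, ndvi) == pytest.approx(expected)


def test_estimate_bnpp_rejects_nonpositive_biomass():
    with pytest.raises(ValueError):
        estimate_bnpp(0.0, 10.0, 0.5)


@pytest.mark.parametrize(
    "aridity, subtype",
    [
        (0.30, "non-dryland"),
        (0.35, "dry-subhumid"),
        (0.49, "dry-subhumid"),
        (0.50, "semiarid"),
        (0.79, "semiarid"),
        (0.80, "arid"),
        (0.85, "arid"),
        (0.95, "hyperarid"),
        (0.99, "hyperarid"),
    ],
)
def test_classify_aridity(aridity, subtype):
    assert classify_aridity(aridity) == subtype


def test_classify_aridity_domain():
    with pytest.raises(ValueError):
        classify_aridity(1.0)
    with pytest.raises(ValueError):
        classify_aridity(-0.1)


def test_tradeoff_screen_combinatorics(default_table, rng):
    m7 = FunctionMatrix.from_table(default_table, FUNCTION_COLUMNS)
    rep = tradeoff_screen(m7)
    assert rep.n_pairs == 21
    x = rng.standard_normal(20)
    m2 = FunctionMatrix(np.column_stack([x, -x + 0.01 * rng.standard_normal(20)]),
                        ["a", "b"], [False, False])
    assert tradeoff_screen(m2).n_pairs == 1
    dup = FunctionMatrix(np.column_stack([x, x]), ["a", "a_copy"], [False, False])
    rep_dup = tradeoff_screen(dup)
    assert rep_dup.pairs.iloc[0]["r"] == pytest.approx(1.0)
    assert rep_dup.n_redundant == 1


def test_tradeoff_screen_zero_variance_flagged(rng):
    m = FunctionMatrix(
        np.column_stack([np.full(10, 2.0), rng.standard_normal(10)]),
        ["flat", "ok"], [False, False],
    )
    rep = tradeoff_screen(m)
    assert not rep.pairs.iloc[0]["defined"]
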