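"""Mixed-model engine: design, REML, sequential ANOVA, region OLS."""

import numpy as np
import pandas as pd
import pytest

from aridishift import GeneratorConfig, generate_sites
from aridishift.mixed import (
    ModelSpec,
    build_design,
    fit_mixed,
    ols_by_region,
    prepare_analysis_table,
)
from aridishift.reml import reml_fit


def test_build_design_standardization(prepared_table):
    design = build_design(prepared_table, ModelSpec(variant="simplified"))
    X = design.X
    np.testing.assert_allclose(X[:, 0], 1.0)
    for j in range(1, 5):  # main-effect columns
        assert abs(X[:, j].mean()) < 1e-10
        assert X[:, j].std(ddof=1) == pytest.approx(1.0)
    assert abs(design.y.mean()) < 1e-10


def test_full_design_has_13_fixed_terms(prepared_table):
    design = build_design(prepared_table, ModelSpec(variant="full"))
    assert len(design.terms) == 13
    assert design.X.shape[1] == 14  # + intercept


def test_interaction_of_orthogonal_mains_has_unit_vif(rng):
    n = 4000
    t = pd.DataFrame(
        {
            "a": rng.standard_normal(n),
            "b": rng.standard_normal(n),
            "y": rng.standard_normal(n),
            "g": rng.integers(0, 3, n),
        }
    )
    from aridishift.mixed import _vif

    za = (t["a"] - t["a"].mean()) / t["a"].std(ddof=1)
    zb = (t["b"] - t["b"].mean()) / t["b"].std(ddof=1)
    X = np.column_stack([np.ones(n), za, zb, za * zb])
    vifs = _vif(X)
    np.testing.assert_allclose(vifs, 1.0, atol=0.1)


def test_build_design_missing_column(prepared_table):
    t = prepared_table.drop(columns=["aridity"])
    with pytest.raises((KeyError, ValueError)):
        build_design(t, ModelSpec(variant="simplified"))


def test_reml_matches_statsmodels():
    smf = pytest.importorskip("statsmodels.formula.api")
    # strong random effects keep the oracle's optimizer off the boundary
    cfg = GeneratorConfig(seed=3, sigma_soil=0.3, sigma_veg=0.25)
    table = prepare_analysis_table(generate_sites(cfg))
    design = build_design(table, ModelSpec(variant="simplified"))
    ours = reml_fit(design.X, design.y, design.random_factors)

    df = pd.DataFrame(
        design.X[:, 1:], columns=[f"t{i}" for i in range(len(design.terms))]
    )
    df["y"] = design.y
    df["soil"] = design.random_factors["soil_type"]
    df["veg"] = design.random_factors["vegetation_type"]
    df["g"] = 1
    model = smf.mixedlm(
        "y ~ " + " + ".join(f"t{i}" for i in range(len(design.terms))),
        df, groups="g",
        vc_formula={"soil": "0 + C(soil)", "veg": "0 + C(veg)"},
    ).fit(reml=True)
    np.testing.assert_allclose(ours.beta, model.fe_params.values, atol=1e-4)
    np.testing.assert_allclose(ours.sigma2, model.scale, rtol=1e-3)
    np.testing.assert_allclose(
        [ours.variances["soil_type"], ours.variances["vegetation_type"]],
        model.vcomp, rtol=5e-2, atol=1e-4,
    )


def test_zero_random_effect_reduces_to_ols():
    # a replicate whose REML solution sits at the zero boundary for both
    # random terms (positive boundary-away estimates are equally valid REML
    # answers on other replicates and are not "singular")
    cfg = GeneratorConfig(seed=1, sigma_soil=0.0, sigma_veg=0.0)
    t = prepare_analysis_table(generate_sites(cfg))
    design = build_design(t, ModelSpec(variant="simplified"))
    report = fit_mixed(design)
    assert report.singular_flag
    ols_beta, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    np.testing.assert_allclose(report.beta, ols_beta, atol=1e-6)
    assert report.marginal_R2 == pytest.approx(report.conditional_R2)


def test_sequential_ss_partitions_total_in_ols_limit():
    cfg = GeneratorConfig(seed=4, sigma_soil=0.0, sigma_veg=0.0)
    t = prepare_analysis_table(generate_sites(cfg))
    design = build_design(t, ModelSpec(variant="simplified"))
    report = fit_mixed(design, satterthwaite=False)
    resid = design.y - design.X @ report.beta
    total_ss = float(np.sum((design.y - design.y.mean()) ** 2))
    term_ss = report.table["MS"].sum()  # df=1 per term
    assert term_ss + float(resid @ resid) == pytest.approx(total_ss, abs=1e-6)


def test_orthogonal_terms_order_invariant(rng):
    n = 200
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a -= a.mean(); b -= b.mean()
    b -= a * (a @ b) / (a @ a)  # exactly orthogonal
    a /= a.std(ddof=1); b /= b.std(ddof=1)
    y = 0.5 * a - 0.3 * b + rng.standard_normal(n)
    g = rng.integers(0, 4, n)

    def seq_F(order):
        X = np.column_stack([np.ones(n)] + order)
        from aridishift.mixed import Design

        d = Design(X=X, y=(y - y.mean()) / y.std(ddof=1),
                   terms=["u", "v"], random_factors={},
                   n=n, response="y", spec=ModelSpec())
        rep = fit_mixed(d, satterthwaite=False)
        return dict(zip(rep.table["Term"], rep.table["F"]))

    f1 = seq_F([a, b])
    f2 = seq_F([b, a])
    assert f1["u"] == pytest.approx(f2["v"], rel=1e-8)
    assert f1["v"] == pytest.approx(f2["u"], rel=1e-8)


def test_vif_matches_auxiliary_regressions(prepared_table):
    design = build_design(prepared_table, ModelSpec(variant="full"))
    from aridishift.mixed import _vif

    vifs = _vif(design.X)
    Xc = design.X[:, 1:]
    for j in range(Xc.shape[1]):
        others = np.delete(Xc, j, axis=1)
        A = np.column_stack([np.ones(len(Xc)), others])
        coef, *_ = np.linalg.lstsq(A, Xc[:, j], rcond=None)
        resid = Xc[:, j] - A @ coef
        r2 = 1 - resid @ resid / np.sum((Xc[:, j] - Xc[:, j].mean()) ** 2)
        np.testing.assert_allclose(vifs[j], 1.0 / (1.0 - r2), rtol=1e-6)


def test_fit_mixed_reports_satterthwaite_ddf(prepared_table):
    design = build_design(prepared_table, ModelSpec(variant="simplified"))
    report = fit_mixed(design)
    assert (report.table["ddf"] >= 1).all()
    assert report.table["P"].between(0, 1).all()
    assert (report.table["VIF"] >= 1).all()
    assert report.marginal_R2 <= report.conditional_R2 <= 1.0


def test_ols_by_region_identity_and_partition(prepared_table):
    t = prepared_table.copy()
    t["self"] = t["multifunctionality"]
    rep = ols_by_region(t, metrics=("self",), c=0.80)
    assert rep.loc[rep["region"] == "all", "r2"].iloc[0] == pytest.approx(1.0)
    below = rep.loc[rep["region"] == "below_c", "n"].iloc[0]
    above = rep.loc[rep["region"] == "above_c", "n"].iloc[0]
    assert below + above == len(t)


def test_ols_by_region_recovers_planted_shift():
    """Plant slope significant below the break but not above; microbial
    index slope significant above: the generator's planted structure."""
    agree = 0
    seeds = range(5)
    for seed in seeds:
        t = prepare_analysis_table(generate_sites(GeneratorConfig(seed=seed)))
        rep = ols_by_region(t, metrics=("plant_richness", "microbial_index"))
        r = rep.set_index(["metric", "region"])
        ok = (
            r.loc[("plant_richness", "below_c"), "significant"]
            and r.loc[("plant_richness", "below_c"), "slope"] > 0
            and not r.loc[("plant_richness", "above_c"), "significant"]
            and r.loc[("microbial_index", "above_c"), "significant"]
            and r.loc[("microbial_index", "above_c"), "slope"] > 0
        )
        agree += ok
    assert agree >= 4
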