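"""Mixed-effects models of multifunctionality and the region-split OLS.

The full model regresses soil multifunctionality on sampling year, the biotic
terms (plant species richness, the soil microbial diversity index, BNPP), the
abiotic terms (aridity, soil pH, clay content), the spatial covariates
(elevation, latitude, longitude), and the diversity x aridity interactions,
with soil type and vegetation type as crossed random intercepts.  The
simplified model keeps year, the two diversity terms, aridity, and the
aridity x diversity interactions (including the three-way term).

Fixed terms are tested sequentially (type-I sums of squares) with
Satterthwaite denominator degrees of freedom; all continuous variables are
Z-scored within the fitted subset so estimates are standardized coefficients.
Plant richness and elevation are log10-transformed before standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import indices
from .reml import (
    RandomStructure,
    REMLResult,
    _crossprods,
    cov_beta_at,
    reml_criterion_at,
    reml_fit,
)

__all__ = [
    "ModelSpec",
    "Design",
    "MixedFitReport",
    "build_design",
    "fit_mixed",
    "ols_by_region",
    "prepare_analysis_table",
]

#: Fixed-term sequences; interactions are written "a:b".
FULL_TERMS = (
    "year",
    "plant_richness",
    "microbial_index",
    "aridity",
    "bnpp",
    "soil_pH",
    "clay",
    "elevation",
    "latitude",
    "longitude",
    "plant_richness:microbial_index",
    "aridity:plant_richness",
    "aridity:microbial_index",
)

SIMPLIFIED_TERMS = (
    "year",
    "plant_richness",
    "microbial_index",
    "aridity",
    "aridity:plant_richness",
    "aridity:microbial_index",
    "aridity:plant_richness:microbial_index",
)

#: log10 applied before standardization (richness and elevation).
LOG10_TERMS = {"plant_richness", "elevation"}

DIVERSITY_COMPONENTS = (
    "archaeal_richness",
    "bacterial_richness",
    "fungal_richness",
)


@dataclass
class ModelSpec:
    """Which multifunctionality model to build.

    ``variant``: ``"full"``, ``"simplified"``, or ``"region_components"``
    (simplified with per-taxon richness replacing the microbial index).
    ``region``: ``"all"``, ``"below_c"``, or ``"above_c"`` with the split at
    aridity ``c`` (sites at exactly ``c`` go to the above group).
    """

    variant: str = "simplified"
    response: str = "multifunctionality"
    region: str = "all"
    c: float = 0.80
    random_terms: tuple[str, ...] = ("soil_type", "vegetation_type")
    min_region_sites: int = 20

    def terms(self) -> tuple[str, ...]:
        if self.variant == "full":
            return FULL_TERMS
        if self.variant == "simplified":
            return SIMPLIFIED_TERMS
        if self.variant == "region_components":
            out = []
            for t in SIMPLIFIED_TERMS:
                if t == "aridity:plant_richness:microbial_index":
                    continue  # three-way term not defined per component
                if "microbial_index" in t:
                    out.extend(
                        t.replace("microbial_index", comp)
                        for comp in DIVERSITY_COMPONENTS
                    )
                else:
                    out.append(t)
            return tuple(out)
        raise ValueError(f"unknown model variant {self.variant!r}")


@dataclass
class Design:
    X: np.ndarray  # n x (1 + n_terms), leading intercept column
    y: np.ndarray
    terms: list[str]
    random_factors: dict
    n: int
    response: str
    spec: ModelSpec


@dataclass
class MixedFitReport:
    table: pd.DataFrame  # Term, df, ddf, MS, F, P, Estimate, VIF
    variance_components: dict
    marginal_R2: float
    conditional_R2: float
    singular_flag: bool
    dropped_random_terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    terms: list[str]
    reml: REMLResult | None = None


def prepare_analysis_table(
    table: pd.DataFrame, mf_variant: str = "full7"
) -> pd.DataFrame:
    """Add derived analysis columns (multifunctionality, microbial index, BNPP)."""
    out = table.copy()
    out["multifunctionality"] = indices.multifunctionality(table, mf_variant).mf
    out["microbial_index"] = indices.microbial_diversity_index(table)
    out["bnpp"] = indices.estimate_bnpp(
        table["agb"].to_numpy(), table["root_biomass"].to_numpy(),
        table["ndvi"].to_numpy(),
    )
    return out


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zero variance in term {name!r} within the fitted subset")
    return (x - x.mean()) / sd


def select_region(table: pd.DataFrame, region: str, c: float) -> pd.DataFrame:
    if region == "all":
        return table
    if region == "below_c":
        return table[table["aridity"] < c]
    if region == "above_c":
        return table[table["aridity"] >= c]
    raise ValueError(f"unknown region {region!r}")


def build_design(table: pd.DataFrame, spec: ModelSpec) -> Design:
    """Standardized fixed-effect design for a model spec.

    Continuous predictors and the response are Z-scored within the fitted
    subset; interaction columns are products of the standardized mains.
    """
    terms = spec.terms()
    sub = select_region(table, spec.region, spec.c)
    if spec.region != "all" and len(sub) < spec.min_region_sites:
        raise ValueError(
            f"region {spec.region!r} leaves only {len(sub)} sites "
            f"(< {spec.min_region_sites})"
        )
    if spec.response not in sub.columns or "microbial_index" not in sub.columns:
        sub = prepare_analysis_table(sub) if spec.response == "multifunctionality" \
            else sub
    main_names = sorted({m for t in terms for m in t.split(":")})
    missing = [
        m for m in main_names if m not in sub.columns
    ]
    if missing:
        raise KeyError(f"missing model columns: {missing}")
    mains = {}
    for m in main_names:
        x = sub[m].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"missing values in column {m!r}")
        if m in LOG10_TERMS:
            if np.any(x <= 0):
                x = np.log10(x + 1.0)
            else:
                x = np.log10(x)
        mains[m] = _zscore(x, m)
    cols = [np.ones(len(sub))]
    for t in terms:
        parts = t.split(":")
        col = mains[parts[0]].copy()
        for pnm in parts[1:]:
            col = col * mains[pnm]
        cols.append(col)
    y = sub[spec.response].to_numpy(dtype=float)
    y = _zscore(y, spec.response)
    random_factors = {
        r: sub[r].to_numpy() for r in spec.random_terms if r in sub.columns
    }
    missing_r = [r for r in spec.random_terms if r not in sub.columns]
    if missing_r:
        raise KeyError(f"missing random-term columns: {missing_r}")
    return Design(
        X=np.column_stack(cols),
        y=y,
        terms=list(terms),
        random_factors=random_factors,
        n=len(sub),
        response=spec.response,
        spec=spec,
    )


def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors of the non-intercept columns."""
    Xc = X[:, 1:]
    corr = np.corrcoef(Xc, rowvar=False)
    if Xc.shape[1] == 1:
        return np.array([1.0])
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        inv = np.linalg.pinv(corr)
    return np.clip(np.diag(inv), 1.0, None)


def _satterthwaite_ddf(cp, struct, theta, contrast, scale, n, p):
    """Satterthwaite denominator df for one contrast at theta-hat."""
    k = len(theta)
    h = np.maximum(np.abs(theta) * 1e-4, scale * 1e-7)

    def f(th):
        C = cov_beta_at(cp, struct, th)
        return float(contrast @ C @ contrast)

    grad = np.zeros(k)
    for i in range(k):
        up = theta.copy(); up[i] += h[i]
        dn = theta.copy(); dn[i] = max(dn[i] - h[i], 1e-12 * scale)
        grad[i] = (f(up) - f(dn)) / (up[i] - dn[i])

    # numeric Hessian of half the -2 restricted loglik
    def ll(th):
        return 0.5 * reml_criterion_at(cp, struct, th, n, p)

    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            pp = theta.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = theta.copy(); pm[i] += h[i]; pm[j] = max(pm[j] - h[j], 1e-12 * scale)
            mp = theta.copy(); mp[i] = max(mp[i] - h[i], 1e-12 * scale); mp[j] += h[j]
            mm = theta.copy()
            mm[i] = max(mm[i] - h[i], 1e-12 * scale)
            mm[j] = max(mm[j] - h[j], 1e-12 * scale)
            num = ll(pp) - ll(pm) - ll(mp) + ll(mm)
            den = (pp[i] - mp[i]) * (pp[j] - pm[j])
            H[i, j] = H[j, i] = num / den
    try:
        A = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(H)
    fval = f(theta)
    denom = float(grad @ A @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return None
    return 2.0 * fval**2 / denom


def fit_mixed(
    design: Design,
    satterthwaite: bool = True,
    singular_tol: float = 1e-8,
    vif_threshold: float = 10.0,
) -> MixedFitReport:
    """REML fit with sequential type-I F tests and Nakagawa R-squared.

    Random-intercept variances below ``singular_tol`` mark the fit singular;
    the offending factor is dropped and the model refit.  VIFs at or above
    ``vif_threshold`` are flagged in the report table.
    """
    X, y = design.X, design.y
    n, p = X.shape
    res = reml_fit(X, y, design.random_factors, singular_tol=singular_tol)

    # whitened sequential decomposition
    kept = {
        k: v for k, v in design.random_factors.items() if k not in res.dropped
    }
    struct = RandomStructure.from_labels(kept)
    Z = struct.Z if struct.Z.size else np.zeros((n, 0))
    g = struct.expand(res.gammas) if res.gammas.size else np.empty(0)
    V = res.sigma2 * (np.eye(n) + (Z * g) @ Z.T if g.size else np.eye(n))
    L = np.linalg.cholesky(V)
    from scipy.linalg import solve_triangular

    Xt = solve_triangular(L, X, lower=True)
    yt = solve_triangular(L, y, lower=True)
    Q, R = np.linalg.qr(Xt)
    qty = Q.T @ yt
    ss = qty**2  # sequential SS in whitened units, one per column

    cp = _crossprods(X, y, Z)
    theta = np.array(
        [res.sigma2] + [res.variances[k] for k in struct.names], dtype=float
    )
    scale = res.sigma2

    rows = []
    vifs = _vif(X)
    Rinv_needed = satterthwaite and theta.size > 1
    for j, term in enumerate(design.terms, start=1):
        F = float(ss[j])
        ddf = None
        if Rinv_needed:
            contrast = R[j, :]
            ddf = _satterthwaite_ddf(cp, struct, theta, contrast, scale, n, p)
        if ddf is None:
            ddf = float(n - p)
        ddf = float(np.clip(ddf, 1.0, 10.0 * n))
        P = float(stats.f.sf(F, 1, ddf))
        rows.append(
            dict(
                Term=term, df=1, ddf=round(ddf, 1),
                MS=F * res.sigma2, F=F, P=P,
                Estimate=float(res.beta[j]),
                VIF=float(vifs[j - 1]),
                vif_flag=bool(vifs[j - 1] >= vif_threshold),
            )
        )
    report_table = pd.DataFrame(rows)

    var_fixed = float(np.var(X[:, 1:] @ res.beta[1:]))
    var_random = float(sum(res.variances.values()))
    total = var_fixed + var_random + res.sigma2
    marginal = var_fixed / total
    conditional = (var_fixed + var_random) / total
    se = np.sqrt(np.diag(res.cov_beta))
    return MixedFitReport(
        table=report_table,
        variance_components=res.variance_components,
        marginal_R2=marginal,
        conditional_R2=conditional,
        singular_flag=res.singular,
        dropped_random_terms=list(res.dropped),
        beta=res.beta,
        se=se,
        cov_beta=res.cov_beta,
        terms=list(design.terms),
        reml=res,
    )


DEFAULT_REGION_METRICS = (
    "plant_richness",
    "microbial_index",
    "archaeal_richness",
    "bacterial_richness",
    "fungal_richness",
    "saprotroph_richness",
    "pathogen_richness",
    "symbiont_richness",
)


def ols_by_region(
    table: pd.DataFrame,
    metrics: tuple[str, ...] | list[str] = DEFAULT_REGION_METRICS,
    c: float = 0.80,
    response: str = "multifunctionality",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metric OLS of multifunctionality below/above the aridity split.

    Plant richness enters log10-transformed; other metrics untransformed.
    Returns a tidy frame (metric, region, slope, intercept, r2, p, n,
    significant) for regions below_c / above_c / all.
    """
    if response not in table.columns:
        table = prepare_analysis_table(table)
    regions = {
        "below_c": table[table["aridity"] < c],
        "above_c": table[table["aridity"] >= c],
        "all": table,
    }
    for name, sub in regions.items():
        if len(sub) < 3:
            raise ValueError(f"region {name!r} has fewer than 3 sites")
    rows = []
    for metric in metrics:
        if metric not in table.columns:
            raise KeyError(f"missing metric column {metric!r}")
        for name, sub in regions.items():
            x = sub[metric].to_numpy(dtype=float)
            if metric == "plant_richness":
                x = np.log10(x) if np.all(x > 0) else np.log10(x + 1.0)
            y = sub[response].to_numpy(dtype=float)
            if x.std(ddof=1) == 0:
                rows.append(
                    dict(metric=metric, region=name, slope=np.nan,
                         intercept=np.nan, r2=np.nan, p=np.nan,
                         n=len(sub), significant=False)
                )
                continue
            fit = stats.linregress(x, y)
            rows.append(
                dict(
                    metric=metric, region=name,
                    slope=float(fit.slope), intercept=float(fit.intercept),
                    r2=float(fit.rvalue**2), p=float(fit.pvalue),
                    n=len(sub), significant=bool(fit.pvalue <= alpha),
                )
            )
    return pd.DataFrame(rows)
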