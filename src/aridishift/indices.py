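"""Multifunctionality indices, diversity indices, and function screening.

The averaging index is the mean of Z-scored (log10-transformed where flagged)
soil functions; the soil microbial diversity index is the same construction
applied to archaeal, bacterial, and fungal richness.  The multiple-threshold
analysis counts, per site, how many functions exceed each of 99 percentage
thresholds of their maxima (mean of the top four observed values) and
summarizes the diversity -> count regressions by the Tmin/Tmax/Tmde and
Mmin/Mmax/Mmde indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FunctionMatrix",
    "MultifunctionalityResult",
    "MTResult",
    "TradeoffReport",
    "DegenerateColumnError",
    "site_level_aggregate",
    "standardize",
    "averaging_index",
    "multifunctionality",
    "microbial_diversity_index",
    "simplified_function_columns",
    "multiple_threshold_analysis",
    "estimate_bnpp",
    "classify_aridity",
    "tradeoff_screen",
]

#: Columns dropped for the simplified 5-function multifunctionality variant.
SIMPLIFIED_EXCLUDED = ("total_N", "total_P")


class DegenerateColumnError(ValueError):
    """A function column has zero variance and cannot be Z-scored."""


@dataclass
class FunctionMatrix:
    """Sites x functions block with per-column log10 flags.

    ``values`` must be strictly positive wherever the log10 flag is set.
    """

    values: np.ndarray
    function_names: list[str]
    transform_flags: list[bool] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d sites x functions array")
        n, f = self.values.shape
        if n < 2 or f < 1:
            raise ValueError("need >= 2 sites and >= 1 function")
        if len(self.function_names) != f:
            raise ValueError("function_names length mismatch")
        if self.transform_flags is None:
            self.transform_flags = [True] * f
        if len(self.transform_flags) != f:
            raise ValueError("transform_flags length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing or non-finite cells in function matrix")
        for j, flag in enumerate(self.transform_flags):
            if flag and np.any(self.values[:, j] <= 0):
                raise ValueError(
                    f"column {self.function_names[j]!r} has non-positive values "
                    "but is flagged for log10"
                )

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        columns: list[str] | tuple[str, ...],
        log10: bool = True,
    ) -> "FunctionMatrix":
        missing = [c for c in columns if c not in table.columns]
        if missing:
            raise KeyError(f"missing function columns: {missing}")
        return cls(
            table[list(columns)].to_numpy(float),
            list(columns),
            [log10] * len(columns),
        )


@dataclass
class MultifunctionalityResult:
    z_matrix: np.ndarray
    mf: np.ndarray
    included_functions: list[str]


@dataclass
class TradeoffReport:
    pairs: pd.DataFrame
    n_pairs: int
    n_significant_positive: int
    n_significant_negative: int
    n_redundant: int


@dataclass
class MTResult:
    thresholds: np.ndarray
    counts: np.ndarray  # sites x thresholds
    slopes: np.ndarray
    pvalues: np.ndarray
    max_levels: dict[str, float]
    Tmin: float | None = None
    Tmax: float | None = None
    Tmde: float | None = None
    Mmin: float | None = None
    Mmax: float | None = None
    Mmde: float | None = None
    flags: dict[str, str] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "Tmin": self.Tmin,
            "Tmax": self.Tmax,
            "Tmde": self.Tmde,
            "Mmin": self.Mmin,
            "Mmax": self.Mmax,
            "Mmde": self.Mmde,
            "flags": dict(self.flags),
        }


def site_level_aggregate(
    veg_mean: float, bare_mean: float, perennial_cover: float
) -> float:
    """Cover-weighted site mean of vegetated-area and bare-ground values."""
    if not 0.0 <= perennial_cover <= 1.0:
        raise ValueError(f"perennial_cover {perennial_cover} outside [0, 1]")
    return perennial_cover * veg_mean + (1.0 - perennial_cover) * bare_mean


def standardize(matrix: FunctionMatrix) -> MultifunctionalityResult:
    """Z-score each function column (log10 first where flagged; sample SD).

    Raises :class:`DegenerateColumnError` naming any zero-variance column.
    """
    x = matrix.values.copy()
    for j, flag in enumerate(matrix.transform_flags):
        if flag:
            x[:, j] = np.log10(x[:, j])
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [matrix.function_names[j] for j in bad]
        raise DegenerateColumnError(f"zero-variance column(s): {names}")
    z = (x - x.mean(axis=0)) / sd
    return MultifunctionalityResult(
        z_matrix=z, mf=z.mean(axis=1), included_functions=list(matrix.function_names)
    )


def averaging_index(z_matrix: np.ndarray) -> np.ndarray:
    """Row means of a standardized sites x functions matrix."""
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim == 1:
        return z.copy()
    return z.mean(axis=1)


def simplified_function_columns(
    columns: list[str] | tuple[str, ...] | None = None,
) -> list[str]:
    """The 5-function simplified variant (drops total N and total P)."""
    from .synthetic import FUNCTION_COLUMNS

    columns = columns or FUNCTION_COLUMNS
    return [c for c in columns if c not in SIMPLIFIED_EXCLUDED]


def multifunctionality(
    table: pd.DataFrame,
    variant: str = "full7",
    columns: list[str] | None = None,
) -> MultifunctionalityResult:
    """Averaging multifunctionality index from a site table.

    ``variant`` is ``"full7"`` (all seven nutrient-pool functions) or
    ``"simplified5"`` (excluding total N and total P).
    """
    from .synthetic import FUNCTION_COLUMNS

    if columns is None:
        if variant == "full7":
            columns = list(FUNCTION_COLUMNS)
        elif variant == "simplified5":
            columns = simplified_function_columns()
        else:
            raise ValueError(f"unknown multifunctionality variant {variant!r}")
    return standardize(FunctionMatrix.from_table(table, columns))


def microbial_diversity_index(table: pd.DataFrame) -> np.ndarray:
    """Mean of Z-scored archaeal, bacterial, and fungal OTU richness."""
    cols = ["archaeal_richness", "bacterial_richness", "fungal_richness"]
    matrix = FunctionMatrix(
        table[cols].to_numpy(float), cols, transform_flags=[False] * 3
    )
    return standardize(matrix).mf


def estimate_bnpp(agb: float, root_biomass: float, anpp_proxy: float):
    """Belowground NPP from the biomass ratio with NDVI as the ANPP proxy.

    Assumes ANPP/BNPP ~= aboveground/root biomass, so
    BNPP = anpp_proxy * root_biomass / agb (proxy units).
    """
    agb = np.asarray(agb, dtype=float)
    root_biomass = np.asarray(root_biomass, dtype=float)
    if np.any(agb <= 0) or np.any(root_biomass <= 0):
        raise ValueError("biomass values must be positive")
    out = np.asarray(anpp_proxy, dtype=float) * root_biomass / agb
    return float(out) if out.ndim == 0 else out


_SUBTYPE_EDGES = (
    (0.35, "non-dryland"),
    (0.50, "dry-subhumid"),
    (0.80, "semiarid"),
    (0.95, "arid"),
    (1.00, "hyperarid"),
)


def classify_aridity(aridity: float) -> str:
    """Dryland subtype of an aridity (1 - AI) level, half-open upward.

    Drylands begin at 0.35; 0.80 is the semiarid/arid boundary; 0.50 and 0.95
    follow the UNEP aridity-index convention.
    """
    if not 0.0 <= aridity < 1.0:
        raise ValueError(f"aridity {aridity} outside [0, 1)")
    for edge, label in _SUBTYPE_EDGES:
        if aridity < edge:
            return label
    return "hyperarid"


def multiple_threshold_analysis(
    diversity: np.ndarray,
    matrix: FunctionMatrix,
    alpha: float = 0.05,
) -> MTResult:
    """Multiple-threshold multifunctionality analysis.

    Per-function maxima are the mean of the four largest observed values; for
    each threshold t in 1..99% a site's multifunctionality is the number of
    functions strictly surpassing t x maximum, which is regressed (OLS) on the
    diversity metric.  Tmin/Tmax are the lowest/highest significant thresholds,
    Tmde the threshold of steepest slope; Mmin/Mmax/Mmde are the fitted counts
    at the maximum observed diversity at those thresholds.
    """
    diversity = np.asarray(diversity, dtype=float)
    values = matrix.values
    n, f = values.shape
    if n < 4:
        raise ValueError("multiple-threshold analysis needs >= 4 sites")
    if diversity.shape[0] != n:
        raise ValueError("diversity length must match matrix rows")

    top4 = np.sort(values, axis=0)[-4:, :]
    max_levels = top4.mean(axis=0)

    thresholds = np.arange(1, 100)
    # counts[i, t] = number of functions with value > (t/100) * max
    cut = max_levels[None, :, None] * (thresholds[None, None, :] / 100.0)
    counts = (values[:, :, None] > cut).sum(axis=1)

    slopes = np.full(99, np.nan)
    pvals = np.full(99, np.nan)
    flags: dict[str, str] = {}
    div_sd = diversity.std(ddof=1)
    for t in range(99):
        y = counts[:, t].astype(float)
        if y.std(ddof=1) == 0 or div_sd == 0:
            slopes[t] = 0.0
            pvals[t] = np.nan
            continue
        res = stats.linregress(diversity, y)
        slopes[t] = res.slope
        pvals[t] = res.pvalue

    sig = np.flatnonzero(np.isfinite(pvals) & (pvals < alpha))
    result = MTResult(
        thresholds=thresholds,
        counts=counts,
        slopes=slopes,
        pvalues=pvals,
        max_levels=dict(zip(matrix.function_names, max_levels)),
        flags=flags,
    )
    if counts.max() == 0:
        flags["counts"] = "no function surpasses any threshold"
        return result
    if sig.size == 0:
        flags["Tmin"] = "no significant threshold"
        return result

    def fitted_at_max_diversity(t_idx: int) -> float:
        y = counts[:, t_idx].astype(float)
        res = stats.linregress(diversity, y)
        return float(res.intercept + res.slope * diversity.max())

    t_min, t_max = int(sig[0]), int(sig[-1])
    t_mde = int(sig[np.argmax(np.abs(slopes[sig]))])
    result.Tmin = float(thresholds[t_min])
    result.Tmax = float(thresholds[t_max])
    result.Tmde = float(thresholds[t_mde])
    result.Mmin = fitted_at_max_diversity(t_min)
    result.Mmax = fitted_at_max_diversity(t_max)
    result.Mmde = fitted_at_max_diversity(t_mde)
    return result


def tradeoff_screen(
    matrix: FunctionMatrix, alpha: float = 0.05, redundancy_r: float = 0.7
) -> TradeoffReport:
    """Pairwise Pearson screen for trade-offs and redundancy among functions.

    Pairs with r > ``redundancy_r`` are flagged redundant; significant negative
    correlations indicate trade-offs.  Zero-variance columns yield flagged
    undefined pairs rather than an error.
    """
    values = matrix.values
    n, f = values.shape
    if n < 3:
        raise ValueError("tradeoff screen needs >= 3 sites")
    rows = []
    sds = values.std(axis=0, ddof=1)
    for i in range(f):
        for j in range(i + 1, f):
            name_i, name_j = matrix.function_names[i], matrix.function_names[j]
            if sds[i] == 0 or sds[j] == 0:
                rows.append(
                    dict(
                        function_a=name_i, function_b=name_j,
                        r=np.nan, p=np.nan, defined=False, redundant=False,
                    )
                )
                continue
            r, p = stats.pearsonr(values[:, i], values[:, j])
            rows.append(
                dict(
                    function_a=name_i, function_b=name_j,
                    r=float(r), p=float(p), defined=True,
                    redundant=bool(r > redundancy_r),
                )
            )
    pairs = pd.DataFrame(rows)
    defined = pairs["defined"]
    sig = defined & (pairs["p"] < alpha)
    return TradeoffReport(
        pairs=pairs,
        n_pairs=len(pairs),
        n_significant_positive=int((sig & (pairs["r"] > 0)).sum()),
        n_significant_negative=int((sig & (pairs["r"] < 0)).sum()),
        n_redundant=int(pairs["redundant"].sum()),
    )
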