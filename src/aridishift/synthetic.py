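"""Seeded synthetic dryland survey and microcosm data.

The generator emulates the statistical structure of a dryland field survey
along an aridity gradient: 130 sites split over the four dryland subtypes,
soil-function columns that decline nonlinearly (on the log10 scale) with
aridity, correlated function noise, random soil-type / vegetation-type
intercepts, and a diversity -> multifunctionality signal whose standardized
coefficients change at a planted aridity change point (default 0.80, the
semiarid/arid boundary).  Everything is deterministic given the seed, so the
full downstream analysis pipeline is testable without any field data.

Planted coefficients are expressed on the log10-function scale per standard
deviation of the (Z-scored) diversity predictor; see docs/methods.md for how
this maps onto the standardized coefficients the pipeline recovers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FUNCTION_COLUMNS",
    "MICROCOSM_FUNCTION_COLUMNS",
    "DeclineSpec",
    "GeneratorConfig",
    "generate_sites",
    "generate_microcosm",
    "true_coefficient_profile",
    "write_table",
    "read_table",
]

#: The seven nutrient-pool soil functions of the field survey, in fixed order.
FUNCTION_COLUMNS = (
    "dna_conc",
    "org_C",
    "total_N",
    "ammonium",
    "nitrate",
    "total_P",
    "avail_P",
)

#: The seven process-rate functions of the moisture microcosm experiment.
MICROCOSM_FUNCTION_COLUMNS = (
    "dna_conc",
    "phosphatase",
    "invertase",
    "urease",
    "beta_glucosidase",
    "catalase",
    "respiration",
)

FUNCTION_UNITS = {
    "dna_conc": "ug g-1",
    "org_C": "g kg-1",
    "total_N": "g kg-1",
    "ammonium": "mg kg-1",
    "nitrate": "mg kg-1",
    "total_P": "g kg-1",
    "avail_P": "mg kg-1",
}

#: UNEP-convention aridity bands (aridity = 1 - AI) for the dryland subtypes.
SUBTYPE_BANDS = {
    "dry-subhumid": (0.35, 0.50),
    "semiarid": (0.50, 0.80),
    "arid": (0.80, 0.95),
    "hyperarid": (0.95, 0.99),
}

MOISTURE_LEVELS = (3, 5, 8, 10, 20, 40, 60, 80, 100, 120)
FIELD_CAPACITY = 27.6  # percent mass moisture at 100% field capacity


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class DeclineSpec:
    """Aridity trend of one soil function on the log10 scale.

    ``form`` is ``"linear"`` (single slope) or ``"segmented"`` (slope change at
    ``threshold``); ``base`` is the log10 level at the dry edge of the gradient.
    """

    form: str = "linear"
    base: float = 1.0
    slope: float = -0.5
    threshold: float | None = None
    slope_after: float | None = None

    def __post_init__(self) -> None:
        if self.form not in ("linear", "segmented"):
            raise ConfigurationError(f"unknown decline form {self.form!r}")
        if self.form == "segmented" and (
            self.threshold is None or self.slope_after is None
        ):
            raise ConfigurationError(
                "segmented decline needs 'threshold' and 'slope_after'"
            )

    def __call__(self, aridity: np.ndarray) -> np.ndarray:
        a = np.asarray(aridity, dtype=float)
        a0 = 0.35  # dryland onset; trends anchored there
        if self.form == "linear":
            return self.base + self.slope * (a - a0)
        out = self.base + self.slope * (np.minimum(a, self.threshold) - a0)
        excess = np.clip(a - self.threshold, 0.0, None)
        return out + self.slope_after * excess


def _default_declines() -> dict[str, DeclineSpec]:
    # Five functions decline with an own segmented break; nitrate and total P
    # are nearly flat (the two "less affected" pools of the survey design).
    return {
        "dna_conc": DeclineSpec("segmented", 1.3, -0.2, 0.59, -3.0),
        "org_C": DeclineSpec("segmented", 1.0, -0.25, 0.62, -2.8),
        "total_N": DeclineSpec("segmented", 0.0, -0.2, 0.70, -2.6),
        "ammonium": DeclineSpec("segmented", 0.9, -0.2, 0.87, -3.2),
        "nitrate": DeclineSpec("linear", 0.8, -0.10),
        "total_P": DeclineSpec("linear", -0.2, -0.05),
        "avail_P": DeclineSpec("segmented", 0.7, -0.15, 0.96, -3.5),
    }


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic dryland survey.

    Defaults mirror the field design the pipeline targets: 130 sites with
    12/42/56/20 sites in the dry-subhumid/semiarid/arid/hyperarid subtypes,
    a coefficient change point at aridity 0.80, and diversity effects that are
    plant-dominated below the break and microbially dominated above it.
    """

    n_sites: int = 130
    subtype_counts: dict[str, int] = field(
        default_factory=lambda: {
            "dry-subhumid": 12,
            "semiarid": 42,
            "arid": 56,
            "hyperarid": 20,
        }
    )
    aridity_range: tuple[float, float] = (0.35, 0.99)
    changepoint: float = 0.80
    beta_plant_low: float = 0.35
    beta_plant_high: float = 0.0
    beta_mic_low: float = -0.15
    beta_mic_high: float = 0.40
    function_decline: dict[str, DeclineSpec] = field(default_factory=_default_declines)
    function_correlation: float = 0.5
    sigma_resid: float = 0.25
    sigma_soil: float = 0.10
    sigma_veg: float = 0.10
    n_soil_types: int = 14
    n_veg_types: int = 4
    years: tuple[int, ...] = (2015, 2016, 2017)
    seed: int = 0

    def validate(self) -> None:
        counts = self.subtype_counts
        if sum(counts.values()) != self.n_sites:
            raise ConfigurationError(
                f"subtype counts {counts} sum to {sum(counts.values())}, "
                f"expected n_sites={self.n_sites}"
            )
        lo, hi = self.aridity_range
        if not (0.35 <= lo < hi < 1.0):
            raise ConfigurationError(
                f"aridity_range {self.aridity_range} must lie within [0.35, 1)"
            )
        if not (lo < self.changepoint < hi):
            raise ConfigurationError(
                f"changepoint {self.changepoint} outside aridity_range {self.aridity_range}"
            )
        for name in ("sigma_resid", "sigma_soil", "sigma_veg"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        f = len(self.function_decline)
        rho = self.function_correlation
        # equicorrelation matrix is PSD iff rho in [-1/(F-1), 1]
        if not (-1.0 / (f - 1) <= rho <= 1.0):
            raise ConfigurationError(
                f"function_correlation {rho} gives a non-PSD noise covariance "
                f"for {f} functions"
            )
        missing = [c for c in FUNCTION_COLUMNS if c not in self.function_decline]
        if missing:
            raise ConfigurationError(f"function_decline missing columns: {missing}")


def true_coefficient_profile(
    config: GeneratorConfig, aridity: float
) -> tuple[float, float]:
    """Planted (beta_plant, beta_mic) at an aridity level.

    Piecewise constant with a single break at ``config.changepoint``; sites at
    exactly the break take the high-aridity ("above") coefficients.
    """
    lo, hi = config.aridity_range
    if not (lo <= aridity <= hi):
        raise ValueError(
            f"aridity {aridity} outside configured range {config.aridity_range}"
        )
    if aridity >= config.changepoint:
        return (config.beta_plant_high, config.beta_mic_high)
    return (config.beta_plant_low, config.beta_mic_low)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _equicorr_noise(
    rng: np.random.Generator, n: int, k: int, sigma: float, rho: float
) -> np.ndarray:
    """Draw n x k noise with equicorrelated columns (common-factor form)."""
    if sigma == 0:
        return np.zeros((n, k))
    if rho < 0:
        cov = sigma**2 * ((1 - rho) * np.eye(k) + rho * np.ones((k, k)))
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
        return rng.standard_normal((n, k)) @ chol.T
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, k))
    return sigma * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * own)


def generate_sites(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate a per-site survey table with the planted coefficient shift.

    Returns a DataFrame with one row per site: design covariates, plant and
    microbial richness, NDVI/biomass columns and the seven soil-function
    columns.  Deterministic given ``config.seed``; subtype counts are exact.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.aridity_range

    # aridity drawn uniformly within each subtype's band (clipped to range)
    aridity_parts = []
    subtype_parts = []
    for subtype, count in config.subtype_counts.items():
        b_lo, b_hi = SUBTYPE_BANDS[subtype]
        b_lo, b_hi = max(b_lo, lo), min(b_hi, hi)
        if count > 0 and not b_lo < b_hi:
            raise ConfigurationError(
                f"subtype {subtype} band empty within aridity_range"
            )
        aridity_parts.append(rng.uniform(b_lo, b_hi, size=count))
        subtype_parts.extend([subtype] * count)
    aridity = np.concatenate(aridity_parts)
    subtype = np.array(subtype_parts)
    n = config.n_sites

    # design covariates: geography loosely tied to aridity, plus survey labels
    latitude = rng.uniform(35.9, 50.7, size=n)
    longitude = rng.uniform(76.6, 122.4, size=n)
    elevation = np.clip(rng.normal(1300, 600, size=n), 200, 3600)
    year = rng.choice(np.asarray(config.years), size=n)
    soil_type = np.array(
        [f"soil_{i:02d}" for i in rng.integers(0, config.n_soil_types, size=n)]
    )
    veg_type = np.array(
        [f"veg_{i}" for i in rng.integers(0, config.n_veg_types, size=n)]
    )
    soil_pH = np.clip(rng.normal(7.8 + 0.8 * (aridity - 0.5), 0.4), 6.0, 10.0)
    clay = np.clip(rng.normal(18 - 10 * (aridity - 0.35), 5), 1.0, 45.0)

    # richness: rounded log-normal draws; plant decline steeper than microbial
    rel = (aridity - lo) / (hi - lo)
    log_plant = rng.normal(1.55 - 1.1 * rel, 0.15)
    plant_richness = np.maximum(1, np.round(10**log_plant)).astype(int)
    log_arch = rng.normal(2.6 - 0.25 * rel, 0.12)
    log_bact = rng.normal(3.35 - 0.20 * rel, 0.10)
    log_fung = rng.normal(2.95 - 0.30 * rel, 0.12)
    archaeal_richness = np.maximum(0, np.round(10**log_arch)).astype(int)
    bacterial_richness = np.maximum(0, np.round(10**log_bact)).astype(int)
    fungal_richness = np.maximum(0, np.round(10**log_fung)).astype(int)
    saprotroph_richness = rng.binomial(fungal_richness, 0.45)
    pathogen_richness = rng.binomial(fungal_richness, 0.15)
    symbiont_richness = rng.binomial(fungal_richness, 0.08)

    # vegetation structure
    perennial_cover = np.clip(rng.normal(0.65 - 0.55 * rel, 0.08), 0.02, 0.95)
    ndvi = np.clip(rng.normal(0.55 - 0.45 * rel, 0.05), 0.02, 0.9)
    agb = np.exp(rng.normal(4.8 - 1.8 * rel, 0.3))
    root_biomass = np.exp(rng.normal(5.3 - 1.2 * rel, 0.3))

    # diversity signal with the planted piecewise-constant coefficient profile
    zp = _zscore(np.log10(plant_richness))
    zm = (
        _zscore(archaeal_richness.astype(float))
        + _zscore(bacterial_richness.astype(float))
        + _zscore(fungal_richness.astype(float))
    ) / 3.0
    zm = _zscore(zm)
    high = aridity >= config.changepoint
    beta_p = np.where(high, config.beta_plant_high, config.beta_plant_low)
    beta_m = np.where(high, config.beta_mic_high, config.beta_mic_low)
    signal = beta_p * zp + beta_m * zm

    # random intercepts: one draw per label, shared by sites with that label
    soil_levels = np.unique(soil_type)
    veg_levels = np.unique(veg_type)
    u_soil = dict(
        zip(soil_levels, config.sigma_soil * rng.standard_normal(len(soil_levels)))
    )
    u_veg = dict(
        zip(veg_levels, config.sigma_veg * rng.standard_normal(len(veg_levels)))
    )
    ranef = np.array([u_soil[s] for s in soil_type]) + np.array(
        [u_veg[v] for v in veg_type]
    )

    funcs = list(FUNCTION_COLUMNS)
    noise = _equicorr_noise(
        rng, n, len(funcs), config.sigma_resid, config.function_correlation
    )
    data = {
        "site_id": [f"site_{i:03d}" for i in range(n)],
        "aridity": aridity,
        "subtype": subtype,
        "latitude": latitude,
        "longitude": longitude,
        "elevation": elevation,
        "year": year,
        "soil_type": soil_type,
        "vegetation_type": veg_type,
        "soil_pH": soil_pH,
        "clay": clay,
        "perennial_cover": perennial_cover,
        "plant_richness": plant_richness,
        "archaeal_richness": archaeal_richness,
        "bacterial_richness": bacterial_richness,
        "fungal_richness": fungal_richness,
        "saprotroph_richness": saprotroph_richness,
        "pathogen_richness": pathogen_richness,
        "symbiont_richness": symbiont_richness,
        "ndvi": ndvi,
        "agb": agb,
        "root_biomass": root_biomass,
    }
    for j, name in enumerate(funcs):
        decline = config.function_decline[name]
        log10_value = decline(aridity) + signal + ranef + noise[:, j]
        data[name] = 10.0**log10_value

    table = pd.DataFrame(data)
    table.attrs["units"] = dict(FUNCTION_UNITS)
    table.attrs["config"] = config_to_dict(config)
    return table


def generate_microcosm(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate the 10-moisture-level x 3-replicate microcosm table.

    Microbial richness follows a negative quadratic in moisture content;
    process-rate functions rise with moisture but are depressed at 120% field
    capacity, and the microbial-diversity signal on functions is stronger at
    and below 20% field capacity (the dry-side regime).
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))

    levels = np.repeat(MOISTURE_LEVELS, 3)
    replicate = np.tile([1, 2, 3], len(MOISTURE_LEVELS))
    n = len(levels)

    mc_mean = np.maximum(1.9, FIELD_CAPACITY * levels / 100.0)
    moisture_content = mc_mean + 0.02 * mc_mean * rng.standard_normal(n)

    # negative quadratic richness response, peak near 60% field capacity
    peak = 0.6 * FIELD_CAPACITY
    quad = -((mc_mean - peak) ** 2) / (FIELD_CAPACITY**2)
    log_arch = rng.normal(2.4 + 0.3 * quad, 0.05)
    log_bact = rng.normal(3.2 + 0.8 * quad, 0.04)
    log_fung = rng.normal(2.7 + 0.8 * quad, 0.05)
    arch = np.maximum(0, np.round(10**log_arch)).astype(int)
    bact = np.maximum(0, np.round(10**log_bact)).astype(int)
    fung = np.maximum(0, np.round(10**log_fung)).astype(int)

    zm = (
        _zscore(arch.astype(float))
        + _zscore(bact.astype(float))
        + _zscore(fung.astype(float))
    ) / 3.0
    if zm.std(ddof=1) > 0:
        zm = _zscore(zm)

    dry = levels <= 20
    coef = np.where(dry, 0.30, 0.05)  # stronger diversity signal below 20% FC
    suppress = np.where(levels == 120, -0.12, 0.0)  # waterlogging penalty

    data = {
        "moisture_level": levels,
        "replicate": replicate,
        "moisture_content": moisture_content,
        "archaeal_richness": arch,
        "bacterial_richness": bact,
        "fungal_richness": fung,
    }
    base = {
        "dna_conc": 0.6,
        "phosphatase": 1.2,
        "invertase": 1.0,
        "urease": 0.8,
        "beta_glucosidase": 0.9,
        "catalase": 1.1,
        "respiration": 0.5,
    }
    for name in MICROCOSM_FUNCTION_COLUMNS:
        mean = base[name] + 0.55 * np.log10(mc_mean / 2.0) + suppress + coef * zm
        log10_value = mean + config.sigma_resid * 0.2 * rng.standard_normal(n)
        data[name] = 10.0**log10_value
    table = pd.DataFrame(data)
    table.attrs["config"] = config_to_dict(config)
    return table


# ---------------------------------------------------------------------------
# serialization


def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["function_decline"] = {
        k: dataclasses.asdict(v) for k, v in config.function_decline.items()
    }
    d["years"] = list(config.years)
    d["aridity_range"] = list(config.aridity_range)
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "function_decline" in d:
        d["function_decline"] = {
            k: DeclineSpec(**v) for k, v in d["function_decline"].items()
        }
    if "years" in d:
        d["years"] = tuple(d["years"])
    if "aridity_range" in d:
        d["aridity_range"] = tuple(d["aridity_range"])
    return GeneratorConfig(**d)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a generated table as CSV plus a JSON sidecar with config/units."""
    path = Path(path)
    table.to_csv(path, index=False)
    meta = {k: v for k, v in table.attrs.items()}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1, default=str)
    )


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_table`, restoring metadata."""
    path = Path(path)
    table = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        table.attrs.update(json.loads(sidecar.read_text()))
    return table
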