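# aridishift

Dryland ecosystems deliver multiple soil functions at once — carbon and
nutrient storage, microbial biomass, plant-available N and P — and both plant
diversity and soil microbial diversity help sustain them.  Along an aridity
gradient the relative importance of the two can shift: plant richness tends to
track soil multifunctionality where water is less limiting, while microbial
diversity takes over under strong aridity.  `aridishift` is a Python library
for detecting and localizing that shift in site-level survey data, plus a
seeded synthetic-data generator that plants a known shift so every stage of
the analysis can be validated end to end without any field data.

It is written for ecologists and biostatisticians working with gradient
surveys (one row per site: aridity, diversity metrics, several soil-function
measurements) and for method developers who need a tested reference
implementation of the full protocol.

## What it computes

- **Multifunctionality indices.** The averaging index
  `MF_i = (1/F) Σ_j z_ij`, where `z_ij` is the Z-score of (log10-transformed)
  function `j` at site `i`; a simplified 5-function variant; the
  multiple-threshold analysis (counts of functions exceeding t% of their
  top-4 maximum for t = 1..99, with the `Tmin/Tmax/Tmde` and `Mmin/Mmax/Mmde`
  summary indices); the soil microbial diversity index (mean Z-score of
  archaeal, bacterial, and fungal OTU richness); BNPP from the biomass ratio
  `ANPP/BNPP ≈ AGB/root biomass` with NDVI as the ANPP proxy; and a pairwise
  Pearson trade-off/redundancy screen.
- **Aridity-threshold detection.** Linear vs quadratic vs penalized-spline
  GAM trend comparison with the ΔAIC > 2 rule; step / segmented / stegmented
  change-point regressions fitted by exhaustive grid search
  (`y = β₀ + β₁·1[x>c]`, `y = β₀ + β₁x + β₂(x−c)·1[x>c]`, and both combined);
  a Gaussian-mixture modality screen; and bootstrap side-regression
  validation with Mann–Whitney U comparisons of slopes and predictions at
  the break.
- **Mixed models.** `MF ~ year + diversity + aridity + interactions + ... +
  (1|soil type) + (1|vegetation type)` fitted by REML, with sequential
  (type-I) F tests, Satterthwaite denominator degrees of freedom, VIF
  screening, Nakagawa marginal/conditional R², and singular-fit handling;
  plus per-taxon OLS regressions within the regions below and above the
  aridity split (default 0.80).
- **Moving-window analysis.** Overlapping 60-site windows along the sorted
  gradient; within each window the standardized coefficients of the
  simplified model are bootstrapped (site resampling); per-term coefficient
  trajectories, indexed by window-mean aridity, are smoothed with a P-spline
  GAM and screened for change points with the same threshold protocol.
- **Synthetic data.** A 130-site generator (12 dry-subhumid / 42 semiarid /
  56 arid / 20 hyperarid sites) with nonlinearly declining functions,
  correlated function noise, crossed random intercepts, and a
  piecewise-constant diversity-coefficient profile that switches at aridity
  0.80; and a 10-moisture-level × 3-replicate microcosm table.

## Worked example

```sh
python examples/moving_window_shift.py
```

```
71 windows (70 one-site shifts)
plant_richness               sig+ window aridity 0.62-0.85    trajectory break ~ 0.771
microbial_index              sig+ window aridity 0.73-0.92    trajectory break ~ 0.771
aridity:microbial_index      sig+ window aridity 0.62-0.92    trajectory break ~ 0.810
```

Reading this: 130 generated sites give 71 overlapping 60-site windows.  The
plant-richness coefficient is significantly positive only while windows still
contain low-aridity sites, the microbial-index coefficient becomes
significantly positive from window-mean aridity ≈ 0.73 upward, and the
change-point screen on the aridity × microbial-index trajectory places the
break at 0.810 — close to the planted 0.80.  The other example scripts
(`simulate_survey.py`, `multifunctionality_indices.py`,
`aridity_thresholds.py`, `mixed_model_table.py`, `region_split.py`,
`microcosm_moisture.py`) each demonstrate one capability the same way.

A thin CLI wraps the same pipeline:

```sh
aridishift simulate --seed 7 --out sites.csv
aridishift moving-window --input sites.csv --window 60 --bootstrap 500 --seed 7
aridishift all --seed 7 --outdir run1
```

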