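"""Moisture-manipulation microcosm: diversity-function coupling when dry.

Generates the 10-level x 3-replicate microcosm table and regresses the
process-rate multifunctionality on the microbial diversity index within the
dry (<= 20% field capacity) and wet (> 20%) regimes.
"""

import numpy as np
from scipy import stats

from aridishift import (
    FunctionMatrix,
    GeneratorConfig,
    generate_microcosm,
    standardize,
)
from aridishift.synthetic import MICROCOSM_FUNCTION_COLUMNS

table = generate_microcosm(GeneratorConfig(seed=7))
print(f"{len(table)} microcosms, moisture content "
      f"{table['moisture_content'].min():.1f}-"
      f"{table['moisture_content'].max():.1f}% of soil mass")

mf = standardize(FunctionMatrix.from_table(table, MICROCOSM_FUNCTION_COLUMNS)).mf
cols = ["archaeal_richness", "bacterial_richness", "fungal_richness"]
mic = standardize(
    FunctionMatrix(table[cols].to_numpy(float), cols, [False] * 3)
).mf

dry = table["moisture_level"] <= 20
for name, mask in (("dry (<=20% FC)", dry), ("wet (>20% FC)", ~dry)):
    fit = stats.linregress(mic[np.asarray(mask)], mf[np.asarray(mask)])
    print(f"{name}: slope {fit.slope:+.3f} (P={fit.pvalue:.3g}, n={mask.sum()})")

# The planted structure couples microbial diversity to the process rates
# more tightly below 20% field capacity — the microcosm analogue of the
# field shift at aridity ~0.8.
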