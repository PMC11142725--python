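"""Western-blot band quantities to total GTPase concentrations.

Converts band-intensity ratios (sample band vs a control protein of known
loaded mass) into intracellular molar concentrations, assuming the lysate
represents 1.5 million cells of 10 um diameter and a GTPase molecular
weight of 21 kDa.  This is the route by which the model's total Cdc42,
Rac and Rho concentrations (4.4, 2.4 and 4.0 uM) were obtained.
"""

import pandas as pd

from abpolar.quantify import quantify_table

# synthetic band table: ratios chosen to illustrate the pipeline; the gel
# receives ~0.1% of the total lysate protein
bands = pd.DataFrame({
    "protein": ["Cdc42", "Rac1", "RhoA"],
    "band_ratio": [0.68, 0.37, 0.62],
    "control_mass_pg": [106.5, 22.5, 106.5],
    "lysate_fraction_loaded": [1e-3, 1e-3, 1e-3],
})

print(quantify_table(bands).round(3).to_string(index=False))
print("\nconcentration_uM = band mass per cell / (MW * N_A * cell volume)")
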