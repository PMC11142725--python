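"""Integrin threshold: polarization needs a minimum trigger amplitude.

Sweeps the peak of the initial active-integrin profile from 10 to 30 uM
(coarse 2-uM steps here; use 1-uM steps for the exact threshold) and
prints, per amplitude, whether the downstream outputs polarize.  Below the
threshold the initial integrin kick is too weak to flip the basal region
into the Rac-dominant state, so the GTPase wave never launches.
"""

import numpy as np

from abpolar import GridSpec, ModelParameters
from abpolar.perturbation import SWEEP_VERDICT_OUTPUTS, integrin_sweep

params = ModelParameters()
grid = GridSpec()

amplitudes = np.arange(10.0, 31.0, 2.0)
sweep = integrin_sweep(params, grid, amplitudes)

print("amplitude (uM)  Rac dP%  Rho dP%  Par dP%  polarized")
for amp, res in zip(sweep.amplitudes_uM, sweep.results):
    verdict = all(res.outputs[o].polarized for o in SWEEP_VERDICT_OUTPUTS)
    print(f"{amp:14.0f} {res.outputs['R_a'].delta_p_percent:8.1f}"
          f" {res.outputs['rho_a'].delta_p_percent:8.1f}"
          f" {res.outputs['P_C'].delta_p_percent:8.1f}   {verdict}")
print(f"\nsmallest polarized amplitude on this grid: {sweep.threshold_uM} uM")
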