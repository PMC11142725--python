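# abpolar

A 1D reaction–diffusion model of apical–basal polarization in renal
epithelial cells, with the analyses built around it: polarization scoring,
a multiparametric sensitivity analysis, integrin-threshold sweeps and
in-silico Rho-GTPase degradation/upregulation experiments.

## The scientific problem

Renal epithelial cells organize an apical (lumen-facing) and a basal
(matrix-facing) membrane domain. The polarity axis is set by outside-in
integrin signaling: ECM-bound integrins activate Rac at the basal side,
Rac and Rho mutually inhibit each other, Rho activates Cdc42, and Cdc42
promotes assembly of the apical Par complex, which is in mutual
antagonism with the basolateral Scribble complex. Loss of this
organization is an early step of epithelial-to-mesenchymal transition
(EMT), relevant to renal fibrosis and cancer.

The model tracks twelve concentration fields on the axis `0 ≤ x ≤ L`
(basal at `x = 0`): active/inactive integrin (I_a, I_i), active/inactive
Cdc42, Rac, Rho (C_a/C_i, R_a/R_i, ρ_a/ρ_i) and bound/unbound Par and
Scribble (P_C/P_un, S_C/S_un). Each family obeys a pair of
reaction–diffusion equations with exactly antisymmetric exchange terms,
for example for active Rac

```
∂R_a/∂t = (α_I I_a + I_R) / (1 + (ρ_a/β_ρ)^n + (P_C/β_PR)^n) · (R_i/R_tot)
          − δ_R R_a + D_Ra ∂²R_a/∂x²
```

with Hill-type inhibition (coefficient `n = 4`), membrane-bound species
diffusing slowly (0.1–0.2 µm²/s) and cytosolic species quickly
(2–10 µm²/s). Mass conservation per family plus bistable kinetics make
this a wave-pinning system: a sufficiently strong integrin trigger
launches an activation front that stalls mid-cell, producing a stable
polarized pattern. The equations are integrated by explicit Euler with
central differences and conservative zero-flux boundaries
(31 nodes, dt = 0.005 s by default).

## A worked example

```python
from abpolar import (ModelParameters, GridSpec, simulate,
                     polarization_result, steady_state_time)

params, grid = ModelParameters(), GridSpec()
traj = simulate(params, grid, t_end=100.0)
res = polarization_result(traj.final_state, traj.final_state,
                          steady_time=steady_state_time(traj))
print(res.to_frame()[["basal_uM", "apical_uM", "difference_uM"]].round(4))
```

prints the polarized steady state after 100 s of model time:

```
        basal_uM  apical_uM  difference_uM
output
I_a       9.4898     0.0000         9.4898
R_a       7.1544     0.0040         7.1503
rho_a     0.0105     1.9728         1.9623
C_a       0.2833     2.6782         2.3949
P_C       0.0003     1.3576         1.3574
S_C       1.4102     0.0007         1.4094
```

Active Rac accumulates at the basal pole (driven by the ECM-bound
integrins there), Rho and Cdc42 at the apical pole (mutual Rac/Rho
inhibition), and the polarity complexes segregate: Par apical, Scribble
basal. The detected steady-state time is ≈ 77 s.

Short narrative scripts in `examples/` cover each capability: the
baseline run, the integrin-threshold sweep, the degradation protocol, the
sensitivity analysis and the western-blot concentration calculation. A
thin CLI wraps the same functions
(`abpolar simulate|sweep-integrin|perturb|mpsa|blot-calc`), writing tidy
CSV/JSON plus a run manifest.

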