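# Methods

## Model

The cell is a 1D segment of length L = 10 µm along the apical–basal axis;
`x = 0` is the basal membrane in contact with the extracellular matrix,
`x = L` the apical membrane. Twelve fields evolve by reaction–diffusion:
six protein families (integrin, Cdc42, Rac, Rho, Par, Scribble), each
split into two fractions whose exchange terms are exactly antisymmetric,
so reactions conserve every family's total.

Signaling structure: integrin activation (rate I_I · I_i / I_tot) operates
only where the membrane touches the ECM; active integrin is immobile
(ECM-bound) while every other species diffuses. Active integrin activates
Rac (α_I); Rac and Rho inhibit each other through Hill terms
1/(1 + (c/β)^n) with n = 4; Rho activates Cdc42 (α_ρ); Cdc42 promotes Par
binding (α_C); bound Par and Scribble suppress each other's binding, and
Par additionally inhibits Rac. Inactive/unbound pools enter their
activation terms as saturating fractions (e.g. C_i / C_tot).

Two Hill constants appear in the Rac equations with slightly different
symbols in different places; the model uses a single Par-on-Rac constant
(β_PR = 2.0 µM) in both members of the conjugate pair, which is required
for the pair's source terms to cancel exactly.

### Parameters

Defaults (all strictly positive; units µM, s⁻¹, µM s⁻¹, µm² s⁻¹):

| group | values |
|---|---|
| totals | C_tot 4.4, R_tot 2.4, ρ_tot 4.0, P_tot = S_tot 1.6, I_tot 30 |
| activation inputs | I_C 0.5, I_R 0.5, I_ρ 3.3, I_I 10 |
| decay / off rates | δ_C = δ_R = δ_ρ = δ_I 1.0, k_off,P = k_off,S 2.0 |
| cross-activation | α_ρ = α_C 2.5, α_I 1.5 |
| inhibition constants | β_R 1.5, β_ρ 0.7, β_PR 2.0, β_SP = β_PS 0.2 |
| binding on-rates | k_on,P 0.5, k_on,S 4.0 |
| diffusion | active GTPases 0.1, inactive 10, complexes 0.2, unbound 2.0, inactive integrin 10 |

The GTPase totals derive from quantitative immunoblotting of MDCK lysates
(see the blot-to-concentration module); kinetic constants are adapted
from earlier Rho-GTPase crosstalk models, with the Par/Scribble binding
kinetics taken from the Par-complex literature.

### Initial and boundary conditions

Active integrin starts on the ECM-adjacent sixth of the domain with
I_a(x) = (1/x²)·e^(1/x²−1)·I_tot for node rank x = 1…5 of the reference
31-node grid (exactly I_tot at the boundary node, ≈ 3.54 µM at the
second), zero elsewhere; the same region forms the activation mask. On
other resolutions each of the five values extends over its ~1/3-µm slab
(piecewise-constant interpolation). This choice matters: the profile is
steep, so point-sampling it on a finer grid loses almost half of the
spatially integrated trigger, the wave then fails to launch for ≥ 80
subdomains, and mesh convergence is lost; the slab reading preserves the
trigger integral and gives 30-vs-100-subdomain agreement within 2% on
all outputs. Active GTPases and bound complexes
start uniform (C_a 0.8, ρ_a 1.0, R_a 1.75, P_C = S_C 0.6 µM) with the
inactive/unbound pool making up each family total per node. All
diffusible species obey zero-flux boundaries. Note that R_a(x,0) =
1.75 µM is ~73% of R_tot, well above the ~30% GTP-bound fraction typical
of epithelial measurements — an internal tension in the baseline
parameterisation; the tabulated values are used verbatim.

The domain length is inferred: the cue region is stated to be five nodes
= one-sixth of the domain ≈ 1.67 µm, giving dx ≈ 1/3 µm and L = 10 µm,
consistent with the 10-µm cell diameter used in the concentration
calculation.

## Numerics

Explicit (forward-Euler) time stepping with second-order central
differences; dt = 0.005 s and 30 subdomains (31 nodes) are within the
diffusive stability bound dt ≤ dx²/(2 D_max) ≈ 0.0056 s and are verified
mesh- and step-converged by the test suite (≤ 5% against 100 subdomains,
≤ 1% against dt = 0.001 s). The boundary rows of the Laplacian use the
one-sided zero-flux closure ((f₁−f₀)/dx² and its mirror), which makes the
discrete operator exactly conservative — family totals drift < 10⁻⁸
relative over a full run. Hill inputs are clipped at zero before
exponentiation; negative round-off after a step is clipped to zero and
logged when it exceeds 10⁻⁸ µM. A step that drives any field below
−10³ µM raises an integration error naming the species and node (used to
flag blown-up parameter sets during ensemble runs; the time step is not
adapted per sample, keeping the design uniform).

## Polarization scoring

An output's apical and basal concentrations are read at the last and
first grid node. The delta-P statistic is the absolute apical–basal
difference as a percentage of the same difference in the
baseline-parameter reference run; an output is polarized when
delta-P > 20% (strict; the bound itself counts as unpolarized).
Steady state is detected from 1-s snapshots as the earliest time after
which the max-norm change per second of the bound Par and Scribble
fields, relative to the field magnitude, stays below a tolerance. The
default tolerance is 10⁻³ s⁻¹: on the baseline run this detects ≈ 77 s,
matching the model's known ~80-s settling behavior, whereas 10⁻⁴ s⁻¹
would not fire until ≈ 109 s. The tolerance is a free choice — no
criterion is imposed by the model itself — and is exposed as a
parameter.

## Integrin-threshold sweep

The sweep varies the peak of the exponential initial active-integrin
profile (the boundary node starts at exactly the amplitude A, with
I_i = I_tot − I_a per node); all rate parameters, including I_tot in the
activation kinetics, stay at baseline. The amplitude then acts purely as
the size of the trigger that selects between the homogeneous and the
wave-pinned attractor, so above the threshold the final state coincides
with the baseline run — the strength of polarization is independent of
the amplitude, and the threshold is sharp (18 µM on a 1-µM grid). The
alternative reading in which the integrin total scales jointly with the
profile shifts the threshold to 19 µM and leaves a slight amplitude
dependence in basal Rac; the profile-only reading is used.

A caveat established during development: below the threshold the three
GTPases homogenize, but the Par/Scribble pair — itself a bistable
mutual-inhibition system at these constants — amplifies the minute
transient Cdc42 gradient into a pinned front of its own (a 10⁻⁶ µM seed
on an otherwise uniform state suffices). The sweep's overall verdict
therefore requires all five downstream outputs (Rac, Rho, Cdc42, Par,
Scribble) to clear the 20% bound, not the polarity complexes alone;
per-output results are returned so users can apply other verdicts.

## Degradation / upregulation protocol

Three phases of 100 s each: free dynamics to a polarized steady state; a
ramp in which the targeted GTPase's active amount follows
100 + a(1 − e^(−0.043(t−100))) percent of its steady-state amount
(a ∈ {−100, −80, …, +100}); a hold in which both fields of the target
are frozen (it still enters the other species' rate laws). The ramp is
enforced after each Euler step by rescaling the active field so its
node-sum tracks the prescribed curve exactly (shape preserved), and the
effective total in the target's own saturating kinetics is the baseline
constant scaled by the family's remaining-mass fraction. With a = 0 this
reduces to the unperturbed dynamics (verified to 10⁻⁹ µM). Degraded
protein is removed from the system; upregulated protein is added in
active form; untargeted families remain conserved to 10⁻⁸.

Enforcement alternatives were evaluated: multiplying the active field by
the per-step profile ratio without removing reaction-regenerated protein
lets the GTPase pools re-fill during the ramp, and complete Rho
degradation then fails to collapse the Par front — inconsistent with the
protocol's intent of imposing the prescribed curves. The node-sum pinning
is therefore used.

Known edge: the Par front collapses when apical active Cdc42 stays below
≈ 23% of its steady-state level for on the order of 100 s, and the −80%
prescription ends at 21.1% — just inside the collapse region. In this
implementation the Cdc42 −80% run therefore loses Par/Scribble polarity,
while Rac and Rho tolerate every partial level; small changes in the
boundary discretization can move a run across this knife-edge, and the
degradation tests document the behavior of this implementation.

## Sensitivity analysis (MPSA)

21 interaction parameters are Latin-hypercube sampled uniformly on
[0.2 v, 5 v] around their baselines (3000 samples at full scale; the test
suite uses 300); 21 dummy variables with baseline 1 are sampled
identically but never enter the model. Each run's six outputs are labeled
accepted (delta-P > 20%) or unaccepted; per parameter and output the
Kolmogorov–Smirnov distance between the accepted and unaccepted
empirical distributions (each CDF normalized by its own count) measures
influence, and the per-output significance threshold is the largest dummy
distance. Parameter sets whose explicit integration blows up are labeled
unaccepted and flagged, but excluded from the K-S computation: their
labels reflect solver failure, not a model outcome, and retaining them
attributes spurious influence to any parameter that merely stiffens the
kinetics (visible as the causally isolated integrin output appearing
sensitive to the downstream-only α_I). At 300 samples, ~7% of sets are
flagged.

## What the defaults emulate, and limits

The default configuration is the baseline study condition itself — no
synthetic noise is added anywhere; every experiment is deterministic
apart from the LHS seed. The model abstracts GEF/GAP intermediates,
phosphoinositides, vesicle trafficking, junction formation and
mechanics; its ~80-s polarization time scale is accordingly orders of
magnitude faster than polarization of real epithelia, and passing tests
validate the reaction–diffusion mechanism, not cellular time scales.
1D geometry means "apical/basal concentration" is a boundary-node value;
where exactly a real cell's readout would be taken is outside the model.
Test problem sizes (300-sample MPSA, 1-µM sweep grid, 100-s runs) are the
package's default reduced-scale settings; the full-scale design is a
parameter change away.
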