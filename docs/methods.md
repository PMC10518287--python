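# Methods

## Model structure

The organ is treated as $n$ identical Krogh units in parallel; all transport
is resolved at the level of one unit and every reported resistance is
normalized so that $n$ cancels. A unit is a hexagonal tissue prism of
apothem $r_k$ (half the intercapillary distance) around a central capillary
(radius $r_c$, length $l_c$). Only part of the tissue volume takes part in
osmotic water exchange; that active volume is modelled as an inner hexagonal
prism of apothem $r_a$, and the osmotically inactive fraction $V_b$ follows
from $(r_a, r_k, r_{c0})$. Because the unit's outer boundary is fixed by
symmetry, active-volume changes are absorbed by the capillary lumen:

    r_c(t) = sqrt((2*sqrt(3)*r_a^2 - V(t)/l_c) / pi)

and laminar (Poiseuille) flow makes the baseline-normalized structural
resistance (r_c0/r_c)^4. Perfusion resistance — what a rig measures as
pressure/flow — is the structural resistance times the perfusate's relative
viscosity.

State variables of a loading run are the active volume $V$ and the tissue
CPA concentration $C_t$:

* **Water balance** — the Kedem–Katchalsky volume flux,
  $dV/dt = S L_p [\Delta P - R_g T(\Delta C_{is} + \sigma \Delta C_{cpa})]$,
  with the full impermeant and CPA concentration differences.
* **CPA balance** — a diffusive relaxation over the fixed isotonic active
  volume, $dC_t/dt = S_0\,\omega R_g T (C_f - C_t)/V_0$.

The CPA balance deserves comment, because it is a deliberate design choice.
The package treats $(\omega, \sigma, L_p, r_a)$ as *effective organ-level
constants*: they lump capillary walls, cell membranes, and extracellular
diffusion, and they are fitted by matching exactly this model to perfusion
data. Using them inside a stricter mole-bookkeeping scheme — where the
solute amount $n_{cpa}$ is integrated with the solvent-drag term
$J_v(1-\sigma)\bar{C}$ and the concentration is re-derived from the
shrinking volume — changes the late-time uptake kinetics materially (the
transient shrink at the full-strength step alone concentrates the tissue by
tens of percent) and, with the packaged parameter values, overpredicts both
the final tissue concentration and the accumulated toxicity of the
reference protocols. The concentration-relaxation form is therefore the
default (`SimSettings.solute_update="concentration"`), and the full
mole-bookkeeping Kedem–Katchalsky form remains available
(`solute_update="moles"`) for sensitivity analysis. For the same reason the
membrane exchange area defaults to the fixed isotonic area
(`surface_mode="fixed"`, $S_0 = 2\pi r_{c0} l_c$), with an
instantaneous-area option. `kk_fluxes` itself always evaluates the complete
Kedem–Katchalsky pair, including solvent drag.

Other assumptions: ideal osmometry (osmotic coefficient 1); the CPA
cocktail is a single permeant species; the capillary fluid concentration
equals the arterial inlet concentration (no axial depletion); the carrier's
impermeant background is constant during loading; all parameters are fixed
at 4 °C. The transmembrane hydraulic term defaults to zero: at molar CPA
the osmotic term is ~2.3 MPa per molar while perfusion pressures are ~5 kPa
(40 mmHg), so pressure schedules are recorded on the protocol but inert in
the transport by default.

## Parameters

| symbol | meaning | default | units |
| --- | --- | --- | --- |
| r_c0 | isotonic capillary radius | 3e-6 | m |
| r_k | unit (hexagon) apothem | 7.5e-6 | m |
| l_c | capillary length | 55e-6 | m |
| r_a | active-volume apothem | 3.86e-6 | m (fitted per organ) |
| L_p | hydraulic conductivity | 1.5e-14 | m^3/(N s) |
| omega | CPA permeability | 7.0e-13 | mol/(N s) |
| sigma | reflection coefficient | 0.10 | — |
| alpha | toxicity exponent | 3.12 | — |
| beta | toxicity prefactor | 9.39e-6 | 1/min per M^alpha |
| M_iso | isotonic osmolarity | 290 | mol/m^3 |

The defaults are the rat-kidney reference set for the 8.4 M VMP cocktail at
4 °C, packaged in `cryoperf/data/defaults.json`. The toxicity power law is
evaluated with concentration in mol/L and time in minutes (beta's implied
units); the simulator converts from SI at that boundary. The geometric
defaults imply an isotonic active volume $V_0 = 1.284\times10^{-15}$ m³ per
unit and an inactive fraction $V_b = 0.86$.

With these values the two relaxation times that shape every loading run are
~2 min for water and ~13 min for CPA, which is why full-strength holds of
~25 min are needed to close the last ~0.5 M of the concentration gap.

## Estimation pipeline

Estimation is staged, mirroring the experiments that define the parameters:

1. **r_a** — steady resistances at ≥ 2 perfusate osmolarities; ordinary
   least squares of $1/\sqrt{R}$ on $M_{iso}/M$. Only the slope/intercept
   ratio is used (it is invariant to resistance normalization and to the
   unknown unit count $n$). Steady levels are extracted as the mean of a
   terminal window (default 3 min) guarded by a drift threshold.
2. **L_p** — impermeant challenge (carrier + 300 mM lactose, 15 min);
   bounded Nelder–Mead over $\log_{10} L_p \in [-16, -12]$ with three
   log-spaced starts. With no CPA in the challenge, the response depends on
   $L_p$ alone.
3. **omega, sigma** — quarter-strength CPA challenge (30 min); joint
   bounded Nelder–Mead over $(\log_{10}\omega, \sigma)$, three starts with
   seeded jitter. The dip depth of the shrink–swell transient identifies
   sigma, the recovery rate identifies omega. With $\sigma = 0$ and a
   carrier-matched challenge the volume never moves, so the resistance
   carries no information about omega; such traces are rejected as
   uninformative rather than fitted.
4. **alpha, beta** — per-concentration zero-intercept fits of
   $\ln(\text{viability})$ on exposure time (anchoring $N(0)$ at the
   control, replicates pooled), then a log–log regression of $k$ on $C$.
   The regression is inverse-variance weighted ($w = k^2/\widehat{var}(k)$
   from the stage-1 residuals): at 2.1 M the true decay over a 2-h assay is
   ~1%, below assay noise, and unweighted log-rates at such concentrations
   dominate the exponent's error. Across repeated synthetic assays the
   weighting reduces the sampling scatter of alpha from ~0.6 to ~0.15. An
   unweighted mode and a nonlinear exponential rate fit are available.

Challenge-solution viscosity enters only as a constant multiplier of the
post-switch resistance (default ratio 1.3 for quarter-strength CPA); a
wrong constant rescales but does not reshape the transient, so it biases
none of the shape-determined parameters.

## Protocol optimization

Protocols are ramp–hold–step: a 20-min carrier flush (the normalization
baseline), a linear arterial CPA ramp, a constant plateau (concentration =
rate × duration), and a step to full strength (8.4 M). The full-strength
hold is terminated when the simulated tissue concentration reaches the
vitrifiable target; the target defaults to the simulated endpoint of the
existing reference protocol rather than a hard-coded constant, so it stays
self-consistent under any parameter or model change.

Feasibility applies two osmotic limits to the volume relative to the
end-of-flush baseline: a hard floor of 45%, and at most 25 min below the
73% stress floor. The time below the stress floor is counted cumulatively
by default (a contiguous-stretch mode is provided; with the packaged
parameters the excursion below 73% is a single stretch, so the modes
coincide). The volume reference matters: the carrier is hypertonic relative
to the isotonic tissue (330 vs 290 mOsm), so the flush itself shrinks the
tissue to 88% of $V_0$, and floors referenced to $V_0$ would misclassify
validated protocols as infeasible.

The optimizer is an exhaustive, deterministic sweep (default 40–70 mM/min ×
70–120 min × 4–20 min at 1 × 5 × 1 resolution, ~5800 simulations, a few
minutes on one CPU) with plateau concentrations restricted to 3–7 M. Ties
are broken by shortest total protocol, then lowest ramp rate. The
acceptance-test variant of the sweep uses a 2 × 10 × 2 grid to stay within
a test-suite-friendly runtime; the full-resolution sweep lives in
`scripts/acceptance.py` and selects the same optimum region.

## Numerical choices

Integration uses LSODA with rtol 1e-8 by default and dense output on a 1-s
grid; protocol segments are integrated piecewise so the solver never steps
across a boundary discontinuity, and auto-holds use root-finding on the
dense solution. Volume leaving $(0, V_{max})$ (lumen closure or active
volume collapse) raises `OsmoticCollapseError` via terminal events.
Fitting loops relax rtol to 1e-6; the induced parameter error is far below
either noise or the fit tolerances. Toxicity costs are trapezoidal
integrals on the output grid; halving the grid changes the reference
protocol's final concentration and cost by < 0.01%.

## Synthetic data

The generators emulate the experiment shapes the pipeline consumes —
stepped-osmolarity plateaus (carrier, +150, +300 mM lactose), switch
transients, and slice-viability tables ({2.1, 4.2, 6.3, 8.4} M × {15, 30,
45, 60, 90, 120} min × 4 replicates). Noise defaults are a 2% CV
(multiplicative) on resistance and a 5% sd (multiplicative) on viability
fractions; real replicate variance is unknown, so these are exposed in
`SynthConfig`. All generators are pure functions of (config, seed).

What passing the recovery tests shows — and what it does not: the pipeline
inverts its own forward model under plausible noise. It does not establish
that the Krogh-unit idealization holds in a given organ (regional
heterogeneity, pump/tubing lag, assay chemistry, and edema are all outside
the generators), so parameter values fitted from real rigs should be
validated against held-out traces, as the $R^2$ diagnostics encourage.

The parameter-recovery property test draws membrane parameters from the
physically plausible sub-range ($L_p \in [10^{-15}, 10^{-13}]$, $\omega$
around $10^{-13.5}$–$10^{-12}$, $\sigma \in [0.05, 0.6]$) rather than the
full fit bounds: at the extreme of the omega bound ($10^{-10}$ mol/(N s))
the tissue equilibrates in seconds, faster than the stated trace sampling
can resolve, and no estimator could recover it from such a design.

## Known limitations

* Single effective permeant; multi-component CPA mixtures (components with
  different permeabilities) are out of scope.
* No temperature dependence; all constants are 4 °C values.
* No axial discretization of the capillary and no regional (cortex/medulla)
  heterogeneity; parameters are whole-organ effective values.
* Unloading (CPA washout) protocols are not modelled.
* The viscosity model for display of perfusion resistance is a linear
  ratio in arterial CPA concentration (slope 0.15 per molar, matching the
  1.3 ratio used for quarter-strength challenges); it does not affect
  transport or optimization.
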