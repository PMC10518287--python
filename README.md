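# cryoperf

Model-guided design of cryoprotectant (CPA) perfusion protocols for whole
organs.

Vitrifying an organ for long-term banking requires loading 8–9 M of CPA
through its vasculature — enough to suppress ice, but concentrated enough to
be chemically toxic and osmotically stressful. `cryoperf` implements a
coupled transport/toxicity model of machine perfusion at 4 °C and uses it to
design loading protocols that reach a vitrifiable tissue concentration at
minimum predicted toxicity, for researchers working on organ banking and
perfusion protocol development.

## The model

The organ is a parallel array of identical **Krogh units**: a capillary of
radius $r_c$ and length $l_c$ inside a hexagonal tissue prism (apothem
$r_k$), of which only an inner prism of apothem $r_a$ is osmotically active.
Water crosses the capillary membrane by the Kedem–Katchalsky flux law

$$J_v = S\,L_p\bigl[(P_f - P_t) - R_g T\,(\Delta C_{is} + \sigma\,\Delta C_{cpa})\bigr],$$

and the tissue CPA concentration relaxes toward the arterial value with a
permeability-set rate, $\dot C_t = S\,\omega R_g T\,(C_f - C_t)/V_0$. Since
the unit's outer boundary is fixed, active-volume changes move the capillary
lumen: vascular resistance scales as $(r_{c0}/r_c)^4$, which is what a
pressure/flow-controlled rig actually measures. That single fact makes every
model parameter measurable by perfusion alone:

* $r_a$ — from steady resistances at stepped perfusate osmolarity via the
  **organ Boyle van't Hoff equation** ($1/\sqrt{R}$ is affine in
  $M_{iso}/M$);
* $L_p$ — from the resistance transient after an impermeant (lactose)
  challenge;
* $\omega, \sigma$ — from the shrink–swell transient after a
  quarter-strength CPA challenge.

Chemical toxicity follows the **cost-function model**: viability decays as
$N/N_0 = \exp(-J_{tox})$ with $J_{tox} = \int \beta\,C_t^\alpha\,dt$, and
$(\alpha, \beta)$ are fitted from tissue-slice viability time courses.
Protocol optimization sweeps ramp–hold–step loading schedules, discards
those whose volume excursion crosses the osmotic limits (45% hard floor,
≤ 25 min below 73%), and minimizes $J_{tox}$.

## Worked example

```python
import cryoperf as cp

p = cp.default_params()          # rat-kidney reference set (VMP at 4 C)
geom, mem, tox, settings = p["geometry"], p["membrane"], p["toxicity"], p["settings"]

# the empirically developed protocol: 50 mM/min to 5 M over 100 min,
# 10 min plateau, then 25 min at full-strength 8.4 M
existing = cp.simulate_loading(cp.existing_protocol(), geom, mem, tox, settings)
print(f"final tissue CPA {existing.final_C_tissue_M:.2f} M, "
      f"J_tox {existing.J_tox:.4f}, "
      f"viability {100 * cp.viability_from_cost(existing.J_tox):.1f}%")

# the model-optimized protocol: 62 mM/min for 80 min, 5 min plateau,
# full-strength hold auto-terminated at the same vitrifiable endpoint
optimized = cp.simulate_loading(cp.optimized_protocol(), geom, mem, tox, settings,
                                target_conc_M=existing.final_C_tissue_M)
print(f"required full-strength hold {optimized.full_strength_duration_min:.1f} min, "
      f"J_tox {optimized.J_tox:.4f}, "
      f"viability {100 * cp.viability_from_cost(optimized.J_tox):.1f}%")
```

prints

```
final tissue CPA 7.88 M, J_tox 0.1274, viability 88.0%
required full-strength hold 25.9 min, J_tox 0.1158, viability 89.1%
```

The existing protocol loads the tissue to 7.88 M in 135 min with a
predicted post-loading viability of 88.0%; the optimized schedule reaches
the same vitrifiable endpoint 24 min sooner at lower predicted toxicity.
The same computations are available from the shell:

```
cryoperf simulate --protocol existing --out run.csv
cryoperf optimize --out sweep.csv
cryoperf synth slices --seed 1 --out slices.csv
cryoperf fit-toxicity --in slices.csv --params-out tox.json
```

## Layout

| module | contents |
| --- | --- |
| `cryoperf.krogh` | geometry, KK fluxes, resistance laws, loading simulator |
| `cryoperf.bvh` | organ Boyle van't Hoff fit: r_a and inactive fraction |
| `cryoperf.fitting` | L_p and (omega, sigma) fits from switch transients |
| `cryoperf.toxicity` | toxicity rate/cost/viability and (alpha, beta) fits |
| `cryoperf.protocols` | ramp–hold–step protocols, osmotic constraints, grid optimizer |
| `cryoperf.synth` | synthetic traces, plateaus, and slice tables with controlled noise |
| `cryoperf.io` / `cryoperf.cli` | file formats and the `cryoperf` command |

See `docs/methods.md` for the model's assumptions, numerical choices, and
known limitations.
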