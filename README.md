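# aortasph

Particle-based (SPH) mechanics of the multi-layered murine aortic wall:
elastic lamellae, contractile intra-lamellar smooth muscle, adventitia —
and the focal damage that precedes aortic dissection: lamellar
disruption, loss of smooth-muscle tone, and glycosaminoglycan (GAG)
pooling with osmotic swelling.

## Why

Aortas prone to dissection show medial degeneration: fragmented elastic
lamellae, smooth-muscle cell (SMC) dropout, and localized GAG pools.
Continuum models with homogenized media cannot ask what a *single*
disrupted lamella or a *single* swollen pool does to its neighbours.
`aortasph` resolves the mouse aorta's six lamellae and five
intra-lamellar layers as individual particle bands in a total-Lagrangian
smoothed-particle (corrected-kernel) solid, so damage is literally
neighbour-list surgery, and stress concentrations can be read off
particle by particle.

## Model in brief

Mixture hyperelasticity per particle (stresses in kPa, lengths in µm):

    W = φ_e [ μ/2 (I₁ᵉ − 3) − μ ln J + λ̂/2 (ln J)² ]
      + Σ_k φ_ck c₁ᵏ/(4c₂ᵏ) ( exp(c₂ᵏ (I₄ᵏ − 1)²) − 1 )

with deposition prestretches making the *in vivo* state (102 mmHg, axial
stretch 1.62) the stress-bearing reference (F = I there), separate
tension/compression fiber constants switching at I₄ = 1, parabolic active
SMC stress σ_act = φ_c₂ T_max λ_θ [1 − ((λ_max−λ_θ)/(λ_max−λ_min))²],
and GAG pools as a soft neo-Hookean solid with a Gibbs-Donnan swelling
pressure RT(√(c_FC² + c*²) − c*).  Equilibria come from damped explicit
dynamics under displacement control; luminal pressure is an output via
P = σ_θ h / r_in.  See `docs/methods.md` for the full account.

## Worked example

```python
from aortasph import WallGeometry, WallModel, build_wall

# quarter-scale sector (15 deg, periodic) at the reference density
wall = build_wall(WallGeometry(sector_deg=15.0, density=0.24))
model = WallModel(wall)

ref = model.homeostatic_reference()
print(f"homeostatic: {ref.pressure_mmhg:.1f} mmHg, "
      f"outer diameter {ref.outer_diameter:.0f} um")

passive = model.equilibrate_pressure(102.0, tone_on=False)
active = model.equilibrate_pressure(102.0, tone_on=True)
drop = 100 * (passive.outer_diameter - active.outer_diameter) / passive.outer_diameter
print(f"smooth-muscle activation at 102 mmHg: "
      f"outer radius {passive.r_out:.0f} -> {active.r_out:.0f} um ({drop:.1f}%)")
```

prints

```
homeostatic: 105.2 mmHg, outer diameter 1374 um
smooth-muscle activation at 102 mmHg: outer radius 682 -> 538 um (21.2%)
```

The relaxed prestretched lattice reports the homeostatic pressure to
within a few percent of 102 mmHg with no fitting, and maximal tone
constricts the vessel by ~21% (experimentally ~20-25% for the murine
descending thoracic aorta).  Damage studies are one call away:

```python
from aortasph.scenarios import run_scenario, scenario_single_pool

scen = scenario_single_pool(wall, extent_deg=8.0, support=model.table.support)
table = run_scenario(model, scen, pressures=(102.0, 184.0))
```

which yields a tidy table of maximum circumferential stress per region
(nearest/second-nearest lamellae and intra-lamellar spaces, read along
the radial line through the pool midpoint) after each event: loss of
contractility, GAG replacement, osmotic swelling, lamellar rupture.

There is also a small CLI: `aortasph build|equilibrate|scenario|report`
(`aortasph scenario --scenario two_pools --extent 8 --sector 30`, etc.).

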