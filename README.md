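# lobulefem

Coupled perfusion–metabolism–growth simulation of liver lobules: a
bi-scale, tri-phasic continuum model of the hexagonal functional unit of
the liver, for researchers studying how microperfusion shapes zonated fat
accumulation in metabolic dysfunction-associated steatotic liver disease
(MASLD).

## The model

The lobule is a saturated porous mixture of solid tissue (S), fat (T) and
blood (F) with volume fractions `n_S + n_T + n_F = 1`. On the lobule scale
a mixed finite-element solver (Taylor–Hood: quadratic displacement, linear
pressure/fractions/solutes) advances

* **perfusion** — Darcy flow `n_F w_FS = K_F(−∇p)` with a
  transverse-isotropic permeability biased toward the central vein and
  degraded by fat crowding, `k_eff ∝ (n_F/n⁰_F)^m`;
* **solute transport** — advection–diffusion of FFA and oxygen (plus
  glucose, lactate and glycogen as passive species), with osmotic pressure
  `Π = c R θ` and chemical potential `μ = μ₀ + Rθ ln(c/c_ref)`;
* **growth** — the fat-fraction balance
  `(n_T)'_S + n_T ∇·x'_S = ρ̂_T/ρ_TR` fed by the cell scale, with the
  compensating sink in the mixture mass balance so saturation is preserved
  exactly.

At every quadrature point a hepatocyte ODE model (intracellular FFA,
oxygen, triglyceride store) converts the local plasma milieu into a fat
production rate: Michaelis–Menten uptake, TG synthesis, oxygen-saturable
β-oxidation, background oxygen consumption and TG export. Oxygenated
periportal tissue burns FFA; hypoxic pericentral tissue stores it — this
competition, driven by the computed oxygen gradient, is what zonates the
fat pattern. The scales are weakly coupled: one cell solve per quadrature
point per time step, with exchange terms that close the mixture mass
balance to machine precision.

Scenario presets reproduce the standard boundary-condition studies on a
single lobule or the 7-lobule group: (i) undisturbed perfusion (1 mmHg =
133 Pa inflow–outflow difference), (ii) central-vein obstruction of the
left lobule (periphery held at 100 Pa — no pressure gradient, no
advection), and (iii) obstruction with drainage through the neighbouring
lobules (portal-triad inflow raised by 30 %).

## Worked example

```python
import lobulefem as lf

# high-fat-diet inflow: FFA 3 mmol/l, oxygen 0.091 mmol/l, 1610 s horizon
result = lf.run_scenario(lf.ScenarioConfig())

df = result.zone_df
print(df[(df.lobule == -1) & (df.t == 1610.0)].to_string(index=False))
print("classification:", lf.classify_zonation(result))
rel = lf.velocity_fat_relation(result, zone=2)
print("slope %.3f  R^2 %.5f" % (rel["slope"], rel["r_squared"]))
```

prints

```
     t  lobule  zone  mean_n_T   mean_speed  mean_c_FFA  mean_c_Ox
1610.0      -1     1  0.045280 5.757193e-09    2.299806   0.028246
1610.0      -1     2  0.054427 7.360213e-09    1.628354   0.004566
1610.0      -1     3  0.050654 1.612534e-08    1.126943   0.000677
classification: pericentral
slope -5.562  R^2 0.99995
```

Reading it: after 1610 s the fat fraction has grown from its initial 0.02
everywhere, most strongly in zone 3 (pericentral, mean `n_T` 0.051 vs
0.045 periportally) because the oxygen concentration collapses toward the
central vein (0.028 → 0.0007 mmol/l) and β-oxidation with it. The mid-zone
filter velocity falls nearly linearly as fat crowds the pores (slope −5.6
per unit fat fraction, R² > 0.999). Dropping the inflow FFA to 0.2 mmol/l
(`inflow_conc={"FFA": 0.2, "Ox": 0.091}`) flips the classification to
`periportal`.

A CLI wraps the same machinery:

```bash
lobulefem simulate config.yaml -o rundir   # YAML scenario -> VTU/PVD + CSV
lobulefem mesh group7 --format msh         # tagged lobule meshes
lobulefem cell --plasma-ffa 3.0            # single hepatocyte trajectory
lobulefem postprocess rundir               # zone summary + classification
```

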