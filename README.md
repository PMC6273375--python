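# cocrysol

Thermodynamic prediction of pharmaceutical **cocrystal solubility in
solvent/anti-solvent mixtures**, built on a PC-SAFT activity-coefficient
model. The package ships the complete parameter set for the
nicotinamide/succinic acid (NA/SA) 2:1 cocrystal in water, ethanol,
acetonitrile and ethyl acetate, and is aimed at crystallization-process
screening: which solvent/anti-solvent pair, at which ratio and temperature,
keeps a cocrystal stable and drives it out of solution efficiently.

## The model

A single crystalline solute i (the API or the coformer) saturates a liquid
when its solid and liquid chemical potentials balance:

```
x_i = (1/γ_i) · exp[ −Δh_i/(R T) (1 − T/T0_i) − Δcp_i/R (T0_i/T − 1 − ln(T0_i/T)) ]
```

with melting temperature `T0_i`, fusion enthalpy `Δh_i`, heat-capacity
difference `Δcp_i` and the activity coefficient `γ_i` of the solute in the
saturated liquid. A cocrystal, in contrast, dissociates completely on
dissolution; its saturation states satisfy the **solubility product**

```
Ks = (x_API γ_API)^ν_API · (x_CF γ_CF)^ν_CF
```

which depends on temperature only — not on the solvent. One measured
cocrystal solubility point in any solvent therefore fixes `Ks`, and the
cocrystal line can then be *predicted* in every other solvent system,
provided the activity coefficients capture the liquid-phase non-ideality.
Temperature is handled by a Gibbs–Helmholtz (van 't Hoff) form,
`ln Ks(T) = ln Ks_ref + Δh_ref/R (1/T_ref − 1/T)`.

All activity coefficients come from **PC-SAFT**: residual Helmholtz energy
`a_res = a_hard-chain + a_dispersion + a_association`, Berthelot–Lorentz
combining rules with a temperature-linear binary correction
`k_ij(T) = k_slope·T + k_int`, Wolbach–Sandler cross-association rules, and
induced association (ε = 0, κ = 0.01) for polar but non-self-associating
solvents (acetonitrile, ethyl acetate). Fugacity-coefficient derivatives
are evaluated by complex-step differentiation, exact to machine precision.

## Worked example

Saturation of nicotinamide in an equal-mass ethanol/water mixture:

```sh
$ cocrysol solubility --solute NA --solvents "ethanol:0.5,water:0.5" --temp 298.15
{
  "solute": "NA",
  "solvents": "ethanol:0.5,water:0.5",
  "T_K": 298.15,
  "x_solute": 0.03946720252845616,
  "gamma_solute": 0.8817478903864449
}
```

The saturation mole fraction 0.0395 exceeds the model's values in both pure
water (0.0202) and pure ethanol (0.0172): for nicotinamide the equal-mass
mixture dissolves more than either end member, so neither solvent acts as
an anti-solvent here. The same library calls trace the predicted cocrystal
line in the same mixture:

```sh
$ cocrysol cc-line --solvents "ethanol:0.5,water:0.5" --temp 298.15 --n-points 5
T_K,solvents,x_api,x_cf,gamma_api,gamma_cf,ks_used
298.15,"ethanol:0.5,water:0.5",0.004957...,0.099147...,0.8188...,0.2264...,3.7e-07
...
```

Every reported point satisfies `(x_NA γ_NA)² (x_SA γ_SA) = Ks = 3.7e-07`,
the solubility product calibrated at 298.15 K. Other subcommands:
`phase-diagram` (three saturation branches plus the two eutectic points),
`fit-kij` and `fit-ks` (parameter estimation from saturation tables),
`simulate` (synthetic datasets), `ard` and `reproduce` (accuracy reports),
`state` (diagnostic dump of γ, packing fraction and hydrogen-bonding site
fractions).

In Python the same example is:

```python
from cocrysol import load_parameter_db, solve_solubility

db = load_parameter_db("packaged")
pt = solve_solubility("NA", {"ethanol": 0.5, "water": 0.5}, 298.15, db)
print(pt.x_solute, pt.gamma_solute)   # 0.03946... 0.88174...
```

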