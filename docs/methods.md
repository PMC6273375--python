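# Methods

## Scope

`cocrysol` models solid-liquid equilibria of molecular solutes and of a
dissociating cocrystal in solvent/anti-solvent mixtures. The packaged
system is nicotinamide (NA, the API role) / succinic acid (SA, the
coformer) forming a 2:1 cocrystal, with water, ethanol, acetonitrile and
ethyl acetate as (anti-)solvents. Everything below 1 bar of physics —
vapor-liquid equilibria, polar/ionic Helmholtz terms, polymorph and solvate
equilibria, critical-point analysis — is out of scope; the computation
assumes form-I NA and unreacted SA as the competing solids.

## Equation of state

The liquid phase is described by PC-SAFT. The reduced residual Helmholtz
energy is the sum of hard-chain, dispersion and association contributions.
The hard-chain and dispersion working equations, including the two sets of
seven universal model constants for the dispersion integrals I₁ and I₂,
follow the original perturbed-chain formulation; the temperature-dependent
segment diameter is `d_i = σ_i (1 − 0.12 exp(−3 u_i/k_B T))`. Water uses a
temperature-dependent σ(T) (two-exponential form, decreasing from 2.810 Å
at 273 K to 2.786 Å at 373 K) that compensates the crude two-site picture
of its hydrogen-bond network.

Association is the Wertheim first-order term with explicit donor/acceptor
site inventories: solutes carry two donors and two acceptors (`2/2`),
water and ethanol one of each (`1/1`), and the polar aprotic solvents an
induced pair (one donor + one acceptor with ε = 0 and κ = 0.01). Donors
bond only to acceptors. The bonding strength is

    Δ^AiBj = σ_ij³ g_ij^hs κ^AiBj (exp(ε^AiBj/k_B T) − 1)

with Wolbach–Sandler combining rules for ε and κ. This makes induced
association emergent rather than special-cased: a pure aprotic solvent (or
a mixture of two of them) has ε_cross = 0 and hence exactly zero
association energy, while mixing with a self-associating partner switches
cross-bonding on with half the partner's association energy.

Verification anchors: with the packaged parameters the model reproduces
pure-liquid densities (water 997 kg/m³ within 0.1% at 298.15 K) and vapor
pressures (ethanol 7.87 kPa and water 3.17 kPa at 298.15 K, both within
a few tenths of a percent of standard reference values), which the test
suite does not assert but which guided development of the core.

## Derivatives and solvers

All derivatives of the residual Helmholtz energy — the compressibility
factor and the residual chemical potentials entering ln φ_i — are computed
by complex-step differentiation (step 1e-20). This is exact to machine
precision and avoids hand-deriving the long analytic expressions; a
dedicated test confirms agreement with central finite differences to
better than 1e-6 relative.

* **Association fixed point.** Eight damped successive substitutions
  (damping 0.5) followed by Newton iterations on the site-fraction
  residuals, tolerance 1e-14. The Newton linear solve propagates the
  complex-step channel exactly; a naive substitution loop would terminate
  on the real channel before the derivative channel has converged, which
  corrupts pressure derivatives — the dual-channel treatment is load-bearing.
* **Density.** The packing fraction solves p(η) = p_spec by a directional
  bracket search (downward from close packing for liquids, upward from
  zero for vapors, so the first crossing found is mechanically stable)
  refined by Brent's method; relative pressure consistency at the root is
  better than 1e-9. A warm-start bracket around the previous η accelerates
  iterative algorithms.
* **Activity coefficients.** Symmetric convention, γ_i = φ_i(T,p,x)/φ_i^pure(T,p),
  with pure-liquid reference fugacities cached per (component, T, p). All γ
  are evaluated at 101325 Pa: the liquid-phase γ of these systems are
  insensitive to pressure, and no saturation-pressure bookkeeping is
  warranted. For the solid solutes below their melting points the pure
  reference is the subcooled-liquid density root, taken as-is.
* **Saturation.** The solid-liquid equilibrium equation is solved in ln x
  by one damped substitution followed by secant iteration (relative
  tolerance 1e-9, safeguarded against wild extrapolation). Divergence
  toward x → 1 is reported as full miscibility. Fusion enthalpies are
  stored in kJ/mol and converted to J/mol at exactly one site.
* **Cocrystal lines.** Parameterized by the solute ratio r = x_API/x_CF on
  a logarithmic grid; each node solves for the scale s (x_API = r·s,
  x_CF = s) by bracketed Brent iteration in ln s with the activity product
  as residual, tolerance 1e-12. Failed nodes are logged and skipped.
* **Eutectics.** The discrete crossing of two sampled saturation branches
  seeds a two-dimensional Powell-hybrid root solve of both equilibrium
  residuals in (ln x_API, ln x_CF). Absence of a crossing is a reported
  outcome, not an error. Phase-diagram assembly clips each branch at its
  eutectic (kink = eutectic); no global Gibbs-energy minimization is
  attempted.

## Composition conventions

Solvent/anti-solvent compositions are solute-free mass fractions, the
convention of crystallization screening; conversion to mole fractions uses
the database molar masses. Dissolved cosolutes enter as mole fractions of
the total liquid. The binary interaction parameter between NA and SA is
zero; solvent/solvent k_ij values fitted at other temperatures are applied
unchanged at all temperatures. The gas constant is fixed at 8.314 J/(mol·K).

## Parameter estimation

`fit_kij` minimizes Σ(ln x_calc − ln x_exp)² with a trust-region
least-squares solver. The loss is logarithmic because solubilities span
orders of magnitude and accuracy is judged on relative deviations
(ARD = 100·mean|x_calc − x_exp|/x_exp). Internally the pair
(k_slope, k_int) is reparameterized as (k at the mean data temperature,
slope): over a narrow temperature window the two raw parameters are nearly
collinear, and the centered parameterization is what lets the optimizer
recover generating parameters to ~1e-15 on noise-free data. Reported
standard errors are linearized (Jacobian-based) estimates. Datasets at a
single temperature fit the intercept only. `fit_ks` calibrates the
solubility product from a single two-solute saturation record using model
activity coefficients at that record's full composition — the same
single-point calibration that makes the cocrystal line predictive in every
other solvent.

## Synthetic data

The generator emulates saturation tables from gravimetric/photometric
measurement campaigns: model solubilities on a temperature × solvent-ratio
design with multiplicative lognormal noise, x_obs = x_model·exp(ε),
ε ~ N(0, σ²) independent per record. The default σ = 0.02 mimics the
scatter of triplicate analyses; the noise is multiplicative because the
error metric is relative and the data span decades. One integer seed fixes
the full stream; records are generated temperature-major, then solvent
ratio, then replicate. What the generator does *not* emulate: evaporation
losses, calibration drift, solid-phase misidentification, or any
systematic (non-mean-zero) measurement error. Passing round-trip and
recovery tests on this data therefore demonstrates the internal
consistency of solver + estimator, not the field accuracy of PC-SAFT on
real saturation measurements.

## Problem sizes

The test suite and the acceptance script use compact designs chosen to
exercise every code path at meaningful precision: 5–8 temperatures per
binary fit, 3–5 solvent ratios per mixture line, 25–31 ratio nodes per
cocrystal line, 200 replicates for the noise-distribution check. These are
the package's standard working sizes; finer grids change line values by
less than the solver tolerances.

## Known limitations

* Solute PC-SAFT parameters of this kind are fitted to solubility data and
  inherit the conventions of the code that fitted them; transplanting them
  across implementations can shift absolute saturation levels even when
  pure-component properties and mixture topology (solubility orderings,
  maxima, eutectic structure) are reproduced. Predictions here should be
  read as a faithful realization of the model, not as re-certified
  experimental agreement.
* The `2/2` and `1/1` site labels are interpreted as donor/acceptor counts;
  the induced associators carry one donor and one acceptor each. Chemically,
  nitriles and esters are acceptors only; with ε_cross fixed by the
  combining rules this choice changes the strength, not the existence, of
  induced bonding.
* Strongly non-ideal aqueous mixtures (ethanol/water) are the hardest case
  for the model and carry the largest expected deviations.
* The eutectic logic assumes each pair of branches crosses at most once in
  the sampled window.
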