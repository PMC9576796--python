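# Methods

This note documents the models, conventions and numerical choices behind
`ndapo`, and what the synthetic-data tests do and do not demonstrate.

## Reaction thermodynamics

Reactions are stored as signed rational stoichiometric maps (reactants
negative). Element and charge balancing uses `fractions.Fraction`
throughout, so residuals of balanced reactions are exactly zero rather than
small floats; floating point enters only when energies are evaluated.

ΔG°′ is computed as

    ΔG°′ = Σᵢ νᵢ ΔGf°(i) + ν(H⁺) · RT ln(10⁻ᵖᴴ),

normalised per mole of a designated reference species (propane throughout).
The proton sits in the table at ΔGf° = 0 (unit activity); moving it to pH 7
contributes ≈ −39.9 kJ per mole of proton consumed at 298.15 K. This is the
standard biochemical-standard-state convention.

The packaged formation energies (kJ/mol, 25 °C) are common
microbial-bioenergetics reference values: C₃H₈(g) −23.4, NO₃⁻ −111.3,
NO₂⁻ −37.2, NH₄⁺ −79.4, N₂(g) 0, CO₂(g) −394.4, H₂O(l) −237.2, H⁺ 0,
SO₄²⁻ −744.6, HS⁻ +12.05, HCO₃⁻ −586.85. Conventions worth making explicit:

* **Propane and CO₂ are gas-phase.** With aqueous CO₂ (−386.0, shipped as
  `CO2(aq)`) the computed energies shift by ~25 kJ per propane; the gas-phase
  convention reproduces the literature values for these reactions best.
* **Nitrate.** Reference compilations differ by ~2 kJ/mol for NO₃⁻. The
  default −111.3 gives −1367.6 kJ/mol propane for the nitrate→nitrite
  reaction, ~1.5% from the commonly cited −1347.7; the alternative −113.3
  (shipped as `NO3-(alt)`) reproduces that value to 0.01%. Both are in the
  table; which a given publication used is generally unstated, so the default
  is documented rather than asserted.
* **Temperature.** Energies are evaluated at 298.15 K even though such
  reactors run near 295 K: the reported quantities are standard-state values,
  and ΔGf° temperature dependence is out of scope.
* The sulfate comparison uses the bicarbonate/bisulfide convention,
  C₃H₈ + 2.5 SO₄²⁻ → 3 HCO₃⁻ + 2.5 HS⁻ + 0.5 H⁺ + H₂O (≈ −102.7 kJ/mol).

The table is a user-replaceable YAML file; `ReactionLibrary.from_yaml` loads
alternatives for sensitivity analysis.

## Oxidation states and electron equivalents

Mean oxidation states are assigned by the standard rules (O = −2, H = +1,
single-element species = charge/atoms) with charge closure on the element of
interest, in exact rational arithmetic (carbon in propane is −8/3). Electron
equivalents of a couple are |ΔOS| × atom count: 20 per propane → 3 CO₂, and
2/5/8 per N from nitrate to nitrite/N₂/ammonium (3/6 from nitrite). The test
suite checks every packaged couple against an independent half-reaction
balancer that completes `From → b·To + w H₂O + h H⁺ + e e⁻` by element and
charge closure alone.

## Gas–liquid inventories

Headspace amounts use the ideal gas law (R = 0.082057 L·atm·mol⁻¹·K⁻¹);
dissolved amounts use Henry's law with 25 °C constants (mol·L⁻¹·atm⁻¹):
propane 1.4 × 10⁻³, CO₂ 3.4 × 10⁻², N₂ 6.5 × 10⁻⁴, with no temperature
correction by default. At ≤ 1.5 atm and ~295 K, non-ideality is far below
measurement noise. Whether reported gas amounts include the dissolved
correction varies between workflows, so every inventory function takes a
headspace-only switch. The acidified-CO₂ contract assumes acidification
converts all dissolved inorganic carbon to CO₂ and equilibration is
complete; carbonate speciation at circumneutral pH is deliberately out of
scope.

The balance pipeline itself operates purely on amount time series; gas
conversion is an ingestion concern, keeping the analysis core unit-pure.

## Isotope accounting

Atom fractions are carried as plain fractions in [0, 1] everywhere;
percentages appear only at I/O boundaries. No isotope fractionation is
modelled — at tracer levels of ≤ 8 atom% the kinetic distinction between
isotopologues is negligible for these balances.

The nitrite heavy fraction is recovered by difference from the combined
nitrate+nitrite and nitrate-only measurements via label conservation
(f·A additivity); results within 10⁻⁶ outside [0, 1] are clamped, larger
excursions are rejected as inconsistent measurements.

N₂ isotopologues follow binomial random pairing from a single well-mixed
nitrite pool at atom fraction p: (f²⁸, f²⁹, f³⁰) = ((1−p)², 2p(1−p), p²).
This is the standard isotope-pairing assumption for denitrification; the
simulator also offers single-atom bookkeeping (every heavy atom yields a
²⁹N₂) as a switch. Measured ²⁹N₂ fractions in real experiments can sit
below the instantaneous binomial prediction because the nitrite pool's
fraction evolves as it is produced and consumed; the simulator reproduces
this qualitatively but no quantitative claim is made about observed
isotopologue fractions.

## Two-stage balance analysis

Nitrate reduction in these cultures proceeds in two stages — Stage 1
(nitrate present): nitrate → nitrite + N₂ with negligible ammonium; Stage 2
(after depletion): accumulated nitrite → N₂ + NH₄⁺. The boundary is the
first crossing of nitrate below a threshold, default 2% of the initial
amount (configurable), with linear interpolation between the bracketing
samples; a flat segment at the threshold resolves to its last sample.

Balances use start-to-end deltas, not integrated rates, matching how total
consumption and production are tabulated for such experiments; transient
nitrite enters only as an end-of-run residual. Negative measured deltas
(noise) are clipped to zero with a logged warning. For whole-run balances
the electron coefficients are referenced to nitrate (5/8/2); a Stage-2-only
analysis switches the source to nitrite (3/6, residual coefficient 0).
Electron production can be anchored on propane consumed (20 e⁻ each) or CO₂
produced (20/3 each); the two differ exactly by the assimilated-carbon
fraction, which is why both modes are exposed. Replicates aggregate as mean
± standard error (sample SD/√n; flagged undefined for n = 1). Kinetic rate
fitting and biomass-yield modelling are non-goals.

Unit canonicalisation at ingestion: concentrations in mg N L⁻¹ convert to
µmol N per vessel via × V_liquid × 1000 / 14.007 (nitrogen columns only);
N₂ is counted as N atoms so that all closure ratios are unit-free.

## The synthetic generator

Kinetics are zero-order per stage (piecewise-linear pools) rather than
Monod: consumption profiles in such enrichments are near-linear, the model
needs fewer parameters, and exact closure is verifiable. Forward-Euler
updates with flux capping at pool exhaustion make the truth trajectory
exactly conservative: nitrogen atoms, carbon atoms (with an explicit
assimilated-carbon ledger) and the electron ledger all close to < 10⁻⁹ at
every step, which the tests assert.

Default conditions (deliberately fixed, not tuning knobs): 730 µmol
nitrate-N (20 mg N/L in 500 mL), 2000 µmol propane (excess), nitrate
depletion at ~49 h (r_no3 = 15 µmol N/h), full nitrite consumption by
~104 h within a 120 h horizon at 0.25 h steps, end-product split
φ_N2 = 0.573, labels p13 = 0.08 and p15 = 0.01, triplicates. Rate constants
for such cultures are not tabulated anywhere; these are order-of-magnitude
choices that deplete ~0.7 mmol nitrate over days, not assertions about any
organism. The Stage-2 N₂:NH₄⁺ flux split is solved at the stage switch so
the end-run partition equals φ_N2 exactly (an unreachable φ_N2 — Stage 1
already overshooting the target — is rejected with a clear error).

The assimilation fraction `f_assim` diverts oxidised carbon from CO₂ to a
biomass ledger without claiming a mechanism; it exists so the simulator can
reproduce sub-stoichiometric ¹³CO₂ yields (e.g. a 2.42 label ratio at
f_assim = 0.193) while defaulting to 0 for closure tests.

Noise is independent Gaussian per analyte per timepoint with
sd = noise_sigma × initial nitrate-N, applied to the six main analyte
columns and clipped at zero; isotope columns on the observed series are
carried noise-free (no analysis here depends on label-column noise).
Replicate seeds are master + index, recorded in a manifest for byte-exact
reproduction.

What the simulator does **not** emulate: growth and biomass dynamics, Monod
saturation, pH drift, nitrite toxicity, gas-transfer kinetics, isotope
fractionation, or autocorrelated/instrument-specific noise. Passing the
recovery tests therefore shows the *analysis* is correct and unbiased under
the stated noise model — it does not validate any biological claim about
real cultures, whose reported closure ratios (e.g. 1.03 ± 0.05, 1.10 ± 0.01)
depend on raw data this package does not ship.

## Numerical and interface choices

* Exact rationals for stoichiometry/oxidation states; float64 elsewhere.
* Closure assertions use absolute tolerances of 10⁻⁹ on ratios near 1;
  accumulated float error over ~500 Euler steps is ≲ 10⁻¹².
* Time series are CSV (UTF-8, '.' decimal); configs YAML; reports JSON plus
  a flat text table. Reports are byte-identical across reruns of the same
  inputs, and the run log records input hashes and every decision parameter.
* The statistical recovery test estimates the sampling SD of a triplicate
  mean from 100 independent triplicates and checks a fixed-seed triplicate
  against 2 SD, plus an estimator-bias bound of one percentage point —
  a sound test at known truth without relying on the n = 3 SE estimate,
  whose own sampling error is large.
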