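# ndapo

Stoichiometric, thermodynamic and stable-isotope mass-balance analysis for
**nitrate-dependent anaerobic propane oxidation (n-DAPO)** batch experiments.

## The problem

Anaerobic microbial communities can oxidise short-chain gaseous alkanes such
as propane using nitrate instead of sulfate as the electron acceptor.
Demonstrating that a sealed enrichment culture really performs this coupling
rests on quantitative bookkeeping rather than on any single measurement:

* the redox reactions must be balanced and thermodynamically favourable,

  C₃H₈ + 10 NO₃⁻ → 10 NO₂⁻ + 3 CO₂ + 4 H₂O  (ΔG°′ ≈ −1.35 MJ/mol propane)

  with nitrite further reduced either to N₂ (denitrification, 3 e⁻ per N) or
  to NH₄⁺ (DNRA, 6 e⁻ per N);
* nitrogen must close: nitrate-N consumed ≈ N₂-N + NH₄⁺-N (+ residual
  nitrite) produced;
* electrons must close: 20 e⁻ released per propane oxidised to CO₂ ≈
  5·ΔN₂-N + 8·ΔNH₄-N + 2·ΔNO₂⁻-N demanded by nitrate reduction;
* ¹³C-propane and ¹⁵N-nitrate tracers must reappear in ¹³CO₂ and in
  ²⁹N₂/³⁰N₂/¹⁵NH₄⁺ in the expected proportions.

`ndapo` implements this entire analysis for researchers running (or
re-analysing) such experiments: exact rational-arithmetic reaction balancing
and ΔG°′ evaluation, electron-equivalent accounting, headspace/liquid gas
inventories, tracer-pool algebra including the binomial N₂ isotope-pairing
model and the nitrite-¹⁵N-by-difference mixing equation, two-stage
segmentation of batch time series (Stage 1: nitrate → nitrite + N₂; Stage 2:
nitrite → N₂ + NH₄⁺ after nitrate depletion), and replicate aggregation as
mean ± SE. A synthetic batch-experiment generator with exactly closed
mass/electron ledgers and configurable measurement noise makes the whole
pipeline testable without laboratory data.

## Worked example

```python
import ndapo as nd

params = nd.SimulationParams(noise_sigma=0.02, n_replicates=3, seed=1)
batches, manifest = nd.generate_replicates(params)
rows = [nd.analyze_replicate(b.observed) for b in batches]
report = nd.aggregate_replicates(rows)
print(report.summary_table())
```

prints

```
          statistic    mean        se
         dno3_umolN 737.582   5.03473
          dn2_umolN 416.203    5.6519
         dnh4_umolN 291.016   8.54128
dno2_residual_umolN       0         0
     nitrogen_ratio 1.04386 0.0260187
    e_produced_umol 4740.55   326.223
    e_consumed_umol 4409.15   87.7659
     electron_ratio 1.07476 0.0662635
   partition_n2_pct 58.8647  0.582672
  partition_nh4_pct 41.1353  0.582672
```

Reading the numbers: across three noisy vessels, ~738 µmol of nitrate-N was
consumed against ~707 µmol recovered in N₂ and NH₄⁺, a nitrogen closure ratio
of 1.04 ± 0.03; propane supplied 1.07 ± 0.07 times the electrons the nitrogen
products demanded; and 58.9 ± 0.6% of the reduced nitrogen ended as
dinitrogen (the simulator's true split was 57.3%). Ratios near one and a
recovered partition near truth are exactly what a genuine propane–nitrate
coupling looks like in this analysis.

The `examples/` directory holds one short script per capability (reaction
energetics, simulate-and-balance, isotope tracers, gas inventories). A thin
CLI exposes the same pipeline from the shell:

```sh
ndapo simulate --seed 1 --out scratch/run
ndapo balance scratch/run/observed.csv
ndapo thermo --reaction propane_nitrate_to_nitrite
```

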