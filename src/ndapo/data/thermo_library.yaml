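# Packaged thermodynamic table and reaction library.
#
# Standard Gibbs free energies of formation (kJ/mol, 25 degC) are common
# microbial-bioenergetics reference values. The table is plain data: copy this
# file, edit values, and load it with ReactionLibrary.from_yaml to run a
# sensitivity analysis. Notable entries:
#   - NO3- defaults to -111.3; the alternative -113.3 (shipped as "NO3-(alt)")
#     reproduces the propane/nitrate-to-nitrite energy essentially exactly and
#     is provided because reference compilations differ at the ~2 kJ level.
#   - CO2 is the gas-phase value; "CO2(aq)" is provided for sensitivity runs.
#   - H+ is 0 at unit activity; pH is handled as an activity correction at
#     evaluation time, never in the table.
temperature_K: 298.15

species:
  C3H8:      {formula: C3H8, charge: 0,  phase: gas,          dgf_kj_mol: -23.4}
  CO2:       {formula: CO2,  charge: 0,  phase: gas,          dgf_kj_mol: -394.4}
  "CO2(aq)": {formula: CO2,  charge: 0,  phase: aqueous,      dgf_kj_mol: -386.0}
  H2O:       {formula: H2O,  charge: 0,  phase: liquid-water, dgf_kj_mol: -237.2}
  "H+":      {formula: H,    charge: 1,  phase: aqueous,      dgf_kj_mol: 0.0}
  "NO3-":    {formula: NO3,  charge: -1, phase: aqueous,      dgf_kj_mol: -111.3}
  "NO3-(alt)": {formula: NO3, charge: -1, phase: aqueous,     dgf_kj_mol: -113.3}
  "NO2-":    {formula: NO2,  charge: -1, phase: aqueous,      dgf_kj_mol: -37.2}
  "NH4+":    {formula: NH4,  charge: 1,  phase: aqueous,      dgf_kj_mol: -79.4}
  N2:        {formula: N2,   charge: 0,  phase: gas,          dgf_kj_mol: 0.0}
  "SO42-":   {formula: SO4,  charge: -2, phase: aqueous,      dgf_kj_mol: -744.6}
  "HS-":     {formula: HS,   charge: -1, phase: aqueous,      dgf_kj_mol: 12.05}
  "HCO3-":   {formula: HCO3, charge: -1, phase: aqueous,      dgf_kj_mol: -586.85}

reactions:
  # Propane oxidation to CO2 with nitrate reduced to nitrite.
  propane_nitrate_to_nitrite:
    equation: "C3H8 + 10 NO3- -> 10 NO2- + 3 CO2 + 4 H2O"
    reference: C3H8
  # Propane oxidation with nitrite reduced to ammonium (DNRA branch).
  propane_nitrite_to_ammonium:
    equation: "3 C3H8 + 10 NO2- + 20 H+ -> 10 NH4+ + 9 CO2 + 2 H2O"
    reference: C3H8
  # Propane oxidation with nitrite reduced to dinitrogen (denitrification branch).
  propane_nitrite_to_dinitrogen:
    equation: "3 C3H8 + 20 NO2- + 20 H+ -> 10 N2 + 9 CO2 + 22 H2O"
    reference: C3H8
  # Sulfate-coupled propane oxidation, bicarbonate/bisulfide convention,
  # for the thermodynamic comparison with the nitrate route.
  propane_sulfate:
    equation: "C3H8 + 2.5 SO42- -> 3 HCO3- + 2.5 HS- + 0.5 H+ + H2O"
    reference: C3H8

couples:
  - {from: C3H8,  to: CO2,   element: C}   # 20 e- per propane
  - {from: "NO3-", to: "NO2-", element: N} # 2 e- per N
  - {from: "NO3-", to: N2,    element: N}  # 5 e- per N
  - {from: "NO3-", to: "NH4+", element: N} # 8 e- per N
  - {from: "NO2-", to: N2,    element: N}  # 3 e- per N
  - {from: "NO2-", to: "NH4+", element: N} # 6 e- per N
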