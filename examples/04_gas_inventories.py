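"""Headspace and dissolved gas inventories for the reactor geometry.

Converts headspace partial pressures to total molar inventories for the
2.3 L bioreactor (1.84 L medium, 0.46 L headspace) and demonstrates the
acidified-CO2 measurement contract for a small sampling vial.
"""

import ndapo as nd
from ndapo.gas_liquid import DEFAULT_HENRY

reactor = nd.VesselConfig(v_liquid=1.84, v_headspace=0.46, temperature=295.15)

print("propane at 1.0 atm in the reactor headspace:")
inv = nd.total_inventory("C3H8", 1.0, reactor, DEFAULT_HENRY["C3H8"])
print(f"  headspace {inv.headspace_moles*1e3:.2f} mmol, "
      f"dissolved {inv.dissolved_moles*1e3:.2f} mmol, "
      f"total {inv.total_moles*1e3:.2f} mmol")
print("  the dissolved correction is ~{:.0f}% of the total".format(
    100 * inv.dissolved_moles / inv.total_moles))

p_back = nd.partial_pressure(inv.total_moles, reactor, DEFAULT_HENRY["C3H8"])
print(f"  inverse conversion recovers the pressure: {p_back:.6f} atm")

# acidified subsample in a 12 mL vial with 2 mL of liquid
vial = nd.VesselConfig(v_liquid=0.002, v_headspace=0.010, temperature=298.15)
total_co2 = nd.total_co2_after_acidification(0.01, vial)
print(f"\n1% CO2 in the vial headspace after acidification -> "
      f"{total_co2*1e6:.2f} umol total CO2")
print("acidification pushes all dissolved inorganic carbon into CO2, so this")
print("one reading quantifies the sample's entire carbonate system.")
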