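"""Compute the CO2 trait panel for the toy photoautotroph, day vs night.

Builds the day and night variants of the synthetic C3-plant model, applies
the oxygenation:carboxylation window 0.31-0.55, and prints the trait panel
from one parsimonious flux distribution per condition (night growth capped
at the day optimum so scaled values share a reference).
"""

from respitraits import (RubiscoConstraint, build_inventory, compare_conditions,
                         generate_day_night_pair, traits_to_row)

day, night, truth = generate_day_night_pair(photon_bound=100.0, starch_bound=10.0)
rc = RubiscoConstraint("R_RBC_c", "R_RBC_o")

t_day, t_night = compare_conditions(day, night, build_inventory(day),
                                    build_inventory(night), rc)

for label, t in (("day", t_day), ("night", t_night)):
    row = traits_to_row(t)
    print(f"--- {label} ---")
    for key in ("mu", "A_net", "Vc", "Vo", "Rd", "CUE", "Rg", "Rg_scaled"):
        print(f"  {key:10s} {row[key]:10.4f}")

print()
print("mu is growth (biomass flux); A_net the net CO2 assimilation of the")
print("distribution; CUE = A_net/Vc the fraction of gross carboxylation kept;")
print("Rg_scaled is CO2 released per mol carbon fixed in biomass - higher in")
print("the light here because photorespiratory glycine decarboxylation")
print("dominates daytime CO2 release.")
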