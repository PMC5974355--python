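"""One-at-a-time sensitivity of the fledging-period total food intake.

Each energetic constant is perturbed +-10% with everything else held at
its central value; the elasticity (d log output / d log input) is exact
for power-law dependencies, e.g. -1 for the prey energy density.
"""

from ternergy import EnergeticParams, sensitivity_oat

table = sensitivity_oat(EnergeticParams(), perturbation=0.10, target="tdfi_fledging")
print(table.to_string(index=False))
print(
    "\n|elasticity| ranks the leverage each input has on the total daily food "
    "intake of a provisioning adult: body mass and prey calorific value "
    "dominate; breeding success and chick mass matter only through the "
    "chick's half-share."
)
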