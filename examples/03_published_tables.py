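"""Reproduce the downstream arithmetic on the packaged free-energy tables.

The per-sugar free energies themselves come from long explicit-solvent
simulations and are shipped as data; everything printed here is recomputed
from them: relative solvation, anomer equilibria versus experiment, Km
conversions, anomer-averaged relative binding, enantiomer discrimination
and free-energy spreads.
"""

from sugarosp import (
    anomer_table,
    binding_vs_km_table,
    deviation_stats,
    enantiomer_report,
    free_energy_range,
    km_to_relative_dg,
    load_table,
    relative_solvation,
)

solvation = load_table("solvation")
anomers = load_table("anomers")
binding = load_table("binding")
km = load_table("km")

print("== Relative solvation (water - vacuum), first rows ==")
vac = solvation.rename(columns={"dg_vac": "value", "dg_vac_err": "stderr"})
wat = solvation.rename(columns={"dg_water": "value", "dg_water_err": "stderr"})
cols = ["index", "value", "stderr"]
print(relative_solvation(vac[cols], wat[cols]).head(8).to_string(index=False))

print("\n== Free-energy spreads (kJ/mol) ==")
print(f"vacuum: {free_energy_range(solvation['dg_vac']):.1f}")
print(f"water : {free_energy_range(solvation['dg_water']):.1f}")
print(f"water excluding the most unfavourable isomer: "
      f"{free_energy_range(solvation['dg_water'], exclude_max=True):.1f}")

print("\n== Anomer equilibria: simulation vs experiment (kJ/mol) ==")
water = solvation.rename(columns={"dg_water": "value"})
table = anomer_table(water, experiment=anomers)
print(table.to_string(index=False))
dev = deviation_stats(anomers["dg_beta_alpha_simulation"],
                      anomers["dg_beta_alpha_experiment"])
print(f"signed mean deviation {dev.mean_signed:+.1f}, sd {dev.sd:.1f}, "
      f"max |dev| {dev.max_abs:.1f}")

print("\n== Km conversion at 303.15 K (kJ/mol, relative to glucose) ==")
print(km_to_relative_dg(km, "glucose").to_string(index=False))

print("\n== Anomer-averaged relative binding, pose A (kJ/mol, 300 K) ==")
bound = binding.rename(columns={"dg_poseA": "value"}).assign(pose="A")
print(binding_vs_km_table(water, bound, km).to_string(index=False))

print("\n== Enantiomer discrimination (max |dG_i - dG_mirror|, kJ/mol) ==")
for label, frame, col in (("pose A", binding, "dg_poseA"),
                          ("pose B", binding, "dg_poseB"),
                          ("vacuum", solvation, "dg_vac")):
    rep = enantiomer_report(frame.rename(columns={col: "value"}))
    print(f"{label}: {rep['abs_difference'].max():.1f}")
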