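"""Step 1 for one stock: profile F over 13 levels and select F_MSY.

Profiles the toy web's predator over 13 evenly spaced F values between
0 and 4 x F_OFL (the prey held at calibration fishing) and prints the
equilibrium yield curve. F_MSY is the grid F with the highest
last-5-year mean catch; depletion is the spawning biomass at F_MSY as a
fraction of the unfished (F=0) spawning biomass.
"""

import ecocap as ec

recipe = ec.WebRecipe(preset="toy3", seed=0)
config = ec.generate_toy_web(recipe)
historical, _ = ec.generate_forcings(recipe)

profile = ec.profile_fmsy(config, "pred", historical)

print(f"{'F (1/yr)':>9} {'catch (t)':>12} {'SSB (t)':>14} {'catch CV':>9}")
for F, catch, ssb, cv in profile.grid:
    marker = "  <- F_MSY" if F == profile.F_MSY else ""
    print(f"{F:9.4f} {catch:12.1f} {ssb:14.1f} {cv:9.4f}{marker}")

print()
print(f"F_MSY = {profile.F_MSY:.4f} /yr (F_OFL = {config.f_base('pred'):.2f}),"
      f" MSY = {profile.msy:,.0f} t/yr")
print(f"depletion at F_MSY: {profile.depletion_at_FMSY:.2f} of unfished SSB")
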