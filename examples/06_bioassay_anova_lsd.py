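"""Dose-mortality ANOVA with Fisher's protected LSD letters.

Simulates a six-dose injection bioassay (ten larvae per replicate, twelve
replicates) at the 21-day mortality levels of a metabolite-extract assay,
then tests for dose differences and separates means with compact letters:
doses sharing a letter are statistically indistinguishable at alpha 0.05.
"""

from genrelate import MortalitySimSpec, simulate_mortality
from genrelate.bioassay import group_summaries, mortality_lsd

table = simulate_mortality(MortalitySimSpec(seed=6))
res = mortality_lsd(table, timepoint=21.0, alpha=0.05)

print(f"ANOVA: F = {res.f_statistic:.2f}, p = {res.p_value:.2g} "
      f"({'significant' if res.anova_significant else 'not significant'})")
print(f"LSD at alpha {res.alpha}: {res.lsd_value:.1f} percentage points\n")
print(f"{'dose (ug/larva)':>15}{'mean %':>9}{'sd':>7}  letters")
summary = group_summaries(table, 21.0)
for _, row in summary.iterrows():
    print(f"{row['dose']:>15.2f}{row['mean']:>9.1f}{row['sd']:>7.1f}  "
          f"{res.letter_groups[row['dose']]}")
print("\n-> the buffer control separates cleanly from every extract dose; "
      "the doses themselves overlap (no dose-dependent effect).")
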