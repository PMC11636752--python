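"""The CYP3A4-mediated interaction between herbal-tea retrorsine and rifampicin.

Simulates five weeks of daily tea-borne retrorsine (0.019 µg/kg/day) with
and without a two-week rifampicin course (600 mg/day from day 4), then
prints the enzyme induction, the exposure ratios and the shift in CYP3A4
metabolite formation.
"""

from retropbtk import (ScenarioSpec, auc_cmax_by_day, build_reference_human,
                       day_windows, retrorsine_reference)
from retropbtk.scenarios import metabolite_formation_report, run_scenario

phys = build_reference_human()
sub = retrorsine_reference()

tea = run_scenario(ScenarioSpec("herbal_tea"), sub, phys)
rif = run_scenario(ScenarioSpec("herbal_tea_plus_rifampicin"), sub, phys)

print(f"max fold-induction: liver {rif.enzyme_level_liv.max():.1f}, "
      f"gut {rif.enzyme_level_gut.max():.1f}")

spec = ScenarioSpec("herbal_tea_plus_rifampicin")
wins = day_windows(spec)
ref = auc_cmax_by_day(tea, {"reference": wins["reference"]}).set_index("matrix")
test = auc_cmax_by_day(rif, wins).set_index(["day_label", "matrix"])
print("\nretrorsine AUC24 as % of the rifampicin-free reference:")
for label in ("day_1_after_first_dose", "day_14_after_first_dose",
              "day_2_after_last_dose", "day_14_after_last_dose"):
    row = [100 * test.loc[(label, m), "auc24"] / ref.loc[m, "auc24"]
           for m in ("plasma", "liver", "gut")]
    print(f"  {label:<26s} plasma {row[0]:6.1f}  liver {row[1]:6.1f}  "
          f"gut {row[2]:6.1f}")

met_tea = metabolite_formation_report(tea).set_index(["tissue", "pathway"])
met_rif = metabolite_formation_report(rif).set_index(["tissue", "pathway"])
for tissue in ("liver", "gut"):
    a = met_tea.loc[(tissue, "cyp3a4"), "amount_nmol"]
    b = met_rif.loc[(tissue, "cyp3a4"), "amount_nmol"]
    print(f"\ncumulative {tissue} CYP3A4 metabolites at 5 weeks: "
          f"{a:.1f} -> {b:.1f} nmol ({100 * b / a:.0f}% of reference)")

print("\nInhibition acts instantly (day-1 exposure rises); induction builds "
      "over days and peaks after the course ends, when inhibition is gone — "
      "hence the deepest liver exposure trough and the intestinal surge in "
      "bioactivating CYP3A4 metabolite formation.")
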