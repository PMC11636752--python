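"""Which interaction parameters drive CYP3A4 metabolite formation?

Perturbs f_m,CYP3A4, EC50, Emax and K_i by ±10% and prints the normalized
sensitivity coefficients of the cumulative CYP3A4 metabolite amounts in
liver and gut at five weeks.
"""

from retropbtk import (ScenarioSpec, build_reference_human,
                       retrorsine_reference, sensitivity_coefficients)

phys = build_reference_human()
sub = retrorsine_reference()
spec = ScenarioSpec("herbal_tea_plus_rifampicin")

table = sensitivity_coefficients(spec, sub, phys)
print(table.pivot(index=["parameter", "direction"], columns="tissue",
                  values="coefficient").round(3))
print("\nA coefficient of 1 means a 10% parameter change moves the output "
      "by 10%. The fraction metabolized by CYP3A4 dominates in both "
      "tissues; intestinal formation is additionally sensitive to Emax "
      "because gut rifampicin levels sit closer to EC50 than hepatic ones.")
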