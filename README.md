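# retropbtk

Physiologically-based toxicokinetics of the pyrrolizidine alkaloid
**retrorsine** in humans, with the CYP3A4-mediated drug interaction by the
enzyme inducer **rifampicin**.

Retrorsine, a hepatotoxic contaminant of herbal teas, is a *victim* of
CYP3A4 interactions in an unusual sense: CYP3A4 *bioactivates* it to
reactive dehydro-metabolites, so an inducer increases rather than decreases
the toxic burden. This package implements the full modelling chain needed
to quantify that effect for a chronic low-dose tea consumer:

* **In-vitro kinetics + IVIVE** — monoexponential medium-loss depletion
  (4 °C vs 37 °C, separating passive diffusion from carrier-mediated
  uptake) and microsomal depletion with end-product inhibition
  (v = V·S/((K_M+S)(1+P/IC50))); fitted constants are scaled to whole-liver
  clearances via hepatocellularity and microsomal-protein factors.
* **Bayesian fitting** — adaptive random-walk Metropolis in log-parameter
  space; results reported as posterior mode with equal-tailed 95% credible
  interval, plus 1000-draw Monte-Carlo predictive bands.
* **Whole-body PBTK core** — flow-limited compartments for a 73-kg
  reference human; the liver follows the extended clearance model,

      CL_liv = Q·fu,p·CL_act,in·(CL_met+CL_bile) /
               [Q·(CL_act,ef+CL_met+CL_bile) + fu,p·CL_act,in·(CL_met+CL_bile)]

  with first-order gut absorption (k_a, F_a), intestinal metabolism
  confined to the small-intestinal cellular space, and renal filtration of
  unbound drug.
* **DDI layer** — per-tissue 2-compartment intracellular rifampicin
  disposition driving a CYP3A4 turnover model with Emax induction of the
  synthesis rate (dE/dt = k_deg(1 + Emax·C/(EC50+C)) − k_deg·E) and
  competitive inhibition (K_M scaled by 1 + C/K_i) of the CYP3A4 pathway,
  which carries f_m,CYP3A4 = 52.7% of retrorsine metabolism.
* **Scenarios, metrics and sensitivity** — five weeks of daily tea
  (0.019 µg/kg/day retrorsine) with an optional two-week 600 mg/day
  rifampicin course; AUC24/Cmax per 24-h window, pathway-resolved
  metabolite formation, percent-of-reference interaction ratios and
  normalized local sensitivity coefficients.
* **Synthetic data** — generators for every measured input (replicated
  depletion time courses, intracellular rifampicin profiles) with
  multiplicative lognormal noise, so the entire pipeline is testable
  without any external data.

## Worked example

```sh
python examples/rifampicin_interaction.py
```

```
max fold-induction: liver 9.7, gut 9.1

retrorsine AUC24 as % of the rifampicin-free reference:
  day_1_after_first_dose     plasma  107.7  liver  169.7  gut  103.8
  day_14_after_first_dose    plasma   80.1  liver   64.1  gut   81.1
  day_2_after_last_dose      plasma   66.5  liver   14.9  gut   69.7
  day_14_after_last_dose     plasma   99.7  liver   97.1  gut   99.9

cumulative liver CYP3A4 metabolites at 5 weeks: 48.4 -> 50.7 nmol (105% of reference)
cumulative gut CYP3A4 metabolites at 5 weeks: 5.8 -> 14.9 nmol (257% of reference)
```

Reading the numbers: rifampicin's competitive inhibition acts immediately,
so on day 1 of co-exposure liver retrorsine AUC24 *rises* to ~170% of
reference. Induction of CYP3A4 builds over the two-week course and peaks
about a day after the last rifampicin dose — when the inhibitor is gone but
the enzyme is still ~10-fold elevated — driving liver exposure down to ~15%
of reference. The toxicologically relevant outcome is the ~2.6-fold surge
in intestinal CYP3A4 (bioactivating) metabolite formation, while the
hepatic cumulative amount barely changes because induction also strips the
gut first-pass supply to the liver.

Other entry points: `examples/invitro_to_ivive.py` (assay → clearance
scaling), `examples/single_dose_kinetics.py` (clearance, bioavailability
F = F_a·F_g·F_h = 44%, elimination routes), and
`examples/sensitivity_analysis.py` (f_m,CYP3A4 dominates both tissues).

A thin CLI mirrors the stages:

```sh
retropbtk gen-synthetic --kind medium-loss --out ml.csv --seed 1
retropbtk fit-invitro --data ml.csv --assay medium-loss --condition 37 --out fit.csv
retropbtk simulate-scenario --scenario herbal_tea_plus_rifampicin --out metrics.csv
retropbtk sensitivity --out sens.csv
```

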