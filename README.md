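# mrisubtype

Continuous and categorical MRI atrophy subtyping of mild-cognitive-impairment
(MCI) cohorts, with treatment-response interaction models and a synthetic
randomized-trial generator.

## The problem

Clinical trials of symptomatic AD treatments (e.g. donepezil) recruit
biologically heterogeneous MCI populations, and response may depend on a
patient's baseline pattern of brain atrophy. This package implements the
full analysis for that question on tabular regional morphometry (Desikan
volumes/thicknesses, totals, intracranial volume) plus clinical data:

* **Continuous subtyping dimensions.** Severity = the BV/CSF index,
  `(GM + WM) / CSF` (lower = more global atrophy); typicality = the
  hippocampus-to-cortex ratio, `mean(hipp L, R) / mean over {middle frontal,
  inferior parietal, superior temporal} of the L/R mean volume` (lower =
  limbic-predominant-like, higher = hippocampal-sparing-like).
* **Categorical subtypes** from visual-rating scores with age-banded cut
  points (MTA >= 1.5 / 2.0 / 2.5 at 45-74 / 75-84 / 85-94 years; PA, GCA-F
  >= 1): typical AD, limbic-predominant, hippocampal-sparing, minimal
  atrophy.
* **Efficacy outcomes.** Annualized percentage change
  `APC = (V_followup − V_baseline)/V_baseline × 365/interval × 100` of
  ICV-adjusted hippocampal, ventricular and grey-matter volumes and of the
  AD-signature cortical thickness; plain percentage change of cognitive
  scores. ICV adjustment is the residual approach (one baseline-fitted slope
  applied at both visits).
* **Inference.** OLS interaction models
  `APC ~ treatment + severity + typicality + age (+ field strength) +
  severity×treatment + typicality×treatment`, optional backward selection
  under BIC with marginality; between-subjects subtype×treatment ANCOVA
  (Type-II SS) with Benjamini–Hochberg-adjusted post hocs; baseline
  group-comparison tables (ANOVA / Kruskal–Wallis / chi-square).
* **Simulation.** A fully configurable two-arm two-visit cohort generator
  whose defaults emulate an amnestic-MCI trial (n = 173, 12-month follow-up
  with 10% early scans), with injectable treatment-by-dimension effects, a
  matching null generator, and an amnestic-MCI scenario preset — so type-I
  error, power and parameter recovery are all measurable.

See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
import mrisubtype as ms

cfg = ms.scenario_amnestic_mci(ms.SimulationConfig(n_subjects=173, seed=7))
cohort = ms.generate_cohort(cfg, validate=True)

derived = ms.derive_measures(cohort)               # dimensions, APCs, PCs
profiles, freq = ms.build_subtype_profiles(cohort, derived)
print(freq[freq.kind == "categorical_subtype"].to_string(index=False))

data = ms.build_analysis_table(cohort, derived, profiles)
res = ms.fit_interaction_model(data, ms.ModelSpec("apc_ad_signature"))
print(res.terms.round(4).to_string())
```

prints

```
               kind               level  n       pct
categorical_subtype          typical_AD 10  5.780347
categorical_subtype  limbic_predominant 54 31.213873
categorical_subtype hippocampal_sparing 12  6.936416
categorical_subtype     minimal_atrophy 97 56.069364

                              B      se        t       p
const                   20.9100  0.8839  23.6570  0.0000
age                     -0.1048  0.0088 -11.9302  0.0000
field_strength          -0.0003  0.1314  -0.0021  0.9983
treatment               -1.5831  0.8125  -1.9485  0.0530
severity                 0.0122  0.0065   1.8633  0.0642
typicality             -71.9811  2.7787 -25.9049  0.0000
severity_x_treatment     0.1130  0.0095  11.9241  0.0000
typicality_x_treatment  11.9573  3.9121   3.0565  0.0026
```

The frequency table shows the composition an amnestic-MCI screen produces:
minimal-atrophy and limbic-predominant dominate. In the regression, the two
interaction rows are the effects of interest — here the positive
`severity_x_treatment` and `typicality_x_treatment` coefficients say the
treated arm loses less AD-signature thickness per year than placebo
specifically in subjects with higher BV/CSF index (less global atrophy) and
higher hippocampus-to-cortex ratio (hippocampal sparing). The generator
injected these effects (0.11 and 16.4 %/year per unit), and the fit at a
single n = 173 recovers them within sampling error.

## Command line

```bash
mrisubtype run --simulate --seed 11 --out results/run1      # whole pipeline
mrisubtype simulate --seed 3 --out data/                    # cohort CSVs + truth.json
mrisubtype derive   --morphometry data/morphometry.csv --clinical data/clinical.csv --out derived.csv
mrisubtype subtype  --morphometry ... --clinical ... --out results/
mrisubtype fit      --morphometry ... --clinical ... --selection backward --out results/
```

`run` writes `derived.csv`, `subtypes.csv`, `subtype_frequencies.csv`,
`interaction_models.csv`, `anova_models.csv`, `anova_posthoc.csv`,
`baseline_table.csv`, the two figures (dimension-plane scatter and
severity-band bar chart, SVG) and `manifest.json` with content digests;
reruns with the same seed are byte-identical. Input CSV schemas and all cut
points live in `src/mrisubtype/data/default_config.yaml` (override with
`--config`).

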