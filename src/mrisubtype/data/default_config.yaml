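# Default analysis configuration: controlled vocabularies and cut-point tables.
# All rule tables used by the classifier live here, not in code, so they are
# auditable and versioned.

cortical_regions:
  - bankssts
  - caudalanteriorcingulate
  - caudalmiddlefrontal
  - cuneus
  - entorhinal
  - frontalpole
  - fusiform
  - inferiorparietal
  - inferiortemporal
  - insula
  - isthmuscingulate
  - lateraloccipital
  - lateralorbitofrontal
  - lingual
  - medialorbitofrontal
  - middletemporal
  - paracentral
  - parahippocampal
  - parsopercularis
  - parsorbitalis
  - parstriangularis
  - pericalcarine
  - postcentral
  - posteriorcingulate
  - precentral
  - precuneus
  - rostralanteriorcingulate
  - rostralmiddlefrontal
  - superiorfrontal
  - superiorparietal
  - superiortemporal
  - supramarginal
  - temporalpole
  - transversetemporal

subcortical_structures:
  - hippocampus
  - lateral_ventricle
  - amygdala
  - thalamus
  - caudate
  - putamen

required_subcortical:
  - hippocampus
  - lateral_ventricle

# Cortical aggregates entering the hippocampus-to-cortex (typicality) ratio.
# "Middle frontal" is not a single Desikan label; it is the sum of the caudal
# and rostral middle frontal parcels per hemisphere.
typicality_regions:
  middle_frontal: [caudalmiddlefrontal, rostralmiddlefrontal]
  inferior_parietal: [inferiorparietal]
  superior_temporal: [superiortemporal]

# Regions of the AD-signature cortical thickness composite.
signature_regions: [entorhinal, inferiortemporal, middletemporal, fusiform]

cognitive_tests: [mmse, adas_cog_mci, tmt_a, tmt_b, benton, isaacs_15, isaacs_60]

# Baseline-table variables tested with Kruskal-Wallis instead of one-way ANOVA.
kruskal_variables: []

cutpoints:
  # Age-banded MTA abnormality thresholds (score >= cut is abnormal).
  # Bands are [age_min, age_max); the last band includes its upper edge.
  # Ages outside 45-94 are an error, never extrapolated.
  mta:
    - {age_min: 45, age_max: 75, cut: 1.5}
    - {age_min: 75, age_max: 85, cut: 2.0}
    - {age_min: 85, age_max: 94, cut: 2.5}
  pa: 1.0
  gcaf: 1.0
  # Age-banded thresholds on the BV/CSF index for descriptive severity bands
  # (index >= no_atrophy -> no atrophy; >= mild -> mild; >= moderate ->
  # moderate; below -> severe; a value exactly on a boundary falls in the
  # less-atrophic band).
  # PLACEHOLDER VALUES: the published age-adjusted clinical cut-offs are not
  # restated here; edit this table to use canonical thresholds.
  severity_bands:
    - {age_min: 45, age_max: 75, no_atrophy: 22.0, mild: 16.0, moderate: 11.0}
    - {age_min: 75, age_max: 85, no_atrophy: 18.0, mild: 13.0, moderate: 9.0}
    - {age_min: 85, age_max: 94, no_atrophy: 15.0, mild: 11.0, moderate: 7.0}

# Display scaling applied to the hippocampus-to-cortex ratio in reports only;
# the ratio is stored raw everywhere else.
hc_ratio_display_scale: 100.0
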