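"""Classify cerebral small vessel disease from MRI markers.

Applies the rule: WMH/TIV ratio at or above the cohort median AND the
presence of at least one lacune or cerebral microbleed.
"""

import csvd_brainage as cb

atlas = cb.make_atlas(4, 1, 1, voxels_per_region=4)
config = cb.SimulationConfig(n_app=400, seed=3)
subjects, _, _ = cb.generate_application_cohort(config, atlas)

markers = subjects[["subject_id", "wmh_volume_ml", "tiv_l",
                    "lacune_count", "cmb_count"]]
result = cb.classify_csvd(markers, percentile=50)

counts = result.subgroup_counts()
print(f"WMH/TIV threshold (cohort median): {result.threshold:.2e}")
print(f"CSVD group: {counts['n_csvd']} of {len(subjects)} subjects")
print(f"  with lacunes: {counts['n_lacune']} "
      f"({100 * counts['n_lacune'] / counts['n_csvd']:.1f}%)")
print(f"  with CMBs:    {counts['n_cmb']} "
      f"({100 * counts['n_cmb'] / counts['n_csvd']:.1f}%)")
print(f"  with both:    {counts['n_both']} "
      f"({100 * counts['n_both'] / counts['n_csvd']:.1f}%)")
# Lacune + CMB - both equals the group size because the rule requires at
# least one lesion type in every classified subject.
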