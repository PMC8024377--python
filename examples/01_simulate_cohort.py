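"""Simulate a multi-trial MS cohort and inspect its planted structure.

The generator stands in for pooled clinical-trial MRI data: healthy
controls with covariate-driven features, and patients drawn from three
latent subtypes, each progressing along its own event sequence.
"""

import mssustain as ms

config, controls, patients = ms.default_fixture()

print(f"controls: {controls['subject_id'].nunique()} subjects, "
      f"{len(config.features)} MRI features")
print(f"patients: {patients['subject_id'].nunique()} subjects over "
      f"{patients['dataset_id'].nunique()} pseudo-trials, "
      f"{len(patients)} visits")
print(f"event grid: {len(config.affected_features)} affected features "
      f"x {len(config.thresholds)} z-thresholds = {config.n_events} stages")

base = patients.loc[patients.groupby("subject_id")["visit_time"].idxmin()]
print("\nplanted subtype mix and baseline clinical profile:")
for c, name in enumerate(("cortex-led", "NAWM-led", "lesion-led")):
    sub = base[base["true_subtype"] == c]
    print(f"  {name:<11} fraction {len(sub) / len(base):.3f} "
          f"(planted {config.fractions[c]}), "
          f"mean stage {sub['true_stage'].mean():5.1f}, "
          f"mean EDSS {sub['edss'].mean():.2f}")

# The lesion-led subtype is planted with the most active, most rapidly
# progressing disease; the stage/EDSS gradient above reflects the
# stage-disability coupling used by every downstream endpoint analysis.
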