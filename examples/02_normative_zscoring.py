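"""Fit the normative covariate model on controls and screen features.

Each MRI variable is regressed on TIV, sex, age and age squared in healthy
controls; patients are z-scored against that model (control residual SD as
the unit) and features are kept when the patient-versus-control effect
size exceeds Cohen's D 0.5.
"""

import mssustain as ms

config, controls, patients = ms.default_fixture()

model = ms.fit_normative(controls)
selection = ms.select_features(controls, patients, threshold=0.5,
                               model=model)

print("per-feature Cohen's D (patients at baseline vs controls):")
for f, d in sorted(selection.effect_sizes.items(), key=lambda kv: -abs(kv[1])):
    marker = "retained" if f in selection.retained else "dropped "
    print(f"  {marker}  {f:<18} D = {d:+.2f}")
print(f"\n{len(selection.retained)} of {len(model.features)} features pass "
      f"|D| > {selection.threshold}")

Z = ms.compute_zscores(patients, model, features=list(selection.retained))
print("\nz-score table:", Z.shape[0], "visits x",
      len(selection.retained), "features")
print("sign convention: volumes and T1/T2 ratios are flipped, so higher z "
      "always means worse disease;")
print("mean z of the retained features at baseline:",
      round(Z[list(selection.retained)].to_numpy().mean(), 2))
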