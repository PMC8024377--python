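"""Fit the z-score event-sequence subtype mixture and stage every visit.

Uses a scaled-down cohort so the example runs in about a minute; the
fitted sequences are compared with the planted orderings by rank
correlation.
"""

import numpy as np
from scipy.stats import kendalltau

import mssustain as ms

config = ms.default_config()
controls = ms.generate_controls(config, 300)
patients = ms.generate_patients(config, 600, n_datasets=3, n_visits=1)

norm = ms.fit_normative(controls)
sel = ms.select_features(controls, patients, model=norm)
Z = ms.compute_zscores(patients, norm, features=list(sel.retained))
grid = ms.build_event_grid(sel.retained)

opts = ms.SustainOptions(starts=3, split_starts=2, em_max_iter=10,
                         em_tol=0.01, sigma=config.noise_scale, seed=0)
model = ms.fit_sustain(Z, grid, 3, opts)
print("fitted mixture fractions:", np.round(model.fractions, 3))

truth = ms.planted_model(config)
for c in range(3):
    taus = [kendalltau(np.argsort(truth.sequences[t]),
                       np.argsort(model.sequences[c])).statistic
            for t in range(3)]
    t_best = int(np.argmax(taus))
    print(f"fitted subtype {c}: closest planted sequence {t_best} "
          f"(Kendall tau {taus[t_best]:.2f})")

asg = ms.assign(Z, model)
acc_table = asg.table.copy()
acc_table["true_subtype"] = patients["true_subtype"].to_numpy()
print("\nper-visit staging: modal stage mean",
      round(asg.table["modal_stage"].mean(), 1),
      "(planted stage mean", round(patients["true_stage"].mean(), 1), ")")
print("a high Kendall tau per subtype means the temporal ordering of MRI "
      "abnormalities was recovered, not just the cluster membership")
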