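"""Classify subjects from one-hot pattern encodings.

A planted group-unique transition motif makes the task learnable: subjects
of one group take excursions through the anticorrelated-block state that
the other group's chain never produces.  RF and LDA are tuned on a
stratified 80/20 split and evaluated by repeated stratified 10-fold CV.
"""

import numpy as np

from dfncpm import (
    ClassificationProtocol, GroupSpec, MiningSpec, MotifSpec, SyntheticConfig,
    WindowSpec, assign_states, dichotomic_split, estimate_windowed_fc,
    evaluate_classifiers, fit_states, mine_patterns, one_hot_encode,
    simulate_cohort,
)

base = ((0.97, 0.015, 0.015), (0.03, 0.97, 0.0), (0.03, 0.0, 0.97))
cfg = SyntheticConfig(
    seed=42,
    groups=(GroupSpec("PD", 24, base), GroupSpec("HC", 24, base)),
    motifs=(MotifSpec("PD", (2, 3, 2, 3, 2), 1.0, dwell_volumes=28),),
)
cohort, _ = simulate_cohort(cfg)
series = [estimate_windowed_fc(s.data, WindowSpec(), subject_id=s.subject_id)
          for s in cohort.subjects]
model = fit_states(np.vstack([s.values for s in series]), k=3, seed=0)
seqs = {s.subject_id: assign_states(model, ser)
        for s, ser in zip(cohort.subjects, series)}
groups = {s.subject_id: s.group for s in cohort.subjects}

mining = MiningSpec(max_length=5)
pd_pat = mine_patterns([q for i, q in seqs.items() if groups[i] == "PD"], mining)
hc_pat = mine_patterns([q for i, q in seqs.items() if groups[i] == "HC"], mining)
dpm = dichotomic_split(pd_pat, hc_pat)
feats = one_hot_encode(list(seqs.values()), dpm.unique_a, n_states=3, groups=groups)
print(f"features: {feats.values.shape[0]} subjects x "
      f"{feats.values.shape[1]} PD-unique patterns")

protocol = ClassificationProtocol(cv_repeats=20, seed=0)  # 100 in full runs
report = evaluate_classifiers(feats, protocol)
for name in ("rf", "lda"):
    m = report.cv_metrics[name]
    print(f"{name.upper()}: accuracy {m['accuracy'][0]:.3f} ± {m['accuracy'][1]:.3f}, "
          f"AUC {m['auc'][0]:.3f}")
    top = ", ".join(f for f, _ in report.importances[name][:3])
    print(f"  top discriminative patterns: {top}")
# High accuracy with the planted motif among the top patterns shows the
# pipeline recovers group-specific transition structure end to end.
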