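"""Simulate a synthetic two-group cohort of network time courses.

Each subject is a 196-volume x 11-component matrix whose instantaneous
covariance switches among three latent connectivity states (hypo-connected,
hyper-connected, anticorrelated-block) under a group-specific Markov chain.
The impaired-like group dwells longer in the hypo-connected state 1.
"""

import numpy as np

from dfncpm import SyntheticConfig, simulate_cohort
from dfncpm.synthetic import stationary_distribution

cfg = SyntheticConfig(seed=42)
cohort, truth = simulate_cohort(cfg)

print(f"cohort: {len(cohort.subjects)} subjects, "
      f"matrix shape {cohort.subjects[0].data.shape} (volumes x components)")
for group in cfg.groups:
    pi = stationary_distribution(group.matrix())
    occ = np.mean([
        np.mean(truth.state_paths[s.subject_id] == 1)
        for s in cohort.subjects if s.group == group.label
    ])
    print(f"  {group.label}: stationary P(state 1) = {pi[0]:.3f}, "
          f"empirical occupancy of state 1 = {occ:.3f}")
# The impaired-like group should show the higher state-1 occupancy: its
# chain has an elevated self-transition for the hypo-connected state.
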