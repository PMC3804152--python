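"""Classify an oracle-labeled seat-off cohort with both pendulum models.

Labels ~150 seat-off states by exhaustive admissible-torque search, then
scores the stability predictions of the inertia-variable and the simple
map against those labels.
"""

from dataclasses import replace

import numpy as np

from stsbalance import (
    SyntheticSpec,
    classify_state,
    classify_trials,
    compute_balance_map,
    make_inertia_profile,
    make_subject,
    oracle_label_batch,
)
import pandas as pd

spec = SyntheticSpec(seed=1)
sub = make_subject(spec, 0)
sub = replace(sub, tau_pf_max=2.2 * sub.mass, tau_df_max=0.8 * sub.mass)
profile = make_inertia_profile(sub, variation=0.25)
bmap_var = compute_balance_map(sub, profile, model="variable")
bmap_simple = compute_balance_map(sub, profile, model="simple")

rng = np.random.default_rng(11)
xs = rng.uniform(0.15, 1.9, 150)
vs = rng.uniform(0.0, 0.85, 150)
labels = oracle_label_batch(xs, vs, sub, profile)
keep = labels != "indeterminate"
df = pd.DataFrame({"trial_id": [f"T{i}" for i in range(int(keep.sum()))],
                   "x_footlen": xs[keep], "v_heights_per_s": vs[keep],
                   "outcome": labels[keep]})
print(f"cohort: {len(df)} labeled seat-off states "
      f"({(df.outcome == 'success').sum()} success, "
      f"{(df.outcome == 'failure').sum()} failure)")

for name, bmap in [("inertia-variable", bmap_var), ("simple", bmap_simple)]:
    rep = classify_trials(df, bmap, dx=0.0)
    print(f"{name:17s}: sensitivity "
          f"{100 * rep.sensitivity:.1f}%  specificity "
          f"{100 * rep.specificity:.1f}%  "
          f"(TP={rep.tp} FN={rep.fn} TN={rep.tn} FP={rep.fp})")
print("\nThe simple model misses some high-velocity failures (false "
      "positives near the forward-fall boundary); the variable model "
      "tracks the oracle.")
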