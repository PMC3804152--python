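"""Fit the CM rotational-radius function l(theta) from marker trials.

Simulates two natural sit-to-stands at 120 Hz marker level (1 mm noise),
estimates the CM segmentally, converts to polar kinematics and fits the
cubic radius function, comparing with the generator's ground truth.
"""

from dataclasses import replace

import numpy as np

from stsbalance import (
    SyntheticSpec,
    estimate_cm,
    fit_inertia_profile,
    kinematics_to_polar,
    make_inertia_profile,
    make_marker_trial,
    make_subject,
)

spec = SyntheticSpec(seed=1)
sub = make_subject(spec, 0)
sub = replace(sub, tau_pf_max=2.2 * sub.mass, tau_df_max=0.8 * sub.mass)
truth = make_inertia_profile(sub, variation=0.25)

polars = []
for seat, seed in [((1.5, 0.32), 11), ((2.1, 0.5), 12)]:
    trial = make_marker_trial(sub, truth, seat, noise_sd=0.001, seed=seed)
    print(f"trial from seat-off x={seat[0]}, v={seat[1]}: {trial.outcome}, "
          f"{len(trial.frames)} frames")
    cm = estimate_cm(trial.frames, sub)
    polars.append(kinematics_to_polar(cm))

fit = fit_inertia_profile(polars, sub.mass)
names = ("a0", "a1", "a3", "a4")
print("\ncoef   fitted      true        SE")
for n, est, tru, se in zip(names, fit.profile.coefficients,
                           truth.coefficients, fit.coef_se):
    print(f"{n}  {est:+.5f}  {tru:+.5f}  {se:.5f}")
print(f"residual RMS: {fit.residual_rms * 1000:.2f} mm over "
      f"{fit.n_samples} samples")
print("\nEach coefficient should sit within a few SE of the generating "
      "value; the RMS reflects the 1 mm marker noise after segmental "
      "averaging.")
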