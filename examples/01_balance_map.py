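"""Compute a sit-to-stand balance map for one synthetic subject.

Builds the stability boundaries and the zero-torque trajectory for both
pendulum models and prints the admissible seat-off velocity window at a
few CM positions.
"""

from dataclasses import replace

from stsbalance import (
    SyntheticSpec,
    compute_balance_map,
    make_inertia_profile,
    make_subject,
)

spec = SyntheticSpec(seed=1)
sub = make_subject(spec, 0)
# generous strength: boundaries limited by foot geometry, not muscle
sub = replace(sub, tau_pf_max=2.2 * sub.mass, tau_df_max=0.8 * sub.mass)
profile = make_inertia_profile(sub, variation=0.25)

print(f"subject: {sub.mass:.1f} kg, {sub.height:.2f} m, "
      f"foot {sub.foot_length * 100:.1f} cm")
print(f"radius profile l(theta): upright {profile.l(1.5708):.3f} m, "
      f"crouched (theta=2.2) {profile.l(2.2):.3f} m")

bmap = compute_balance_map(sub, profile, model="variable")
print("\nx [foot lengths posterior of toe] : admissible seat-off velocity "
      "window [heights/s]")
for x in (0.5, 1.0, 1.5, 1.9):
    lo, hi = float(bmap.lower_at(x)), float(bmap.upper_at(x))
    vz = float(bmap.zero_at(x))
    print(f"  x = {x:.1f}: v in ({lo:+.3f}, {hi:+.3f}), "
          f"zero-torque v = {vz:+.3f}")
print("\nStates inside the window can stop the CM over the foot without "
      "moving it; the zero-torque value is the most energy-efficient "
      "successful velocity at that position.")
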