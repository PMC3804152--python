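"""Synthetic subjects, inertia profiles, marker trials and labeled cohorts.

Everything the analysis modules consume can be generated here, fully
deterministically from a seed:

* subjects with plausible anthropometry and constraint parameters,
* cubic radius profiles l(theta) whose variation amplitude emulates the
  multi-joint shortening of the body between seat-off (crouched, short CM
  radius) and upright stance (long radius),
* 120 Hz marker trials: a 5-segment kinematic chain (15 markers) whose
  body CM follows a forward-simulated pendulum trajectory exactly, with
  optional additive Gaussian marker noise and the ground-truth CM stored
  alongside,
* seat-off cohorts labeled by an exhaustive-control oracle: a vectorised
  breadth-first search over piecewise-constant torque levels (fractions of
  the admissible interval) that decides whether *any* admissible control
  stops the CM over the base of support.

The natural-trial control policy tracks a velocity target a safety margin
above the zero-torque curve, emulating the observation that natural
sit-to-stands carry extra kinetic energy relative to the most
energy-efficient trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .body import MarkerFrame, SubjectModel
from .maps import map_to_state
from .pendulum import (
    G_ACCEL,
    InertiaProfile,
    PendulumState,
    _kinematic_coeffs,
    simulate,
    torque_range_arrays,
)

__all__ = [
    "SyntheticSpec",
    "make_subject",
    "make_inertia_profile",
    "make_marker_trial",
    "MarkerTrial",
    "margin_policy",
    "oracle_label",
    "oracle_label_batch",
    "make_trial_cohort",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters for the synthetic cohort generator."""

    seed: int = 0
    n_subjects: int = 6
    height_range: tuple[float, float] = (1.62, 1.88)   # m, healthy male adults
    mass_range: tuple[float, float] = (55.0, 90.0)     # kg
    foot_ratio: float = 0.152          # foot length / height
    heel_ratio: float = 0.25           # d_heel / foot length
    ankle_height_ratio: float = 0.039  # ankle joint height / height
    mu: float = 0.8                    # shoe sole on lab floor
    tau_pf_per_kg: float = 1.8         # N m / kg, max plantarflexion
    tau_df_per_kg: float = 0.5         # N m / kg, max dorsiflexion
    variation: float = 0.2             # l(theta) variation amplitude
    marker_noise_sd: float = 0.0       # m
    policy: str = "margin"

    def __post_init__(self) -> None:
        for name in ("foot_ratio", "heel_ratio", "ankle_height_ratio", "mu",
                     "tau_pf_per_kg", "tau_df_per_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.variation < 0 or self.marker_noise_sd < 0:
            raise ValueError("variation and marker_noise_sd must be >= 0")
        for name in ("height_range", "mass_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive increasing range")


def make_subject(spec: SyntheticSpec, index: int) -> SubjectModel:
    """Deterministic subject draw: same (seed, index) -> identical subject."""
    rng = np.random.default_rng([spec.seed, 1000 + index])
    height = rng.uniform(*spec.height_range)
    mass = rng.uniform(*spec.mass_range)
    foot_length = spec.foot_ratio * height
    d_heel = spec.heel_ratio * foot_length
    return SubjectModel(
        mass=mass,
        height=height,
        d_toe=foot_length - d_heel,
        d_heel=d_heel,
        ankle_height=spec.ankle_height_ratio * height,
        foot_length=foot_length,
        mu=spec.mu,
        tau_pf_max=spec.tau_pf_per_kg * mass,
        tau_df_max=spec.tau_df_per_kg * mass,
    )


_THETA_MIN, _THETA_MAX = 1.0, 2.45  # rad, seat-off crouch to anterior lean
_THETA_SCALE = 0.7                  # rad, shape scale of the radius variation


def make_inertia_profile(
    subject: SubjectModel,
    variation: float,
    theta_min: float = _THETA_MIN,
    theta_max: float = _THETA_MAX,
) -> InertiaProfile:
    """Cubic radius profile: upright radius 0.55*height, shrinking with
    posterior lean by the given relative ``variation`` amplitude.

    The shape is built directly in the cubic family that the fitting
    routine estimates, so fitting noiseless samples returns the generator's
    coefficients exactly.  A profile that would cross l <= 0 anywhere in
    the domain is rejected and retried with damped variation.
    """
    if variation < 0:
        raise ValueError("variation must be >= 0")
    l_up = 0.55 * subject.height
    c, s0 = np.pi / 2, _THETA_SCALE
    var = float(variation)
    for _ in range(20):
        # l = l_up * (1 - var * (d**2 + 0.1*d**3)),  d = (theta - c)/s0
        k2 = l_up * var / s0**2
        k3 = 0.1 * l_up * var / s0**3
        a0 = -k3
        a1 = -(k2 - 3 * c * k3)
        a3 = -(-2 * c * k2 + 3 * c**2 * k3)
        a4 = l_up - (c**2 * k2 - c**3 * k3)
        th = np.linspace(theta_min, theta_max, 512)
        lv = ((a0 * th + a1) * th + a3) * th + a4
        if np.all(lv > 0.05):
            return InertiaProfile(a0, a1, a3, a4, theta_min, theta_max, subject.mass)
        var *= 0.7
    raise ValueError("could not build a positive radius profile")


# --- natural-trial control policy -------------------------------------------


def margin_policy(subject, profile: InertiaProfile, margin: float = 0.08,
                  gain: float = 8.0):
    """Torque policy tracking a velocity target above the zero-torque curve.

    The target anterior velocity is the simple energy-conservation
    zero-torque velocity at the current radius plus ``margin`` [heights/s];
    the commanded torque realises a proportional correction toward it.
    Emulates the natural strategy of carrying extra kinetic energy for
    safety against the backward-fall boundary.
    """
    m, H = profile.mass, subject.height

    def policy(state: PendulumState) -> float:
        th, om = state.theta, state.omega
        lv = profile.l(th)
        A_u, B_u, _, _ = _kinematic_coeffs(th, profile)
        v = B_u * om / H
        s = np.sin(th)
        if th > np.pi / 2:
            om_zt = -np.sqrt(max(2.0 * G_ACCEL * (1.0 - s) / lv, 0.0))
        else:
            om_zt = 0.0
        # fade the target to zero just past upright so the trial settles at
        # rest over the mid-foot instead of coasting beyond the BOS
        fade = min(max((th - (np.pi / 2 - 0.08)) / 0.15, 0.0), 1.0)
        v_t = (B_u * om_zt / H + margin) * fade
        alpha_c = (-gain * (v - v_t) * H - A_u * om**2) / B_u
        grav = m * G_ACCEL * lv * np.cos(th)
        return float(m * lv**2 * alpha_c + grav + profile.dinertia(th) * om**2)

    return policy


# --- marker-level trial generation ------------------------------------------

_MARKER_Y = {"ANK": 0.05, "HEEL": 0.05, "TOE": 0.05, "KNEE": 0.07, "HIP": 0.09}


def _posture_markers(theta: float, subject: SubjectModel, profile: InertiaProfile):
    """15-marker posture whose segmental body CM is exactly the pendulum CM.

    Foot, shank and thigh follow a smooth crouch-to-stand schedule in
    theta; the trunk and head segments are then positioned along the trunk
    axis so that the mass-fraction-weighted CM of all five segments equals
    the target (l(theta)*cos(theta), l(theta)*sin(theta)) ankle-relative CM
    by construction.
    """
    H = subject.height
    a = subject.ankle_height
    xa = 0.3  # lab-frame ankle x, arbitrary
    lv = profile.l(theta)
    target = np.array([xa + lv * np.cos(theta), a + lv * np.sin(theta)])

    crouch = np.clip((theta - np.pi / 2) / 0.8, -0.3, 1.3)
    phi_sh = 0.05 + 0.45 * crouch          # shank lean, forward of vertical
    psi_th = -0.05 - 1.15 * crouch         # thigh lean, hip posterior of knee
    chi_tr = 0.08 + 0.90 * crouch          # trunk lean

    ank = np.array([xa, a])
    knee = ank + 0.246 * H * np.array([np.sin(phi_sh), np.cos(phi_sh)])
    hip = knee + 0.245 * H * np.array([np.sin(psi_th), np.cos(psi_th)])
    heel = np.array([xa - subject.d_heel, 0.02])
    toe = np.array([xa + subject.d_toe, 0.02])

    segs = {s.name: s for s in subject.segment_table}
    c_foot = 0.5 * (heel + toe)
    c_shank = 0.5 * (knee + ank)
    c_thigh = 0.5 * (hip + knee)
    f_known = (segs["foot"].fraction * c_foot
               + segs["shank"].fraction * c_shank
               + segs["thigh"].fraction * c_thigh)
    f_rest = segs["trunk"].fraction + segs["head"].fraction
    c_rest = (target - f_known) / f_rest

    e = np.array([np.sin(chi_tr), np.cos(chi_tr)])   # trunk axis, up-forward
    n = np.array([np.cos(chi_tr), -np.sin(chi_tr)])  # anterior normal
    L_tr, L_hd = 0.30 * H, 0.13 * H
    h_vec = 0.5 * (L_tr + L_hd) * e                  # head CM - trunk CM
    c_tr = c_rest - (segs["head"].fraction / f_rest) * h_vec
    sacrum = c_tr - 0.5 * L_tr * e
    c7 = sacrum + L_tr * e
    vertex = c7 + L_hd * e
    sternum = sacrum + 0.6 * L_tr * e + 0.08 * n
    forehead = vertex - 0.04 * e + 0.09 * n

    def lat(name, p):
        y = _MARKER_Y[name]
        return {f"L{name}": (p[0], -y, p[1]), f"R{name}": (p[0], y, p[1])}

    markers: dict[str, tuple[float, float, float]] = {}
    for name, p in (("ANK", ank), ("HEEL", heel), ("TOE", toe),
                    ("KNEE", knee), ("HIP", hip)):
        markers.update(lat(name, p))
    for name, p in (("SACRUM", sacrum), ("C7", c7), ("VERTEX", vertex),
                    ("STERNUM", sternum), ("FOREHEAD", forehead)):
        markers[name] = (p[0], 0.0, p[1])
    return markers


@dataclass
class MarkerTrial:
    """One synthetic sit-to-stand trial at marker level."""

    frames: list[MarkerFrame]
    truth: pd.DataFrame            # time, u, h, theta, omega (ground truth)
    seatoff_x: float
    seatoff_v: float
    outcome: str                   # "success" | "failure"
    failure_mode: str = ""
    meta: dict = field(default_factory=dict)


def make_marker_trial(
    subject: SubjectModel,
    profile: InertiaProfile,
    seatoff: tuple[float, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    fs: float = 120.0,
    t_max: float = 3.0,
    policy=None,
    margin: float = 0.08,
) -> MarkerTrial:
    """Forward-simulate a sit-to-stand from a seat-off state (x, v) and
    emit 120 Hz marker frames; ground-truth CM stored alongside."""
    x0, v0 = seatoff
    state0 = map_to_state(x0, v0, subject, profile)
    if policy is None:
        policy = margin_policy(subject, profile, margin=margin)
    H = subject.height
    v_stop = 0.02  # heights/s

    def stopped(st: PendulumState) -> bool:
        u = profile.l(st.theta) * np.cos(st.theta)
        _, B_u, _, _ = _kinematic_coeffs(st.theta, profile)
        v = B_u * st.omega / H
        return (-subject.d_heel < u < subject.d_toe) and abs(v) <= v_stop

    dt = 1.0 / fs
    res = simulate(state0, policy, profile, subject, dt, int(round(t_max * fs)),
                   stop=stopped)
    final = PendulumState(float(res.theta[-1]), float(res.omega[-1]))
    if res.status == "ok" and stopped(final):
        outcome, mode = "success", ""
    else:
        outcome = "failure"
        mode = res.status if res.status != "ok" else "timeout"

    rng = np.random.default_rng([seed, 77])
    frames = []
    us, hs = [], []
    for i, (t, th) in enumerate(zip(res.time, res.theta)):
        markers = _posture_markers(float(th), subject, profile)
        if noise_sd > 0:
            noisy = {}
            for name, p in markers.items():
                noisy[name] = tuple(np.asarray(p) + rng.normal(0.0, noise_sd, 3))
            markers = noisy
        frames.append(MarkerFrame(time=float(t), positions=markers))
        lv = profile.l(float(th))
        us.append(lv * np.cos(float(th)))
        hs.append(lv * np.sin(float(th)))
    truth = pd.DataFrame({
        "time": res.time, "u": us, "h": hs,
        "theta": res.theta, "omega": res.omega,
    })
    return MarkerTrial(frames, truth, x0, v0, outcome, mode,
                       meta={"clamped": res.clamped, "noise_sd": noise_sd,
                             "seed": seed, "fs": fs})


# --- exhaustive-control reachability oracle ----------------------------------


def _alpha_vec(th, om, tau, profile):
    lv = profile.l(th)
    grav = profile.mass * G_ACCEL * lv * np.cos(th)
    return (tau - grav - profile.dinertia(th) * om**2) / (profile.mass * lv**2)


def _rk4_vec(th, om, tau, profile, dt):
    k1t, k1o = om, _alpha_vec(th, om, tau, profile)
    k2t = om + 0.5 * dt * k1o
    k2o = _alpha_vec(th + 0.5 * dt * k1t, k2t, tau, profile)
    k3t = om + 0.5 * dt * k2o
    k3o = _alpha_vec(th + 0.5 * dt * k2t, k3t, tau, profile)
    k4t = om + dt * k3o
    k4o = _alpha_vec(th + dt * k3t, k4t, tau, profile)
    return (th + dt * (k1t + 2 * k2t + 2 * k3t + k4t) / 6.0,
            om + dt * (k1o + 2 * k2o + 2 * k3o + k4o) / 6.0)


def _check_success(th, om, subject, profile, v_stop):
    """Captured: CM over the BOS, nearly at rest, and statically holdable."""
    lv = profile.l(th)
    u = lv * np.cos(th)
    _, B_u, _, _ = _kinematic_coeffs(th, profile)
    v = B_u * om / subject.height
    cand = ((u > -subject.d_heel) & (u < subject.d_toe)
            & (np.abs(v) <= v_stop))
    if not np.any(cand):
        return cand
    idx = np.nonzero(cand)[0]
    lo, hi, ok, _, _ = torque_range_arrays(
        th[idx], np.zeros(idx.size), profile, subject
    )
    grav = profile.mass * G_ACCEL * profile.l(th[idx]) * np.cos(th[idx])
    hold = ok & (lo <= grav) & (grav <= hi)
    out = np.zeros_like(cand)
    out[idx] = hold
    return out


def oracle_label_batch(
    xs,
    vs,
    subject: SubjectModel,
    profile: InertiaProfile,
    depth: int = 8,
    n_levels: int = 5,
    seg_dt: float = 0.2,
    n_sub: int = 12,
    v_stop: float = 0.02,
    n_bins: int = 240,
) -> np.ndarray:
    """Label seat-off states by exhaustive piecewise-constant torque search.

    Controls are sequences (one per segment of duration ``seg_dt``) of
    fractions of the admissible torque interval, on ``n_levels`` levels;
    the fraction is held for a segment while the interval itself is
    re-evaluated along the trajectory, so every candidate control is
    admissible by construction.  Branches are deduplicated per root on an
    (theta, omega) bin grid, making the search a breadth-first reachable-set
    sweep.  Returns per state: "success" if some control stops the CM over
    the BOS, "failure" if every branch falls (constraint infeasibility or
    leaving the domain), "indeterminate" if branches survive the horizon
    without stopping.
    """
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    vs = np.atleast_1d(np.asarray(vs, dtype=float))
    n = xs.size
    th0 = np.empty(n)
    om0 = np.empty(n)
    for i in range(n):
        st = map_to_state(float(xs[i]), float(vs[i]), subject, profile)
        th0[i], om0[i] = st.theta, st.omega

    success = np.zeros(n, dtype=bool)
    exhausted = np.zeros(n, dtype=bool)  # horizon reached with live branches
    th, om, root = th0.copy(), om0.copy(), np.arange(n)

    # initial capture check
    cap = _check_success(th, om, subject, profile, v_stop)
    success[root[cap]] = True
    keep = ~cap
    th, om, root = th[keep], om[keep], root[keep]

    levels = np.linspace(0.0, 1.0, n_levels)
    dth_bin = (profile.theta_max - profile.theta_min) / n_bins
    dom_bin = 12.0 / n_bins
    dt = seg_dt / n_sub

    for _ in range(depth):
        if th.size == 0:
            break
        th = np.repeat(th, n_levels)
        om = np.repeat(om, n_levels)
        root_b = np.repeat(root, n_levels)
        frac = np.tile(levels, root.size)
        alive = np.ones(th.size, dtype=bool)
        for _ in range(n_sub):
            inside = ((th >= profile.theta_min) & (th <= profile.theta_max)
                      & (np.abs(om) < 12.0))
            alive &= inside
            if not np.any(alive):
                break
            ia = np.nonzero(alive)[0]
            lo, hi, ok, _, _ = torque_range_arrays(th[ia], om[ia], profile, subject)
            dead = ~ok
            alive[ia[dead]] = False
            ia = ia[~dead]
            if ia.size == 0:
                break
            tau = lo[~dead] + frac[ia] * (hi[~dead] - lo[~dead])
            th_n, om_n = _rk4_vec(th[ia], om[ia], tau, profile, dt)
            th[ia], om[ia] = th_n, om_n
            cap = _check_success(th_n, om_n, subject, profile, v_stop)
            if np.any(cap):
                success[root_b[ia[cap]]] = True
                alive[ia[cap]] = False  # captured branches need no expansion
        keep = alive & ~success[root_b]
        th, om, root = th[keep], om[keep], root_b[keep]
        if th.size == 0:
            break
        # deduplicate per root on a state-bin grid
        bi = np.clip(np.round((th - profile.theta_min) / dth_bin), 0, n_bins + 1).astype(np.int64)
        bj = np.clip(np.round((om + 6.0) / dom_bin), 0, n_bins + 1).astype(np.int64)
        key = (root * (n_bins + 2) + bi) * (n_bins + 2) + bj
        _, first = np.unique(key, return_index=True)
        th, om, root = th[first], om[first], root[first]

    exhausted[np.unique(root)] = True
    labels = np.where(success, "success",
                      np.where(exhausted, "indeterminate", "failure"))
    return labels


def oracle_label(
    seatoff: tuple[float, float],
    subject: SubjectModel,
    profile: InertiaProfile,
    **kwargs,
) -> str:
    """Single-state convenience wrapper around :func:`oracle_label_batch`."""
    return str(oracle_label_batch([seatoff[0]], [seatoff[1]], subject, profile,
                                  **kwargs)[0])


# --- labeled cohorts ---------------------------------------------------------


def make_trial_cohort(
    subject: SubjectModel,
    profile: InertiaProfile,
    n_trials: int = 120,
    seed: int = 0,
    x_range: tuple[float, float] = (0.2, 2.4),
    v_range: tuple[float, float] = (0.0, 0.7),
    condition_threshold: float = 2.48,
    oracle_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Seat-off cohort labeled by the exhaustive-control oracle.

    States are drawn uniformly over the (x, v) window and labeled
    success/failure/indeterminate; the condition column splits trials at
    the configurable seat-off distance threshold (in foot lengths).
    """
    rng = np.random.default_rng([seed, 4242])
    xs = rng.uniform(x_range[0], x_range[1], n_trials)
    vs = rng.uniform(v_range[0], v_range[1], n_trials)
    labels = oracle_label_batch(xs, vs, subject, profile, **(oracle_kwargs or {}))
    return pd.DataFrame({
        "trial_id": [f"T{i:04d}" for i in range(n_trials)],
        "x_footlen": xs,
        "v_heights_per_s": vs,
        "outcome": labels,
        "condition": np.where(xs <= condition_threshold, "normal", "demanding"),
    })
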