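"""Single-joint inverted-pendulum dynamics for sagittal-plane balance.

Two models share one code path.  The *simple* model is the classical
inverted pendulum with constant center-of-mass (CM) rotational radius
``l``:

    tau - m g l cos(theta) = m l**2 * alpha

The *variable* (telescopic) model lets the radius vary with the CM angle,
``l = l(theta)``, which captures the multi-joint shortening and lengthening
of the body during sit-to-stand while keeping a single degree of freedom.
With rotational inertia ``I(theta) = m l(theta)**2`` the angular-momentum
theorem about the ankle gives

    tau - m g l(theta) cos(theta) = I'(theta) * omega**2 + I(theta) * alpha

``theta`` is measured from the anterior horizontal axis (``theta = pi/2``
when the CM is directly above the ankle, larger when posterior), and
positive ``tau`` is plantarflexion (the braking direction for a forward
fall).  Both equations are exact statements of d(I*omega)/dt = net torque
about the ankle, so no further dynamic terms appear even though the radius
change is driven by internal (muscular) forces.

The admissible ankle torque at a state is bounded by the requirements that
the foot neither slides nor tips and that the torque stays within
physiological limits.  Because the angular acceleration is affine in tau,
every one of those constraints is an affine inequality in tau and the
admissible set is a (possibly empty) closed interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

G_ACCEL = 9.81  # m/s^2

__all__ = [
    "G_ACCEL",
    "InertiaProfile",
    "PendulumState",
    "TorqueRange",
    "angular_acceleration",
    "reaction_forces",
    "admissible_torque_range",
    "torque_range_arrays",
    "step",
    "simulate",
    "SimulationResult",
]


@dataclass(frozen=True)
class InertiaProfile:
    """Cubic CM rotational-radius function l(theta) and derived inertia.

    l(theta) = a0*theta**3 + a1*theta**2 + a3*theta + a4   [m]
    I(theta) = mass * l(theta)**2                          [kg m^2]

    Coefficient names follow the a0, a1, a3, a4 convention of the fitted
    radius polynomial (there is no coefficient named a2).
    """

    a0: float
    a1: float
    a3: float
    a4: float
    theta_min: float
    theta_max: float
    mass: float

    def __post_init__(self) -> None:
        if not (self.mass > 0):
            raise ValueError(f"mass must be positive, got {self.mass}")
        if not (self.theta_max > self.theta_min):
            raise ValueError("theta_domain must satisfy theta_min < theta_max")
        th = np.linspace(self.theta_min, self.theta_max, 512)
        if np.any(self.l(th) <= 0):
            raise ValueError("l(theta) must be positive over theta_domain")

    # -- radius and derivatives -------------------------------------------------
    def l(self, theta):  # noqa: E743 - field notation
        return ((self.a0 * theta + self.a1) * theta + self.a3) * theta + self.a4

    def dl(self, theta):
        return (3.0 * self.a0 * theta + 2.0 * self.a1) * theta + self.a3

    def d2l(self, theta):
        return 6.0 * self.a0 * theta + 2.0 * self.a1

    def inertia(self, theta):
        return self.mass * self.l(theta) ** 2

    def dinertia(self, theta):
        return 2.0 * self.mass * self.l(theta) * self.dl(theta)

    @property
    def is_constant(self) -> bool:
        return self.a0 == 0.0 and self.a1 == 0.0 and self.a3 == 0.0

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.a0, self.a1, self.a3, self.a4)

    @classmethod
    def constant(
        cls,
        length: float,
        mass: float,
        theta_min: float = 0.2,
        theta_max: float = np.pi - 0.2,
    ) -> "InertiaProfile":
        """Constant-radius profile: the simple inverted pendulum."""
        return cls(0.0, 0.0, 0.0, float(length), theta_min, theta_max, mass)

    def to_constant(self, theta: float = np.pi / 2) -> "InertiaProfile":
        """Freeze the radius at ``l(theta)`` (default: upright radius)."""
        return InertiaProfile(
            0.0, 0.0, 0.0, float(self.l(theta)),
            self.theta_min, self.theta_max, self.mass,
        )

    def contains(self, theta) -> np.ndarray:
        return (theta >= self.theta_min) & (theta <= self.theta_max)


@dataclass(frozen=True)
class PendulumState:
    """CM angle [rad] and angular velocity [rad/s]."""

    theta: float
    omega: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and np.isfinite(self.omega)):
            raise ValueError("state must be finite")


@dataclass(frozen=True)
class TorqueRange:
    """Admissible ankle-torque interval [N m] at one state."""

    tau_lo: float
    tau_hi: float
    feasible: bool
    binding_lo: str = ""
    binding_hi: str = ""

    def contains(self, tau: float) -> bool:
        return self.feasible and self.tau_lo <= tau <= self.tau_hi

    def clamp(self, tau: float) -> float:
        if not self.feasible:
            raise ValueError("no admissible torque at this state")
        return float(min(max(tau, self.tau_lo), self.tau_hi))


def _check_model(model: str, profile: InertiaProfile) -> None:
    if model not in ("simple", "variable"):
        raise ValueError(f"model must be 'simple' or 'variable', got {model!r}")
    if model == "simple" and not profile.is_constant:
        raise ValueError("model='simple' requires a constant inertia profile")


def angular_acceleration(
    state: PendulumState,
    tau: float,
    profile: InertiaProfile,
    model: str = "variable",
) -> float:
    """Angular acceleration alpha [rad/s^2] at a state under torque tau."""
    _check_model(model, profile)
    th, om = state.theta, state.omega
    inertia = profile.inertia(th)
    if inertia == 0.0:
        raise ValueError("I(theta) = 0: degenerate geometry")
    grav = profile.mass * G_ACCEL * profile.l(th) * np.cos(th)
    if model == "simple":
        return float((tau - grav) / inertia)
    return float((tau - grav - profile.dinertia(th) * om**2) / inertia)


def _kinematic_coeffs(theta, profile: InertiaProfile):
    """Coefficients of the CM acceleration, affine in alpha.

    u = l cos(theta), h = l sin(theta) with l = l(theta) give
        u_dd = A_u * omega^2 + B_u * alpha
        h_dd = A_h * omega^2 + B_h * alpha
    """
    lv = profile.l(theta)
    lp = profile.dl(theta)
    lpp = profile.d2l(theta)
    c, s = np.cos(theta), np.sin(theta)
    A_u = lpp * c - 2.0 * lp * s - lv * c
    B_u = lp * c - lv * s
    A_h = lpp * s + 2.0 * lp * c - lv * s
    B_h = lp * s + lv * c
    return A_u, B_u, A_h, B_h


def reaction_forces(
    state: PendulumState,
    alpha: float,
    profile: InertiaProfile,
) -> tuple[float, float]:
    """Ground reaction force (Fx anterior, Fz vertical) [N] on the body.

    The foot is static, so the reaction transmitted through the ankle equals
    the ground reaction: Fx = m*u_dd and Fz = m*(h_dd + g).
    """
    th, om = state.theta, state.omega
    A_u, B_u, A_h, B_h = _kinematic_coeffs(th, profile)
    u_dd = A_u * om**2 + B_u * alpha
    h_dd = A_h * om**2 + B_h * alpha
    return float(profile.mass * u_dd), float(profile.mass * (h_dd + G_ACCEL))


# --- admissible torque range ------------------------------------------------
#
# alpha(tau) = p*tau + q with p = 1/I, q = -(G + I' omega^2)/I, so
# Fx, Fz are affine in tau and every constraint below is affine in tau:
#   (1) Fz >= fz_min          (ground contact maintained)
#   (2) |Fx| <= mu * Fz       (no slip)
#   (3) -d_heel <= u_p <= d_toe with u_p = (tau - Fx*ankle_height)/Fz
#       (center of pressure within the foot; massless-foot moment balance,
#        valid under constraint 1, Fz > 0)
#   (4) -tau_df_max <= tau <= tau_pf_max  (physiological limits)

_CONSTRAINT_NAMES = (
    "contact", "slip+", "slip-", "cop_toe", "cop_heel", "tau_pf", "tau_df",
)


def torque_range_arrays(
    theta,
    omega,
    profile: InertiaProfile,
    subject,
    fz_min: float = 1e-9,
):
    """Vectorised admissible torque interval at states (theta, omega).

    Returns (tau_lo, tau_hi, feasible, i_lo, i_hi); i_lo/i_hi index
    the binding constraint in ``_CONSTRAINT_NAMES``.
    """
    theta = np.asarray(theta, dtype=float)
    omega = np.asarray(omega, dtype=float)
    m = profile.mass
    lv = profile.l(theta)
    inertia = m * lv**2
    grav = m * G_ACCEL * lv * np.cos(theta)
    dI = profile.dinertia(theta)
    p = 1.0 / inertia
    q = -(grav + dI * omega**2) / inertia

    A_u, B_u, A_h, B_h = _kinematic_coeffs(theta, profile)
    om2 = omega**2
    # F = f0 + f1 * tau
    fx1 = m * B_u * p
    fx0 = m * (A_u * om2 + B_u * q)
    fz1 = m * B_h * p
    fz0 = m * (A_h * om2 + B_h * q) + m * G_ACCEL

    mu = subject.mu
    a = subject.ankle_height
    d_toe, d_heel = subject.d_toe, subject.d_heel

    # each constraint written as c1 * tau <= c0
    ones = np.ones_like(theta)
    c1 = np.stack([
        -fz1,                               # contact: Fz >= fz_min
        fx1 - mu * fz1,                     # slip+:  Fx - mu Fz <= 0
        -fx1 - mu * fz1,                    # slip-: -Fx - mu Fz <= 0
        (1.0 - a * fx1 - d_toe * fz1) * ones,    # CoP <= d_toe
        -(1.0 - a * fx1 + d_heel * fz1) * ones,  # CoP >= -d_heel
        ones,                               # tau <= tau_pf_max
        -ones,                              # -tau <= tau_df_max
    ])
    c0 = np.stack([
        fz0 - fz_min,
        -(fx0 - mu * fz0),
        fx0 + mu * fz0,
        d_toe * fz0 + a * fx0,
        -(a * fx0 - d_heel * fz0),
        subject.tau_pf_max * ones,
        subject.tau_df_max * ones,
    ])

    tiny = 1e-12
    pos = c1 > tiny
    neg = c1 < -tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        bound = c0 / c1
    hi_cand = np.where(pos, bound, np.inf)
    lo_cand = np.where(neg, bound, -np.inf)
    i_hi = np.argmin(hi_cand, axis=0)
    i_lo = np.argmax(lo_cand, axis=0)
    tau_hi = np.min(hi_cand, axis=0)
    tau_lo = np.max(lo_cand, axis=0)
    # constraints with c1 ~ 0 are feasibility gates independent of tau
    gate_ok = np.all(pos | neg | (c0 >= -tiny), axis=0)
    feasible = (tau_lo <= tau_hi) & gate_ok
    return tau_lo, tau_hi, feasible, i_lo, i_hi


def admissible_torque_range(
    state: PendulumState,
    profile: InertiaProfile,
    subject,
    fz_min: float = 1e-9,
) -> TorqueRange:
    """Admissible ankle torque interval at one state.

    An empty intersection means the state cannot be controlled without the
    foot sliding or tipping; it is reported with ``feasible=False``, not
    raised.
    """
    if not bool(profile.contains(state.theta)):
        raise ValueError(
            f"theta={state.theta:.4f} outside profile domain "
            f"[{profile.theta_min:.4f}, {profile.theta_max:.4f}]"
        )
    lo, hi, ok, i_lo, i_hi = torque_range_arrays(
        np.array(state.theta), np.array(state.omega), profile, subject, fz_min
    )
    return TorqueRange(
        float(lo), float(hi), bool(ok),
        _CONSTRAINT_NAMES[int(i_lo)], _CONSTRAINT_NAMES[int(i_hi)],
    )


# --- time stepping -----------------------------------------------------------


@dataclass
class SimulationResult:
    """Trajectory of a forward simulation with constraint bookkeeping."""

    time: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    tau: np.ndarray
    status: str            # "ok", "slip", "tip", "torque-limit", "contact", "domain"
    clamped: int = 0       # number of policy outputs clamped into the range
    message: str = field(default="")


_FAILURE_BY_CONSTRAINT = {
    "contact": "contact",
    "slip+": "slip",
    "slip-": "slip",
    "cop_toe": "tip",
    "cop_heel": "tip",
    "tau_pf": "torque-limit",
    "tau_df": "torque-limit",
}


def _rk4(theta, omega, tau, profile, dt):
    def f(th, om):
        return om, angular_acceleration(PendulumState(th, om), tau, profile)

    k1 = f(theta, omega)
    k2 = f(theta + 0.5 * dt * k1[0], omega + 0.5 * dt * k1[1])
    k3 = f(theta + 0.5 * dt * k2[0], omega + 0.5 * dt * k2[1])
    k4 = f(theta + dt * k3[0], omega + dt * k3[1])
    theta += dt * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]) / 6.0
    omega += dt * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]) / 6.0
    return theta, omega


def step(
    state: PendulumState,
    tau_policy,
    profile: InertiaProfile,
    subject,
    dt: float,
) -> PendulumState:
    """Advance one fixed RK4 step; the policy torque is clamped admissible."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = admissible_torque_range(state, profile, subject)
    if not rng.feasible:
        raise RuntimeError(
            f"no admissible torque at theta={state.theta:.3f}, "
            f"omega={state.omega:.3f} ({_FAILURE_BY_CONSTRAINT[rng.binding_lo]})"
        )
    tau = rng.clamp(float(tau_policy(state)))
    th, om = _rk4(state.theta, state.omega, tau, profile, dt)
    return PendulumState(float(th), float(om))


def simulate(
    state: PendulumState,
    tau_policy,
    profile: InertiaProfile,
    subject,
    dt: float,
    n_steps: int,
    stop=None,
) -> SimulationResult:
    """Fixed-step RK4 simulation with per-step admissibility enforcement.

    ``tau_policy(state) -> tau`` is clamped into the admissible range
    (clamps are counted).  ``stop(state) -> bool`` optionally terminates
    early (e.g. on reaching rest over the base of support).  Infeasibility
    or leaving the profile domain terminates with a labelled failure mode.
    """
    th, om = float(state.theta), float(state.omega)
    times = [0.0]
    thetas = [th]
    omegas = [om]
    taus = []
    clamped = 0
    status = "ok"
    msg = ""
    for i in range(n_steps):
        if not (profile.theta_min <= th <= profile.theta_max):
            status, msg = "domain", f"theta left domain at t={i*dt:.3f}s"
            break
        rng = admissible_torque_range(PendulumState(th, om), profile, subject)
        if not rng.feasible:
            status = _FAILURE_BY_CONSTRAINT[rng.binding_lo]
            msg = f"infeasible at t={i*dt:.3f}s (binding: {rng.binding_lo})"
            break
        tau_cmd = float(tau_policy(PendulumState(th, om)))
        tau = rng.clamp(tau_cmd)
        if tau != tau_cmd:
            clamped += 1
        th, om = _rk4(th, om, tau, profile, dt)
        times.append((i + 1) * dt)
        thetas.append(th)
        omegas.append(om)
        taus.append(tau)
        if stop is not None and stop(PendulumState(th, om)):
            break
    return SimulationResult(
        np.array(times), np.array(thetas), np.array(omegas),
        np.array(taus), status, clamped, msg,
    )
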