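"""Velocity-position balance feasibility maps.

A *balance map* collects, in normalized coordinates, the CM
velocity-position conditions at seat-off from which static balance can be
restored without moving the feet:

* ``x`` — posterior CM distance from the toe in foot lengths (0 = toe,
  1 = heel, larger = further behind the heel),
* ``v`` — anterior CM velocity in body heights per second.

The upper boundary is the trajectory that just manages to stop the CM over
the toe using the maximal admissible plantarflexion at every instant;
states above it fall forward.  The lower boundary mirrors it through the
heel with maximal dorsiflexion; states below it (for ``x > 1``) fall
backward.  The zero-torque curve is the trajectory that coasts to the
upright equilibrium with no ankle torque at all — the most energy-efficient
successful strategy.

All three curves are computed as extremal-field trajectories.  Because each
terminal state (CM at rest over the toe or heel, or the upright
equilibrium) is a saddle of the time flow, the curves are integrated with
the angle as the independent variable, propagating ``w = omega**2`` via
``dw/dtheta = 2*alpha`` under the extremal admissible torque.  This passes
through the degenerate terminal states cleanly and, for the simple model
with tau = 0, reproduces the closed-form energy-conservation curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .pendulum import (
    G_ACCEL,
    InertiaProfile,
    PendulumState,
    _kinematic_coeffs,
    torque_range_arrays,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BalanceMap",
    "state_to_map",
    "map_to_state",
    "theta_at_x",
    "upper_boundary",
    "lower_boundary",
    "zero_torque_curve",
    "compute_balance_map",
    "classify_state",
    "map_similarity",
    "validity_velocity",
    "region_area",
    "plot_map",
]


# --- coordinate transforms ---------------------------------------------------


def state_to_map(state: PendulumState, subject, profile: InertiaProfile):
    """(theta, omega) -> (x [foot lengths], v [heights/s])."""
    th, om = state.theta, state.omega
    u = profile.l(th) * np.cos(th)
    _, B_u, _, _ = _kinematic_coeffs(th, profile)
    x = (subject.d_toe - u) / subject.foot_length
    v = B_u * om / subject.height
    return float(x), float(v)


def theta_at_x(x: float, subject, profile: InertiaProfile) -> float:
    """CM angle at horizontal map position x (u = l(theta) cos(theta))."""
    u = subject.d_toe - x * subject.foot_length

    def f(th):
        return profile.l(th) * np.cos(th) - u

    a, b = profile.theta_min, profile.theta_max
    fa, fb = f(a), f(b)
    if fa * fb > 0:
        raise ValueError(
            f"x={x:.3f} (u={u:.3f} m) unreachable within the profile domain"
        )
    return float(brentq(f, a, b, xtol=1e-12))


def map_to_state(x: float, v: float, subject, profile: InertiaProfile) -> PendulumState:
    """(x, v) -> (theta, omega); exact inverse of :func:`state_to_map`."""
    th = theta_at_x(x, subject, profile)
    _, B_u, _, _ = _kinematic_coeffs(th, profile)
    if B_u == 0:
        raise ValueError("du/dtheta = 0: velocity conversion degenerate")
    om = v * subject.height / B_u
    return PendulumState(th, float(om))


# --- extremal-field curve integration ---------------------------------------


def _extremal_alpha_factory(profile, subject, side):
    """alpha(theta, w) under the extremal admissible torque.

    side = +1: maximal torque (plantarflexion extreme, braking a forward
    fall); side = -1: minimal torque (dorsiflexion extreme).  Returns NaN
    where no admissible torque exists.  The branch's omega sign only enters
    through omega**2 = w, so it does not need to be known here.
    """
    m = profile.mass

    def alpha(theta, w):
        w = max(w, 0.0)
        om = np.sqrt(w)
        lo, hi, ok, _, _ = torque_range_arrays(
            np.array(theta), np.array(om), profile, subject
        )
        if not bool(ok):
            return np.nan
        tau = float(hi) if side > 0 else float(lo)
        lv = profile.l(theta)
        grav = m * G_ACCEL * lv * np.cos(theta)
        return (tau - grav - profile.dinertia(theta) * w) / (m * lv**2)

    return alpha


def _zero_torque_alpha(profile):
    m = profile.mass

    def alpha(theta, w):
        lv = profile.l(theta)
        grav = m * G_ACCEL * lv * np.cos(theta)
        return (-grav - profile.dinertia(theta) * max(w, 0.0)) / (m * lv**2)

    return alpha


def _integrate_w(alpha_fn, thetas, w0):
    """RK4 on dw/dtheta = 2*alpha(theta, w) along the given theta nodes.

    Steps may be non-uniform.  Stops early (truncating the branch) if alpha
    becomes NaN (admissible torque set empty) or w would turn negative.
    """
    thetas = np.asarray(thetas, dtype=float)
    ws = np.empty_like(thetas)
    ws[0] = w0
    w = w0
    n_ok = 0

    def f(t, wv):
        return 2.0 * alpha_fn(t, max(wv, 0.0))

    for i in range(thetas.size - 1):
        th = thetas[i]
        h = thetas[i + 1] - th
        k1 = f(th, w)
        k2 = f(th + 0.5 * h, w + 0.5 * h * k1)
        k3 = f(th + 0.5 * h, w + 0.5 * h * k2)
        k4 = f(th + h, w + h * k3)
        if not np.all(np.isfinite([k1, k2, k3, k4])):
            break
        w_new = w + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        if w_new < -1e-12:
            break
        w = max(w_new, 0.0)
        ws[i + 1] = w
        n_ok = i + 1
    return thetas[: n_ok + 1], ws[: n_ok + 1]


def _nodes_from(theta0, theta1, n_steps):
    return np.linspace(theta0, theta1, n_steps + 1)


def _branch_to_xv(thetas, ws, omega_sign, subject, profile):
    om = omega_sign * np.sqrt(np.maximum(ws, 0.0))
    u = profile.l(thetas) * np.cos(thetas)
    _, B_u, _, _ = _kinematic_coeffs(thetas, profile)
    x = (subject.d_toe - u) / subject.foot_length
    v = B_u * om / subject.height
    return x, v


def _theta_end(x_target, subject, profile, default):
    try:
        return theta_at_x(x_target, subject, profile)
    except ValueError:
        return default


def _effective_terminal(alpha_fn, side, theta_geom, th_lo, th_hi):
    """Terminal angle of a boundary: rest state the extremal torque can hold.

    When the center-of-pressure constraint binds at the geometric toe/heel
    the extremal static angular acceleration vanishes there exactly and the
    terminal is the geometric one.  When a physiological torque limit binds
    first, the holdable rest state sits strictly inside the foot; it is the
    root of the extremal static acceleration.
    """
    a_geom = alpha_fn(theta_geom, 0.0)
    if not np.isfinite(a_geom):
        return None
    tol = 1e-9
    if side > 0:
        # forward-fall boundary: need alpha_max >= 0 at and behind terminal
        if a_geom >= -tol:
            return theta_geom
        lo, hi = theta_geom, th_hi
    else:
        # backward-fall boundary: need alpha_min <= 0 at and ahead of terminal
        if a_geom <= tol:
            return theta_geom
        lo, hi = th_lo, theta_geom
    f = lambda t: alpha_fn(t, 0.0)  # noqa: E731
    # bracket the sign change on a grid, skipping infeasible (NaN) stretches
    grid = np.linspace(lo, hi, 96)
    vals = np.array([f(t) for t in grid])
    root = None
    for i in range(grid.size - 1):
        a, b = vals[i], vals[i + 1]
        if np.isfinite(a) and np.isfinite(b) and a * b <= 0:
            root = float(brentq(f, grid[i], grid[i + 1], xtol=1e-12))
            break
    if root is None:
        return None
    logger.info("torque-limited terminal: theta=%.4f (geometric %.4f)", root, theta_geom)
    return root


def _boundary_curve(subject, profile, side, theta_geom, x_min, x_max, n_theta):
    """Both branches of one boundary, merged and sorted by x.

    ``side=+1`` builds the forward-fall (upper) boundary from the toe;
    ``side=-1`` the backward-fall (lower) boundary from the heel.  The
    posterior branch carries omega < 0 (anterior CM velocity), the anterior
    branch omega > 0.
    """
    alpha_fn = _extremal_alpha_factory(profile, subject, side)
    th_hi = _theta_end(x_max, subject, profile, profile.theta_max)
    th_lo = _theta_end(x_min, subject, profile, profile.theta_min)
    theta_terminal = _effective_terminal(alpha_fn, side, theta_geom, th_lo, th_hi)
    if theta_terminal is None:
        name = "toe" if side > 0 else "heel"
        raise ValueError(
            f"no holdable rest state near the {name}: boundary terminal infeasible"
        )

    xs, vs = [], []
    if th_hi > theta_terminal:
        t_p, w_p = _integrate_w(alpha_fn, _nodes_from(theta_terminal, th_hi, n_theta), 0.0)
        x_p, v_p = _branch_to_xv(t_p, w_p, -1.0, subject, profile)
        xs.append(x_p)
        vs.append(v_p)
    if th_lo < theta_terminal:
        t_a, w_a = _integrate_w(alpha_fn, _nodes_from(theta_terminal, th_lo, n_theta), 0.0)
        x_a, v_a = _branch_to_xv(t_a, w_a, +1.0, subject, profile)
        xs.append(x_a[::-1])
        vs.append(v_a[::-1])
    return _merge_branches(xs, vs, innermost=(np.minimum if side > 0 else np.maximum))


def _merge_branches(xs, vs, innermost):
    """Merge curve branches sorted by x; collapse overlaps conservatively."""
    for xb in xs:
        if np.any(np.diff(xb) <= 0):
            logger.warning("non-monotone boundary parameterisation; "
                           "taking innermost values")
    x = np.concatenate(xs)
    v = np.concatenate(vs)
    order = np.argsort(x, kind="stable")
    x, v = x[order], v[order]
    if np.any(np.diff(x) <= 0):
        xu, inv = np.unique(x, return_inverse=True)
        vu = np.full(xu.shape, np.inf if innermost is np.minimum else -np.inf)
        agg_at = np.minimum.at if innermost is np.minimum else np.maximum.at
        agg_at(vu, inv, v)
        x, v = xu, vu
    return x, v


def _sample_on_grid(x_src, v_src, x_grid):
    out = np.full_like(x_grid, np.nan)
    if len(x_src) < 2:
        return out
    inside = (x_grid >= x_src[0]) & (x_grid <= x_src[-1])
    out[inside] = np.interp(x_grid[inside], x_src, v_src)
    return out


def upper_boundary(subject, profile: InertiaProfile, model: str = "variable",
                   x_min: float = -0.2, x_max: float = 3.0, n_theta: int = 800):
    """Forward-fall boundary v_max(x): stop the CM just over the toe
    using maximal admissible plantarflexion.  Returns (x, v) samples."""
    profile = _resolve_profile(profile, model)
    th_toe = theta_at_x(0.0, subject, profile)
    _require_terminal_feasible(th_toe, subject, profile, "toe")
    return _boundary_curve(subject, profile, +1, th_toe, x_min, x_max, n_theta)


def lower_boundary(subject, profile: InertiaProfile, model: str = "variable",
                   x_min: float = -0.2, x_max: float = 3.0, n_theta: int = 800):
    """Backward-fall boundary v_min(x): bring the CM just over the heel
    using maximal admissible dorsiflexion.  Returns (x, v) samples."""
    profile = _resolve_profile(profile, model)
    th_heel = theta_at_x(1.0, subject, profile)
    _require_terminal_feasible(th_heel, subject, profile, "heel")
    return _boundary_curve(subject, profile, -1, th_heel, x_min, x_max, n_theta)


def zero_torque_curve(subject, profile: InertiaProfile, model: str = "variable",
                      x_min: float = -0.2, x_max: float = 3.0,
                      n_theta: int = 800, eps: float = 1e-6):
    """Zero-ankle-torque trajectory reaching the upright equilibrium.

    Integrated from an eps-perturbation of the unstable equilibrium (CM
    directly above the ankle, theta = pi/2, at rest).  For the simple model
    this equals the energy-conservation curve
    0.5*l**2*omega**2 + g*l*sin(theta) = g*l.
    """
    profile = _resolve_profile(profile, model)
    th_eq = np.pi / 2
    if not (profile.theta_min < th_eq < profile.theta_max):
        raise ValueError("upright equilibrium outside the profile theta domain")
    alpha_fn = _zero_torque_alpha(profile)
    th_hi = _theta_end(x_max, subject, profile, profile.theta_max)
    th_lo = _theta_end(x_min, subject, profile, profile.theta_min)
    # local stable-manifold expansion: w ~ (g / l) * eps**2
    w_eps = G_ACCEL * eps**2 / profile.l(th_eq)
    xs, vs = [], []
    if th_hi > th_eq + eps:
        # theta nodes anchored at the equilibrium (not at the eps-start) so
        # the sampled curve is insensitive to the choice of eps
        nodes = np.concatenate([[th_eq + eps],
                                _nodes_from(th_eq, th_hi, n_theta)[1:]])
        t_p, w_p = _integrate_w(alpha_fn, nodes, w_eps)
        x_p, v_p = _branch_to_xv(t_p, w_p, -1.0, subject, profile)
        xs.append(x_p)
        vs.append(v_p)
    if th_lo < th_eq - eps:
        nodes = np.concatenate([[th_eq - eps],
                                _nodes_from(th_eq, th_lo, n_theta)[1:]])
        t_a, w_a = _integrate_w(alpha_fn, nodes, w_eps)
        x_a, v_a = _branch_to_xv(t_a, w_a, +1.0, subject, profile)
        xs.append(x_a[::-1])
        vs.append(v_a[::-1])
    x = np.concatenate(xs)
    v = np.concatenate(vs)
    order = np.argsort(x, kind="stable")
    return x[order], v[order]


def _resolve_profile(profile: InertiaProfile, model: str) -> InertiaProfile:
    if model == "variable":
        return profile
    if model == "simple":
        if profile.is_constant:
            return profile
        return profile.to_constant()
    raise ValueError(f"model must be 'simple' or 'variable', got {model!r}")


def _require_terminal_feasible(theta, subject, profile, name):
    lo, hi, ok, i_lo, _ = torque_range_arrays(
        np.array(theta), np.array(0.0), profile, subject
    )
    if not bool(ok):
        from .pendulum import _CONSTRAINT_NAMES

        raise ValueError(
            f"terminal state over the {name} is infeasible "
            f"(violated constraint: {_CONSTRAINT_NAMES[int(i_lo)]})"
        )


# --- the map object ----------------------------------------------------------


@dataclass
class BalanceMap:
    """Sampled balance-control boundaries on a normalized x grid.

    NaN marks positions a curve does not cover (e.g. the boundary was
    truncated by constraint infeasibility).
    """

    x: np.ndarray
    v_upper: np.ndarray
    v_lower: np.ndarray
    v_zero: np.ndarray
    model: str
    meta: dict = field(default_factory=dict)

    def _interp(self, arr, xq):
        xq = np.asarray(xq, dtype=float)
        valid = np.isfinite(arr)
        if valid.sum() < 2:
            raise ValueError("curve not sampled")
        xs, vs = self.x[valid], arr[valid]
        out_of_range = (xq < xs[0]) | (xq > xs[-1])
        if np.any(out_of_range):
            raise ValueError(
                f"query x={np.atleast_1d(xq)[np.atleast_1d(out_of_range)][0]:.4f} "
                f"outside sampled range [{xs[0]:.4f}, {xs[-1]:.4f}]"
            )
        return np.interp(xq, xs, vs)

    def upper_at(self, xq):
        return self._interp(self.v_upper, xq)

    def lower_at(self, xq):
        return self._interp(self.v_lower, xq)

    def zero_at(self, xq):
        return self._interp(self.v_zero, xq)

    def tolerance_width(self, v):
        """Position control tolerance W(v): horizontal width of the stable
        region at anterior velocity v, in foot lengths (W(0) = 1)."""
        return _width(self, np.asarray(v, dtype=float))


def compute_balance_map(
    subject,
    profile: InertiaProfile,
    model: str = "variable",
    x_min: float = -0.2,
    x_max: float = 3.0,
    n_x: int = 400,
    n_theta: int = 800,
    eps: float = 1e-6,
) -> BalanceMap:
    """Compute upper/lower boundaries and the zero-torque curve on a grid."""
    prof = _resolve_profile(profile, model)
    x_grid = np.linspace(x_min, x_max, n_x)
    xu, vu = upper_boundary(subject, prof, "variable", x_min, x_max, n_theta)
    xl, vl = lower_boundary(subject, prof, "variable", x_min, x_max, n_theta)
    xz, vz = zero_torque_curve(subject, prof, "variable", x_min, x_max, n_theta, eps)
    meta = {
        "model": model,
        "profile": list(prof.coefficients),
        "theta_domain": [prof.theta_min, prof.theta_max],
        "subject": {
            "mass": subject.mass,
            "height": subject.height,
            "foot_length": subject.foot_length,
            "d_toe": subject.d_toe,
            "d_heel": subject.d_heel,
            "ankle_height": subject.ankle_height,
            "mu": subject.mu,
            "tau_pf_max": subject.tau_pf_max,
            "tau_df_max": subject.tau_df_max,
        },
        "x_min": x_min,
        "x_max": x_max,
        "n_x": n_x,
        "n_theta": n_theta,
        "eps": eps,
    }
    return BalanceMap(
        x=x_grid,
        v_upper=_sample_on_grid(xu, vu, x_grid),
        v_lower=_sample_on_grid(xl, vl, x_grid),
        v_zero=_sample_on_grid(xz, vz, x_grid),
        model=model,
        meta=meta,
    )


# --- classification ----------------------------------------------------------


def classify_state(x: float, v: float, dx: float, bmap: BalanceMap) -> str:
    """'stable' iff the whole horizontal error bar [x-dx, x+dx] lies
    strictly inside the boundaries; boundary contact counts as unstable."""
    if dx < 0:
        raise ValueError("dx must be non-negative")
    for xq in (x - dx, x, x + dx):
        lo = float(bmap.lower_at(xq))
        hi = float(bmap.upper_at(xq))
        if not (lo < v < hi):
            return "unstable"
    return "stable"


# --- similarity --------------------------------------------------------------


def _monotone_inverse(x, v, v_query):
    """Invert a sampled boundary curve v(x) at velocities v_query.

    Only the non-negative-velocity limb is used.  Non-monotone stretches
    are flattened with a running max so a conservative crossing is
    returned.  NaN outside the covered velocity range.
    """
    valid = np.isfinite(v)
    x, v = x[valid], v[valid]
    if v.size < 2:
        return np.full(np.shape(v_query), np.nan)
    v_mono = np.maximum.accumulate(v)
    inb = (v_query >= v_mono[0]) & (v_query <= v_mono[-1])
    res = np.interp(v_query, v_mono, x)
    return np.where(inb, res, np.nan)


def _width(bmap: BalanceMap, v):
    x_up = _monotone_inverse(bmap.x, bmap.v_upper, v)
    x_lo = _monotone_inverse(bmap.x, bmap.v_lower, v)
    return x_lo - x_up


def map_similarity(map_a: BalanceMap, map_b: BalanceMap, v):
    """Similarity of position-control tolerances at velocity v.

    similarity(v) = 1 - |W_a(v) - W_b(v)| / W_b(v), with map_b the
    reference map.  NaN where either width is undefined or W_b <= 0.
    """
    v = np.asarray(v, dtype=float)
    w_a = _width(map_a, v)
    w_b = _width(map_b, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - np.abs(w_a - w_b) / w_b
    bad = ~np.isfinite(w_a) | ~np.isfinite(w_b) | (w_b <= 0)
    if np.any(bad & np.isfinite(v)):
        logger.info("similarity undefined at %d of %d velocities", int(np.sum(bad)), v.size)
    return np.where(bad, np.nan, sim)


def validity_velocity(map_a: BalanceMap, map_b: BalanceMap,
                      threshold: float = 0.85, n_v: int = 200) -> float:
    """Largest v* such that similarity(v) >= threshold for all v <= v*."""
    v_max_a = np.nanmax(np.where(np.isfinite(map_a.v_upper), map_a.v_upper, np.nan))
    v_max_b = np.nanmax(np.where(np.isfinite(map_b.v_upper), map_b.v_upper, np.nan))
    v_grid = np.linspace(0.0, min(v_max_a, v_max_b), n_v)
    sim = map_similarity(map_a, map_b, v_grid)
    ok = np.isfinite(sim) & (sim >= threshold)
    if not ok[0]:
        return 0.0
    bad = np.nonzero(~ok)[0]
    if bad.size == 0:
        return float(v_grid[-1])
    return float(v_grid[bad[0] - 1])


def region_area(bmap: BalanceMap, x_window: tuple[float, float] | None = None) -> float:
    """Area of the stable region between the boundaries (foot lengths x
    heights/s), over the x range where both boundaries are defined.

    ``x_window`` restricts the integral to a fixed position window, which
    makes areas of maps with different coverage (boundaries truncated at
    different positions by constraint infeasibility) comparable.
    """
    valid = np.isfinite(bmap.v_upper) & np.isfinite(bmap.v_lower)
    if x_window is not None:
        valid &= (bmap.x >= x_window[0]) & (bmap.x <= x_window[1])
    if valid.sum() < 2:
        return 0.0
    gap = np.clip(bmap.v_upper[valid] - bmap.v_lower[valid], 0.0, None)
    return float(np.trapezoid(gap, bmap.x[valid]))


def plot_map(bmap: BalanceMap, ax=None, **kwargs):
    """Plot boundaries (solid) and zero-torque curve (dashed)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(bmap.x, bmap.v_upper, "k-", label="forward-fall boundary", **kwargs)
    ax.plot(bmap.x, bmap.v_lower, "k-", label="backward-fall boundary", **kwargs)
    ax.plot(bmap.x, bmap.v_zero, "k--", label="zero-torque trajectory", **kwargs)
    ax.set_xlabel("CM position posterior of toe [foot lengths]")
    ax.set_ylabel("anterior CM velocity [heights/s]")
    ax.legend(loc="best", fontsize="small")
    return ax
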