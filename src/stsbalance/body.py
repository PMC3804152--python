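"""Anthropometry and segment-based center-of-mass estimation.

The body CM is estimated from reflective-marker trajectories by a standard
segmental analysis: each segment's mass is a fixed fraction of body mass,
its mass is assumed uniformly distributed so the segment CM sits at the
midpoint between its proximal and distal markers, and the body CM is the
mass-fraction-weighted mean of the segment CMs.  Left/right limb markers
are averaged into a single sagittal-plane segment.  Arm segments are
excluded and the remaining fractions renormalized to one.

All positions are expressed relative to the ankle joint (average of the
ankle markers): anterior = +u, up = +h, SI units.  Normalization to foot
lengths and body heights happens only at the map layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "SubjectModel",
    "MarkerFrame",
    "DEFAULT_SEGMENT_TABLE",
    "estimate_cm",
    "cm_position_error",
    "kinematics_to_polar",
]


@dataclass(frozen=True)
class Segment:
    """One body segment: mass fraction, its SD, and its marker pairs.

    ``proximal``/``distal`` are tuples of marker names that are averaged
    (bilateral segments list the left and right marker).
    """

    name: str
    fraction: float
    fraction_sd: float
    proximal: tuple[str, ...]
    distal: tuple[str, ...]


# Five-segment sagittal table, arms excluded and renormalized.  Fractions
# follow standard gait-analysis anthropometry (head+neck, trunk, both
# thighs, both shanks, both feet); SDs reflect inter-individual spread of
# the mass-distribution model and are configurable, as is the whole table.
DEFAULT_SEGMENT_TABLE: tuple[Segment, ...] = (
    Segment("head", 0.090, 0.009, ("C7",), ("VERTEX",)),
    Segment("trunk", 0.552, 0.028, ("SACRUM",), ("C7",)),
    Segment("thigh", 0.222, 0.016, ("LHIP", "RHIP"), ("LKNEE", "RKNEE")),
    Segment("shank", 0.103, 0.007, ("LKNEE", "RKNEE"), ("LANK", "RANK")),
    Segment("foot", 0.033, 0.003, ("LHEEL", "RHEEL"), ("LTOE", "RTOE")),
)


@dataclass(frozen=True)
class SubjectModel:
    """Subject anthropometry, foot geometry and constraint parameters.

    Units: kg, m; torque limits in N m; mu dimensionless.  ``d_toe`` and
    ``d_heel`` are the horizontal ankle-to-toe and ankle-to-heel distances
    (both positive) and must sum to ``foot_length``.
    """

    mass: float
    height: float
    d_toe: float
    d_heel: float
    ankle_height: float
    foot_length: float
    mu: float
    tau_pf_max: float
    tau_df_max: float
    segment_table: tuple[Segment, ...] = DEFAULT_SEGMENT_TABLE
    ankle_markers: tuple[str, ...] = ("LANK", "RANK")

    def __post_init__(self) -> None:
        for name in ("mass", "height"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("mu", "tau_pf_max", "tau_df_max", "ankle_height",
                     "d_toe", "d_heel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if abs(self.foot_length - (self.d_toe + self.d_heel)) > 1e-9:
            raise ValueError(
                f"foot_length ({self.foot_length}) must equal d_toe + d_heel "
                f"({self.d_toe + self.d_heel})"
            )
        total = sum(s.fraction for s in self.segment_table)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"segment mass fractions sum to {total}, expected 1")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([s.fraction for s in self.segment_table])

    @property
    def fraction_sds(self) -> np.ndarray:
        return np.array([s.fraction_sd for s in self.segment_table])


@dataclass
class MarkerFrame:
    """One sampled frame: time [s] and marker name -> (x, y, z) [m]."""

    time: float
    positions: dict[str, tuple[float, float, float]]

    def get(self, names: tuple[str, ...]):
        """Average position of a marker group; None if any is missing."""
        pts = []
        for n in names:
            p = self.positions.get(n)
            if p is None or not np.all(np.isfinite(p)):
                return None
            pts.append(p)
        return np.mean(np.asarray(pts, dtype=float), axis=0)


def _frame_cm(frame: MarkerFrame, subject: SubjectModel):
    """Per-segment and body CM of one frame, ankle-relative, sagittal.

    Returns (u_segments, h_segments, u_body, h_body) or None if a marker
    is missing.
    """
    ankle = frame.get(subject.ankle_markers)
    if ankle is None:
        return None
    us, hs = [], []
    for seg in subject.segment_table:
        p = frame.get(seg.proximal)
        d = frame.get(seg.distal)
        if p is None or d is None:
            return None
        cm = 0.5 * (p + d)
        us.append(cm[0] - ankle[0])
        hs.append(cm[2] - ankle[2])
    us = np.array(us)
    hs = np.array(hs)
    f = subject.fractions
    return us, hs, float(f @ us), float(f @ hs)


def estimate_cm(frames, subject: SubjectModel, max_gap_fraction: float = 0.2) -> pd.DataFrame:
    """Body CM time series (ankle-relative u anterior, h vertical) [m].

    Frames with any missing segment or ankle marker are flagged and
    excluded (reported in ``df.attrs['gaps']``); more than
    ``max_gap_fraction`` missing frames raises.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    times, us, hs, gaps = [], [], [], []
    last_t = -np.inf
    for i, fr in enumerate(frames):
        if fr.time <= last_t:
            raise ValueError(f"time not strictly increasing at frame {i}")
        last_t = fr.time
        res = _frame_cm(fr, subject)
        if res is None:
            gaps.append(i)
            continue
        _, _, u, h = res
        times.append(fr.time)
        us.append(u)
        hs.append(h)
    if gaps:
        logger.warning("%d of %d frames excluded for missing markers", len(gaps), len(frames))
    if len(gaps) > max_gap_fraction * len(frames):
        raise ValueError(
            f"{len(gaps)}/{len(frames)} frames have marker gaps "
            f"(> {max_gap_fraction:.0%} allowed)"
        )
    df = pd.DataFrame({"time": times, "u": us, "h": hs})
    df.attrs["gaps"] = gaps
    return df


def cm_position_error(subject: SubjectModel, frames, override: float | None = None) -> float:
    """Half-width [m] of the horizontal CM position uncertainty.

    First-order propagation of the segment mass-fraction SDs through the
    (renormalized) weighted mean, taken at the worst-case posture over the
    trial: Var(u) = sum_i sd_i**2 * (u_i - u_body)**2, since perturbing
    fraction i (with renormalization) moves the CM along u_i - u_body.
    ``override`` short-circuits to a fixed measured/assumed value.
    """
    if override is not None:
        return float(override)
    worst = 0.0
    sds = subject.fraction_sds
    for fr in frames:
        res = _frame_cm(fr, subject)
        if res is None:
            continue
        us, _, u_body, _ = res
        var = float(np.sum(sds**2 * (us - u_body) ** 2))
        worst = max(worst, np.sqrt(var))
    return worst


def kinematics_to_polar(cm: pd.DataFrame, cutoff_hz: float | None = 6.0) -> pd.DataFrame:
    """Convert an ankle-relative CM series to (theta, omega, l).

    theta is measured from the anterior horizontal axis (pi/2 = CM above
    the ankle, larger = posterior); l = sqrt(u**2 + h**2).  omega is
    obtained by central differences of theta, optionally after low-pass
    filtering theta with a zero-phase 2nd-order Butterworth at
    ``cutoff_hz`` (None disables filtering).
    """
    t = cm["time"].to_numpy(dtype=float)
    u = cm["u"].to_numpy(dtype=float)
    h = cm["h"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(h))):
        raise ValueError("CM series contains non-finite values")
    l = np.hypot(u, h)  # noqa: E741
    if np.any(l == 0):
        raise ValueError("l = 0 at some frame: degenerate geometry")
    theta = np.arctan2(h, u)
    theta_s = theta
    if cutoff_hz is not None and len(t) > 12:
        fs = 1.0 / np.median(np.diff(t))
        wn = cutoff_hz / (0.5 * fs)
        if wn < 1.0:
            b, a = butter(2, wn)
            theta_s = filtfilt(b, a, theta)
    omega = np.gradient(theta_s, t)
    return pd.DataFrame({"time": t, "theta": theta, "omega": omega, "l": l})
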