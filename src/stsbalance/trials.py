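"""Fitting subject inertia profiles and evaluating balance predictions.

The subject-specific radius function l(theta) is estimated by ordinary
least squares of a cubic in theta on (theta, l) samples pooled from natural
sit-to-stand trials.  Measured (or synthetic) seat-off states are then
classified against a balance map, and the predictions scored against
observed outcomes with sensitivity/specificity.  The positive class is
"stable prediction of a successful trial": sensitivity is the fraction of
successful trials predicted stable, specificity the fraction of failed
trials predicted unstable (configurable via ``positive``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maps import BalanceMap, classify_state
from .pendulum import InertiaProfile

__all__ = [
    "TrialRecord",
    "InertiaFit",
    "fit_inertia_profile",
    "classify_trials",
    "ClassificationReport",
    "energy_strategy",
]


@dataclass(frozen=True)
class TrialRecord:
    """One sit-to-stand trial: seat-off state in map coordinates + outcome."""

    trial_id: str
    x: float                 # foot lengths posterior of toe
    v: float                 # heights/s
    outcome: str             # "success" | "failure"
    condition: str = ""      # "normal" | "demanding"

    def __post_init__(self) -> None:
        if self.outcome not in ("success", "failure"):
            raise ValueError(f"outcome must be success/failure, got {self.outcome!r}")


@dataclass
class InertiaFit:
    """OLS cubic radius fit: profile, standard errors and residual RMS."""

    profile: InertiaProfile
    coef_se: np.ndarray      # SE of (a0, a1, a3, a4)
    residual_rms: float
    n_samples: int


def fit_inertia_profile(polar_series, mass: float,
                        min_theta_span: float = 0.15) -> InertiaFit:
    """Fit l(theta) = a0*theta^3 + a1*theta^2 + a3*theta + a4 by OLS.

    ``polar_series`` is a sequence of DataFrames with columns theta and l
    (as returned by ``body.kinematics_to_polar``); samples from all trials
    are pooled.  The profile's theta domain is the observed range.
    """
    thetas, ls = [], []
    for df in polar_series:
        thetas.append(np.asarray(df["theta"], dtype=float))
        ls.append(np.asarray(df["l"], dtype=float))
    th = np.concatenate(thetas)
    lv = np.concatenate(ls)
    if th.size < 8:
        raise ValueError("too few samples to fit a cubic")
    span = float(th.max() - th.min())
    if span < min_theta_span:
        raise ValueError(
            f"theta span {span:.3f} rad too small for a stable cubic fit "
            f"(need >= {min_theta_span})"
        )
    X = np.column_stack([th**3, th**2, th, np.ones_like(th)])
    coef, _, rank, _ = np.linalg.lstsq(X, lv, rcond=None)
    if rank < 4:
        raise ValueError("rank-deficient design: theta coverage degenerate")
    resid = lv - X @ coef
    dof = max(th.size - 4, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    profile = InertiaProfile(*map(float, coef),
                             float(th.min()), float(th.max()), mass)
    return InertiaFit(profile, np.sqrt(np.diag(cov)),
                      float(np.sqrt(np.mean(resid**2))), int(th.size))


@dataclass
class ClassificationReport:
    """Per-trial predictions and the pooled confusion matrix."""

    table: pd.DataFrame
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float | None:
        """Successful trials predicted stable / all successful; None if no
        successful trials."""
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        """Failed trials predicted unstable / all failed; None if no
        failed trials."""
        neg = self.tn + self.fp
        return self.tn / neg if neg else None


def classify_trials(trials, bmap: BalanceMap, dx: float,
                    positive: str = "success") -> ClassificationReport:
    """Classify trial seat-off states against a map and score predictions.

    ``trials`` is an iterable of TrialRecord or a DataFrame with columns
    trial_id, x_footlen, v_heights_per_s, outcome[, condition].  ``dx`` is
    the CM position uncertainty in foot lengths (whole error bar must be
    inside the boundaries for a stable call).
    """
    if positive not in ("success", "failure"):
        raise ValueError("positive must be 'success' or 'failure'")
    if isinstance(trials, pd.DataFrame):
        recs = [
            TrialRecord(str(r.trial_id), float(r.x_footlen),
                        float(r.v_heights_per_s), str(r.outcome),
                        str(getattr(r, "condition", "")))
            for r in trials.itertuples(index=False)
        ]
    else:
        recs = list(trials)
    rows = []
    tp = fn = tn = fp = 0
    for rec in recs:
        pred = classify_state(rec.x, rec.v, dx, bmap)
        hi = float(bmap.upper_at(rec.x))
        lo = float(bmap.lower_at(rec.x))
        margin = min(hi - rec.v, rec.v - lo)
        obs_pos = rec.outcome == positive
        pred_pos = pred == "stable"
        if obs_pos and pred_pos:
            tp += 1
        elif obs_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
        rows.append({
            "trial_id": rec.trial_id, "x_footlen": rec.x,
            "v_heights_per_s": rec.v, "outcome": rec.outcome,
            "condition": rec.condition, "prediction": pred, "margin": margin,
        })
    table = pd.DataFrame(rows)
    return ClassificationReport(table, tp, fn, tn, fp)


def energy_strategy(trajectory: pd.DataFrame, bmap: BalanceMap,
                    delta: float = 0.01) -> str:
    """Compare a CM trajectory with the zero-torque curve.

    ``trajectory`` needs columns x_footlen and v_heights_per_s sampled over
    the map's x range.  Returns:

    * ``extra_energy`` — faster than the zero-torque trajectory throughout
      (above the curve by more than ``delta`` somewhere, never materially
      below it),
    * ``crossing``     — crosses the curve (sign of v - v_zero changes by
      more than ``delta`` in both directions),
    * ``on_curve``     — within ``delta`` [heights/s] of the curve
      throughout,
    * ``below_curve``  — materially below the curve throughout (slower
      than the most energy-efficient successful trajectory).
    """
    x = np.asarray(trajectory["x_footlen"], dtype=float)
    v = np.asarray(trajectory["v_heights_per_s"], dtype=float)
    vz = np.asarray(bmap.zero_at(x), dtype=float)  # raises outside map range
    d = v - vz
    if np.all(np.abs(d) <= delta):
        return "on_curve"
    above = np.any(d > delta)
    below = np.any(d < -delta)
    if above and below:
        return "crossing"
    return "extra_energy" if above else "below_curve"
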