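"""Triangle-completion error statistics, exclusion rules and summaries.

Each trial yields four error statistics:

* location error — Euclidean distance between the responded and true cone1
  locations (the primary outcome, in meters);
* distance error — |D_true - D_estimated|, the accuracy of return-path
  length reproduction;
* absolute angular error — |A_true - A_estimated|, where each A is the
  signed angle at cone3 between the second outward leg (v1, cone2 -> cone3)
  and the return vector (v2, cone3 -> true or responded cone1);
* signed allocentric angular error — A_true - A_estimated wrapped into
  [-180, 180); negative values indicate overturning, positive underturning.

Trials are excluded when the participant never initiated/completed the
return (``no_return``), walked beyond the test-space boundary
(``out_of_bounds``), or retraced the outward path via cone2 (``retracing``).
For out-of-bounds trials the boundary-crossing point of the return path is
used as a proxy initial heading estimate, so the signed angular error can
still be computed and the overturning bias of exclusion avoided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from ._angles import angle_between, wrap_to_180
from .trajectory import CONDITIONS, Trajectory

__all__ = [
    "TrialOutcome",
    "location_error",
    "signed_angular_error",
    "angular_errors",
    "distance_error",
    "classify_trial",
    "boundary_crossing",
    "oob_proxy_signed_error",
    "score_trial",
    "score_trials",
    "summarize",
    "condition_deltas",
    "oob_chisq",
]

#: default corridor radius (m) around cone2 that flags a retracing strategy
R_RETRACE = 0.5


@dataclass
class TrialOutcome:
    """Scored errors and exclusion status for one trial."""

    location_error: float
    distance_error: float
    abs_angular_error: float
    signed_angular_error: float
    excluded: bool
    exclusion_reason: str  # none | retracing | no_return | out_of_bounds
    oob_proxy_signed_error: float  # NaN unless out_of_bounds


def location_error(response, cone1_true) -> float:
    """Euclidean distance (m) between estimated and actual cone1 locations."""
    p = np.asarray(response, dtype=float)
    q = np.asarray(cone1_true, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("location_error requires finite coordinates")
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def signed_angular_error(a_true_deg: float, a_est_deg: float) -> float:
    """Signed allocentric angular error: wrap(A_true - A_estimated) into
    [-180, 180). Negative = overturning, positive = underturning."""
    return float(wrap_to_180(a_true_deg - a_est_deg))


def _return_vectors(traj: Trajectory):
    v1 = traj.cones[2] - traj.cones[1]  # cone2 -> cone3
    v2_true = traj.cones[0] - traj.cones[2]  # cone3 -> true cone1
    return v1, v2_true


def _cumulative_turn(traj: Trajectory, v1) -> float:
    """Unwrapped turn estimate: initial return heading relative to v1 plus
    accumulated heading changes along the return path. May exceed +/-180."""
    path = traj.return_path()
    steps = np.diff(path, axis=0)
    keep = np.hypot(steps[:, 0], steps[:, 1]) > 1e-9
    steps = steps[keep]
    if len(steps) == 0:
        raise ValueError("return path too short for cumulative turn estimate")
    total = angle_between(v1, steps[0])
    for a, b in zip(steps[:-1], steps[1:]):
        total += angle_between(a, b)
    return total


def angular_errors(traj: Trajectory, estimator: str = "allocentric"):
    """(absolute, signed) angular error in degrees for a completed trial.

    ``estimator="allocentric"`` (default) takes A_est as the atan2 angle
    between v1 and the cone3 -> response vector. ``"cumulative"`` instead
    integrates heading changes along the return path, which can exceed
    +/-180 deg; the signed error is identical after wrapping.
    """
    resp = traj.response
    if resp is None:
        raise ValueError("angular_errors requires a completed trial (trigger)")
    v1, v2_true = _return_vectors(traj)
    a_true = angle_between(v1, v2_true)
    if estimator == "allocentric":
        a_est = angle_between(v1, resp - traj.cones[2])
    elif estimator == "cumulative":
        a_est = _cumulative_turn(traj, v1)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return abs(a_true - a_est), signed_angular_error(a_true, a_est)


def distance_error(traj: Trajectory) -> float:
    """|D_true - D_estimated| in meters for a completed trial."""
    resp = traj.response
    if resp is None:
        raise ValueError("distance_error requires a completed trial")
    d_true = np.hypot(*(traj.cones[0] - traj.cones[2]))
    d_est = np.hypot(*(resp - traj.cones[2]))
    return float(abs(d_true - d_est))


def _min_dist_to_point(path: np.ndarray, point: np.ndarray) -> float:
    """Minimum distance from a polyline to a point (vectorized segments)."""
    if len(path) == 1:
        return float(np.hypot(*(path[0] - point)))
    p, q = path[:-1], path[1:]
    d = q - p
    len2 = np.einsum("ij,ij->i", d, d)
    len2[len2 == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", point - p, d) / len2, 0.0, 1.0)
    proj = p + t[:, None] * d
    return float(np.min(np.hypot(proj[:, 0] - point[0], proj[:, 1] - point[1])))


def classify_trial(traj: Trajectory, r_retrace: float = R_RETRACE) -> str:
    """Exclusion decision for one trial.

    Returns one of ``included``, ``no_return``, ``out_of_bounds``,
    ``retracing``. The out-of-bounds test uses the arena square itself (the
    30 cm warning band outside it is a simulator/task detail, not part of
    the exclusion rule). Retracing is flagged when the return path passes
    within ``r_retrace`` of cone2 — a reproducible proxy for the manual
    judgment used on the real data.
    """
    if traj.trigger_index is None:
        return "no_return"
    path = traj.return_path()
    inside = traj.arena.contains(path)
    if not inside[0]:
        warnings.warn(
            "return path starts outside the arena; treating as no_return",
            stacklevel=2,
        )
        return "no_return"
    if not np.all(inside):
        return "out_of_bounds"
    if _min_dist_to_point(path, traj.cones[1]) < r_retrace:
        return "retracing"
    return "included"


def boundary_crossing(traj: Trajectory) -> np.ndarray:
    """First intersection of the return path with the arena border.

    Walks the return-path segments in sample order and returns the point
    where the path first exits the square. Raises if no crossing exists
    (inconsistent with an out-of-bounds classification).
    """
    path = traj.return_path() - np.asarray(traj.arena.origin)
    h = traj.arena.half
    inside = (np.abs(path[:, 0]) <= h) & (np.abs(path[:, 1]) <= h)
    for i in range(len(path) - 1):
        if inside[i] and not inside[i + 1]:
            p, q = path[i], path[i + 1]
            d = q - p
            ts = []
            for axis in (0, 1):
                for wall in (-h, h):
                    if d[axis] != 0:
                        t = (wall - p[axis]) / d[axis]
                        if 0.0 <= t <= 1.0:
                            other = p[1 - axis] + t * d[1 - axis]
                            if abs(other) <= h + 1e-12:
                                ts.append(t)
            if ts:
                cross = p + min(ts) * d
                return cross + np.asarray(traj.arena.origin)
    raise ValueError("no boundary crossing found on the return path")


def oob_proxy_signed_error(traj: Trajectory) -> float:
    """Signed angular error using the boundary-collision point as the proxy
    estimate of the initial return heading (out-of-bounds trials only)."""
    if classify_trial(traj) != "out_of_bounds":
        raise ValueError("oob proxy is defined for out_of_bounds trials only")
    v1, v2_true = _return_vectors(traj)
    a_true = angle_between(v1, v2_true)
    a_est = angle_between(v1, boundary_crossing(traj) - traj.cones[2])
    return signed_angular_error(a_true, a_est)


def score_trial(
    traj: Trajectory, r_retrace: float = R_RETRACE, estimator: str = "allocentric"
) -> TrialOutcome:
    """Classify one trial and compute its error statistics.

    Error fields are NaN for excluded trials; out-of-bounds trials carry the
    boundary-collision proxy signed error.
    """
    reason = classify_trial(traj, r_retrace=r_retrace)
    nan = float("nan")
    if reason == "included":
        abs_ang, signed_ang = angular_errors(traj, estimator=estimator)
        return TrialOutcome(
            location_error=location_error(traj.response, traj.cones[0]),
            distance_error=distance_error(traj),
            abs_angular_error=abs_ang,
            signed_angular_error=signed_ang,
            excluded=False,
            exclusion_reason="none",
            oob_proxy_signed_error=nan,
        )
    proxy = oob_proxy_signed_error(traj) if reason == "out_of_bounds" else nan
    return TrialOutcome(nan, nan, nan, nan, True, reason, proxy)


ERROR_COLS = (
    "location_error",
    "distance_error",
    "abs_angular_error",
    "signed_angular_error",
)


def score_trials(trajectories, r_retrace: float = R_RETRACE) -> pd.DataFrame:
    """Score many trials into a tidy per-trial table.

    Uses each trajectory's ``meta`` for pid / trial / environment columns.
    """
    rows = []
    for traj in trajectories:
        out = score_trial(traj, r_retrace=r_retrace)
        rows.append(
            {
                "pid": traj.meta.get("pid"),
                "trial": traj.meta.get("trial"),
                "condition": traj.condition,
                "environment": traj.meta.get("environment"),
                "included": not out.excluded,
                "reason": out.exclusion_reason,
                "location_error": out.location_error,
                "distance_error": out.distance_error,
                "abs_angular_error": out.abs_angular_error,
                "signed_angular_error": out.signed_angular_error,
                "oob_proxy_signed_error": out.oob_proxy_signed_error,
            }
        )
    return pd.DataFrame(rows)


def summarize(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant per-condition summary over included trials.

    Returns one row per (pid, condition) with the mean of each error
    statistic over included trials, counts per exclusion category, and
    ``delta_*`` columns (condition mean minus the participant's condition-A
    baseline mean; missing when either mean is undefined).
    """
    df = trial_table
    groups = []
    for (pid, cond), g in df.groupby(["pid", "condition"], sort=True):
        inc = g[g["included"]]
        row = {"pid": pid, "condition": cond, "n_included": len(inc)}
        row["n_oob"] = int((g["reason"] == "out_of_bounds").sum())
        row["n_retrace"] = int((g["reason"] == "retracing").sum())
        row["n_no_return"] = int((g["reason"] == "no_return").sum())
        for col in ERROR_COLS:
            row[f"mean_{col}"] = inc[col].mean() if len(inc) else np.nan
        groups.append(row)
    summary = pd.DataFrame(groups)
    baseline = (
        summary[summary["condition"] == "A"]
        .set_index("pid")[[f"mean_{c}" for c in ERROR_COLS]]
        .rename(columns=lambda c: c.replace("mean_", "base_"))
    )
    summary = summary.join(baseline, on="pid")
    for col in ERROR_COLS:
        summary[f"delta_{col}"] = summary[f"mean_{col}"] - summary[f"base_{col}"]
    return summary.drop(columns=[c for c in summary if c.startswith("base_")])


def condition_deltas(summary: pd.DataFrame, statistic: str = "location_error"):
    """Wide per-participant change scores (B-A and C-A) for one statistic."""
    col = f"delta_{statistic}"
    wide = summary.pivot(index="pid", columns="condition", values=col)
    wide = wide.rename(columns={"B": "delta_BA", "C": "delta_CA"})
    return wide[[c for c in ("delta_BA", "delta_CA") if c in wide]]


def oob_chisq(trial_table: pd.DataFrame, group: pd.Series):
    """Chi-square test of out-of-bounds proportions between groups.

    ``group`` maps pid -> group label (e.g. risk stratum or above/below
    median CAIDE). Returns (chi2, p, contingency table).
    """
    df = trial_table.copy()
    df["group"] = df["pid"].map(group)
    df["oob"] = df["reason"] == "out_of_bounds"
    table = pd.crosstab(df["group"], df["oob"])
    if table.shape[0] < 2:
        raise ValueError("need at least two groups for the chi-square test")
    # expected counts are large (hundreds of trials per cell), so the
    # uncorrected statistic is well calibrated; Yates' correction would be
    # needlessly conservative here
    chi2, p, _, _ = chi2_contingency(table.values, correction=False)
    return float(chi2), float(p), table
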