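"""Circular helpers shared across scoring and grid-code modules.

All public angles in this package are degrees; counter-clockwise is positive.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_to_180",
    "wrap_to_period",
    "angle_between",
    "circular_mean_deg",
    "circular_sd_deg",
]


def wrap_to_180(angle_deg):
    """Wrap angles into [-180, 180) degrees.

    Periodic: ``wrap_to_180(x + 360k) == wrap_to_180(x)`` for every integer k
    (both +180 and -180 inputs map to -180).
    """
    return (np.asarray(angle_deg, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_to_period(angle_deg, period_deg: float):
    """Wrap angles into [-period/2, period/2) degrees for a given period."""
    half = period_deg / 2.0
    return (np.asarray(angle_deg, dtype=float) + half) % period_deg - half


def angle_between(v1, v2) -> float:
    """Signed angle from ``v1`` to ``v2`` in degrees, in (-180, 180].

    Computed as atan2 of the z-component of the cross product and the dot
    product, so positive values are counter-clockwise rotations from v1 to v2.
    Raises ``ValueError`` for zero-length input (the heading is undefined,
    which downstream signals a degenerate triangle leg).
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
        raise ValueError("angle_between requires finite vectors")
    if np.hypot(*v1) == 0.0 or np.hypot(*v2) == 0.0:
        raise ValueError("angle_between is undefined for zero-length vectors")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = v1[0] * v2[0] + v1[1] * v2[1]
    return float(np.degrees(np.arctan2(cross, dot)))


def circular_mean_deg(angles_deg, weights=None) -> float:
    """(Weighted) circular mean direction of angles in degrees, in [0, 360)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    if a.size == 0:
        raise ValueError("circular mean of empty set")
    s = np.sum(w * np.sin(a))
    c = np.sum(w * np.cos(a))
    ang = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return 0.0 if ang >= 360.0 else ang  # guard the -eps % 360 == 360 case


def circular_sd_deg(angles_deg) -> float:
    """Circular standard deviation sqrt(-2 ln R) of angles in degrees."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    r = np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a)))
    r = min(max(r, 1e-300), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))
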