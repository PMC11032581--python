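"""Test-space geometry: the square VR arena and triangle generation.

The triangle-completion task runs in a square open-field test space (4 x 4 m
by default) centered on the origin. Each trial places three cones; the
participant walks cone1 -> cone2 -> cone3 and then returns to the remembered
cone1 location. Return-path lengths are drawn from a restricted band
(3.6-4.0 m by default) to control difficulty, and a warning band outside the
arena border (30 cm by default) marks where an out-of-border warning fires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArenaSpec", "generate_triangle"]

# outward legs must be walkable inside the square; lower bound keeps cone2
# distinguishable from its neighbours for retracing detection
MIN_OUTWARD_LEG = 1.0
MAX_OUTWARD_LEG = 4.0
# cone2 stays clear of the direct return line so a direct homing response is
# never confusable with a retracing strategy (degenerate flat triangles are
# not usable task geometry)
MIN_CONE2_RETURN_CLEARANCE = 1.2


@dataclass(frozen=True)
class ArenaSpec:
    """Square test-space geometry, arena-centered coordinates in meters."""

    side_length: float = 4.0
    border_margin: float = 0.30
    min_return: float = 3.6
    max_return: float = 4.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if not (0 <= self.border_margin < self.side_length / 2):
            raise ValueError("border_margin must be in [0, side_length/2)")
        diag = self.side_length * np.sqrt(2.0)
        if not (0 < self.min_return <= self.max_return < diag):
            raise ValueError(
                "need 0 < min_return <= max_return < side_length*sqrt(2)"
            )

    @property
    def half(self) -> float:
        return self.side_length / 2.0

    def contains(self, xy) -> np.ndarray:
        """Boolean mask of points inside the (closed) arena square."""
        p = np.atleast_2d(np.asarray(xy, dtype=float)) - np.asarray(self.origin)
        return (np.abs(p[:, 0]) <= self.half) & (np.abs(p[:, 1]) <= self.half)


def _point_segment_dist(p, a, b):
    """Distance from point(s) p to segment(s) a-b, broadcasting over rows."""
    p, a, b = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (p, a, b))
    d = b - a
    len2 = np.einsum("ij,ij->i", d, d)
    safe = np.where(len2 == 0, 1.0, len2)
    t = np.clip(np.einsum("ij,ij->i", p - a, d) / safe, 0.0, 1.0)
    proj = a + t[:, None] * d
    out = np.hypot(proj[:, 0] - p[:, 0], proj[:, 1] - p[:, 1])
    return out if out.size > 1 else float(out[0])


def generate_triangle(
    arena: ArenaSpec, rng_seed, max_attempts: int = 20_000
) -> np.ndarray:
    """Draw pseudo-random cone positions for one trial.

    Rejection-samples three points strictly inside the arena such that the
    return leg |cone3 - cone1| lies in [min_return, max_return] and each
    outward leg is walkable (1-4 m). Deterministic given the seed.

    Returns a (3, 2) array of cone coordinates. Raises ``RuntimeError`` if
    the constraints cannot be satisfied (inconsistent ``ArenaSpec``).
    """
    rng = np.random.default_rng(rng_seed)
    half = arena.half
    origin = np.asarray(arena.origin, dtype=float)
    margin = 0.05  # keep cones strictly off the wall
    lo, hi = -half + margin, half - margin
    batch = 128
    for _ in range(max(max_attempts // batch, 1)):
        c1 = rng.uniform(lo, hi, size=(batch, 2))
        # cone3 at a valid return distance from cone1, then cone2 anywhere
        r = rng.uniform(arena.min_return, arena.max_return, size=batch)
        phi = rng.uniform(0.0, 2 * np.pi, size=batch)
        c3 = c1 + r[:, None] * np.column_stack([np.cos(phi), np.sin(phi)])
        c2 = rng.uniform(lo, hi, size=(batch, 2))
        leg1 = np.hypot(*(c2 - c1).T)
        leg2 = np.hypot(*(c3 - c2).T)
        ok = (
            (np.abs(c3) <= hi).all(axis=1)
            & (leg1 >= MIN_OUTWARD_LEG)
            & (leg1 <= MAX_OUTWARD_LEG)
            & (leg2 >= MIN_OUTWARD_LEG)
            & (leg2 <= MAX_OUTWARD_LEG)
            & (_point_segment_dist(c2, c3, c1) >= MIN_CONE2_RETURN_CLEARANCE)
        )
        if ok.any():
            i = int(np.argmax(ok))
            return np.vstack([c1[i], c2[i], c3[i]]) + origin
    raise RuntimeError(
        "could not place a triangle satisfying the arena constraints; "
        "check min_return/max_return against the arena size"
    )
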