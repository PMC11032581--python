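"""Generative agent walking the triangle-completion task.

The agent walks the two outward legs exactly, then produces a homing
response from a noisy internal estimate: the return heading is the true
heading plus a von Mises error (concentration set per return condition),
and the return length is the true length times a multiplicative lognormal
gain. A 2D Gaussian encoding noise can additionally blur the endpoint.
If the planned return segment exits the arena, the agent either walks past
the wall (an out-of-bounds trial, with the out-of-border warning recorded
30 cm beyond the wall) or stops just inside it, with probability
``oob_propensity`` of the former.

This is a deliberately simple stand-in for human homing behavior: its one
job is to let planted angular-noise effects propagate into exactly the
error statistics the scoring layer extracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import ArenaSpec
from .trajectory import CONDITIONS, Trajectory

__all__ = ["AgentParams", "simulate_trial", "sigma_deg_to_kappa", "kappa_to_sigma_deg"]

SAMPLE_DT = 0.1  # tracking sample interval, seconds
WALK_SPEED = 1.0  # m/s, constant
STOP_INSIDE = 0.02  # m inside the wall when the agent refuses to go out


def sigma_deg_to_kappa(sigma_deg: float) -> float:
    """Von Mises concentration for a small-angle heading SD in degrees.

    Uses the concentrated-regime relation kappa = 1/sigma_rad^2; returns
    inf for sigma = 0.
    """
    if sigma_deg <= 0:
        return float("inf")
    return float(1.0 / np.radians(sigma_deg) ** 2)


def kappa_to_sigma_deg(kappa: float) -> float:
    if np.isinf(kappa):
        return 0.0
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    return float(np.degrees(1.0 / np.sqrt(kappa)))


@dataclass
class AgentParams:
    """Noise parameters of the homing agent.

    ``heading_noise_kappa`` is either a scalar or a per-condition mapping
    {A, B, C} -> von Mises concentration (dimensionless; inf = noiseless).
    ``distance_gain_mean``/``distance_gain_sd`` parameterize the lognormal
    multiplicative distance-reproduction gain (mean on the natural scale).
    ``participant_sd_*`` are between-participant SDs used by the cohort
    simulator to draw per-participant random effects.
    """

    heading_noise_kappa: float | dict = field(
        default_factory=lambda: {
            "A": sigma_deg_to_kappa(12.0),
            "B": sigma_deg_to_kappa(16.0),
            "C": sigma_deg_to_kappa(20.0),
        }
    )
    distance_gain_mean: float = 1.0
    distance_gain_sd: float = 0.12
    encoding_noise_sd: float = 0.0
    oob_propensity: float = 0.6
    participant_sd_heading_deg: float = 4.0
    participant_sd_log_gain: float = 0.05

    def __post_init__(self) -> None:
        kappas = (
            self.heading_noise_kappa.values()
            if isinstance(self.heading_noise_kappa, dict)
            else [self.heading_noise_kappa]
        )
        if any(k < 0 for k in kappas):
            raise ValueError("heading_noise_kappa must be >= 0")
        if self.distance_gain_mean <= 0:
            raise ValueError("distance_gain_mean must be positive")
        if min(self.distance_gain_sd, self.encoding_noise_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (0.0 <= self.oob_propensity <= 1.0):
            raise ValueError("oob_propensity must be in [0, 1]")

    def kappa_for(self, condition: str) -> float:
        if isinstance(self.heading_noise_kappa, dict):
            return float(self.heading_noise_kappa[condition])
        return float(self.heading_noise_kappa)


def _segment_points(a: np.ndarray, b: np.ndarray, include_start: bool):
    """Sample points along a->b at the walking speed and tracking rate."""
    length = float(np.hypot(*(b - a)))
    n = max(int(np.ceil(length / (WALK_SPEED * SAMPLE_DT))), 1)
    ts = np.linspace(0.0, 1.0, n + 1)
    if not include_start:
        ts = ts[1:]
    return a[None, :] + ts[:, None] * (b - a)[None, :]


def _exit_time(p: np.ndarray, d: np.ndarray, half: float) -> float | None:
    """Smallest t > 0 where p + t*d leaves the centered square, else None."""
    ts = []
    for axis in (0, 1):
        for wall in (-half, half):
            if d[axis] != 0.0:
                t = (wall - p[axis]) / d[axis]
                if t > 1e-12:
                    other = p[1 - axis] + t * d[1 - axis]
                    if abs(other) <= half + 1e-12:
                        ts.append(t)
    return min(ts) if ts else None


def simulate_trial(
    cones: np.ndarray,
    agent: AgentParams,
    condition: str,
    arena: ArenaSpec | None = None,
    rng_seed=None,
    meta: dict | None = None,
) -> Trajectory:
    """Simulate one trial and return its Trajectory (always legal).

    The outward path visits cone1 -> cone2 -> cone3 exactly; the return is a
    straight walk along the noisy homing vector. Deterministic given
    ``rng_seed`` (an int, SeedSequence or Generator).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    arena = arena or ArenaSpec()
    rng = np.random.default_rng(rng_seed)
    cones = np.asarray(cones, dtype=float)
    c1, c2, c3 = cones

    pts = [c1[None, :]]
    events = [(0, "cone1_reached")]
    pts.append(_segment_points(c1, c2, include_start=False))
    n_so_far = 1 + len(pts[-1])
    events.append((n_so_far - 1, "cone2_reached"))
    pts.append(_segment_points(c2, c3, include_start=False))
    n_so_far += len(pts[-1])
    events.append((n_so_far - 1, "cone3_reached"))

    # noisy homing vector
    true_vec = c1 - c3
    true_len = float(np.hypot(*true_vec))
    kappa = agent.kappa_for(condition)
    eps = 0.0 if np.isinf(kappa) else float(rng.vonmises(0.0, kappa))
    heading = np.arctan2(true_vec[1], true_vec[0]) + eps
    if agent.distance_gain_sd > 0:
        sd_log = float(
            np.sqrt(np.log1p((agent.distance_gain_sd / agent.distance_gain_mean) ** 2))
        )
        gain = agent.distance_gain_mean * np.exp(
            rng.normal(0.0, sd_log) - 0.5 * sd_log**2
        )
    else:
        gain = agent.distance_gain_mean
    endpoint = c3 + gain * true_len * np.array([np.cos(heading), np.sin(heading)])
    if agent.encoding_noise_sd > 0:
        endpoint = endpoint + rng.normal(0.0, agent.encoding_noise_sd, size=2)

    origin = np.asarray(arena.origin)
    p0 = c3 - origin
    d = endpoint - c3
    t_exit = _exit_time(p0, d, arena.half) if np.hypot(*d) > 0 else None
    goes_out = t_exit is not None and t_exit < 1.0
    oob_fires = bool(goes_out and rng.random() < agent.oob_propensity)
    if goes_out and not oob_fires:
        # stop just inside the wall along the same heading
        t_stop = max(t_exit - STOP_INSIDE / max(np.hypot(*d), 1e-12), 1e-6)
        endpoint = c3 + min(t_stop, 1.0) * d

    ret = _segment_points(c3, endpoint, include_start=False)
    if len(ret):
        pts.append(ret)
    n_total = n_so_far + len(ret)
    events.append((n_total - 1, "trigger"))

    xy = np.vstack(pts)
    if oob_fires:
        # warning fires when the walk passes 30 cm beyond the wall
        rel = xy - origin
        beyond = np.maximum(np.abs(rel[:, 0]), np.abs(rel[:, 1])) > (
            arena.half + arena.border_margin
        )
        beyond[: n_so_far] = False
        if beyond.any():
            events.append((int(np.argmax(beyond)), "oob_warning"))

    times = np.arange(len(xy)) * SAMPLE_DT
    return Trajectory(
        times=times,
        xy=xy,
        cones=cones,
        condition=condition,
        events=sorted(events),
        arena=arena,
        meta=meta or {},
    )
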