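"""Shared fixtures: hand-built trajectories and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from gridpi import ArenaSpec, Trajectory


def make_trajectory(
    cones,
    return_points,
    condition="A",
    arena=None,
    with_trigger=True,
    extra_events=(),
):
    """Build a trajectory from cone geometry and explicit return-path points.

    The outward path is sampled along the straight legs; ``return_points``
    are appended after cone3 (each becomes one 0.1 s sample).
    """
    arena = arena or ArenaSpec()
    cones = np.asarray(cones, dtype=float)
    pts = [cones[0]]
    events = [(0, "cone1_reached")]
    for a, b, label in (
        (cones[0], cones[1], "cone2_reached"),
        (cones[1], cones[2], "cone3_reached"),
    ):
        n = max(int(np.ceil(np.hypot(*(b - a)) / 0.1)), 1)
        seg = a + np.linspace(0, 1, n + 1)[1:, None] * (b - a)
        pts.extend(seg)
        events.append((len(pts) - 1, label))
    for p in np.atleast_2d(np.asarray(return_points, dtype=float)):
        pts.append(p)
    if with_trigger:
        events.append((len(pts) - 1, "trigger"))
    events.extend(extra_events)
    xy = np.asarray(pts)
    return Trajectory(
        times=np.arange(len(xy)) * 0.1,
        xy=xy,
        cones=cones,
        condition=condition,
        events=sorted(events),
        arena=arena,
    )


@pytest.fixture
def arena():
    return ArenaSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_cones():
    """A comfortable triangle well inside the default arena."""
    return np.array([[-1.2, -1.0], [1.2, -1.0], [1.0, 1.4]])
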