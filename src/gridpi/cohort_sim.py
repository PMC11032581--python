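"""Synthetic cohorts for the risk-factor analyses.

Generates a participant table (family history of dementia, APOE e4 carrier
status, CAIDE dementia risk score, sex, age, education) with marginals
defaulting to the midlife at-risk cohort the task was designed for, plus a
full set of 36 triangle-completion trials per participant (12 per return
condition, pseudo-randomized order).

Planted effects enter through the angular-noise scale: an effect key
``(term, condition, sex)`` adds its value (degrees of heading-noise SD, per
unit of the term) to participants matching the term whenever they perform
the given condition. ``term`` is a ``:``-joined product of binary columns
(``"fh"``, ``"apoe4"``, ``"fh:apoe4"``) or ``"caide"`` (continuous,
centered at its cohort mean, effect per point). ``condition``/``sex`` of
``None`` mean "all". With all effects zero the generator is an exact null:
no participant characteristic influences performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent import AgentParams, kappa_to_sigma_deg, sigma_deg_to_kappa
from .arena import ArenaSpec, generate_triangle
from .agent import simulate_trial
from .trajectory import CONDITIONS, Trajectory

__all__ = ["CohortSpec", "default_caide_pmf", "simulate_cohort"]

MIN_SIGMA_DEG = 2.0  # floor on per-trial heading-noise SD
CAIDE_CENTER = 5.0  # centering point for the continuous CAIDE effect


def default_caide_pmf() -> np.ndarray:
    """Discrete CAIDE distribution on 0..15: a discretized normal matching
    the cohort's reported mean 5.02, SD 2.21, observed range 0-11."""
    scores = np.arange(16)
    dens = np.exp(-0.5 * ((scores - 5.02) / 2.21) ** 2)
    dens[12:] = 0.0  # observed range 0-11
    return dens / dens.sum()


@dataclass
class CohortSpec:
    """Cohort size, risk-factor prevalences and planted effects."""

    n_participants: int = 99
    p_fh: float = 0.62
    p_apoe4: float = 0.32
    p_female: float = 0.65
    caide_pmf: np.ndarray = field(default_factory=default_caide_pmf)
    age_range: tuple[float, float] = (43.0, 66.0)
    education_range: tuple[float, float] = (10.0, 24.0)
    #: {(term, condition|None, sex|None): degrees of added heading-noise SD}
    effect_sizes: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        for p in (self.p_fh, self.p_apoe4, self.p_female):
            if not (0.0 <= p <= 1.0):
                raise ValueError("prevalences must be in [0, 1]")
        pmf = np.asarray(self.caide_pmf, dtype=float)
        if pmf.shape != (16,) or abs(pmf.sum() - 1.0) > 1e-9 or (pmf < 0).any():
            raise ValueError("caide_pmf must be a length-16 probability vector")
        for term, cond, sex in self.effect_sizes:
            for part in term.split(":"):
                if part not in ("fh", "apoe4", "caide"):
                    raise ValueError(f"unknown effect term component {part!r}")
            if cond is not None and cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} in effect key")
            if sex is not None and sex not in ("F", "M"):
                raise ValueError(f"unknown sex {sex!r} in effect key")


def _draw_participants(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_participants
    return pd.DataFrame(
        {
            "pid": [f"p{i:03d}" for i in range(n)],
            "fh": (rng.random(n) < spec.p_fh).astype(int),
            "apoe4": (rng.random(n) < spec.p_apoe4).astype(int),
            "caide": rng.choice(16, size=n, p=np.asarray(spec.caide_pmf)),
            "sex": np.where(rng.random(n) < spec.p_female, "F", "M"),
            "age_y": np.round(rng.uniform(*spec.age_range, size=n), 1),
            "edu_y": rng.integers(
                int(spec.education_range[0]), int(spec.education_range[1]) + 1, size=n
            ),
        }
    )


def _effect_shift(row: pd.Series, condition: str, spec: CohortSpec) -> float:
    """Planted additive shift (deg) of heading-noise SD for one trial."""
    shift = 0.0
    for (term, cond, sex), size in spec.effect_sizes.items():
        if cond is not None and cond != condition:
            continue
        if sex is not None and sex != row["sex"]:
            continue
        value = 1.0
        for part in term.split(":"):
            if part == "caide":
                value *= row["caide"] - CAIDE_CENTER
            else:
                value *= row[part]
        shift += size * value
    return shift


def _condition_order(rng: np.random.Generator) -> np.ndarray:
    """Pseudo-randomized order of 36 trials, 12 per condition."""
    order = np.repeat(list(CONDITIONS), 12)
    rng.shuffle(order)
    return order


def simulate_cohort(
    spec: CohortSpec,
    agent: AgentParams | None = None,
    arena: ArenaSpec | None = None,
) -> tuple[pd.DataFrame, list[Trajectory]]:
    """Simulate a full cohort: participant table + all trial trajectories.

    Fully reproducible from ``spec.seed``. Participant-level random effects
    (heading-noise SD and log distance gain) are drawn from the agent's
    ``participant_sd_*`` fields; planted effects are added to the
    heading-noise SD per (term, condition, sex) before conversion to the
    von Mises concentration, floored at 2 degrees.
    """
    agent = agent or AgentParams()
    arena = arena or ArenaSpec()
    root = np.random.SeedSequence(spec.seed)
    ss_cohort, ss_trials = root.spawn(2)
    rng = np.random.default_rng(ss_cohort)
    cohort = _draw_participants(spec, rng)

    # validate that planted effects can be realized in this draw
    for (term, cond, sex), size in spec.effect_sizes.items():
        if size == 0.0:
            continue
        mask = np.ones(len(cohort), dtype=bool)
        if sex is not None:
            mask &= (cohort["sex"] == sex).to_numpy()
        for part in term.split(":"):
            if part != "caide":
                mask &= cohort[part].to_numpy() == 1
        if not mask.any():
            raise ValueError(
                f"planted effect {(term, cond, sex)} references an empty cell"
            )

    base_sigma = {
        c: kappa_to_sigma_deg(agent.kappa_for(c)) for c in CONDITIONS
    }
    trial_streams = ss_trials.spawn(len(cohort))
    trajectories: list[Trajectory] = []
    for (_, row), ss in zip(cohort.iterrows(), trial_streams):
        prng = np.random.default_rng(ss)
        sigma_re = prng.normal(0.0, agent.participant_sd_heading_deg)
        gain_re = prng.normal(0.0, agent.participant_sd_log_gain)
        order = _condition_order(prng)
        for trial_idx, condition in enumerate(order):
            sigma = max(
                base_sigma[condition] + sigma_re + _effect_shift(row, condition, spec),
                MIN_SIGMA_DEG,
            )
            trial_agent = AgentParams(
                heading_noise_kappa=sigma_deg_to_kappa(sigma),
                distance_gain_mean=agent.distance_gain_mean * np.exp(gain_re),
                distance_gain_sd=agent.distance_gain_sd,
                encoding_noise_sd=agent.encoding_noise_sd,
                oob_propensity=agent.oob_propensity,
            )
            cones = generate_triangle(arena, prng)
            traj = simulate_trial(
                cones,
                trial_agent,
                condition,
                arena=arena,
                rng_seed=prng,
                meta={
                    "pid": row["pid"],
                    "trial": trial_idx,
                    "environment": int(prng.integers(3)),
                },
            )
            trajectories.append(traj)
    return cohort, trajectories
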