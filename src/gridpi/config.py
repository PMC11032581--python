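"""Run configuration: one YAML file describing a full reproducible run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .agent import AgentParams
from .arena import ArenaSpec
from .bold_sim import GridSimSpec
from .cohort_sim import CohortSpec

__all__ = ["RunConfig"]


def _pyify(obj):
    """Recursively convert numpy scalars/arrays to built-in types for YAML."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_pyify(v) for v in obj.tolist()]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _effects_to_yaml(effects: dict) -> list:
    return [
        {"term": term, "condition": cond, "sex": sex, "size": float(size)}
        for (term, cond, sex), size in effects.items()
    ]


def _effects_from_yaml(items) -> dict:
    return {
        (e["term"], e.get("condition"), e.get("sex")): float(e["size"])
        for e in items or []
    }


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulate-score-gridfit-cohort run.

    The single ``seed`` is expanded into independent per-stage streams via
    ``numpy.random.SeedSequence`` so stages can be rerun in isolation.
    ``grid`` may be None, in which case the pipeline runs behavioral-only.
    """

    seed: int = 0
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    agent: AgentParams = field(default_factory=AgentParams)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    grid: GridSimSpec | None = field(default_factory=GridSimSpec)
    n_elasticnet_permutations: int = 200
    out_dir: str = "gridpi_run"
    log_level: str = "INFO"

    def stage_seeds(self) -> dict:
        children = np.random.SeedSequence(self.seed).spawn(4)
        return dict(zip(("simulate", "score", "gridfit", "cohort"), children))

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "arena": asdict(self.arena),
            "agent": asdict(self.agent),
            "cohort": asdict(self.cohort),
            "grid": asdict(self.grid) if self.grid is not None else None,
            "n_elasticnet_permutations": self.n_elasticnet_permutations,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }
        d["arena"]["origin"] = list(d["arena"]["origin"])
        d["cohort"]["caide_pmf"] = [float(p) for p in d["cohort"]["caide_pmf"]]
        d["cohort"]["effect_sizes"] = _effects_to_yaml(self.cohort.effect_sizes)
        d["cohort"]["age_range"] = list(d["cohort"]["age_range"])
        d["cohort"]["education_range"] = list(d["cohort"]["education_range"])
        return _pyify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        arena_kw = dict(d.get("arena", {}))
        if "origin" in arena_kw:
            arena_kw["origin"] = tuple(arena_kw["origin"])
        cohort_kw = dict(d.get("cohort", {}))
        if "effect_sizes" in cohort_kw:
            cohort_kw["effect_sizes"] = _effects_from_yaml(cohort_kw["effect_sizes"])
        if "caide_pmf" in cohort_kw:
            cohort_kw["caide_pmf"] = np.asarray(cohort_kw["caide_pmf"], dtype=float)
        for key in ("age_range", "education_range"):
            if key in cohort_kw:
                cohort_kw[key] = tuple(cohort_kw[key])
        grid_kw = d.get("grid")
        return cls(
            seed=int(d.get("seed", 0)),
            arena=ArenaSpec(**arena_kw),
            agent=AgentParams(**d.get("agent", {})),
            cohort=CohortSpec(**cohort_kw),
            grid=GridSimSpec(**grid_kw) if grid_kw is not None else None,
            n_elasticnet_permutations=int(d.get("n_elasticnet_permutations", 200)),
            out_dir=d.get("out_dir", "gridpi_run"),
            log_level=d.get("log_level", "INFO"),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), newline="\n"
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
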