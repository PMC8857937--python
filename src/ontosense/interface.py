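"""Scenario configuration, serialization and fixture generation.

A :class:`ScenarioConfig` gathers every knob of a run -- model parameters,
experiment parameters and seeds -- and round-trips losslessly through a
plain YAML file.  Every output file written by the command-line layer
embeds the resolved configuration and the code version string so each
artifact is reproducible from its own header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .core import (
    CueReliabilitySchedule,
    EnvironmentState,
    FitnessMapping,
    build_schedule,
)
from .solver import Policy, solve_policy
from .twins import TwinStudyConfig

__all__ = [
    "ScenarioConfig",
    "load_config",
    "load_policy_header",
    "generate_fixtures",
    "PRIOR_PRESETS",
]

logger = logging.getLogger("ontosense.interface")

#: Standard priors for P(E1): uniform plus two informative presets.
PRIOR_PRESETS = (0.5, 0.7, 0.9)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one scenario.

    ``max_payoff`` defaults to ``T`` so that the linear mapping has unit
    marginal effects (``f(y) = y``); ``baseline`` defaults to the
    worst-case penalty, keeping fitness non-negative.
    """

    T: int = 20
    prior_p1: float = 0.5
    pattern: str = "increasing"
    r_min: float = 0.55
    r_max: float = 0.95
    reward_shape: str = "linear"
    penalty_shape: str = "linear"
    max_payoff: float | None = None
    baseline: float | None = None
    environment: str = "E1"
    n: int = 10_000
    seed: int = 1
    twin: dict = field(
        default_factory=lambda: {
            "treatment": "reciprocal_opposite",
            "duration": "permanent",
            "measurement": "end_of_ontogeny",
            "n_pairs": 10_000,
            "dose_q": None,
        }
    )

    def schedule(self) -> CueReliabilitySchedule:
        return build_schedule(self.pattern, self.r_min, self.r_max, self.T)

    def fitness_mapping(self) -> FitnessMapping:
        return FitnessMapping(
            reward_shape=self.reward_shape,
            penalty_shape=self.penalty_shape,
            max_payoff=self.max_payoff if self.max_payoff is not None else float(self.T),
            baseline=self.baseline,
        )

    def environment_state(self) -> EnvironmentState:
        return EnvironmentState[self.environment]

    def twin_config(self, separation_period: int = 1) -> TwinStudyConfig:
        tw = dict(self.twin)
        duration = tw.get("duration", "permanent")
        if duration != "permanent":
            duration = int(duration)
        return TwinStudyConfig(
            separation_period=separation_period,
            treatment=tw.get("treatment", "reciprocal_opposite"),
            duration=duration,
            measurement=tw.get("measurement", "end_of_ontogeny"),
            n_pairs=int(tw.get("n_pairs", 10_000)),
            seed=self.seed,
            dose_q=tw.get("dose_q"),
        )

    def solve(self, **kwargs) -> Policy:
        return solve_policy(self.prior_p1, self.schedule(), self.fitness_mapping(), **kwargs)

    # -- round-tripping ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def comment_header(self) -> str:
        """Single-line JSON echo of the resolved config plus the code
        version, embedded as a comment in tabular outputs."""
        from . import __version__

        return "config: " + json.dumps(
            {"version": __version__, **self.to_dict()}, sort_keys=True
        )


def load_config(path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ScenarioConfig.from_dict(data)


def load_policy_header(path) -> ScenarioConfig:
    """Recover the scenario encoded in a policy file's parameter header."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "ontosense-policy":
        raise ValueError(f"{path} is not a policy file")
    sched = doc["schedule"]
    mapping = doc["mapping"]
    return ScenarioConfig(
        T=int(doc["T"]),
        prior_p1=float(doc["prior_p1"]),
        pattern=sched["pattern"],
        r_min=float(sched["r_min"]),
        r_max=float(sched["r_max"]),
        reward_shape=mapping["reward_shape"],
        penalty_shape=mapping["penalty_shape"],
        max_payoff=float(mapping["max_payoff"]),
        baseline=float(mapping["baseline"]),
    )


def generate_fixtures(directory) -> list[Path]:
    """Write the canned scenario configs used throughout the test suite
    and documentation.

    Twelve fixtures: a T=3 uninformative scenario (all actions tie), a
    T=5 constant high-reliability scenario (fast specialization), a T=6
    twin-oracle scenario small enough for exhaustive enumeration, and the
    nine standard panels (three priors x three reliability patterns) at
    T=20.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, cfg: ScenarioConfig) -> None:
        path = directory / f"{name}.yaml"
        cfg.to_yaml(path)
        written.append(path)

    emit(
        "uninformative_T3",
        ScenarioConfig(T=3, pattern="constant", r_min=0.5, r_max=0.5, n=1000,
                       twin={"n_pairs": 1000}),
    )
    emit(
        "constant09_T5",
        ScenarioConfig(T=5, pattern="constant", r_min=0.9, r_max=0.9, n=1000,
                       twin={"n_pairs": 1000}),
    )
    emit(
        "twin_oracle_T6",
        ScenarioConfig(T=6, pattern="increasing", n=2000,
                       twin={"n_pairs": 2000}),
    )
    for prior in PRIOR_PRESETS:
        for pattern in ("increasing", "decreasing", "triangular"):
            name = f"panel_prior{str(prior).replace('.', '')}_{pattern}_T20"
            emit(name, ScenarioConfig(prior_p1=prior, pattern=pattern))
    logger.info("wrote %d fixture configs to %s", len(written), directory)
    return written
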