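"""Forward simulation of organisms following a solved policy.

Populations are stepped in vectorized form, one period at a time: sample
the cue, descend the belief DAG, look up the set of optimal actions, and
break ties uniformly.  Randomness is organized so that one master seed
derives an independent substream per organism (cue draws, tie-break draws
and, when needed, the environment draw); re-running any subset of
organisms reproduces those organisms exactly, and twin experiments can
share cue streams while decoupling tie-break streams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .core import (
    ACTIONS,
    Cue,
    CueKind,
    CueReliabilitySchedule,
    EnvironmentState,
)
from .solver import _MASK_BITS, _POPCOUNT, Policy

__all__ = [
    "Trajectory",
    "Population",
    "sample_cue_sequence",
    "simulate_organism",
    "simulate_population",
]


def sample_cue_sequence(
    environment: EnvironmentState,
    schedule: CueReliabilitySchedule,
    rng: np.random.Generator,
) -> list[Cue]:
    """Draw one cue per period: the kind matching ``environment`` with
    probability ``r_t``, the mismatching kind otherwise."""
    environment = EnvironmentState(environment)
    u = rng.random(schedule.T)
    match = u < schedule.array
    kinds = np.where(match, int(environment), 1 - int(environment))
    return [Cue(kind=CueKind(int(k)), period=t) for t, k in enumerate(kinds, start=1)]


@dataclass(frozen=True)
class Trajectory:
    """One organism's development: per-period cues, beliefs, actions and
    cumulative phenotype counters, plus terminal fitness.

    Counters never decrease and exactly one increments per period, so
    ``y0 + y1 + yw == t`` after every period and ``== T`` at maturity.
    """

    environment: EnvironmentState | None
    cues: np.ndarray
    p1: np.ndarray
    actions: np.ndarray
    y0: np.ndarray
    y1: np.ndarray
    yw: np.ndarray
    fitness: float

    @property
    def T(self) -> int:
        return len(self.cues)

    @property
    def final_phenotype(self) -> tuple[int, int]:
        return int(self.y0[-1]), int(self.y1[-1])

    def phenotype_at(self, period: int) -> tuple[int, int]:
        if not 1 <= period <= self.T:
            raise ValueError(f"period {period} outside 1..{self.T}")
        return int(self.y0[period - 1]), int(self.y1[period - 1])

    def to_frame(self, organism_id: int = 0) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "organism_id": organism_id,
                "period": np.arange(1, self.T + 1),
                "cue": [CueKind(int(c)).name for c in self.cues],
                "p1": self.p1,
                "action": [ACTIONS[int(a)] for a in self.actions],
                "y0": self.y0,
                "y1": self.y1,
                "yw": self.yw,
            }
        )
        fitness = np.full(self.T, np.nan)
        fitness[-1] = self.fitness
        df["fitness"] = fitness
        return df


class Population:
    """A set of trajectories stored column-wise as ``(n, T)`` arrays."""

    def __init__(
        self,
        policy: Policy,
        environments: np.ndarray,
        cues: np.ndarray,
        p1: np.ndarray,
        actions: np.ndarray,
        y0: np.ndarray,
        y1: np.ndarray,
        yw: np.ndarray,
        fitness: np.ndarray,
    ):
        self.policy = policy
        self.environments = environments
        self.cues = cues
        self.p1 = p1
        self.actions = actions
        self.y0 = y0
        self.y1 = y1
        self.yw = yw
        self.fitness = fitness

    @property
    def n(self) -> int:
        return self.cues.shape[0]

    @property
    def T(self) -> int:
        return self.cues.shape[1]

    def __len__(self) -> int:
        return self.n

    def trajectory(self, i: int) -> Trajectory:
        env = self.environments[i]
        return Trajectory(
            environment=EnvironmentState(int(env)) if env >= 0 else None,
            cues=self.cues[i],
            p1=self.p1[i],
            actions=self.actions[i],
            y0=self.y0[i],
            y1=self.y1[i],
            yw=self.yw[i],
            fitness=float(self.fitness[i]),
        )

    def __iter__(self) -> Iterator[Trajectory]:
        return (self.trajectory(i) for i in range(self.n))

    def to_frame(self) -> pd.DataFrame:
        """Long-format trajectory table, one row per organism-period."""
        return pd.concat(
            [self.trajectory(i).to_frame(organism_id=i) for i in range(self.n)],
            ignore_index=True,
        )


def _advance(policy: Policy, cue_kinds: np.ndarray, tie_u: np.ndarray) -> dict:
    """Step ``n`` organisms through all ``T`` periods of a policy.

    ``cue_kinds`` and ``tie_u`` are ``(n, T)``: the cue received each
    period and the uniform draw used to break ties among optimal actions.
    """
    n, T = cue_kinds.shape
    if T != policy.T:
        raise ValueError(f"cue array covers {T} periods but the policy has T={policy.T}")
    levels = policy.levels
    b = np.zeros(n, dtype=np.int64)
    y0 = np.zeros(n, dtype=np.int64)
    y1 = np.zeros(n, dtype=np.int64)
    p1_out = np.empty((n, T))
    act_out = np.empty((n, T), dtype=np.int8)
    y0_out = np.empty((n, T), dtype=np.int16)
    y1_out = np.empty((n, T), dtype=np.int16)
    for t in range(1, T + 1):
        b = levels.child[t - 1][b, cue_kinds[:, t - 1]]
        p1_out[:, t - 1] = levels.p1[t][b]
        j = policy.pheno.index(t - 1, y0, y1)
        mask = policy.action_masks[t][b, j]
        k = _POPCOUNT[mask]
        pick = np.minimum((tie_u[:, t - 1] * k).astype(np.int64), k - 1)
        a = _MASK_BITS[mask, pick]
        y0 = y0 + (a == 0)
        y1 = y1 + (a == 1)
        act_out[:, t - 1] = a
        y0_out[:, t - 1] = y0
        y1_out[:, t - 1] = y1
    periods = np.arange(1, T + 1, dtype=np.int16)
    yw_out = periods[None, :] - y0_out - y1_out
    mapping = policy.mapping
    fR = mapping.reward_function(T)
    fP = mapping.penalty_function(T)
    pT = p1_out[:, -1]
    fitness = (
        mapping.baseline
        + (1.0 - pT) * fR(y0) + pT * fR(y1)
        - ((1.0 - pT) * fP(y1) + pT * fP(y0))
    )
    return {
        "cues": cue_kinds.astype(np.int8),
        "p1": p1_out,
        "actions": act_out,
        "y0": y0_out,
        "y1": y1_out,
        "yw": yw_out,
        "fitness": fitness,
    }


def simulate_organism(
    policy: Policy, cues: Sequence[Cue], rng: np.random.Generator
) -> Trajectory:
    """Develop a single organism on a fixed cue sequence.

    Each period the belief is updated with the period's cue, an action is
    drawn uniformly from the policy's optimal set, and the matching
    counter is incremented; terminal fitness is evaluated at ``T``.
    """
    T = policy.T
    periods = sorted(c.period for c in cues)
    if periods != list(range(1, T + 1)):
        raise ValueError(
            f"cues must cover periods 1..{T} exactly once, got periods {periods}"
        )
    kinds = np.zeros((1, T), dtype=np.int64)
    for c in cues:
        kinds[0, c.period - 1] = int(c.kind)
    res = _advance(policy, kinds, rng.random(T)[None, :])
    return Trajectory(
        environment=None,
        cues=res["cues"][0],
        p1=res["p1"][0],
        actions=res["actions"][0],
        y0=res["y0"][0],
        y1=res["y1"][0],
        yw=res["yw"][0],
        fitness=float(res["fitness"][0]),
    )


def _organism_uniforms(seed, n: int, T: int) -> np.ndarray:
    """Per-organism uniform draws, shape ``(n, 3, T)``: row 0 cues, row 1
    tie-breaks, row 2 auxiliary (environment draw uses ``[2, 0]``)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = np.empty((n, 3, T))
    for i, child in enumerate(ss.spawn(n)):
        out[i] = np.random.Generator(np.random.PCG64(child)).random((3, T))
    return out


def simulate_population(
    policy: Policy,
    environment: EnvironmentState | None,
    n: int,
    seed,
) -> Population:
    """Simulate ``n`` independent organisms under a fixed environmental
    state (or, when ``environment`` is None, states drawn per organism
    from the policy's prior).  Deterministic given ``(seed, n)`` and the
    policy parameters."""
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    T = policy.T
    u = _organism_uniforms(seed, n, T)
    if environment is None:
        envs = (u[:, 2, 0] < policy.prior).astype(np.int8)
    else:
        envs = np.full(n, int(EnvironmentState(environment)), dtype=np.int8)
    r = policy.schedule.array
    cue1_prob = np.where(envs[:, None] == 1, r[None, :], 1.0 - r[None, :])
    kinds = (u[:, 0, :] < cue1_prob).astype(np.int64)
    res = _advance(policy, kinds, u[:, 1, :])
    return Population(policy=policy, environments=envs, **res)
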