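"""Domain primitives for incremental development under environmental uncertainty.

Organisms live for ``T`` discrete periods in a patch whose hidden state is
``E0`` or ``E1`` and never changes within a lifetime.  Each period they
receive a binary cue (``C0`` or ``C1``) whose reliability ``r_t`` may change
across ontogeny, update a Bayesian belief about the patch state, and then
irreversibly allocate the period to one of two phenotypic specializations
(counters ``y0`` and ``y1``) or to waiting (``yw``).  Fitness is paid once,
at maturity, from the match between the accumulated phenotype and the
posterior-weighted environmental state.

This module holds the model's vocabulary: environments, cues, reliability
schedules, exact log-odds beliefs, developmental states, and the
phenotype-to-fitness mapping.  The dynamic-programming solver builds on
these in :mod:`ontosense.solver`.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "ACTIONS",
    "PATTERNS",
    "SHAPES",
    "PROB_ATOL",
    "MERGE_DECIMALS",
    "EnvironmentState",
    "CueKind",
    "Cue",
    "CueReliabilitySchedule",
    "Belief",
    "DevelopmentalState",
    "FitnessMapping",
    "build_schedule",
    "posterior_update",
    "posterior_from_sequence",
    "marginal_fitness_function",
    "terminal_fitness",
]

#: Absolute tolerance used for probability comparisons throughout.
PROB_ATOL = 1e-12
#: Decimal places at which log-odds are rounded before merging equal beliefs.
MERGE_DECIMALS = 12

PATTERNS = ("increasing", "decreasing", "triangular", "constant")
SHAPES = ("linear", "diminishing", "accelerating")
_SHAPE_EXPONENT = {"linear": 1.0, "diminishing": 0.5, "accelerating": 2.0}

#: Developmental actions, in canonical order.  ``specialize0`` increments
#: ``y0``, ``specialize1`` increments ``y1``, ``wait`` increments ``yw``.
ACTIONS = ("specialize0", "specialize1", "wait")


class EnvironmentState(enum.IntEnum):
    """Hidden state of a patch.  Exactly two states exist and a patch's
    state never changes within one ontogeny."""

    E0 = 0
    E1 = 1


class CueKind(enum.IntEnum):
    """Kind of a binary environmental cue.  ``C1`` points towards ``E1``."""

    C0 = 0
    C1 = 1


@dataclass(frozen=True)
class Cue:
    """A cue of a given kind received at a given ontogenetic period.

    The period matters because cue reliability is period-indexed.
    """

    kind: CueKind
    period: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", CueKind(self.kind))
        if self.period < 1:
            raise ValueError(f"cue period must be >= 1, got {self.period}")


@dataclass(frozen=True)
class CueReliabilitySchedule:
    """Per-period cue reliabilities ``r_1 .. r_T``.

    ``r_t`` is the probability that the period-``t`` cue matches the true
    environmental state; it is the same in both states, so the probability
    of a mismatching cue is ``1 - r_t``.  Reliabilities live in
    ``[0.5, 1)``: 0.5 is an uninformative cue, and 1.0 is excluded because
    a perfectly reliable cue creates zero-probability branches (and
    undefined updates when experimental treatments deliver contradicting
    cues).
    """

    T: int
    pattern: str
    r_min: float
    r_max: float
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != self.T:
            raise ValueError(
                f"schedule has {len(self.values)} values but T={self.T}"
            )
        for t, v in enumerate(self.values, start=1):
            if not 0.5 <= v < 1.0:
                raise ValueError(
                    f"reliability r_{t}={v} outside the allowed range [0.5, 1)"
                )

    def r(self, period: int) -> float:
        """Reliability of the cue received at ``period`` (1-based)."""
        if not 1 <= period <= self.T:
            raise ValueError(f"period {period} outside 1..{self.T}")
        return self.values[period - 1]

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def log_likelihood_ratios(self) -> np.ndarray:
        """``lambda_t = log(r_t / (1 - r_t))`` for each period."""
        r = self.array
        return np.log(r / (1.0 - r))

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "pattern": self.pattern,
            "r_min": self.r_min,
            "r_max": self.r_max,
            "values": list(self.values),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CueReliabilitySchedule":
        return cls(
            T=int(d["T"]),
            pattern=str(d["pattern"]),
            r_min=float(d["r_min"]),
            r_max=float(d["r_max"]),
            values=tuple(float(v) for v in d["values"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def build_schedule(
    pattern: str, r_min: float, r_max: float, T: int
) -> CueReliabilitySchedule:
    """Construct one of the standard cue-reliability patterns.

    ``increasing`` is a linear ramp from ``r_min`` to ``r_max``;
    ``decreasing`` is its exact reverse; ``triangular`` (even ``T`` only)
    ramps up over periods ``1..T/2`` and mirrors back down over
    ``T/2+1..T``, so the peak value is attained twice.  All three have the
    same arithmetic mean, ``(r_min + r_max) / 2``, for the same bounds --
    total information across ontogeny is controlled.  ``constant`` repeats
    ``r_min`` (a convenience for tests and degenerate scenarios).
    """
    if pattern not in PATTERNS:
        raise ValueError(
            f"unknown pattern {pattern!r}; expected one of {PATTERNS}"
        )
    if r_min < 0.5:
        raise ValueError(f"r_min={r_min} violates the lower bound 0.5")
    if r_max >= 1.0:
        raise ValueError(f"r_max={r_max} violates the upper bound r_max < 1")
    if r_min > r_max:
        raise ValueError(f"r_min={r_min} exceeds r_max={r_max}")
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")

    if pattern == "constant":
        values = np.full(T, r_min)
        return CueReliabilitySchedule(T, pattern, r_min, r_min, tuple(values))
    if pattern == "increasing":
        values = np.linspace(r_min, r_max, T)
    elif pattern == "decreasing":
        values = np.linspace(r_min, r_max, T)[::-1]
    else:  # triangular
        if T % 2 != 0:
            raise ValueError(
                f"triangular pattern requires an even T, got {T}"
            )
        half = np.linspace(r_min, r_max, T // 2)
        values = np.concatenate([half, half[::-1]])
    return CueReliabilitySchedule(T, pattern, r_min, r_max, tuple(values))


@dataclass(frozen=True)
class Belief:
    """Posterior probability of ``E1`` given the cues sampled so far.

    The belief carries an exact signed log-odds accumulator,
    ``logit(prior) + sum_i s_i * lambda_i`` with
    ``lambda_i = log(r_i / (1 - r_i))`` and ``s_i = +1`` for a ``C1`` cue
    at period ``i`` and ``-1`` for ``C0``, alongside the canonical cue
    history (one entry per period, sorted by period).  Because the
    log-odds is a plain sum, the posterior is invariant to the order in
    which the same (period, cue) pairs are applied.
    """

    p1: float
    log_odds: float
    history: tuple[tuple[int, CueKind], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.p1 < 1.0:
            raise ValueError(f"belief p1={self.p1} must lie strictly in (0, 1)")
        if abs(self.p1 - float(expit(self.log_odds))) > 1e-9:
            raise ValueError(
                "belief p1 is inconsistent with its log-odds accumulator"
            )
        periods = [p for p, _ in self.history]
        if len(set(periods)) != len(periods):
            raise ValueError("belief history contains a duplicate period")
        object.__setattr__(self, "history", tuple(sorted(self.history)))

    @classmethod
    def from_prior(cls, p1: float) -> "Belief":
        if not 0.0 < p1 < 1.0:
            raise ValueError(f"prior {p1} must lie strictly in (0, 1)")
        return cls(p1=float(p1), log_odds=float(logit(p1)), history=())

    @property
    def t(self) -> int:
        """Number of cues integrated so far."""
        return len(self.history)

    @property
    def history_key(self) -> tuple[tuple[int, int], ...]:
        """Canonical encoding of the cue sequence: one (period, kind) pair
        per period, sorted by period."""
        return tuple((p, int(k)) for p, k in self.history)

    @property
    def periods(self) -> frozenset[int]:
        return frozenset(p for p, _ in self.history)


def posterior_update(
    belief: Belief, cue: Cue, schedule: CueReliabilitySchedule
) -> Belief:
    """One Bayesian update with the period-specific cue reliability.

    The incoming belief serves as the prior for the step; the log-odds
    moves by ``+log(r_t/(1-r_t))`` for a ``C1`` cue and by the negative of
    that for ``C0``.  Each period delivers exactly one cue, so a duplicate
    period is rejected.
    """
    if not 1 <= cue.period <= schedule.T:
        raise ValueError(
            f"cue period {cue.period} outside the schedule's range 1..{schedule.T}"
        )
    if cue.period in belief.periods:
        raise ValueError(
            f"period {cue.period} already delivered a cue to this belief"
        )
    r = schedule.r(cue.period)
    lam = math.log(r / (1.0 - r))
    sign = 1.0 if cue.kind == CueKind.C1 else -1.0
    log_odds = belief.log_odds + sign * lam
    p1 = float(expit(log_odds))
    history = belief.history + ((cue.period, CueKind(cue.kind)),)
    return Belief(p1=p1, log_odds=log_odds, history=history)


def posterior_from_sequence(
    prior: float, cues: Iterable[Cue], schedule: CueReliabilitySchedule
) -> Belief:
    """Fold :func:`posterior_update` over a sequence of cues.

    Equivalent to the closed-form log-odds sum; the previous posterior is
    reused as the prior at every step.
    """
    belief = Belief.from_prior(prior)
    for cue in cues:
        belief = posterior_update(belief, cue, schedule)
    return belief


def marginal_fitness_function(
    shape: str, max_payoff: float, T: int
) -> Callable[[float | np.ndarray], float | np.ndarray]:
    """Map a specialization count ``y`` in ``0..T`` to fitness units.

    Implemented as the power family ``f(y) = max_payoff * (y/T)**gamma``
    with ``gamma = 1`` (linear: constant marginal effects), ``gamma = 0.5``
    (diminishing: strictly decreasing marginal effects) and ``gamma = 2``
    (accelerating: strictly increasing marginal effects).  All shapes share
    ``f(0) = 0`` and ``f(T) = max_payoff``, so the attainable payoff of a
    perfectly matched organism is identical across shapes.  The family is a
    documented, replaceable choice; any monotone map with these properties
    would slot in here.
    """
    if shape not in _SHAPE_EXPONENT:
        raise ValueError(f"unknown fitness shape {shape!r}; expected one of {SHAPES}")
    if max_payoff <= 0:
        raise ValueError(f"max_payoff must be positive, got {max_payoff}")
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    gamma = _SHAPE_EXPONENT[shape]

    def f(y):
        arr = np.asarray(y, dtype=float)
        out = max_payoff * (arr / T) ** gamma
        if arr.ndim == 0:
            return float(out)
        return out

    f.shape_name = shape  # type: ignore[attr-defined]
    return f


@dataclass(frozen=True)
class FitnessMapping:
    """Reward and penalty mappings from phenotype counters to fitness.

    ``reward_shape`` scales fitness gains from specializations matching the
    environment; ``penalty_shape`` scales losses from mismatching ones.
    The two shapes may differ.  ``baseline`` is the fitness of an organism
    that waited throughout ontogeny; when left unset it defaults to the
    worst-case penalty ``fP(T) = max_payoff`` so total fitness is never
    negative.  Optimal policies are invariant to this additive constant.
    """

    reward_shape: str = "linear"
    penalty_shape: str = "linear"
    max_payoff: float = 20.0
    baseline: float | None = None

    def __post_init__(self) -> None:
        for shape in (self.reward_shape, self.penalty_shape):
            if shape not in _SHAPE_EXPONENT:
                raise ValueError(
                    f"unknown fitness shape {shape!r}; expected one of {SHAPES}"
                )
        if self.max_payoff <= 0:
            raise ValueError(f"max_payoff must be positive, got {self.max_payoff}")
        if self.baseline is None:
            object.__setattr__(self, "baseline", float(self.max_payoff))

    @property
    def is_linear(self) -> bool:
        return self.reward_shape == "linear" and self.penalty_shape == "linear"

    def reward_function(self, T: int) -> Callable:
        return marginal_fitness_function(self.reward_shape, self.max_payoff, T)

    def penalty_function(self, T: int) -> Callable:
        return marginal_fitness_function(self.penalty_shape, self.max_payoff, T)

    def to_dict(self) -> dict:
        return {
            "reward_shape": self.reward_shape,
            "penalty_shape": self.penalty_shape,
            "max_payoff": self.max_payoff,
            "baseline": self.baseline,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitnessMapping":
        return cls(
            reward_shape=str(d["reward_shape"]),
            penalty_shape=str(d["penalty_shape"]),
            max_payoff=float(d["max_payoff"]),
            baseline=float(d["baseline"]) if d.get("baseline") is not None else None,
        )


def terminal_fitness(
    y0: int,
    y1: int,
    belief_T: Belief | float,
    mapping: FitnessMapping,
    T: int,
) -> float:
    """Total fitness at maturity.

    ``baseline + P(E0)*fR(y0) + P(E1)*fR(y1) - (P(E0)*fP(y1) + P(E1)*fP(y0))``
    where the probabilities are the end-of-ontogeny posterior and ``fR``,
    ``fP`` are the reward and penalty functions.  Accepts either a
    :class:`Belief` or a bare posterior probability of ``E1``.
    """
    if y0 < 0 or y1 < 0:
        raise ValueError("specialization counters must be non-negative")
    if y0 + y1 > T:
        raise ValueError(
            f"y0 + y1 = {y0 + y1} exceeds the number of periods T={T}"
        )
    p1 = belief_T.p1 if isinstance(belief_T, Belief) else float(belief_T)
    p0 = 1.0 - p1
    fR = mapping.reward_function(T)
    fP = mapping.penalty_function(T)
    reward = p0 * fR(y0) + p1 * fR(y1)
    penalty = p0 * fP(y1) + p1 * fP(y0)
    return float(mapping.baseline + reward - penalty)


@dataclass(frozen=True)
class DevelopmentalState:
    """The full organismal state ``(D_t, y0, y1, yw, t)``.

    ``belief`` summarizes the cue history ``D_t``; the counters record how
    each completed period was spent, so they always sum to ``t``.
    """

    t: int
    belief: Belief
    y0: int
    y1: int
    yw: int

    def __post_init__(self) -> None:
        if min(self.y0, self.y1, self.yw) < 0:
            raise ValueError("phenotype counters must be non-negative")
        if self.y0 + self.y1 + self.yw != self.t:
            raise ValueError(
                f"counters sum to {self.y0 + self.y1 + self.yw}, expected t={self.t}"
            )
        if self.belief.t != self.t:
            raise ValueError(
                f"belief integrates {self.belief.t} cues, expected t={self.t}"
            )
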