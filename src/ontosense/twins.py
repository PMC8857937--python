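"""Simulated twin experiments: adoption and cross-fostering paradigms.

Plasticity at a separation period ``s`` is quantified by cloning each
simulated organism at ``s``, manipulating the clone's cues from ``s``
onwards (while the focal stays in its natal patch), and measuring the
Euclidean distance between the twins' phenotypes ``(y0, y1)``.  Twins
share both the cue stream and the tie-break stream strictly before ``s``,
which guarantees identical phenotypes and posteriors at the moment of
separation; tie-break streams are independent between twins from ``s``
onwards.  Clones always apply the ordinary Bayesian update -- they do not
know their cues are manipulated.

Treatments
----------
``reciprocal_opposite``
    the clone receives the exact flip of every focal cue;
``opposite_patch``
    the clone's cues are drawn fresh from the opposite environmental
    state under the same schedule;
``deprivation``
    the clone's cues are uniform coin flips, preventing learning;
``dose``
    each focal cue is flipped independently with probability ``q``
    (``dose(1)`` recovers the reciprocal treatment, ``dose(0)`` is a null
    treatment).

Separation is permanent (through the end of ontogeny) or a temporary
window of ``w`` periods after which the clone resumes receiving the
focal's cues; posteriors are not reset on reunion.  Measurement happens at
the end of ontogeny or at the end of the separation window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CueReliabilitySchedule, EnvironmentState
from .simulate import Trajectory, _advance
from .solver import _MASK_BITS, _POPCOUNT, Policy

__all__ = [
    "TREATMENTS",
    "TwinStudyConfig",
    "TwinStudyResult",
    "phenotypic_distance",
    "absolute_plasticity",
    "proportional_plasticity",
    "posterior_distance",
    "run_twin_study",
    "plasticity_curve",
    "exact_reciprocal_expectation",
]

TREATMENTS = ("reciprocal_opposite", "opposite_patch", "deprivation", "dose")

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class TwinStudyConfig:
    """Parameters of one simulated twin study.

    ``duration`` is ``"permanent"``, an integer window length ``w`` (the
    clone's cues are manipulated for periods ``s .. s + w - 1``), or
    ``"temporary"`` for the default window of 5 periods.  ``dose_q`` is
    the per-period flip probability of the ``dose`` treatment and is
    ignored otherwise.
    """

    DEFAULT_WINDOW = 5

    separation_period: int
    treatment: str = "reciprocal_opposite"
    duration: str | int = "permanent"
    measurement: str = "end_of_ontogeny"
    n_pairs: int = 10_000
    seed: int | np.random.SeedSequence = 0
    dose_q: float | None = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        if self.measurement not in ("end_of_ontogeny", "end_of_separation"):
            raise ValueError(f"unknown measurement time {self.measurement!r}")
        if self.separation_period < 1:
            raise ValueError("separation period must be >= 1")
        if isinstance(self.duration, str):
            if self.duration not in ("permanent", "temporary"):
                raise ValueError(
                    "duration must be 'permanent', 'temporary' or an integer, "
                    f"got {self.duration!r}"
                )
        elif self.duration < 0:
            raise ValueError("temporary window length must be >= 0")
        if self.treatment == "dose":
            if self.dose_q is None or not 0.0 <= self.dose_q <= 1.0:
                raise ValueError("dose treatment requires dose_q in [0, 1]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")

    def window_end(self, T: int) -> int:
        """Last period of the manipulation window (inclusive)."""
        s = self.separation_period
        if self.duration == "permanent":
            return T
        w = self.DEFAULT_WINDOW if self.duration == "temporary" else int(self.duration)
        end = s + w - 1
        if end > T:
            raise ValueError(
                f"temporary window s={s}, w={self.duration} extends past T={T}"
            )
        return end

    def validate(self, T: int) -> None:
        if self.separation_period > T:
            raise ValueError(
                f"separation period {self.separation_period} exceeds T={T}"
            )
        self.window_end(T)


@dataclass(frozen=True)
class TwinStudyResult:
    """Plasticity measures from one separation period, with Monte-Carlo
    standard errors."""

    separation_period: int
    measurement_period: int
    n_pairs: int
    mean_distance: float
    absolute: float
    proportional: float
    posterior_distance: float
    se_distance: float
    se_absolute: float
    se_proportional: float
    se_posterior: float

    def to_dict(self) -> dict:
        return {
            "s": self.separation_period,
            "measurement_period": self.measurement_period,
            "absolute": self.absolute,
            "proportional": self.proportional,
            "posterior_distance": self.posterior_distance,
            "se_absolute": self.se_absolute,
            "se_proportional": self.se_proportional,
            "se_posterior": self.se_posterior,
            "n_pairs": self.n_pairs,
        }


def phenotypic_distance(a: Trajectory, b: Trajectory, at_period: int) -> float:
    """Euclidean distance between two trajectories' ``(y0, y1)`` at a period."""
    if a.T != b.T:
        raise ValueError(f"trajectories have different T: {a.T} vs {b.T}")
    x0, x1 = a.phenotype_at(at_period)
    z0, z1 = b.phenotype_at(at_period)
    return math.hypot(x0 - z0, x1 - z1)


def absolute_plasticity(distances: Sequence[float], T: int) -> float:
    """Mean twin distance scaled by the global maximum ``T * sqrt(2)``."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("cannot average an empty set of distances")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    return float(d.mean() / (T * SQRT2))


def proportional_plasticity(distances: Sequence[float], s: int, T: int) -> float:
    """Mean twin distance scaled by the maximum attainable from the
    separation period onward, ``sqrt(2) * (T - s + 1)``.

    Separation at period ``s`` means the clone's manipulated cues begin
    with the period-``s`` cue itself, so ``T - s + 1`` periods can diverge;
    at ``s = 1`` the normalizer coincides with the absolute one.
    """
    if not 1 <= s <= T:
        raise ValueError(f"separation period {s} outside 1..{T}")
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("cannot average an empty set of distances")
    return float(d.mean() / (SQRT2 * (T - s + 1)))


def posterior_distance(pairs, at_period: int) -> float:
    """Mean absolute difference in posteriors ``|p1_focal - p1_clone|``
    across twin pairs at a period."""
    diffs = [
        abs(float(f.p1[at_period - 1]) - float(c.p1[at_period - 1]))
        for f, c in pairs
    ]
    if not diffs:
        raise ValueError("no twin pairs supplied")
    return float(np.mean(diffs))


def _clone_cues(
    focal_kinds: np.ndarray,
    clone_u: np.ndarray,
    config: TwinStudyConfig,
    environment: EnvironmentState,
    schedule: CueReliabilitySchedule,
    window: tuple[int, int],
) -> np.ndarray:
    """Clone cue kinds: the focal's outside the window, the treatment inside."""
    kinds = focal_kinds.copy()
    s, e = window
    cols = slice(s - 1, e)
    if config.treatment == "reciprocal_opposite":
        kinds[:, cols] = 1 - focal_kinds[:, cols]
    elif config.treatment == "opposite_patch":
        opp = 1 - int(EnvironmentState(environment))
        r = schedule.array[cols]
        p_c1 = np.where(opp == 1, r, 1.0 - r)
        kinds[:, cols] = (clone_u[:, cols] < p_c1[None, :]).astype(np.int64)
    elif config.treatment == "deprivation":
        kinds[:, cols] = (clone_u[:, cols] < 0.5).astype(np.int64)
    else:  # dose
        flip = clone_u[:, cols] < config.dose_q
        kinds[:, cols] = np.where(flip, 1 - focal_kinds[:, cols], focal_kinds[:, cols])
    return kinds


def run_twin_study(
    policy: Policy,
    environment: EnvironmentState,
    config: TwinStudyConfig,
) -> TwinStudyResult:
    """Run one simulated twin study at the configured separation period.

    Pairs share cue and tie-break streams strictly before ``s``; from
    ``s`` through the end of the treatment window the clone's cues follow
    the treatment, after which (temporary separation) it resumes the
    focal's cues.  Measures are averaged over ``n_pairs`` at the
    configured measurement time.
    """
    T = policy.T
    config.validate(T)
    environment = EnvironmentState(environment)
    s = config.separation_period
    e = config.window_end(T)

    ss = (
        config.seed
        if isinstance(config.seed, np.random.SeedSequence)
        else np.random.SeedSequence(config.seed)
    )
    n = config.n_pairs
    u = np.empty((n, 4, T))
    for i, child in enumerate(ss.spawn(n)):
        u[i] = np.random.Generator(np.random.PCG64(child)).random((4, T))
    focal_cue_u, focal_tie_u, clone_cue_u, clone_tie_u = (
        u[:, 0, :], u[:, 1, :], u[:, 2, :], u[:, 3, :],
    )

    r = policy.schedule.array
    p_c1 = r if environment == EnvironmentState.E1 else 1.0 - r
    focal_kinds = (focal_cue_u < p_c1[None, :]).astype(np.int64)
    clone_kinds = _clone_cues(
        focal_kinds, clone_cue_u, config, environment, policy.schedule, (s, e)
    )
    # shared tie-break stream strictly before the separation period
    clone_ties = clone_tie_u.copy()
    clone_ties[:, : s - 1] = focal_tie_u[:, : s - 1]

    focal = _advance(policy, focal_kinds, focal_tie_u)
    clone = _advance(policy, clone_kinds, clone_ties)

    m = T if config.measurement == "end_of_ontogeny" else e
    col = m - 1
    d0 = focal["y0"][:, col].astype(float) - clone["y0"][:, col].astype(float)
    d1 = focal["y1"][:, col].astype(float) - clone["y1"][:, col].astype(float)
    distances = np.hypot(d0, d1)
    post = np.abs(focal["p1"][:, col] - clone["p1"][:, col])

    se = distances.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
    se_post = post.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
    abs_norm = T * SQRT2
    prop_norm = SQRT2 * (m - s + 1)
    return TwinStudyResult(
        separation_period=s,
        measurement_period=m,
        n_pairs=n,
        mean_distance=float(distances.mean()),
        absolute=float(distances.mean() / abs_norm),
        proportional=float(distances.mean() / prop_norm),
        posterior_distance=float(post.mean()),
        se_distance=float(se),
        se_absolute=float(se / abs_norm),
        se_proportional=float(se / prop_norm),
        se_posterior=float(se_post),
    )


def plasticity_curve(
    policy: Policy,
    environment: EnvironmentState,
    base_config: TwinStudyConfig,
) -> list[TwinStudyResult]:
    """One twin study per separation period ``s = 1..T``, with independent
    seeds derived from the master seed."""
    T = policy.T
    master = (
        base_config.seed
        if isinstance(base_config.seed, np.random.SeedSequence)
        else np.random.SeedSequence(base_config.seed)
    )
    results = []
    for s, child in zip(range(1, T + 1), master.spawn(T)):
        cfg = replace(base_config, separation_period=s, seed=child)
        results.append(run_twin_study(policy, environment, cfg))
    return results


def curve_frame(results: Sequence[TwinStudyResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def exact_reciprocal_expectation(
    policy: Policy,
    environment: EnvironmentState,
    s: int,
) -> tuple[float, float]:
    """Exact expected twin distance and posterior distance by full
    enumeration (permanent reciprocal treatment, measured at maturity).

    Enumerates every focal cue sequence with its probability under the
    true environment and every tie-break branch of both twins (shared
    before ``s``, independent after), aggregating joint states at each
    period.  Feasible at small ``T``; the Monte-Carlo study converges to
    these values.
    """
    T = policy.T
    if not 1 <= s <= T:
        raise ValueError(f"separation period {s} outside 1..{T}")
    environment = EnvironmentState(environment)
    levels = policy.levels
    r_arr = policy.schedule.array

    deltas = ((1, 0), (0, 1), (0, 0))

    # Phase 1 (t < s): twins are identical; track single states.
    states: dict[tuple, float] = {(0, 0, 0): 1.0}
    for t in range(1, s):
        p_c1 = r_arr[t - 1] if environment == EnvironmentState.E1 else 1.0 - r_arr[t - 1]
        nxt: dict[tuple, float] = {}
        for (b, y0, y1), p in states.items():
            for cue, pc in ((0, 1.0 - p_c1), (1, p_c1)):
                if pc == 0.0:
                    continue
                b2 = int(levels.child[t - 1][b, cue])
                j = int(policy.pheno.index(t - 1, y0, y1))
                mask = int(policy.action_masks[t][b2, j])
                k = _POPCOUNT[mask]
                for a in range(3):
                    if not mask >> a & 1:
                        continue
                    d0, d1 = deltas[a]
                    key = (b2, y0 + d0, y1 + d1)
                    nxt[key] = nxt.get(key, 0.0) + p * pc / k
        states = nxt

    # Phase 2 (t >= s): joint states (focal, clone); clone cues flipped,
    # tie-breaks independent.
    joint: dict[tuple, float] = {
        (b, y0, y1, b, y0, y1): p for (b, y0, y1), p in states.items()
    }
    for t in range(s, T + 1):
        p_c1 = r_arr[t - 1] if environment == EnvironmentState.E1 else 1.0 - r_arr[t - 1]
        nxt = {}
        for (bf, f0, f1, bc, c0, c1), p in joint.items():
            for cue, pc in ((0, 1.0 - p_c1), (1, p_c1)):
                if pc == 0.0:
                    continue
                bf2 = int(levels.child[t - 1][bf, cue])
                bc2 = int(levels.child[t - 1][bc, 1 - cue])
                jf = int(policy.pheno.index(t - 1, f0, f1))
                jc = int(policy.pheno.index(t - 1, c0, c1))
                mf = int(policy.action_masks[t][bf2, jf])
                mc = int(policy.action_masks[t][bc2, jc])
                kf, kc = _POPCOUNT[mf], _POPCOUNT[mc]
                w = p * pc / (kf * kc)
                for af in range(3):
                    if not mf >> af & 1:
                        continue
                    for ac in range(3):
                        if not mc >> ac & 1:
                            continue
                        key = (
                            bf2, f0 + deltas[af][0], f1 + deltas[af][1],
                            bc2, c0 + deltas[ac][0], c1 + deltas[ac][1],
                        )
                        nxt[key] = nxt.get(key, 0.0) + w
        joint = nxt

    exp_dist = 0.0
    exp_post = 0.0
    for (bf, f0, f1, bc, c0, c1), p in joint.items():
        exp_dist += p * math.hypot(f0 - c0, f1 - c1)
        exp_post += p * abs(float(levels.p1[T][bf]) - float(levels.p1[T][bc]))
    return exp_dist, exp_post
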