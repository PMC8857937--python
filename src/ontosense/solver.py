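"""Exact stochastic dynamic programming over the developmental state space.

The solver computes, by backward induction, the policy that maximizes
expected terminal fitness.  Within each period the event order is
cue-then-decision: the organism receives the period's cue, updates its
belief, and then chooses among incrementing ``y0``, incrementing ``y1``,
or waiting.  The value of a completed state is therefore the expectation,
over the next cue drawn from the belief's prior-predictive distribution
``P(C1 next) = b * r + (1 - b) * (1 - r)``, of the best post-cue action
value.

Two exact state-space reductions keep the computation tractable:

* beliefs with numerically equal posteriors are merged (log-odds rounded
  at 12 decimals), collapsing the ``2^t`` cue-history tree wherever the
  schedule produces coinciding likelihood-ratio sums;
* when both fitness shapes are linear, terminal fitness depends on the
  phenotype only through ``d = y0 - y1``, so the phenotype component of
  the state key collapses to that difference.  The collapse is an
  automatic optimization with outputs identical to the general path.

States are keyed by ``(t, log_odds, y0, y1)`` where ``t`` in ``1..T`` is
the period whose decision is being made: the belief has integrated ``t``
cues and the counters cover the ``t - 1`` completed decisions (``yw`` is
derived, never stored).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import (
    ACTIONS,
    MERGE_DECIMALS,
    CueReliabilitySchedule,
    FitnessMapping,
)

__all__ = [
    "Policy",
    "StateProbabilityTable",
    "solve_policy",
    "action_distribution",
    "state_probabilities",
    "expected_policy_value",
]

logger = logging.getLogger("ontosense.solver")

#: Relative tie tolerance: actions tie when their values agree to within
#: ``TIE_RTOL * max(1, |best|)``.  Exact ties (uninformative cues,
#: symmetric states) must be detected despite floating-point noise, and the
#: tie rule changes simulated trajectories, so it is explicit.
TIE_RTOL = 1e-12

#: Refuse to solve when the total number of decision states exceeds this.
DEFAULT_STATE_CAP = 500_000_000

_CHUNK_ELEMENTS = 30_000_000

_POPCOUNT = np.array([bin(m).count("1") for m in range(8)], dtype=np.int64)
# _MASK_BITS[m, k] is the k-th set bit of mask m (-1 padding).
_MASK_BITS = np.full((8, 3), -1, dtype=np.int64)
for _m in range(8):
    for _k, _b in enumerate([b for b in range(3) if _m >> b & 1]):
        _MASK_BITS[_m, _k] = _b


@dataclass
class BeliefLevels:
    """Merged belief nodes per period, as a layered DAG.

    ``log_odds[t]`` are the distinct (rounded) log-odds reachable after
    ``t`` cues, sorted ascending; ``child[t]`` maps a level-``t`` node and
    a cue kind (column 0 = C0, column 1 = C1) to its level-``t+1`` node.
    """

    log_odds: list[np.ndarray]
    p1: list[np.ndarray]
    child: list[np.ndarray]

    @property
    def sizes(self) -> list[int]:
        return [arr.size for arr in self.log_odds]

    def index(self, t: int, log_odds: float) -> int:
        """Locate the node for a given log-odds at level ``t``."""
        arr = self.log_odds[t]
        key = np.round(log_odds, MERGE_DECIMALS)
        i = int(np.searchsorted(arr, key))
        for j in (i - 1, i, i + 1):
            if 0 <= j < arr.size and abs(arr[j] - key) <= 1e-9:
                return j
        raise KeyError(
            f"no belief with log-odds {log_odds} at period {t}"
        )


def build_belief_levels(
    prior: float, schedule: CueReliabilitySchedule
) -> BeliefLevels:
    lo0 = np.array([np.round(float(logit(prior)), MERGE_DECIMALS)])
    log_odds = [lo0]
    child = []
    lam = schedule.log_likelihood_ratios()
    for t in range(1, schedule.T + 1):
        parent = log_odds[t - 1]
        n = parent.size
        cand = np.concatenate([parent - lam[t - 1], parent + lam[t - 1]])
        uniq, inv = np.unique(np.round(cand, MERGE_DECIMALS), return_inverse=True)
        child.append(np.stack([inv[:n], inv[n:]], axis=1))
        log_odds.append(uniq)
    p1 = [expit(lo) for lo in log_odds]
    return BeliefLevels(log_odds=log_odds, p1=p1, child=child)


class DiffIndexer:
    """Phenotype keyed by ``d = y0 - y1`` (linear-payoff collapse)."""

    collapsed = True

    def __init__(self, T: int):
        self.T = T

    def size(self, t: int) -> int:
        return 2 * t + 1

    def index(self, t, y0, y1):
        return np.asarray(y0) - np.asarray(y1) + t

    def pairs(self, t: int):
        d = np.arange(-t, t + 1)
        # Representative (y0, y1) with yw = 0 wherever possible; only used
        # for terminal evaluation, which depends on d alone.
        y0 = np.where(d >= 0, d, 0)
        y1 = np.where(d < 0, -d, 0)
        return y0, y1

    def action_targets(self, t: int) -> np.ndarray:
        """Map a pre-decision index at ``t-1`` to post-action indices at
        ``t`` for (specialize0, specialize1, wait)."""
        j = np.arange(self.size(t - 1))
        return np.stack([j + 2, j, j + 1], axis=1)


class PairIndexer:
    """Phenotype keyed by the full ``(y0, y1)`` pair (general payoffs)."""

    collapsed = False

    def __init__(self, T: int):
        self.T = T
        self._pairs: list[np.ndarray] = []
        self._table: list[np.ndarray] = []
        for t in range(T + 1):
            pairs = [(a, b) for a in range(t + 1) for b in range(t + 1 - a)]
            table = np.full((t + 2, t + 2), -1, dtype=np.int64)
            for i, (a, b) in enumerate(pairs):
                table[a, b] = i
            self._pairs.append(np.array(pairs, dtype=np.int64))
            self._table.append(table)

    def size(self, t: int) -> int:
        return len(self._pairs[t])

    def index(self, t, y0, y1):
        return self._table[t][np.asarray(y0), np.asarray(y1)]

    def pairs(self, t: int):
        p = self._pairs[t]
        return p[:, 0], p[:, 1]

    def action_targets(self, t: int) -> np.ndarray:
        y0, y1 = self.pairs(t - 1)
        tab = self._table[t]
        return np.stack([tab[y0 + 1, y1], tab[y0, y1 + 1], tab[y0, y1]], axis=1)


def _terminal_values(
    p1_T: np.ndarray, pheno, mapping: FitnessMapping, T: int
) -> np.ndarray:
    if pheno.collapsed:
        slope = mapping.max_payoff / T
        d = np.arange(-T, T + 1, dtype=float)
        return mapping.baseline + slope * np.outer(1.0 - 2.0 * p1_T, d)
    fR = mapping.reward_function(T)
    fP = mapping.penalty_function(T)
    y0, y1 = pheno.pairs(T)
    p1 = p1_T[:, None]
    p0 = 1.0 - p1
    return (
        mapping.baseline
        + p0 * fR(y0)[None, :]
        + p1 * fR(y1)[None, :]
        - p0 * fP(y1)[None, :]
        - p1 * fP(y0)[None, :]
    )


def _decide_numpy(U: np.ndarray, targets: np.ndarray, tie_rtol: float):
    n = U.shape[0]
    m = targets.shape[0]
    D = np.empty((n, m))
    mask = np.empty((n, m), dtype=np.uint8)
    rows = max(1, _CHUNK_ELEMENTS // (3 * m))
    for start in range(0, n, rows):
        sl = slice(start, min(start + rows, n))
        cand = U[sl][:, targets]  # (rows, m, 3)
        best = cand.max(axis=2)
        thr = best - tie_rtol * np.maximum(1.0, np.abs(best))
        tied = cand >= thr[:, :, None]
        mask[sl] = (
            tied[:, :, 0].astype(np.uint8)
            | (tied[:, :, 1].astype(np.uint8) << 1)
            | (tied[:, :, 2].astype(np.uint8) << 2)
        )
        D[sl] = best
    return D, mask


try:  # compiled kernel for the hot inner loop; numpy path is the reference
    import numba as _numba

    @_numba.njit(cache=False)
    def _decide_kernel(U, targets, tie_rtol):  # pragma: no cover - jit
        n = U.shape[0]
        m = targets.shape[0]
        D = np.empty((n, m))
        mask = np.empty((n, m), dtype=np.uint8)
        for i in range(n):
            for j in range(m):
                v0 = U[i, targets[j, 0]]
                v1 = U[i, targets[j, 1]]
                vw = U[i, targets[j, 2]]
                best = v0
                if v1 > best:
                    best = v1
                if vw > best:
                    best = vw
                scale = abs(best)
                if scale < 1.0:
                    scale = 1.0
                thr = best - tie_rtol * scale
                mk = 0
                if v0 >= thr:
                    mk |= 1
                if v1 >= thr:
                    mk |= 2
                if vw >= thr:
                    mk |= 4
                D[i, j] = best
                mask[i, j] = mk
        return D, mask

    def _decide(U, targets, tie_rtol):
        return _decide_kernel(U, np.ascontiguousarray(targets), tie_rtol)

except ImportError:  # pragma: no cover
    _decide = _decide_numpy


@dataclass
class Policy:
    """An optimal developmental policy.

    ``action_masks[t]`` (``t = 1..T``) is a ``(n_beliefs_t, n_phenotypes_{t-1})``
    array of 3-bit masks naming every fitness-maximizing action at the
    period-``t`` decision (bit 0 = specialize0, bit 1 = specialize1,
    bit 2 = wait); ``q_values[t]`` holds the corresponding state values.
    ``root_value`` is the expected fitness before the first cue.
    """

    prior: float
    schedule: CueReliabilitySchedule
    mapping: FitnessMapping
    levels: BeliefLevels
    pheno: DiffIndexer | PairIndexer
    action_masks: list
    root_value: float
    q_values: list | None = None
    tie_rtol: float = TIE_RTOL

    @property
    def T(self) -> int:
        return self.schedule.T

    @property
    def state_count(self) -> int:
        return sum(
            self.levels.sizes[t] * self.pheno.size(t - 1)
            for t in range(1, self.T + 1)
        )

    def state_counts_per_period(self) -> list[int]:
        return [
            self.levels.sizes[t] * self.pheno.size(t - 1)
            for t in range(1, self.T + 1)
        ]

    # -- state lookup ------------------------------------------------------

    def _locate(self, t: int, log_odds, y0: int, y1: int):
        if not 1 <= t <= self.T:
            raise KeyError(f"period {t} outside 1..{self.T}")
        lo = getattr(log_odds, "log_odds", log_odds)
        b = self.levels.index(t, float(lo))
        if y0 < 0 or y1 < 0 or y0 + y1 > t - 1:
            raise KeyError(
                f"phenotype ({y0}, {y1}) unreachable before the period-{t} decision"
            )
        j = int(self.pheno.index(t - 1, y0, y1))
        return b, j

    def optimal_actions(self, t: int, log_odds, y0: int, y1: int) -> tuple[str, ...]:
        b, j = self._locate(t, log_odds, y0, y1)
        mask = int(self.action_masks[t][b, j])
        return tuple(a for i, a in enumerate(ACTIONS) if mask >> i & 1)

    def value(self, t: int, log_odds, y0: int, y1: int) -> float:
        if self.q_values is None:
            raise ValueError("policy was solved with store_values=False")
        b, j = self._locate(t, log_odds, y0, y1)
        return float(self.q_values[t][b, j])

    def action_distribution(self, t: int, log_odds, y0: int, y1: int) -> dict[str, float]:
        """Uniform distribution over the optimal actions, zero elsewhere."""
        acts = self.optimal_actions(t, log_odds, y0, y1)
        p = 1.0 / len(acts)
        return {a: (p if a in acts else 0.0) for a in ACTIONS}

    # -- value surfaces ----------------------------------------------------

    def terminal_values(self) -> np.ndarray:
        """Terminal fitness over (belief node, phenotype index) at ``T``."""
        return _terminal_values(
            self.levels.p1[self.T], self.pheno, self.mapping, self.T
        )

    def post_decision_values(self, t: int) -> np.ndarray:
        """Expected future fitness of completed states at ``t`` (after the
        period-``t`` decision): the expectation over the next cue of the
        best child value, or terminal fitness at ``t = T``."""
        if t == self.T:
            return self.terminal_values()
        if self.q_values is None:
            raise ValueError("policy was solved with store_values=False")
        D = self.q_values[t + 1]
        r = self.schedule.r(t + 1)
        p1 = self.levels.p1[t]
        pc1 = p1 * r + (1.0 - p1) * (1.0 - r)
        ch = self.levels.child[t]
        return pc1[:, None] * D[ch[:, 1]] + (1.0 - pc1)[:, None] * D[ch[:, 0]]

    # -- serialization -----------------------------------------------------

    def header(self) -> dict:
        from . import __version__

        return {
            "format": "ontosense-policy",
            "version": __version__,
            "prior_p1": self.prior,
            "T": self.T,
            "schedule": self.schedule.to_dict(),
            "mapping": self.mapping.to_dict(),
        }

    def to_json(self, path=None, entry_cap: int = 50_000):
        """Serialize to a JSON document: the parameter header, the root
        value, per-period state counts, and (when the policy is small
        enough) one record per state with stable key ordering."""
        doc = dict(self.header())
        doc["root_value"] = self.root_value
        doc["state_counts"] = self.state_counts_per_period()
        n_entries = sum(
            self.levels.sizes[t] * (t * (t + 1)) // 2 for t in range(1, self.T + 1)
        )
        if self.q_values is not None and n_entries <= entry_cap:
            entries = []
            for t in range(1, self.T + 1):
                lo = self.levels.log_odds[t]
                for b in range(lo.size):
                    for y0 in range(t):
                        for y1 in range(t - y0):
                            entries.append(
                                {
                                    "t": t,
                                    "log_odds": float(lo[b]),
                                    "y0": y0,
                                    "y1": y1,
                                    "value": self.value(t, lo[b], y0, y1),
                                    "optimal_actions": list(
                                        self.optimal_actions(t, lo[b], y0, y1)
                                    ),
                                }
                            )
            doc["entries"] = entries
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def solve_policy(
    prior: float,
    schedule: CueReliabilitySchedule,
    mapping: FitnessMapping,
    *,
    collapse: bool | str = "auto",
    store_values: bool = True,
    state_cap: int = DEFAULT_STATE_CAP,
    tie_rtol: float = TIE_RTOL,
) -> Policy:
    """Backward induction over all reachable states.

    Parameters
    ----------
    prior
        Probability of ``E1`` before any cue; strictly inside (0, 1).
    collapse
        ``"auto"`` applies the linear-payoff phenotype collapse whenever
        both fitness shapes are linear; ``False`` forces the general
        ``(y0, y1)`` representation (used to cross-check the collapse).
    store_values
        Keep the per-state value arrays (needed for value lookups and
        Bellman checks).  Disable to halve memory on large runs; action
        masks are always kept.
    state_cap
        Refuse state spaces larger than this; lower ``T`` or rely on
        belief merging for big problems.
    """
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior {prior} must lie strictly in (0, 1)")
    if collapse not in (True, False, "auto"):
        raise ValueError("collapse must be True, False or 'auto'")
    T = schedule.T
    t0 = time.perf_counter()
    levels = build_belief_levels(prior, schedule)
    use_collapse = mapping.is_linear if collapse == "auto" else collapse
    if use_collapse and not mapping.is_linear:
        raise ValueError("phenotype collapse requires linear reward and penalty")
    pheno = DiffIndexer(T) if use_collapse else PairIndexer(T)

    n_states = sum(levels.sizes[t] * pheno.size(t - 1) for t in range(1, T + 1))
    if n_states > state_cap:
        raise ValueError(
            f"state space has {n_states} states, exceeding the cap {state_cap}; "
            "lower T or rely on belief merging (e.g. constant or triangular "
            "schedules) to make the problem tractable"
        )

    U = _terminal_values(levels.p1[T], pheno, mapping, T)
    masks: list = [None] * (T + 1)
    q: list | None = [None] * (T + 1) if store_values else None
    r_arr = schedule.array
    for t in range(T, 0, -1):
        D, mask = _decide(U, pheno.action_targets(t), tie_rtol)
        masks[t] = mask
        if q is not None:
            q[t] = D
        p1 = levels.p1[t - 1]
        pc1 = p1 * r_arr[t - 1] + (1.0 - p1) * (1.0 - r_arr[t - 1])
        ch = levels.child[t - 1]
        U = pc1[:, None] * D[ch[:, 1]] + (1.0 - pc1)[:, None] * D[ch[:, 0]]
    root_value = float(U[0, 0])

    elapsed = time.perf_counter() - t0
    merged = sum(levels.sizes[1:])
    full_tree = sum(2**t for t in range(1, T + 1))
    logger.info(
        "solved policy: T=%d, %d states (%d belief nodes, merge ratio %.3g), "
        "collapse=%s, %.2fs",
        T, n_states, merged, merged / full_tree, use_collapse, elapsed,
    )
    return Policy(
        prior=float(prior),
        schedule=schedule,
        mapping=mapping,
        levels=levels,
        pheno=pheno,
        action_masks=masks,
        root_value=root_value,
        q_values=q,
        tie_rtol=tie_rtol,
    )


def expected_policy_value(policy: Policy) -> float:
    """Expected terminal fitness at the root (prior belief, no decisions)."""
    return policy.root_value


def action_distribution(policy: Policy, state_key) -> dict[str, float]:
    """Uniform probabilities over the optimal actions of a state.

    ``state_key`` is ``(t, log_odds, y0, y1)``; a :class:`~ontosense.core.Belief`
    may stand in for the log-odds.
    """
    t, log_odds, y0, y1 = state_key
    return policy.action_distribution(t, log_odds, y0, y1)


@dataclass
class StateProbabilityTable:
    """Probability of occupying each completed state under the policy.

    One table per period ``t = 0..T``; within each period the
    probabilities sum to one.  States below ``threshold`` are flagged, not
    deleted, mirroring the usual ">0.5 %" display convention.
    """

    threshold: float
    frame: pd.DataFrame  # columns: period, p1, y0, y1, probability, above_threshold

    def period_sums(self) -> pd.Series:
        return self.frame.groupby("period")["probability"].sum()

    def period(self, t: int) -> pd.DataFrame:
        return self.frame[self.frame["period"] == t].reset_index(drop=True)

    def to_csv(self, path, config_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if config_comment:
                fh.write(f"# {config_comment}\n")
            self.frame.to_csv(fh, index=False)


def state_probabilities(
    policy: Policy, display_threshold: float = 0.005
) -> StateProbabilityTable:
    """Forward pass from the root under the solved policy.

    Mass splits by the prior-predictive cue probabilities and uniformly
    across tied actions.  Phenotypes are tracked as full ``(y0, y1)``
    pairs even when the policy was solved with the linear collapse, so the
    table is directly comparable across solver representations.
    """
    levels = policy.levels
    T = policy.T
    b = np.zeros(1, dtype=np.int64)
    y0 = np.zeros(1, dtype=np.int64)
    y1 = np.zeros(1, dtype=np.int64)
    prob = np.ones(1)
    records = []

    def record(t, b, y0, y1, prob):
        records.append(
            pd.DataFrame(
                {
                    "period": t,
                    "p1": levels.p1[t][b],
                    "y0": y0,
                    "y1": y1,
                    "probability": prob,
                }
            )
        )

    record(0, b, y0, y1, prob)
    r_arr = policy.schedule.array
    for t in range(1, T + 1):
        p1 = levels.p1[t - 1][b]
        pc1 = p1 * r_arr[t - 1] + (1.0 - p1) * (1.0 - r_arr[t - 1])
        ch = levels.child[t - 1]
        # cue branching
        bb = np.concatenate([ch[b, 0], ch[b, 1]])
        pp = np.concatenate([prob * (1.0 - pc1), prob * pc1])
        yy0 = np.tile(y0, 2)
        yy1 = np.tile(y1, 2)
        # action branching, uniform over ties
        j = policy.pheno.index(t - 1, yy0, yy1)
        mask = policy.action_masks[t][bb, j]
        counts = _POPCOUNT[mask]
        parts_b, parts_y0, parts_y1, parts_p = [], [], [], []
        deltas = ((1, 0), (0, 1), (0, 0))
        for a, (d0, d1) in enumerate(deltas):
            on = (mask >> a & 1).astype(bool)
            if not on.any():
                continue
            parts_b.append(bb[on])
            parts_y0.append(yy0[on] + d0)
            parts_y1.append(yy1[on] + d1)
            parts_p.append(pp[on] / counts[on])
        bb = np.concatenate(parts_b)
        yy0 = np.concatenate(parts_y0)
        yy1 = np.concatenate(parts_y1)
        pp = np.concatenate(parts_p)
        # merge identical states
        key = (bb * (T + 1) + yy0) * (T + 1) + yy1
        uniq, inv = np.unique(key, return_inverse=True)
        prob = np.bincount(inv, weights=pp)
        b = (uniq // (T + 1)) // (T + 1)
        y0 = (uniq // (T + 1)) % (T + 1)
        y1 = uniq % (T + 1)
        record(t, b, y0, y1, prob)

    frame = pd.concat(records, ignore_index=True)
    frame["above_threshold"] = frame["probability"] > display_threshold
    return StateProbabilityTable(threshold=display_threshold, frame=frame)
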