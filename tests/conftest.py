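import numpy as np
import pytest

import ontosense as ons


def unit_mapping(T, **kwargs):
    """Linear mapping with unit marginal effects, f(y) = y, zero baseline."""
    kwargs.setdefault("baseline", 0.0)
    return ons.FitnessMapping(max_payoff=float(T), **kwargs)


@pytest.fixture
def small_policy():
    """T=4 increasing schedule, uniform prior, unit linear payoffs."""
    sched = ons.build_schedule("increasing", 0.55, 0.95, 4)
    return ons.solve_policy(0.5, sched, unit_mapping(4))


@pytest.fixture
def uninformative_policy():
    """T=4, all cues uninformative, symmetric payoffs: every action ties."""
    sched = ons.build_schedule("constant", 0.5, 0.5, 4)
    return ons.solve_policy(0.5, sched, ons.FitnessMapping(max_payoff=4.0))


def wait_only_policy(T=4):
    """A policy stub whose only optimal action is waiting, everywhere.

    Synthetic: such a policy cannot arise from the solver (full
    specialization always ties with waiting at a symmetric posterior,
    because all mappings award the same f(T)), but cue-independent
    behavior is exactly what null-result tests need.
    """
    sched = ons.build_schedule("constant", 0.6, 0.6, T)
    policy = ons.solve_policy(0.5, sched, unit_mapping(T))
    for t in range(1, T + 1):
        policy.action_masks[t] = np.full_like(policy.action_masks[t], 4)
    return policy


@pytest.fixture(scope="session")
def t20_policies():
    """Lazily solved and cached T=20 panels (linear payoffs, masks only)."""
    cache = {}

    def get(pattern, prior=0.5):
        key = (pattern, prior)
        if key not in cache:
            sched = ons.build_schedule(pattern, 0.55, 0.95, 20)
            cache[key] = ons.solve_policy(
                prior, sched, ons.FitnessMapping(max_payoff=20.0),
                store_values=False,
            )
        return cache[key]

    return get
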