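"""Independent reference computations used to validate the solver.

Everything here deliberately avoids the package's log-odds/merging
machinery: beliefs are plain probabilities updated by direct application
of Bayes' rule, and the optimal value is found by recursing over every
contingency plan without memoization.
"""

import numpy as np


def bayes_posterior(p1, cue_is_c1, r):
    """Direct Bayes rule for one binary cue of reliability r."""
    if cue_is_c1:
        num = r * p1
        den = r * p1 + (1.0 - r) * (1.0 - p1)
    else:
        num = (1.0 - r) * p1
        den = (1.0 - r) * p1 + r * (1.0 - p1)
    return num / den


def brute_force_root_value(prior, schedule, mapping):
    """Maximum expected fitness over all complete contingency plans.

    Exhaustive recursion over the full cue tree (no belief merging, no
    memoization); feasible only for small T.
    """
    T = schedule.T
    fR = mapping.reward_function(T)
    fP = mapping.penalty_function(T)

    def terminal(p1, y0, y1):
        return (
            mapping.baseline
            + (1.0 - p1) * fR(y0) + p1 * fR(y1)
            - ((1.0 - p1) * fP(y1) + p1 * fP(y0))
        )

    def value(p1, y0, y1, t):
        if t == T:
            return terminal(p1, y0, y1)
        r = schedule.r(t + 1)
        pc1 = p1 * r + (1.0 - p1) * (1.0 - r)
        total = 0.0
        for cue_is_c1, pc in ((True, pc1), (False, 1.0 - pc1)):
            pn = bayes_posterior(p1, cue_is_c1, r)
            total += pc * max(
                value(pn, y0 + 1, y1, t + 1),
                value(pn, y0, y1 + 1, t + 1),
                value(pn, y0, y1, t + 1),
            )
        return total

    return value(prior, 0, 0, 0)
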