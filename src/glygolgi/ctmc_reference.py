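"""Exact terminal distribution of the cisternal glycan process.

Within one cisterna each glycan follows a finite continuous-time Markov
chain, so the state distribution after residence time T is p0 @ expm(Q T).
Chaining the per-cisterna propagators and force-resolving leftover Fut8
locks gives the exact terminal glycoform distribution the Gillespie sampler
estimates.  The state space here is small (tens of states), so this is
cheap and serves as the independent ground truth for validating the
stochastic simulator.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .glycan_network import (
    MAN9,
    EnzymeRule,
    GlycanProfile,
    GlycanState,
    canonical_name,
    default_rules,
    enumerate_reachable_states,
    lock_resolution_rule,
)
from .golgi_ssa import ENZYME_NAMES, N_ENZYMES, EnzymeParameterSet

__all__ = ["terminal_distribution"]


def terminal_distribution(
    params: EnzymeParameterSet,
    start: GlycanState = MAN9,
    rules: list[EnzymeRule] | None = None,
) -> GlycanProfile:
    """Exact glycoform distribution after transit through all cisternae."""
    if rules is None:
        rules = default_rules()
    resolver = lock_resolution_rule()
    states = enumerate_reachable_states(rules, start=start)
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    times = params.residence_times()

    p = np.zeros(n)
    p[index[start]] = 1.0
    for c in range(params.n_cisternae):
        q = np.zeros((n, n))
        for s in states:
            i = index[s]
            for rule in rules + [resolver]:
                if rule.applies(s):
                    rate = (
                        params.lock_resolution_rate
                        if rule is resolver
                        else params.activity[ENZYME_NAMES.index(rule.enzyme_name), c]
                    )
                    if rate > 0:
                        j = index[rule.fire(s)]
                        q[i, j] += rate
                        q[i, i] -= rate
        p = p @ expm(q * times[c])

    # force-resolve remaining locks
    out = np.zeros(n)
    for s in states:
        i = index[s]
        if s.locked:
            out[index[resolver.fire(s)]] += p[i]
        else:
            out[i] += p[i]

    fractions: dict[str, float] = {}
    for s in states:
        mass = out[index[s]]
        if mass > 1e-15 and not s.locked:
            name = canonical_name(s)
            fractions[name] = fractions.get(name, 0.0) + float(mass)
    total = sum(fractions.values())
    return GlycanProfile({k: v / total for k, v in fractions.items()})
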