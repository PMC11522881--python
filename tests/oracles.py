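"""Independent oracles used only by the test suite.

These re-derive the one-step transition distribution and short-horizon
optimal values from first principles — enumerating every leaf of the
within-step event tree one Bernoulli coin at a time — deliberately
sharing no code with the package's kernel or solver.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

from settleopt.states import Behaviour, ModelParams, StateConfig


def oracle_kernel(state: StateConfig, behaviour: Behaviour, params: ModelParams):
    """Distribution over next states by explicit event-tree enumeration.

    Returns a dict mapping state index -> probability.  Enumerates all
    2^5 assignments of the five Bernoulli events (behaviour success,
    savings loss, forced move, tenure-on-forced-move, family growth),
    giving impossible events probability zero.
    """
    h0, s0, l0, f0 = state.house, state.savings, state.tenure, state.family
    fg = params.family_growth
    g = fg.base_prob * (1 + fg.house_bonus * h0 + fg.tenure_bonus * l0)
    if s0 == 1:
        g *= fg.savings_penalty
    g = min(max(g, 0.0), 1.0)

    out: dict[int, float] = defaultdict(float)
    for b_succ, lost, forced, f_ten, grew in itertools.product((True, False), repeat=5):
        h, s, l, f = h0, s0, l0, f0
        prob = 1.0

        # 1. behaviour resolution
        if behaviour == Behaviour.SAVE:
            p_eff = params.p_s_save if s == 0 else 0.0
        elif behaviour == Behaviour.BUILD:
            possible = h == 0 and not (params.build_condition == 1 and s == 0)
            p_eff = params.p_h_build if possible else 0.0
        else:
            p_eff = params.p_l_move
        prob *= p_eff if b_succ else 1.0 - p_eff
        if b_succ:
            if behaviour == Behaviour.SAVE:
                s = 1
            elif behaviour == Behaviour.BUILD:
                h = 1
                if params.build_condition == 1:
                    s = 0
            else:
                l = 1
                h = 0

        # 2. savings-loss shock
        p_eff = params.p_s_loss if s == 1 else 0.0
        prob *= p_eff if lost else 1.0 - p_eff
        if lost:
            s = 0

        # 3. forced move, only without tenure
        p_eff = params.p_force_move if l == 0 else 0.0
        prob *= p_eff if forced else 1.0 - p_eff
        if forced:
            h = 0
        p_eff = params.p_l_move if forced else 0.0
        prob *= p_eff if f_ten else 1.0 - p_eff
        if f_ten:
            l = 1

        # 4. family growth from start-of-step covariates
        prob *= g if grew else 1.0 - g
        if grew:
            f = min(f + 1, 2)

        if prob > 0.0:
            out[StateConfig(h, s, l, f).index] += prob
    return dict(out)


def oracle_values(params: ModelParams):
    """Optimal values at t = 0 by exhaustive recursion over behaviours
    and oracle-kernel outcomes.  Exponential in the horizon."""
    payoffs = params.payoffs()

    def value(idx: int, t: int) -> float:
        if t == params.horizon:
            return float(payoffs[idx])
        best = -1.0
        for b in Behaviour:
            dist = oracle_kernel(StateConfig.from_index(idx), b, params)
            ev = sum(p * value(j, t + 1) for j, p in dist.items())
            best = max(best, ev)
        return best

    return [value(i, 0) for i in range(24)]


def random_params(rng, **overrides) -> ModelParams:
    """A random parameter draw for property tests."""
    kwargs = dict(
        p_s_save=rng.random(),
        p_h_build=rng.random(),
        p_l_move=rng.random(),
        p_s_loss=rng.random(),
        p_force_move=rng.random(),
        build_condition=int(rng.integers(2)),
        payoff_scenario=["material_baseline", "family_priority", "additive", "house_priority"][
            rng.integers(4)
        ],
    )
    kwargs.update(overrides)
    return ModelParams(**kwargs)
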