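"""Finite-horizon backward-induction solver for the household model.

The solver computes, for every state configuration and time step, the
behaviour that maximizes the expected terminal pay-off, together with
that expected pay-off.  There is no discounting and no per-step reward:
pay-offs accrue only at the end of the horizon.

Values satisfy the dynamic-programming recursion

    V[T](s)  = payoff(s)
    V[t](s)  = max_b  sum_s' K[b](s, s') V[t+1](s')        (t < T)

with ties broken deterministically in the order save > build > move
(saving is prioritized when behaviours are equally good).  Ties are
declared at a configurable absolute tolerance; because values are exact
sums of products of probabilities, genuine ties are near-exact and the
default tolerance is tiny.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import (
    BEHAVIOUR_LABELS,
    N_STATES,
    Behaviour,
    ModelParams,
    StateConfig,
    enumerate_states,
    kernel_tensor,
)

TIE_TOL = 1e-12


@dataclass(frozen=True)
class Policy:
    """Optimal behaviour per (state, time step).

    ``actions`` has shape (24, horizon) and holds behaviour indices;
    :attr:`tensor` exposes the (2, 2, 2, 3, horizon) view indexed by
    (house, savings, tenure, family, time).
    """

    actions: np.ndarray
    params: ModelParams

    @property
    def horizon(self) -> int:
        return self.actions.shape[1]

    @property
    def tensor(self) -> np.ndarray:
        return self.actions.reshape(2, 2, 2, 3, self.horizon)

    def behaviour(self, state: StateConfig | int, t: int) -> Behaviour:
        idx = state.index if isinstance(state, StateConfig) else int(state)
        return Behaviour(int(self.actions[idx, t]))


@dataclass(frozen=True)
class ValueTensor:
    """Expected terminal pay-off per (state, time step).

    ``values`` has shape (24, horizon + 1); the slice at t = horizon is
    the terminal pay-off table itself.
    """

    values: np.ndarray
    params: ModelParams

    @property
    def horizon(self) -> int:
        return self.values.shape[1] - 1

    @property
    def tensor(self) -> np.ndarray:
        return self.values.reshape(2, 2, 2, 3, self.horizon + 1)

    def value(self, state: StateConfig | int, t: int) -> float:
        idx = state.index if isinstance(state, StateConfig) else int(state)
        return float(self.values[idx, t])


def solve(params: ModelParams, tie_tol: float = TIE_TOL) -> tuple[Policy, ValueTensor]:
    """Solve the model by backward induction.

    Returns the optimal policy and the value tensor.  Deterministic:
    identical parameters give bit-identical results.
    """
    T = params.horizon
    K = kernel_tensor(params)  # (3, 24, 24)
    values = np.empty((N_STATES, T + 1))
    actions = np.empty((N_STATES, T), dtype=np.int8)
    values[:, T] = params.payoffs()
    for t in range(T - 1, -1, -1):
        ev = K @ values[:, t + 1]  # (3, 24): expected value per behaviour
        best = ev.max(axis=0)
        # first behaviour (in save > build > move order) within tolerance of max
        actions[:, t] = (ev >= best - tie_tol).argmax(axis=0)
        values[:, t] = ev[actions[:, t], np.arange(N_STATES)]
    return Policy(actions, params), ValueTensor(values, params)


_BRUTE_FORCE_MAX_HORIZON = 4


def brute_force_values(params: ModelParams, tie_tol: float = TIE_TOL) -> ValueTensor:
    """Optimal values by exhaustive recursion, for short horizons only.

    Recurses over every behaviour and every reachable next state with no
    memoization, so the cost grows combinatorially; refused above a
    horizon of 4.  Exists as a cross-check on :func:`solve` in tests.
    """
    if params.horizon > _BRUTE_FORCE_MAX_HORIZON:
        raise ValueError(
            f"brute force is limited to horizon <= {_BRUTE_FORCE_MAX_HORIZON}"
        )
    K = kernel_tensor(params)
    payoffs = params.payoffs()
    T = params.horizon

    def value(state: int, t: int) -> float:
        if t == T:
            return float(payoffs[state])
        best = -np.inf
        for b in Behaviour:
            ev = 0.0
            for nxt in np.nonzero(K[b, state] > 0)[0]:
                ev += K[b, state, nxt] * value(int(nxt), t + 1)
            best = max(best, ev)
        return best

    values = np.empty((N_STATES, T + 1))
    values[:, T] = payoffs
    for t in range(T):
        for s in range(N_STATES):
            values[s, t] = value(s, t)
    return ValueTensor(values, params)


def policy_to_table(policy: Policy, values: ValueTensor | None = None) -> pd.DataFrame:
    """Long-format policy table: one row per (state, time step)."""
    states = enumerate_states()
    rows = []
    for t in range(policy.horizon):
        for i, s in enumerate(states):
            house, savings, tenure, family = s.labels()
            row = {
                "state_index": i,
                "house": house,
                "savings": savings,
                "tenure": tenure,
                "family": family,
                "time": t,
                "behaviour": BEHAVIOUR_LABELS[policy.actions[i, t]],
            }
            if values is not None:
                row["value"] = values.values[i, t]
            rows.append(row)
    return pd.DataFrame(rows)


def table_to_policy(table: pd.DataFrame, params: ModelParams) -> Policy:
    """Rebuild a :class:`Policy` from its long-format table."""
    horizon = int(table["time"].max()) + 1
    actions = np.empty((N_STATES, horizon), dtype=np.int8)
    b_codes = {label: i for i, label in enumerate(BEHAVIOUR_LABELS)}
    for _, row in table.iterrows():
        actions[int(row["state_index"]), int(row["time"])] = b_codes[row["behaviour"]]
    return Policy(actions, params)


def policy_table_roundtrip(policy: Policy) -> Policy:
    """Write the policy table to CSV text and read it back."""
    buf = io.StringIO()
    policy_to_table(policy).to_csv(buf, index=False)
    buf.seek(0)
    return table_to_policy(pd.read_csv(buf), policy.params)
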