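"""State space, terminal pay-offs and one-step transition kernel.

Households are described by four state variables:

* ``house`` — mobile dwelling (ger) or fixed self-built house (bashin),
* ``savings`` — without / with savings,
* ``tenure`` — without / with a secure claim to the occupied plot,
* ``family`` — single occupant, couple, or family with dependants,

giving 2 x 2 x 2 x 3 = 24 state configurations.  At every time step a
household enacts one of three behaviours (save, build, move) whose
consequences are probabilistic, and is additionally exposed to two
stochastic shocks (loss of savings, forced relocation while untenured).
Family size cannot be acted on directly: it advances as a side effect of
the household's material situation.

This module holds the canonical state indexing shared by the solver and
the forward simulator, the four terminal pay-off scenarios, and the exact
one-step transition distribution obtained by composing the within-step
events in a fixed order:

1. behaviour resolution,
2. savings-loss shock,
3. forced-move shock (only for households without tenure after step 2),
4. family-growth event, whose probability is read from the
   start-of-step state so that the current decision cannot influence
   family growth within its own step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HOUSE_LEVELS = ("mobile", "fixed")
SAVINGS_LEVELS = ("none", "has")
TENURE_LEVELS = ("none", "has")
FAMILY_LEVELS = ("single", "couple", "family_with_dependants")

SCENARIOS = ("material_baseline", "family_priority", "additive", "house_priority")

N_STATES = 24


class Behaviour(IntEnum):
    """The three behaviours a household can enact, in tie-break order."""

    SAVE = 0
    BUILD = 1
    MOVE = 2


BEHAVIOUR_LABELS = ("save", "build", "move")


def state_index(house: int, savings: int, tenure: int, family: int):
    """Canonical (house-major) index of a state configuration."""
    return ((house * 2 + savings) * 2 + tenure) * 3 + family


# Decoded level of each state variable, indexed by state index.
_ALL = np.arange(N_STATES)
HOUSE_OF = _ALL // 12
SAVINGS_OF = (_ALL // 6) % 2
TENURE_OF = (_ALL // 3) % 2
FAMILY_OF = _ALL % 3


@dataclass(frozen=True, order=True)
class StateConfig:
    """One of the 24 household state configurations.

    All four fields are integer levels; label forms are available via
    :meth:`labels`.  ``index`` and :meth:`from_index` form a bijection
    with ``range(24)`` under house-major ordering.
    """

    house: int
    savings: int
    tenure: int
    family: int

    def __post_init__(self):
        if self.house not in (0, 1) or self.savings not in (0, 1) or self.tenure not in (0, 1):
            raise ValueError("house, savings and tenure are binary (0 or 1)")
        if self.family not in (0, 1, 2):
            raise ValueError("family takes levels 0 (single), 1 (couple), 2 (dependants)")

    @property
    def index(self) -> int:
        return state_index(self.house, self.savings, self.tenure, self.family)

    @classmethod
    def from_index(cls, index: int) -> "StateConfig":
        if not 0 <= index < N_STATES:
            raise ValueError(f"state index must be in [0, {N_STATES})")
        return cls(
            house=int(HOUSE_OF[index]),
            savings=int(SAVINGS_OF[index]),
            tenure=int(TENURE_OF[index]),
            family=int(FAMILY_OF[index]),
        )

    @classmethod
    def from_labels(cls, house: str, savings: str, tenure: str, family: str) -> "StateConfig":
        return cls(
            HOUSE_LEVELS.index(house),
            SAVINGS_LEVELS.index(savings),
            TENURE_LEVELS.index(tenure),
            FAMILY_LEVELS.index(family),
        )

    def labels(self) -> tuple[str, str, str, str]:
        return (
            HOUSE_LEVELS[self.house],
            SAVINGS_LEVELS[self.savings],
            TENURE_LEVELS[self.tenure],
            FAMILY_LEVELS[self.family],
        )


def enumerate_states() -> list[StateConfig]:
    """All 24 state configurations in canonical house-major order."""
    return [StateConfig.from_index(i) for i in range(N_STATES)]


@dataclass(frozen=True)
class FamilyGrowthSpec:
    """Per-step family-growth probability model.

    The probability that the family advances one level in a step is

        clamp(base_prob * (1 + house_bonus*h + tenure_bonus*l)
                        * (savings_penalty if savings else 1))

    where h, l and the savings flag are read from the start-of-step
    state.  Growth is more likely with a fixed house and tenure (long
    term capital) and less likely with savings held (resources diverted
    from family formation).
    """

    base_prob: float = 0.1
    house_bonus: float = 1.0
    tenure_bonus: float = 1.0
    savings_penalty: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.base_prob <= 1.0:
            raise ValueError("base_prob must be a probability")
        if self.house_bonus < 0 or self.tenure_bonus < 0:
            raise ValueError("bonuses must be non-negative")
        if not 0.0 <= self.savings_penalty <= 1.0:
            raise ValueError("savings_penalty must be in [0, 1]")

    def probability(self, house, savings, tenure):
        """Growth probability for (arrays of) state variable levels."""
        p = self.base_prob * (1.0 + self.house_bonus * house + self.tenure_bonus * tenure)
        p = p * np.where(savings == 1, self.savings_penalty, 1.0)
        return np.clip(p, 0.0, 1.0)


_PROB_FIELDS = ("p_s_save", "p_h_build", "p_l_move", "p_s_loss", "p_force_move")


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of the household decision model.

    Parameters
    ----------
    p_s_save : probability that saving behaviour gains the savings state.
    p_h_build : probability that building gains the fixed-house state.
    p_l_move : probability that moving relocates the household and gains
        tenure; also the probability of gaining tenure after a forced move.
    p_s_loss : per-step probability of losing held savings.
    p_force_move : per-step probability that an untenured household is
        forcibly relocated.
    build_condition : 1 if savings are required (and consumed) to build a
        fixed house, 0 if building is free of that requirement.
    payoff_scenario : terminal pay-off scenario name.
    horizon : number of decision steps (an adult decision-making lifespan).
    family_growth : family-growth probability model.
    payoff_weights : optional override of the scenario's pay-off weights,
        see :func:`payoff_table`.
    """

    p_s_save: float
    p_h_build: float
    p_l_move: float
    p_s_loss: float
    p_force_move: float
    build_condition: int = 0
    payoff_scenario: str = "additive"
    horizon: int = 40
    family_growth: FamilyGrowthSpec = field(default_factory=FamilyGrowthSpec)
    payoff_weights: tuple[float, float, float, float] | None = None

    def __post_init__(self):
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} is not a probability")
        if self.build_condition not in (0, 1):
            raise ValueError("build_condition must be 0 or 1")
        if self.payoff_scenario not in SCENARIOS:
            raise ValueError(
                f"unknown payoff scenario {self.payoff_scenario!r}; expected one of {SCENARIOS}"
            )
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.payoff_weights is not None:
            object.__setattr__(self, "payoff_weights", tuple(float(w) for w in self.payoff_weights))

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def payoffs(self) -> np.ndarray:
        return payoff_table(self.payoff_scenario, weights=self.payoff_weights)


# Default pay-off weights on (house, savings, tenure, family/2) per scenario.
# Each terminal pay-off is the weighted sum w_h*h + w_s*s + w_l*l + w_f*(f/2),
# so with non-negative weights summing to one, pay-offs span exactly [0, 1].
DEFAULT_PAYOFF_WEIGHTS: dict[str, tuple[float, float, float, float]] = {
    "material_baseline": (0.0, 0.5, 0.5, 0.0),
    "family_priority": (0.0, 0.0, 0.0, 1.0),
    "additive": (0.25, 0.25, 0.25, 0.25),
    "house_priority": (0.6, 0.15, 0.25, 0.0),
}


def payoff_table(scenario: str, weights: Sequence[float] | None = None) -> np.ndarray:
    """Terminal pay-off for every state configuration, scaled to [0, 1].

    Parameters
    ----------
    scenario : one of ``material_baseline`` (savings and tenure only),
        ``family_priority`` (family level only), ``additive`` (all states
        weighted equally) or ``house_priority`` (house foremost, then
        tenure, then savings; family-insensitive).
    weights : optional override — four non-negative weights on
        (house, savings, tenure, family level / 2), normalized to sum 1.

    Returns
    -------
    numpy.ndarray of shape (24,), indexed by canonical state index.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown payoff scenario {scenario!r}; expected one of {SCENARIOS}")
    w = DEFAULT_PAYOFF_WEIGHTS[scenario] if weights is None else tuple(weights)
    if len(w) != 4 or any(x < 0 for x in w) or sum(w) <= 0:
        raise ValueError("weights must be four non-negative values with a positive sum")
    w = np.asarray(w, dtype=float) / sum(w)
    return (
        w[0] * HOUSE_OF + w[1] * SAVINGS_OF + w[2] * TENURE_OF + w[3] * (FAMILY_OF / 2.0)
    ).astype(float)


def payoff_frame(scenario: str, weights: Sequence[float] | None = None) -> pd.DataFrame:
    """Pay-off table in long form (one row per state), for CSV export."""
    table = payoff_table(scenario, weights)
    rows = [
        {"state_index": i, **dict(zip(("house", "savings", "tenure", "family"), s.labels())),
         "payoff": table[i]}
        for i, s in enumerate(enumerate_states())
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TransitionDistribution:
    """Distribution over next-step state configurations."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape != (N_STATES,):
            raise ValueError("a transition distribution has one entry per state")
        if (p < -1e-15).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must be non-negative and sum to 1")

    def __getitem__(self, state: StateConfig | int) -> float:
        idx = state.index if isinstance(state, StateConfig) else int(state)
        return float(self.probs[idx])

    def support(self) -> list[StateConfig]:
        return [StateConfig.from_index(int(i)) for i in np.nonzero(self.probs > 0)[0]]


def _E(h, s, l, f):
    """Vectorized canonical index."""
    return ((h * 2 + s) * 2 + l) * 3 + f


def family_growth_probs(params: ModelParams) -> np.ndarray:
    """Per-state family-growth probability, read from start-of-step levels."""
    return params.family_growth.probability(HOUSE_OF, SAVINGS_OF, TENURE_OF)


def kernel_tensor(params: ModelParams) -> np.ndarray:
    """Exact one-step transition kernel for all states and behaviours.

    Returns an array ``K`` of shape (3, 24, 24) with
    ``K[b, i, j] = P(next state j | state i, behaviour b)``, obtained by
    composing the within-step events in their fixed order.  Event
    matrices are built by direct indexing, so the kernel is exact (no
    sampling involved).
    """
    eye = np.eye(N_STATES)

    # -- 1. behaviour resolution ------------------------------------------
    save = eye.copy()
    can_save = SAVINGS_OF == 0
    to = _E(HOUSE_OF, 1, TENURE_OF, FAMILY_OF)
    save[can_save, can_save.nonzero()[0]] = 1.0 - params.p_s_save
    save[_ALL[can_save], to[can_save]] += params.p_s_save

    build = eye.copy()
    if params.build_condition == 1:
        can_build = (HOUSE_OF == 0) & (SAVINGS_OF == 1)
        to = _E(1, 0, TENURE_OF, FAMILY_OF)  # savings consumed on success
    else:
        can_build = HOUSE_OF == 0
        to = _E(1, SAVINGS_OF, TENURE_OF, FAMILY_OF)
    build[can_build, can_build.nonzero()[0]] = 1.0 - params.p_h_build
    build[_ALL[can_build], to[can_build]] += params.p_h_build

    move = (1.0 - params.p_l_move) * eye
    to = _E(0, SAVINGS_OF, 1, FAMILY_OF)
    np.add.at(move, (_ALL, to), params.p_l_move)

    # -- 2. savings-loss shock --------------------------------------------
    loss = eye.copy()
    holders = SAVINGS_OF == 1
    to = _E(HOUSE_OF, 0, TENURE_OF, FAMILY_OF)
    loss[holders, holders.nonzero()[0]] = 1.0 - params.p_s_loss
    loss[_ALL[holders], to[holders]] += params.p_s_loss

    # -- 3. forced move (untenured households only) ------------------------
    forced = eye.copy()
    untenured = TENURE_OF == 0
    idx = untenured.nonzero()[0]
    forced[idx, idx] = 1.0 - params.p_force_move
    to_tenure = _E(0, SAVINGS_OF, 1, FAMILY_OF)
    to_no_tenure = _E(0, SAVINGS_OF, 0, FAMILY_OF)
    np.add.at(forced, (idx, to_tenure[idx]), params.p_force_move * params.p_l_move)
    np.add.at(forced, (idx, to_no_tenure[idx]), params.p_force_move * (1.0 - params.p_l_move))

    # -- 4. family growth, at the start-of-step state's probability --------
    grow = np.zeros_like(eye)
    grow[_ALL, _E(HOUSE_OF, SAVINGS_OF, TENURE_OF, np.minimum(FAMILY_OF + 1, 2))] = 1.0
    g = family_growth_probs(params)[:, None]

    shocks = loss @ forced
    out = np.empty((3, N_STATES, N_STATES))
    for b, mat in zip(Behaviour, (save, build, move)):
        m = mat @ shocks
        out[b] = (1.0 - g) * m + g * (m @ grow)
    return out


def transition_kernel(
    state: StateConfig | int, behaviour: Behaviour | int, params: ModelParams
) -> TransitionDistribution:
    """Distribution over next states for one (state, behaviour) pair."""
    idx = state.index if isinstance(state, StateConfig) else int(state)
    return TransitionDistribution(kernel_tensor(params)[int(behaviour), idx].copy())


def kernel_frame(params: ModelParams) -> pd.DataFrame:
    """Kernel in long form (state, behaviour, next state, probability)."""
    K = kernel_tensor(params)
    b_idx, s_idx, n_idx = np.nonzero(K > 0)
    return pd.DataFrame(
        {
            "state_index": s_idx,
            "behaviour": [BEHAVIOUR_LABELS[b] for b in b_idx],
            "next_state_index": n_idx,
            "probability": K[b_idx, s_idx, n_idx],
        }
    )
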