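"""Forward simulation of agent households enacting an optimal policy.

Agents are placed in the state space, and at every step look up the
solved policy at their (state, time step), enact the prescribed
behaviour by sampling the same within-step event sequence that defines
the transition kernel, and log what happened.  The simulator produces
longitudinal trajectories; cross-sections, per-step behaviour-frequency
series and dwelling-transition categories are derived from them.

All sampling is vectorized over agents and driven by a single seeded
generator, so a run is fully reproducible from (policy, parameters,
stay lengths, seed).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .solver import Policy, solve
from .states import (
    BEHAVIOUR_LABELS,
    FAMILY_OF,
    HOUSE_OF,
    N_STATES,
    SAVINGS_OF,
    SCENARIOS,
    TENURE_OF,
    ModelParams,
    state_index,
)

TRANSITION_LABELS = ("mobile-mobile", "mobile-fixed", "fixed-mobile", "fixed-fixed")
#: Empirical names of the four dwelling-transition categories, same order.
TRANSITION_ALIASES = ("ger-ger", "ger-bashin", "bashin-ger", "bashin-bashin")


def transition_category(first_house, current_house):
    """Category index from (first, current) house state: 2*first + current."""
    return 2 * np.asarray(first_house) + np.asarray(current_house)


def init_agents(n: int, mode: str = "uniform", seed: int | None = 0) -> np.ndarray:
    """Draw initial state indices for ``n`` agents.

    ``uniform`` draws independently and uniformly over all 24
    configurations; ``all_mobile`` fixes the house state to mobile
    (most households arriving in the Ger districts start in a ger) and
    draws savings, tenure and family uniformly.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        return rng.integers(0, N_STATES, size=n)
    if mode == "all_mobile":
        return rng.integers(0, N_STATES // 2, size=n)  # indices 0..11 have house=0
    raise ValueError(f"unknown init mode {mode!r}")


@dataclass
class SimulationResult:
    """Trajectories of a simulated agent population.

    Arrays are agent-major; step arrays are only meaningful for
    ``t < stay_lengths[agent]``.  ``states[:, t]`` is the state at the
    start of step t, so ``states[:, L]`` is an agent's final state after
    a stay of length L, and consecutive records chain by construction.
    """

    states: np.ndarray  # (n, horizon+1) int
    behaviours: np.ndarray  # (n, horizon) int8, -1 when past stay length
    success: np.ndarray  # (n, horizon) bool — behaviour's event occurred
    loss_shock: np.ndarray  # (n, horizon) bool
    forced_move: np.ndarray  # (n, horizon) bool
    forced_tenure: np.ndarray  # (n, horizon) bool — tenure gained in forced move
    family_event: np.ndarray  # (n, horizon) bool
    stay_lengths: np.ndarray  # (n,) int
    params: ModelParams
    seed: object = None

    @property
    def n_agents(self) -> int:
        return self.states.shape[0]

    @property
    def horizon(self) -> int:
        return self.states.shape[1] - 1

    def final_states(self) -> np.ndarray:
        return self.states[np.arange(self.n_agents), self.stay_lengths]

    def trajectory(self, agent: int) -> pd.DataFrame:
        """Per-step records for one agent (its stay length many rows)."""
        L = int(self.stay_lengths[agent])
        steps = np.arange(L)
        return pd.DataFrame(
            {
                "time": steps,
                "start_state": self.states[agent, :L],
                "behaviour": [BEHAVIOUR_LABELS[b] for b in self.behaviours[agent, :L]],
                "success": self.success[agent, :L],
                "loss_shock": self.loss_shock[agent, :L],
                "forced_move": self.forced_move[agent, :L],
                "family_event": self.family_event[agent, :L],
                "end_state": self.states[agent, 1 : L + 1],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """All trajectories in long form (one row per agent-step)."""
        frames = []
        for i in range(self.n_agents):
            df = self.trajectory(i)
            df.insert(0, "agent", i)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def simulate(
    policy: Policy,
    params: ModelParams,
    n: int | None = None,
    stay_lengths=None,
    seed: object = 0,
    start_states=None,
    init_mode: str = "uniform",
) -> SimulationResult:
    """Simulate ``n`` agents enacting ``policy`` under ``params``.

    Each agent runs for its stay length (default: the full horizon),
    at each step enacting the policy's behaviour for its current state
    and sampling behaviour success, the savings-loss and forced-move
    shocks, and the family-growth event exactly as the transition
    kernel defines them.  ``start_states`` (state indices) overrides the
    random initialization.
    """
    if params != policy.params:
        raise ValueError("policy was solved under different parameters")
    T = params.horizon
    rng = np.random.default_rng(seed)

    if start_states is not None:
        start_states = np.asarray(start_states, dtype=int)
        if n is None:
            n = len(start_states)
        if len(start_states) != n:
            raise ValueError("start_states length must equal n")
    else:
        if n is None:
            raise ValueError("either n or start_states is required")
        start_states = init_agents(n, mode=init_mode, seed=rng)

    if stay_lengths is None:
        stay_lengths = np.full(n, T, dtype=int)
    else:
        stay_lengths = np.asarray(stay_lengths, dtype=int)
        if len(stay_lengths) != n:
            raise ValueError("stay_lengths length must equal n")
        if (stay_lengths < 1).any() or (stay_lengths > T).any():
            raise ValueError("stay lengths must lie in [1, horizon]")

    states = np.empty((n, T + 1), dtype=np.int16)
    states[:, 0] = start_states
    behaviours = np.full((n, T), -1, dtype=np.int8)
    success = np.zeros((n, T), dtype=bool)
    loss_shock = np.zeros((n, T), dtype=bool)
    forced_move = np.zeros((n, T), dtype=bool)
    forced_tenure = np.zeros((n, T), dtype=bool)
    family_event = np.zeros((n, T), dtype=bool)

    bc = params.build_condition
    growth = params.family_growth

    for t in range(T):
        cur = states[:, t]
        active = t < stay_lengths
        h = HOUSE_OF[cur].copy()
        s = SAVINGS_OF[cur].copy()
        l = TENURE_OF[cur].copy()
        f = FAMILY_OF[cur].copy()
        g = growth.probability(h, s, l)  # start-of-step covariates

        b = policy.actions[cur, t]
        behaviours[active, t] = b[active]
        u = rng.random((5, n))

        # 1. behaviour resolution
        saved = active & (b == 0) & (s == 0) & (u[0] < params.p_s_save)
        can_build = (h == 0) & ((bc == 0) | (s == 1))
        built = active & (b == 1) & can_build & (u[0] < params.p_h_build)
        moved = active & (b == 2) & (u[0] < params.p_l_move)
        s[saved] = 1
        h[built] = 1
        if bc == 1:
            s[built] = 0  # savings spent on building
        l[moved] = 1
        h[moved] = 0
        success[:, t] = saved | built | moved

        # 2. savings-loss shock
        lost = active & (s == 1) & (u[1] < params.p_s_loss)
        s[lost] = 0
        loss_shock[:, t] = lost

        # 3. forced move for untenured households
        forced = active & (l == 0) & (u[2] < params.p_force_move)
        h[forced] = 0
        ften = forced & (u[3] < params.p_l_move)
        l[ften] = 1
        forced_move[:, t] = forced
        forced_tenure[:, t] = ften

        # 4. family growth (probability from start-of-step state)
        grew = active & (f < 2) & (u[4] < g)
        f[grew] = f[grew] + 1
        family_event[:, t] = grew

        nxt = state_index(h, s, l, f)
        states[:, t + 1] = np.where(active, nxt, cur)

    return SimulationResult(
        states,
        behaviours,
        success,
        loss_shock,
        forced_move,
        forced_tenure,
        family_event,
        stay_lengths,
        params,
        seed,
    )


def behaviour_frequencies(sim: SimulationResult) -> pd.DataFrame:
    """Per-step counts of enacted behaviours over still-active agents.

    Returns one row per time step with columns ``save``, ``build``,
    ``move`` and ``active``; the three counts sum to ``active`` at every
    step (agents past their stay length are excluded).
    """
    T = sim.horizon
    out = np.zeros((T, 3), dtype=int)
    for b in range(3):
        out[:, b] = (sim.behaviours == b).sum(axis=0)
    df = pd.DataFrame(out, columns=list(BEHAVIOUR_LABELS))
    df.insert(0, "time", np.arange(T))
    df["active"] = (sim.behaviours >= 0).sum(axis=0)
    return df


def cross_section(sim: SimulationResult) -> pd.DataFrame:
    """One household record per agent, observed at its stay length.

    Columns mirror the cross-sectional survey schema: time in the
    environment (years), savings and tenure flags, family category,
    first and current dwelling type and the dwelling-transition
    category.
    """
    final = sim.final_states()
    first_house = HOUSE_OF[sim.states[:, 0]]
    current_house = HOUSE_OF[final]
    cat = transition_category(first_house, current_house)
    return pd.DataFrame(
        {
            "household": np.arange(sim.n_agents),
            "time_in_env": sim.stay_lengths,
            "savings": SAVINGS_OF[final],
            "tenure": TENURE_OF[final],
            "family": FAMILY_OF[final],
            "first_house": first_house,
            "current_house": current_house,
            "transition": [TRANSITION_LABELS[c] for c in cat],
        }
    )


@dataclass(frozen=True)
class SweepGrid:
    """A Cartesian parameter grid for the theoretical sweep."""

    params_list: tuple[ModelParams, ...]
    agents_per_run: int = 100
    replicates: int = 10

    def __len__(self) -> int:
        return len(self.params_list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.params_list):
            rows.append(
                {
                    "combo": i,
                    "p_s_save": p.p_s_save,
                    "p_h_build": p.p_h_build,
                    "p_l_move": p.p_l_move,
                    "p_s_loss": p.p_s_loss,
                    "p_force_move": p.p_force_move,
                    "build_condition": p.build_condition,
                    "payoff_scenario": p.payoff_scenario,
                }
            )
        return pd.DataFrame(rows)


def build_sweep_grid(
    prob_values=(0.25, 0.5, 0.75),
    scenarios=SCENARIOS,
    build_conditions=(0, 1),
    horizon: int = 40,
    agents_per_run: int = 100,
    replicates: int = 10,
) -> SweepGrid:
    """Default sweep: 3^5 probability combinations x 2 build conditions
    x 4 pay-off scenarios = 1944 parameter combinations."""
    combos = []
    for scenario in scenarios:
        for bc in build_conditions:
            for ps, ph, pl, pls, pfm in itertools.product(prob_values, repeat=5):
                combos.append(
                    ModelParams(
                        p_s_save=ps,
                        p_h_build=ph,
                        p_l_move=pl,
                        p_s_loss=pls,
                        p_force_move=pfm,
                        build_condition=bc,
                        payoff_scenario=scenario,
                        horizon=horizon,
                    )
                )
    return SweepGrid(tuple(combos), agents_per_run, replicates)


def run_sweep(
    grid: SweepGrid,
    seed: int = 0,
    out_dir: str | Path | None = None,
    stay_mode: str = "full",
) -> pd.DataFrame:
    """Run every (combination, replicate) of the sweep.

    Each run solves the model, simulates ``grid.agents_per_run`` agents
    and records the per-step behaviour-frequency series plus the four
    dwelling-transition category counts.  With ``out_dir`` set, results
    stream to ``frequencies.csv`` / ``transitions.csv`` as runs finish
    and a ``manifest.json`` tracks progress, so an interrupted sweep can
    be resumed.  ``stay_mode`` is ``full`` (all agents stay the whole
    horizon) or ``varying`` (stay lengths uniform on 1..horizon, as used
    for the transition plots).

    Returns the per-run transition/behaviour totals as a data frame.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    done: set[tuple[int, int]] = set()
    freq_file = trans_file = None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        manifest_path = out_path / "manifest.json"
        if manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())
            if manifest.get("seed") != seed or manifest.get("n_combos") != len(grid):
                raise ValueError(
                    f"existing sweep in {out_path} was started with a different "
                    "seed or grid; use a fresh output directory"
                )
            done = {tuple(x) for x in manifest["completed"]}
        else:
            manifest = {
                "seed": seed,
                "n_combos": len(grid),
                "replicates": grid.replicates,
                "agents_per_run": grid.agents_per_run,
                "stay_mode": stay_mode,
                "completed": [],
            }
        header = not (out_path / "frequencies.csv").exists()
        freq_file = (out_path / "frequencies.csv").open("a")
        trans_file = (out_path / "transitions.csv").open("a")
        if header:
            freq_file.write("combo,replicate,time,save,build,move,active\n")
            trans_file.write(
                "combo,replicate," + ",".join(TRANSITION_LABELS) + ",builds_enacted\n"
            )

    records = []
    try:
        for i, params in enumerate(grid.params_list):
            policy, _ = solve(params)
            for rep in range(grid.replicates):
                if (i, rep) in done:
                    continue
                run_seed = np.random.SeedSequence(entropy=seed, spawn_key=(i, rep))
                rng = np.random.default_rng(run_seed)
                n = grid.agents_per_run
                stays = (
                    rng.integers(1, params.horizon + 1, size=n)
                    if stay_mode == "varying"
                    else None
                )
                sim = simulate(policy, params, n=n, stay_lengths=stays, seed=rng)
                freqs = behaviour_frequencies(sim)
                cs = cross_section(sim)
                counts = cs["transition"].value_counts()
                rec = {"combo": i, "replicate": rep}
                for lab in TRANSITION_LABELS:
                    rec[lab] = int(counts.get(lab, 0))
                rec["builds_enacted"] = int((sim.behaviours == 1).sum())
                rec["saves_enacted"] = int((sim.behaviours == 0).sum())
                rec["moves_enacted"] = int((sim.behaviours == 2).sum())
                records.append(rec)
                if out_path is not None:
                    freqs.insert(0, "replicate", rep)
                    freqs.insert(0, "combo", i)
                    freqs.to_csv(freq_file, header=False, index=False)
                    trans_file.write(
                        f"{i},{rep},"
                        + ",".join(str(rec[lab]) for lab in TRANSITION_LABELS)
                        + f",{rec['builds_enacted']}\n"
                    )
                    manifest["completed"].append([i, rep])
        if out_path is not None:
            manifest_path.write_text(json.dumps(manifest))
    finally:
        if freq_file is not None:
            freq_file.close()
            trans_file.close()
    return pd.DataFrame(records)
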