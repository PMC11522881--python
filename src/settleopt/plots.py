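"""Diagnostic figures: behaviour-frequency curves, dwelling-transition
trajectories, and prior/posterior comparisons."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .abc import ABCResult, PriorSpec, sample_prior
from .simulate import SimulationResult, TRANSITION_LABELS, behaviour_frequencies, cross_section
from .states import HOUSE_OF

BEHAVIOUR_COLOURS = {"save": "tab:blue", "build": "tab:red", "move": "tab:purple"}
TRANSITION_COLOURS = {
    "mobile-mobile": "darkred",
    "mobile-fixed": "lightblue",
    "fixed-mobile": "lightcoral",
    "fixed-fixed": "darkblue",
}


def behaviour_frequency_plot(freqs: pd.DataFrame | list[pd.DataFrame], ax=None):
    """Per-step counts of save/build/move; one line set per run."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    runs = [freqs] if isinstance(freqs, pd.DataFrame) else list(freqs)
    alpha = max(0.08, 1.0 / max(len(runs), 1) ** 0.5)
    for df in runs:
        for b, colour in BEHAVIOUR_COLOURS.items():
            ax.plot(df["time"], df[b], color=colour, alpha=alpha)
    for b, colour in BEHAVIOUR_COLOURS.items():
        ax.plot([], [], color=colour, label=b)
    ax.set_xlabel("time step")
    ax.set_ylabel("households enacting behaviour")
    ax.legend()
    return ax


def transition_plot(sim: SimulationResult, jitter: float = 0.15, seed: int = 0, ax=None):
    """Jittered per-agent house-state trajectories, coloured by
    dwelling-transition category."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    rng = np.random.default_rng(seed)
    cs = cross_section(sim)
    offsets = rng.uniform(-jitter, jitter, size=sim.n_agents)
    for i in range(sim.n_agents):
        L = int(sim.stay_lengths[i])
        house = HOUSE_OF[sim.states[i, : L + 1]]
        ax.plot(
            np.arange(L + 1),
            house + offsets[i],
            color=TRANSITION_COLOURS[cs["transition"].iloc[i]],
            alpha=0.3,
            linewidth=0.8,
        )
    ax.set_yticks([0, 1], ["mobile (ger)", "fixed (bashin)"])
    ax.set_xlabel("time in environment")
    return ax


def prior_posterior_plot(result: ABCResult, posterior: pd.DataFrame, spec: PriorSpec | None = None):
    """Prior vs posterior densities for the three continuous parameters
    and bar charts for the two categorical ones."""
    spec = spec or PriorSpec()
    prior = sample_prior(len(posterior), spec, seed=0)
    fig, axes = plt.subplots(1, 5, figsize=(18, 3.2))
    for ax, name in zip(axes[:3], ("p_s_save", "p_l_move", "p_h_build")):
        ax.hist(prior[name], bins=30, density=True, alpha=0.4, label="prior")
        ax.hist(posterior[name], bins=30, density=True, alpha=0.6, label="posterior")
        ax.set_title(name)
        ax.legend()
    for ax, name in zip(axes[3:], ("payoff_scenario", "build_condition")):
        p = prior[name].value_counts(normalize=True)
        q = posterior[name].value_counts(normalize=True)
        labels = sorted(set(p.index) | set(q.index), key=str)
        x = np.arange(len(labels))
        ax.bar(x - 0.2, [p.get(v, 0) for v in labels], width=0.4, label="prior")
        ax.bar(x + 0.2, [q.get(v, 0) for v in labels], width=0.4, label="posterior")
        ax.set_xticks(x, [str(v) for v in labels], rotation=30, ha="right")
        ax.set_title(name)
        ax.legend()
    fig.tight_layout()
    return fig


def transition_frequency_plot(counts: np.ndarray, ref_stats=None, ax=None):
    """Distributions of the four transition-category counts over
    regenerated datasets, with reference values as dashed lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for j, lab in enumerate(TRANSITION_LABELS):
        ax.hist(counts[:, j], bins=30, alpha=0.5, color=TRANSITION_COLOURS[lab], label=lab)
        if ref_stats is not None:
            ax.axvline(ref_stats[j], color=TRANSITION_COLOURS[lab], linestyle="--")
    ax.set_xlabel("households per transition category")
    ax.legend()
    return ax
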