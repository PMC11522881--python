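# settleopt

Optimality modelling and simulation-based inference for household
housing strategy: when is it best to **build** a fixed house, **move**
(and try to secure land tenure), or **save**?

The package is aimed at human behavioural ecologists and quantitative
social scientists studying settlement dynamics — in particular the Ger
districts of Ulaanbaatar, where households shift between mobile felt
dwellings (*gers*) and immobile self-built houses (*bashins*) on fenced
land plots (*khashaas*). It provides three layers:

1. **A finite-horizon stochastic dynamic program.** A household is
   described by four state variables — house (mobile/fixed), savings
   (no/yes), tenure (no/yes), family (single/couple/dependants) — giving
   24 configurations. Each step the household enacts one of three
   behaviours whose outcomes are probabilistic, and is exposed to two
   shocks (losing savings; forced relocation while untenured). Family
   size advances only indirectly, helped by a house and tenure and
   hindered by held savings. Backward induction over a 40-step adult
   lifespan maximizes the expected terminal pay-off

   `V_T(s) = R(s)`,  `V_t(s) = max_b Σ_s' P(s'|s,b) V_{t+1}(s')`

   for four terminal pay-off scenarios `R` (material baseline, family
   priority, additive, house priority), yielding a 2×2×2×3×40 policy
   tensor. Ties favour saving.

2. **A forward simulator.** Agent populations enact the policy,
   producing longitudinal trajectories, behaviour-frequency curves,
   cross-sections matching a household-survey schema and the four
   dwelling-transition categories (ger–ger, ger–bashin, bashin–ger,
   bashin–bashin), plus the 1944-combination theoretical parameter
   sweep.

3. **ABC with importance weighting.** The generative pipeline is fitted
   to cross-sectional data by comparing an 11-component summary
   statistic (4 transition counts + savings, tenure and family
   marginals) between simulated and reference data, weighting each prior
   draw by `w ∝ exp(−Σ|sim − ref|)` and resampling. Includes HPDI
   computation, posterior predictive checks and parameter-recovery
   validation on synthetic references.

## Worked example

```python
import settleopt as so

params = so.ModelParams(
    p_s_save=0.5, p_h_build=0.5, p_l_move=0.5,
    p_s_loss=0.25, p_force_move=0.25,
    build_condition=1,            # savings are required (and spent) to build
    payoff_scenario="additive",   # all four states rewarded equally
)
policy, values = so.solve(params)

start = so.StateConfig.from_labels("mobile", "none", "none", "couple")
print("optimal first behaviour:", policy.behaviour(start, 0).name)
print("expected terminal pay-off:", round(values.value(start, 0), 3))

sim = so.simulate(policy, params, n=100, seed=42)
print(so.behaviour_frequencies(sim).iloc[[0, 20, 39]])
```

prints

```
optimal first behaviour: MOVE
expected terminal pay-off: 0.9
    time  save  build  move  active
0      0    27     29    44     100
20    20    97      3     0     100
39    39   100      0     0     100
```

A newly arrived untenured couple in a ger should first try to move to
secure tenure; a household following the optimal strategy can expect
90% of the maximal terminal pay-off. At the population level, moving
and building dominate early residence years while saving takes over
later — saving counts rise from 27 of 100 households at step 0 to all
100 by the final step.

The inference layer runs the same pipeline in reverse — from data to
parameters:

```python
times = so.generate_time_structure(825, seed=1)          # residence years, 1..40
ref = so.generate_reference_dataset(params, times, seed=2)
result = so.run_abc(so.summarize(ref), n_draws=10_000, times=times, seed=3)
posterior = so.posterior_sample(result, m=1000, seed=4)
print(posterior["p_s_save"].median(), so.hpdi(posterior["p_s_save"], mass=0.89))
```

A command-line interface mirrors the library
(`settleopt solve | simulate | sweep | make-synthetic | abc-run |
abc-validate | posterior-predict`); every command writes CSV artifacts
and a JSON manifest with the resolved configuration and master seed.

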