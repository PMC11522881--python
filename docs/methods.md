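# Methods

## The decision model

A household is described by four state variables: house `h ∈ {mobile,
fixed}`, savings `s ∈ {none, has}`, tenure `l ∈ {none, has}` and family
`f ∈ {single, couple, family with dependants}` — 24 configurations,
indexed house-major so that (mobile, none, none, single) is index 0.
Time runs in 40 discrete steps, representing the span of adult
decision-making. There is no discounting and no per-step reward: a
single terminal pay-off `R(s) ∈ [0, 1]` is accrued at the horizon.

Each step the household enacts exactly one behaviour, then experiences
shocks and a family event, in this fixed within-step order:

1. **Behaviour.** *Save*: if without savings, gain them with probability
   `p_s_save`. *Build*: if in a mobile dwelling — and, when the build
   condition BC = 1, only if savings are held — gain a fixed house with
   probability `p_h_build`; under BC = 1 a successful build consumes the
   savings (a failed attempt does not). *Move*: with probability
   `p_l_move` the household relocates — the house state falls back to
   mobile — and gains tenure. A household that moves while already
   tenured still relocates; tenure is kept. A failed move changes
   nothing (the household does not move).
2. **Savings-loss shock.** Held savings are lost with probability
   `p_s_loss` (this applies to savings gained in step 1 of the same
   step).
3. **Forced-move shock.** A household without tenure (after step 2) is
   forcibly relocated with probability `p_force_move`: the house state
   falls to mobile, and tenure is gained with probability `p_l_move`.
4. **Family growth.** Family advances one level (capped at the top)
   with probability

   `clamp(base · (1 + b_h·h₀ + b_l·l₀) · (π_s if s₀ else 1))`

   where `h₀, l₀, s₀` are read from the **start-of-step** state.
   Defaults: base 0.1, house bonus `b_h` = 1, tenure bonus `b_l` = 1,
   savings penalty `π_s` = 0.5, so the per-step probability ranges over
   0.05–0.3. Start-of-step covariates mean the current decision cannot
   influence family growth within its own step — which is why, at the
   final decision step, no behaviour can affect a family-only pay-off
   and all three behaviours tie. The source text fixes only the
   direction of these effects; the magnitudes are this package's
   defaults, chosen so that family growth plays out over a 40-step
   lifetime rather than saturating immediately, and they are fully
   configurable.

The event order (behaviour → savings loss → forced move → family) is a
design choice where the source description is silent; fixing it makes
the kernel a well-defined total function. The kernel is computed
exactly, by composing per-event 24×24 transition matrices; the test
suite re-derives it leaf-by-leaf from the event tree with independent
code.

## Terminal pay-off scenarios

All four scenarios are weighted sums `w_h·h + w_s·s + w_l·l + w_f·(f/2)`
with non-negative weights normalized to 1, so every table spans exactly
[0, 1]:

| scenario | w_h | w_s | w_l | w_f | rewards |
|---|---|---|---|---|---|
| material_baseline | 0 | .5 | .5 | 0 | savings and tenure only |
| family_priority | 0 | 0 | 0 | 1 | family level only |
| additive | .25 | .25 | .25 | .25 | every state equally |
| house_priority | .6 | .15 | .25 | 0 | house foremost; best with tenure and savings; family-insensitive |

The published bar charts give orderings but not magnitudes; these
weights reproduce every stated ordering (e.g. under house priority,
house+tenure+savings ≻ house+tenure ≻ house alone) and can be
overridden per run.

## Solver

Backward induction with exact expectations (matrix products against the
kernel tensor). Ties are declared at an absolute tolerance of 1e−12 —
values are finite sums of products of probabilities, so genuine ties
are exact — and broken deterministically in the order save ≻ build ≻
move. "Saving is prioritized" is the modelled rule; the secondary
build ≻ move order is fixed only for determinism and is configurable in
effect through the behaviour ordering. A brute-force recursion with no
memoization (horizon ≤ 4) serves as the solver's oracle.

A structural consequence worth knowing: in any state whose value is
behaviour-invariant — family at its top level under a family-only
pay-off, or savings already held in a fixed house — all behaviours tie
and the policy prescribes save. Populations simulated under the family
priority scenario therefore *do* show pre-terminal saving once agents
absorb into those states; the claim "nobody saves before the terminal
step" holds only outside them.

## Forward simulation

Agents are initialized uniformly over the state space (or with the
house state pinned to mobile, matching newly arriving households), then
enact the policy step by step, sampling the same event sequence the
kernel defines. Sampling is vectorized over agents from a single seeded
generator per run; sweep and ABC units of work derive independent
streams from `SeedSequence(seed, spawn_key=...)`, so multi-run results
do not depend on execution order. Agents past their stay length are
frozen and excluded from behaviour-frequency denominators.

The theoretical sweep is the Cartesian grid {0.25, 0.5, 0.75}⁵ × BC
{0, 1} × 4 scenarios = 1944 combinations, by default 100 agents × 40
steps × 10 replicates, streamed to CSV with a resumable manifest.
Stay lengths for transition plots are drawn uniformly on 1..40 (the
distribution behind the published plots is unstated).

## Synthetic reference data

The generator emulates an 825-household cross-sectional survey:
residence times come from a mixture of arrival years — 90% uniform
1990–2020 (the post-deregulation influx), 10% uniform 1942–1989 —
converted relative to reference year 2020 and coerced into [1, 40]
(households resident longer than 40 years are treated as having run
their full decision-making lifetime). Each household is simulated to
its residence time and recorded with savings, tenure, family, first and
current dwelling and the implied transition category. The published
marginal tables (savings 521/304, tenure 247/578, family 57/81/687,
housing 375/450, transitions 349/264/26/186) ship as a fixture standing
in for the deposited per-household data.

What synthetic data does *not* emulate: real household heterogeneity
(mixed strategies, intended stay, apartment exit), non-random
missingness, or the deposited dataset's exact residence-time
distribution. Passing recovery tests therefore demonstrate correctness
of the inference machinery on model-generated data, not fidelity of the
model to Ulaanbaatar.

## ABC with importance weighting

Five parameters are inferred: `p_s_save` ~ Beta(2, 5) (mode 0.2),
`p_l_move` ~ Beta(2, 2) (mode 0.5), `p_h_build` ~ Beta(5, 2) (mode
0.8), P(BC = 1) = 0.7, and a flat prior over the four pay-off
scenarios. Beta shapes are chosen to match the stated prior modes (the
shapes themselves are not published); the BC prior value and the
inclusion of the material baseline in the flat scenario prior are
configurable. The two shock probabilities are held fixed at 0.25
during inference (their effects mirror `p_s_save` and `p_l_move`; the
values used in the original analysis are unpublished).

Each draw simulates one household per reference residence time,
producing the 11-component summary (four transition counts; savings,
tenure and family marginals — house marginals are excluded as the
transition categories already encode them). The distance is the sum of
*absolute* component differences on counts (a signed sum would cancel);
a proportion mode is available when simulated and reference sample
sizes differ. Weights are `exp(−(d − min d))` normalized to sum to 1 —
identical after normalization to `exp(−d)` but immune to underflow.
Posterior samples (default 1000) are drawn with replacement under these
weights; intervals are 89% HPDIs (narrowest contiguous window of the
sorted samples).

**Known limitation — weight degeneracy at small draw counts.** With
count distances, a one-unit count difference changes a weight e-fold,
so the weight mass concentrates on the few draws nearest the minimum
distance. At production scale (~10⁶ draws against 825 households) many
draws sit within O(1) of the minimum and the posterior is well spread;
at desk scale (e.g. 5000 draws against 200 households, the size used in
the tests and acceptance script) the effective sample size often falls
to single digits. Point estimates remain good — posterior medians of
`p_s_save` beat the prior median in essentially every recovery
replicate — but HPDIs collapse toward zero width and under-cover the
truth. This is a property of the published weighting scheme at reduced
scale, not of the implementation. `p_l_move` and especially `p_h_build`
are weakly identified (tenure saturates through forced moves; building
outcomes are censored by the policy), consistent with the original
study's own validation.

Recovery experiments use truths on the sweep grid displaced from the
prior medians (e.g. `p_s_save` = 0.5 against a prior median of 0.26)
so that "posterior beats prior" is informative; a truth at the prior
median would make that comparison a coin flip.

## Problem sizes

The shipped tests and the acceptance script use: full 486-combination
probability grid for the material-baseline logic check (100 agents
each); 10,000 agents for Monte-Carlo value consistency; 5000 draws ×
200 households × 5–10 replicates for ABC recovery; horizon-3 exhaustive
enumeration for solver verification. Production-scale runs (10⁶ draws,
20-truth validation at 100,000 candidates, 1000-dataset posterior
predictive distributions) use the same code paths via the documented
defaults and the CLI.

## Degenerate inputs and edge cases

Zero agents, empty datasets and single-draw ABC runs are handled
explicitly (empty series, errors, unit weight respectively). Residence
times outside [1, horizon] are rejected at the API boundary and coerced
only in the arrival-year converter. Probabilities are validated on
construction; family level never decreases; a build attempt without the
required savings is a no-op rather than an error.
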