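# Methods

## The generative model

`cbtsim` models a person deciding whether to approach or avoid a feared but
objectively harmless stimulus as a discrete-state active-inference (POMDP)
agent.  A trial spans T = 4 time points.  Hidden states factorize into

| factor | levels | role |
|---|---|---|
| `stimulus` | no_spider, spider | whether the feared stimulus is present |
| `safety_belief` | dangerous, safe | the explicit, reportable appraisal |
| `behavior` | start, observe, approach, interact, avoid, safety_cost | the controllable behavioral state |

and outcomes arrive over four modalities: the perceived stimulus,
interoceptive arousal (low/high), the affective consequence of action
(positive affect, negative affect, serious harm, plus a neutral pre-choice
placeholder), and a veridical readout of the agent's own action.  Exactly two
policies exist: approach (start → observe → approach → interact) and avoid
(start → observe → avoid → safety + cost).  Transitions for the stimulus and
safety-belief factors are identity maps — within a trial, perception cannot
change what is there or what the person explicitly believes about it; only
learning between trials can.

The likelihood mapping `A` carries the cognition–affect–behavior (CAB)
interaction.  Under a danger belief, approaching predicts negative affect and
interacting predicts serious harm.  Under a safe belief those columns are
softened by the interaction strength `cab_i` ∈ [0, 1]: approach predicts
positive affect with probability `cab_i` (else negative affect), interact
predicts positive affect with probability `cab_i` (else serious harm).  At
`cab_i = 0` a safe belief predicts exactly what a danger belief predicts —
explicit cognition has no purchase on affect or behavior.  In the default
`belief_modulated` arousal dialect the same interaction governs arousal at
approach/interact (low with probability `cab_i` under a safe belief, high
under danger); a `literal_text` dialect makes arousal belief-independent
except for the surprise response on first observing the spider and during
flight.  First observing the spider always produces a burst of high arousal;
fleeing produces high arousal and negative affect; reaching safety produces
low arousal but negative affect (the opportunity cost of avoidance).

Preferences are raw values softmax-normalized per modality and taken in log
space: serious harm −12, negative affect −1, high arousal −1, everything else
0.  They are constant over the four time steps.

The pre-choice states (start, observe) emit a fourth, *neutral* consequence
level with preference 0.  This keeps the pre-choice steps from providing
spurious evidence about safety: with only three consequence levels those
steps would have to emit one of the affect outcomes and thereby load the
inference before any choice is made.  A config switch
(`pre_choice_outcome="positive_affect"`) exposes the alternative mapping.

## Within-trial computation

Because the uncontrolled factors have identity transitions and behavior is
fully determined by the policy, the state posterior is exact: direct Bayes
over the four (stimulus × safety) joint states given all observations so far
and the policy's behavioral trajectory.  A mean-field coordinate-ascent
scheme (`infer_states_variational`) is provided as an independent route; on
this model the two agree to ≤ 1e-6 because the factors never conflict — the
stimulus is either unobserved (flat likelihood) or resolved exactly by the
veridical stimulus modality — and the test suite enforces the equivalence.

Policies are scored by expected free energy accumulated over the remaining
time steps and all modalities,

    G(π) = Σ_τ Σ_m  KL(o_pred ∥ C̃_m)  +  E_q[H(A_m)]  −  novelty,

where `o_pred` is the predicted outcome distribution under the current
posterior, `C̃` the softmax preference distribution, the middle term the
expected conditional entropy of the likelihood (ambiguity), and novelty the
expected information gain over Dirichlet counts, 0.5·Σ A·(1/a − 1/a₀),
active whenever counts are in play.  The policy posterior is
`softmax(ln E − F − γ·G)` with `F` the accumulated negative log evidence per
policy (equal across policies before the choice point, since the policies
share their first two states) and `E` the prior over policies.  Actions are
sampled from the marginal over next actions implied by the policy posterior;
an optional `alpha_action` resharpens that marginal (default: none — the
policy precision γ is the single source of decision noise).

Exposure is implemented as a highly precise prior over policies,
E = (1 − ε, ε) on approach with ε = 1e-15 by default.  ε must satisfy
ln((1−ε)/ε) > γ·ΔG₀, where ΔG₀ ≈ 11 nats is the initial expected-free-energy
gap under a strong danger prior; with the default γ this requires
ε ≲ 1e-12, and 1e-15 leaves margin.  A `response_prevention` mode that masks
the avoid branch outright is available as an alternative forcing mechanism.

The generative process (the "true world") is deterministic: the spider is
present and harmless; approach and interact yield positive affect and low
arousal; avoidance yields high arousal, negative affect, and then the
safety + cost outcomes.  It emulates a canonical exposure session distilled
to its logical skeleton.  Real exposure involves stochastic, graded outcomes,
habituation within sessions, and context shifts between them; none of these
are modeled, so passing tests say nothing about, e.g., optimal session
spacing or partial-reinforcement effects.

## Between-trial learning

Implicit beliefs are Dirichlet concentration counts `a` on the arousal and
action-consequence modalities; explicit beliefs are counts `d` on the
stimulus and safety-belief priors.  The identity modalities and the behavior
factor are treated as veridical and not learned.  After each trial, for every
time step and learned modality, the count cell selected by the observed
outcome and visited behavioral state gains `eta_a` times the smoothed
(stimulus × safety) posterior, and `d` gains `eta_d` times the smoothed
initial-state posterior (identical to the final posterior here, by the
identity transitions).  Normalized counts refresh the agent's `A` and `D`, so
the agent always acts on its current beliefs.

Counts are initialized from `base_scale · A`, with one modification: an
**implicit-association leak** `cab_leak` (default 0.1).  The danger-context
approach/interact columns are built as if the CAB interaction were `cab_leak`
rather than zero, and the safe-context columns at `max(cab_i, cab_leak)` —
conditioned danger associations never assign exactly zero probability to
benign outcomes.  The leak is what makes the model's two learning routes
separable.  When `cab_i` is at or below the leak, the two explicit-belief
contexts make identical outcome predictions, so benign exposure outcomes
carry no evidence about safety versus danger: explicit beliefs stay where
cognitive restructuring left them and the outcome counts are credited to both
contexts in proportion to the prior — behavior change by *over-writing* the
implicit associations, which survives a later return of danger thoughts.
When `cab_i` is well above the leak, benign outcomes are strong evidence for
the safe context: the explicit prior shifts, counts concentrate on the safe
columns, and the danger-context associations remain intact — behavior change
that collapses if danger thoughts return.  Without the leak, an outcome the
danger context rules out entirely would constitute effectively unbounded
evidence for safety, and every condition would collapse onto the explicit
route.  With `cab_leak = 0` (and the optional uniform pseudocount floor
`a_floor = 0`) the initialization reduces exactly to `base_scale · A`.

## Experiments

* `simulate_single_trial` — one free-choice trial, learning off.
* `approach_rate_sweep` — free-choice approach percentage over a
  (P(safe), CAB-i) grid, learning off (novelty off too, since there are no
  counts to learn).
* `exposure_experiment` — forced-approach trials with learning, probed at
  requested exposure lengths by free-choice trials whose count updates are
  frozen (probing more densely therefore cannot change what is learned; the
  novelty drive stays on, as in any learning-enabled trial).  "Consistent
  approach" is operationalized as ≥ 95 % approach over 50 probe repetitions —
  the published curves never define the criterion, so this is the package's
  choice.
* `generalization_test` — reset the explicit prior to a reinstated danger
  level while keeping the learned counts, then probe.
* `consecutive_avoidance_run` — free choice with learning on; counts the
  initial avoidance streak of the untreated agent.

All randomness flows from one integer seed through named `SeedSequence`
substreams keyed by (experiment, condition, repetition index), so enlarging a
grid or adding repetitions never reshuffles earlier draws, and every
experiment is bit-reproducible.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `danger` | per experiment | probability | explicit prior P(dangerous); the cognitive-restructuring dial |
| `cab_i` | per experiment | dimensionless [0, 1] | strength of cognition→affect/behavior coupling |
| preferences (harm, negative, high arousal) | −12, −1, −1 | log-preference units | fixed model constants |
| `gamma` | 2.5 | dimensionless | policy precision ("moderate decision noise"); calibrated, see below |
| `alpha_action` | none | dimensionless | extra action precision; off — γ is the single noise source |
| `exposure_eps` | 1e-15 | probability | residual avoid-prior during forcing; must beat γ·ΔG₀ (see above) |
| `base_scale` | 2.0 | counts | prior precision of implicit beliefs |
| `base_scale_d` | 10.0 | counts | prior precision of explicit beliefs |
| `eta_a` | 0.155 | counts/observation | implicit learning rate |
| `eta_d` | 0.24 | counts/trial | explicit learning rate |
| `cab_leak` | 0.1 | probability | implicit-association leak (see above) |
| `a_floor` | 0 | counts | optional uniform pseudocount floor on approach/interact columns |
| `approach_criterion` | 0.95 | proportion | "consistent approach" over 50 probes |

The learning magnitudes and γ were calibrated once, jointly, against a single
anchor — the strong-danger, weak-CAB condition reaching the approach
criterion at roughly 100 exposure trials — and then left fixed for every
other condition and experiment.  γ also has to sit in a window: large enough
that the post-learning approach preference clears the 0.95 criterion on the
steep part of its curve (γ ≳ 2, or the criterion crossing rides a flat
asymptote and its location is dominated by binomial probe noise), and small
enough that the exposure prior still forces approach (see `exposure_eps`).

## Numerical choices

* All likelihood log operations floor probabilities at 1e-16, so degenerate
  parameter settings (danger = 0 or 1) remain finite.
* Prior zeros are *not* floored: a state the prior rules out stays ruled out
  (log prior −inf), so fully precise explicit beliefs are absorbing even
  under evidence the model deems impossible.
* Policies inconsistent with actions already executed are masked out of the
  policy posterior (their F would diverge anyway; masking avoids relying on
  floor arithmetic).
* The variational route iterates coordinate ascent to a 1e-12 fixed-point
  tolerance, max 500 iterations.
* Ties in action sampling are impossible in practice (probabilities are
  continuous); the sampler draws from the exact marginal.

## What the model reproduces, and known limitations

With the single calibration above, the packaged tests and
`scripts/acceptance.py` compute: an untreated avoidance streak covering every
free-choice trial run (150/150); criterion exposure lengths of roughly
80–100 trials (across seeds) in both the weak-CAB (implicit route) and
strong-CAB (explicit route) strong-danger conditions; a moderate-CAB
condition that is consistently the slowest of the three (110–150); and an
uncertain-prior weak-CAB condition at 120–180 trials.
The qualitative dissociations all hold and are tested: explicit beliefs stay
flat at weak CAB while the danger-context associations are over-written
(exactly flat at the uncertain prior, by the leak's evidence symmetry);
explicit beliefs climb at moderate/strong CAB while danger-context
associations stay put; approach collapses under reinstated danger after the
explicit route but persists after the implicit route; approach rates rise
with P(safe) and the rise is attenuated as CAB-i falls.

Two quantitative features of the original report are *not* reproduced, and
the corresponding acceptance tests are left failing rather than tuned around.
First, the moderate-CAB criterion length here is ~1.4× the strong-CAB length,
not ~2×: in this implementation the extra cost of the moderate condition is
relearning a half-informative safe column, which is bounded by the harm-mass
ratios the CAB-i formula fixes.  Second, the uncertain-prior weak-CAB
condition is not faster than the strong-danger weak-CAB condition (let alone
under 50 trials): with the prior split evenly, counts and decision weight are
split evenly across the two context columns, so criterion crossing needs the
same per-column count mass at roughly half the accrual rate.  Both are
structural properties of Dirichlet-count learning on this architecture, not
calibration artifacts; closing them would require additional mechanisms
(e.g., uncertainty-dependent learning rates, which the model deliberately
omits).

Beyond that, the model inherits the scope limits of its design: a single
binary explicit appraisal rather than rich clinical cognition; no habit
learning on `E`, no dynamic learning rates, no policy-precision manipulation
as a therapy mechanism; one environmental context; and a deterministic,
always-benign world.
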