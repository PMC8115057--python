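# cbtsim

Active-inference simulations of cognitive and behavioral therapy for
maladaptive avoidance.

`cbtsim` is a small research tool for computational psychiatry.  It implements
a discrete-state active-inference (POMDP) agent that models a patient
confronting a feared but objectively safe stimulus — spider phobia is the
running example, but the structure is generic to phobic and anxious avoidance —
and simulation protocols for the two classic CBT interventions:

* **cognitive restructuring**, modeled as setting the explicit prior belief
  that the stimulus is dangerous vs. safe (`danger` ∈ [0, 1]);
* **exposure**, modeled as blocks of forced approach trials during which the
  agent learns from what it observes.

The point of the model is to separate *two belief systems* that can each
produce the same behavior change: explicit (reportable) safety beliefs, held
as the prior `D` over a safety/danger state, and implicit (associative)
expectations about the outcomes of approach and avoidance, held as Dirichlet
counts on the likelihood mapping `A`.  How strongly explicit beliefs shape the
predicted outcomes of action is governed by a single
cognition–affect–behavior interaction parameter, CAB-i ∈ [0, 1]:

    P(consequence | approach, safe)  = (CAB-i, 1 − CAB-i, 0)
    P(consequence | interact, safe)  = (CAB-i, 0, 1 − CAB-i)

over (positive affect, negative affect, serious harm), while danger beliefs
predict negative affect when approaching and serious harm when interacting.

## The model

Each trial has 4 time steps over three hidden-state factors — stimulus
(no spider / spider), explicit safety belief (dangerous / safe), and a
six-level behavioral state (start → observe → approach → interact, or
start → observe → avoid → safety + cost) — and four outcome modalities
(observed stimulus, arousal, action consequence, observed action).  Two
policies (approach, avoid) are scored by expected free energy

    G(π) = Σ risk + ambiguity − novelty
    q(π) = softmax( ln E − F(π) − γ·G(π) )

with risk the KL divergence from predicted outcomes to softmax-normalized
preferences (serious harm −12, negative affect and high arousal −1, all else
0, in log-preference units), ambiguity the expected outcome entropy, and
novelty the expected information gain over Dirichlet counts.  State inference
is exact (enumeration over the four stimulus × safety joint states); a
mean-field variational scheme is included and tested to agree with it.
Between trials, outcome counts update the likelihood (implicit beliefs,
learning rate `eta_a`) and initial-state counts update the safety prior
(explicit beliefs, `eta_d`).  See `docs/methods.md` for the full account.

## Worked example

A patient before therapy (precise danger belief, strong CAB interactions)
meets a harmless spider:

```python
from cbtsim import simulate_single_trial
from cbtsim.model import CBTParams, BEHAVIOR_LEVELS, AROUSAL_LEVELS
from cbtsim.protocols import substream

trial = simulate_single_trial(CBTParams(danger=1.0, cab_i=0.9), substream(1, 9))
print([BEHAVIOR_LEVELS[b] for b in trial.behaviors])
print([AROUSAL_LEVELS[a] for a in trial.arousal_trace])
print(float(trial.beliefs[1].policy_posterior[0]))
```

```
['start', 'observe', 'avoid', 'safety_cost']
['low', 'high', 'high', 'low']
9.357622968839333e-14
```

The agent observes the spider (surprise arousal at step 2), assigns the
approach policy essentially zero posterior probability, flees (arousal stays
high while running away), and reaches safety at an opportunity cost
(negative affect, low arousal).  Because it always avoids, it never sees the
observations that could correct either belief system — untreated avoidance is
self-sustaining.

Exposure changes that.  Forcing approach for increasing numbers of trials and
then probing free choice (50 frozen-learning probes per length):

```python
from cbtsim import ExperimentConfig, exposure_experiment, exposure_length_to_criterion

cfg = ExperimentConfig(danger_prior=0.9, cab_i=0.9, seed=1)
res = exposure_experiment(cfg)
print(res.table[["exposure_length", "approach_rate", "p_safe_explicit"]].round(3))
print(exposure_length_to_criterion(res))
```

```
 exposure_length  approach_rate  p_safe_explicit
               0           0.00            0.100
              10           0.00            0.274
              25           0.02            0.437
              50           0.16            0.591
              75           0.86            0.678
             100           0.98            0.735
             150           1.00            0.804
             200           1.00            0.845
100
```

(Approach rate is the proportion of probe trials on which the agent chose to
approach; `p_safe_explicit` is the normalized explicit prior.  The criterion
length — the smallest exposure at which ≥ 95 % of probes approach — is 100
trials here.)  With strong CAB interactions the behavior change rides on the
explicit belief, which climbs from 0.1 toward 1; reinstating a danger prior
afterwards (`generalization_test(model, store, reinstated_danger=0.9)`)
collapses approach back to 0.0 — the classic relapse vulnerability.  Repeat
the experiment with `cab_i=0.1` and the opposite happens: explicit beliefs
barely move, the implicit danger associations are over-written instead, and
approach survives reinstated danger thoughts.

The same experiments are available from the shell:

```bash
cbtsim simulate examples/single_trial.yaml --out results/trial
cbtsim simulate examples/exposure.yaml --out results/exposure
cbtsim simulate examples/sweep.yaml --out results/sweep
cbtsim figures results/sweep
```

Each run writes tidy CSVs plus a `manifest.json` embedding the seed and a
hash of the full configuration; identical config and seed give byte-identical
outputs.

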