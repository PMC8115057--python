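"""Within-trial perception, policy evaluation, and action selection.

A trial spans ``T = 4`` time points.  At each step the agent receives one
outcome per modality from the generative process (:class:`WorldProcess`),
updates its posterior over the hidden ``(stimulus, safety_belief)`` joint for
each policy, scores the two allowable policies by expected free energy

    G(pi) = sum over future steps and modalities of  risk + ambiguity - novelty

where risk is the KL divergence from predicted outcomes to the (softmax)
preference distribution, ambiguity the expected conditional entropy of the
likelihood, and novelty the expected information gain over Dirichlet counts
(active only when likelihood learning is in play), and forms the policy
posterior

    q(pi) = softmax( ln E - F(pi) - gamma * G(pi) )

with F the variational free energy (negative log evidence) accumulated by the
policy.  Actions are sampled from the marginal over next actions implied by
q(pi).

Because the uncontrolled factors have identity transitions and the behavioral
trajectory is fully determined by the policy, state inference is *exact*:
direct enumeration over the four ``(stimulus, safety)`` joint states.  A
mean-field variational scheme is provided as an independent route and agrees
with enumeration on this model (the two factors are never in conflict: the
stimulus is either unobserved, leaving the likelihood flat, or resolved
exactly by the veridical stimulus modality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.special import logsumexp, softmax

from .model import (
    APPROACH,
    APPROACH_POLICY,
    AVOID,
    HIGH,
    INTERACT,
    LOW,
    NEGATIVE,
    NEUTRAL,
    NO_SPIDER,
    OBSERVE,
    POSITIVE,
    SAFETY_COST,
    SPIDER,
    START,
    GenerativeModel,
    floored_log,
)

if TYPE_CHECKING:  # pragma: no cover
    from .learning import DirichletStore

__all__ = [
    "WorldProcess",
    "BeliefState",
    "PolicyEvaluation",
    "TrialRecord",
    "generate_observation",
    "infer_states_exact",
    "infer_states_variational",
    "expected_free_energy",
    "policy_posterior",
    "select_action",
    "run_trial",
    "EXPOSURE_PRIOR_EPS",
]

#: default residual prior mass on the avoid policy during forced exposure
EXPOSURE_PRIOR_EPS = 1e-15


# ---------------------------------------------------------------------------
# generative process (the true world)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorldProcess:
    """The true world: a spider is present and objectively safe.

    Emissions are deterministic given the behavioral state; no harm is ever
    delivered.  ``pre_choice_outcome`` mirrors the agent's convention for the
    consequence emitted before any approach/avoid choice has been made.
    """

    spider_present: bool = True
    pre_choice_outcome: int = NEUTRAL

    def observe(self, behavior_state: int, t: int) -> tuple[int, int, int, int]:
        return generate_observation(self, behavior_state, t)


def generate_observation(world: WorldProcess, behavior_state: int, t: int) -> tuple[int, int, int, int]:
    """Outcomes (stimulus, arousal, consequence, observed action) for one step.

    ``t`` is the 1-based time point within the trial.
    """
    if not 1 <= t <= 4:
        raise ValueError(f"t must be in 1..4, got {t}")
    stim = SPIDER if (world.spider_present and behavior_state != START) else NO_SPIDER
    pre = world.pre_choice_outcome
    if behavior_state == START:
        return (NO_SPIDER, LOW, pre, START)
    if behavior_state == OBSERVE:
        surprise = HIGH if world.spider_present else LOW
        return (stim, surprise, pre, OBSERVE)
    if behavior_state in (APPROACH, INTERACT):
        return (stim, LOW, POSITIVE, behavior_state)
    if behavior_state == AVOID:
        return (stim, HIGH, NEGATIVE, AVOID)
    if behavior_state == SAFETY_COST:
        return (stim, LOW, NEGATIVE, SAFETY_COST)
    raise ValueError(f"unknown behavioral state {behavior_state}")


# ---------------------------------------------------------------------------
# state inference
# ---------------------------------------------------------------------------


def _policy_behavior_trajectory(model: GenerativeModel, policy: Sequence[int]) -> list[int]:
    return [START, *list(policy)]


def _log_prior(d: np.ndarray) -> np.ndarray:
    """True log prior: exact zeros stay -inf so degenerate priors are absorbing.

    Only likelihoods are floored; a state the prior rules out cannot be
    resurrected by floor-level likelihood mismatches elsewhere.
    """
    with np.errstate(divide="ignore"):
        return np.log(d)


def infer_states_exact(
    model: GenerativeModel,
    observations: Sequence[Sequence[int]],
    policy: Sequence[int],
) -> tuple[np.ndarray, float]:
    """Exact posterior over the (stimulus, safety) joint under one policy.

    Direct Bayes by enumeration of the four joint states, conditioning on all
    observations received so far and the behavioral trajectory the policy
    implies.  Returns ``(q_joint, F)`` where ``q_joint`` has shape (2, 2) and
    ``F`` is the negative log evidence of the observation sequence.
    """
    traj = _policy_behavior_trajectory(model, policy)
    log_joint = _log_prior(model.D[0])[:, None] + _log_prior(model.D[1])[None, :]
    for t, obs in enumerate(observations):
        b = traj[t]
        for m, o in enumerate(obs):
            log_joint = log_joint + floored_log(model.A[m][o, :, :, b])
    log_evidence = logsumexp(log_joint)
    q = np.exp(log_joint - log_evidence)
    return q / q.sum(), float(-log_evidence)


def infer_states_variational(
    model: GenerativeModel,
    observations: Sequence[Sequence[int]],
    policy: Sequence[int],
    *,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Mean-field (coordinate-ascent) posterior over (stimulus, safety).

    Independent route used to cross-check :func:`infer_states_exact`; returns
    the outer product of the factor marginals and the variational free energy.
    """
    traj = _policy_behavior_trajectory(model, policy)
    # accumulated log-likelihood tensor over the joint, shape (2, 2)
    ll = np.zeros((2, 2))
    for t, obs in enumerate(observations):
        b = traj[t]
        for m, o in enumerate(obs):
            ll = ll + floored_log(model.A[m][o, :, :, b])
    log_d0 = _log_prior(model.D[0])
    log_d1 = _log_prior(model.D[1])
    q0 = model.D[0].copy()
    q1 = model.D[1].copy()
    for _ in range(max_iter):
        new0 = softmax(log_d0 + ll @ q1)
        new1 = softmax(log_d1 + new0 @ ll)
        delta = max(np.abs(new0 - q0).max(), np.abs(new1 - q1).max())
        q0, q1 = new0, new1
        if delta < tol:
            break
    q = np.outer(q0, q1)
    # F = E_q[ln q - ln p(o, s)]; 0 * (-inf) terms from zero-prior states vanish
    eps = 1e-300
    with np.errstate(invalid="ignore"):
        kl0 = np.where(q0 > 0, q0 * (np.log(q0 + eps) - log_d0), 0.0)
        kl1 = np.where(q1 > 0, q1 * (np.log(q1 + eps) - log_d1), 0.0)
    F = float(np.sum(kl0) + np.sum(kl1) - np.sum(q * ll))
    return q, F


# ---------------------------------------------------------------------------
# expected free energy
# ---------------------------------------------------------------------------


@dataclass
class PolicyEvaluation:
    """Per-policy expected free energy and its decomposition (nats)."""

    G: np.ndarray
    risk: np.ndarray
    ambiguity: np.ndarray
    novelty: np.ndarray
    F: np.ndarray

    def __post_init__(self):
        for name in ("G", "risk", "ambiguity", "novelty", "F"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")


def _novelty_weights(counts: np.ndarray) -> np.ndarray:
    """Expected information gain per (outcome, state) cell of a count array.

    Standard Dirichlet novelty: W = 0.5 * (1/a - 1/a0) per cell, where a0 is
    the column total; the per-state bonus is sum_o A[o, s] * W[o, s] >= 0.
    """
    with np.errstate(divide="ignore"):
        inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1e-300), 0.0)
    col = counts.sum(axis=0, keepdims=True)
    inv_col = np.where(col > 0, 1.0 / np.maximum(col, 1e-300), 0.0)
    return 0.5 * (inv - inv_col)


def expected_free_energy(
    model: GenerativeModel,
    policy: Sequence[int],
    q_joint: np.ndarray,
    t: int,
    *,
    store: "DirichletStore | None" = None,
    include_novelty: bool = False,
) -> tuple[float, float, float, float]:
    """Expected free energy of one policy from the perspective of time ``t``.

    Sums risk, ambiguity, and (optionally) a novelty bonus over the remaining
    steps ``t+1 .. T`` and all modalities.  ``t`` is 1-based; the posterior
    ``q_joint`` is over (stimulus, safety), which is constant over time under
    the identity transition maps.  Returns ``(G, risk, ambiguity, novelty)``
    with ``G = risk + ambiguity - novelty``.
    """
    traj = _policy_behavior_trajectory(model, policy)
    risk = 0.0
    ambiguity = 0.0
    novelty = 0.0
    for tau in range(t, model.T):  # future time points (0-based index tau)
        b = traj[tau]
        for m in range(model.n_modalities):
            A_slice = model.A[m][:, :, :, b]  # (n_o, 2, 2)
            o_pred = np.tensordot(A_slice, q_joint, axes=([1, 2], [0, 1]))
            risk += float(np.sum(o_pred * (floored_log(o_pred) - model.C[m])))
            H = -np.sum(A_slice * floored_log(A_slice) * (A_slice > 0), axis=0)
            ambiguity += float(np.sum(q_joint * H))
            if include_novelty and store is not None and m in store.a:
                W = _novelty_weights(store.a[m][:, :, :, b].reshape(A_slice.shape[0], -1))
                W = W.reshape(A_slice.shape)
                novelty += float(np.sum(A_slice * W * q_joint[None, :, :]))
    G = risk + ambiguity - novelty
    return G, risk, ambiguity, novelty


def policy_posterior(
    G: np.ndarray,
    F: np.ndarray,
    E: np.ndarray,
    gamma: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior over policies: softmax(ln E - F - gamma * G), masked.

    ``mask`` marks policies consistent with the actions already executed.
    """
    logits = floored_log(np.asarray(E, dtype=float)) - np.asarray(F) - gamma * np.asarray(G)
    if mask is not None:
        logits = np.where(mask, logits, -np.inf)
    logits = logits - logits.max()
    q = np.exp(logits)
    return q / q.sum()


def select_action(
    q_pi: np.ndarray,
    policies: np.ndarray,
    t: int,
    rng: np.random.Generator,
    *,
    alpha_action: float | None = None,
) -> tuple[int, float]:
    """Sample the next action from the policy-marginal over actions.

    ``t`` is the 1-based current time point; the action taken determines the
    behavioral state at ``t + 1``.  With ``alpha_action`` set, the marginal is
    resharpened by softmax(alpha * ln p) before sampling.  Returns the action
    and the probability with which it was drawn.
    """
    actions = policies[:, t - 1]
    uniq = np.unique(actions)
    p = np.array([q_pi[actions == u].sum() for u in uniq])
    p = p / p.sum()
    if alpha_action is not None:
        p = softmax(alpha_action * floored_log(p))
    idx = rng.choice(len(uniq), p=p)
    return int(uniq[idx]), float(p[idx])


# ---------------------------------------------------------------------------
# trial loop
# ---------------------------------------------------------------------------


@dataclass
class BeliefState:
    """Posterior beliefs at one time point."""

    q_joint_per_policy: np.ndarray  # (n_policies, 2, 2)
    q_stimulus: np.ndarray  # BMA marginal (2,)
    q_safety: np.ndarray  # BMA marginal (2,)
    policy_posterior: np.ndarray  # (n_policies,)


@dataclass
class TrialRecord:
    """Full record of one 4-step trial."""

    observations: np.ndarray  # (T, n_modalities) outcome indices
    behaviors: np.ndarray  # (T,) behavioral states actually visited
    actions: np.ndarray  # (T-1,) actions taken
    action_probs: np.ndarray  # (T-1,) probability of each sampled action
    beliefs: list[BeliefState] = field(default_factory=list)
    evaluations: list[PolicyEvaluation] = field(default_factory=list)

    @property
    def arousal_trace(self) -> np.ndarray:
        return self.observations[:, 1]

    @property
    def approached(self) -> bool:
        return int(self.behaviors[2]) == APPROACH

    @property
    def final_q_joint(self) -> np.ndarray:
        """Policy-averaged (stimulus, safety) posterior given all observations."""
        last = self.beliefs[-1]
        return np.tensordot(last.policy_posterior, last.q_joint_per_policy, axes=(0, 0))

    def to_frame(self):
        """Tidy per-timestep export: columns (trial, t, channel, level, value).

        Rows cover the observed outcome per modality (value 1 for the observed
        level), the policy-averaged posteriors over stimulus and safety, and
        the policy posterior.
        """
        import pandas as pd

        from .model import FACTOR_NAMES, MODALITY_NAMES, OUTCOME_SPACE, STATE_SPACE

        rows = []
        for t in range(len(self.behaviors)):
            for m, mname in enumerate(MODALITY_NAMES):
                levels = OUTCOME_SPACE.modalities[mname]
                rows.append(
                    {
                        "trial": 0,
                        "t": t + 1,
                        "channel": f"observation:{mname}",
                        "level": levels[int(self.observations[t, m])],
                        "value": 1.0,
                    }
                )
            belief = self.beliefs[t]
            for fname, post in (
                ("stimulus", belief.q_stimulus),
                ("safety_belief", belief.q_safety),
            ):
                for lvl, p in zip(STATE_SPACE.factors[fname], post):
                    rows.append(
                        {
                            "trial": 0,
                            "t": t + 1,
                            "channel": f"belief:{fname}",
                            "level": lvl,
                            "value": float(p),
                        }
                    )
            for pi, p in enumerate(belief.policy_posterior):
                rows.append(
                    {
                        "trial": 0,
                        "t": t + 1,
                        "channel": "policy_posterior",
                        "level": ("approach", "avoid")[pi],
                        "value": float(p),
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "observations": self.observations.tolist(),
                "behaviors": self.behaviors.tolist(),
                "actions": self.actions.tolist(),
                "action_probs": self.action_probs.tolist(),
                "policy_posteriors": [b.policy_posterior.tolist() for b in self.beliefs],
                "q_safety": [b.q_safety.tolist() for b in self.beliefs],
                "q_stimulus": [b.q_stimulus.tolist() for b in self.beliefs],
                "G": [e.G.tolist() for e in self.evaluations],
                "risk": [e.risk.tolist() for e in self.evaluations],
                "ambiguity": [e.ambiguity.tolist() for e in self.evaluations],
                "novelty": [e.novelty.tolist() for e in self.evaluations],
                "F": [e.F.tolist() for e in self.evaluations],
            },
            indent=1,
        )


def _exposure_E(n_policies: int, eps: float) -> np.ndarray:
    E = np.full(n_policies, eps / max(n_policies - 1, 1))
    E[APPROACH_POLICY] = 1.0 - eps
    return E


def run_trial(
    model: GenerativeModel,
    world: WorldProcess,
    rng: np.random.Generator,
    *,
    forced_policy: int | None = None,
    store: "DirichletStore | None" = None,
    include_novelty: bool | None = None,
    exposure_mode: str = "habit_prior",
    exposure_eps: float = EXPOSURE_PRIOR_EPS,
) -> TrialRecord:
    """Run the perception-evaluation-action loop for one 4-step trial.

    ``forced_policy`` implements exposure: the prior over policies ``E`` is
    replaced by a highly precise prior on the given policy (``habit_prior``
    mode), or the alternative branch is masked outright (``response_prevention``
    mode).  ``store`` supplies Dirichlet counts for the novelty term of G;
    novelty defaults to on whenever a store is supplied.
    """
    if include_novelty is None:
        include_novelty = store is not None
    n_pi = len(model.policies)
    E = model.E
    mask = np.ones(n_pi, dtype=bool)
    if forced_policy is not None:
        if exposure_mode == "habit_prior":
            E = np.roll(_exposure_E(n_pi, exposure_eps), forced_policy - APPROACH_POLICY)
        elif exposure_mode == "response_prevention":
            mask = np.zeros(n_pi, dtype=bool)
            mask[forced_policy] = True
        else:
            raise ValueError(f"unknown exposure_mode {exposure_mode!r}")

    T = model.T
    observations = np.zeros((T, model.n_modalities), dtype=int)
    behaviors = np.zeros(T, dtype=int)
    actions = np.zeros(T - 1, dtype=int)
    action_probs = np.zeros(T - 1)
    beliefs: list[BeliefState] = []
    evaluations: list[PolicyEvaluation] = []

    b = START
    for t in range(1, T + 1):
        behaviors[t - 1] = b
        observations[t - 1] = world.observe(b, t)
        obs_so_far = observations[:t]

        q_per_policy = np.zeros((n_pi, 2, 2))
        F = np.zeros(n_pi)
        G = np.zeros(n_pi)
        risk = np.zeros(n_pi)
        ambiguity = np.zeros(n_pi)
        novelty = np.zeros(n_pi)
        for p in range(n_pi):
            if not mask[p]:
                q_per_policy[p] = 0.25
                F[p] = 0.0
                continue
            q_per_policy[p], F[p] = infer_states_exact(model, obs_so_far, model.policies[p])
            G[p], risk[p], ambiguity[p], novelty[p] = expected_free_energy(
                model,
                model.policies[p],
                q_per_policy[p],
                t,
                store=store,
                include_novelty=include_novelty,
            )
        q_pi = policy_posterior(G, F, E, model.gamma, mask)
        q_joint_bma = np.tensordot(q_pi, q_per_policy, axes=(0, 0))
        beliefs.append(
            BeliefState(
                q_joint_per_policy=q_per_policy,
                q_stimulus=q_joint_bma.sum(axis=1),
                q_safety=q_joint_bma.sum(axis=0),
                policy_posterior=q_pi,
            )
        )
        evaluations.append(PolicyEvaluation(G=G, risk=risk, ambiguity=ambiguity, novelty=novelty, F=F))

        if t < T:
            action, prob = select_action(q_pi, model.policies, t, rng, alpha_action=model.alpha_action)
            actions[t - 1] = action
            action_probs[t - 1] = prob
            # prune policies inconsistent with the executed action
            mask = mask & (model.policies[:, t - 1] == action)
            b = action

    return TrialRecord(
        observations=observations,
        behaviors=behaviors,
        actions=actions,
        action_probs=action_probs,
        beliefs=beliefs,
        evaluations=evaluations,
    )
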