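"""Generative model of approach-avoidance under explicit safety/danger beliefs.

The agent is a discrete-state active-inference (POMDP) model of a person
confronting a feared but objectively safe stimulus (the running example is a
spider, but the structure is generic to phobic/anxious avoidance).  Hidden
states factorize into

* ``stimulus`` -- whether the spider is present,
* ``safety_belief`` -- the explicit (consciously reportable) belief that the
  spider is dangerous or safe,
* ``behavior`` -- a six-level behavioral state: ``start``, ``observe``, then
  either the approach trajectory (``approach`` -> ``interact``) or the
  avoidance trajectory (``avoid`` -> ``safety_cost``).

Observations arrive over four outcome modalities: the perceived stimulus,
interoceptive arousal (low/high), the affective consequence of action
(positive affect, negative affect, serious harm, or a neutral pre-choice
placeholder), and a veridical readout of the agent's own behavior.

The likelihood mapping ``A`` carries the cognition-affect-behavior (CAB)
interaction: under an explicit *danger* belief, approaching predicts negative
affect and interacting predicts serious harm; under a *safe* belief those
columns are softened by the CAB interaction strength ``cab_i`` in [0, 1],

    P(consequence | approach, safe) = (cab_i, 1 - cab_i, 0)
    P(consequence | interact, safe) = (cab_i, 0, 1 - cab_i)

over (positive, negative, harm).  At ``cab_i = 1`` a safe belief fully
suppresses the aversive expectations; at ``cab_i = 0`` the safe columns
collapse onto the danger columns and explicit beliefs lose all behavioral
influence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import log_softmax

__all__ = [
    "StateSpace",
    "OutcomeSpace",
    "CBTParams",
    "GenerativeModel",
    "build_cbt_model",
    "preference_log_probs",
    "validate_model",
    "STATE_SPACE",
    "OUTCOME_SPACE",
]

# ---------------------------------------------------------------------------
# fixed coordinate conventions
# ---------------------------------------------------------------------------

STIMULUS_LEVELS = ("no_spider", "spider")
SAFETY_LEVELS = ("dangerous", "safe")
BEHAVIOR_LEVELS = ("start", "observe", "approach", "interact", "avoid", "safety_cost")

AROUSAL_LEVELS = ("low", "high")
CONSEQUENCE_LEVELS = ("positive_affect", "negative_affect", "serious_harm", "neutral")

# state indices
NO_SPIDER, SPIDER = 0, 1
DANGEROUS, SAFE = 0, 1
START, OBSERVE, APPROACH, INTERACT, AVOID, SAFETY_COST = range(6)

# outcome indices
LOW, HIGH = 0, 1
POSITIVE, NEGATIVE, HARM, NEUTRAL = range(4)

MODALITY_NAMES = ("observed_stimulus", "arousal", "action_consequence", "observed_action")
FACTOR_NAMES = ("stimulus", "safety_belief", "behavior")
LEARNED_MODALITIES = (1, 2)  # arousal, action_consequence
LEARNED_FACTORS = (0, 1)  # stimulus, safety_belief

T_HORIZON = 4
# two allowable policies: action at step t is the behavioral state entered at t+1
POLICIES = np.array(
    [
        [OBSERVE, APPROACH, INTERACT],
        [OBSERVE, AVOID, SAFETY_COST],
    ]
)
APPROACH_POLICY, AVOID_POLICY = 0, 1

#: floor used inside every log() so degenerate priors (danger = 0 or 1) stay finite
P_FLOOR = 1e-16


def floored_log(p: np.ndarray) -> np.ndarray:
    """log with probabilities floored at :data:`P_FLOOR`."""
    return np.log(np.maximum(p, P_FLOOR))


# ---------------------------------------------------------------------------
# spaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateSpace:
    """Named hidden-state factors with named levels."""

    factors: dict[str, tuple[str, ...]]

    def __post_init__(self):
        if tuple(self.factors) != FACTOR_NAMES:
            raise ValueError(f"expected factors {FACTOR_NAMES}, got {tuple(self.factors)}")
        cards = tuple(len(v) for v in self.factors.values())
        if cards != (2, 2, 6):
            raise ValueError(f"factor cardinalities must be (2, 2, 6), got {cards}")
        for name, levels in self.factors.items():
            if len(set(levels)) != len(levels):
                raise ValueError(f"duplicate level names in factor {name!r}")

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.factors.values())


@dataclass(frozen=True)
class OutcomeSpace:
    """Named outcome modalities with named levels."""

    modalities: dict[str, tuple[str, ...]]

    def __post_init__(self):
        if tuple(self.modalities) != MODALITY_NAMES:
            raise ValueError(f"expected modalities {MODALITY_NAMES}")
        if len(self.modalities["observed_action"]) != len(BEHAVIOR_LEVELS):
            raise ValueError("observed_action cardinality must equal behavior cardinality")

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.modalities.values())


STATE_SPACE = StateSpace(
    {"stimulus": STIMULUS_LEVELS, "safety_belief": SAFETY_LEVELS, "behavior": BEHAVIOR_LEVELS}
)
OUTCOME_SPACE = OutcomeSpace(
    {
        "observed_stimulus": STIMULUS_LEVELS,
        "arousal": AROUSAL_LEVELS,
        "action_consequence": CONSEQUENCE_LEVELS,
        "observed_action": BEHAVIOR_LEVELS,
    }
)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CBTParams:
    """Clinically interpretable parameters of the avoidance model.

    Parameters
    ----------
    danger:
        Prior probability assigned to the explicit belief "the spider is
        dangerous" (the D vector is ``[danger, 1 - danger]``).  ``danger = 1``
        models a patient before cognitive restructuring; ``danger = 0`` a fully
        effective restructuring; ``danger = 0.5`` uncertainty induction.
    cab_i:
        Cognition-affect-behavior interaction strength in [0, 1]; how strongly
        explicit safety beliefs attenuate the implicit aversive expectations
        attached to approach.
    preference_harm, preference_negative, preference_high_arousal:
        Raw (pre-softmax) preference values for the aversive outcomes, in the
        same units as log-probabilities after normalization.  All non-aversive
        outcomes have raw value 0.
    arousal_dialect:
        ``"belief_modulated"`` (default): approach/interact arousal follows the
        CAB-i interaction (low under an effective safe belief, high under
        danger).  ``"literal_text"``: arousal is belief-independent except for
        the surprise response on first observing the spider and during flight.
    pre_choice_outcome:
        Consequence outcome emitted by the pre-choice states (start, observe):
        ``"neutral"`` (default, a preference-0 placeholder carrying no evidence
        about safety) or ``"positive_affect"``.
    """

    danger: float
    cab_i: float
    preference_harm: float = -12.0
    preference_negative: float = -1.0
    preference_high_arousal: float = -1.0
    arousal_dialect: str = "belief_modulated"
    pre_choice_outcome: str = "neutral"

    def __post_init__(self):
        if not 0.0 <= self.danger <= 1.0:
            raise ValueError(f"danger must be in [0, 1], got {self.danger}")
        if not 0.0 <= self.cab_i <= 1.0:
            raise ValueError(f"cab_i must be in [0, 1], got {self.cab_i}")
        if self.arousal_dialect not in ("belief_modulated", "literal_text"):
            raise ValueError(f"unknown arousal_dialect {self.arousal_dialect!r}")
        if self.pre_choice_outcome not in ("neutral", "positive_affect"):
            raise ValueError(f"unknown pre_choice_outcome {self.pre_choice_outcome!r}")
        for name in ("preference_harm", "preference_negative", "preference_high_arousal"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


# ---------------------------------------------------------------------------
# generative model container
# ---------------------------------------------------------------------------


@dataclass
class GenerativeModel:
    """A/B/C/D/E structure of the avoidance model.

    ``A[m]`` has shape ``(n_outcomes_m, 2, 2, 6)`` over the joint state
    ``(stimulus, safety_belief, behavior)`` -- this enumeration order is fixed.
    ``B`` maps factor name to a ``(n, n, n_actions)`` transition array.
    ``C[m]`` holds log-preference probabilities (softmax of ``C_raw[m]``).
    """

    A: list[np.ndarray]
    B: dict[str, np.ndarray]
    C_raw: list[np.ndarray]
    C: list[np.ndarray]
    D: list[np.ndarray]
    E: np.ndarray
    policies: np.ndarray
    gamma: float
    alpha_action: float | None
    T: int
    params: CBTParams

    @property
    def n_modalities(self) -> int:
        return len(self.A)

    def copy(self) -> "GenerativeModel":
        return GenerativeModel(
            A=[a.copy() for a in self.A],
            B={k: v.copy() for k, v in self.B.items()},
            C_raw=[c.copy() for c in self.C_raw],
            C=[c.copy() for c in self.C],
            D=[d.copy() for d in self.D],
            E=self.E.copy(),
            policies=self.policies.copy(),
            gamma=self.gamma,
            alpha_action=self.alpha_action,
            T=self.T,
            params=self.params,
        )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "factors": {k: list(v) for k, v in STATE_SPACE.factors.items()},
            "modalities": {k: list(v) for k, v in OUTCOME_SPACE.modalities.items()},
            "A": {name: a.tolist() for name, a in zip(MODALITY_NAMES, self.A)},
            "B": {k: v.tolist() for k, v in self.B.items()},
            "C_raw": {name: c.tolist() for name, c in zip(MODALITY_NAMES, self.C_raw)},
            "D": {name: d.tolist() for name, d in zip(FACTOR_NAMES, self.D)},
            "E": self.E.tolist(),
            "policies": self.policies.tolist(),
            "gamma": self.gamma,
            "alpha_action": self.alpha_action,
            "T": self.T,
            "params": {
                "danger": self.params.danger,
                "cab_i": self.params.cab_i,
                "preference_harm": self.params.preference_harm,
                "preference_negative": self.params.preference_negative,
                "preference_high_arousal": self.params.preference_high_arousal,
                "arousal_dialect": self.params.arousal_dialect,
                "pre_choice_outcome": self.params.pre_choice_outcome,
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GenerativeModel":
        doc = json.loads(text)
        params = CBTParams(**doc["params"])
        model = cls(
            A=[np.asarray(doc["A"][name], dtype=float) for name in MODALITY_NAMES],
            B={k: np.asarray(v, dtype=float) for k, v in doc["B"].items()},
            C_raw=[np.asarray(doc["C_raw"][name], dtype=float) for name in MODALITY_NAMES],
            C=[],
            D=[np.asarray(doc["D"][name], dtype=float) for name in FACTOR_NAMES],
            E=np.asarray(doc["E"], dtype=float),
            policies=np.asarray(doc["policies"], dtype=int),
            gamma=float(doc["gamma"]),
            alpha_action=doc["alpha_action"],
            T=int(doc["T"]),
            params=params,
        )
        model.C = preference_log_probs(model.C_raw)
        return model


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def preference_log_probs(raw_values: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Convert raw per-modality preference values into log-probabilities.

    Each modality's raw values are softmax-normalized into a proper probability
    distribution and the result is returned in log space, so
    ``exp(C[m]).sum() == 1`` for every modality.
    """
    out = []
    for values in raw_values:
        values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("preference values must be finite")
        out.append(log_softmax(values))
    return out


def _build_A(params: CBTParams) -> list[np.ndarray]:
    cab = params.cab_i
    pre = NEUTRAL if params.pre_choice_outcome == "neutral" else POSITIVE

    # observed_stimulus: identity on stimulus, except the start state, which
    # precedes stimulus presentation and always maps to "no spider"
    A_stim = np.zeros((2, 2, 2, 6))
    for b in range(6):
        if b == START:
            A_stim[NO_SPIDER, :, :, b] = 1.0
        else:
            for s in (NO_SPIDER, SPIDER):
                A_stim[s, s, :, b] = 1.0

    # observed_action: identity on behavior
    A_act = np.zeros((6, 2, 2, 6))
    for b in range(6):
        A_act[b, :, :, b] = 1.0

    # arousal
    A_ar = np.zeros((2, 2, 2, 6))
    A_ar[LOW] = 1.0  # default: low arousal everywhere
    # first observing a spider generates brief surprise-like high arousal
    A_ar[:, SPIDER, :, OBSERVE] = 0.0
    A_ar[HIGH, SPIDER, :, OBSERVE] = 1.0
    # flight itself generates high arousal
    A_ar[LOW, :, :, AVOID] = 0.0
    A_ar[HIGH, :, :, AVOID] = 1.0
    if params.arousal_dialect == "belief_modulated":
        # approach/interact arousal tracks the CAB interaction when the spider
        # is present: high under danger beliefs, low under an effective safe
        # belief (probability cab_i), high otherwise
        for b in (APPROACH, INTERACT):
            A_ar[:, SPIDER, DANGEROUS, b] = (0.0, 1.0)
            A_ar[:, SPIDER, SAFE, b] = (cab, 1.0 - cab)

    # action consequence
    A_cons = np.zeros((4, 2, 2, 6))
    for b in (START, OBSERVE):
        A_cons[pre, :, :, b] = 1.0
    A_cons[NEGATIVE, :, :, AVOID] = 1.0
    A_cons[NEGATIVE, :, :, SAFETY_COST] = 1.0
    # without a spider, approach/interact just carry on with the desired activity
    A_cons[POSITIVE, NO_SPIDER, :, APPROACH] = 1.0
    A_cons[POSITIVE, NO_SPIDER, :, INTERACT] = 1.0
    # with a spider: danger belief predicts negative affect then serious harm;
    # a safe belief softens those columns by the CAB interaction strength
    A_cons[NEGATIVE, SPIDER, DANGEROUS, APPROACH] = 1.0
    A_cons[HARM, SPIDER, DANGEROUS, INTERACT] = 1.0
    A_cons[POSITIVE, SPIDER, SAFE, APPROACH] = cab
    A_cons[NEGATIVE, SPIDER, SAFE, APPROACH] = 1.0 - cab
    A_cons[POSITIVE, SPIDER, SAFE, INTERACT] = cab
    A_cons[HARM, SPIDER, SAFE, INTERACT] = 1.0 - cab

    return [A_stim, A_ar, A_cons, A_act]


def _build_B() -> dict[str, np.ndarray]:
    # stimulus and safety beliefs cannot change within a trial: identity maps
    B = {
        "stimulus": np.eye(2)[:, :, None],
        "safety_belief": np.eye(2)[:, :, None],
    }
    # behavior is fully controllable: action u moves the agent to state u
    Bb = np.zeros((6, 6, 6))
    for u in range(6):
        Bb[u, :, u] = 1.0
    B["behavior"] = Bb
    return B


def build_cbt_model(
    params: CBTParams,
    *,
    gamma: float = 1.0,
    alpha_action: float | None = None,
) -> GenerativeModel:
    """Construct the avoidance generative model for a given parameterization.

    ``gamma`` is the policy precision (inverse decision noise) applied to the
    expected-free-energy term of the policy posterior; ``alpha_action`` is an
    optional extra precision applied when sampling actions from the policy
    marginal (``None`` samples the marginal directly).
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    A = _build_A(params)
    C_raw = [
        np.zeros(2),
        np.array([0.0, params.preference_high_arousal]),
        np.array([0.0, params.preference_negative, params.preference_harm, 0.0]),
        np.zeros(6),
    ]
    D = [
        np.array([0.5, 0.5]),
        np.array([params.danger, 1.0 - params.danger]),
        np.eye(6)[START],
    ]
    model = GenerativeModel(
        A=A,
        B=_build_B(),
        C_raw=C_raw,
        C=preference_log_probs(C_raw),
        D=D,
        E=np.array([0.5, 0.5]),
        policies=POLICIES.copy(),
        gamma=float(gamma),
        alpha_action=alpha_action,
        T=T_HORIZON,
        params=params,
    )
    violations = validate_model(model)
    if violations:  # pragma: no cover - constructor satisfies its own contract
        raise ValueError("constructed model violates invariants: " + "; ".join(violations))
    return model


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_NORM_TOL = 1e-9


def validate_model(model: GenerativeModel) -> list[str]:
    """Return a list of invariant violations (empty iff the model is valid)."""
    v: list[str] = []
    cards = OUTCOME_SPACE.cardinalities
    for m, (name, a) in enumerate(zip(MODALITY_NAMES, model.A)):
        if a.shape != (cards[m], 2, 2, 6):
            v.append(f"A[{name}] has shape {a.shape}, expected {(cards[m], 2, 2, 6)}")
            continue
        if np.any(a < -_NORM_TOL):
            v.append(f"A[{name}] has negative entries")
        sums = a.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=_NORM_TOL):
            v.append(f"A[{name}] has columns not summing to 1")
    for fname in ("stimulus", "safety_belief"):
        b = model.B.get(fname)
        if b is None or b.shape[:2] != (2, 2) or not np.allclose(b[:, :, 0], np.eye(2), atol=_NORM_TOL):
            v.append(f"B[{fname}] is not an identity map")
    bb = model.B.get("behavior")
    if bb is None or bb.shape != (6, 6, 6) or not np.allclose(bb.sum(axis=0), 1.0, atol=_NORM_TOL):
        v.append("B[behavior] columns do not sum to 1")
    for fname, d, n in zip(FACTOR_NAMES, model.D, (2, 2, 6)):
        if d.shape != (n,) or np.any(d < -_NORM_TOL) or abs(d.sum() - 1.0) > _NORM_TOL:
            v.append(f"D[{fname}] is not a valid distribution")
    if model.E.shape != (len(model.policies),) or abs(model.E.sum() - 1.0) > _NORM_TOL:
        v.append("E is not a valid distribution over policies")
    if model.policies.shape != (2, model.T - 1):
        v.append(f"expected 2 policies of length T-1={model.T - 1}")
    for m, (name, c) in enumerate(zip(MODALITY_NAMES, model.C)):
        if c.shape != (cards[m],) or abs(np.exp(c).sum() - 1.0) > 1e-6:
            v.append(f"C[{name}] is not a normalized log-probability vector")
    return v
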