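"""Between-trial belief updating via Dirichlet concentration parameters.

Two belief systems learn at different levels of the model:

* **implicit beliefs** -- Dirichlet counts ``a`` over the learnable likelihood
  modalities (arousal and action consequence).  These encode the automatic,
  associative expectations attached to approach/avoid behavior and move only
  gradually, in proportion to how much posterior mass sat on each explicit
  belief when an outcome was observed;
* **explicit beliefs** -- Dirichlet counts ``d`` over the initial-state priors
  for the stimulus and safety-belief factors.  Normalizing ``d`` for the
  safety factor gives the reportable prior P(safe) that cognitive
  restructuring manipulates and that exposure may (or may not) shift.

The identity modalities (observed stimulus, observed action) and the behavior
factor are treated as veridical and are not learned.

Counts for the learned modalities are initialized from ``base_scale * A``,
with one modification to the belief-dependent approach/interact columns: an
*implicit-association leak* ``cab_leak`` (default 0.1).  In the learned model
the danger-context columns are built as if the CAB interaction were
``cab_leak`` rather than zero, and the safe-context columns as if it were
``max(cab_i, cab_leak)`` -- i.e., conditioned danger associations never assign
*exactly* zero probability to benign outcomes.  The leak keeps the Dirichlet
prior proper over everything the world can emit and has a psychologically
meaningful consequence: when the CAB interaction strength is at or below the
leak, the two explicit-belief contexts make identical outcome predictions, so
benign exposure outcomes carry no evidence about safety versus danger.
Explicit beliefs then stay where cognitive restructuring left them, and the
outcome counts are credited to both contexts in proportion to the prior --
the "over-writing" route to behavior change.  Without the leak, an outcome
that the danger context assigns probability zero would constitute effectively
infinite evidence for safety, and that route would collapse onto explicit
belief updating at every CAB-i > 0.  An optional uniform pseudocount floor
``a_floor`` on the same columns is also available (default 0).  With
``cab_leak = 0`` and ``a_floor = 0`` the counts are exactly
``base_scale * A``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    APPROACH,
    CONSEQUENCE_LEVELS,
    INTERACT,
    LEARNED_FACTORS,
    LEARNED_MODALITIES,
    MODALITY_NAMES,
    SAFE,
    SAFETY_LEVELS,
    SPIDER,
    GenerativeModel,
)
from .engine import TrialRecord

__all__ = ["DirichletStore", "init_counts", "update_after_trial", "extract_belief_trajectories"]

#: default residual probability of benign outcomes under the danger context
CAB_LEAK_DEFAULT = 0.1
#: default uniform pseudocount floor on the approach/interact columns
A_FLOOR_DEFAULT = 0.0


@dataclass
class DirichletStore:
    """Concentration-parameter counterparts of the learned A modalities and D factors."""

    a: dict[int, np.ndarray]
    d: dict[int, np.ndarray]
    eta_a: float
    eta_d: float
    base_scale: float

    def copy(self) -> "DirichletStore":
        return DirichletStore(
            a={m: arr.copy() for m, arr in self.a.items()},
            d={f: arr.copy() for f, arr in self.d.items()},
            eta_a=self.eta_a,
            eta_d=self.eta_d,
            base_scale=self.base_scale,
        )

    def normalized_a(self, m: int) -> np.ndarray:
        counts = self.a[m]
        return counts / counts.sum(axis=0, keepdims=True)

    def normalized_d(self, f: int) -> np.ndarray:
        counts = self.d[f]
        return counts / counts.sum()

    def p_safe(self) -> float:
        return float(self.normalized_d(1)[SAFE])

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "a": {MODALITY_NAMES[m]: arr.tolist() for m, arr in self.a.items()},
                "d": {("stimulus", "safety_belief")[f]: arr.tolist() for f, arr in self.d.items()},
                "eta_a": self.eta_a,
                "eta_d": self.eta_d,
                "base_scale": self.base_scale,
            },
            indent=1,
        )


def _leaky_columns(model: GenerativeModel, cab_leak: float) -> dict[int, np.ndarray]:
    """Learned-modality likelihoods with the implicit-association leak applied.

    Rebuilds the spider approach/interact columns with an effective CAB
    interaction of ``cab_leak`` for the danger context and
    ``max(cab_i, cab_leak)`` for the safe context.
    """
    from .model import DANGEROUS, HARM, HIGH, LOW, NEGATIVE, POSITIVE, SAFE

    params = model.params
    cab_d = cab_leak
    cab_s = max(params.cab_i, cab_leak)
    out = {m: model.A[m].copy() for m in LEARNED_MODALITIES}
    cons = out[2]
    for belief, cab in ((DANGEROUS, cab_d), (SAFE, cab_s)):
        cons[:, SPIDER, belief, APPROACH] = 0.0
        cons[POSITIVE, SPIDER, belief, APPROACH] = cab
        cons[NEGATIVE, SPIDER, belief, APPROACH] = 1.0 - cab
        cons[:, SPIDER, belief, INTERACT] = 0.0
        cons[POSITIVE, SPIDER, belief, INTERACT] = cab
        cons[HARM, SPIDER, belief, INTERACT] = 1.0 - cab
    if params.arousal_dialect == "belief_modulated":
        ar = out[1]
        for belief, cab in ((DANGEROUS, cab_d), (SAFE, cab_s)):
            for b in (APPROACH, INTERACT):
                ar[LOW, SPIDER, belief, b] = cab
                ar[HIGH, SPIDER, belief, b] = 1.0 - cab
    return out


def init_counts(
    model: GenerativeModel,
    base_scale: float,
    eta_a: float,
    eta_d: float,
    *,
    base_scale_d: float | None = None,
    a_floor: float = A_FLOOR_DEFAULT,
    cab_leak: float = CAB_LEAK_DEFAULT,
) -> DirichletStore:
    """Initialize Dirichlet counts from the model's current A and D.

    ``a = base_scale * A`` for the learned modalities (arousal, action
    consequence), with the implicit-association leak ``cab_leak`` applied to
    the belief-dependent approach/interact columns (see module docstring) and
    an optional uniform pseudocount floor ``a_floor`` on those same columns;
    ``d = base_scale_d * D`` for the learned factors (stimulus, safety
    belief).  With ``cab_leak = 0`` and ``a_floor = 0`` the normalized counts
    reproduce the model's A exactly.  The model's A and D for the learned
    components are refreshed from the counts so that agent and store agree.
    """
    if base_scale <= 0:
        raise ValueError("base_scale must be positive")
    if base_scale_d is None:
        base_scale_d = base_scale
    if base_scale_d <= 0:
        raise ValueError("base_scale_d must be positive")
    if eta_a < 0 or eta_d < 0:
        raise ValueError("learning rates must be nonnegative")
    if a_floor < 0:
        raise ValueError("a_floor must be nonnegative")
    if not 0.0 <= cab_leak <= 1.0:
        raise ValueError("cab_leak must be in [0, 1]")
    A_eff = _leaky_columns(model, cab_leak)
    a = {}
    for m in LEARNED_MODALITIES:
        counts = base_scale * A_eff[m]
        counts[:, :, :, APPROACH] += a_floor
        counts[:, :, :, INTERACT] += a_floor
        a[m] = counts
    d = {f: base_scale_d * model.D[f] for f in LEARNED_FACTORS}
    store = DirichletStore(a=a, d=d, eta_a=eta_a, eta_d=eta_d, base_scale=base_scale)
    _refresh_model(model, store)
    return store


def _refresh_model(model: GenerativeModel, store: DirichletStore) -> None:
    for m in store.a:
        model.A[m] = store.normalized_a(m)
    for f in store.d:
        model.D[f] = store.normalized_d(f)


def update_after_trial(
    store: DirichletStore,
    trial: TrialRecord,
    model: GenerativeModel | None = None,
) -> DirichletStore:
    """Accumulate counts from one completed trial and refresh the model.

    For every time step and learned modality, the count cell selected by the
    observed outcome and the visited behavioral state gains ``eta_a`` times the
    smoothed posterior over (stimulus, safety); the learned ``d`` factors gain
    ``eta_d`` times the smoothed initial-state posterior (identical to the
    final posterior here, since the uncontrolled factors have identity
    transitions).  The store is updated in place and returned.
    """
    q_joint = trial.final_q_joint
    for t in range(len(trial.behaviors)):
        b = int(trial.behaviors[t])
        for m in store.a:
            o = int(trial.observations[t, m])
            if store.a[m][o, :, :, b].shape != q_joint.shape:  # pragma: no cover
                raise ValueError("count/posterior shape mismatch")
            store.a[m][o, :, :, b] += store.eta_a * q_joint
    marginals = {0: q_joint.sum(axis=1), 1: q_joint.sum(axis=0)}
    for f in store.d:
        store.d[f] += store.eta_d * marginals[f]
    if model is not None:
        _refresh_model(model, store)
    return store


def extract_belief_trajectories(history: list[DirichletStore]) -> pd.DataFrame:
    """Tidy time series of explicit and implicit beliefs from store snapshots.

    One snapshot per trial (index 0 = before any learning).  Rows report the
    explicit P(safe) and, for each explicit belief and each of the approach and
    interact states, the normalized action-consequence column (the implicit
    belief about what approaching predicts, spider present).
    """
    if not history:
        raise ValueError("empty store history")
    rows = []
    for trial_idx, store in enumerate(history):
        rows.append(
            {
                "trial": trial_idx,
                "quantity": "explicit",
                "belief": "safe",
                "behavior": "",
                "outcome": "",
                "value": store.p_safe(),
            }
        )
        a_cons = store.normalized_a(2)
        for belief_idx, belief in enumerate(SAFETY_LEVELS):
            for b, bname in ((APPROACH, "approach"), (INTERACT, "interact")):
                col = a_cons[:, SPIDER, belief_idx, b]
                for o, oname in enumerate(CONSEQUENCE_LEVELS):
                    rows.append(
                        {
                            "trial": trial_idx,
                            "quantity": "implicit",
                            "belief": belief,
                            "behavior": bname,
                            "outcome": oname,
                            "value": float(col[o]),
                        }
                    )
    return pd.DataFrame(rows)
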