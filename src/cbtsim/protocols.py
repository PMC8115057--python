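"""Simulation experiments: single trials, behavioral sweeps, exposure, generalization.

These protocols reproduce the study designs the model was built for:

* single free-choice trials under different explicit priors and CAB
  interaction strengths (foundational illustrations of avoidance, approach,
  and avoidance-despite-safety-beliefs);
* a grid sweep of free-choice approach rates over P(safe) and CAB-i with
  learning disabled;
* exposure: blocks of forced-approach trials with learning on, probed at
  checkpoints by frozen-learning free-choice trials, tracking explicit
  (prior) and implicit (likelihood) belief trajectories;
* generalization: reinstating a danger prior after exposure and asking
  whether approach survives.

All randomness flows from a single integer seed expanded into independent
substreams keyed by (condition, trial/probe index), so adding repetitions or
conditions never reshuffles earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    APPROACH,
    CBTParams,
    GenerativeModel,
    INTERACT,
    NEUTRAL,
    POSITIVE,
    SPIDER,
    build_cbt_model,
)
from .engine import APPROACH_POLICY, EXPOSURE_PRIOR_EPS, TrialRecord, WorldProcess, run_trial
from .learning import (
    A_FLOOR_DEFAULT,
    CAB_LEAK_DEFAULT,
    DirichletStore,
    init_counts,
    update_after_trial,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "simulate_single_trial",
    "approach_rate_sweep",
    "exposure_experiment",
    "exposure_length_to_criterion",
    "generalization_test",
    "consecutive_avoidance_run",
    "belief_displacements",
    "substream",
]

# ---------------------------------------------------------------------------
# calibrated defaults (single calibration; see docs/methods.md)
# ---------------------------------------------------------------------------

GAMMA_DEFAULT = 2.5
BASE_SCALE_DEFAULT = 2.0
BASE_SCALE_D_DEFAULT = 10.0
ETA_A_DEFAULT = 0.155
ETA_D_DEFAULT = 0.24

DEFAULT_EXPOSURE_LENGTHS = (0, 10, 25, 50, 75, 100, 150, 200)


def substream(seed: int, *path: int) -> np.random.Generator:
    """Independent generator for one (experiment, condition, repetition) cell."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(path)))


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one exposure experiment condition."""

    danger_prior: float = 0.9
    cab_i: float = 0.9
    exposure_lengths: tuple[int, ...] = DEFAULT_EXPOSURE_LENGTHS
    n_probe_reps: int = 50
    n_sweep_trials: int = 100
    approach_criterion: float = 0.95
    seed: int = 0
    learning: bool = True
    # engine options
    gamma: float = GAMMA_DEFAULT
    alpha_action: float | None = None
    arousal_dialect: str = "belief_modulated"
    pre_choice_outcome: str = "neutral"
    exposure_mode: str = "habit_prior"
    exposure_eps: float = EXPOSURE_PRIOR_EPS
    include_novelty: bool | None = None  # None: on iff learning
    # learning options
    base_scale: float = BASE_SCALE_DEFAULT
    base_scale_d: float = BASE_SCALE_D_DEFAULT
    a_floor: float = A_FLOOR_DEFAULT
    cab_leak: float = CAB_LEAK_DEFAULT
    eta_a: float = ETA_A_DEFAULT
    eta_d: float = ETA_D_DEFAULT

    def __post_init__(self):
        if not 0.0 < self.approach_criterion <= 1.0:
            raise ValueError("approach_criterion must be in (0, 1]")
        if self.n_probe_reps <= 0 or self.n_sweep_trials <= 0:
            raise ValueError("repetition counts must be positive")
        if any(l < 0 for l in self.exposure_lengths):
            raise ValueError("exposure lengths must be nonnegative")

    def params(self) -> CBTParams:
        return CBTParams(
            danger=self.danger_prior,
            cab_i=self.cab_i,
            arousal_dialect=self.arousal_dialect,
            pre_choice_outcome=self.pre_choice_outcome,
        )

    def world(self) -> WorldProcess:
        return WorldProcess(pre_choice_outcome=NEUTRAL if self.pre_choice_outcome == "neutral" else POSITIVE)


@dataclass
class ExperimentResult:
    """Tidy outputs of an exposure experiment.

    ``table`` has one row per exposure length with the probe approach rate and
    the explicit P(safe) at that point; ``trajectories`` tracks explicit and
    implicit beliefs trial by trial; ``snapshots`` maps exposure length to the
    (model, store) pair frozen at that point, for generalization tests.
    """

    table: pd.DataFrame
    trajectories: pd.DataFrame
    snapshots: dict[int, tuple[GenerativeModel, DirichletStore]] = field(default_factory=dict)
    config: ExperimentConfig | None = None


# ---------------------------------------------------------------------------
# foundational single trials and the behavioral sweep
# ---------------------------------------------------------------------------


def simulate_single_trial(
    params: CBTParams,
    rng: np.random.Generator,
    *,
    gamma: float = GAMMA_DEFAULT,
    alpha_action: float | None = None,
) -> TrialRecord:
    """One free-choice trial with learning off (panel-style inspection)."""
    model = build_cbt_model(params, gamma=gamma, alpha_action=alpha_action)
    world = WorldProcess(
        pre_choice_outcome=NEUTRAL if params.pre_choice_outcome == "neutral" else POSITIVE
    )
    return run_trial(model, world, rng)


def approach_rate_sweep(
    danger_grid,
    cab_grid,
    n_sweep_trials: int = 100,
    seed: int = 0,
    *,
    gamma: float = GAMMA_DEFAULT,
    arousal_dialect: str = "belief_modulated",
) -> pd.DataFrame:
    """Free-choice approach percentage per (P(safe), CAB-i) grid point.

    Learning is off: every trial is independent, so the sweep characterizes the
    static decision policy rather than any learning dynamics.
    """
    rows = []
    for i, danger in enumerate(danger_grid):
        for j, cab in enumerate(cab_grid):
            params = CBTParams(danger=float(danger), cab_i=float(cab), arousal_dialect=arousal_dialect)
            model = build_cbt_model(params, gamma=gamma)
            world = WorldProcess(
                pre_choice_outcome=NEUTRAL if params.pre_choice_outcome == "neutral" else POSITIVE
            )
            n_app = 0
            for k in range(n_sweep_trials):
                trial = run_trial(model, world, substream(seed, 0, i, j, k))
                n_app += int(trial.approached)
            rows.append(
                {
                    "p_safe": 1.0 - float(danger),
                    "cab_i": float(cab),
                    "n_trials": n_sweep_trials,
                    "approach_rate": n_app / n_sweep_trials,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exposure
# ---------------------------------------------------------------------------


def _probe_approach_rate(
    model: GenerativeModel,
    store: DirichletStore,
    world: WorldProcess,
    n_reps: int,
    seed: int,
    *path: int,
    include_novelty: bool | None = None,
) -> float:
    """Free-choice probe trials with frozen counts; returns approach proportion.

    Probes freeze the count updates, not the agent: the novelty drive stays
    active by default whenever Dirichlet counts are in play, as in ordinary
    learning-enabled trials.
    """
    n_app = 0
    for rep in range(n_reps):
        trial = run_trial(
            model,
            world,
            substream(seed, *path, rep),
            store=store,
            include_novelty=include_novelty,
        )
        n_app += int(trial.approached)
    return n_app / n_reps


def exposure_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Forced-approach exposure with learning, probed at each requested length.

    For each exposure length L in ``config.exposure_lengths``: run L
    forced-approach trials with learning on (incrementally -- one pass through
    ``max(lengths)`` trials with checkpoints), then freeze learning and run
    ``n_probe_reps`` free-choice probe trials.  Probes do not alter beliefs.
    """
    model = build_cbt_model(config.params(), gamma=config.gamma, alpha_action=config.alpha_action)
    world = config.world()
    store = init_counts(
        model,
        config.base_scale,
        config.eta_a,
        config.eta_d,
        base_scale_d=config.base_scale_d,
        a_floor=config.a_floor,
        cab_leak=config.cab_leak,
    )
    checkpoints = sorted(set(int(l) for l in config.exposure_lengths))
    max_len = max(checkpoints) if checkpoints else 0
    history = [store.copy()]
    rows = []
    snapshots: dict[int, tuple[GenerativeModel, DirichletStore]] = {}

    def _checkpoint(L: int) -> None:
        rate = _probe_approach_rate(
            model,
            store,
            world,
            config.n_probe_reps,
            config.seed,
            1,
            L,
            include_novelty=config.include_novelty,
        )
        rows.append(
            {
                "p_safe": 1.0 - config.danger_prior,
                "cab_i": config.cab_i,
                "exposure_length": L,
                "approach_rate": rate,
                "p_safe_explicit": store.p_safe(),
                "n_probe_reps": config.n_probe_reps,
                "seed": config.seed,
            }
        )
        snapshots[L] = (model.copy(), store.copy())

    for trial_idx in range(max_len + 1):
        if trial_idx in checkpoints:
            _checkpoint(trial_idx)
        if trial_idx == max_len:
            break
        trial = run_trial(
            model,
            world,
            substream(config.seed, 2, trial_idx),
            forced_policy=APPROACH_POLICY if config.learning else None,
            store=store,
            include_novelty=config.include_novelty,
            exposure_mode=config.exposure_mode,
            exposure_eps=config.exposure_eps,
        )
        if config.learning:
            update_after_trial(store, trial, model)
        history.append(store.copy())

    from .learning import extract_belief_trajectories

    trajectories = extract_belief_trajectories(history)
    trajectories.insert(0, "cab_i", config.cab_i)
    trajectories.insert(0, "p_safe", 1.0 - config.danger_prior)
    return ExperimentResult(
        table=pd.DataFrame(rows), trajectories=trajectories, snapshots=snapshots, config=config
    )


def exposure_length_to_criterion(result: ExperimentResult | pd.DataFrame, criterion: float = 0.95):
    """Smallest exposure length whose probe approach rate meets the criterion.

    Returns ``None`` if the criterion is never reached.
    """
    table = result.table if isinstance(result, ExperimentResult) else result
    if len(table) == 0:
        raise ValueError("empty experiment result")
    ok = table.loc[table["approach_rate"] >= criterion, "exposure_length"]
    return None if ok.empty else int(ok.min())


# ---------------------------------------------------------------------------
# generalization
# ---------------------------------------------------------------------------


def generalization_test(
    model: GenerativeModel,
    store: DirichletStore,
    reinstated_danger: float,
    *,
    n_probe_reps: int = 50,
    seed: int = 0,
    world: WorldProcess | None = None,
    include_novelty: bool | None = None,
) -> float:
    """Approach rate after reinstating an explicit danger prior.

    The explicit safety prior is reset to ``[reinstated_danger,
    1 - reinstated_danger]`` while the learned likelihood counts are kept, then
    frozen-learning free-choice probes measure whether approach survives.
    """
    if not 0.0 <= reinstated_danger <= 1.0:
        raise ValueError("reinstated_danger must be in [0, 1]")
    probe_model = model.copy()
    probe_model.D[1] = np.array([reinstated_danger, 1.0 - reinstated_danger])
    if world is None:
        world = WorldProcess(
            pre_choice_outcome=NEUTRAL if model.params.pre_choice_outcome == "neutral" else POSITIVE
        )
    return _probe_approach_rate(
        probe_model, store, world, n_probe_reps, seed, 3, include_novelty=include_novelty
    )


# ---------------------------------------------------------------------------
# free-running avoidance and belief displacement summaries
# ---------------------------------------------------------------------------


def consecutive_avoidance_run(config: ExperimentConfig, n_trials: int = 120) -> int:
    """Free-choice trials with learning on; counts initial consecutive avoidances.

    Models the untreated patient: under a strong danger prior and strong CAB
    interactions the agent avoids on every trial, which denies it the
    observations that would revise either belief system.
    """
    model = build_cbt_model(config.params(), gamma=config.gamma, alpha_action=config.alpha_action)
    world = config.world()
    store = init_counts(
        model,
        config.base_scale,
        config.eta_a,
        config.eta_d,
        base_scale_d=config.base_scale_d,
        a_floor=config.a_floor,
        cab_leak=config.cab_leak,
    )
    streak = 0
    for trial_idx in range(n_trials):
        trial = run_trial(
            model,
            world,
            substream(config.seed, 4, trial_idx),
            store=store,
            include_novelty=config.include_novelty,
        )
        if config.learning:
            update_after_trial(store, trial, model)
        if trial.approached:
            break
        streak += 1
    return streak


def belief_displacements(
    store0: DirichletStore, store: DirichletStore, *, belief: str = "both"
) -> tuple[float, float]:
    """Total-variation displacement of explicit vs implicit beliefs.

    Explicit: TV between the initial and current normalized safety prior.
    Implicit: mean TV across the spider action-consequence columns
    (approach/interact), averaged over the explicit-belief contexts named by
    ``belief`` (``"both"``, ``"dangerous"``, or ``"safe"``).  Restricting to
    the danger context isolates the over-writing that confers generalization
    (whether danger thoughts still predict aversive outcomes); the default
    scores total implicit movement.
    """
    d0 = store0.normalized_d(1)
    d1 = store.normalized_d(1)
    explicit_tv = 0.5 * float(np.abs(d1 - d0).sum())
    a0 = store0.normalized_a(2)
    a1 = store.normalized_a(2)
    beliefs = {"dangerous": (0,), "safe": (1,), "both": (0, 1)}[belief]
    tvs = []
    for belief_idx in beliefs:
        for b in (APPROACH, INTERACT):
            tvs.append(
                0.5 * float(np.abs(a1[:, SPIDER, belief_idx, b] - a0[:, SPIDER, belief_idx, b]).sum())
            )
    return explicit_tv, float(np.mean(tvs))
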