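import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbtsim.engine import (
    EXPOSURE_PRIOR_EPS,
    WorldProcess,
    expected_free_energy,
    generate_observation,
    infer_states_exact,
    infer_states_variational,
    policy_posterior,
    run_trial,
    select_action,
)
from cbtsim.model import (
    APPROACH,
    APPROACH_POLICY,
    AVOID,
    AVOID_POLICY,
    HIGH,
    INTERACT,
    LOW,
    NEGATIVE,
    NEUTRAL,
    NO_SPIDER,
    OBSERVE,
    POLICIES,
    POSITIVE,
    SAFE,
    SAFETY_COST,
    SPIDER,
    START,
    CBTParams,
    build_cbt_model,
)

probs = st.floats(0.0, 1.0, allow_nan=False)


# ---------------------------------------------------------------------------
# generative process
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "behavior,expected",
    [
        (START, (NO_SPIDER, LOW, NEUTRAL, START)),
        (OBSERVE, (SPIDER, HIGH, NEUTRAL, OBSERVE)),
        (APPROACH, (SPIDER, LOW, POSITIVE, APPROACH)),
        (INTERACT, (SPIDER, LOW, POSITIVE, INTERACT)),
        (AVOID, (SPIDER, HIGH, NEGATIVE, AVOID)),
        (SAFETY_COST, (SPIDER, LOW, NEGATIVE, SAFETY_COST)),
    ],
)
def test_safe_world_emissions(behavior, expected):
    world = WorldProcess()
    assert generate_observation(world, behavior, 2) == expected


def test_world_rejects_bad_inputs():
    world = WorldProcess()
    with pytest.raises(ValueError):
        generate_observation(world, START, 0)
    with pytest.raises(ValueError):
        generate_observation(world, 17, 2)


# ---------------------------------------------------------------------------
# state inference
# ---------------------------------------------------------------------------


def brute_force_posterior(model, observations, policy):
    """Independent oracle: explicit loop over the four joint states."""
    traj = [START, *list(policy)]
    post = np.zeros((2, 2))
    for s0 in range(2):
        for s1 in range(2):
            p = model.D[0][s0] * model.D[1][s1]
            for t, obs in enumerate(observations):
                for m, o in enumerate(obs):
                    p *= max(model.A[m][o, s0, s1, traj[t]], 1e-16)
            post[s0, s1] = p
    return post / post.sum()


def exposure_observations():
    world = WorldProcess()
    traj = [START, OBSERVE, APPROACH, INTERACT]
    return [world.observe(b, t + 1) for t, b in enumerate(traj)]


def test_uninformative_evidence_leaves_prior():
    model = build_cbt_model(CBTParams(danger=0.7, cab_i=0.4))
    obs = [WorldProcess().observe(START, 1)]  # pre-stimulus step carries no evidence
    q, _ = infer_states_exact(model, obs, POLICIES[APPROACH_POLICY])
    np.testing.assert_allclose(q.sum(axis=1), model.D[0], atol=1e-12)
    np.testing.assert_allclose(q.sum(axis=0), model.D[1], atol=1e-12)


def test_positive_affect_at_approach_is_evidence_for_safety():
    model = build_cbt_model(CBTParams(danger=0.5, cab_i=0.9))
    obs = exposure_observations()[:3]  # through the approach step
    q, _ = infer_states_exact(model, obs, POLICIES[APPROACH_POLICY])
    oracle = brute_force_posterior(model, obs, POLICIES[APPROACH_POLICY])
    np.testing.assert_allclose(q, oracle, atol=1e-12)
    assert q.sum(axis=0)[SAFE] > 0.5


def test_degenerate_prior_is_absorbing():
    model = build_cbt_model(CBTParams(danger=1.0, cab_i=0.9))
    q, _ = infer_states_exact(model, exposure_observations(), POLICIES[APPROACH_POLICY])
    assert q.sum(axis=0)[SAFE] < 1e-6


@pytest.mark.parametrize("danger", [0.0, 0.1, 0.5, 0.9, 1.0])
@pytest.mark.parametrize("cab", [0.1, 0.5, 0.9])
def test_exact_matches_variational(danger, cab):
    """Mean-field coordinate ascent agrees with enumeration on this model."""
    model = build_cbt_model(CBTParams(danger=danger, cab_i=cab))
    for policy in POLICIES:
        world = WorldProcess()
        traj = [START, *list(policy)]
        obs = [world.observe(b, t + 1) for t, b in enumerate(traj)]
        for upto in (1, 2, 4):
            q_exact, F_exact = infer_states_exact(model, obs[:upto], policy)
            q_var, F_var = infer_states_variational(model, obs[:upto], policy)
            np.testing.assert_allclose(q_var, q_exact, atol=1e-6)
            assert abs(F_var - F_exact) < 1e-5


# ---------------------------------------------------------------------------
# expected free energy and policy selection
# ---------------------------------------------------------------------------


@given(danger=probs, cab=probs)
@settings(max_examples=40, deadline=None)
def test_risk_and_ambiguity_are_nonnegative(danger, cab):
    model = build_cbt_model(CBTParams(danger=danger, cab_i=cab))
    q = np.outer(model.D[0], model.D[1])
    for policy in POLICIES:
        G, risk, ambiguity, novelty = expected_free_energy(model, policy, q, 1)
        assert risk >= -1e-9
        assert ambiguity >= -1e-9
        assert np.isfinite(G)
        assert novelty == 0.0  # no Dirichlet store supplied


@pytest.mark.parametrize(
    "danger,faster",
    [(1.0, AVOID_POLICY), (0.0, APPROACH_POLICY)],
)
def test_efe_orders_policies_by_explicit_belief(danger, faster):
    model = build_cbt_model(CBTParams(danger=danger, cab_i=0.9))
    q = np.outer(np.array([0.0, 1.0]), model.D[1])  # spider observed
    G = [expected_free_energy(model, POLICIES[p], q, 2)[0] for p in range(2)]
    assert G[faster] < G[1 - faster]


def test_avoidance_persists_under_weak_cab_despite_safety_belief():
    model = build_cbt_model(CBTParams(danger=0.0, cab_i=0.1))
    q = np.outer(np.array([0.0, 1.0]), model.D[1])
    G = [expected_free_energy(model, POLICIES[p], q, 2)[0] for p in range(2)]
    assert G[AVOID_POLICY] < G[APPROACH_POLICY]


class TestPolicyPosterior:
    def test_symmetry(self):
        q = policy_posterior(np.zeros(2), np.zeros(2), np.array([0.5, 0.5]), 2.0)
        np.testing.assert_allclose(q, [0.5, 0.5])

    def test_precise_exposure_prior_dominates_moderate_g_differences(self):
        E = np.array([1 - 1e-6, 1e-6])
        q = policy_posterior(np.array([3.0, 0.0]), np.zeros(2), E, 1.0)
        assert q[APPROACH_POLICY] > 0.99

    def test_zero_precision_limit_is_uniform(self):
        q = policy_posterior(np.array([5.0, 1.0]), np.zeros(2), np.array([0.5, 0.5]), 0.0)
        np.testing.assert_allclose(q, [0.5, 0.5])

    def test_mask_excludes_policies(self):
        q = policy_posterior(np.zeros(2), np.zeros(2), np.array([0.5, 0.5]), 1.0,
                             mask=np.array([True, False]))
        np.testing.assert_allclose(q, [1.0, 0.0])


class TestSelectAction:
    def test_degenerate_posterior(self, rng):
        action, p = select_action(np.array([1.0, 0.0]), POLICIES, 2, rng)
        assert action == APPROACH and p == 1.0

    def test_law_of_large_numbers(self, rng):
        draws = [select_action(np.array([0.5, 0.5]), POLICIES, 2, rng)[0] for _ in range(10_000)]
        frac = np.mean([a == APPROACH for a in draws])
        assert abs(frac - 0.5) < 0.02

    def test_same_seed_same_sequence(self):
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            seqs.append([select_action(np.array([0.3, 0.7]), POLICIES, 2, rng)[0] for _ in range(50)])
        assert seqs[0] == seqs[1]


# ---------------------------------------------------------------------------
# full trials
# ---------------------------------------------------------------------------


def one_trial(danger, cab, seed=3, **kw):
    model = build_cbt_model(CBTParams(danger=danger, cab_i=cab), **kw)
    return run_trial(model, WorldProcess(), np.random.default_rng(seed))


def test_precise_danger_beliefs_produce_avoidance_with_sustained_arousal():
    trial = one_trial(1.0, 0.9)
    assert trial.behaviors.tolist() == [START, OBSERVE, AVOID, SAFETY_COST]
    assert trial.arousal_trace.tolist() == [LOW, HIGH, HIGH, LOW]


def test_precise_safety_beliefs_produce_approach_with_transient_arousal():
    trial = one_trial(0.0, 0.9)
    assert trial.behaviors.tolist() == [START, OBSERVE, APPROACH, INTERACT]
    assert trial.arousal_trace.tolist() == [LOW, HIGH, LOW, LOW]


def test_weak_cab_interactions_preserve_avoidance_despite_safety_belief():
    trial = one_trial(0.0, 0.1)
    assert trial.behaviors.tolist() == [START, OBSERVE, AVOID, SAFETY_COST]


def test_policies_share_free_energy_before_the_choice_point():
    trial = one_trial(0.5, 0.5)
    for t in (0, 1):
        F = trial.evaluations[t].F
        assert abs(F[0] - F[1]) < 1e-9


def test_forced_exposure_selects_approach():
    model = build_cbt_model(CBTParams(danger=0.9, cab_i=0.9))
    trial = run_trial(
        model,
        WorldProcess(),
        np.random.default_rng(0),
        forced_policy=APPROACH_POLICY,
        exposure_eps=EXPOSURE_PRIOR_EPS,
    )
    assert trial.behaviors.tolist() == [START, OBSERVE, APPROACH, INTERACT]


def test_response_prevention_masks_avoidance():
    model = build_cbt_model(CBTParams(danger=1.0, cab_i=0.9))
    trial = run_trial(
        model,
        WorldProcess(),
        np.random.default_rng(0),
        forced_policy=APPROACH_POLICY,
        exposure_mode="response_prevention",
    )
    assert trial.behaviors.tolist() == [START, OBSERVE, APPROACH, INTERACT]


def test_softer_harm_aversion_never_decreases_approach_probability():
    previous = -np.inf
    for harm in (-12.0, -8.0, -4.0, -2.0, 0.0):
        model = build_cbt_model(CBTParams(danger=0.5, cab_i=0.9, preference_harm=harm))
        trial = run_trial(model, WorldProcess(), np.random.default_rng(0))
        p_approach = trial.beliefs[1].policy_posterior[APPROACH_POLICY]
        assert p_approach >= previous - 1e-9
        previous = p_approach


def test_seeded_trials_are_bit_reproducible():
    a = one_trial(0.6, 0.5, seed=11)
    b = one_trial(0.6, 0.5, seed=11)
    assert np.array_equal(a.behaviors, b.behaviors)
    assert np.array_equal(a.observations, b.observations)
    assert a.to_json() == b.to_json()


def test_trial_record_exports():
    trial = one_trial(1.0, 0.9)
    frame = trial.to_frame()
    assert set(frame.columns) == {"trial", "t", "channel", "level", "value"}
    assert frame["t"].max() == 4
    assert (frame[frame.channel == "observation:arousal"].level == "high").sum() == 2
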