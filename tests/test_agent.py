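"""Recurrent actor-critic: forward dynamics, losses, BPTT gradients."""

import numpy as np
import pytest

from metabandit import agent
from metabandit.agent import (
    Rollout,
    SubnetParams,
    TrainConfig,
    compute_losses,
    extract_unit_activity,
    init_params,
    n_step_returns,
    recurrent_step,
    run_session,
    segment_gradients,
    session_update,
)
from metabandit.task_env import TaskConfig


def toy_cfg(**kw):
    defaults = dict(n_units=4, trials_per_session=5, unroll_length=1000)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestRecurrentStep:
    def test_zero_params_give_zero_output(self):
        sub = SubnetParams(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros(3))
        y = recurrent_step(sub, np.array([1.0, 0.5, -1.0]), np.ones(3))
        assert np.allclose(y, 0)

    def test_pure_bias_gives_tanh_of_bias(self):
        sub = SubnetParams(np.zeros((3, 3)), np.zeros((3, 3)), np.ones(3))
        y = recurrent_step(sub, np.zeros(3), np.zeros(3))
        assert np.allclose(y, np.tanh(1.0))

    def test_outputs_bounded_by_one(self, rng):
        sub = SubnetParams(rng.normal(size=(5, 3)), rng.normal(size=(5, 5)),
                           rng.normal(size=5))
        y = recurrent_step(sub, rng.normal(size=3), rng.normal(size=5))
        assert np.all(np.abs(y) < 1)

    def test_rejects_non_finite(self):
        sub = SubnetParams(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros(3))
        with pytest.raises(ValueError):
            recurrent_step(sub, np.array([np.nan, 0, 0]), np.zeros(3))


class TestRunSession:
    def test_untrained_agent_is_unbiased(self):
        cfg = toy_cfg(n_units=50, trials_per_session=500)
        params = init_params(50, np.random.default_rng(0))
        rec, _ = run_session(params, TaskConfig(), cfg,
                             np.random.default_rng(1))
        from metabandit.task_env import p_choose_high
        p = p_choose_high(rec)
        assert abs(p - 0.5) < 4 * np.sqrt(0.25 / 500)

    def test_first_trial_inputs_all_zero(self):
        cfg = toy_cfg()
        params = init_params(cfg.n_units, np.random.default_rng(0))
        _, ro = run_session(params, TaskConfig(), cfg,
                            np.random.default_rng(2))
        first_trial = ro.trial_of_step == 0
        assert np.all(ro.x[first_trial] == 0)

    def test_input_active_only_at_first_step_after_choice(self):
        cfg = toy_cfg(trials_per_session=20)
        params = init_params(cfg.n_units, np.random.default_rng(0))
        _, ro = run_session(params, TaskConfig(), cfg,
                            np.random.default_rng(3))
        for t in range(1, 20):
            steps = np.flatnonzero(ro.trial_of_step == t)
            assert np.any(ro.x[steps[0], 1:] != 0)  # choice input present
            assert np.all(ro.x[steps[1:]] == 0)

    def test_bit_reproducible_under_seed(self):
        cfg = toy_cfg(trials_per_session=50)
        params = init_params(cfg.n_units, np.random.default_rng(0))
        a = run_session(params, TaskConfig(), cfg, np.random.default_rng(5))
        b = run_session(params, TaskConfig(), cfg, np.random.default_rng(5))
        assert a[0].choices == b[0].choices
        assert np.array_equal(a[1].y_actor, b[1].y_actor)

    def test_zero_fraction_inactivation_is_identity(self):
        cfg = toy_cfg(trials_per_session=30)
        params = init_params(cfg.n_units, np.random.default_rng(0))
        flags = np.zeros(30, dtype=bool)
        flags[::5] = True
        a = run_session(params, TaskConfig(), cfg, np.random.default_rng(6))
        b = run_session(params, TaskConfig(), cfg, np.random.default_rng(6),
                        inactivation_trials=flags,
                        inactivated_units=np.empty(0, dtype=int))
        assert a[0].choices == b[0].choices
        assert np.array_equal(a[1].y_actor, b[1].y_actor)

    def test_inactivation_zeroes_selected_units_at_penultimate_step(self):
        cfg = toy_cfg(trials_per_session=30, n_units=6)
        params = init_params(6, np.random.default_rng(1))
        flags = np.zeros(30, dtype=bool)
        flags[10] = True
        units = np.array([0, 1, 7])  # two actor units, one critic unit
        _, ro = run_session(params, TaskConfig(), cfg,
                            np.random.default_rng(7),
                            inactivation_trials=flags,
                            inactivated_units=units)
        steps = np.flatnonzero(ro.trial_of_step == 10)
        pen = steps[-2]
        assert np.all(ro.y_actor[pen, [0, 1]] == 0)
        assert ro.y_critic[pen, 1] == 0
        assert not np.all(ro.y_actor[steps[-1], [0, 1]] == 0)


def _toy_rollout():
    """Hand-built two-step rollout matching the worked loss example."""
    return Rollout(
        x=np.zeros((2, 3)),
        y_actor=np.zeros((2, 2)), y_critic=np.zeros((2, 2)),
        mask_actor=np.ones((2, 2)), mask_critic=np.ones((2, 2)),
        value=np.array([0.5, 0.0]),
        reward=np.array([1.0, 0.0]),
        is_choice=np.array([True, False]),
        action=np.array([0, -1]),
        pi=np.array([[0.5, 0.5], [np.nan, np.nan]]),
        trial_of_step=np.array([0, 0]),
    )


class TestLosses:
    def test_entropy_of_uniform_policy(self):
        ro = _toy_rollout()
        cfg = toy_cfg(n_units=2)
        # with delta known, entropy enters as -beta_e * ln 2
        R = n_step_returns(ro, 0, 2, cfg.gamma)
        delta = R - ro.value
        L_pi, _, _ = compute_losses(ro, cfg, 0, 2)
        expected = -np.log(0.5) * delta[0] - 0.5 * np.log(2)
        assert L_pi == pytest.approx(expected)

    def test_bootstrapped_return_hand_example(self):
        """Rewards (1, 0), bootstrap V=0.2 two steps ahead, gamma=0.5:
        R_0 = 1 + 0 + 0.25*0.2 = 1.05; with V(s_0)=0.5, delta = 0.55."""
        ro = _toy_rollout()
        ro3 = Rollout(
            x=np.zeros((3, 3)),
            y_actor=np.zeros((3, 2)), y_critic=np.zeros((3, 2)),
            mask_actor=np.ones((3, 2)), mask_critic=np.ones((3, 2)),
            value=np.array([0.5, 0.0, 0.2]),
            reward=np.array([1.0, 0.0, 0.0]),
            is_choice=np.array([False, False, False]),
            action=np.array([-1, -1, -1]),
            pi=np.full((3, 2), np.nan),
            trial_of_step=np.array([0, 0, 0]),
        )
        R = n_step_returns(ro3, 0, 2, gamma=0.5)
        assert R[0] == pytest.approx(1.05)
        assert R[0] - ro3.value[0] == pytest.approx(0.55)

    def test_policy_and_value_loss_hand_example(self):
        """pi(a)=0.5, A=1, beta_e=0.5 -> L_pi = -ln 0.5 - 0.5 ln 2 = 0.3466;
        R=1, V=0, beta_v=0.01 -> L_v contribution 0.005."""
        ro = Rollout(
            x=np.zeros((1, 3)),
            y_actor=np.zeros((1, 2)), y_critic=np.zeros((1, 2)),
            mask_actor=np.ones((1, 2)), mask_critic=np.ones((1, 2)),
            value=np.array([0.0]),
            reward=np.array([1.0]),
            is_choice=np.array([True]),
            action=np.array([0]),
            pi=np.array([[0.5, 0.5]]),
            trial_of_step=np.array([0]),
        )
        cfg = toy_cfg(n_units=2)
        L_pi, L_v, L_tot = compute_losses(ro, cfg, 0, 1)
        # R_0 = 1 (no bootstrap beyond session end), V=0 -> delta = 1
        assert L_pi == pytest.approx(-np.log(0.5) - 0.5 * np.log(2))
        assert L_pi == pytest.approx(0.34657, abs=1e-4)
        assert L_v == pytest.approx(0.005)
        assert L_tot == pytest.approx(L_pi + L_v)


def surrogate_loss(params, rollout, cfg, R_frozen):
    """Teacher-forced total loss with frozen returns and advantages.

    This is the objective whose exact gradient the A2C semi-gradient
    defines; it replays the forward pass under perturbed parameters while
    holding R_t, delta, actions and inputs at their rollout values.
    """
    H = params.n_units
    y_a = np.zeros(H)
    y_c = np.zeros(H)
    L = 0.0
    for i in range(rollout.n_steps):
        x = rollout.x[i]
        y_a = np.tanh(params.actor.Wx @ x + params.actor.Wy @ y_a
                      + params.actor.b) * rollout.mask_actor[i]
        y_c = np.tanh(params.critic.Wx @ x + params.critic.Wy @ y_c
                      + params.critic.b) * rollout.mask_critic[i]
        v = params.Wv @ y_c + params.bv
        delta_frozen = R_frozen[i] - rollout.value[i]
        if rollout.is_choice[i]:
            z = params.Wa @ y_a + params.ba
            z = z - z.max()
            pi = np.exp(z) / np.exp(z).sum()
            a = rollout.action[i]
            ent = -np.sum(pi * np.log(pi))
            L += -np.log(pi[a]) * delta_frozen - cfg.beta_e * ent
        L += cfg.beta_v * 0.5 * (R_frozen[i] - v) ** 2
    return L


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        """Analytic BPTT gradients agree with central finite differences of
        the teacher-forced surrogate loss to better than 1e-5 relative."""
        cfg = toy_cfg()
        params = init_params(cfg.n_units, np.random.default_rng(2))
        _, ro = run_session(params, TaskConfig(rng_seed=3), cfg,
                            np.random.default_rng(7))
        R = n_step_returns(ro, 0, ro.n_steps, cfg.gamma)
        g = segment_gradients(params, ro, cfg, 0, ro.n_steps)
        gvec = np.concatenate(
            [g[name].ravel() for name, _ in params._arrays()]
            + [np.atleast_1d(g["bv"])])
        vec0 = params.to_vector()
        eps = 1e-6
        fd = np.zeros_like(vec0)
        for j in range(len(vec0)):
            vp = vec0.copy(); vp[j] += eps
            vm = vec0.copy(); vm[j] -= eps
            fd[j] = (surrogate_loss(params.from_vector(vp), ro, cfg, R)
                     - surrogate_loss(params.from_vector(vm), ro, cfg, R)
                     ) / (2 * eps)
        rel = np.linalg.norm(gvec - fd) / np.linalg.norm(fd)
        assert rel < 1e-5

    def test_gradients_blocked_through_silenced_units(self):
        cfg = toy_cfg(trials_per_session=4)
        params = init_params(cfg.n_units, np.random.default_rng(4))
        flags = np.array([False, True, False, True])
        units = np.array([0, 5])
        _, ro = run_session(params, TaskConfig(), cfg,
                            np.random.default_rng(8),
                            inactivation_trials=flags,
                            inactivated_units=units)
        R = n_step_returns(ro, 0, ro.n_steps, cfg.gamma)
        g = segment_gradients(params, ro, cfg, 0, ro.n_steps)
        gvec = np.concatenate(
            [g[name].ravel() for name, _ in params._arrays()]
            + [np.atleast_1d(g["bv"])])
        vec0 = params.to_vector()
        eps = 1e-6
        fd = np.zeros_like(vec0)
        for j in range(len(vec0)):
            vp = vec0.copy(); vp[j] += eps
            vm = vec0.copy(); vm[j] -= eps
            fd[j] = (surrogate_loss(params.from_vector(vp), ro, cfg, R)
                     - surrogate_loss(params.from_vector(vm), ro, cfg, R)
                     ) / (2 * eps)
        rel = np.linalg.norm(gvec - fd) / np.linalg.norm(fd)
        assert rel < 1e-5


class TestSessionUpdate:
    def test_zero_learning_rate_leaves_params_unchanged(self):
        cfg = toy_cfg(learning_rate=0.0, trials_per_session=10,
                      unroll_length=10)
        params = init_params(cfg.n_units, np.random.default_rng(0))
        before = params.to_vector().copy()
        _, ro = run_session(params, TaskConfig(), cfg,
                            np.random.default_rng(1))
        opt = agent.RMSProp(params, cfg)
        session_update(params, ro, cfg, opt)
        assert np.array_equal(params.to_vector(), before)

    def test_update_modes_both_run(self):
        for mode in ("sequential", "averaged"):
            cfg = toy_cfg(trials_per_session=10, unroll_length=10,
                          update_mode=mode)
            params = init_params(cfg.n_units, np.random.default_rng(0))
            before = params.to_vector().copy()
            _, ro = run_session(params, TaskConfig(), cfg,
                                np.random.default_rng(1))
            session_update(params, ro, cfg, agent.RMSProp(params, cfg))
            assert not np.array_equal(params.to_vector(), before)


class TestActivityExtraction:
    def test_prechoice_mean_covers_three_steps_before_choice(self):
        cfg = toy_cfg(trials_per_session=10, n_units=2)
        params = init_params(2, np.random.default_rng(0))
        _, ro = run_session(params, TaskConfig(), cfg,
                            np.random.default_rng(9))
        act = extract_unit_activity(ro, "prechoice_mean3")
        acts = np.hstack([ro.y_actor, ro.y_critic])
        for t in range(10):
            steps = np.flatnonzero(ro.trial_of_step == t)
            cs = steps[-1]
            expect = acts[max(steps[0], cs - 3):cs].mean(axis=0)
            assert np.allclose(act.activity[t], expect)

    def test_postchoice_is_first_step_of_next_trial(self):
        cfg = toy_cfg(trials_per_session=6, n_units=2)
        params = init_params(2, np.random.default_rng(0))
        _, ro = run_session(params, TaskConfig(), cfg,
                            np.random.default_rng(10))
        act = extract_unit_activity(ro, "postchoice")
        acts = np.hstack([ro.y_actor, ro.y_critic])
        steps1 = np.flatnonzero(ro.trial_of_step == 1)
        assert np.allclose(act.activity[0], acts[steps1[0]])
        assert not act.included[-1]  # last trial has no post-choice step

    def test_unknown_epoch_rejected(self):
        cfg = toy_cfg(trials_per_session=4, n_units=2)
        params = init_params(2, np.random.default_rng(0))
        _, ro = run_session(params, TaskConfig(), cfg,
                            np.random.default_rng(11))
        with pytest.raises(ValueError):
            extract_unit_activity(ro, "nonsense")
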