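"""Recurrent actor-critic (A2C) agent meta-trained across bandit sessions.

Two parallel tanh recurrent subnetworks (50 units each for actor and critic)
receive three input neurons carrying the previous trial's outcome and choice
(reward, left, right), active only at the single time step immediately after
the previous choice.  Each trial lasts 4 or 5 recurrent time steps (drawn per
trial); the action is sampled from the softmax over the two actor logits at
the trial's final step, and the critic reads out a scalar state value at every
step.

Training follows single-worker A2C with truncated backpropagation through
time: per 50-step unroll segment,

    L_pi = -ln pi(a_t|s_t) * delta(s_t) - beta_e * H(pi)
    L_v  = beta_v * 0.5 * (R_t - V(s_t))^2

with the n-step bootstrapped return R_t (discount gamma per time step) and
TD-error advantage delta = R_t - V(s_t).  Crucially for meta-learning, the
weights are frozen *within* each 500-trial session and RMSProp updates are
applied only at session boundaries, so trial-by-trial learning must be carried
by recurrent activity dynamics rather than synaptic plasticity.

Gradients are computed analytically (hand-derived BPTT for the tanh
recurrence, softmax policy head and linear value head) and are validated
against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .task_env import (
    HighSideWindow,
    SessionRecord,
    TaskConfig,
    TrialRecord,
    bait_and_step,
    maybe_transition,
    new_state,
)

__all__ = [
    "SubnetParams",
    "AgentParams",
    "TrainConfig",
    "Rollout",
    "init_params",
    "recurrent_step",
    "run_session",
    "compute_losses",
    "segment_gradients",
    "session_update",
    "train",
    "inactivate_and_run",
    "extract_unit_activity",
]


@dataclass
class SubnetParams:
    """One tanh recurrent subnetwork: y_t = tanh(Wx x_t + Wy y_{t-1} + b)."""

    Wx: np.ndarray  # (H, 3)
    Wy: np.ndarray  # (H, H)
    b: np.ndarray   # (H,)

    def copy(self) -> "SubnetParams":
        return SubnetParams(self.Wx.copy(), self.Wy.copy(), self.b.copy())


@dataclass
class AgentParams:
    """Full parameter set: actor subnet + policy head, critic subnet + value head."""

    actor: SubnetParams
    Wa: np.ndarray  # (2, H) action logits head
    ba: np.ndarray  # (2,)
    critic: SubnetParams
    Wv: np.ndarray  # (H,) value head
    bv: float

    @property
    def n_units(self) -> int:
        return self.actor.Wy.shape[0]

    def copy(self) -> "AgentParams":
        return AgentParams(self.actor.copy(), self.Wa.copy(), self.ba.copy(),
                           self.critic.copy(), self.Wv.copy(), float(self.bv))

    # -- flat vector view, used by the finite-difference gradient oracle -----
    def _arrays(self) -> list[tuple[str, np.ndarray]]:
        return [
            ("actor.Wx", self.actor.Wx), ("actor.Wy", self.actor.Wy),
            ("actor.b", self.actor.b), ("Wa", self.Wa), ("ba", self.ba),
            ("critic.Wx", self.critic.Wx), ("critic.Wy", self.critic.Wy),
            ("critic.b", self.critic.b), ("Wv", self.Wv),
        ]

    def to_vector(self) -> np.ndarray:
        parts = [a.ravel() for _, a in self._arrays()] + [np.array([self.bv])]
        return np.concatenate(parts)

    def from_vector(self, vec: np.ndarray) -> "AgentParams":
        out = self.copy()
        i = 0
        for _, arr in out._arrays():
            n = arr.size
            arr[...] = vec[i:i + n].reshape(arr.shape)
            i += n
        out.bv = float(vec[i])
        return out


@dataclass(frozen=True)
class TrainConfig:
    """A2C meta-training hyperparameters."""

    learning_rate: float = 0.0005
    gamma: float = 0.5
    beta_e: float = 0.5
    beta_v: float = 0.01
    unroll_length: int = 50
    trials_per_session: int = 500
    n_sessions: int = 300
    n_units: int = 50
    steps_per_trial: tuple[int, int] = (4, 5)
    rmsprop_decay: float = 0.99
    rmsprop_eps: float = 1e-5
    update_mode: str = "sequential"  # or "averaged"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_units", "trials_per_session", "n_sessions",
                     "unroll_length"):
            if not isinstance(getattr(self, name), int):
                raise ValueError(f"{name} must be an integer")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must be in (0, 1]")
        if self.unroll_length < 1:
            raise ValueError("unroll_length must be >= 1")
        if self.update_mode not in ("sequential", "averaged"):
            raise ValueError(f"unknown update_mode {self.update_mode!r}")


@dataclass
class Rollout:
    """Per-time-step traces of one session."""

    x: np.ndarray          # (T, 3) inputs
    y_actor: np.ndarray    # (T, H) actor activations (post-inactivation)
    y_critic: np.ndarray   # (T, H)
    mask_actor: np.ndarray   # (T, H) 1 where unit active, 0 where silenced
    mask_critic: np.ndarray  # (T, H)
    value: np.ndarray      # (T,) critic output V(s_t)
    reward: np.ndarray     # (T,) reward delivered at this step
    is_choice: np.ndarray  # (T,) bool, action sampled at this step
    action: np.ndarray     # (T,) 0=L, 1=R, -1 elsewhere
    pi: np.ndarray         # (T, 2) softmax policy at choice steps (else nan)
    trial_of_step: np.ndarray  # (T,)

    @property
    def n_steps(self) -> int:
        return len(self.value)


def init_params(n_units: int = 50, rng: np.random.Generator | None = None,
                scale: float | None = None) -> AgentParams:
    """Glorot-uniform weights, zero biases."""
    rng = rng or np.random.default_rng(0)

    def glorot(shape):
        fan_out, fan_in = shape[0], (shape[1] if len(shape) > 1 else 1)
        limit = scale if scale is not None else np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    def subnet():
        return SubnetParams(Wx=glorot((n_units, 3)), Wy=glorot((n_units, n_units)),
                            b=np.zeros(n_units))

    return AgentParams(
        actor=subnet(), Wa=glorot((2, n_units)), ba=np.zeros(2),
        critic=subnet(), Wv=glorot((n_units,)), bv=0.0,
    )


def recurrent_step(subnet: SubnetParams, x_t: np.ndarray,
                   y_prev: np.ndarray) -> np.ndarray:
    """One tanh recurrence: y_t = tanh(Wx x_t + Wy y_prev + b)."""
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(y_prev))):
        raise ValueError("non-finite inputs to recurrent_step")
    return np.tanh(subnet.Wx @ x_t + subnet.Wy @ y_prev + subnet.b)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# Forward pass: one session in the environment
# ---------------------------------------------------------------------------

def run_session(
    params: AgentParams,
    task_cfg: TaskConfig,
    train_cfg: TrainConfig,
    rng: np.random.Generator,
    inactivation_trials: np.ndarray | None = None,
    inactivated_units: np.ndarray | None = None,
    inactivation_step: str = "penultimate",
) -> tuple[SessionRecord, Rollout]:
    """Run one frozen-weight session of the agent in the baited bandit.

    ``inactivation_trials`` is a boolean per-trial flag; on flagged trials the
    units listed in ``inactivated_units`` (indices into the concatenated
    [actor 0..H-1, critic H..2H-1] population) have their activations set to
    zero at the time step immediately before the action-selection step
    (``inactivation_step='penultimate'``, the analogue of silencing the
    prechoice period) or at the action-selection step itself (``'final'``).
    The zeroed state propagates through the recurrence either way.
    """
    H = params.n_units
    n_trials = train_cfg.trials_per_session
    if inactivation_trials is None:
        inactivation_trials = np.zeros(n_trials, dtype=bool)
    units_a = np.empty(0, dtype=int)
    units_c = np.empty(0, dtype=int)
    if inactivated_units is not None and len(inactivated_units):
        u = np.asarray(inactivated_units, dtype=int)
        units_a = u[u < H]
        units_c = u[u >= H] - H

    state = new_state(task_cfg, rng)
    window = HighSideWindow(task_cfg.postpone_window)

    xs, yas, ycs, mas, mcs = [], [], [], [], []
    values, rewards_step, is_choice, actions, pis, trial_ids = [], [], [], [], [], []
    trials: list[TrialRecord] = []

    y_a = np.zeros(H)
    y_c = np.zeros(H)
    prev_choice, prev_reward = None, 0
    lo_s, hi_s = train_cfg.steps_per_trial

    for t in range(n_trials):
        n_steps = int(rng.integers(lo_s, hi_s + 1))
        a_l, a_r = state.probs(task_cfg)
        high = task_cfg.high_side(state.pair_index)
        inact_here = bool(inactivation_trials[t])
        for s in range(n_steps):
            x = np.zeros(3)
            if s == 0 and prev_choice is not None:
                x[0] = prev_reward
                x[1] = 1.0 if prev_choice == "L" else 0.0
                x[2] = 1.0 if prev_choice == "R" else 0.0
            y_a = recurrent_step(params.actor, x, y_a)
            y_c = recurrent_step(params.critic, x, y_c)
            m_a = np.ones(H)
            m_c = np.ones(H)
            final = s == n_steps - 1
            inact_now = inact_here and (
                s == n_steps - 2 if inactivation_step == "penultimate"
                else final)
            if inact_now:
                y_a = y_a.copy()
                y_c = y_c.copy()
                y_a[units_a] = 0.0
                m_a[units_a] = 0.0
                y_c[units_c] = 0.0
                m_c[units_c] = 0.0
            v = float(params.Wv @ y_c + params.bv)
            xs.append(x); yas.append(y_a); ycs.append(y_c)
            mas.append(m_a); mcs.append(m_c)
            values.append(v); trial_ids.append(t)
            if final:
                logits = params.Wa @ y_a + params.ba
                pi = _softmax(logits)
                a = int(rng.random() < pi[1])  # 0=L with prob pi[0]
                choice = "L" if a == 0 else "R"
                reward, state = bait_and_step(state, choice, task_cfg, rng)
                is_choice.append(True); actions.append(a); pis.append(pi)
                rewards_step.append(float(reward))
                trials.append(TrialRecord(
                    trial=t, choice=choice, reward=reward, A_L=a_l, A_R=a_r,
                    block=state.block_index, included=True,
                    inactivation=inact_here,
                ))
                window.push(choice == high)
                state = maybe_transition(state, window.fraction(), task_cfg, rng)
                prev_choice, prev_reward = choice, reward
            else:
                is_choice.append(False); actions.append(-1)
                pis.append(np.full(2, np.nan)); rewards_step.append(0.0)

    rollout = Rollout(
        x=np.array(xs), y_actor=np.array(yas), y_critic=np.array(ycs),
        mask_actor=np.array(mas), mask_critic=np.array(mcs),
        value=np.array(values), reward=np.array(rewards_step),
        is_choice=np.array(is_choice), action=np.array(actions),
        pi=np.array(pis), trial_of_step=np.array(trial_ids),
    )
    record = SessionRecord(trials=trials, config=task_cfg,
                           generator="meta_rl_agent", seed=train_cfg.seed)
    return record, rollout


# ---------------------------------------------------------------------------
# Losses and truncated-BPTT gradients
# ---------------------------------------------------------------------------

def _segment_bounds(n_steps: int, unroll: int) -> list[tuple[int, int]]:
    return [(s, min(s + unroll, n_steps)) for s in range(0, n_steps, unroll)]


def n_step_returns(rollout: Rollout, start: int, end: int,
                   gamma: float) -> np.ndarray:
    """Bootstrapped returns R_t = r_t + gamma R_{t+1} within [start, end).

    The bootstrap is the critic's value at the first step of the next segment
    (0 at session end).
    """
    v_boot = rollout.value[end] if end < rollout.n_steps else 0.0
    R = np.empty(end - start)
    acc = v_boot
    for i in range(end - 1, start - 1, -1):
        acc = rollout.reward[i] + gamma * acc
        R[i - start] = acc
    return R


def compute_losses(rollout: Rollout, cfg: TrainConfig,
                   start: int = 0, end: int | None = None
                   ) -> tuple[float, float, float]:
    """Policy, value and total loss summed over one unroll segment."""
    end = rollout.n_steps if end is None else end
    R = n_step_returns(rollout, start, end, cfg.gamma)
    delta = R - rollout.value[start:end]
    L_pi = 0.0
    for i in range(start, end):
        if not rollout.is_choice[i]:
            continue
        pi = rollout.pi[i]
        a = rollout.action[i]
        if pi[a] <= 0:
            raise FloatingPointError("zero action probability")
        ent = -np.sum(pi * np.log(pi))
        L_pi += -np.log(pi[a]) * delta[i - start] - cfg.beta_e * ent
    L_v = float(cfg.beta_v * 0.5 * np.sum(delta ** 2))
    return float(L_pi), L_v, float(L_pi) + L_v


def _zero_grads(params: AgentParams) -> dict[str, np.ndarray]:
    g = {name: np.zeros_like(arr) for name, arr in params._arrays()}
    g["bv"] = np.zeros(())
    return g


def segment_gradients(params: AgentParams, rollout: Rollout, cfg: TrainConfig,
                      start: int, end: int) -> dict[str, np.ndarray]:
    """Analytic gradients of the segment's total loss wrt all parameters.

    BPTT is truncated at segment boundaries: no gradient flows into earlier
    segments' activations, and the bootstrap value and the advantage are
    treated as constants (standard A2C; the value loss trains the critic
    through -beta_v * delta * dV/dtheta_c only).
    """
    H = params.n_units
    g = _zero_grads(params)
    R = n_step_returns(rollout, start, end, cfg.gamma)
    delta = R - rollout.value[start:end]

    dy_a_next = np.zeros(H)
    dy_c_next = np.zeros(H)
    for i in range(end - 1, start - 1, -1):
        y_a = rollout.y_actor[i]
        y_c = rollout.y_critic[i]
        # at the segment boundary the previous activation is a constant wrt
        # BPTT, but its value still enters the Wy gradient
        y_a_prev = rollout.y_actor[i - 1] if i > 0 else np.zeros(H)
        y_c_prev = rollout.y_critic[i - 1] if i > 0 else np.zeros(H)
        x = rollout.x[i]

        # ----- actor: policy + entropy loss at choice steps ----------------
        dy_a = dy_a_next.copy()
        if rollout.is_choice[i]:
            pi = rollout.pi[i]
            a = rollout.action[i]
            ent = -np.sum(pi * np.log(pi))
            onehot = np.zeros(2)
            onehot[a] = 1.0
            # d(-ln pi_a * delta)/dz = -delta (onehot - pi)
            # d(-beta_e H)/dz_j     = beta_e pi_j (ln pi_j + H)
            dz = -delta[i - start] * (onehot - pi) \
                + cfg.beta_e * pi * (np.log(pi) + ent)
            g["Wa"] += np.outer(dz, y_a)
            g["ba"] += dz
            dy_a += params.Wa.T @ dz

        # ----- critic: value loss at every step ----------------------------
        dv = -cfg.beta_v * delta[i - start]
        dy_c = dy_c_next + params.Wv * dv
        g["Wv"] += dv * y_c
        g["bv"] += dv

        # ----- backprop through the tanh recurrence ------------------------
        # silenced units pass no gradient (their output was clamped to 0)
        dpre_a = dy_a * (1.0 - y_a ** 2) * rollout.mask_actor[i]
        dpre_c = dy_c * (1.0 - y_c ** 2) * rollout.mask_critic[i]
        g["actor.Wx"] += np.outer(dpre_a, x)
        g["actor.Wy"] += np.outer(dpre_a, y_a_prev)
        g["actor.b"] += dpre_a
        g["critic.Wx"] += np.outer(dpre_c, x)
        g["critic.Wy"] += np.outer(dpre_c, y_c_prev)
        g["critic.b"] += dpre_c
        if i > start:
            dy_a_next = params.actor.Wy.T @ dpre_a
            dy_c_next = params.critic.Wy.T @ dpre_c
    return g


class RMSProp:
    """Root-mean-square-propagation optimizer state."""

    def __init__(self, params: AgentParams, cfg: TrainConfig):
        self.cache = _zero_grads(params)
        self.lr = cfg.learning_rate
        self.decay = cfg.rmsprop_decay
        self.eps = cfg.rmsprop_eps

    def apply(self, params: AgentParams, grads: dict[str, np.ndarray]) -> None:
        arrays = dict(params._arrays())
        for name, grad in grads.items():
            c = self.cache[name]
            c *= self.decay
            c += (1 - self.decay) * grad ** 2
            step = self.lr * grad / (np.sqrt(c) + self.eps)
            if name == "bv":
                params.bv = float(params.bv - step)
            else:
                arrays[name] -= step


def session_update(params: AgentParams, rollout: Rollout, cfg: TrainConfig,
                   opt: RMSProp) -> AgentParams:
    """Apply the session's per-segment BPTT gradients at the session boundary.

    Gradients for every 50-step unroll segment are computed against the
    frozen within-session parameters, then applied in order with RMSProp
    (``update_mode='sequential'``) or averaged into a single step
    (``'averaged'``).  Parameters are modified in place and returned.
    """
    segs = _segment_bounds(rollout.n_steps, cfg.unroll_length)
    grads = [segment_gradients(params, rollout, cfg, s, e) for s, e in segs]
    for gseg in grads:
        for name, arr in gseg.items():
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite gradient in {name}")
    if cfg.update_mode == "sequential":
        for gseg in grads:
            opt.apply(params, gseg)
    else:
        avg = _zero_grads(params)
        for gseg in grads:
            for name in avg:
                avg[name] = avg[name] + gseg[name]
        for name in avg:
            avg[name] = avg[name] / len(grads)
        opt.apply(params, avg)
    return params


def train(
    task_cfg: TaskConfig,
    train_cfg: TrainConfig,
    seed: int | None = None,
    keep_rollouts: bool = False,
    progress: Callable[[int, dict], None] | None = None,
) -> dict:
    """Meta-train the agent: n_sessions updates plus one frozen evaluation
    session.

    Returns a dict with the final parameters, per-session SessionRecords
    (n_sessions + 1, the last one from the evaluation session), a per-session
    log (mean reward, losses) and optionally the evaluation rollout.
    """
    seed = train_cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    params = init_params(train_cfg.n_units, rng)
    opt = RMSProp(params, train_cfg)
    records: list[SessionRecord] = []
    rollouts: list[Rollout] = []
    log: list[dict] = []
    for k in range(train_cfg.n_sessions):
        record, rollout = run_session(params, task_cfg, train_cfg, rng)
        record.session_number = k
        L_pi, L_v, L_tot = compute_losses(rollout, train_cfg)
        session_update(params, rollout, train_cfg, opt)
        records.append(record)
        if keep_rollouts:
            rollouts.append(rollout)
        entry = {"session": k, "mean_reward": float(record.rewards.mean()),
                 "L_pi": L_pi, "L_v": L_v, "L_tot": L_tot}
        log.append(entry)
        if progress is not None:
            progress(k, entry)
    # frozen evaluation session
    record, rollout = run_session(params, task_cfg, train_cfg, rng)
    record.session_number = train_cfg.n_sessions
    records.append(record)
    return {"params": params, "sessions": records, "log": log,
            "eval_rollout": rollout, "rollouts": rollouts}


def inactivate_and_run(
    params: AgentParams,
    fraction: float,
    task_cfg: TaskConfig,
    train_cfg: TrainConfig,
    n_repeats: int = 50,
    rate: float = 0.13,
    min_gap: int = 4,
    seed: int = 0,
) -> list[tuple[SessionRecord, Rollout]]:
    """Silence a random fraction of recurrent units on ~13% of trials.

    Each repeat draws a fresh unit subset (floor(fraction * 2H) units out of
    the concatenated actor+critic population) and a fresh inactivation-trial
    schedule (every flagged trial followed by >= min_gap control trials), then
    runs one frozen-weight session.  Results are averaged downstream by the
    split history regression.
    """
    from .synth import gen_inactivation_schedule

    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    total = 2 * params.n_units
    n_off = int(np.floor(fraction * total))
    out = []
    rng = np.random.default_rng(seed)
    for r in range(n_repeats):
        units = rng.choice(total, size=n_off, replace=False) if n_off else \
            np.empty(0, dtype=int)
        flags = gen_inactivation_schedule(
            train_cfg.trials_per_session, rate=rate, min_gap=min_gap,
            rng=rng) if n_off else np.zeros(train_cfg.trials_per_session, bool)
        record, rollout = run_session(
            params, task_cfg, train_cfg, rng,
            inactivation_trials=flags, inactivated_units=units)
        record.session_number = r
        out.append((record, rollout))
    return out


def extract_unit_activity(rollout: Rollout, epoch: str = "prechoice_mean3"):
    """Trials x 100 activity table of the concatenated recurrent units.

    ``prechoice_mean3``: mean activation over the three time steps preceding
    the choice step of each trial (the epoch used for value decoding).
    ``postchoice``: activation at the first step of the following trial (the
    step that receives the outcome input); the session's last trial has no
    such step and is marked not included.
    """
    from .decoding import PopulationActivity

    trial_ids = rollout.trial_of_step
    n_trials = int(trial_ids.max()) + 1
    acts = np.hstack([rollout.y_actor, rollout.y_critic])
    n_units = acts.shape[1]
    table = np.zeros((n_trials, n_units))
    included = np.ones(n_trials, dtype=bool)
    choice_steps = np.flatnonzero(rollout.is_choice)
    if epoch == "prechoice_mean3":
        for t, cs in enumerate(choice_steps):
            first = np.searchsorted(trial_ids, t)
            lo = max(first, cs - 3)
            table[t] = acts[lo:cs].mean(axis=0)
    elif epoch == "postchoice":
        for t, cs in enumerate(choice_steps):
            if cs + 1 < len(acts):
                table[t] = acts[cs + 1]
            else:
                included[t] = False
    else:
        raise ValueError(f"unknown epoch {epoch!r}")
    return PopulationActivity(
        session_id="rollout", activity=table,
        neuron_ids=np.arange(n_units), included=included, epoch=epoch)
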