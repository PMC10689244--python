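"""Synthetic behavior and neural populations with known ground truth.

Every analysis stage in this package is validated on data generated here:

* behavior from a forgetting-Q-learning *teacher* (or a logistic
  history-kernel teacher) playing the real baited-bandit environment, with
  its true value trajectories recorded, plus optional lapse (alarm/miss
  analogue) trials marked ``included=False``;
* population activity as a linear readout of standardized value signals
  (dQ, sumQ, Q_ch) through per-neuron coding weights, plus a slow smoothed
  random-walk drift and white noise — exactly the structure the
  trial-difference decoder assumes, and the structure that defeats naive
  per-trial decoders;
* longitudinal studies with two interleaved imaging "planes" per subject,
  persistent neuron identities, per-session neuron dropout, and coding
  weights/behavior kernels that rotate early in training and stabilize late;
* inactivation-trial schedules with a target flag rate and an enforced run
  of control trials after every flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import N_LAGS, RLParams, rl_update, choice_prob, run_rl_values, ValueSeries
from .decoding import PopulationActivity
from .task_env import (
    HighSideWindow,
    SessionRecord,
    TaskConfig,
    TrialRecord,
    bait_and_step,
    maybe_transition,
    new_state,
    session_to_frame,
)

__all__ = [
    "TeacherSpec",
    "NeuralGenSpec",
    "gen_behavior_session",
    "gen_history_behavior_session",
    "gen_population",
    "gen_population_epochs",
    "gen_longitudinal_study",
    "gen_inactivation_schedule",
    "write_dataset",
]

DEFAULT_RL = RLParams(alpha_rew=0.6, alpha_unr=0.2, omega=0.1,
                      beta_dq=3.0, beta_0=0.0)
# teacher history kernel: recency-weighted reward following, no choice kernel
DEFAULT_KERNEL_R = np.array([0.8, 0.4, 0.2, 0.1, 0.05])


@dataclass(frozen=True)
class TeacherSpec:
    """Generative behavioral model and its longitudinal schedule."""

    rl: RLParams = DEFAULT_RL
    lapse_rate: float = 0.0          # alarm/miss analogue, included=False
    kernel_r: tuple = tuple(DEFAULT_KERNEL_R)
    kernel_c: tuple = (0.0,) * N_LAGS
    kernel_bias: float = 0.0
    schedule: str = "fixed"          # "fixed" | "rotate_then_freeze"
    rotation_deg: float = 45.0       # initial per-session rotation
    rotation_tau: float = 4.0        # e-folding of the rotation, in sessions

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse_rate < 1.0):
            raise ValueError("lapse_rate must be in [0, 1)")
        if self.schedule not in ("fixed", "rotate_then_freeze"):
            raise ValueError(f"unknown schedule {self.schedule!r}")

    def rotation_at(self, k: int) -> float:
        """Rotation magnitude (degrees) applied going into session k."""
        if self.schedule == "fixed" or k == 0:
            return 0.0
        return self.rotation_deg * float(np.exp(-(k - 1) / self.rotation_tau))


@dataclass(frozen=True)
class NeuralGenSpec:
    """Linear-readout population model.

    Default scales put the drift at twice the coding signal and the white
    noise at the coding signal's scale, so slow-drift artifacts are a real
    hazard for naive decoders without burying the true code.
    """

    n_neurons: int = 80
    targets: tuple = ("dQ", "sumQ", "Q_ch")
    coding_sd: float = 1.0
    noise_sd: float = 1.0
    drift_sd: float = 2.0
    drift_smooth_tau: float = 20.0   # trials
    dropout_rate: float = 0.1        # per-session neuron dropout
    epoch_gains: tuple = (("prechoice_mean3", 1.0),)

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        for name in ("coding_sd", "noise_sd", "drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Behavior generators
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)


def gen_behavior_session(
    teacher: TeacherSpec,
    task_cfg: TaskConfig,
    seed=0,
    n_trials: int | None = None,
) -> tuple[SessionRecord, ValueSeries]:
    """RL teacher plays the baited bandit; true value series recorded.

    Lapse trials (choice='none', included=False) are inserted at
    ``teacher.lapse_rate``; the teacher's values are frozen through them.
    The returned ValueSeries is indexed over included choice trials, matching
    the convention of the fitting and decoding code.
    """
    rng = _as_rng(seed)
    n = n_trials if n_trials is not None else task_cfg.n_trials_per_session
    p = teacher.rl
    variant = "deepRL" if p.beta_c is not None else "mouse"
    state = new_state(task_cfg, rng)
    window = HighSideWindow(task_cfg.postpone_window)
    trials: list[TrialRecord] = []
    q_l = q_r = 0.5
    prev = 0
    Q_L, Q_R, Q_ch = [], [], []
    prev_side = None
    for t in range(n):
        a_l, a_r = state.probs(task_cfg)
        high = task_cfg.high_side(state.pair_index)
        if rng.random() < teacher.lapse_rate:
            _, state = bait_and_step(state, "none", task_cfg, rng)
            trials.append(TrialRecord(trial=t, choice="none", reward=0,
                                      A_L=a_l, A_R=a_r,
                                      block=state.block_index,
                                      included=False))
        else:
            p_l = choice_prob(q_l, q_r, prev, p, variant)
            choice = "L" if rng.random() < p_l else "R"
            reward, state = bait_and_step(state, choice, task_cfg, rng)
            Q_L.append(q_l)
            Q_R.append(q_r)
            Q_ch.append((q_l if prev_side == "L" else q_r)
                        if prev_side is not None else np.nan)
            if choice == "L":
                q_l, q_r = rl_update(q_l, q_r, reward, p)
                prev = 1
            else:
                q_r, q_l = rl_update(q_r, q_l, reward, p)
                prev = -1
            prev_side = choice
            trials.append(TrialRecord(trial=t, choice=choice, reward=reward,
                                      A_L=a_l, A_R=a_r,
                                      block=state.block_index))
            window.push(choice == high)
        state = maybe_transition(state, window.fraction(), task_cfg, rng)
    record = SessionRecord(trials=trials, config=task_cfg,
                           generator="rl_teacher", seed=task_cfg.rng_seed)
    values = ValueSeries(Q_L=np.array(Q_L), Q_R=np.array(Q_R),
                         Q_ch=np.array(Q_ch))
    return record, values


def gen_history_behavior_session(
    kernel_r: np.ndarray,
    kernel_c: np.ndarray,
    bias: float,
    task_cfg: TaskConfig,
    seed=0,
    n_trials: int | None = None,
    lapse_rate: float = 0.0,
) -> SessionRecord:
    """Logistic history-kernel teacher playing the baited bandit.

    The left-choice log-odds are the 5-lag signed reward- and choice-history
    differences weighted by the given kernels, plus a constant bias — the
    generative counterpart of the history regression that analysis refits.
    """
    rng = _as_rng(seed)
    n = n_trials if n_trials is not None else task_cfg.n_trials_per_session
    kernel_r = np.asarray(kernel_r, dtype=float)
    kernel_c = np.asarray(kernel_c, dtype=float)
    state = new_state(task_cfg, rng)
    window = HighSideWindow(task_cfg.postpone_window)
    trials: list[TrialRecord] = []
    rdiff_hist: list[float] = []   # over included choice trials
    cdiff_hist: list[float] = []
    for t in range(n):
        a_l, a_r = state.probs(task_cfg)
        high = task_cfg.high_side(state.pair_index)
        if rng.random() < lapse_rate:
            _, state = bait_and_step(state, "none", task_cfg, rng)
            trials.append(TrialRecord(trial=t, choice="none", reward=0,
                                      A_L=a_l, A_R=a_r,
                                      block=state.block_index,
                                      included=False))
        else:
            z = bias
            for i in range(1, N_LAGS + 1):
                if len(rdiff_hist) >= i:
                    z += kernel_r[i - 1] * rdiff_hist[-i]
                    z += kernel_c[i - 1] * cdiff_hist[-i]
            p_l = 1.0 / (1.0 + np.exp(-z))
            choice = "L" if rng.random() < p_l else "R"
            reward, state = bait_and_step(state, choice, task_cfg, rng)
            sign = 1.0 if choice == "L" else -1.0
            rdiff_hist.append(reward * sign)
            cdiff_hist.append(sign)
            trials.append(TrialRecord(trial=t, choice=choice, reward=reward,
                                      A_L=a_l, A_R=a_r,
                                      block=state.block_index))
            window.push(choice == high)
        state = maybe_transition(state, window.fraction(), task_cfg, rng)
    return SessionRecord(trials=trials, config=task_cfg,
                         generator="history_teacher", seed=task_cfg.rng_seed)


# ---------------------------------------------------------------------------
# Neural generators
# ---------------------------------------------------------------------------

def _standardize(series: np.ndarray) -> np.ndarray:
    s = np.asarray(series, dtype=float).copy()
    m = np.nanmean(s)
    sd = np.nanstd(s)
    if sd > 0:
        s = (s - m) / sd
    else:
        s = s - m
    return np.nan_to_num(s, nan=0.0)


def _smoothed_walk(n_trials: int, n_neurons: int, tau: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Random walk smoothed by an exponential moving average, unit variance."""
    steps = rng.standard_normal((n_trials, n_neurons))
    walk = np.cumsum(steps, axis=0)
    alpha = 1.0 / max(tau, 1.0)
    out = np.empty_like(walk)
    acc = walk[0]
    for t in range(n_trials):
        acc = (1 - alpha) * acc + alpha * walk[t]
        out[t] = acc
    out -= out.mean(axis=0)
    sd = out.std(axis=0)
    sd[sd == 0] = 1.0
    return out / sd


def draw_coding_weights(spec: NeuralGenSpec,
                        rng: np.random.Generator) -> np.ndarray:
    """(n_neurons, n_targets) weights; per-neuron coding variance ~ coding_sd^2."""
    k = len(spec.targets)
    return rng.standard_normal((spec.n_neurons, k)) * (
        spec.coding_sd / np.sqrt(k))


def gen_population(
    session: SessionRecord,
    values: ValueSeries | dict,
    spec: NeuralGenSpec,
    seed=0,
    coding_weights: np.ndarray | None = None,
    neuron_ids: np.ndarray | None = None,
    session_id: str = "synthetic",
    epoch: str = "prechoice_mean3",
    gain: float = 1.0,
) -> PopulationActivity:
    """Activity = coding weights x standardized value signals + drift + noise.

    One row per included choice trial of the session, matching the indexing
    of the ValueSeries produced by the behavior generators.
    """
    rng = _as_rng(seed)
    if isinstance(values, ValueSeries):
        sigmap = {"dQ": values.dQ, "sumQ": values.sumQ, "Q_ch": values.Q_ch}
    else:
        sigmap = dict(values)
    Z = np.column_stack([_standardize(sigmap[t]) for t in spec.targets])
    n_trials = Z.shape[0]
    W = coding_weights if coding_weights is not None else \
        draw_coding_weights(spec, rng)
    n_neurons = W.shape[0]  # may be < spec.n_neurons after dropout
    A = gain * (Z @ W.T)
    if spec.drift_sd > 0:
        A = A + spec.drift_sd * _smoothed_walk(
            n_trials, n_neurons, spec.drift_smooth_tau, rng)
    if spec.noise_sd > 0:
        A = A + spec.noise_sd * rng.standard_normal((n_trials, n_neurons))
    ids = neuron_ids if neuron_ids is not None else np.arange(n_neurons)
    return PopulationActivity(
        session_id=session_id, activity=A, neuron_ids=np.asarray(ids),
        included=np.ones(n_trials, dtype=bool), epoch=epoch)


def gen_population_epochs(session, values, spec: NeuralGenSpec, seed=0,
                          **kw) -> dict[str, PopulationActivity]:
    """One activity table per epoch label, with epoch-specific coding gains."""
    rng = _as_rng(seed)
    W = kw.pop("coding_weights", None)
    if W is None:
        W = draw_coding_weights(spec, rng)
    out = {}
    for label, gain in spec.epoch_gains:
        out[label] = gen_population(session, values, spec, seed=rng,
                                    coding_weights=W, epoch=label,
                                    gain=gain, **kw)
    return out


# ---------------------------------------------------------------------------
# Longitudinal study
# ---------------------------------------------------------------------------

def _rotate_toward_random(vec: np.ndarray, deg: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Rotate a vector by ``deg`` degrees toward a random orthogonal
    direction, preserving its norm."""
    norm = np.linalg.norm(vec)
    if norm == 0 or deg == 0:
        return vec.copy()
    unit = vec / norm
    u = rng.standard_normal(vec.shape)
    u -= (u @ unit) * unit
    un = np.linalg.norm(u)
    if un == 0:
        return vec.copy()
    u /= un
    phi = np.radians(deg)
    return norm * (np.cos(phi) * unit + np.sin(phi) * u)


def gen_longitudinal_study(
    n_subjects: int = 2,
    n_sessions: int = 12,
    teacher: TeacherSpec | None = None,
    neural: NeuralGenSpec | None = None,
    task_cfg: TaskConfig | None = None,
    seed: int = 0,
    n_trials: int | None = None,
) -> dict:
    """Multi-session study with two interleaved planes per subject.

    Behavior comes from the history-kernel teacher; under the
    ``rotate_then_freeze`` schedule the reward kernel rotates by
    ``rotation_at(k)`` degrees going into session k (decaying with k), so the
    behavioral policy drifts early and stabilizes late.  Each plane's
    per-neuron coding weights rotate by the *same* session-indexed magnitude,
    so coding axes co-rotate with the policy.  Value signals for the neural
    readout are the RW value recursion applied to each session's realized
    choices and rewards (fixed RL parameters).

    Session pairs for axis comparisons are same-plane sessions two apart
    (k, k+2), with the registered neuron set the intersection of the two
    sessions' retained neurons after dropout.
    """
    teacher = teacher or TeacherSpec()
    neural = neural or NeuralGenSpec()
    task_cfg = task_cfg or TaskConfig()
    rng = np.random.default_rng(seed)
    subjects = []
    for s in range(n_subjects):
        kernel_r = np.asarray(teacher.kernel_r, dtype=float).copy()
        kernel_c = np.asarray(teacher.kernel_c, dtype=float).copy()
        plane_weights = [draw_coding_weights(neural, rng) for _ in range(2)]
        plane_ids = [np.arange(neural.n_neurons) + p * 10000 for p in range(2)]
        sessions = []
        for k in range(n_sessions):
            deg = teacher.rotation_at(k)
            plane = k % 2
            if deg > 0:
                # kernel and both planes' coding weights co-rotate by the
                # same session-indexed magnitude
                kernel_r = _rotate_toward_random(kernel_r, deg, rng)
                for W in plane_weights:
                    for j in range(W.shape[1]):
                        W[:, j] = _rotate_toward_random(W[:, j], deg, rng)
            record = gen_history_behavior_session(
                kernel_r, kernel_c, teacher.kernel_bias, task_cfg,
                seed=rng, n_trials=n_trials, lapse_rate=teacher.lapse_rate)
            record.subject = f"sub{s}"
            record.session_number = k
            values = run_rl_values(record, teacher.rl)
            keep = rng.random(neural.n_neurons) >= neural.dropout_rate
            ids = plane_ids[plane][keep]
            activity = gen_population(
                record, values, neural, seed=rng,
                coding_weights=plane_weights[plane][keep],
                neuron_ids=ids, session_id=f"sub{s}_ses{k}")
            sessions.append({
                "subject": f"sub{s}", "session_number": k, "plane": plane,
                "record": record, "values": values, "activity": activity,
                "kernel_r": kernel_r.copy(),
                "coding_weights": plane_weights[plane].copy(),
                "neuron_ids": ids,
            })
        pairs = []
        for k in range(n_sessions - 2):
            a, b = sessions[k], sessions[k + 2]
            shared = np.intersect1d(a["neuron_ids"], b["neuron_ids"])
            pairs.append({"k": k, "sessions": (k, k + 2), "shared": shared})
        subjects.append({"subject": f"sub{s}", "sessions": sessions,
                         "pairs": pairs})
    return {"subjects": subjects, "seed": seed}


# ---------------------------------------------------------------------------
# Inactivation schedule
# ---------------------------------------------------------------------------

def gen_inactivation_schedule(
    n_trials: int,
    rate: float = 0.13,
    min_gap: int = 4,
    seed=0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Boolean inactivation flags with a refractory run of control trials.

    Flags occur at long-run frequency ``rate`` with the constraint that every
    flagged trial is followed by at least ``min_gap`` consecutive unflagged
    trials (flags are also disallowed in the final ``min_gap`` trials, where
    the constraint could not be honored).  Internally this is a renewal
    process flagging eligible trials with probability
    q = rate / (1 - rate * min_gap), which yields mean rate q/(1+q*min_gap).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    max_rate = 1.0 / (1 + min_gap)
    if rate > max_rate:
        raise ValueError(
            f"rate {rate} infeasible with min_gap {min_gap} "
            f"(max {max_rate:.3f})")
    rng = rng if rng is not None else _as_rng(seed)
    if rate == 0:
        return np.zeros(n_trials, dtype=bool)
    q = rate / (1.0 - rate * min_gap)
    flags = np.zeros(n_trials, dtype=bool)
    cooldown = 0
    for t in range(n_trials):
        if cooldown > 0:
            cooldown -= 1
            continue
        if t >= n_trials - min_gap:
            continue
        if rng.random() < q:
            flags[t] = True
            cooldown = min_gap
    return flags


# ---------------------------------------------------------------------------
# On-disk dataset
# ---------------------------------------------------------------------------

def write_dataset(dataset: dict, outdir) -> list[str]:
    """Write a longitudinal dataset as a directory tree of plain-text files.

    Per subject and session: behavior CSV, long-format activity CSV
    (trial, neuron_id, value) and a ground-truth JSON (teacher kernel,
    coding weights, seeds).  Returns the list of written paths (manifest).
    """
    outdir = Path(outdir)
    written: list[str] = []
    for sub in dataset["subjects"]:
        sdir = outdir / sub["subject"]
        sdir.mkdir(parents=True, exist_ok=True)
        for ses in sub["sessions"]:
            stem = sdir / f"session{ses['session_number']:03d}"
            behav = f"{stem}_behavior.csv"
            session_to_frame(ses["record"]).to_csv(behav, index=False)
            written.append(behav)
            act = ses["activity"]
            n_t, n_c = act.activity.shape
            long = pd.DataFrame({
                "trial": np.repeat(np.arange(n_t), n_c),
                "neuron_id": np.tile(act.neuron_ids, n_t),
                "value": act.activity.ravel(),
            })
            actp = f"{stem}_activity.csv"
            long.to_csv(actp, index=False)
            written.append(actp)
            gt = f"{stem}_truth.json"
            with open(gt, "w") as fh:
                json.dump({
                    "subject": ses["subject"],
                    "session_number": ses["session_number"],
                    "plane": ses["plane"],
                    "kernel_r": list(ses["kernel_r"]),
                    "neuron_ids": [int(i) for i in ses["neuron_ids"]],
                    "coding_weights": np.asarray(
                        ses["coding_weights"]).tolist(),
                }, fh)
            written.append(gt)
    return written
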