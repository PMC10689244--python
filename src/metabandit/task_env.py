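"""Baited probabilistic reversal-learning environment and performance metrics.

The task is a two-port bandit with concurrent variable-interval ("baiting")
reward schedules.  On every trial each port is independently loaded with a
reward with its current assignment probability; once loaded, the reward stays
on the port until that port is next chosen.  Assignment probabilities come in
left/right pairs that reverse in a fixed cycle every 60-80 trials, with block
transitions postponed until the subject's recent high-side choice fraction
reaches 50%.

Because rewards accumulate on an unchosen port, the probability that a reward
is available on side ``s`` at trial ``t`` is

    P_avail(t) = 1 - prod_{x = t-n(t)}^{t} (1 - A_s(x))

where ``n(t)`` counts the trials since side ``s`` was last chosen.  The
session-mean of this quantity on the chosen side is the *optimality score*,
a de-noised measure of how well a policy harvests the baited schedule.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "BanditState",
    "TrialRecord",
    "SessionRecord",
    "bait_and_step",
    "maybe_transition",
    "p_reward_available",
    "optimality_score",
    "p_choose_high",
    "session_to_frame",
    "frame_to_session",
    "save_session_csv",
    "load_session_csv",
]

# The canonical reversal cycle: one rich and one lean port per pair, with the
# rich side alternating and the contrast alternating between 60/10 and
# 52.5/17.5.
DEFAULT_PROB_PAIRS: tuple[tuple[float, float], ...] = (
    (0.60, 0.10),
    (0.10, 0.60),
    (0.525, 0.175),
    (0.175, 0.525),
)

HIGH_PROBS = frozenset({0.60, 0.525})
LOW_PROBS = frozenset({0.10, 0.175})


@dataclass(frozen=True)
class TaskConfig:
    """Static parameters of the baited reversal bandit."""

    prob_pairs: tuple[tuple[float, float], ...] = DEFAULT_PROB_PAIRS
    block_len_range: tuple[int, int] = (60, 80)
    postpone_window: int = 60
    postpone_threshold: float = 0.5
    n_trials_per_session: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.block_len_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid block_len_range {self.block_len_range}")
        for pair in self.prob_pairs:
            if not (set(pair) & HIGH_PROBS and set(pair) & LOW_PROBS):
                raise ValueError(
                    f"pair {pair} must contain one high (0.60/0.525) and one "
                    f"low (0.10/0.175) probability"
                )

    def high_side(self, pair_index: int) -> str:
        a_l, a_r = self.prob_pairs[pair_index % len(self.prob_pairs)]
        return "L" if a_l > a_r else "R"


@dataclass
class BanditState:
    """Mutable per-session state of the bandit scheduler."""

    pair_index: int = 0
    trials_in_block: int = 0
    scheduled_block_len: int = 60
    baited_L: bool = False
    baited_R: bool = False
    trial_index: int = 0
    block_index: int = 0

    def probs(self, cfg: TaskConfig) -> tuple[float, float]:
        return cfg.prob_pairs[self.pair_index % len(cfg.prob_pairs)]


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial."""

    trial: int
    choice: str  # "L", "R" or "none"
    reward: int
    A_L: float
    A_R: float
    block: int
    included: bool = True
    inactivation: bool = False

    def __post_init__(self) -> None:
        if self.choice not in ("L", "R", "none"):
            raise ValueError(f"bad choice {self.choice!r}")
        if self.choice == "none" and self.reward:
            raise ValueError("no-choice trials cannot be rewarded")
        if not self.included and self.reward:
            raise ValueError("excluded trials are never rewarded")


@dataclass
class SessionRecord:
    """Ordered trials of one behavioral session plus provenance."""

    trials: list[TrialRecord]
    config: TaskConfig
    generator: str = "unknown"
    seed: int = 0
    subject: str = "sim"
    session_number: int = 0

    def __post_init__(self) -> None:
        for i, tr in enumerate(self.trials):
            if tr.trial != i:
                raise ValueError("trial indices must be consecutive from 0")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def choices(self) -> list[str]:
        return [t.choice for t in self.trials]

    @property
    def rewards(self) -> np.ndarray:
        return np.array([t.reward for t in self.trials], dtype=int)

    def included_choice_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.included and t.choice != "none"]


# ---------------------------------------------------------------------------
# Bandit dynamics
# ---------------------------------------------------------------------------

def new_state(cfg: TaskConfig, rng: np.random.Generator) -> BanditState:
    """Fresh scheduler state with a drawn first block length."""
    lo, hi = cfg.block_len_range
    return BanditState(scheduled_block_len=int(rng.integers(lo, hi + 1)))


def bait_and_step(
    state: BanditState,
    choice: str,
    cfg: TaskConfig,
    rng: np.random.Generator,
) -> tuple[int, BanditState]:
    """Run the reward-assignment step for one trial.

    At trial start each unbaited side is loaded with its current assignment
    probability; the chosen side's bait (if any) is collected and cleared.
    ``choice='none'`` collects nothing but baits still accrue.
    """
    if choice not in ("L", "R", "none"):
        raise ValueError(f"bad choice {choice!r}")
    a_l, a_r = state.probs(cfg)
    baited_L = state.baited_L or (rng.random() < a_l)
    baited_R = state.baited_R or (rng.random() < a_r)
    reward = 0
    if choice == "L":
        reward = int(baited_L)
        baited_L = False
    elif choice == "R":
        reward = int(baited_R)
        baited_R = False
    new = replace_state(
        state,
        baited_L=baited_L,
        baited_R=baited_R,
        trials_in_block=state.trials_in_block + 1,
        trial_index=state.trial_index + 1,
    )
    return reward, new


def replace_state(state: BanditState, **kw) -> BanditState:
    out = BanditState(**{**state.__dict__, **kw})
    return out


def maybe_transition(
    state: BanditState,
    recent_high_fraction: float | None,
    cfg: TaskConfig,
    rng: np.random.Generator,
) -> BanditState:
    """Advance the probability block if due and not postponed.

    Called once per trial after the choice.  The transition fires when the
    scheduled block length has elapsed and the fraction of recent included
    choices on the currently rich side is at least the postponement threshold.
    ``recent_high_fraction`` is None when no included choices exist yet, in
    which case the transition is postponed.
    """
    if state.trials_in_block < state.scheduled_block_len:
        return state
    if recent_high_fraction is None or recent_high_fraction < cfg.postpone_threshold:
        return state  # postponed; re-checked next trial
    lo, hi = cfg.block_len_range
    return replace_state(
        state,
        pair_index=(state.pair_index + 1) % len(cfg.prob_pairs),
        trials_in_block=0,
        scheduled_block_len=int(rng.integers(lo, hi + 1)),
        block_index=state.block_index + 1,
    )


class HighSideWindow:
    """Sliding window of high-side indicators over included choice trials."""

    def __init__(self, size: int):
        self._buf: deque[bool] = deque(maxlen=size)

    def push(self, chose_high: bool) -> None:
        self._buf.append(chose_high)

    def fraction(self) -> float | None:
        if not self._buf:
            return None
        return sum(self._buf) / len(self._buf)


def play_session(
    policy,
    cfg: TaskConfig,
    rng: np.random.Generator,
    n_trials: int | None = None,
) -> SessionRecord:
    """Run a callable policy through one session of the bandit.

    ``policy(trial_index, prev_choice, prev_reward, rng) -> choice`` is called
    once per trial.  Used by simple scripted/teacher policies; the deep RL
    agent drives the environment through its own loop.
    """
    n = n_trials if n_trials is not None else cfg.n_trials_per_session
    state = new_state(cfg, rng)
    window = HighSideWindow(cfg.postpone_window)
    trials: list[TrialRecord] = []
    prev_choice, prev_reward = "none", 0
    for t in range(n):
        a_l, a_r = state.probs(cfg)
        high = cfg.high_side(state.pair_index)
        choice = policy(t, prev_choice, prev_reward, rng)
        reward, state = bait_and_step(state, choice, cfg, rng)
        trials.append(
            TrialRecord(
                trial=t, choice=choice, reward=reward, A_L=a_l, A_R=a_r,
                block=state.block_index, included=choice != "none",
            )
        )
        if choice != "none":
            window.push(choice == high)
        state = maybe_transition(state, window.fraction(), cfg, rng)
        prev_choice, prev_reward = choice, reward
    return SessionRecord(trials=trials, config=cfg, generator="play_session",
                         seed=cfg.rng_seed)


# ---------------------------------------------------------------------------
# Performance metrics
# ---------------------------------------------------------------------------

def p_reward_available(session: SessionRecord, t: int, side: str) -> float:
    """Probability that a reward is loaded on ``side`` at trial ``t``.

    Equals ``1 - prod_{x=t-n}^{t} (1 - A_side(x))`` where ``n`` is the number
    of trials since ``side`` was last chosen (all trials since session start
    if it never was).  Baits accrue on every trial, including no-choice
    trials.
    """
    if side not in ("L", "R"):
        raise ValueError(f"bad side {side!r}")
    if not (0 <= t < len(session.trials)):
        raise IndexError(f"trial {t} out of range")
    start = 0
    for x in range(t - 1, -1, -1):
        if session.trials[x].choice == side:
            start = x + 1
            break
    prod = 1.0
    for x in range(start, t + 1):
        tr = session.trials[x]
        a = tr.A_L if side == "L" else tr.A_R
        prod *= 1.0 - a
    return 1.0 - prod


def optimality_score(session: SessionRecord) -> float:
    """Session-mean probability of reward availability on the chosen side."""
    terms = [
        p_reward_available(session, tr.trial, tr.choice)
        for tr in session.included_choice_trials()
    ]
    if not terms:
        raise ValueError("no included choice trials in session")
    return float(np.mean(terms))


def p_choose_high(session: SessionRecord) -> float:
    """Fraction of included choices on the side with the higher assignment
    probability that trial."""
    trials = session.included_choice_trials()
    if not trials:
        raise ValueError("no included choice trials in session")
    hits = sum(
        1 for tr in trials
        if (tr.choice == "L") == (tr.A_L > tr.A_R)
    )
    return hits / len(trials)


# ---------------------------------------------------------------------------
# Serialization: CSV trial table + JSON sidecar
# ---------------------------------------------------------------------------

SESSION_COLUMNS = ["trial", "choice", "reward", "A_L", "A_R", "block",
                   "included", "inactivation"]


def session_to_frame(session: SessionRecord) -> pd.DataFrame:
    rows = [
        (t.trial, t.choice, t.reward, t.A_L, t.A_R, t.block,
         int(t.included), int(t.inactivation))
        for t in session.trials
    ]
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def frame_to_session(df: pd.DataFrame, cfg: TaskConfig | None = None,
                     **meta) -> SessionRecord:
    trials = [
        TrialRecord(
            trial=int(r.trial), choice=str(r.choice), reward=int(r.reward),
            A_L=float(r.A_L), A_R=float(r.A_R), block=int(r.block),
            included=bool(r.included), inactivation=bool(r.inactivation),
        )
        for r in df.itertuples(index=False)
    ]
    return SessionRecord(trials=trials, config=cfg or TaskConfig(), **meta)


def save_session_csv(session: SessionRecord, path) -> None:
    session_to_frame(session).to_csv(path, index=False)
    sidecar = str(path) + ".json"
    cfg = session.config
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "prob_pairs": [list(p) for p in cfg.prob_pairs],
                "block_len_range": list(cfg.block_len_range),
                "postpone_window": cfg.postpone_window,
                "postpone_threshold": cfg.postpone_threshold,
                "n_trials_per_session": cfg.n_trials_per_session,
                "rng_seed": cfg.rng_seed,
                "generator": session.generator,
                "seed": session.seed,
                "subject": session.subject,
                "session_number": session.session_number,
            },
            fh, indent=1,
        )


def load_session_csv(path) -> SessionRecord:
    df = pd.read_csv(path)
    sidecar = str(path) + ".json"
    meta: dict = {}
    cfg = None
    try:
        with open(sidecar) as fh:
            raw = json.load(fh)
        cfg = TaskConfig(
            prob_pairs=tuple(tuple(p) for p in raw["prob_pairs"]),
            block_len_range=tuple(raw["block_len_range"]),
            postpone_window=raw["postpone_window"],
            postpone_threshold=raw["postpone_threshold"],
            n_trials_per_session=raw["n_trials_per_session"],
            rng_seed=raw["rng_seed"],
        )
        meta = {k: raw[k] for k in ("generator", "seed", "subject",
                                    "session_number")}
    except FileNotFoundError:
        pass
    return frame_to_session(df, cfg, **meta)
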