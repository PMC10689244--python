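"""Behavioral policy and value models for the baited reversal bandit.

Two model families quantify a session's action policy:

* A logistic *history-kernel* regression predicting the left-choice
  probability from signed reward-history and choice-history differences over
  the past five trials plus a constant bias.  Its two 5-vectors of lag
  weights are the session's *policy axes*; cross-session angles between them
  measure policy stability.  A split variant fits separate control and
  inactivation weights (with L2 regularization and control-trial subsampling)
  to quantify inactivation effects.

* A Rescorla-Wagner Q-learning model with asymmetric learning rates
  (alpha_rew / alpha_unr), trial-wise forgetting of the unchosen value
  (omega), and a softmax readout with inverse temperature beta_dq, constant
  bias beta_0 and, for the deep-RL variant, a previous-choice alternation
  term beta_c.  Fitting is penalized maximum likelihood with the L2 weight
  lambda chosen by tenfold cross-validation; the fitted model yields the
  per-trial value series dQ = Q_L - Q_R, sumQ = Q_L + Q_R and Q_ch (value of
  the previously chosen side) that downstream neural decoders target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from .task_env import SessionRecord

__all__ = [
    "HistoryFit",
    "PolicyAxes",
    "RLParams",
    "RLFit",
    "ValueSeries",
    "history_design",
    "fit_history_logit",
    "fit_history_logit_split",
    "policy_axes",
    "axis_angle",
    "summed_history_weights",
    "reward_history_dependence",
    "rl_update",
    "choice_prob",
    "run_rl_values",
    "fit_rl_model",
]

N_LAGS = 5


@dataclass
class HistoryFit:
    """Fitted history-kernel logistic regression (11 coefficients)."""

    beta_r: np.ndarray            # (5,) reward-history lags t-1..t-5
    beta_c: np.ndarray            # (5,) choice-history lags
    beta_bias: float
    converged: bool = True
    log_likelihood: float = np.nan
    warning: str | None = None
    # split-fit extras
    beta_r_opto: np.ndarray | None = None
    beta_c_opto: np.ndarray | None = None
    beta_bias_opto: float | None = None
    abs_bias: float | None = None       # mean over iterations of |bias_ctrl|
    abs_bias_opto: float | None = None
    n_iterations: int = 1


@dataclass(frozen=True)
class PolicyAxes:
    """Per-session policy axes: the 5-lag reward and choice kernels."""

    p_r: np.ndarray
    p_c: np.ndarray


@dataclass(frozen=True)
class RLParams:
    """Parameters of the forgetting Q-learning model."""

    alpha_rew: float
    alpha_unr: float
    omega: float
    beta_dq: float
    beta_0: float = 0.0
    beta_c: float | None = None  # deep-RL variant only

    def __post_init__(self) -> None:
        for name in ("alpha_rew", "alpha_unr", "omega"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beta_dq < 0:
            raise ValueError("beta_dq must be >= 0")


@dataclass
class RLFit:
    """Fitted RL model with diagnostics."""

    params: RLParams
    variant: str
    lam: float
    cost: float                 # penalized objective J at optimum
    neg_log_likelihood: float
    n_trials: int
    cv_curve: np.ndarray | None = None  # (n_lambda, 2): lambda, mean CV nll


@dataclass
class ValueSeries:
    """Per-trial value signals implied by an RL parameterization."""

    Q_L: np.ndarray
    Q_R: np.ndarray

    @property
    def dQ(self) -> np.ndarray:
        return self.Q_L - self.Q_R

    @property
    def sumQ(self) -> np.ndarray:
        return self.Q_L + self.Q_R

    Q_ch: np.ndarray = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# History-kernel logistic regression
# ---------------------------------------------------------------------------

def _choice_arrays(session: SessionRecord) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(choice_is_left, reward, inactivation) over included choice trials."""
    trials = session.included_choice_trials()
    left = np.array([t.choice == "L" for t in trials], dtype=float)
    rew = np.array([t.reward for t in trials], dtype=float)
    opto = np.array([t.inactivation for t in trials], dtype=bool)
    return left, rew, opto


def history_design(session: SessionRecord) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix of signed history differences over lags 1..5.

    Rows are included choice trials with a complete 5-trial history (the
    first five are dropped).  Columns 0-4 are reward-history differences
    r_L - r_R in {-1, 0, 1}; columns 5-9 are choice-history differences
    c_L - c_R in {-1, 1}.  Returns (X, y_left, opto_flags).
    """
    left, rew, opto = _choice_arrays(session)
    n = len(left)
    if n <= N_LAGS:
        raise ValueError("too few included choice trials for history design")
    sign = 2 * left - 1            # +1 left, -1 right
    rdiff = rew * sign             # r_L - r_R
    cdiff = sign                   # c_L - c_R
    rows = np.arange(N_LAGS, n)
    X = np.empty((len(rows), 2 * N_LAGS))
    for i in range(1, N_LAGS + 1):
        X[:, i - 1] = rdiff[rows - i]
        X[:, N_LAGS + i - 1] = cdiff[rows - i]
    return X, left[rows], opto[rows]


def fit_history_logit(session: SessionRecord, min_trials: int = 50) -> HistoryFit:
    """Unregularized ML logistic fit of choice on 5-lag histories (L-BFGS)."""
    X, y, _ = history_design(session)
    if len(y) < min_trials:
        raise ValueError(f"need >= {min_trials} usable trials, got {len(y)}")
    if len(np.unique(y)) < 2:
        return HistoryFit(
            beta_r=np.full(N_LAGS, np.nan), beta_c=np.full(N_LAGS, np.nan),
            beta_bias=np.nan, converged=False,
            warning="degenerate: single choice class (perfect separation)")
    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(X, y)
        conv_warn = any(issubclass(w.category, ConvergenceWarning)
                        for w in caught)
    w = model.coef_[0]
    p = model.predict_proba(X)[:, 1]
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    big = np.max(np.abs(w)) > 30
    return HistoryFit(
        beta_r=w[:N_LAGS], beta_c=w[N_LAGS:], beta_bias=float(model.intercept_[0]),
        converged=not (conv_warn or big), log_likelihood=ll,
        warning="possible separation (unbounded weights)" if big else (
            "solver did not converge" if conv_warn else None))


def _split_design(X: np.ndarray, opto: np.ndarray) -> np.ndarray:
    """Interaction design: [hist*ctrl, ctrl, hist*opto, opto] (22 columns)."""
    ctrl = (~opto).astype(float)[:, None]
    op = opto.astype(float)[:, None]
    return np.hstack([X * ctrl, ctrl, X * op, op])


def fit_history_logit_split(
    session: SessionRecord,
    seed: int = 0,
    cs_grid: int = 100,
    cv_folds: int = 5,
) -> HistoryFit:
    """Control/inactivation split history regression with trial matching.

    Fits separate control and inactivation kernels in one L2-penalized
    logistic model (inverse penalty chosen from a 100-point log grid in
    [1e-4, 1e4] by fivefold CV).  Control trials are randomly subsampled to
    the inactivation-trial count; subsampling repeats with the minimum number
    of iterations that covers every control trial at least once, and weights
    are averaged over iterations (|bias| is taken per iteration before
    averaging).
    """
    X, y, opto = history_design(session)
    idx_ctrl = np.flatnonzero(~opto)
    idx_opto = np.flatnonzero(opto)
    if len(idx_opto) == 0 or len(idx_ctrl) == 0:
        raise ValueError("both control and inactivation trials are required")
    n_iter = int(np.ceil(len(idx_ctrl) / len(idx_opto)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(idx_ctrl)
    chunks = [perm[i * len(idx_opto):(i + 1) * len(idx_opto)]
              for i in range(n_iter)]
    short = len(idx_opto) - len(chunks[-1])
    if short > 0:  # top up the last chunk with re-drawn control trials
        extra = rng.choice(np.setdiff1d(idx_ctrl, chunks[-1]), size=short,
                           replace=False)
        chunks[-1] = np.concatenate([chunks[-1], extra])

    Cs = np.logspace(-4, 4, cs_grid)
    coefs, biases_ctrl, biases_opto = [], [], []
    for chunk in chunks:
        rows = np.sort(np.concatenate([chunk, idx_opto]))
        Xd = _split_design(X[rows], opto[rows])
        yb = y[rows]
        if len(np.unique(yb)) < 2:
            continue
        model = LogisticRegressionCV(
            Cs=Cs, cv=cv_folds, penalty="l2", solver="lbfgs",
            fit_intercept=False, max_iter=1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            # sklearn's LogisticRegressionCV attribute-transition notice;
            # only coef_ is read here
            warnings.simplefilter("ignore", FutureWarning)
            model.fit(Xd, yb)
        w = model.coef_[0]
        coefs.append(w)
        biases_ctrl.append(w[N_LAGS * 2])
        biases_opto.append(w[-1])
    if not coefs:
        raise ValueError("all subsample iterations were degenerate")
    w = np.mean(coefs, axis=0)
    return HistoryFit(
        beta_r=w[:N_LAGS], beta_c=w[N_LAGS:2 * N_LAGS],
        beta_bias=float(w[2 * N_LAGS]),
        beta_r_opto=w[2 * N_LAGS + 1:3 * N_LAGS + 1],
        beta_c_opto=w[3 * N_LAGS + 1:4 * N_LAGS + 1],
        beta_bias_opto=float(w[-1]),
        abs_bias=float(np.mean(np.abs(biases_ctrl))),
        abs_bias_opto=float(np.mean(np.abs(biases_opto))),
        n_iterations=len(coefs),
    )


def policy_axes(fit: HistoryFit) -> PolicyAxes:
    return PolicyAxes(p_r=np.asarray(fit.beta_r, dtype=float).copy(),
                      p_c=np.asarray(fit.beta_c, dtype=float).copy())


def axis_angle(p_a: np.ndarray, p_b: np.ndarray) -> tuple[float, float]:
    """Cosine similarity and angle (degrees) between two axis vectors."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    na, nb = np.linalg.norm(p_a), np.linalg.norm(p_b)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for zero vector")
    cos = float(np.clip(np.dot(p_a, p_b) / (na * nb), -1.0, 1.0))
    return cos, float(np.degrees(np.arccos(cos)))


def summed_history_weights(fit: HistoryFit) -> tuple[float, float]:
    """(sum beta_r, sum beta_c) over the five lags."""
    return float(np.sum(fit.beta_r)), float(np.sum(fit.beta_c))


def reward_history_dependence(fit: HistoryFit) -> float:
    """Magnitude of reward-history dependence: sum of |beta_r| over lags."""
    return float(np.sum(np.abs(fit.beta_r)))


# ---------------------------------------------------------------------------
# Forgetting RL model
# ---------------------------------------------------------------------------

def rl_update(q_ch: float, q_unch: float, reward: int,
              params: RLParams) -> tuple[float, float]:
    """One trial of the value update: chosen side moves toward the outcome,
    unchosen side decays toward zero at the forgetting rate."""
    alpha = params.alpha_rew if reward else params.alpha_unr
    q_ch2 = q_ch + alpha * (reward - q_ch)
    q_unch2 = (1.0 - params.omega) * q_unch
    return q_ch2, q_unch2


def choice_prob(q_l: float, q_r: float, prev_choice: int,
                params: RLParams, variant: str = "mouse") -> float:
    """Left-choice probability under the softmax readout.

    ``prev_choice`` is +1 for a previous left choice, -1 for right (ignored
    by the mouse variant).
    """
    drive = params.beta_0 + q_l - q_r
    if variant == "deepRL":
        if params.beta_c is None:
            raise ValueError("deepRL variant requires beta_c")
        drive = drive + params.beta_c * prev_choice
    elif variant != "mouse":
        raise ValueError(f"unknown variant {variant!r}")
    z = params.beta_dq * drive
    return float(1.0 / (1.0 + np.exp(-z)))


@njit(cache=False)
def _rl_nll_masked(theta, left, reward, mask, use_beta_c, q0):  # pragma: no cover (jit)
    """Negative log-likelihood summed over trials where mask is 1.

    The value recursion always runs over *all* trials (so held-out folds see
    the same value trajectories), but only masked trials contribute to the
    sum; this is how the contiguous-fold cross-validation scores a fold.
    """
    a_rew, a_unr, omega, b_dq, b_0, b_c = (
        theta[0], theta[1], theta[2], theta[3], theta[4], theta[5])
    q_l = q0
    q_r = q0
    nll = 0.0
    prev = 0.0
    n = left.shape[0]
    for t in range(n):
        drive = b_0 + q_l - q_r
        if use_beta_c:
            drive += b_c * prev
        z = b_dq * drive
        if z > 35.0:
            z = 35.0
        elif z < -35.0:
            z = -35.0
        p_l = 1.0 / (1.0 + np.exp(-z))
        if mask[t]:
            if left[t] > 0.5:
                nll -= np.log(p_l + 1e-12)
            else:
                nll -= np.log(1.0 - p_l + 1e-12)
        r = reward[t]
        alpha = a_rew if r > 0.5 else a_unr
        if left[t] > 0.5:
            q_l = q_l + alpha * (r - q_l)
            q_r = (1.0 - omega) * q_r
            prev = 1.0
        else:
            q_r = q_r + alpha * (r - q_r)
            q_l = (1.0 - omega) * q_l
            prev = -1.0
    return nll


def _rl_nll(theta, left, reward, use_beta_c, q0=0.5):
    return _rl_nll_masked(theta, left, reward,
                          np.ones(len(left), dtype=np.bool_), use_beta_c, q0)


def run_rl_values(session: SessionRecord, params: RLParams,
                  q0: float = 0.5) -> ValueSeries:
    """Replay the value recursion over a session's included choice trials.

    ``Q_ch[t]`` is the value (at trial t) of the side chosen on the previous
    trial; it is NaN on the first trial.
    """
    left, rew, _ = _choice_arrays(session)
    n = len(left)
    Q_L = np.empty(n)
    Q_R = np.empty(n)
    Q_ch = np.full(n, np.nan)
    q_l = q_r = q0
    for t in range(n):
        Q_L[t] = q_l
        Q_R[t] = q_r
        if t > 0:
            Q_ch[t] = q_l if left[t - 1] > 0.5 else q_r
        if left[t] > 0.5:
            q_l, q_r = rl_update(q_l, q_r, int(rew[t]), params)
        else:
            q_r, q_l = rl_update(q_r, q_l, int(rew[t]), params)
    return ValueSeries(Q_L=Q_L, Q_R=Q_R, Q_ch=Q_ch)


_BOUNDS = [(0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 50.0),
           (-5.0, 5.0), (-5.0, 5.0)]


def _fit_once(left, reward, mask, use_beta_c, lam, theta0, free):
    def obj(theta):
        pen = 0.5 * lam * np.sum(theta[free] ** 2)
        return _rl_nll_masked(theta, left, reward, mask, use_beta_c, 0.5) + pen

    res = minimize(obj, theta0, method="L-BFGS-B", bounds=_BOUNDS)
    return res


def _multistart(left, reward, mask, use_beta_c, lam, rng, n_starts):
    free = np.arange(6) if use_beta_c else np.arange(5)
    best = None
    for s in range(n_starts):
        theta0 = np.array([
            rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95),
            rng.uniform(0.0, 0.5), rng.uniform(0.5, 10.0),
            rng.uniform(-0.5, 0.5),
            rng.uniform(-0.5, 0.5) if use_beta_c else 0.0,
        ])
        res = _fit_once(left, reward, mask, use_beta_c, lam, theta0, free)
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_rl_model(
    session: SessionRecord,
    variant: str = "mouse",
    n_starts: int = 10,
    cv_folds: int = 10,
    lam_grid: np.ndarray | None = None,
    min_trials: int = 100,
    seed: int = 0,
) -> tuple[RLFit, ValueSeries]:
    """Fit the forgetting RL model by penalized maximum likelihood.

    The L2 weight lambda is chosen by tenfold cross-validation on contiguous
    unshuffled folds (minimum held-out negative log-likelihood), then the
    final parameters are refit on all trials with multi-start L-BFGS-B.
    """
    if variant not in ("mouse", "deepRL"):
        raise ValueError(f"unknown variant {variant!r}")
    use_beta_c = variant == "deepRL"
    left, rew, _ = _choice_arrays(session)
    left = left.astype(np.float64)
    rew = rew.astype(np.float64)
    n = len(left)
    if n < min_trials:
        raise ValueError(f"need >= {min_trials} included choice trials, got {n}")
    if lam_grid is None:
        lam_grid = np.logspace(-4, 2, 20)
    rng = np.random.default_rng(seed)

    folds = np.array_split(np.arange(n), cv_folds)
    cv_nll = np.zeros(len(lam_grid))
    for j, lam in enumerate(lam_grid):
        for fold in folds:
            train_mask = np.ones(n, dtype=np.bool_)
            train_mask[fold] = False
            res = _multistart(left, rew, train_mask, use_beta_c,
                              lam, rng, n_starts=2)
            cv_nll[j] += _rl_nll_masked(res.x, left, rew, ~train_mask,
                                        use_beta_c, 0.5)
    lam_best = float(lam_grid[int(np.argmin(cv_nll))])

    all_mask = np.ones(n, dtype=np.bool_)
    best = _multistart(left, rew, all_mask, use_beta_c, lam_best, rng, n_starts)
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("RL model optimization failed to converge")
    theta = best.x
    params = RLParams(
        alpha_rew=float(theta[0]), alpha_unr=float(theta[1]),
        omega=float(theta[2]), beta_dq=float(theta[3]),
        beta_0=float(theta[4]),
        beta_c=float(theta[5]) if use_beta_c else None)
    nll = float(_rl_nll(theta, left, rew, use_beta_c, 0.5))
    fit = RLFit(params=params, variant=variant, lam=lam_best,
                cost=float(best.fun), neg_log_likelihood=nll, n_trials=n,
                cv_curve=np.column_stack([lam_grid, cv_nll]))
    values = run_rl_values(session, params)
    return fit, values
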