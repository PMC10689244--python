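"""Trial-difference decoding of value signals from population activity.

Action values and neural activity both drift slowly across trials, so a
naive per-trial regression of value on activity picks up spurious
correlations between two autocorrelated variables.  The decoders here
regress the *between-adjacent-trial change* in a value signal on the
between-adjacent-trial change in each neuron's activity,

    v(t+1) - v(t) = sum_i beta_i (a_i(t+1) - a_i(t)) + beta_0,

which removes most of the slow autocorrelation from both sides.  Decoding
accuracy is the Pearson correlation between held-out predicted and observed
differences under tenfold cross-validation on contiguous, unshuffled folds.
Chance floors come from shuffling the value differences within session, or
from decoding foreign sessions' value series (circularly rotated at a random
offset) with this session's activity.

A session's decoder weight vector over registered neurons is its *coding
axis*; cosine similarity between the coding axes of paired sessions measures
representational stability, and its relation to the behavioral policy-axis
angle links neural and behavioral drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PopulationActivity",
    "DecoderFit",
    "CodingAxis",
    "trial_diff_design",
    "fit_value_decoder",
    "subsample_decode",
    "chance_within",
    "chance_cross",
    "coding_axis",
    "coding_axis_angle",
    "axis_policy_relation",
    "condition_restricted_decode",
]


@dataclass
class PopulationActivity:
    """Trials x neurons activity with persistent neuron identities."""

    session_id: str
    activity: np.ndarray      # (n_trials, n_neurons)
    neuron_ids: np.ndarray    # (n_neurons,)
    included: np.ndarray      # (n_trials,) bool
    epoch: str = "prechoice_mean3"

    def __post_init__(self) -> None:
        if len(np.unique(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron IDs must be unique within a session")
        if self.activity.shape[0] != len(self.included):
            raise ValueError("included flags must match trial count")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[1]

    def subset_neurons(self, ids: np.ndarray) -> "PopulationActivity":
        """Restrict to the given neuron IDs, in the given order."""
        pos = {int(i): k for k, i in enumerate(self.neuron_ids)}
        idx = np.array([pos[int(i)] for i in ids], dtype=int)
        return PopulationActivity(
            session_id=self.session_id, activity=self.activity[:, idx],
            neuron_ids=np.asarray(ids).copy(), included=self.included,
            epoch=self.epoch)


@dataclass
class DecoderFit:
    """Fitted trial-difference decoder for one value signal."""

    target: str
    weights: np.ndarray       # per-neuron coefficients (population order)
    intercept: float
    accuracy: float           # cross-validated correlation r
    neuron_ids: np.ndarray
    n_rows: int
    in_sample_r: float = np.nan
    rank_deficient: bool = False
    n_draws: int = 1          # >1 for subsampled decoding


@dataclass
class CodingAxis:
    """Decoder weight vector over the registered shared neurons."""

    target: str
    weights: np.ndarray
    neuron_ids: np.ndarray
    session_index: int = 0


# ---------------------------------------------------------------------------
# Design construction and OLS decoding
# ---------------------------------------------------------------------------

def trial_diff_design(activity: PopulationActivity,
                      values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Adjacent-trial difference rows over retained trials.

    Trials are first restricted to included trials with a finite value;
    "adjacent" means adjacent within that retained sequence (excluded trials
    are skipped over).  Returns (X_diff, y_diff) with n_retained - 1 rows.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != activity.activity.shape[0]:
        raise ValueError("value series length must match trial count")
    keep = activity.included & np.isfinite(values)
    if keep.sum() < 3:
        raise ValueError("need at least 3 retained trials")
    A = activity.activity[keep]
    v = values[keep]
    return np.diff(A, axis=0), np.diff(v)


def _contiguous_folds(n: int, k: int) -> list[np.ndarray]:
    return [f for f in np.array_split(np.arange(n), k) if len(f)]


def fit_value_decoder(
    X: np.ndarray,
    y: np.ndarray,
    target: str = "dQ",
    neuron_ids: np.ndarray | None = None,
    cv_folds: int = 10,
    min_rows_per_fold: int = 1,
) -> DecoderFit:
    """OLS trial-difference decoder with contiguous unshuffled 10-fold CV.

    Accuracy is the correlation between pooled held-out predictions and the
    observed differences.  Rank-deficient designs fall back to the
    least-norm solution and are flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < cv_folds * min_rows_per_fold:
        raise ValueError(f"too few rows ({n}) for {cv_folds}-fold CV")
    if neuron_ids is None:
        neuron_ids = np.arange(p)

    def ols(Xt, yt):
        D = np.column_stack([Xt, np.ones(len(Xt))])
        coef, _, rank, _ = np.linalg.lstsq(D, yt, rcond=None)
        return coef[:-1], coef[-1], rank < D.shape[1]

    w, b, deficient = ols(X, y)
    pred_in = X @ w + b
    in_r = _safe_corr(pred_in, y)

    preds = np.empty(n)
    for fold in _contiguous_folds(n, cv_folds):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        wf, bf, _ = ols(X[mask], y[mask])
        preds[fold] = X[fold] @ wf + bf
    acc = _safe_corr(preds, y)
    return DecoderFit(target=target, weights=w, intercept=float(b),
                      accuracy=acc, neuron_ids=np.asarray(neuron_ids),
                      n_rows=n, in_sample_r=in_r, rank_deficient=deficient)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def per_trial_decoder_accuracy(activity: PopulationActivity,
                               values: np.ndarray,
                               cv_folds: int = 10) -> float:
    """CV accuracy of the naive per-trial (level, not difference) decoder.

    Used as the comparison arm in the spurious-correlation demonstrations;
    on slowly drifting null data this decoder reports inflated accuracy.
    """
    values = np.asarray(values, dtype=float)
    keep = activity.included & np.isfinite(values)
    fit = fit_value_decoder(activity.activity[keep], values[keep],
                            target="per_trial", cv_folds=cv_folds)
    return fit.accuracy


def subsample_decode(
    activity: PopulationActivity,
    values: np.ndarray,
    cells_per_draw: int = 55,
    rng: np.random.Generator | None = None,
    cv_folds: int = 10,
) -> DecoderFit:
    """Covering-rule subsampled decoding (accuracy averaged over draws).

    Draws ``cells_per_draw`` neurons without replacement until every cell has
    been used; the last draw holds the leftover cells topped up with
    re-sampled ones.  With a population at or below the draw size, a single
    draw uses all cells.
    """
    rng = rng or np.random.default_rng(0)
    ids = np.asarray(activity.neuron_ids)
    n_cells = len(ids)
    if n_cells <= cells_per_draw:
        X, y = trial_diff_design(activity, values)
        fit = fit_value_decoder(X, y, neuron_ids=ids, cv_folds=cv_folds)
        fit.n_draws = 1
        return fit
    perm = rng.permutation(n_cells)
    n_draws = int(np.ceil(n_cells / cells_per_draw))
    accs, last = [], None
    for d in range(n_draws):
        draw = perm[d * cells_per_draw:(d + 1) * cells_per_draw]
        if len(draw) < cells_per_draw:
            pool = np.setdiff1d(perm, draw)
            extra = rng.choice(pool, size=cells_per_draw - len(draw),
                               replace=False)
            draw = np.concatenate([draw, extra])
        sub = activity.subset_neurons(ids[draw])
        X, y = trial_diff_design(sub, values)
        last = fit_value_decoder(X, y, neuron_ids=ids[draw], cv_folds=cv_folds)
        accs.append(last.accuracy)
    out = last
    out.accuracy = float(np.mean(accs))
    out.n_draws = n_draws
    return out


# ---------------------------------------------------------------------------
# Chance floors
# ---------------------------------------------------------------------------

def chance_within(X: np.ndarray, y: np.ndarray, n_shuffles: int = 100,
                  rng: np.random.Generator | None = None,
                  cv_folds: int = 10) -> float:
    """Within-session chance: value differences shuffled across rows."""
    rng = rng or np.random.default_rng(0)
    accs = []
    for _ in range(n_shuffles):
        ys = rng.permutation(y)
        accs.append(fit_value_decoder(X, ys, cv_folds=cv_folds).accuracy)
    return float(np.mean(accs))


def chance_within_distribution(X: np.ndarray, y: np.ndarray,
                               n_shuffles: int = 100,
                               rng: np.random.Generator | None = None,
                               cv_folds: int = 10) -> np.ndarray:
    """Full shuffle-null accuracy distribution (for band tests)."""
    rng = rng or np.random.default_rng(0)
    return np.array([
        fit_value_decoder(X, rng.permutation(y), cv_folds=cv_folds).accuracy
        for _ in range(n_shuffles)
    ])


def chance_cross(
    activity: PopulationActivity,
    foreign_values: list[np.ndarray],
    n_draws: int = 100,
    rng: np.random.Generator | None = None,
    cv_folds: int = 10,
) -> float:
    """Cross-session chance: decode foreign sessions' value series.

    Each drawn foreign series is circularly rotated at a random offset
    (offset 0 allowed) to randomize block phase, then length-aligned to this
    session's trial count and decoded with this session's activity.
    """
    rng = rng or np.random.default_rng(0)
    if not foreign_values:
        raise ValueError("empty foreign value pool")
    n_trials = activity.activity.shape[0]
    accs = []
    for _ in range(n_draws):
        series = foreign_values[int(rng.integers(len(foreign_values)))]
        series = np.asarray(series, dtype=float)
        series = np.roll(series, int(rng.integers(len(series))))
        if len(series) < n_trials:
            series = np.resize(series, n_trials)
        else:
            series = series[:n_trials]
        X, y = trial_diff_design(activity, series)
        accs.append(fit_value_decoder(X, y, cv_folds=cv_folds).accuracy)
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# Coding-axis geometry
# ---------------------------------------------------------------------------

def coding_axis(fit: DecoderFit, shared_ids: np.ndarray,
                session_index: int = 0) -> CodingAxis:
    """Restrict a decoder's weights to the registered shared neurons."""
    pos = {int(i): k for k, i in enumerate(fit.neuron_ids)}
    missing = [int(i) for i in shared_ids if int(i) not in pos]
    if missing:
        raise ValueError(f"neurons {missing[:5]} not in the decoder")
    idx = np.array([pos[int(i)] for i in shared_ids], dtype=int)
    return CodingAxis(target=fit.target, weights=fit.weights[idx],
                      neuron_ids=np.asarray(shared_ids).copy(),
                      session_index=session_index)


def coding_axis_angle(c_a: CodingAxis, c_b: CodingAxis) -> tuple[float, float]:
    """Cosine similarity and angle in degrees between two coding axes."""
    if not np.array_equal(c_a.neuron_ids, c_b.neuron_ids):
        raise ValueError("coding axes must share neuron registration/order")
    na, nb = np.linalg.norm(c_a.weights), np.linalg.norm(c_b.weights)
    if na == 0 or nb == 0:
        raise ValueError("angle undefined for zero axis")
    cos = float(np.clip(np.dot(c_a.weights, c_b.weights) / (na * nb), -1, 1))
    return cos, float(np.degrees(np.arccos(cos)))


def axis_policy_relation(
    theta_coding: np.ndarray,
    theta_policy: np.ndarray,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Spearman rank correlation between paired coding- and policy-axis
    angles, with a permutation p-value.

    The permutation test is a deliberately simple substitute for hierarchical
    (mixed-effects) inference and ignores any nesting of the pairs.
    """
    theta_coding = np.asarray(theta_coding, dtype=float)
    theta_policy = np.asarray(theta_policy, dtype=float)
    if len(theta_coding) != len(theta_policy) or len(theta_coding) < 3:
        raise ValueError("need >= 3 matched angle pairs")
    rho = float(stats.spearmanr(theta_coding, theta_policy).statistic)
    rng = rng or np.random.default_rng(0)
    null = np.array([
        stats.spearmanr(theta_coding,
                        rng.permutation(theta_policy)).statistic
        for _ in range(n_permutations)
    ])
    p = float((np.sum(np.abs(null) >= abs(rho)) + 1) / (n_permutations + 1))
    return {"rho": rho, "p_perm": p, "n_pairs": len(theta_coding),
            "pairs": np.column_stack([theta_coding, theta_policy])}


def condition_restricted_decode(
    activity: PopulationActivity,
    values: np.ndarray,
    condition_mask: np.ndarray,
    condition: str = "",
    min_trials: int = 12,
    cv_folds: int = 10,
) -> DecoderFit:
    """Decode using only trials satisfying a behavioral condition.

    The design is restricted to adjacent pairs *within* the condition subset
    before differencing (left / right / rewarded / unrewarded analyses).
    """
    condition_mask = np.asarray(condition_mask, dtype=bool)
    keep = activity.included & condition_mask
    if keep.sum() < min_trials:
        raise ValueError(
            f"condition {condition!r} too sparse: {int(keep.sum())} trials "
            f"(< {min_trials})")
    sub = PopulationActivity(
        session_id=activity.session_id, activity=activity.activity,
        neuron_ids=activity.neuron_ids, included=keep, epoch=activity.epoch)
    X, y = trial_diff_design(sub, values)
    fit = fit_value_decoder(X, y, target=f"restricted:{condition}",
                            neuron_ids=activity.neuron_ids, cv_folds=cv_folds)
    return fit
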