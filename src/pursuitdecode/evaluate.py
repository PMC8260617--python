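"""Cross-validation, cross-task generalization, and significance machinery.

The central object is a 5x5 train-task x test-task matrix of decoding scores:
same-task cells are estimated by tenfold cross-validation, cross-task cells
by training on all trials of one task and testing on all trials of another.
Two complementary scores are used: the Pearson correlation r (temporal shape
only, affine-invariant) and the coefficient of determination
R2 = 1 - SS_res/SS_tot (shape *and* amplitude, unbounded below).  Cross-task
scores are normalised by the corresponding same-task score, giving a
generalization ratio whose diagonal is 1 by construction, and classified as
high (>= 0.6), middle (>= 0.2) or low (< 0.2).

Significance uses a permutation null that shuffles the trial correspondence
between predicted and true series and circularly shifts each series (which
preserves within-trial autocorrelation), with Benjamini-Hochberg control
across cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .protocol import TASKS
from .slir import (
    ARDSettings,
    DecodingModel,
    REGRESSANDS,
    SLiRConfig,
    fit_from_stats,
    fit_slir,
    predict,
    train_decoder,
    trial_suffstats,
)

COVERT_TASKS = frozenset({"covert_0.5", "covert_0.8"})
OVERT_TASKS = frozenset({"overt_0.5", "overt_0.8"})


# ---------------------------------------------------------------------------
# splits and coefficients


def tenfold_split(n_trials: int, seed: int, n_folds: int = 10) -> list[np.ndarray]:
    """Seeded disjoint folds, balanced to within one trial."""
    if n_trials < n_folds:
        raise ValueError(f"need at least {n_folds} trials, got {n_trials}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_trials)
    return [np.sort(order[k::n_folds]) for k in range(n_folds)]


def correlation_coefficient(true: np.ndarray, pred: np.ndarray) -> float:
    """Pearson correlation between a true and predicted series."""
    t, p = _check_pair(true, pred)
    if t.std() == 0 or p.std() == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    return float(np.corrcoef(t, p)[0, 1])


def determination_coefficient(true: np.ndarray, pred: np.ndarray) -> float:
    """R2 = 1 - SS_res / SS_tot; sensitive to amplitude, can be negative."""
    t, p = _check_pair(true, pred)
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R2 undefined for a zero-variance true series")
    return float(1.0 - np.sum((t - p) ** 2) / ss_tot)


def _check_pair(true, pred):
    t = np.asarray(true, float).ravel()
    p = np.asarray(pred, float).ravel()
    if t.size != p.size:
        raise ValueError("series lengths differ")
    if t.size < 3:
        raise ValueError("need at least 3 samples")
    return t, p


# ---------------------------------------------------------------------------
# generalization matrix


@dataclass
class TaskData:
    """Decoder inputs for one task: per-trial currents and target series."""

    currents: list[np.ndarray]  # each (n_dipoles, n_samples)
    targets: dict[str, list[np.ndarray]]  # regressand -> per-trial series

    @property
    def n_trials(self) -> int:
        return len(self.currents)


@dataclass
class GeneralizationMatrix:
    """One replicate's 5x5x2 grid of decoding scores.

    ``r``/``R2`` hold per-cell trial-averaged coefficients; ``trial_scores``
    keeps the per-trial values (used by the permutation test and the ANOVA
    stage); ``p_r``/``p_R2`` are permutation p-values when computed.
    """

    tasks: tuple[str, ...]
    r: np.ndarray  # (train, test, regressand)
    R2: np.ndarray
    p_r: np.ndarray
    p_R2: np.ndarray
    trial_scores: dict[tuple[str, str, str], dict[str, np.ndarray]]
    models: dict[str, DecodingModel]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, train in enumerate(self.tasks):
            for b, test in enumerate(self.tasks):
                for k, reg in enumerate(REGRESSANDS):
                    rows.append(
                        {
                            "train": train, "test": test, "regressand": reg,
                            "r": self.r[a, b, k], "R2": self.R2[a, b, k],
                            "p_r": self.p_r[a, b, k], "p_R2": self.p_R2[a, b, k],
                        }
                    )
        return pd.DataFrame(rows)


def build_generalization_matrix(
    task_data: dict[str, TaskData],
    cfg: SLiRConfig | None = None,
    ard: ARDSettings | None = None,
    folds: int = 10,
    seed: int = 0,
    n_perm: int = 0,
    aggregate: str = "per-trial",
    row_stride: int = 1,
) -> GeneralizationMatrix:
    """Train per-task decoders and score every train-task x test-task pair.

    Same-task cells use ``folds``-fold cross-validation; cross-task cells use
    the model trained on all trials of the training task.  Coefficients are
    computed per test trial and averaged (``aggregate='per-trial'``) or on the
    concatenated series (``aggregate='concatenated'``).  ``row_stride`` thins
    the regression rows at training time (predictions always use every
    sample).  Constant predictions (a decoder that selected no dipoles) score
    r = 0 by convention.
    """
    missing = [t for t in TASKS if t not in task_data]
    if missing:
        raise ValueError(f"missing task data for {missing}")
    if aggregate not in ("per-trial", "concatenated"):
        raise ValueError("aggregate must be 'per-trial' or 'concatenated'")
    cfg = cfg or SLiRConfig()
    ard = ard or ARDSettings()
    n = len(TASKS)
    r = np.full((n, n, 2), np.nan)
    R2 = np.full((n, n, 2), np.nan)
    p_r = np.full((n, n, 2), np.nan)
    p_R2 = np.full((n, n, 2), np.nan)
    trial_scores: dict = {}

    # per-trial sufficient statistics, shared by all folds and the full fits
    stats = {
        task: [
            trial_suffstats(J, {reg: td.targets[reg][k] for reg in REGRESSANDS},
                            cfg, row_stride)
            for k, J in enumerate(td.currents)
        ]
        for task, td in task_data.items()
    }
    full_models = {task: fit_from_stats(stats[task], ard) for task in task_data}

    rng = np.random.default_rng(seed)
    for a, train_task in enumerate(TASKS):
        for b, test_task in enumerate(TASKS):
            td_test = task_data[test_task]
            pred_series: dict[str, list[np.ndarray]] = {reg: [] for reg in REGRESSANDS}
            true_by_reg: dict[str, list[np.ndarray]] = {reg: [] for reg in REGRESSANDS}
            if train_task == test_task:
                fold_idx = tenfold_split(td_test.n_trials, seed=int(rng.integers(2**31 - 1)),
                                         n_folds=folds)
                for fold in fold_idx:
                    keep = np.setdiff1d(np.arange(td_test.n_trials), fold)
                    model = fit_from_stats([stats[test_task][i] for i in keep], ard)
                    for i in fold:
                        preds, valid = predict(model, td_test.currents[i])
                        for reg in REGRESSANDS:
                            pred_series[reg].append(preds[reg])
                            true_by_reg[reg].append(
                                np.asarray(td_test.targets[reg][i], float)[valid]
                            )
            else:
                model = full_models[train_task]
                for i in range(td_test.n_trials):
                    preds, valid = predict(model, td_test.currents[i])
                    for reg in REGRESSANDS:
                        pred_series[reg].append(preds[reg])
                        true_by_reg[reg].append(
                            np.asarray(td_test.targets[reg][i], float)[valid]
                        )

            for k, reg in enumerate(REGRESSANDS):
                trues, preds = true_by_reg[reg], pred_series[reg]
                if aggregate == "per-trial":
                    rs = np.array([_safe_r(t, p) for t, p in zip(trues, preds)])
                    r2s = np.array([determination_coefficient(t, p) for t, p in zip(trues, preds)])
                    r[a, b, k], R2[a, b, k] = rs.mean(), r2s.mean()
                else:
                    tc, pc = np.concatenate(trues), np.concatenate(preds)
                    rs = np.array([_safe_r(tc, pc)])
                    r2s = np.array([determination_coefficient(tc, pc)])
                    r[a, b, k], R2[a, b, k] = rs[0], r2s[0]
                trial_scores[(train_task, test_task, reg)] = {"r": rs, "R2": r2s}
                if n_perm > 0:
                    p_r[a, b, k] = permutation_test(
                        trues, preds, statistic=_mean_trial_r,
                        n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
                    )
                    p_R2[a, b, k] = permutation_test(
                        trues, preds, statistic=_mean_trial_R2,
                        n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
                    )

    return GeneralizationMatrix(
        tasks=TASKS, r=r, R2=R2, p_r=p_r, p_R2=p_R2,
        trial_scores=trial_scores, models=full_models,
    )


def _safe_r(true, pred) -> float:
    """Pearson r, scoring constant predictions as 0 (no linear association)."""
    t = np.asarray(true, float).ravel()
    p = np.asarray(pred, float).ravel()
    if t.std() == 0 or p.std() == 0:
        return 0.0
    return float(np.corrcoef(t, p)[0, 1])


def _mean_trial_r(trues, preds):
    return float(np.mean([_safe_r(t, p) for t, p in zip(trues, preds)]))


def _mean_trial_R2(trues, preds):
    return float(np.mean([determination_coefficient(t, p) for t, p in zip(trues, preds)]))


# ---------------------------------------------------------------------------
# normalization and classification


@dataclass
class NormalizedScores:
    """Replicate mean +/- SD of diagonal-normalised scores."""

    mean: np.ndarray  # (train, test, regressand) or (train, test)
    sd: np.ndarray
    mode: str
    n_replicates: int


def normalize_scores(score_matrices: list[np.ndarray], mode: str = "by-test") -> NormalizedScores:
    """Normalise each replicate's matrix by its same-task diagonal, then average.

    ``by-test`` (default) divides cell (train, test) by the (test, test)
    value — the achievable ceiling on the test data; ``by-train`` divides by
    (train, train).  Replicates with a zero diagonal entry are excluded with
    a warning.
    """
    if mode not in ("by-test", "by-train"):
        raise ValueError("mode must be 'by-test' or 'by-train'")
    mats = [np.asarray(m, float) for m in score_matrices]
    normed = []
    for i, m in enumerate(mats):
        diag = np.einsum("iik->ik", m) if m.ndim == 3 else np.diag(m)
        if np.any(diag == 0):
            warnings.warn(f"replicate {i} has a zero same-task score; excluded", RuntimeWarning)
            continue
        if m.ndim == 3:
            denom = diag[None, :, :] if mode == "by-test" else diag[:, None, :]
        else:
            denom = diag[None, :] if mode == "by-test" else diag[:, None]
        normed.append(m / denom)
    if not normed:
        raise ValueError("no replicates with nonzero diagonals")
    arr = np.stack(normed)
    return NormalizedScores(mean=arr.mean(axis=0), sd=arr.std(axis=0, ddof=0),
                            mode=mode, n_replicates=len(normed))


def classify_generalization(value: float) -> str:
    """Classify a normalised score: high >= 0.6, middle >= 0.2, low < 0.2."""
    if not np.isfinite(value):
        raise ValueError("normalised score must be finite")
    if value >= 0.6:
        return "high"
    if value >= 0.2:
        return "middle"
    return "low"


# ---------------------------------------------------------------------------
# significance


def permutation_test(
    true_trials: list[np.ndarray],
    pred_trials: list[np.ndarray],
    statistic=None,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for the correspondence between true and predicted trials.

    The null shuffles which predicted series is paired with which true series
    and circularly shifts each predicted series by a random offset (preserving
    its autocorrelation).  p = (1 + #{null >= observed}) / (1 + n_perm).  When
    fewer than 100 distinct permutations exist, all of them are enumerated
    (without shifts) and the exact p-value is returned.
    """
    if len(true_trials) != len(pred_trials) or len(true_trials) < 2:
        raise ValueError("need >= 2 paired trials")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    statistic = statistic or _mean_trial_r
    observed = statistic(true_trials, pred_trials)
    m = len(true_trials)

    if math.factorial(m) < 100:
        warnings.warn(
            f"only {math.factorial(m)} distinct permutations; enumerating exactly",
            RuntimeWarning,
        )
        count = 0
        total = 0
        for perm in iter_permutations(range(m)):
            null = statistic(true_trials, [pred_trials[j] for j in perm])
            count += null >= observed
            total += 1
        return count / total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        shifted = []
        for j in perm:
            p = pred_trials[j]
            shifted.append(np.roll(p, int(rng.integers(1, p.size))))
        count += statistic(true_trials, shifted) >= observed
    return (1 + count) / (1 + n_perm)


def bh_correct(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# shared-dipole categorisation


SHARING_CATEGORIES = (
    "exclusive-control",
    "exclusive-covert_0.5",
    "exclusive-covert_0.8",
    "exclusive-overt_0.5",
    "exclusive-overt_0.8",
    "covert-shared",
    "overt-shared",
    "0.5Hz-shared",
    "0.8Hz-shared",
    "other-2-task",
    ">=3-tasks-shared",
)


def categorize_shared_dipoles(selected: dict[str, np.ndarray]) -> pd.DataFrame:
    """Assign every selected dipole to exactly one sharing category.

    Dipoles selected by one task are exclusive to it; the named two-task
    categories are the covert pair, the overt pair, and the covert/overt pair
    at each frequency; dipoles selected by three or more tasks share the
    '>=3' category.  Two-task combinations involving the control task fall in
    the residual 'other-2-task' category so the fractions sum to one.
    """
    sets = {t: set(np.asarray(list(selected.get(t, []))).tolist()) for t in TASKS}
    union = set().union(*sets.values())
    counts = dict.fromkeys(SHARING_CATEGORIES, 0)
    for dip in union:
        members = frozenset(t for t in TASKS if dip in sets[t])
        counts[_sharing_category(members)] += 1
    total = max(len(union), 1)
    return pd.DataFrame(
        {
            "category": SHARING_CATEGORIES,
            "count": [counts[c] for c in SHARING_CATEGORIES],
            "fraction": [counts[c] / total for c in SHARING_CATEGORIES],
        }
    )


def _sharing_category(members: frozenset[str]) -> str:
    if len(members) == 1:
        return f"exclusive-{next(iter(members))}"
    if len(members) >= 3:
        return ">=3-tasks-shared"
    if members == COVERT_TASKS:
        return "covert-shared"
    if members == OVERT_TASKS:
        return "overt-shared"
    if members == {"covert_0.5", "overt_0.5"}:
        return "0.5Hz-shared"
    if members == {"covert_0.8", "overt_0.8"}:
        return "0.8Hz-shared"
    return "other-2-task"


def shared_fraction(table: pd.DataFrame) -> float:
    """Fraction of selected dipoles shared by two or more tasks."""
    excl = table["category"].str.startswith("exclusive-")
    return float(table.loc[~excl, "fraction"].sum())


# ---------------------------------------------------------------------------
# time-lag sweep


def lag_sweep(
    trial_currents: list[np.ndarray],
    trial_targets: list[np.ndarray],
    lag_grid_ms: np.ndarray,
    fs: float = 200.0,
    ard: ARDSettings | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Correlation profile over the current-to-target time lag.

    For each lag L (ms; negative = currents precede the target), the target
    x(t) is regressed instantaneously on the currents J(t + L) with half the
    trials for training and half for testing; the mean held-out per-trial
    correlation is reported.  Returns (lags_ms, r_curve, argmax_lag_ms).
    """
    lag_grid_ms = np.asarray(lag_grid_ms, float)
    ard = ard or ARDSettings()
    T = trial_currents[0].shape[1]
    shifts = np.round(lag_grid_ms * fs / 1000.0).astype(int)
    if np.any(np.abs(shifts) >= T):
        raise ValueError("lag grid exceeds the epoch length")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trial_currents))
    half = len(order) // 2
    train_i, test_i = order[:half], order[half:]

    curve = np.empty(lag_grid_ms.size)
    for li, s in enumerate(shifts):
        lo, hi = max(0, -s), T - max(0, s)
        Xtr = np.vstack([trial_currents[i][:, lo + s : hi + s].T for i in train_i])
        ytr = np.concatenate([np.asarray(trial_targets[i], float)[lo:hi] for i in train_i])
        fit = fit_slir(Xtr, ytr, ard, group_size=1)
        w = fit.weights.ravel()
        rs = []
        for i in test_i:
            pred = trial_currents[i][:, lo + s : hi + s].T @ w + fit.bias
            true = np.asarray(trial_targets[i], float)[lo:hi]
            if pred.std() == 0 or true.std() == 0:
                rs.append(0.0)
            else:
                rs.append(correlation_coefficient(true, pred))
        curve[li] = float(np.mean(rs))
    best = float(lag_grid_ms[int(np.argmax(curve))])
    return lag_grid_ms, curve, best
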