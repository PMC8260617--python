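"""Sparse linear regression (SLiR) decoding of target kinematics.

Target position and velocity at time ``t`` are predicted from lagged source
currents,

    x(t) = sum_i sum_j w_ij J_i(t - (tpred + tau*j)) + w_0,   j = 0..dtau,

with automatic relevance determination on the *spatial* dimension only: all
``dtau+1`` lag weights of a dipole share one relevance hyperparameter, so a
dipole is either kept (all lags free) or pruned (all lags exactly zero).
With the defaults (tau=6, dtau=10, tpred=1 sample at 200 Hz) the lag window
spans 5-305 ms before the predicted sample, 11 taps.

Position and velocity are fit as two independent models with separate
relevances.  Fitting is variational Bayes on sufficient statistics with hard
pruning of groups whose implied prior variance collapses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri

REGRESSANDS = ("position", "velocity")


@dataclass(frozen=True)
class SLiRConfig:
    """Lag-embedding geometry. All temporal quantities in resampled samples."""

    tau: int = 6  # lag spacing
    dtau: int = 10  # extra lag steps -> dtau+1 taps
    tpred: int = 1  # prediction offset (1 sample = 5 ms at 200 Hz)
    fs: float = 200.0

    @property
    def lags(self) -> np.ndarray:
        return self.tpred + self.tau * np.arange(self.dtau + 1)

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs

    @property
    def n_taps(self) -> int:
        return self.dtau + 1


@dataclass
class ARDSettings:
    """Hyperparameters of the grouped-ARD fit."""

    max_iter: int = 200
    tol: float = 1e-3  # convergence: max relative movement of log-relevances
    a0: float = 1e-12  # gamma hyperprior shape on relevance precisions (near-improper)
    b0: float = 1e-12  # gamma hyperprior rate
    prune_fraction: float = 1e-8  # prune groups with prior variance < frac * max
    prune_contribution: float = 1e-2  # ... or supporting < this fraction of var(y)
    prune_burnin: int = 5  # contribution rule waits until relevances concentrate
    update_relevance: bool = True
    update_noise: bool = True
    noise_var: float | None = None
    alpha_init: float | None = None  # initial relevance precision (all groups)


@dataclass
class SLiRFit:
    """One fitted regressand: dense weights with exact zeros for pruned dipoles."""

    weights: np.ndarray  # (n_dipoles, n_taps)
    bias: float
    relevance: np.ndarray  # (n_dipoles,) prior variances 1/alpha
    selected: np.ndarray  # indices of retained dipoles
    objective: np.ndarray
    n_iter: int
    converged: bool
    noise_var: float

    @property
    def n_dipoles(self) -> int:
        return self.weights.shape[0]


@dataclass
class DecodingModel:
    """Position + velocity SLiR fits plus the training-data standardiser."""

    fits: dict[str, SLiRFit]
    cfg: SLiRConfig
    scaler_mean: np.ndarray  # (n_dipoles,)
    scaler_sd: np.ndarray  # (n_dipoles,)

    @property
    def n_dipoles(self) -> int:
        return self.scaler_mean.size

    def selected(self, regressand: str) -> np.ndarray:
        return self.fits[regressand].selected


def embed_lags(currents: np.ndarray, cfg: SLiRConfig) -> tuple[np.ndarray, np.ndarray]:
    """Lag-embed a (dipoles x samples) current array.

    Returns the design matrix (valid rows x dipoles*(dtau+1), dipole-major
    column order) and the sample indices of the valid rows (those with a
    complete lag history).
    """
    J = np.atleast_2d(np.asarray(currents, float))
    d, T = J.shape
    lags = cfg.lags
    max_lag = int(lags.max())
    if T <= max_lag:
        raise ValueError(f"epoch of {T} samples is shorter than the {max_lag}-sample lag window")
    valid = np.arange(max_lag, T)
    design = np.empty((valid.size, d * lags.size))
    for j, lag in enumerate(lags):
        design[:, j :: lags.size] = J[:, valid - lag].T
    return design, valid


def fit_slir(
    design: np.ndarray,
    target: np.ndarray,
    ard: ARDSettings | None = None,
    group_size: int = 1,
) -> SLiRFit:
    """Grouped-ARD regression of one regressand on a lag-embedded design.

    Columns are grouped in consecutive blocks of ``group_size`` (the dipole's
    taps); each group shares one relevance hyperparameter with a gamma
    hyperprior.  Groups whose posterior prior-variance collapses below
    ``prune_fraction`` of the largest group are pruned to exact zeros.
    """
    ard = ard or ARDSettings()
    X = np.asarray(design, float)
    y = np.asarray(target, float).ravel()
    n, D = X.shape
    if y.size != n:
        raise ValueError("design rows and target length differ")
    if D % group_size:
        raise ValueError("design width is not a multiple of group_size")
    y_var = float(np.var(y))
    if y_var == 0.0:
        # degenerate target: bias-only model
        L = group_size
        G = D // L
        return SLiRFit(
            weights=np.zeros((G, L)), bias=float(y.mean()),
            relevance=np.zeros(G), selected=np.array([], dtype=int),
            objective=np.zeros(1), n_iter=0, converged=True, noise_var=0.0,
        )

    col_mean = X.mean(axis=0)
    Xc = X - col_mean
    ybar = float(y.mean())
    yc = y - ybar
    G0 = Xc.T @ Xc
    c = Xc.T @ yc
    yy = float(yc @ yc)
    mu_full, relevance, selected, trace, n_iter, conv, sigma2 = _grouped_ard_core(
        G0, c, yy, n, D // group_size, group_size, ard, y_var
    )
    weights = mu_full.reshape(D // group_size, group_size)
    bias = ybar - float(col_mean @ mu_full)
    return SLiRFit(
        weights=weights, bias=bias, relevance=relevance, selected=selected,
        objective=trace, n_iter=n_iter, converged=conv, noise_var=sigma2,
    )


def _sym_inv(H: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a symmetric PD matrix via Cholesky."""
    Lc = np.linalg.cholesky(H)
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(Lc))))
    inv, info = dpotri(Lc, lower=1)
    if info != 0:  # pragma: no cover
        raise np.linalg.LinAlgError("dpotri failed")
    inv = np.tril(inv) + np.tril(inv, -1).T
    return inv, -logdet_H


def _grouped_ard_core(G0, c, yy, n, n_groups, L, ard: ARDSettings, y_var):
    """Evidence-maximising iterations on sufficient statistics with hard pruning.

    Relevance precisions follow the MacKay fixed-point update
    ``alpha_g = (2 a0 + sum_g gamma_i) / (2 b0 + sum_g mu_i^2)`` with
    ``gamma_i = 1 - alpha_g Sigma_ii`` (the effective number of
    well-determined weights in the group), which drives irrelevant groups'
    precisions to infinity geometrically; the noise variance uses the
    companion update ``resid / (n - sum gamma)``.
    """
    D = n_groups * L
    col_power = np.maximum(np.diag(G0), 1e-300)
    if ard.alpha_init is not None:
        alpha = np.full(n_groups, float(ard.alpha_init))
    else:
        # scale-consistent broad start: prior variance ~ var(y) / mean column power
        alpha = np.full(n_groups, float(col_power.mean()) / (y_var * n))
    sigma2 = ard.noise_var if ard.noise_var is not None else 0.1 * y_var

    # prior "supportable variance" of a group: v_g * sum of its column powers / n
    group_power = col_power.reshape(n_groups, L).sum(axis=1) / n

    active = np.arange(n_groups)
    trace: list[float] = []
    converged = False
    mu = np.zeros(0)
    it = 0
    for it in range(1, ard.max_iter + 1):
        cols = (active[:, None] * L + np.arange(L)).ravel()
        a_rep = np.repeat(alpha[active], L)
        H = G0[np.ix_(cols, cols)] / sigma2 + np.diag(a_rep)
        Sigma, logdet_S = _sym_inv(H)
        mu = Sigma @ c[cols] / sigma2
        gamma = 1.0 - a_rep * np.diag(Sigma)
        g_sum = gamma.reshape(-1, L).sum(axis=1)
        mu2_sum = (mu**2).reshape(-1, L).sum(axis=1)

        pruned_now = False
        alpha_move = 0.0
        sigma_move = 0.0
        if ard.update_relevance:
            alpha_new = (2 * ard.a0 + np.maximum(g_sum, 0.0)) / (2 * ard.b0 + mu2_sum)
            alpha_move = float(np.max(np.abs(np.log(alpha_new / alpha[active]))))
            alpha[active] = alpha_new
            v = 1.0 / alpha_new
            keep = v >= ard.prune_fraction * v.max()
            if it >= ard.prune_burnin:
                # gradual contribution pruning: collinear groups share the signal,
                # so drop only the weakest quarter below threshold per iteration
                # and let the survivors' relevances regrow
                contrib = v * group_power[active]
                below = np.flatnonzero(keep & (contrib < ard.prune_contribution * y_var))
                if below.size:
                    n_drop = min(below.size, max(1, active.size // 4))
                    drop = below[np.argsort(contrib[below])[:n_drop]]
                    keep[drop] = False
            if not keep.all():
                active = active[keep]
                pruned_now = True

        resid = yy - 2 * mu @ c[cols] + float(mu @ (G0[np.ix_(cols, cols)] @ mu))
        resid = max(resid, 0.0)
        if ard.update_noise:
            dof = max(n - float(np.sum(gamma)), 1.0)
            sigma2_new = max(resid / dof, 1e-12 * y_var)
            sigma_move = abs(np.log(sigma2_new / sigma2))
            sigma2 = sigma2_new

        # marginal-likelihood trace (type-II log evidence up to constants)
        evidence = (
            -0.5 * n * np.log(2 * np.pi * sigma2)
            - 0.5 * (resid / sigma2 + float(a_rep @ mu**2))
            + 0.5 * (logdet_S + float(np.sum(np.log(a_rep))))
        )
        trace.append(float(evidence))

        if active.size == 0:
            break
        if not (ard.update_relevance or ard.update_noise):
            converged = True
            break
        past_burnin = not ard.update_relevance or it >= ard.prune_burnin
        if not pruned_now and past_burnin and max(alpha_move, sigma_move) <= ard.tol:
            converged = True
            break
    else:
        warnings.warn("SLiR fit did not converge; model flagged", RuntimeWarning)

    mu_full = np.zeros(D)
    relevance = np.zeros(n_groups)
    if active.size:
        cols = (active[:, None] * L + np.arange(L)).ravel()
        # final re-solve on the surviving support
        a_rep = np.repeat(alpha[active], L)
        H = G0[np.ix_(cols, cols)] / sigma2 + np.diag(a_rep)
        mu = cho_solve(cho_factor(H, lower=True), c[cols]) / sigma2
        mu_full[cols] = mu
        relevance[active] = 1.0 / alpha[active]
    return mu_full, relevance, active.copy(), np.array(trace), it, converged, float(sigma2)


@dataclass
class TrialStats:
    """Sufficient statistics of one trial's lag-embedded regression.

    Caching these per trial makes cross-validation cheap: a training set's
    statistics are the sums over its trials, and the per-dipole z-scoring of
    the currents is an affine column transform applied analytically.
    """

    XtX: np.ndarray  # raw design Gram, (D, D)
    Xty: dict[str, np.ndarray]  # regressand -> (D,)
    x_sum: np.ndarray  # design column sums, (D,)
    y_sum: dict[str, float]
    y_sq: dict[str, float]
    n_rows: int
    cur_sum: np.ndarray  # per-dipole current sums, (d,)
    cur_sq: np.ndarray
    n_cur: int
    cfg: SLiRConfig


def trial_suffstats(
    currents: np.ndarray,
    targets: dict[str, list[np.ndarray]] | dict[str, np.ndarray],
    cfg: SLiRConfig,
    row_stride: int = 1,
) -> TrialStats:
    """Accumulate one trial's regression statistics (rows optionally thinned)."""
    J = np.atleast_2d(np.asarray(currents, float))
    X, valid = embed_lags(J, cfg)
    if row_stride > 1:
        X, valid = X[::row_stride], valid[::row_stride]
    Xty, y_sum, y_sq = {}, {}, {}
    for r in REGRESSANDS:
        y = np.asarray(targets[r], float)[valid]
        Xty[r] = X.T @ y
        y_sum[r] = float(y.sum())
        y_sq[r] = float(y @ y)
    return TrialStats(
        XtX=X.T @ X, Xty=Xty, x_sum=X.sum(axis=0), y_sum=y_sum, y_sq=y_sq,
        n_rows=X.shape[0], cur_sum=J.sum(axis=1), cur_sq=(J**2).sum(axis=1),
        n_cur=J.shape[1], cfg=cfg,
    )


def fit_from_stats(stats: list[TrialStats], ard: ARDSettings | None = None) -> DecodingModel:
    """Fit both regressands from pooled per-trial sufficient statistics."""
    ard = ard or ARDSettings()
    cfg = stats[0].cfg
    L = cfg.n_taps
    XtX = sum(s.XtX for s in stats)
    x_sum = sum(s.x_sum for s in stats)
    n = sum(s.n_rows for s in stats)
    D = x_sum.size
    d = D // L

    # pooled z-scoring of the currents, applied as a column transform
    n_cur = sum(s.n_cur for s in stats)
    mean = sum(s.cur_sum for s in stats) / n_cur
    var = sum(s.cur_sq for s in stats) / n_cur - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    sd[sd == 0] = 1.0
    s_rep = np.repeat(sd, L)

    xbar = x_sum / n
    G0 = (XtX - np.outer(x_sum, xbar)) / np.outer(s_rep, s_rep)
    G0 = 0.5 * (G0 + G0.T)

    fits = {}
    for r in REGRESSANDS:
        Xty = sum(s.Xty[r] for s in stats)
        y_sum = sum(s.y_sum[r] for s in stats)
        y_sq = sum(s.y_sq[r] for s in stats)
        ybar = y_sum / n
        c = (Xty - x_sum * ybar) / s_rep
        yy = max(y_sq - n * ybar**2, 0.0)
        y_var = yy / n
        if y_var == 0.0:
            fits[r] = SLiRFit(
                weights=np.zeros((d, L)), bias=ybar, relevance=np.zeros(d),
                selected=np.array([], dtype=int), objective=np.zeros(1),
                n_iter=0, converged=True, noise_var=0.0,
            )
            continue
        mu_full, relevance, selected, trace, n_iter, conv, sigma2 = _grouped_ard_core(
            G0, c, yy, n, d, L, ard, y_var
        )
        # bias on the z-scored scale; scaler means enter through xbar
        bias = ybar - float((xbar / s_rep - np.repeat(mean / sd, L)) @ mu_full)
        fits[r] = SLiRFit(
            weights=mu_full.reshape(d, L), bias=bias, relevance=relevance,
            selected=selected, objective=trace, n_iter=n_iter, converged=conv,
            noise_var=sigma2,
        )
    return DecodingModel(fits=fits, cfg=cfg, scaler_mean=mean, scaler_sd=sd)


def train_decoder(
    trial_currents: list[np.ndarray],
    trial_targets: dict[str, list[np.ndarray]],
    cfg: SLiRConfig | None = None,
    ard: ARDSettings | None = None,
    row_stride: int = 1,
) -> DecodingModel:
    """Fit position and velocity decoders on a set of training trials.

    Currents are z-scored per dipole with statistics pooled over the training
    trials (the same transform is applied at prediction time); each trial is
    lag-embedded and the valid rows of all trials are pooled.
    """
    cfg = cfg or SLiRConfig()
    stats = [
        trial_suffstats(J, {r: trial_targets[r][k] for r in REGRESSANDS}, cfg, row_stride)
        for k, J in enumerate(trial_currents)
    ]
    return fit_from_stats(stats, ard)


def predict(model: DecodingModel, currents: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Predict position and velocity series from one trial's currents.

    Returns predictions per regressand over the valid rows, and the sample
    indices those rows correspond to on the trial's time grid.
    """
    J = np.atleast_2d(np.asarray(currents, float))
    if J.shape[0] != model.n_dipoles:
        raise ValueError(
            f"model was fit on {model.n_dipoles} dipoles, got {J.shape[0]}"
        )
    Jz = (J - model.scaler_mean[:, None]) / model.scaler_sd[:, None]
    X, valid = embed_lags(Jz, model.cfg)
    out = {}
    for r, fit in model.fits.items():
        out[r] = X @ fit.weights.ravel() + fit.bias
    return out, valid


def selection_report(models: dict[str, DecodingModel], regions: np.ndarray) -> pd.DataFrame:
    """Per-region counts of SLiR-selected dipoles for each task and regressand.

    ``regions`` gives the region label of each decoder input dipole (for
    reduced-grid decoding, the label at each reduced dipole's location).
    """
    regions = np.asarray(regions)
    rows = []
    for task, model in models.items():
        if model.n_dipoles != regions.size:
            raise ValueError("models and region labels use different dipole indexing")
        for r in REGRESSANDS:
            sel = model.selected(r)
            for reg in np.unique(regions):
                rows.append(
                    {
                        "task": task,
                        "regressand": r,
                        "region": reg,
                        "n_selected": int(np.sum(regions[sel] == reg)),
                    }
                )
    df = pd.DataFrame(rows)
    totals = df.groupby(["task", "regressand"])["n_selected"].sum().rename("input_dims")
    return df.merge(totals, on=["task", "regressand"])
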