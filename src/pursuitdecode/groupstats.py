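"""Randomized-block (within-subject) ANOVA, Tukey HSD, simple main effects.

Designs are complete and balanced: every block (subject or replicate)
contributes exactly one observation per factor-level combination.  Each
effect is tested against its own interaction with the block factor, the
within-subject convention — for a levels and n blocks the treatment df pair
is (a-1, (a-1)(n-1)); for an a x b two-way design the interaction df pair is
((a-1)(b-1), (a-1)(b-1)(n-1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaEffect:
    name: str
    ss: float
    df: int
    ms: float
    F: float
    p: float


def _effects_frame(effects: list[AnovaEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"effect": e.name, "SS": e.ss, "df": e.df, "MS": e.ms, "F": e.F, "p": e.p}
         for e in effects]
    )


def rb_anova1(data: np.ndarray) -> pd.DataFrame:
    """One-way randomized-block ANOVA on a (blocks x levels) array.

    Returns a table with the treatment effect (tested against the
    block x treatment residual) and the block effect.
    """
    y = _check_design(data, 2)
    n, a = y.shape
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    ss_blocks = a * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_treat = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_err = ss_total - ss_blocks - ss_treat

    df_treat = a - 1
    df_err = (a - 1) * (n - 1)
    ms_treat = ss_treat / df_treat
    ms_err = ss_err / df_err
    F = ms_treat / ms_err if ms_err > 0 else (0.0 if ms_treat == 0 else np.inf)
    p = float(stats.f.sf(F, df_treat, df_err))
    effects = [
        AnovaEffect("treatment", float(ss_treat), df_treat, float(ms_treat), float(F), p),
        AnovaEffect("block", float(ss_blocks), n - 1, float(ss_blocks / (n - 1)), np.nan, np.nan),
        AnovaEffect("error", float(ss_err), df_err, float(ms_err), np.nan, np.nan),
    ]
    return _effects_frame(effects)


def rb_anova2(data: np.ndarray) -> pd.DataFrame:
    """Two-way randomized-block ANOVA on a (blocks x a x b) array.

    Main effects and the interaction are each tested against their own
    interaction with the block factor.
    """
    y = _check_design(data, 3)
    n, a, b = y.shape
    grand = y.mean()

    m_s = y.mean(axis=(1, 2))  # per block
    m_a = y.mean(axis=(0, 2))  # per level of A
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)  # (a, b)
    m_sa = y.mean(axis=2)  # (n, a)
    m_sb = y.mean(axis=1)  # (n, b)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_sab = ss_total - ss_a - ss_b - ss_s - ss_ab - ss_sa - ss_sb

    rows = []
    for name, ss, df_eff, ss_err, df_err in (
        ("A", ss_a, a - 1, ss_sa, (a - 1) * (n - 1)),
        ("B", ss_b, b - 1, ss_sb, (b - 1) * (n - 1)),
        ("A:B", ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (n - 1)),
    ):
        ms_eff = ss / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
        p = float(stats.f.sf(F, df_eff, df_err))
        rows.append(AnovaEffect(name, float(ss), df_eff, float(ms_eff), float(F), p))
        rows.append(
            AnovaEffect(f"{name} x block", float(ss_err), df_err, float(ms_err), np.nan, np.nan)
        )
    rows.append(AnovaEffect("block", float(ss_s), n - 1, float(ss_s / (n - 1)), np.nan, np.nan))
    return _effects_frame(rows)


def tukey_hsd(
    means: np.ndarray,
    ms_error: float,
    df_error: int,
    n_per_level: int,
) -> pd.DataFrame:
    """Tukey HSD pairwise p-values from level means and an error term.

    Accepts the error mean square and df directly so it composes with the
    within-subject ANOVA (whose error term is the effect's block interaction).
    """
    if ms_error <= 0:
        raise ValueError("ms_error must be positive")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    means = np.asarray(means, float)
    k = means.size
    se = np.sqrt(ms_error / n_per_level)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(means[i] - means[j]) / se
            p = float(stats.studentized_range.sf(q, k, df_error))
            rows.append({"level_a": i, "level_b": j,
                         "diff": float(means[i] - means[j]), "q": float(q), "p": min(p, 1.0)})
    return pd.DataFrame(rows)


def simple_main_effects(data: np.ndarray, fix: str = "B") -> dict[int, pd.DataFrame]:
    """One-way block ANOVA of one factor within each level of the other.

    ``fix='B'`` tests factor A separately at every level of B (and vice
    versa) on a (blocks x a x b) array.
    """
    y = _check_design(data, 3)
    if fix not in ("A", "B"):
        raise ValueError("fix must be 'A' or 'B'")
    out = {}
    n_levels = y.shape[2] if fix == "B" else y.shape[1]
    for lvl in range(n_levels):
        slab = y[:, :, lvl] if fix == "B" else y[:, lvl, :]
        out[lvl] = rb_anova1(slab)
    return out


def _check_design(data: np.ndarray, ndim: int) -> np.ndarray:
    y = np.asarray(data, float)
    if y.ndim != ndim:
        raise ValueError(f"expected a {ndim}-dimensional balanced design array")
    if np.any(~np.isfinite(y)):
        raise ValueError("design contains missing or non-finite responses")
    if y.shape[0] < 2 or min(y.shape[1:]) < 2:
        raise ValueError("need >= 2 blocks and >= 2 levels per factor")
    return y
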