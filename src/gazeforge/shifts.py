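"""Robust distributional comparison and effect sizes.

The centrepiece is the shift function: both samples are summarised by their
nine deciles (Harrell-Davis estimator, a beta-weighted average of all order
statistics), the decile-wise differences quantify where and how the two
distributions differ, a percentile bootstrap gives each decile a confidence
interval, and Hochberg's step-up procedure controls the family-wise error
across the nine deciles.  Supporting routines compute Hedges-g standardised
mean differences, eta-squared / rank-based epsilon-squared, per-subject
learning slopes (handaxe score against the square root of practice hours),
and the within-condition subject permutation used to summarise per-window
gaze parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DECILES = np.arange(1, 10) / 10.0

_weight_cache: dict[tuple[int, float], np.ndarray] = {}


def hd_weights(n: int, q: float) -> np.ndarray:
    """Beta weights of the order statistics for the HD quantile estimator.

    w_i = I(i/n; a, b) - I((i-1)/n; a, b) with a = (n+1)q, b = (n+1)(1-q),
    where I is the regularised incomplete beta function.  The weights sum
    to 1.
    """
    key = (n, round(q, 12))
    if key not in _weight_cache:
        a = (n + 1) * q
        b = (n + 1) * (1 - q)
        grid = np.arange(n + 1) / n
        cdf = stats.beta.cdf(grid, a, b)
        _weight_cache[key] = np.diff(cdf)
    return _weight_cache[key]


def hd_quantile(sample: np.ndarray, q: float) -> float:
    """Harrell-Davis estimate of the q-th quantile."""
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    return float(hd_weights(x.size, q) @ x)


def hd_deciles(sample: np.ndarray) -> np.ndarray:
    """All nine HD decile estimates q_0.1 ... q_0.9 (non-decreasing)."""
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    W = np.column_stack([hd_weights(x.size, q) for q in DECILES])
    return x @ W


@dataclass
class ShiftFunction:
    """Decile differences (b - a) with bootstrap CIs and Hochberg flags."""

    deciles_a: np.ndarray
    deciles_b: np.ndarray
    differences: np.ndarray  # (9,)
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray  # Hochberg-adjusted
    significant: np.ndarray  # boolean, at level alpha
    n_boot: int
    alpha: float
    degenerate: bool = False


def shift_function(
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ShiftFunction:
    """Shift function between two independent samples.

    Differences are HD_b(q) - HD_a(q) at the nine deciles.  Each group is
    resampled independently ``n_boot`` times; percentile bootstrap CIs and
    two-sided bootstrap p-values (2 * min tail probability of the bootstrap
    difference distribution around 0) are computed per decile, and the nine
    p-values are adjusted with Hochberg's step-up method.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 10:
        warnings.warn("fewer than 10 observations per group: shift function "
                      "estimates will be unstable", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(seed)
    da, db = hd_deciles(a), hd_deciles(b)
    diffs = db - da
    boot = _bootstrap_deciles(b, n_boot, rng) - _bootstrap_deciles(a, n_boot, rng)
    lo = np.percentile(boot, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot, 100 * (1 - alpha / 2), axis=0)
    # keep the point estimate inside its interval under extreme skew
    lo = np.minimum(lo, diffs)
    hi = np.maximum(hi, diffs)
    p_less = (np.sum(boot < 0, axis=0) + 0.5 * np.sum(boot == 0, axis=0)) / n_boot
    p_raw = np.clip(2 * np.minimum(p_less, 1 - p_less), 0, 1)
    p_adj = hochberg(p_raw)
    degenerate = np.ptp(a) == 0 and np.ptp(b) == 0
    if degenerate:
        warnings.warn("both samples are constant: CIs collapse to a point",
                      stacklevel=2)
    return ShiftFunction(
        deciles_a=da,
        deciles_b=db,
        differences=diffs,
        ci_low=lo,
        ci_high=hi,
        p_values=p_adj,
        significant=(p_adj <= alpha) & ~degenerate,
        n_boot=n_boot,
        alpha=alpha,
        degenerate=bool(degenerate),
    )


def _bootstrap_deciles(x: np.ndarray, n_boot: int, rng) -> np.ndarray:
    n = x.size
    W = np.column_stack([hd_weights(n, q) for q in DECILES])
    idx = rng.integers(0, n, size=(n_boot, n))
    return np.sort(x[idx], axis=1) @ W


def hochberg(p: np.ndarray) -> np.ndarray:
    """Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, (m - rank) * p[order[rank]])
        adj[order[rank]] = min(running, 1.0)
    return adj


def hedges_g(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD standardised mean difference (a minus b) with the
    small-sample correction J = 1 - 3 / (4 df - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    df = a.size + b.size - 2
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    )
    if pooled <= 1e-300:
        raise ValueError("zero pooled standard deviation")
    J = 1 - 3 / (4 * df - 1)
    return float(J * (a.mean() - b.mean()) / pooled)


@dataclass
class EffectSizes:
    eta_squared: float
    epsilon_squared: float
    degenerate: bool = False


def eta_sq_epsilon_sq(groups: list[np.ndarray]) -> EffectSizes:
    """ANOVA eta-squared and rank-based (Kruskal-Wallis) epsilon-squared.

    eta^2 = SS_between / SS_total; epsilon^2 = H / ((n^2 - 1) / (n + 1)).
    All-identical values are guarded and reported as 0 with a flag.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    allv = np.concatenate(groups)
    n = allv.size
    if np.ptp(allv) == 0:
        warnings.warn("all values identical: effect sizes are 0/0; returning 0",
                      stacklevel=2)
        return EffectSizes(0.0, 0.0, degenerate=True)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    H = stats.kruskal(*groups).statistic
    eps = float(H / ((n**2 - 1) / (n + 1)))
    return EffectSizes(ss_between / ss_total, eps)


@dataclass
class LearningSlope:
    subject: str
    slope: float
    intercept: float
    n: int


def learning_slope(
    hours: np.ndarray, scores: np.ndarray, subject: str = ""
) -> LearningSlope:
    """OLS slope of handaxe score against sqrt(practice hours).

    Because performance follows a power curve -- rapid early gains that
    level off -- score is roughly linear in the square root of practice
    time, and the slope summarises a participant's learning rate (a flatter
    slope indicates higher initial aptitude).
    """
    hours = np.asarray(hours, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if np.unique(hours).size < 2:
        raise ValueError("need at least 2 distinct practice-hour values")
    x = np.sqrt(hours)
    res = stats.linregress(x, scores)
    return LearningSlope(
        subject=subject,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=hours.size,
    )


def permute_within_condition(
    table: pd.DataFrame,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    value_cols: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffle subject identity within each session, then average over windows.

    ``table`` is long-format with columns subject, session, window plus value
    columns.  Within each session the subject labels are permuted as whole
    blocks (every window row of subject s is relabelled to the same target),
    after which the per-subject per-session mean across windows is taken.
    Returns ``(permuted_table, session_means)``.
    """
    required = {"subject", "session", "window"}
    if not required <= set(table.columns):
        raise ValueError(f"table missing columns: {sorted(required - set(table.columns))}")
    if value_cols is None:
        value_cols = [c for c in table.columns if c not in required]
    if rng is None:
        rng = np.random.default_rng(seed)
    # completeness check: every subject x window cell present exactly once
    missing = []
    for sess, grp in table.groupby("session", sort=True):
        subjects = sorted(grp["subject"].unique())
        wins = sorted(grp["window"].unique())
        cells = grp.groupby(["subject", "window"]).size()
        for s in subjects:
            for w in wins:
                if (s, w) not in cells.index:
                    missing.append((sess, s, w))
    if missing:
        raise ValueError(f"missing cells (session, subject, window): {missing}")

    permuted = table.copy()
    for sess in sorted(table["session"].unique()):
        mask = permuted["session"] == sess
        subjects = sorted(permuted.loc[mask, "subject"].unique())
        perm = rng.permutation(len(subjects))
        mapping = {subjects[i]: subjects[perm[i]] for i in range(len(subjects))}
        permuted.loc[mask, "subject"] = permuted.loc[mask, "subject"].map(mapping)
    means = (
        permuted.groupby(["subject", "session"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )
    return permuted, means
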