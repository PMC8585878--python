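"""Canonical correlation analysis between performance and gaze variates.

Given a subject x variable performance matrix Xa (learning slope, handaxe
score, percussion error) and a gaze matrix Xb (gaze CV, mean distance from
core, gaze variability from core), CCA finds paired linear combinations
(canonical variates Za = Xa Wa, Zb = Xb Wb) maximising their correlation.
The implementation follows the classical whitening route: z-score columns,
form the sample covariance blocks, whiten with Cholesky factors and take
the SVD of the whitened cross-covariance

    La^{-1} S_ab Lb^{-T} = U D V^T,   Wa = La^{-T} U,  Wb = Lb^{-T} V,

so the singular values D are the canonical correlations, non-increasing and
in [0, 1].  Weights are sign-indeterminate mode-wise; the convention here
makes the first nonzero element of each Wa column positive (flipping Wb in
step so corr(Za_m, Zb_m) stays equal to +S_m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

PERFORMANCE_VARS = ("learning_slope", "handaxe_score", "percussion_error")
GAZE_VARS = ("gaze_cv", "mean_distance", "edge_variability")

_COND_LIMIT = 1e10


def zscore_columns(X):
    """Standardise columns to mean 0 and sample SD 1 (ddof=1).

    Accepts an array or DataFrame and returns the same type.  A constant
    column is an error (it carries no correlation information and breaks
    the whitening step).
    """
    df = isinstance(X, pd.DataFrame)
    A = X.to_numpy(dtype=float) if df else np.asarray(X, dtype=float)
    sd = A.std(axis=0, ddof=1)
    bad = np.nonzero(sd <= 1e-300)[0]
    if bad.size:
        names = (
            [X.columns[i] for i in bad] if df else [f"column {i}" for i in bad]
        )
        raise ValueError(f"constant column(s): {names}")
    Z = (A - A.mean(axis=0)) / sd
    if df:
        return pd.DataFrame(Z, index=X.index, columns=X.columns)
    return Z


@dataclass
class CCAResult:
    weights_a: np.ndarray  # (p, m)
    weights_b: np.ndarray  # (q, m)
    variates_a: np.ndarray  # (n, m) subject scores
    variates_b: np.ndarray
    correlations: np.ndarray  # (m,) canonical correlations S, non-increasing
    var_names_a: list[str] = field(default_factory=list)
    var_names_b: list[str] = field(default_factory=list)
    session: str | None = None

    @property
    def r_squared(self) -> np.ndarray:
        return self.correlations**2

    @property
    def n_modes(self) -> int:
        return len(self.correlations)


def cca(Xa, Xb, session: str | None = None) -> CCAResult:
    """Canonical correlation analysis of two variable sets on the same subjects."""
    names_a = list(Xa.columns) if isinstance(Xa, pd.DataFrame) else [
        f"a{i}" for i in range(np.asarray(Xa).shape[1])
    ]
    names_b = list(Xb.columns) if isinstance(Xb, pd.DataFrame) else [
        f"b{i}" for i in range(np.asarray(Xb).shape[1])
    ]
    A = np.asarray(Xa, dtype=float)
    B = np.asarray(Xb, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.shape[0] != B.shape[0]:
        raise ValueError("variates must have the same subjects in the same order")
    n, p = A.shape
    q = B.shape[1]
    if n <= max(p, q):
        raise ValueError(f"n={n} subjects cannot support p={p}, q={q} variables")
    if n < 5 * max(p, q):
        warnings.warn(
            f"n={n} is small for p={p}, q={q}: canonical correlations will be "
            "high-variance (upward biased)",
            stacklevel=2,
        )
    Za = zscore_columns(A)
    Zb = zscore_columns(B)
    Saa = np.cov(Za, rowvar=False, ddof=1).reshape(p, p)
    Sbb = np.cov(Zb, rowvar=False, ddof=1).reshape(q, q)
    Sab = (Za.T @ Zb) / (n - 1)
    for name, S in (("performance", Saa), ("gaze", Sbb)):
        c = np.linalg.cond(S)
        if c > _COND_LIMIT:
            raise ValueError(
                f"{name} covariance block is rank-deficient "
                f"(condition number {c:.3g})"
            )
    La = cholesky(Saa, lower=True)
    Lb = cholesky(Sbb, lower=True)
    M = solve_triangular(La, Sab, lower=True)  # La^{-1} Sab
    M = solve_triangular(Lb, M.T, lower=True).T  # ... Lb^{-T}
    U, D, Vt = np.linalg.svd(M)
    m = min(p, q)
    U, D, V = U[:, :m], np.clip(D[:m], 0.0, 1.0), Vt[:m].T
    Wa = solve_triangular(La, U, lower=True, trans="T")  # La^{-T} U
    Wb = solve_triangular(Lb, V, lower=True, trans="T")
    # sign convention: first nonzero element of each Wa column positive
    for j in range(m):
        col = Wa[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            Wa[:, j] = -Wa[:, j]
            Wb[:, j] = -Wb[:, j]
    Va = Za @ Wa
    Vb = Zb @ Wb
    # internal consistency: Pearson r of the variates reproduces S
    for j in range(m):
        if Va[:, j].std() > 0 and Vb[:, j].std() > 0:
            r = np.corrcoef(Va[:, j], Vb[:, j])[0, 1]
            if abs(r - D[j]) > 1e-8:
                raise RuntimeError(
                    f"mode {j + 1}: corr(Za, Zb)={r:.10f} != S={D[j]:.10f}"
                )
    return CCAResult(
        weights_a=Wa,
        weights_b=Wb,
        variates_a=Va,
        variates_b=Vb,
        correlations=D,
        var_names_a=names_a,
        var_names_b=names_b,
        session=session,
    )


def mode_report(result: CCAResult) -> pd.DataFrame:
    """Tidy per-mode table: r^2 and per-variable canonical weights."""
    rows = []
    for j in range(result.n_modes):
        for role, names, W in (
            ("performance", result.var_names_a, result.weights_a),
            ("gaze", result.var_names_b, result.weights_b),
        ):
            for i, name in enumerate(names):
                rows.append(
                    (
                        result.session,
                        j + 1,
                        float(result.correlations[j]),
                        float(result.correlations[j] ** 2),
                        role,
                        name,
                        float(W[i, j]),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["session", "mode", "S", "r_squared", "role", "variable", "weight"],
    )
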