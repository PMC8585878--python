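"""Temporal dispersion of gaze within selected windows.

Continuous x-axis gaze from all subjects is organised into a time x subject
matrix per window.  Two complementary summaries are computed: the gaze
coefficient of variation per subject (SD of gaze position divided by its
mean over the window), and an agglomerative hierarchical clustering of the
time rows (Ward's minimum-variance criterion on Euclidean distances) whose
output is decomposed into within-/between-class variance and reduced to one
"central object" per cluster -- the actual time row closest to the cluster
mean, whose timestamp is the time centroid used by the edge-referenced
spatial analysis.

Only x-gaze enters these statistics; the y coordinate is carried in the
streams but unused here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


@dataclass
class GazeStream:
    """Gaze samples for one subject in one session at a nominal 60 Hz.

    ``samples`` has columns ``t_s, x, y, valid`` with strictly increasing
    timestamps; x and y are normalised screen coordinates in [0, 1].
    """

    subject_id: str
    session: str
    samples: pd.DataFrame

    def __post_init__(self):
        t = self.samples["t_s"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(
                f"timestamps not strictly increasing for subject "
                f"{self.subject_id!r}, session {self.session!r}"
            )


@dataclass
class WindowGazeMatrix:
    """x-gaze resampled onto a shared 60 Hz grid inside one window."""

    window_id: int
    times: np.ndarray  # (n_rows,) grid timestamps
    subjects: list[str]
    values: np.ndarray  # (n_rows, n_subjects)
    session: str | None = None


@dataclass
class CVRecord:
    subject: str
    session: str
    window_id: int
    cv: float


@dataclass
class ClusterResult:
    """Ward clustering of time rows plus derived summaries."""

    assignments: np.ndarray  # (n_rows,) labels 1..k, in order of first appearance
    k: int
    within_class_pct: float
    between_class_pct: float
    merge_heights: np.ndarray
    cluster_means: np.ndarray  # (k, n_subjects)
    central_indices: np.ndarray  # (k,) row index of each central object
    time_centroids: np.ndarray  # (k,) timestamps of the central objects
    central_vectors: np.ndarray  # (k, n_subjects) per-subject gaze at centroids
    degenerate: bool = False


def extract_window_matrix(
    streams: list[GazeStream],
    window,
    rate_hz: float = 60.0,
    window_id: int = 0,
) -> WindowGazeMatrix:
    """Resample each subject's x-gaze onto a common grid inside [start, end).

    ``window`` is anything with ``start_s``/``end_s`` attributes or a
    ``(start, end)`` pair.  Invalid samples are linearly interpolated from
    valid neighbours; a subject with more than 50% invalid samples in the
    window is excluded with a warning.
    """
    start, end = _window_bounds(window)
    n_rows = int(round((end - start) * rate_hz))
    grid = start + np.arange(n_rows) / rate_hz
    cols, subjects = [], []
    session = streams[0].session if streams else None
    for stream in streams:
        df = stream.samples
        in_win = (df["t_s"].to_numpy() >= start) & (df["t_s"].to_numpy() < end)
        sub = df.loc[in_win]
        if len(sub) == 0:
            warnings.warn(
                f"subject {stream.subject_id!r} has no samples in window "
                f"[{start}, {end}); excluded",
                stacklevel=2,
            )
            continue
        valid_frac = float(sub["valid"].mean())
        if valid_frac < 0.5:
            warnings.warn(
                f"subject {stream.subject_id!r} has {100 * (1 - valid_frac):.0f}% "
                f"invalid samples in window [{start}, {end}); excluded",
                stacklevel=2,
            )
            continue
        good = sub.loc[sub["valid"].astype(bool)]
        cols.append(np.interp(grid, good["t_s"].to_numpy(), good["x"].to_numpy()))
        subjects.append(stream.subject_id)
    values = np.column_stack(cols) if cols else np.empty((n_rows, 0))
    return WindowGazeMatrix(
        window_id=window_id, times=grid, subjects=subjects, values=values,
        session=session,
    )


def gaze_cv(stream: GazeStream, window, window_id: int = 0) -> CVRecord:
    """Coefficient of variation of x-gaze over the window's continuous segment."""
    start, end = _window_bounds(window)
    df = stream.samples
    mask = (
        (df["t_s"].to_numpy() >= start)
        & (df["t_s"].to_numpy() < end)
        & df["valid"].to_numpy().astype(bool)
    )
    x = df.loc[mask, "x"].to_numpy()
    if len(x) < 2:
        raise ValueError(
            f"window [{start}, {end}) has {len(x)} valid samples for subject "
            f"{stream.subject_id!r}; need at least 2"
        )
    mean = x.mean()
    if mean <= 1e-12:
        raise ValueError(
            f"mean gaze position {mean} too small for a defined CV "
            f"(subject {stream.subject_id!r})"
        )
    return CVRecord(
        subject=stream.subject_id,
        session=stream.session,
        window_id=window_id,
        cv=float(x.std(ddof=1) / mean),
    )


def ward_cluster(matrix: WindowGazeMatrix, k: int | None = None) -> ClusterResult:
    """Agglomerative Ward clustering of the time rows.

    If ``k`` is not given, the tree is truncated at the largest gap in
    successive merge heights among k in [2, 5] (ties resolved toward 3, then
    toward the smaller k).  Assignments are relabelled 1..k in order of first
    appearance so the output is deterministic for a given matrix.
    """
    X = matrix.values
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = linkage(X, method="ward")  # Euclidean distances between time rows
    heights = Z[:, 2]
    if k is None:
        k = _auto_k(heights, n)
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    raw = fcluster(Z, t=k, criterion="maxclust")
    assignments = _relabel_first_appearance(raw)
    k_eff = int(assignments.max())
    within, between, degenerate = variance_decomposition(X, assignments)
    means = np.stack(
        [X[assignments == c].mean(axis=0) for c in range(1, k_eff + 1)]
    )
    idx, t_cent, vecs = central_objects(matrix, assignments)
    return ClusterResult(
        assignments=assignments,
        k=k_eff,
        within_class_pct=within,
        between_class_pct=between,
        merge_heights=heights,
        cluster_means=means,
        central_indices=idx,
        time_centroids=t_cent,
        central_vectors=vecs,
        degenerate=degenerate,
    )


def variance_decomposition(
    X: np.ndarray | WindowGazeMatrix, assignments: np.ndarray
) -> tuple[float, float, bool]:
    """Within-/between-class sums of squares as percentages of the total.

    Returns ``(within_pct, between_pct, degenerate)``; the percentages sum to
    100 except in the degenerate all-rows-identical case, which is flagged
    and reported as (0, 0).
    """
    if isinstance(X, WindowGazeMatrix):
        X = X.values
    assignments = np.asarray(assignments)
    if len(assignments) != X.shape[0]:
        raise ValueError("assignment length does not match matrix rows")
    grand = X.mean(axis=0)
    total = float(((X - grand) ** 2).sum())
    if total <= 1e-300:
        warnings.warn("all rows identical: total sum of squares is 0", stacklevel=2)
        return 0.0, 0.0, True
    within = 0.0
    for c in np.unique(assignments):
        rows = X[assignments == c]
        within += float(((rows - rows.mean(axis=0)) ** 2).sum())
    within_pct = 100.0 * within / total
    return within_pct, 100.0 - within_pct, False


def central_objects(
    matrix: WindowGazeMatrix, assignments: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per cluster, the actual time row closest to the cluster mean.

    Ties are broken by the earliest timestamp.  Returns the row indices, the
    timestamps (time centroids), and the per-subject gaze vectors of those
    rows, ordered by cluster label.
    """
    X = matrix.values
    assignments = np.asarray(assignments)
    idx_out, t_out, vec_out = [], [], []
    for c in np.unique(assignments):
        rows = np.nonzero(assignments == c)[0]
        mean = X[rows].mean(axis=0)
        d2 = ((X[rows] - mean) ** 2).sum(axis=1)
        best = rows[int(np.argmin(d2))]  # argmin returns first min: earliest t
        idx_out.append(best)
        t_out.append(matrix.times[best])
        vec_out.append(X[best])
    return np.array(idx_out), np.array(t_out), np.stack(vec_out)


def subject_central_objects(
    matrix: WindowGazeMatrix, assignments: np.ndarray
) -> pd.DataFrame:
    """Per-subject central objects: each subject's own most representative sample.

    For every cluster and every subject, the time sample whose gaze value is
    closest to that subject's coordinate of the cluster centroid -- "an
    actual value for each subject closest to the cluster centroid".  Ties go
    to the earliest timestamp.  Selecting representative values per subject
    makes the downstream edge-referenced statistics robust to transient
    excursions (a subject glancing away is never represented by the glance).
    Returns a tidy frame with columns cluster, subject, t_centroid, gaze_x.
    """
    X = matrix.values
    assignments = np.asarray(assignments)
    rows = []
    for c in np.unique(assignments):
        members = np.nonzero(assignments == c)[0]
        mean = X[members].mean(axis=0)
        for j, subj in enumerate(matrix.subjects):
            best = members[int(np.argmin(np.abs(X[members, j] - mean[j])))]
            rows.append(
                (int(c), subj, float(matrix.times[best]), float(X[best, j]))
            )
    return pd.DataFrame(rows, columns=["cluster", "subject", "t_centroid", "gaze_x"])


def dissimilarity_summary(result: ClusterResult) -> float:
    """Mean pairwise Euclidean distance between cluster centroids.

    Quantifies how far apart the gaze clusters sit.  Undefined for a single
    cluster: returns NaN with a warning.
    """
    if result.k < 2:
        warnings.warn("dissimilarity undefined for k=1", stacklevel=2)
        return float("nan")
    return float(pdist(result.cluster_means).mean())


def _window_bounds(window) -> tuple[float, float]:
    if hasattr(window, "start_s"):
        return float(window.start_s), float(window.end_s)
    try:  # pandas row / mapping
        return float(window["start_s"]), float(window["end_s"])
    except (TypeError, KeyError, IndexError):
        start, end = window
        return float(start), float(end)


def _auto_k(heights: np.ndarray, n: int) -> int:
    candidates = [k for k in range(2, 6) if k <= n]
    best_k, best_gap = candidates[0], -np.inf
    for k in candidates:
        # k clusters <-> cutting between merge n-k-1 and merge n-k
        if n - k - 1 < 0:
            continue
        gap = heights[n - k] - heights[n - k - 1] if n - k < len(heights) else 0.0
        better = gap > best_gap + 1e-15
        tie = abs(gap - best_gap) <= 1e-15
        if better or (tie and (abs(k - 3), k) < (abs(best_k - 3), best_k)):
            best_k, best_gap = k, gap
    return best_k


def _relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    mapping, out = {}, np.empty(len(labels), dtype=int)
    nxt = 1
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out[i] = mapping[lab]
    return out
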