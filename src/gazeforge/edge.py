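"""Robust tracking of the core's working edge and edge-referenced gaze dispersion.

The working edge (rightmost edge of the stone core, where flake removals
concentrate) is localised per video frame by registering a template feature
cloud onto the frame's candidate points with RANSAC.  The model family is a
translation by default (optionally translation + isotropic scale): a rigid
core moves little between nearby frames, so one correspondence suffices per
hypothesis.  The fitted template bounding box gives the per-frame edge
x-coordinate (box x-maximum); subject-level gaze central objects are then
referenced to the edge to yield a signed distance per cluster time centroid
and a per-window dispersion (standard deviation of those distances).

All coordinates are normalised to [0, 1] by the 1680 x 1050 frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class TemplatePoints:
    """Feature cloud of the core in a reference frame."""

    points: np.ndarray  # (n, 2)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("template needs at least 3 (x, y) points")
        object.__setattr__(self, "points", pts)

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) enclosing all template points."""
        lo = self.points.min(axis=0)
        hi = self.points.max(axis=0)
        return float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1])


@dataclass
class FramePoints:
    """Candidate feature points of one video frame."""

    frame_index: int
    t_s: float
    points: np.ndarray  # (m, 2): transformed template inliers + outliers

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)


@dataclass
class Registration:
    """Result of registering the template onto a single frame."""

    frame_index: int
    t_s: float
    translation: np.ndarray  # (2,)
    scale: float
    inlier_count: int
    n_points: int
    inlier_frac: float
    edge_x: float
    box: tuple[float, float, float, float]
    quality_ok: bool


@dataclass
class EdgeTrajectory:
    """Per-frame edge estimates; low-quality frames are interpolated."""

    frames: pd.DataFrame  # frame, t_s, tx, ty, scale, inlier_frac, edge_x, quality_ok

    @property
    def low_quality_frac(self) -> float:
        return float(1.0 - self.frames["quality_ok"].mean())

    def edge_at(self, t_s: float) -> float:
        """Edge x at the nearest frame to ``t_s`` (raises if uncovered)."""
        t = self.frames["t_s"].to_numpy()
        dt = np.median(np.diff(t)) if len(t) > 1 else 1 / 30
        i = int(np.argmin(np.abs(t - t_s)))
        if abs(t[i] - t_s) > dt:
            raise ValueError(f"no frame within {dt:.4f} s of t={t_s:.4f}")
        return float(self.frames["edge_x"].iloc[i])


def _evaluate_translations(
    template: np.ndarray,
    tree: cKDTree,
    frame_pts: np.ndarray,
    translations: np.ndarray,
    tol: float,
) -> np.ndarray:
    """Inlier counts for a batch of translation hypotheses.

    A frame point is an inlier of hypothesis t if, after removing t, it lies
    within ``tol`` of its nearest template point.
    """
    shifted = frame_pts[None, :, :] - translations[:, None, :]
    d, _ = tree.query(shifted.reshape(-1, 2))
    return (d.reshape(len(translations), -1) <= tol).sum(axis=1)


def _refit(
    template: np.ndarray,
    tree: cKDTree,
    frame_pts: np.ndarray,
    translation: np.ndarray,
    tol: float,
) -> tuple[np.ndarray, int]:
    """Least-squares refit of the translation on the consensus inliers."""
    d, nn = tree.query(frame_pts - translation)
    mask = d <= tol
    if not mask.any():
        return translation, 0
    refined = (frame_pts[mask] - template[nn[mask]]).mean(axis=0)
    return refined, int(mask.sum())


def ransac_register(
    template: TemplatePoints,
    frame: FramePoints,
    n_iter: int = 500,
    inlier_tol: float = 0.005,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    warm_start: np.ndarray | None = None,
    inlier_floor: float = 0.3,
    accept_frac: float | None = None,
    with_scale: bool = False,
) -> Registration:
    """Estimate the template -> frame transform with RANSAC.

    Hypotheses are translations from single sampled correspondences (a pair
    of correspondences when ``with_scale``); the consensus-maximal model is
    refit by least squares on its inliers.  ``warm_start`` (e.g. the previous
    frame's translation) is evaluated first and, when ``accept_frac`` is set
    and the warm start already explains that fraction of the template,
    sampling is skipped entirely -- the fast path used by frame-to-frame
    tracking.  A frame whose inlier fraction falls below ``inlier_floor`` is
    flagged low-quality.
    """
    tpl = template.points
    pts = frame.points
    if pts.shape[0] < (2 if with_scale else 1):
        raise ValueError("frame has fewer points than the minimal sample")
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = cKDTree(tpl)
    n_tpl = tpl.shape[0]
    scale = 1.0

    best_t, best_count = None, -1
    if warm_start is not None:
        t0, c0 = _refit(tpl, tree, pts, np.asarray(warm_start, float), inlier_tol)
        best_t, best_count = t0, c0
        if accept_frac is not None and c0 / n_tpl >= accept_frac:
            return _finish(template, frame, t0, scale, c0, inlier_floor)
    if with_scale:
        i = rng.integers(0, n_tpl, size=(n_iter, 2))
        j = rng.integers(0, pts.shape[0], size=(n_iter, 2))
        dt = tpl[i[:, 1]] - tpl[i[:, 0]]
        df_ = pts[j[:, 1]] - pts[j[:, 0]]
        norm_t = np.linalg.norm(dt, axis=1)
        norm_f = np.linalg.norm(df_, axis=1)
        ok = norm_t > 1e-12
        scales = np.where(ok, norm_f / np.where(ok, norm_t, 1.0), 1.0)
        best_s, best_count_s = 1.0, -1
        for s, ti, fj in zip(scales, i[:, 0], j[:, 0]):
            t = pts[fj] - s * tpl[ti]
            c = _evaluate_translations(s * tpl, cKDTree(s * tpl), pts,
                                       t[None, :], inlier_tol)[0]
            if c > best_count_s:
                best_s, best_t, best_count_s = s, t, c
        scale = best_s
        best_count = best_count_s
        tpl_s = scale * tpl
        tree_s = cKDTree(tpl_s)
        best_t, best_count = _refit(tpl_s, tree_s, pts, best_t, inlier_tol)
        return _finish(template, frame, best_t, scale, best_count, inlier_floor)

    i = rng.integers(0, n_tpl, size=n_iter)
    j = rng.integers(0, pts.shape[0], size=n_iter)
    hyps = pts[j] - tpl[i]
    counts = _evaluate_translations(tpl, tree, pts, hyps, inlier_tol)
    k = int(np.argmax(counts))
    if counts[k] > best_count:
        best_t, best_count = hyps[k], counts[k]
    best_t, best_count = _refit(tpl, tree, pts, best_t, inlier_tol)
    return _finish(template, frame, best_t, scale, best_count, inlier_floor)


def _finish(template, frame, translation, scale, count, inlier_floor):
    xmin, ymin, xmax, ymax = template.bbox
    box = (
        scale * xmin + translation[0],
        scale * ymin + translation[1],
        scale * xmax + translation[0],
        scale * ymax + translation[1],
    )
    frac = count / template.points.shape[0]
    return Registration(
        frame_index=frame.frame_index,
        t_s=frame.t_s,
        translation=np.asarray(translation, float),
        scale=float(scale),
        inlier_count=int(count),
        n_points=int(frame.points.shape[0]),
        inlier_frac=float(frac),
        edge_x=float(box[2]),
        box=box,
        quality_ok=bool(frac >= inlier_floor),
    )


def track_edge(
    template: TemplatePoints,
    frames: list[FramePoints],
    n_iter: int = 500,
    inlier_tol: float = 0.005,
    seed: int | None = None,
    inlier_floor: float = 0.3,
    accept_frac: float = 0.8,
) -> EdgeTrajectory:
    """Frame-by-frame registration with the previous translation as warm start.

    Low-quality frames get their edge_x linearly interpolated from the
    nearest good frames; an all-bad sequence is returned fully flagged with
    NaN edges.
    """
    rng = np.random.default_rng(seed)
    rows = []
    prev = None
    for fr in frames:
        reg = ransac_register(
            template,
            fr,
            n_iter=n_iter,
            inlier_tol=inlier_tol,
            rng=rng,
            warm_start=prev,
            inlier_floor=inlier_floor,
            accept_frac=accept_frac,
        )
        prev = reg.translation if reg.quality_ok else prev
        rows.append(
            (
                fr.frame_index,
                fr.t_s,
                reg.translation[0],
                reg.translation[1],
                reg.scale,
                reg.inlier_frac,
                reg.edge_x,
                reg.quality_ok,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "frame", "t_s", "tx", "ty", "scale", "inlier_frac", "edge_x",
            "quality_ok",
        ],
    )
    good = df["quality_ok"].to_numpy()
    if good.any() and not good.all():
        df.loc[~good, "edge_x"] = np.interp(
            df.loc[~good, "t_s"], df.loc[good, "t_s"], df.loc[good, "edge_x"]
        )
    elif not good.any():
        df["edge_x"] = np.nan
    return EdgeTrajectory(frames=df)


def centroid_distances(
    centroids: pd.DataFrame, trajectory: EdgeTrajectory
) -> pd.DataFrame:
    """Signed gaze - edge distance at each cluster time centroid.

    ``centroids`` needs columns subject, session, window, cluster,
    t_centroid, gaze_x.  The edge is looked up at the nearest frame (gaze at
    60 Hz vs frames at 30 fps keeps the timestamp discrepancy under half a
    frame).  Positive distance = gaze right of the edge.
    """
    required = {"subject", "session", "window", "cluster", "t_centroid", "gaze_x"}
    missing = required - set(centroids.columns)
    if missing:
        raise ValueError(f"centroid table missing columns: {sorted(missing)}")
    order = np.argsort(trajectory.frames["t_s"].to_numpy(), kind="stable")
    t_frames = trajectory.frames["t_s"].to_numpy()[order]
    edge_x = trajectory.frames["edge_x"].to_numpy()[order]
    dt = float(np.median(np.diff(t_frames))) if len(t_frames) > 1 else 1 / 30
    out = centroids.copy()
    t_c = out["t_centroid"].to_numpy(dtype=float)
    # nearest frame via binary search on the sorted frame times
    pos = np.searchsorted(t_frames, t_c)
    pos = np.clip(pos, 1, len(t_frames) - 1)
    left_closer = np.abs(t_c - t_frames[pos - 1]) <= np.abs(t_frames[pos] - t_c)
    nearest = np.where(left_closer, pos - 1, pos)
    gap = np.abs(t_frames[nearest] - t_c)
    if np.any(gap > dt):
        bad = out.iloc[int(np.argmax(gap > dt))]
        raise ValueError(
            f"no frame coverage for centroid at t={bad['t_centroid']:.3f} "
            f"(subject {bad['subject']!r}, window {bad['window']})"
        )
    out["edge_x"] = edge_x[nearest]
    out["distance"] = out["gaze_x"].to_numpy() - edge_x[nearest]
    return out


def spatial_dispersion(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of centroid distances per subject x session x window.

    ``edge_variability`` is the sample SD of the signed distances across the
    window's cluster time centroids; with fewer than two centroids it is
    reported missing (NaN) while the mean is still returned.
    """
    rows = []
    for (subj, sess, win), grp in records.groupby(
        ["subject", "session", "window"], sort=True
    ):
        d = grp["distance"].to_numpy()
        rows.append(
            (
                subj,
                sess,
                win,
                float(np.mean(d)),
                float(np.std(d, ddof=1)) if len(d) >= 2 else float("nan"),
                len(d),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "session", "window", "mean_distance", "edge_variability",
            "n_centroids",
        ],
    )
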