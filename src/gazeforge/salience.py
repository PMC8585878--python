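"""Button-press salience: press matrices, phase counts, and window selection.

During action observation, participants press a button whenever they judge
the demonstrator to have completed a meaningful unit of action.  This module
turns those press logs into a binary subject x second matrix, scores each
action phase by how many presses fall inside it, computes a sliding-window
probability of a meaningful event, and selects the high-probability windows
(by default core-move windows at or above the 90th percentile) that all
downstream gaze analysis is restricted to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The closed six-item action-phase vocabulary used to annotate each second
#: of the demonstration video.
PHASES = (
    "core_reposition",
    "core_move",
    "light_percussion",
    "percussion",
    "grinding",
    "tool_change",
)


class ConfigError(ValueError):
    """Raised for invalid configuration (e.g. unknown phase labels)."""


@dataclass(frozen=True)
class PhaseTrack:
    """Per-second action-phase annotation of the demonstration video."""

    labels: np.ndarray  # (T,) array of strings from PHASES

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=object)
        unknown = set(labels) - set(PHASES)
        if unknown:
            raise ConfigError(f"unknown phase labels: {sorted(unknown)}")
        object.__setattr__(self, "labels", labels)

    @property
    def duration_s(self) -> int:
        return len(self.labels)

    def segments(self) -> list[tuple[int, int, str]]:
        """Contiguous runs as (start_s, end_s, phase), end exclusive."""
        out = []
        labels = self.labels
        start = 0
        for t in range(1, len(labels) + 1):
            if t == len(labels) or labels[t] != labels[start]:
                out.append((start, t, labels[start]))
                start = t
        return out

    def onsets(self, phase: str) -> np.ndarray:
        """Start seconds of every segment of ``phase``."""
        if phase not in PHASES:
            raise ConfigError(f"unknown phase label: {phase!r}")
        return np.array([s for s, _, p in self.segments() if p == phase])


@dataclass
class PressLog:
    """Button-press latencies (seconds from video onset) for one viewing."""

    subject_id: str
    session: str
    latencies: np.ndarray

    def __post_init__(self):
        self.latencies = np.sort(np.asarray(self.latencies, dtype=float))


@dataclass
class PressMatrix:
    """Binary subject x second matrix: 1 = at least one press in that second."""

    subjects: list[str]
    values: np.ndarray  # (n_subjects, T) of {0, 1}
    session: str | None = None

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> int:
        return self.values.shape[1]


@dataclass
class SalienceSeries:
    """Sliding-window probability of a meaningful-event press."""

    window_starts: np.ndarray
    window_len_s: float
    probabilities: np.ndarray
    session: str | None = None


@dataclass
class SelectedWindows:
    """Retained high-salience windows plus bookkeeping.

    ``windows`` holds the unmerged retained windows (one row per sliding
    window); ``merged`` collapses overlapping retained windows into maximal
    runs so gaze samples are not double-counted when a single continuous
    stretch is wanted.
    """

    windows: pd.DataFrame  # start_s, end_s, dominant_phase, probability
    merged: pd.DataFrame  # start_s, end_s
    threshold: float
    percentile: float
    phase: str = "core_move"
    per_session: bool = False
    extra: dict = field(default_factory=dict)


def build_press_matrix(logs: list[PressLog], duration_s: float) -> PressMatrix:
    """Round press latencies to the nearest second (half-up) and binarise.

    A latency of exactly ``x.5`` maps to second ``x+1``.  Latencies rounding
    to ``duration_s`` are clamped into the final second.  Multiple presses in
    one second collapse to a single 1.
    """
    T = int(round(duration_s))
    subjects = [log.subject_id for log in logs]
    values = np.zeros((len(logs), T), dtype=np.uint8)
    for i, log in enumerate(logs):
        for lat in log.latencies:
            if lat < 0 or lat > duration_s:
                raise ValueError(
                    f"press latency {lat} for subject {log.subject_id!r} "
                    f"outside video [0, {duration_s}]"
                )
        secs = np.floor(log.latencies + 0.5).astype(int)  # round half-up
        secs = np.clip(secs, 0, T - 1)
        values[i, secs] = 1
    session = logs[0].session if logs else None
    return PressMatrix(subjects=subjects, values=values, session=session)


def phase_press_counts(
    matrix: PressMatrix, track: PhaseTrack
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subject press counts within each action phase, plus phase means.

    Returns ``(counts, means)`` where ``counts`` is indexed by subject with
    one column per phase and ``means`` averages each phase's count across
    subjects.
    """
    if matrix.duration_s != track.duration_s:
        raise ValueError(
            f"press matrix spans {matrix.duration_s} s but phase track "
            f"spans {track.duration_s} s"
        )
    counts = pd.DataFrame(
        0, index=pd.Index(matrix.subjects, name="subject"), columns=list(PHASES)
    )
    for phase in PHASES:
        mask = track.labels == phase
        counts[phase] = matrix.values[:, mask].sum(axis=1)
    return counts, counts.mean(axis=0)


def salience_series(
    matrix: PressMatrix, window_s: float = 10.0, slide_s: float = 5.0
) -> SalienceSeries:
    """Probability of a meaningful event per sliding window.

    Each window's probability is the fraction of subjects with at least one
    press inside the window; a subject counts at most once per window.
    Windows advance by ``slide_s`` and windows extending past the end of the
    video are dropped.
    """
    if not (window_s >= slide_s > 0):
        raise ValueError("require window_s >= slide_s > 0")
    if matrix.n_subjects == 0:
        raise ValueError("empty press matrix")
    T = matrix.duration_s
    starts = np.arange(0, T - window_s + 1e-9, slide_s)
    probs = np.empty(len(starts))
    for i, s in enumerate(starts):
        lo, hi = int(round(s)), int(round(s + window_s))
        probs[i] = matrix.values[:, lo:hi].any(axis=1).mean()
    return SalienceSeries(
        window_starts=starts,
        window_len_s=float(window_s),
        probabilities=probs,
        session=matrix.session,
    )


def window_dominant_phase(track: PhaseTrack, start_s: float, end_s: float) -> str:
    """Phase of the strict majority of the window's seconds.

    Ties are broken by the earliest-occurring phase within the window.
    """
    lo, hi = int(round(start_s)), min(int(round(end_s)), track.duration_s)
    labels = track.labels[lo:hi]
    best = None  # ((-count, first_index), phase)
    for phase in PHASES:
        hits = np.nonzero(labels == phase)[0]
        if not hits.size:
            continue
        key = (-len(hits), int(hits[0]))
        if best is None or key < best[0]:
            best = (key, phase)
    return best[1] if best is not None else None


def longest_phase_run(
    track: PhaseTrack, start_s: float, end_s: float, phase: str
) -> tuple[float, float]:
    """Longest continuous run of ``phase`` seconds within [start_s, end_s).

    Selected windows are onset-aligned, so they typically contain a stretch
    of the preceding phase; continuous gaze analysis is restricted to the
    salient phase's own continuous data segment.  Ties go to the earliest
    run.  Raises if the window contains no second of the phase.
    """
    lo, hi = int(round(start_s)), min(int(round(end_s)), track.duration_s)
    mask = track.labels[lo:hi] == phase
    if not mask.any():
        raise ValueError(f"no {phase!r} second in [{start_s}, {end_s})")
    best_len, best_start, run_start = 0, lo, None
    for i in range(len(mask) + 1):
        if i < len(mask) and mask[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    return float(lo + best_start), float(lo + best_start + best_len)


def _merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, r in df.sort_values("start_s").iterrows():
        if rows and r["start_s"] <= rows[-1][1]:
            rows[-1][1] = max(rows[-1][1], r["end_s"])
        else:
            rows.append([r["start_s"], r["end_s"]])
    return pd.DataFrame(rows, columns=["start_s", "end_s"])


def select_windows(
    series: SalienceSeries | list[SalienceSeries],
    track: PhaseTrack,
    percentile: float = 90.0,
    phase: str = "core_move",
    top_k: int | None = None,
) -> SelectedWindows:
    """Retain windows at/above the percentile threshold whose phase matches.

    When several per-session series are given their probabilities are pooled
    (averaged window-wise) so that a single set of windows is shared by all
    sessions.  The threshold is the requested percentile of the pooled
    probability series (linear interpolation between order statistics).  If
    ``top_k`` is set and more windows qualify, the ``top_k`` highest-
    probability windows (earliest first on ties) are kept.
    """
    if phase not in PHASES:
        raise ConfigError(f"unknown phase label: {phase!r}")
    series_list = [series] if isinstance(series, SalienceSeries) else list(series)
    starts = series_list[0].window_starts
    for s in series_list[1:]:
        if not np.array_equal(s.window_starts, starts):
            raise ValueError("salience series have mismatched window grids")
    pooled = np.mean([s.probabilities for s in series_list], axis=0)
    window_len = series_list[0].window_len_s
    threshold = float(np.percentile(pooled, percentile))

    rows = []
    for s0, p in zip(starts, pooled):
        if p < threshold:
            continue
        dom = window_dominant_phase(track, s0, s0 + window_len)
        if dom == phase:
            rows.append((float(s0), float(s0 + window_len), dom, float(p)))
    windows = pd.DataFrame(
        rows, columns=["start_s", "end_s", "dominant_phase", "probability"]
    )
    if windows.empty:
        warnings.warn(
            f"no window at/above the {percentile}th percentile has dominant "
            f"phase {phase!r}",
            stacklevel=2,
        )
    if top_k is not None and len(windows) > top_k:
        windows = (
            windows.sort_values(["probability", "start_s"], ascending=[False, True])
            .head(top_k)
            .sort_values("start_s")
            .reset_index(drop=True)
        )
    merged = (
        _merge_intervals(windows)
        if not windows.empty
        else pd.DataFrame(columns=["start_s", "end_s"])
    )
    return SelectedWindows(
        windows=windows.reset_index(drop=True),
        merged=merged,
        threshold=threshold,
        percentile=float(percentile),
        phase=phase,
    )
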