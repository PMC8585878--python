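"""End-to-end orchestration of the perceptuomotor analysis.

Stages: button-press salience -> high-probability window selection -> Ward
clustering of window gaze matrices (CV, variance decomposition, central
objects) -> RANSAC edge tracking and edge-referenced dispersion -> within-
condition permutation and session means -> shift functions (Shift1 = Post1
vs Pre, Shift2 = Post2 vs Post1) and effect sizes -> per-session canonical
correlation between the performance and gaze variates.

All randomness flows from one root seed split per stage, so two runs with
the same configuration produce byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import cca as cca_mod
from . import clustering, edge, salience, shifts
from . import synth as synth_mod

logger = logging.getLogger("gazeforge")

SHIFT_VARS = (
    "gaze_cv", "mean_distance", "edge_variability", "handaxe_score",
    "percussion_error",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    synth: synth_mod.SynthConfig = field(default_factory=synth_mod.SynthConfig)
    window_s: float = 10.0
    slide_s: float = 5.0
    percentile: float = 90.0
    phase: str = "core_move"
    top_k: int | None = 40
    k_clusters: int | None = None  # None -> automatic truncation in [2, 5]
    ransac_iters: int = 300
    ransac_tol: float = 0.005
    inlier_floor: float = 0.3
    accept_frac: float = 0.8
    n_boot: int = 2000
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        self.synth.validate()
        if not (self.window_s >= self.slide_s > 0):
            raise salience.ConfigError("require window_s >= slide_s > 0")
        if not 0 < self.percentile < 100:
            raise salience.ConfigError("percentile must be in (0, 100)")
        if self.phase not in salience.PHASES:
            raise salience.ConfigError(f"unknown phase {self.phase!r}")
        if not 0 < self.alpha < 1:
            raise salience.ConfigError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"]["phase_segment_spec"] = {
            k: list(v) for k, v in d["synth"]["phase_segment_spec"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sd = dict(d.pop("synth", {}))
        if "phase_segment_spec" in sd:
            sd["phase_segment_spec"] = {
                k: tuple(v) for k, v in sd["phase_segment_spec"].items()
            }
        for key in ("session_labels", "gaze_cv_by_session",
                    "edge_offset_sd_by_session", "hours_by_session",
                    "percussion_by_session"):
            if key in sd:
                sd[key] = tuple(sd[key])
        return cls(synth=synth_mod.SynthConfig(**sd), **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ResultsBundle:
    """All stage outputs plus a manifest tying them to the configuration."""

    tables: dict[str, pd.DataFrame]
    manifest: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(cfg: RunConfig, dataset: synth_mod.SynthDataset | None = None
                 ) -> ResultsBundle:
    """Execute the full analysis on a synthetic (or pre-built) dataset."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    synth_seed, ransac_seed, perm_seed, boot_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)
    )
    timings = {}

    t0 = _stage("synthesize")
    if dataset is None:
        dataset = synth_mod.generate_dataset(replace(cfg.synth, seed=synth_seed))
    scfg = dataset.cfg
    sessions = list(scfg.session_labels)
    track = dataset.phase_track
    timings["synthesize"] = time.perf_counter() - t0

    # --- salience: press matrices and pooled window selection -------------
    t0 = _stage("salience")
    series_list, salience_rows = [], []
    for session in sessions:
        logs = [l for l in dataset.press_logs if l.session == session]
        matrix = salience.build_press_matrix(logs, scfg.video_duration_s)
        series = salience.salience_series(matrix, cfg.window_s, cfg.slide_s)
        series_list.append(series)
        salience_rows.append(
            pd.DataFrame(
                {
                    "session": session,
                    "window_start": series.window_starts,
                    "probability": series.probabilities,
                }
            )
        )
    selected = salience.select_windows(
        series_list, track, percentile=cfg.percentile, phase=cfg.phase,
        top_k=cfg.top_k,
    )
    if selected.windows.empty:
        raise RuntimeError("salience stage: no window passed selection")
    # continuous gaze analysis runs over the salient phase's own continuous
    # segment inside each window, not the onset-aligned 10-s span
    runs = [
        salience.longest_phase_run(track, w["start_s"], w["end_s"], cfg.phase)
        for _, w in selected.windows.iterrows()
    ]
    selected.windows["run_start_s"] = [r[0] for r in runs]
    selected.windows["run_end_s"] = [r[1] for r in runs]
    timings["salience"] = time.perf_counter() - t0

    # --- edge tracking over the selected windows --------------------------
    t0 = _stage("edge_tracking")
    frames = synth_mod.frame_points_in(dataset, intervals=selected.merged)
    trajectory = edge.track_edge(
        dataset.template,
        frames,
        n_iter=cfg.ransac_iters,
        inlier_tol=cfg.ransac_tol,
        seed=ransac_seed,
        inlier_floor=cfg.inlier_floor,
        accept_frac=cfg.accept_frac,
    )
    timings["edge_tracking"] = time.perf_counter() - t0

    # --- clustering, CV and central objects per window x session ----------
    t0 = _stage("gaze_clustering")
    cluster_rows, central_rows, cv_rows = [], [], []
    for session in sessions:
        streams = [s for s in dataset.gaze_streams if s.session == session]
        for wi, win in selected.windows.iterrows():
            span = (win["run_start_s"], win["run_end_s"])
            matrix = clustering.extract_window_matrix(
                streams, span, rate_hz=scfg.sample_rate_hz, window_id=wi
            )
            result = clustering.ward_cluster(matrix, cfg.k_clusters)
            cluster_rows.append(
                (
                    session, wi, win["start_s"], result.k,
                    result.within_class_pct, result.between_class_pct,
                    clustering.dissimilarity_summary(result),
                )
            )
            subj_centrals = clustering.subject_central_objects(
                matrix, result.assignments
            )
            for _, r in subj_centrals.iterrows():
                central_rows.append(
                    (
                        r["subject"], session, wi, int(r["cluster"]),
                        float(r["t_centroid"]), float(r["gaze_x"]),
                    )
                )
            for stream in streams:
                rec = clustering.gaze_cv(stream, span, window_id=wi)
                cv_rows.append((rec.subject, rec.session, rec.window_id, rec.cv))
    cluster_summary = pd.DataFrame(
        cluster_rows,
        columns=["session", "window", "start_s", "k", "within_pct",
                 "between_pct", "dissimilarity"],
    )
    centrals = pd.DataFrame(
        central_rows,
        columns=["subject", "session", "window", "cluster", "t_centroid", "gaze_x"],
    )
    cv_table = pd.DataFrame(
        cv_rows, columns=["subject", "session", "window", "gaze_cv"]
    )
    timings["gaze_clustering"] = time.perf_counter() - t0

    # --- edge-referenced spatial dispersion -------------------------------
    t0 = _stage("spatial_dispersion")
    distances = edge.centroid_distances(centrals, trajectory)
    dispersion = edge.spatial_dispersion(distances)
    gaze_params = cv_table.merge(
        dispersion[["subject", "session", "window", "mean_distance",
                    "edge_variability"]],
        on=["subject", "session", "window"],
        how="left",
    ).sort_values(["session", "window", "subject"], ignore_index=True)
    timings["spatial_dispersion"] = time.perf_counter() - t0

    # --- permutation + session means --------------------------------------
    t0 = _stage("session_means")
    _, session_means = shifts.permute_within_condition(
        gaze_params, rng=np.random.default_rng(perm_seed)
    )
    timings["session_means"] = time.perf_counter() - t0

    # --- performance: learning slopes, perceptuomotor table ---------------
    t0 = _stage("performance")
    slope_rows = []
    for subj, grp in dataset.performance.groupby("subject", sort=True):
        ls = shifts.learning_slope(
            grp["hours"].to_numpy(), grp["handaxe_score"].to_numpy(), subj
        )
        slope_rows.append((subj, ls.slope, ls.intercept, ls.n))
    slopes = pd.DataFrame(
        slope_rows, columns=["subject", "learning_slope", "intercept", "n_points"]
    )
    pm = (
        session_means.merge(
            dataset.performance[
                ["subject", "session", "handaxe_score", "percussion_error"]
            ],
            on=["subject", "session"],
        )
        .merge(slopes[["subject", "learning_slope"]], on="subject")
        .sort_values(["session", "subject"], ignore_index=True)
    )
    timings["performance"] = time.perf_counter() - t0

    # --- shift functions and effect sizes ---------------------------------
    t0 = _stage("shift_functions")
    boot_rng = np.random.default_rng(boot_seed)
    comparisons = []
    if len(sessions) >= 2:
        comparisons.append(("Shift1", sessions[0], sessions[1]))
    if len(sessions) >= 3:
        comparisons.append(("Shift2", sessions[1], sessions[2]))
    shift_rows, effect_rows = [], []
    by_session = {s: pm[pm["session"] == s] for s in sessions}
    for var in SHIFT_VARS:
        if var not in pm.columns:
            continue
        groups = [by_session[s][var].to_numpy() for s in sessions]
        es = shifts.eta_sq_epsilon_sq(groups)
        for name, s_a, s_b in comparisons:
            a = by_session[s_a][var].to_numpy()
            b = by_session[s_b][var].to_numpy()
            sf = shifts.shift_function(
                a, b, n_boot=cfg.n_boot, alpha=cfg.alpha, rng=boot_rng
            )
            for d in range(9):
                shift_rows.append(
                    (
                        name, var, (d + 1) / 10, sf.differences[d],
                        sf.ci_low[d], sf.ci_high[d], sf.p_values[d],
                        bool(sf.significant[d]),
                    )
                )
            effect_rows.append(
                (var, f"{s_b} vs {s_a}", shifts.hedges_g(b, a),
                 es.eta_squared, es.epsilon_squared)
            )
    shift_table = pd.DataFrame(
        shift_rows,
        columns=["comparison", "variable", "decile", "difference", "ci_low",
                 "ci_high", "p_adjusted", "significant"],
    )
    effect_table = pd.DataFrame(
        effect_rows,
        columns=["variable", "comparison", "hedges_g", "eta_squared",
                 "epsilon_squared"],
    )
    timings["shift_functions"] = time.perf_counter() - t0

    # --- canonical correlation per session --------------------------------
    t0 = _stage("cca")
    mode_frames = []
    for session in sessions:
        sub = by_session[session].set_index("subject")
        Xa = sub[list(cca_mod.PERFORMANCE_VARS)]
        Xb = sub[list(cca_mod.GAZE_VARS)]
        result = cca_mod.cca(Xa, Xb, session=session)
        mode_frames.append(cca_mod.mode_report(result))
    cca_table = pd.concat(mode_frames, ignore_index=True)
    cca_modes = (
        cca_table[["session", "mode", "S", "r_squared"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    timings["cca"] = time.perf_counter() - t0

    tables = {
        "salience_series": pd.concat(salience_rows, ignore_index=True),
        "selected_windows": selected.windows.assign(window=selected.windows.index),
        "cluster_summary": cluster_summary,
        "central_objects": centrals,
        "edge_trajectory": trajectory.frames,
        "edge_distances": distances,
        "gaze_params": gaze_params,
        "session_means": session_means,
        "perceptuomotor": pm,
        "shift_functions": shift_table,
        "effect_sizes": effect_table,
        "cca_modes": cca_modes,
        "cca_weights": cca_table,
    }
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "versions": {"gazeforge": _version, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "selection": {
            "threshold": selected.threshold,
            "percentile": selected.percentile,
            "n_windows": int(len(selected.windows)),
        },
        "rows": {name: int(len(df)) for name, df in tables.items()},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    return ResultsBundle(tables=tables, manifest=manifest)


_SCHEMAS = {
    "gaze": (
        ["subject", "session", "t_s", "x", "y", "valid"],
        {"x": (0.0, 1.0), "y": (0.0, 1.0)},
    ),
    "press": (["subject", "session", "latency_s"], {"latency_s": (0.0, None)}),
    "phase": (["second", "phase"], {}),
    "performance": (
        ["subject", "session", "hours", "handaxe_score", "percussion_error"],
        {"hours": (0.0, None)},
    ),
    "edge": (["frame", "t_s", "edge_x"], {"edge_x": (0.0, 1.0)}),
    "feature_points": (["frame", "point_id", "x", "y"], {}),
}


def validate_inputs(paths: dict[str, str]) -> dict:
    """Schema- and consistency-check a set of input CSVs.

    Never raises: returns a machine-readable report with entries of severity
    "error" (unusable), "warning" (suspicious) or "info".  Checks per file:
    required columns, value ranges, monotone timestamps; across files:
    subject/session agreement between gaze, press and performance tables.
    """
    report = {"entries": [], "n_errors": 0, "n_warnings": 0}

    def add(severity, file, message):
        report["entries"].append(
            {"severity": severity, "file": file, "message": message}
        )
        if severity == "error":
            report["n_errors"] += 1
        elif severity == "warning":
            report["n_warnings"] += 1

    frames = {}
    for kind, path in paths.items():
        if kind not in _SCHEMAS:
            add("info", kind, f"no schema registered for {kind!r}; skipped")
            continue
        cols, ranges = _SCHEMAS[kind]
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - report, never raise
            add("error", kind, f"unreadable CSV: {exc}")
            continue
        missing = [c for c in cols if c not in df.columns]
        if missing:
            add("error", kind, f"missing columns: {missing}")
            continue
        frames[kind] = df
        for col, (lo, hi) in ranges.items():
            v = df[col]
            if lo is not None and (v < lo).any():
                add("error", kind, f"{col} below {lo} "
                    f"({int((v < lo).sum())} rows)")
            if hi is not None and (v > hi).any():
                add("error", kind, f"{col} above {hi} "
                    f"({int((v > hi).sum())} rows)")
        if kind == "gaze":
            for (subj, sess), grp in df.groupby(["subject", "session"]):
                t = grp["t_s"].to_numpy()
                if len(t) > 1 and not np.all(np.diff(t) > 0):
                    add("error", kind,
                        f"timestamps not strictly increasing for "
                        f"subject {subj!r}, session {sess!r}")

    if "gaze" in frames and "press" in frames:
        gaze_subj = set(frames["gaze"]["subject"])
        press_subj = set(frames["press"]["subject"])
        for s in sorted(gaze_subj - press_subj):
            add("warning", "press", f"subject {s!r} present in gaze but has "
                "no press records")
        for s in sorted(press_subj - gaze_subj):
            add("warning", "gaze", f"subject {s!r} present in presses but has "
                "no gaze records")
    if "gaze" in frames and "performance" in frames:
        g = set(frames["gaze"]["subject"])
        p = set(frames["performance"]["subject"])
        for s in sorted(g ^ p):
            add("warning", "performance",
                f"subject {s!r} not shared between gaze and performance")
    return report
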