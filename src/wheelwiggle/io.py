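"""Session-bundle readers/writers and the end-to-end analysis pipeline.

A session is a directory of tab-delimited text tables:

    trials.tsv        trial_id, contrast_signed_pct, p_left, choice, correct,
                      rt_s, stim_on_s, go_cue_s, feedback_s, quiescence_s,
                      response_duration_s
    wheel/trial_<id>.tsv   t_s, pos_deg
    metrics.tsv       (written by the pipeline)
    spikes.tsv        t_s, cluster_id           (optional)
    pupil.tsv         t_s, diameter_au          (optional)
    groundtruth.tsv   (synthetic sessions only)
    config.txt        key=value parameters

Times are seconds, positions wheel degrees, contrast percent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, kinematics
from .kinematics import WheelTrace
from .synthetic import SyntheticSession, TaskConfig

__all__ = ["SessionBundle", "write_session", "read_session", "compute_session_metrics",
           "run_pipeline"]

logger = logging.getLogger("wheelwiggle")

SCHEMA_VERSION = "1"
FLOAT_FMT = "%.10g"

TRIALS_COLUMNS = [
    "trial_id", "contrast_signed_pct", "p_left", "choice", "correct", "rt_s",
    "stim_on_s", "go_cue_s", "feedback_s", "quiescence_s", "response_duration_s",
]


@dataclass
class SessionBundle:
    path: Path
    trials: pd.DataFrame
    wheel: dict[int, WheelTrace]
    spikes: pd.DataFrame | None
    pupil: pd.DataFrame | None
    ground_truth: pd.DataFrame | None
    config: dict


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_session(session: SyntheticSession, out_dir) -> Path:
    """Serialize a synthetic session to a bundle directory."""
    out = Path(out_dir)
    (out / "wheel").mkdir(parents=True, exist_ok=True)
    _write_tsv(session.trials, out / "trials.tsv")
    _write_tsv(session.ground_truth, out / "groundtruth.tsv")
    for tid, trace in session.wheel.items():
        _write_tsv(
            pd.DataFrame({"t_s": trace.t, "pos_deg": trace.pos}),
            out / "wheel" / f"trial_{tid}.tsv",
        )
    if session.spikes is not None:
        _write_tsv(session.spikes, out / "spikes.tsv")
    if session.pupil is not None:
        _write_tsv(session.pupil, out / "pupil.tsv")

    cfg = {"schema_version": SCHEMA_VERSION, "seed": session.spec.seed,
           "n_trials": session.spec.n_trials}
    for f in dataclasses.fields(TaskConfig):
        v = getattr(session.config, f.name)
        cfg[f.name] = ",".join(str(x) for x in v) if isinstance(v, tuple) else v
    with open(out / "config.txt", "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k}={v}\n")
    return out


def _read_config(path: Path) -> dict:
    cfg = {}
    if path.exists():
        for line in path.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                cfg[k.strip()] = v.strip()
    return cfg


def read_session(session_dir) -> SessionBundle:
    """Load and validate a session bundle.

    Checks the trials schema, strict monotonicity of wheel timestamps and
    event ordering (stim_on < feedback); raises descriptive errors naming
    the offending file/column.
    """
    d = Path(session_dir)
    if not d.is_dir():
        raise FileNotFoundError(f"session directory not found: {d}")
    trials_path = d / "trials.tsv"
    if not trials_path.exists():
        raise FileNotFoundError(f"missing trials.tsv in {d}")
    trials = pd.read_csv(trials_path, sep="\t")
    missing = set(TRIALS_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"{trials_path}: missing columns {sorted(missing)}")

    wheel: dict[int, WheelTrace] = {}
    for _, row in trials.iterrows():
        tid = int(row["trial_id"])
        wpath = d / "wheel" / f"trial_{tid}.tsv"
        if not wpath.exists():
            continue
        wdf = pd.read_csv(wpath, sep="\t")
        t = wdf["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{wpath}: non-monotone timestamps")
        wheel[tid] = WheelTrace(t, wdf["pos_deg"].to_numpy(dtype=float),
                                stim_on=float(row["stim_on_s"]),
                                feedback=float(row["feedback_s"]))

    spikes = pupil = ground_truth = None
    if (d / "spikes.tsv").exists():
        spikes = pd.read_csv(d / "spikes.tsv", sep="\t")
    if (d / "pupil.tsv").exists():
        pupil = pd.read_csv(d / "pupil.tsv", sep="\t")
    if (d / "groundtruth.tsv").exists():
        ground_truth = pd.read_csv(d / "groundtruth.tsv", sep="\t")
    return SessionBundle(path=d, trials=trials, wheel=wheel, spikes=spikes,
                         pupil=pupil, ground_truth=ground_truth,
                         config=_read_config(d / "config.txt"))


def compute_session_metrics(
    bundle: SessionBundle, rate: float = 1000.0, cutoff: float = 20.0
) -> pd.DataFrame:
    """Per-trial wiggle metrics for every trial with a wheel trace."""
    rows = []
    for tid in sorted(bundle.wheel):
        m = kinematics.compute_metrics(bundle.wheel[tid], rate=rate, cutoff=cutoff)
        rows.append(dict(trial_id=tid, k=m.k, is_wiggle=int(m.is_wiggle),
                         speed_deg_s=m.speed, amplitude_deg=m.amplitude,
                         duration_s=m.duration, motion_energy_deg2_s2=m.motion_energy))
    return pd.DataFrame(rows)


def _config_hash(config: dict) -> str:
    blob = "\n".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(session_dir, seed: int = 0, rate: float = 1000.0,
                 cutoff: float = 20.0) -> dict:
    """Run metrics -> behavior stats -> (optional pupil summaries) on a
    session bundle, writing stage outputs next to the inputs.

    Stages are logged with the seed and a config hash; decoding is left to
    the dedicated CLI because it needs cohort-level settings.
    """
    bundle = read_session(session_dir)
    logger.info("pipeline start: %s seed=%d config=%s", session_dir, seed,
                _config_hash(bundle.config))
    report: dict = {"session": str(session_dir), "seed": seed,
                    "config_hash": _config_hash(bundle.config)}

    metrics = compute_session_metrics(bundle, rate=rate, cutoff=cutoff)
    _write_tsv(metrics, bundle.path / "metrics.tsv")
    report["n_trials_with_traces"] = len(metrics)

    table = bundle.trials.merge(metrics, on="trial_id", how="inner")
    filtered, counts = behavior.filter_trials(table)
    report["filter"] = counts

    try:
        params = behavior.fit_psychometric(filtered)
        _write_tsv(pd.DataFrame([dataclasses.asdict(params)]),
                   bundle.path / "psychometric.tsv")
        report["psychometric"] = dataclasses.asdict(params)
    except ValueError as exc:
        report["psychometric"] = {"error": str(exc)}

    # session typing is defined on low-contrast (6.25%) trials only
    low = filtered[np.isclose(filtered["contrast_signed_pct"].abs(), 6.25)]
    try:
        result = behavior.k_regression(low)
        label = behavior.classify_session(result)
        _write_tsv(pd.DataFrame([{"slope": result.slope, "r2": result.r2,
                                  "pearson_r": result.pearson_r, "label": label}]),
                   bundle.path / "classification.tsv")
        report["classification"] = {"slope": result.slope, "r2": result.r2,
                                    "pearson_r": result.pearson_r, "label": label}
    except ValueError as exc:
        report["classification"] = {"error": str(exc)}

    if bundle.pupil is not None:
        from . import pupil as pupil_mod
        trace = pupil_mod.normalize_pupil(
            pupil_mod.PupilTrace(bundle.pupil["t_s"].to_numpy(),
                                 bundle.pupil["diameter_au"].to_numpy())
        )
        windows = pupil_mod.trial_pupil_windows(
            trace, bundle.trials["stim_on_s"].to_numpy())
        windows.insert(0, "trial_id", bundle.trials["trial_id"].to_numpy())
        _write_tsv(windows, bundle.path / "pupil_windows.tsv")
        report["pupil"] = {"n_trials": len(windows),
                           "n_missing": int(windows["baseline"].isna().sum())}
    else:
        report["pupil"] = "skipped (no pupil.tsv)"
    logger.info("pipeline done: %s", report)
    return report
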