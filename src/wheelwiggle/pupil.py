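"""Pupil-linked arousal analyses.

Pupil diameter (arbitrary units, e.g. vertical landmark distance) is
normalized within each session to the session maximum.  Per trial, a
baseline window [-0.5, 0) s and a post-stimulus window [0, 0.5) s around
stimulus onset are averaged.  Session-level weighted regressions relate
wiggle metrics to pupil diameter; the pupil-stratified analysis re-tests the
wiggle-speed/accuracy relationship within narrow pupil bins (0.05 a.u. steps
from 0.10 to 0.45) so that any accuracy benefit of wiggling is assessed at
matched arousal; mixed-effects models add mouse or session random
intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .behavior import octile_bin, N_OCTILES

__all__ = [
    "PupilTrace",
    "PUPIL_BIN_EDGES",
    "normalize_pupil",
    "trial_pupil_windows",
    "session_metric_regression",
    "pupil_stratified_accuracy",
    "mixed_accuracy_model",
    "pupil_by_session_type",
    "compare_session_type_distributions",
]

#: Post-stimulus normalized-pupil bins: 0.05 a.u. steps over [0.10, 0.45).
PUPIL_BIN_EDGES = np.round(np.arange(0.10, 0.451, 0.05), 10)

BASELINE_WINDOW = (-0.5, 0.0)
POST_WINDOW = (0.0, 0.5)


@dataclass
class PupilTrace:
    t: np.ndarray
    diameter: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if self.t.size != self.diameter.size:
            raise ValueError("t and diameter must match in length")
        if self.t.size and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.diameter)):
            raise ValueError("diameter must be finite")


def normalize_pupil(trace: PupilTrace) -> PupilTrace:
    """Divide the diameter by the session maximum; output lies in (0, 1] and
    the operation is idempotent."""
    m = trace.diameter.max() if trace.diameter.size else 0.0
    if m <= 0:
        raise ValueError("session maximum must be positive")
    return PupilTrace(trace.t, trace.diameter / m)


def trial_pupil_windows(trace: PupilTrace, stim_times: np.ndarray) -> pd.DataFrame:
    """Mean normalized diameter in [-0.5, 0) s (baseline) and [0, 0.5) s
    (post) around each stimulus onset; windows with no samples yield NaN."""
    stim_times = np.asarray(stim_times, dtype=float)
    out = {"baseline": [], "post": []}
    for st in stim_times:
        for key, (lo, hi) in (("baseline", BASELINE_WINDOW), ("post", POST_WINDOW)):
            m = (trace.t >= st + lo) & (trace.t < st + hi)
            out[key].append(float(trace.diameter[m].mean()) if m.any() else np.nan)
    return pd.DataFrame(out)


def session_metric_regression(
    metric_medians: np.ndarray,
    pupil_medians: np.ndarray,
    weights: np.ndarray,
) -> dict:
    """Weighted least squares of per-session median pupil diameter on a
    per-session median wiggle metric, weighted by wiggle-trial counts."""
    x = np.asarray(metric_medians, dtype=float)
    y = np.asarray(pupil_medians, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 sessions")
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "r2": float(fit.rsquared),
        "p_value": float(fit.pvalues[1]),
    }


def pupil_stratified_accuracy(
    table: pd.DataFrame,
    pupil_col: str = "pupil_post",
    speed_col: str = "speed_deg_s",
    min_per_bin: int = 3,
) -> dict:
    """Accuracy vs wiggle-speed octile within narrow post-stimulus pupil bins.

    Trials are assigned to half-open pupil bins [0.10, 0.15) ... [0.40,
    0.45); trials outside [0.10, 0.45) are excluded (count reported).  Within
    each populated bin, trials are split into speed octiles and an OLS of
    correctness on the octile index is fit at the trial level.
    """
    pupil = table[pupil_col].to_numpy(dtype=float)
    in_range = (pupil >= PUPIL_BIN_EDGES[0]) & (pupil < PUPIL_BIN_EDGES[-1])
    results = {"bins": [], "n_excluded": int((~in_range).sum())}
    sub_all = table.loc[in_range]
    which = np.digitize(sub_all[pupil_col].to_numpy(dtype=float), PUPIL_BIN_EDGES) - 1
    for b in range(PUPIL_BIN_EDGES.size - 1):
        sub = sub_all.loc[which == b]
        entry = {
            "lo": float(PUPIL_BIN_EDGES[b]),
            "hi": float(PUPIL_BIN_EDGES[b + 1]),
            "n": int(len(sub)),
            "skipped": False,
        }
        bin_index, excluded, _ = octile_bin(sub[speed_col].to_numpy(dtype=float),
                                            min_per_bin=min_per_bin)
        if bin_index is None or excluded:
            entry["skipped"] = True
            results["bins"].append(entry)
            continue
        correct = sub["correct"].to_numpy(dtype=float)
        acc = np.array([correct[bin_index == i].mean() if (bin_index == i).any() else np.nan
                        for i in range(N_OCTILES)])
        fit = sm.OLS(correct, sm.add_constant(bin_index.astype(float))).fit()
        entry.update(
            accuracy=acc,
            slope=float(fit.params[1]),
            r2=float(fit.rsquared),
            p_value=float(fit.pvalues[1]),
        )
        results["bins"].append(entry)
    return results


def mixed_accuracy_model(octile_table: pd.DataFrame) -> dict:
    """Linear mixed-effects model of octile-level accuracy on wiggle speed
    and pupil diameter with a per-mouse random intercept (REML).

    ``octile_table`` has one row per session per octile with columns
    accuracy, speed, pupil, mouse.  With a single mouse the random intercept
    is degenerate; the model falls back to OLS with a flag.
    """
    required = {"accuracy", "speed", "pupil", "mouse"}
    missing = required - set(octile_table.columns)
    if missing:
        raise KeyError(f"octile table missing columns: {sorted(missing)}")
    if octile_table["mouse"].nunique() < 2:
        fit = smf.ols("accuracy ~ speed + pupil", data=octile_table).fit()
        return {
            "beta_speed": float(fit.params["speed"]),
            "p_speed": float(fit.pvalues["speed"]),
            "beta_pupil": float(fit.params["pupil"]),
            "p_pupil": float(fit.pvalues["pupil"]),
            "degenerate_random_effect": True,
        }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("accuracy ~ speed + pupil", data=octile_table,
                            groups=octile_table["mouse"])
        fit = model.fit(reml=True)
    return {
        "beta_speed": float(fit.params["speed"]),
        "p_speed": float(fit.pvalues["speed"]),
        "beta_pupil": float(fit.params["pupil"]),
        "p_pupil": float(fit.pvalues["pupil"]),
        "degenerate_random_effect": False,
    }


def pupil_by_session_type(octile_table: pd.DataFrame) -> dict:
    """Per session type, mixed model of median pupil on median speed with a
    session random intercept.

    ``octile_table`` has one row per session per speed octile with columns
    speed, pupil, session, label (benefiting / neutral / non_benefiting).
    Types with fewer than 2 sessions are skipped with a flag.
    """
    out = {}
    for label, sub in octile_table.groupby("label"):
        if sub["session"].nunique() < 2:
            out[label] = {"skipped": True, "n_sessions": int(sub["session"].nunique())}
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm("pupil ~ speed", data=sub, groups=sub["session"]).fit(reml=True)
        out[label] = {
            "skipped": False,
            "n_sessions": int(sub["session"].nunique()),
            "slope": float(fit.params["speed"]),
            "p_value": float(fit.pvalues["speed"]),
        }
    return out


def compare_session_type_distributions(values_by_type: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis and one-way ANOVA across session-type groups (e.g.
    pupil diameters of benefiting vs neutral vs non-benefiting sessions)."""
    groups = [np.asarray(v, dtype=float) for v in values_by_type.values() if len(v)]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    kw = stats.kruskal(*groups)
    an = stats.f_oneway(*groups)
    return {
        "kruskal_h": float(kw.statistic),
        "kruskal_p": float(kw.pvalue),
        "anova_f": float(an.statistic),
        "anova_p": float(an.pvalue),
    }
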