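"""Trial filtering, psychometric fitting, and accuracy-vs-wiggle statistics.

The choice model is the standard erf psychometric function with lapses:

    P(rightward | c) = gamma + (1 - gamma - lambda) * 1/2 * [1 + erf((c - mu) / (sqrt(2) sigma))]

with c the signed contrast in percent (negative = left stimulus), gamma and
lambda the left/right lapse rates, mu the bias, and sigma the contrast
threshold.  Accuracy-vs-wiggle analyses bin trials into wiggle-speed octiles
or k-categories {0, 1, 2, 3, >=4} and regress proportion correct on the bin
index (trial-level logistic, or weighted linear with per-bin trial counts as
weights), from which mice and sessions are classified as benefiting from
wiggling or not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import erf, ndtri

__all__ = [
    "PsychometricParams",
    "BinnedAccuracy",
    "ClassificationResult",
    "FALSE_START_RT_S",
    "RT_WINDOW_S",
    "GO_CUE_TOLERANCE_S",
    "filter_trials",
    "classify_false_start",
    "predict_psychometric",
    "fit_psychometric",
    "octile_bin",
    "accuracy_vs_speed",
    "normalized_gain",
    "accuracy_glm",
    "k_regression",
    "classify_mouse",
    "classify_session",
    "wiggle_fraction_trend",
    "side_asymmetry",
    "dprime",
    "wilson_interval",
    "bonferroni_alpha",
]

FALSE_START_RT_S = 0.08
RT_WINDOW_S = (0.08, 1.20)
GO_CUE_TOLERANCE_S = 0.05
N_OCTILES = 8
K_BIN_MAX = 4  # k-categories 0, 1, 2, 3, >=4


@dataclass
class PsychometricParams:
    """Lapse rates, bias and threshold of the erf choice model."""

    gamma: float = 0.05
    lambda_: float = 0.05
    mu: float = 0.0
    sigma: float = 10.0

    def __post_init__(self) -> None:
        if not (0 <= self.gamma <= 0.5 and 0 <= self.lambda_ <= 0.5):
            raise ValueError("lapse rates must lie in [0, 0.5]")
        if self.gamma + self.lambda_ >= 1:
            raise ValueError("gamma + lambda must be < 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class BinnedAccuracy:
    bin_index: np.ndarray       # per-trial bin assignment
    n_per_bin: np.ndarray
    accuracy: np.ndarray        # proportion correct per bin
    excluded: bool              # True if any bin fails the min-per-bin rule
    degenerate: bool = False    # all values tied


@dataclass
class ClassificationResult:
    slope: float
    r2: float
    pearson_r: float
    intercept: float = float("nan")
    p_value: float = float("nan")


# ---------------------------------------------------------------------------
# trial filtering


def classify_false_start(rt: float) -> bool:
    """A false start is a response at or before 0.08 s, i.e. a movement not
    triggered by the visual stimulus."""
    return rt <= FALSE_START_RT_S


def filter_trials(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the behavioral inclusion criteria.

    Keeps trials with |go_cue - stim_on| <= 0.05 s and reaction time in
    [0.08, 1.20] s (bounds inclusive).  Returns the filtered table (order
    preserved) and a dict with kept/dropped counts.
    """
    required = {"rt_s", "stim_on_s", "go_cue_s"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"trial table missing columns: {sorted(missing)}")
    ok = (
        ((table["go_cue_s"] - table["stim_on_s"]).abs() <= GO_CUE_TOLERANCE_S)
        & (table["rt_s"] >= RT_WINDOW_S[0])
        & (table["rt_s"] <= RT_WINDOW_S[1])
    )
    kept = table.loc[ok]
    return kept, {"kept": int(ok.sum()), "dropped": int((~ok).sum())}


# ---------------------------------------------------------------------------
# psychometric model


def predict_psychometric(params: PsychometricParams, c) -> np.ndarray | float:
    """Probability of a rightward choice at signed contrast ``c`` (percent)."""
    c = np.asarray(c, dtype=float)
    z = (c - params.mu) / (np.sqrt(2.0) * params.sigma)
    p = params.gamma + (1.0 - params.gamma - params.lambda_) * 0.5 * (1.0 + erf(z))
    return p if p.ndim else float(p)


def _neg_log_likelihood(theta, contrasts, n_right, n_total):
    gamma, lam, mu, sigma = theta
    p = gamma + (1.0 - gamma - lam) * 0.5 * (
        1.0 + erf((contrasts - mu) / (np.sqrt(2.0) * sigma))
    )
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -np.sum(n_right * np.log(p) + (n_total - n_right) * np.log1p(-p))


def fit_psychometric(table: pd.DataFrame, choice_col: str = "choice") -> PsychometricParams:
    """Maximum-likelihood fit of the erf psychometric function.

    Trials are aggregated by unique signed contrast (the likelihood is a
    product of binomials), then optimized with bounded L-BFGS-B from a fixed
    grid of starting points; the best likelihood wins, so refitting the same
    data is deterministic.
    """
    contrasts = table["contrast_signed_pct"].to_numpy(dtype=float)
    right = (table[choice_col].to_numpy() > 0).astype(float)
    uniq, inv = np.unique(contrasts, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct contrasts to fit")
    n_total = np.bincount(inv).astype(float)
    n_right = np.bincount(inv, weights=right)

    bounds = [(0.0, 0.5), (0.0, 0.5), (-100.0, 100.0), (0.1, 200.0)]
    starts = [
        (0.02, 0.02, 0.0, 10.0),
        (0.1, 0.1, 0.0, 20.0),
        (0.05, 0.05, -10.0, 5.0),
        (0.05, 0.05, 10.0, 5.0),
        (0.2, 0.2, 0.0, 50.0),
        (0.01, 0.01, 0.0, 2.0),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _neg_log_likelihood,
            x0,
            args=(uniq, n_right, n_total),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    gamma, lam, mu, sigma = best.x
    return PsychometricParams(gamma=gamma, lambda_=lam, mu=mu, sigma=sigma)


# ---------------------------------------------------------------------------
# binning and accuracy regressions


def octile_bin(values, min_per_bin: int = 3, n_bins: int = N_OCTILES):
    """Assign values to equal-count quantile bins (ties broken by stable sort).

    Returns ``(bin_index, excluded, degenerate)``: per-value bin assignments,
    whether any bin falls below ``min_per_bin`` (the session-exclusion rule),
    and whether all values are identical (degenerate binning).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < n_bins:
        return None, True, False
    order = np.argsort(values, kind="stable")
    bin_index = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_index[chunk] = b
    counts = np.bincount(bin_index, minlength=n_bins)
    excluded = bool((counts < min_per_bin).any())
    degenerate = bool(np.all(values == values[0]))
    return bin_index, excluded, degenerate


def _binned_accuracy(bin_index: np.ndarray, correct: np.ndarray, n_bins: int) -> BinnedAccuracy:
    n_per = np.bincount(bin_index, minlength=n_bins).astype(float)
    hits = np.bincount(bin_index, weights=correct, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        acc = np.where(n_per > 0, hits / np.maximum(n_per, 1), np.nan)
    return BinnedAccuracy(bin_index=bin_index, n_per_bin=n_per, accuracy=acc, excluded=False)


def accuracy_vs_speed(
    table: pd.DataFrame,
    speed_col: str = "speed_deg_s",
    min_per_bin: int = 3,
) -> dict:
    """Octile-binned accuracy versus wiggle speed with a trial-level logistic
    regression of correctness on the octile index (0-7).

    Returns a dict with beta, its SE, per-octile accuracies/counts and flags
    (session exclusion, complete separation).
    """
    speeds = table[speed_col].to_numpy(dtype=float)
    correct = table["correct"].to_numpy(dtype=float)
    bin_index, excluded, degenerate = octile_bin(speeds, min_per_bin=min_per_bin)
    if bin_index is None:
        return {"excluded": True, "separation": False, "beta": np.nan, "se": np.nan,
                "accuracy": None, "n_per_bin": None, "degenerate": degenerate}
    binned = _binned_accuracy(bin_index, correct, N_OCTILES)
    out = {
        "excluded": excluded,
        "degenerate": degenerate,
        "accuracy": binned.accuracy,
        "n_per_bin": binned.n_per_bin,
        "separation": False,
        "beta": np.nan,
        "se": np.nan,
    }
    if correct.min() == correct.max():
        out["separation"] = True
        return out
    X = sm.add_constant(bin_index.astype(float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(correct, X).fit(disp=0)
        out["beta"] = float(fit.params[1])
        out["se"] = float(fit.bse[1])
        out["p_value"] = float(fit.pvalues[1])
    except Exception:  # perfect separation or singular design
        out["separation"] = True
    return out


def normalized_gain(accuracy: np.ndarray) -> np.ndarray:
    """Relative accuracy gain of each bin over the lowest-speed bin:
    (acc_i - acc_0) / acc_0.  Undefined (all-NaN) when the baseline is 0."""
    accuracy = np.asarray(accuracy, dtype=float)
    if accuracy.size < 2:
        raise ValueError("need at least 2 bins")
    if accuracy[0] == 0:
        return np.full(accuracy.size - 1, np.nan)
    return (accuracy[1:] - accuracy[0]) / accuracy[0]


def accuracy_glm(table: pd.DataFrame) -> dict:
    """Trial-level logistic regression of correctness on k and response
    duration jointly; returns coefficients, SEs and z statistics, with a
    collinearity warning flag based on the design condition number."""
    k = table["k"].to_numpy(dtype=float)
    dur = table["response_duration_s"].to_numpy(dtype=float)
    correct = table["correct"].to_numpy(dtype=float)
    if np.ptp(k) == 0 or np.ptp(dur) == 0:
        raise ValueError("both predictors must vary")
    X = sm.add_constant(np.column_stack([k, dur]))
    cond = np.linalg.cond((X - X.mean(0)) / np.maximum(X.std(0), 1e-12))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(correct, X).fit(disp=0)
    return {
        "beta_k": float(fit.params[1]),
        "se_k": float(fit.bse[1]),
        "z_k": float(fit.tvalues[1]),
        "beta_dur": float(fit.params[2]),
        "se_dur": float(fit.bse[2]),
        "z_dur": float(fit.tvalues[2]),
        "collinear": bool(cond > 1e6),
    }


def _weighted_pearson(x, y, w):
    w = w / np.sum(w)
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def k_regression(table: pd.DataFrame, k_col: str = "k") -> ClassificationResult:
    """Weighted linear regression of proportion correct on the k-category
    index (0, 1, 2, 3, >=4), weighted by the number of trials per category.

    Returns slope, weighted R-squared and weighted Pearson r.
    """
    kbin = np.minimum(table[k_col].to_numpy(dtype=int), K_BIN_MAX)
    correct = table["correct"].to_numpy(dtype=float)
    cats = np.unique(kbin)
    if cats.size < 2:
        raise ValueError("need at least 2 populated k-categories")
    props = np.array([correct[kbin == c].mean() for c in cats])
    n = np.array([(kbin == c).sum() for c in cats], dtype=float)
    X = sm.add_constant(cats.astype(float))
    fit = sm.WLS(props, X, weights=n).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(fit.rsquared)  # -inf/nan when accuracies are exactly flat
    return ClassificationResult(
        slope=float(fit.params[1]),
        r2=r2 if np.isfinite(r2) else 0.0,
        pearson_r=_weighted_pearson(cats.astype(float), props, n),
        intercept=float(fit.params[0]),
        p_value=float(fit.pvalues[1]) if cats.size > 2 else float("nan"),
    )


def classify_mouse(result: ClassificationResult) -> tuple[str, bool]:
    """Label a mouse from its k-accuracy regression.

    positive/negative slope with R^2 >= 0.1, else unclassified; the second
    element flags a strong fit (R^2 >= 0.7).
    """
    strong = result.r2 >= 0.7
    if result.r2 >= 0.1 and result.slope > 0:
        return "positive", strong
    if result.r2 >= 0.1 and result.slope < 0:
        return "negative", strong
    return "unclassified", strong


def classify_session(result: ClassificationResult) -> str:
    """benefiting if weighted Pearson r > 0.3; non_benefiting if r < -0.3;
    otherwise neutral."""
    if result.pearson_r > 0.3:
        return "benefiting"
    if result.pearson_r < -0.3:
        return "non_benefiting"
    return "neutral"


def wiggle_fraction_trend(
    table: pd.DataFrame, bin_width_s: float = 500.0
) -> dict:
    """Fraction of wiggle trials in consecutive session-time bins plus the
    OLS slope of that fraction against bin midpoint time."""
    t = table["stim_on_s"].to_numpy(dtype=float)
    wig = table["is_wiggle"].to_numpy(dtype=float)
    edges = np.arange(t.min(), t.max() + bin_width_s, bin_width_s)
    if edges.size < 3:
        raise ValueError("session too short for a trend (need >= 2 time bins)")
    which = np.clip(np.digitize(t, edges) - 1, 0, edges.size - 2)
    mids, fracs, ns = [], [], []
    n_empty = 0
    for b in range(edges.size - 1):
        m = which == b
        if not m.any():
            n_empty += 1
            continue
        mids.append(0.5 * (edges[b] + edges[b + 1]))
        fracs.append(wig[m].mean())
        ns.append(int(m.sum()))
    mids, fracs = np.asarray(mids), np.asarray(fracs)
    if mids.size < 2:
        raise ValueError("fewer than 2 populated time bins")
    fit = sm.OLS(fracs, sm.add_constant(mids)).fit()
    return {
        "bin_mid_s": mids,
        "fraction": fracs,
        "n_per_bin": np.asarray(ns),
        "slope": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "p_value": float(fit.pvalues[1]),
        "n_empty_bins": n_empty,
    }


def side_asymmetry(
    table: pd.DataFrame,
    mouse_col: str = "mouse",
    low_contrast_pct: float = 6.25,
) -> dict:
    """Fraction of wiggles directed toward each mouse's non-preferred side.

    Preferred side = the side (by choice direction) with higher accuracy on
    low-contrast trials.  Returns per-mouse fractions, their median, and a
    one-sample Wilcoxon test of the fractions against 0.5.
    """
    fractions = {}
    for mouse, sub in table.groupby(mouse_col):
        low = sub[np.isclose(np.abs(sub["contrast_signed_pct"]), low_contrast_pct)]
        left = low[low["contrast_signed_pct"] < 0]
        right = low[low["contrast_signed_pct"] > 0]
        if not len(left) or not len(right):
            continue
        preferred = +1 if right["correct"].mean() >= left["correct"].mean() else -1
        wig = sub[sub["is_wiggle"].astype(bool)]
        if not len(wig):
            continue
        toward_nonpref = (np.sign(wig["choice"]) == -preferred).mean()
        fractions[mouse] = float(toward_nonpref)
    vals = np.array(list(fractions.values()))
    if vals.size == 0:
        raise ValueError("no mouse has wiggles and both stimulus sides")
    if np.allclose(vals, 0.5):
        p = 1.0
    else:
        p = float(stats.wilcoxon(vals - 0.5).pvalue)
    return {"per_mouse": fractions, "median": float(np.median(vals)), "wilcoxon_p": p}


# ---------------------------------------------------------------------------
# signal detection and small utilities


def dprime(hit_rate: float, fa_rate: float, n_signal: int, n_noise: int) -> float:
    """Signal-detection sensitivity d' = z(hit) - z(FA), with rates clipped
    to [1/(2n), 1 - 1/(2n)] for their respective trial counts so extreme
    proportions stay invertible."""
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("trial counts must be positive")
    if not (0 <= hit_rate <= 1 and 0 <= fa_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    hit = np.clip(hit_rate, 1.0 / (2 * n_signal), 1.0 - 1.0 / (2 * n_signal))
    fa = np.clip(fa_rate, 1.0 / (2 * n_noise), 1.0 - 1.0 / (2 * n_noise))
    return float(ndtri(hit) - ndtri(fa))


def wilson_interval(n_success: int, n_total: int, alpha: float = 0.05):
    """Wilson score confidence interval for a binomial proportion."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    z = ndtri(1 - alpha / 2)
    p = n_success / n_total
    denom = 1 + z**2 / n_total
    center = (p + z**2 / (2 * n_total)) / denom
    half = z * np.sqrt(p * (1 - p) / n_total + z**2 / (4 * n_total**2)) / denom
    return float(center - half), float(center + half)


def bonferroni_alpha(alpha: float = 0.05, n_comparisons: int = 3) -> float:
    """Bonferroni-corrected per-comparison significance level."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return alpha / n_comparisons
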