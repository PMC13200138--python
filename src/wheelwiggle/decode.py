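"""Stimulus-side decoding from spike counts and wiggle firing-rate modulation.

Spikes are binned at 20 ms, flattened per trial to a (neurons x bins) row
vector, and fed to an L2-regularized logistic regression trained to predict
the visual stimulus side (left vs right).  Decoding is repeated over
stratified train/test splits; comparing post-stimulus windows of 0.2 s and
1.0 s asks whether longer wiggle epochs carry more side information.  The
modulation analysis compares smoothed, baseline-normalized firing rates on
wiggle trials against their nearest non-wiggle trials (paired one-sided
Wilcoxon, gated by Cohen's d >= 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit

__all__ = [
    "SpikeTensor",
    "DecoderResult",
    "ModulationResult",
    "bin_spikes",
    "flatten_trials",
    "unflatten_trials",
    "decode_stimulus_side",
    "compare_windows",
    "smooth_normalize_rates",
    "match_nonwiggle_trials",
    "wiggle_modulated_fraction",
    "insertion_passes_qc",
]

MIN_WIGGLE_TRIALS = 20  # session-inclusion floor for decoding


@dataclass
class SpikeTensor:
    """Spike counts with shape (neurons, time bins, trials)."""

    counts: np.ndarray
    bin_width: float
    window: tuple[float, float]
    neuron_ids: np.ndarray
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be neurons x bins x trials")
        expected = int(round((self.window[1] - self.window[0]) / self.bin_width))
        if self.counts.shape[1] != expected:
            raise ValueError(
                f"{self.counts.shape[1]} bins inconsistent with window/bin_width "
                f"(expected {expected})"
            )


@dataclass
class DecoderResult:
    accuracies: np.ndarray
    mean: float
    sem: float
    window_label: str


@dataclass
class ModulationResult:
    p_values: np.ndarray
    effect_sizes: np.ndarray
    significant: np.ndarray
    fraction_significant: float


def bin_spikes(
    spikes: pd.DataFrame,
    stim_times: np.ndarray,
    window: tuple[float, float],
    bin_width: float = 0.02,
    neuron_ids: np.ndarray | None = None,
) -> SpikeTensor:
    """Bin a (t_s, cluster_id) event list around each stimulus onset.

    Bins are half-open [start + j*bin, start + (j+1)*bin); a spike exactly on
    an interior edge lands in the right-hand bin.  Unsorted events are sorted
    internally.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not window[0] < window[1]:
        raise ValueError("window must be well-ordered")
    t = spikes["t_s"].to_numpy(dtype=float)
    cl = spikes["cluster_id"].to_numpy(dtype=int)
    if t.size and np.any(np.diff(t) < 0):
        warnings.warn("spike times unsorted; sorting internally", stacklevel=2)
        order = np.argsort(t, kind="stable")
        t, cl = t[order], cl[order]
    if neuron_ids is None:
        neuron_ids = np.unique(cl) if cl.size else np.array([], dtype=int)
    neuron_ids = np.asarray(neuron_ids)
    stim_times = np.asarray(stim_times, dtype=float)
    T = int(round((window[1] - window[0]) / bin_width))
    N, K = neuron_ids.size, stim_times.size
    counts = np.zeros((N, T, K), dtype=int)
    nrn_index = {int(nid): i for i, nid in enumerate(neuron_ids)}
    for k, st in enumerate(stim_times):
        lo = np.searchsorted(t, st + window[0], side="left")
        hi = np.searchsorted(t, st + window[1], side="left")
        rel = t[lo:hi] - (st + window[0])
        bins = np.minimum((rel / bin_width).astype(int), T - 1)
        for b, c in zip(bins, cl[lo:hi]):
            i = nrn_index.get(int(c))
            if i is not None:
                counts[i, b, k] += 1
    return SpikeTensor(counts, bin_width, window, neuron_ids, np.arange(K))


def flatten_trials(tensor: SpikeTensor) -> np.ndarray:
    """K x (N*T) design matrix: row i is trial i's counts, neuron-major then
    time (so columns 0..T-1 are neuron 0's bins)."""
    N, T, K = tensor.counts.shape
    return tensor.counts.transpose(2, 0, 1).reshape(K, N * T).astype(float)


def unflatten_trials(matrix: np.ndarray, n_neurons: int, n_bins: int) -> np.ndarray:
    """Inverse of :func:`flatten_trials`: back to (N, T, K)."""
    K = matrix.shape[0]
    return matrix.reshape(K, n_neurons, n_bins).transpose(1, 2, 0)


def decode_stimulus_side(
    matrix: np.ndarray,
    labels: np.ndarray,
    n_repeats: int = 100,
    test_fraction: float = 0.2,
    seed: int = 0,
    window_label: str = "",
) -> DecoderResult:
    """Repeated stratified-split logistic decoding of stimulus side.

    Each repeat draws a class-ratio-preserving train/test split, fits an
    L2-regularized (C = 1) logistic regression, and scores test accuracy.
    Deterministic given the seed.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two classes to decode")
    if labels.size < MIN_WIGGLE_TRIALS:
        raise ValueError(f"need >= {MIN_WIGGLE_TRIALS} trials to decode")
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_fraction, random_state=seed
    )
    accs = np.empty(n_repeats)
    for r, (tr, te) in enumerate(splitter.split(matrix, labels)):
        clf = LogisticRegression(C=1.0, max_iter=500)  # default L2 penalty
        clf.fit(matrix[tr], labels[tr])
        accs[r] = clf.score(matrix[te], labels[te])
    return DecoderResult(
        accuracies=accs,
        mean=float(accs.mean()),
        sem=float(accs.std(ddof=1) / np.sqrt(n_repeats)) if n_repeats > 1 else 0.0,
        window_label=window_label,
    )


def compare_windows(
    spikes: pd.DataFrame,
    stim_times: np.ndarray,
    labels: np.ndarray,
    short: float = 0.2,
    long: float = 1.0,
    n_repeats: int = 100,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> dict:
    """Decode stimulus side from short [0, 0.2] s and long [0, 1.0] s
    post-stimulus windows with identical repeats and seeds; returns both
    results plus a paired Wilcoxon across repeats."""
    out = {}
    for label, end in (("short", short), ("long", long)):
        tensor = bin_spikes(spikes, stim_times, window=(0.0, end))
        out[label] = decode_stimulus_side(
            flatten_trials(tensor), labels, n_repeats=n_repeats,
            test_fraction=test_fraction, seed=seed, window_label=label,
        )
    diff = out["long"].accuracies - out["short"].accuracies
    if np.allclose(diff, 0):
        out["wilcoxon_p"] = 1.0
    else:
        out["wilcoxon_p"] = float(stats.wilcoxon(diff).pvalue)
    return out


def smooth_normalize_rates(
    tensor: SpikeTensor,
    baseline_window: tuple[float, float] = (-0.5, 0.0),
    sigma_bins: float = 3.0,
) -> np.ndarray:
    """Counts -> rates (/bin width), Gaussian-smoothed along time (sigma = 3
    bins), then divided per neuron per trial by (mean baseline rate + 1
    spike/s).  The tensor's window must cover the baseline window."""
    start, end = tensor.window
    if baseline_window[0] < start - 1e-9 or baseline_window[1] > end + 1e-9:
        raise ValueError("tensor window does not cover the baseline window")
    rates = tensor.counts / tensor.bin_width
    smoothed = gaussian_filter1d(rates.astype(float), sigma=sigma_bins, axis=1, mode="nearest")
    edges = start + np.arange(tensor.counts.shape[1]) * tensor.bin_width
    base_mask = (edges >= baseline_window[0]) & (edges < baseline_window[1])
    baseline = rates[:, base_mask, :].mean(axis=1)  # N x K, unsmoothed baseline
    return smoothed / (baseline[:, None, :] + 1.0)


def match_nonwiggle_trials(
    wiggle_times: np.ndarray, nonwiggle_times: np.ndarray
) -> np.ndarray:
    """For each wiggle trial, the index of the non-wiggle trial closest in
    session time (with replacement; ties go to the earlier trial)."""
    nonwiggle_times = np.asarray(nonwiggle_times, dtype=float)
    if nonwiggle_times.size == 0:
        raise ValueError("no non-wiggle trials to match against")
    wiggle_times = np.asarray(wiggle_times, dtype=float)
    order = np.argsort(nonwiggle_times, kind="stable")
    sorted_times = nonwiggle_times[order]
    pos = np.searchsorted(sorted_times, wiggle_times)
    pairs = np.empty(wiggle_times.size, dtype=int)
    for i, (w, p) in enumerate(zip(wiggle_times, pos)):
        lo = max(p - 1, 0)
        hi = min(p, sorted_times.size - 1)
        # earlier candidate wins ties strictly (<=)
        pairs[i] = order[lo] if abs(sorted_times[lo] - w) <= abs(sorted_times[hi] - w) else order[hi]
    return pairs


def wiggle_modulated_fraction(
    wiggle_rates: np.ndarray,
    matched_rates: np.ndarray,
    window_mask: np.ndarray | None = None,
    alpha: float = 0.05,
    d_threshold: float = 0.8,
    min_pairs: int = 5,
) -> ModulationResult:
    """Per-neuron test for higher normalized firing on wiggle trials.

    Inputs are normalized rate tensors (N x T x pairs) for wiggle trials and
    their matched non-wiggle trials.  Each neuron gets a one-sided paired
    Wilcoxon on the window-mean rate plus a paired Cohen's d (mean of the
    differences over their SD); significance requires p <= alpha and
    d >= d_threshold.
    """
    if wiggle_rates.shape != matched_rates.shape:
        raise ValueError("rate tensors must have identical shapes")
    N, T, P = wiggle_rates.shape
    if P < min_pairs:
        raise ValueError(f"need >= {min_pairs} matched pairs")
    if window_mask is None:
        window_mask = np.ones(T, dtype=bool)
    wm = wiggle_rates[:, window_mask, :].mean(axis=1)   # N x P
    nm = matched_rates[:, window_mask, :].mean(axis=1)
    p_values = np.ones(N)
    d_values = np.zeros(N)
    for n in range(N):
        diff = wm[n] - nm[n]
        sd = diff.std(ddof=1)
        d_values[n] = diff.mean() / sd if sd > 0 else 0.0
        if np.allclose(diff, 0):
            continue
        p_values[n] = stats.wilcoxon(diff, alternative="greater").pvalue
    significant = (p_values <= alpha) & (d_values >= d_threshold)
    return ModulationResult(
        p_values=p_values,
        effect_sizes=d_values,
        significant=significant,
        fraction_significant=float(significant.mean()),
    )


def insertion_passes_qc(drift_um: float, n_units: int) -> bool:
    """Electrode-insertion inclusion rule: at most 80 um of drift and at
    least 10 sorted units."""
    return drift_um <= 80.0 and n_units >= 10
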