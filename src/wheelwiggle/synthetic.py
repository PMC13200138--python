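"""Synthetic sessions of the biased-block 2AFC wheel task with known ground truth.

The generator emulates the statistical structure of the task so every
downstream analysis stage can be tested without external data:

* block structure — 90 unbiased trials (p_left = 0.5) followed by strictly
  alternating 80:20 / 20:80 blocks of 20-100 trials;
* quiescence — 0.2 s plus an exponential component (scale 0.35 s) rejection-
  sampled onto [0.20, 0.50] s, so totals lie in [0.40, 0.70] s;
* choices — drawn from the erf psychometric model, with the block prior
  entering as an additive shift of the bias mu;
* wheel trajectories — piecewise half-cosine segments between alternating
  extrema, so the smooth velocity changes sign exactly ``k_true`` times;
  optional measurement noise is band-limited and velocity-gated so the
  20 Hz-filtered sign-change count is preserved;
* reaction times — a bimodal mixture of false starts (rt <= 0.08 s) and
  stimulus-triggered responses (median ~0.16 s);
* spikes — Poisson counts in 20 ms bins with a subset of neurons whose rate
  is multiplied by (1 + coding_strength) on their preferred stimulus side;
* pupil — a slow (sub-1 Hz) positive diameter series, optionally coupled
  linearly to per-trial wiggle speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .behavior import PsychometricParams, predict_psychometric
from .decode import SpikeTensor
from .kinematics import WheelTrace

__all__ = [
    "TaskConfig",
    "SessionSpec",
    "SyntheticSession",
    "DEFAULT_WIGGLE_POLICY",
    "generate_block_sequence",
    "sample_quiescence_duration",
    "generate_wheel_trace",
    "generate_choice",
    "generate_spike_tensor",
    "generate_pupil_trace",
    "generate_session",
    "generate_k_accuracy_table",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class TaskConfig:
    """Fixed task parameters (units in field names or docstring)."""

    visuomotor_gain: float = 4.0              # visual deg per mm
    wheel_deg_per_35_visual_deg: float = 17.2  # wheel deg equal to 35 visual deg
    spatial_frequency: float = 0.10            # cycles per visual degree
    stim_azimuth: float = 35.0                 # visual deg (stimulus appears at +/-)
    contrast_set: tuple = (0.0, 6.25, 12.5, 25.0, 100.0)  # percent
    false_start_threshold: float = 0.08        # s
    rt_window: tuple = (0.08, 1.20)            # s
    quiescence_base: float = 0.2               # s
    quiescence_exp_mean: float = 0.35          # s (exponential scale)
    quiescence_exp_range: tuple = (0.20, 0.50)  # s (accepted support)
    reversed_contingency: bool = False
    open_loop: bool = False

    def __post_init__(self) -> None:
        if self.visuomotor_gain <= 0 or self.spatial_frequency <= 0:
            raise ValueError("gain and spatial frequency must be positive")
        if self.rt_window[0] != self.false_start_threshold:
            raise ValueError("rt window must start at the false-start threshold")
        if any(not 0 <= c <= 100 for c in self.contrast_set):
            raise ValueError("contrasts must lie in [0, 100] percent")


#: Per-contrast wiggle statistics: probability of a wiggle trial, extremum
#: excursion scale (wheel deg), and per-segment duration scale (s).  Both the
#: occurrence and the size of wiggles shrink as contrast rises, mirroring the
#: dependence of the behavior on stimulus strength.
DEFAULT_WIGGLE_POLICY: dict[float, dict] = {
    0.0:   {"p_wiggle": 0.55, "amp_scale": 4.5, "seg_dur": 0.16},
    6.25:  {"p_wiggle": 0.50, "amp_scale": 4.0, "seg_dur": 0.15},
    12.5:  {"p_wiggle": 0.40, "amp_scale": 3.5, "seg_dur": 0.13},
    25.0:  {"p_wiggle": 0.30, "amp_scale": 3.0, "seg_dur": 0.12},
    100.0: {"p_wiggle": 0.18, "amp_scale": 2.2, "seg_dur": 0.10},
}


@dataclass
class SessionSpec:
    """Everything needed to reproduce one synthetic session."""

    n_trials: int
    seed: int
    n_neurons: int | None = None
    coding_strength: float = 0.0
    pupil_coupling: float | None = None
    wiggle_policy: dict | None = None
    psychometric: PsychometricParams = field(default_factory=PsychometricParams)
    bias_shift_pct: float = 8.0   # additive shift of mu per full block prior swing
    p_false_start: float = 0.05
    make_traces: bool = True
    noise_frac: float = 0.01      # trace noise as a fraction of the excursion
    k_geometric_p: float = 0.45   # wiggle k drawn 1 + Geometric(p), capped at 8

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 <= self.p_false_start <= 1:
            raise ValueError("p_false_start must be a probability")
        if self.coding_strength < -1:
            raise ValueError("coding_strength must be >= -1")


@dataclass
class SyntheticSession:
    trials: pd.DataFrame
    ground_truth: pd.DataFrame
    wheel: dict[int, WheelTrace]
    spikes: pd.DataFrame | None
    pupil: pd.DataFrame | None
    spec: SessionSpec
    config: TaskConfig


# ---------------------------------------------------------------------------
# task-structure samplers


def generate_block_sequence(n_trials: int, seed) -> np.ndarray:
    """Per-trial p(left stimulus): 90 unbiased trials then alternating biased
    blocks with p_left in {0.8, 0.2} and lengths uniform on [20, 100]."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _rng(seed)
    p = [0.5] * min(90, n_trials)
    p_left = 0.8 if rng.random() < 0.5 else 0.2
    while len(p) < n_trials:
        length = int(rng.integers(20, 101))
        p.extend([p_left] * length)
        p_left = round(1.0 - p_left, 10)
    return np.asarray(p[:n_trials])


def sample_quiescence_duration(
    n: int, seed, config: TaskConfig | None = None
) -> np.ndarray:
    """Total quiescence durations: 0.2 s base plus an exponential component
    (scale 0.35 s) rejection-sampled onto [0.20, 0.50] s; totals therefore lie
    in [0.40, 0.70] s."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config or TaskConfig()
    rng = _rng(seed)
    lo, hi = cfg.quiescence_exp_range
    out = np.empty(0)
    while out.size < n:
        x = rng.exponential(cfg.quiescence_exp_mean, size=max(4 * n, 64))
        out = np.concatenate([out, x[(x >= lo) & (x <= hi)]])
    return cfg.quiescence_base + out[:n]


def _reaction_times(n: int, p_false_start: float, rng: np.random.Generator) -> np.ndarray:
    """Bimodal RTs: false starts uniform on [-0.20, 0.08] s, otherwise
    0.08 s + lognormal with median 0.08 s (overall median ~0.16 s)."""
    fs = rng.random(n) < p_false_start
    rt = 0.08 + rng.lognormal(mean=np.log(0.08), sigma=0.8, size=n)
    rt[fs] = rng.uniform(-0.20, 0.08, size=int(fs.sum()))
    return np.minimum(rt, 59.0)


# ---------------------------------------------------------------------------
# wheel trajectories


def _waypoints(k: int, displacement: float, amplitude: float) -> np.ndarray:
    """Extremum sequence 0 -> ... -> displacement with exactly k interior
    direction reversals; requires amplitude > |displacement| / (k + 1)."""
    D = abs(displacement)
    if k == 0:
        w = np.array([0.0, D])
    else:
        if amplitude <= D / (k + 1):
            raise ValueError(
                f"amplitude {amplitude:.3f} too small for k={k} reversals over "
                f"displacement {D:.3f}; need > {D / (k + 1):.3f}"
            )
        c = D * np.arange(1, k + 1) / (k + 1)
        w = np.concatenate(
            [[0.0], c + np.where(np.arange(1, k + 1) % 2 == 1, amplitude, -amplitude), [D]]
        )
    return w * np.sign(displacement) if displacement < 0 else w


def generate_wheel_trace(
    k_true: int,
    choice: int,
    stim_on: float,
    rt: float,
    move_duration: float,
    *,
    amplitude_deg: float | None = None,
    config: TaskConfig | None = None,
    seed=None,
    rate: float = 1000.0,
    noise_frac: float = 0.01,
    max_speed_deg_s: float = 3000.0,
) -> WheelTrace:
    """Simulate one trial's wheel position.

    The trace is flat until motion onset (``stim_on + rt``), then follows
    piecewise half-cosine segments through ``k_true`` alternating extrema,
    ending at the reward displacement (+/-17.2 wheel deg, sign set by
    ``choice``: +1 counterclockwise/rightward report).  Velocity is zero at
    segment boundaries and changes sign exactly at the interior extrema.
    Optional noise is 40 Hz-low-passed white noise scaled to ``noise_frac``
    of the excursion and gated by the local speed, so it cannot flip the
    filtered velocity where it matters.
    """
    cfg = config or TaskConfig()
    if k_true < 0:
        raise ValueError("k_true must be >= 0")
    if move_duration <= 0:
        raise ValueError("move_duration must be positive")
    D = float(choice) / abs(choice) * cfg.wheel_deg_per_35_visual_deg
    amp = amplitude_deg
    if amp is None:
        amp = max(3.0, 1.2 * abs(D) / (k_true + 1))
    if k_true > 0 and amp <= 0:
        raise ValueError("amplitude must be positive for wiggle trials")
    w = _waypoints(k_true, D, amp)

    n_seg = k_true + 1
    seg_dur = move_duration / n_seg
    peak_speed = np.pi * np.max(np.abs(np.diff(w))) / (2.0 * seg_dur)
    if peak_speed > max_speed_deg_s:
        raise ValueError(
            f"duration {move_duration:.3f}s too short for k={k_true} at bounded speed"
        )

    onset = stim_on + rt
    feedback = onset + move_duration
    t_start = min(stim_on, onset) - 0.1
    n = int(np.floor((feedback - t_start) * rate)) + 1
    t = t_start + np.arange(n) / rate
    if t[-1] < feedback - 1e-9:  # include the feedback endpoint exactly
        t = np.append(t, feedback)
        n += 1

    pos = np.zeros(n)
    vel = np.zeros(n)
    moving = t >= onset
    tm = t[moving] - onset
    seg = np.minimum((tm / seg_dur).astype(int), n_seg - 1)
    u = tm / seg_dur - seg
    dw = np.diff(w)
    pos[moving] = w[seg] + dw[seg] * 0.5 * (1.0 - np.cos(np.pi * u))
    vel[moving] = dw[seg] * np.pi / (2.0 * seg_dur) * np.sin(np.pi * u)
    pos[t >= feedback] = w[-1]

    if noise_frac > 0:
        rng = _rng(seed)
        raw = rng.standard_normal(n)
        b, a = signal.butter(3, 40.0, fs=rate)
        lp = signal.filtfilt(b, a, raw)
        scale = noise_frac * (amp if k_true > 0 else abs(D))
        lp *= scale / max(np.max(np.abs(lp)), 1e-12)
        vmax = max(np.max(np.abs(vel)), 1e-12)
        pos = pos + lp * (np.abs(vel) / vmax)

    return WheelTrace(t, pos, stim_on, feedback)


# ---------------------------------------------------------------------------
# choices, spikes, pupil


def generate_choice(
    contrast_signed: float,
    p_left: float,
    params: PsychometricParams,
    seed,
    bias_shift_pct: float = 0.0,
    stim_side: int | None = None,
) -> tuple[int, int]:
    """Draw a choice from the psychometric model and score it.

    Returns (choice, correct) with choice +1 = counterclockwise (rightward
    report) and -1 = clockwise.  The block prior shifts the bias additively:
    mu_eff = mu + bias_shift_pct * 2 (p_left - 1/2).  For 0% contrast trials
    in biased blocks, correctness means matching the block-majority side.
    """
    if not -100 <= contrast_signed <= 100:
        raise ValueError("signed contrast must lie in [-100, 100]")
    rng = _rng(seed)
    if stim_side is None:
        if contrast_signed != 0:
            stim_side = 1 if contrast_signed > 0 else -1
        else:
            stim_side = -1 if rng.random() < p_left else 1
    mu_eff = params.mu + bias_shift_pct * 2.0 * (p_left - 0.5)
    p_right = predict_psychometric(replace(params, mu=mu_eff), contrast_signed)
    choice = 1 if rng.random() < p_right else -1
    if contrast_signed == 0 and p_left != 0.5:
        majority = -1 if p_left > 0.5 else 1
        correct = int(choice == majority)
    else:
        correct = int(choice == stim_side)
    return choice, correct


def generate_spike_tensor(
    sides: np.ndarray,
    n_neurons: int,
    coding_strength: float,
    seed,
    window: tuple[float, float] = (0.0, 1.0),
    bin_width: float = 0.02,
    base_rate_hz: float = 10.0,
    frac_selective: float = 0.5,
    coding_window: tuple[float, float] | None = None,
) -> SpikeTensor:
    """Poisson spike-count tensor (neurons x 20 ms bins x trials).

    A seeded subset (``frac_selective``) of neurons multiplies its rate by
    (1 + coding_strength) on its preferred stimulus side.  By default the
    modulation is active throughout the window, so longer windows contain
    more informative bins; ``coding_window`` restricts it (e.g. to the first
    0.2 s) for controls.  ``coding_strength = 0`` yields side-independent
    rates.
    """
    if n_neurons < 1:
        raise ValueError("need at least one neuron")
    if coding_strength < -1:
        raise ValueError("coding_strength must be >= -1")
    rng = _rng(seed)
    sides = np.asarray(sides)
    K = sides.size
    T = int(round((window[1] - window[0]) / bin_width))
    base = rng.gamma(4.0, base_rate_hz / 4.0, size=n_neurons)
    preferred = np.where(rng.random(n_neurons) < 0.5, 1, -1)
    selective = rng.random(n_neurons) < frac_selective

    rates = np.broadcast_to(base[:, None, None], (n_neurons, T, K)).copy()
    match = selective[:, None] & (sides[None, :] == preferred[:, None])  # N x K
    gain = np.where(match, 1.0 + coding_strength, 1.0)
    bin_starts = window[0] + np.arange(T) * bin_width
    if coding_window is None:
        active = np.ones(T, dtype=bool)
    else:
        active = (bin_starts >= coding_window[0]) & (bin_starts < coding_window[1])
    rates[:, active, :] *= gain[:, None, :]
    counts = rng.poisson(rates * bin_width)
    return SpikeTensor(
        counts=counts,
        bin_width=bin_width,
        window=window,
        neuron_ids=np.arange(n_neurons),
        trial_ids=np.arange(K),
    )


def generate_pupil_trace(
    stim_times: np.ndarray,
    wiggle_speeds: np.ndarray,
    coupling: float,
    seed,
    rate: float = 30.0,
    t_end: float | None = None,
) -> pd.DataFrame:
    """Slow positive pupil-diameter series (arbitrary units) with optional
    linear coupling to per-trial wiggle speed.

    The baseline is sub-0.1 Hz filtered noise spanning roughly 0.15-0.45 of
    the session maximum (one broad excursion sets that maximum), so that
    after session-max normalization most trials fall in the analyzed 0.10-
    0.45 range.  With ``coupling > 0``, a transient bump proportional to the
    trial's (max-normalized) wiggle speed is added around stimulus onset;
    ``coupling = 0`` leaves the pupil independent of the wheel.
    """
    if coupling < 0:
        raise ValueError("coupling must be >= 0")
    rng = _rng(seed)
    stim_times = np.asarray(stim_times, dtype=float)
    if t_end is None:
        t_end = float(stim_times.max()) + 5.0
    t = np.arange(0.0, t_end, 1.0 / rate)
    b, a = signal.butter(2, 0.05, fs=rate)
    slow = signal.filtfilt(b, a, rng.standard_normal(t.size))
    slow = slow / max(np.std(slow), 1e-12)
    diameter = 5.5 + 1.5 * np.clip(slow, -2.0, 2.0)
    # one broad excursion defines the session maximum used for normalization
    center = rng.uniform(0.1, 0.9) * t_end
    diameter = diameter + 13.0 * np.exp(-0.5 * ((t - center) / 20.0) ** 2)
    if coupling > 0 and stim_times.size:
        speeds = np.asarray(wiggle_speeds, dtype=float)
        norm = speeds / max(np.nanmax(speeds), 1e-12)
        for st, sp in zip(stim_times, norm):
            if np.isnan(sp):
                continue
            m = np.abs(t - st - 0.25) < 1.5
            diameter[m] += coupling * sp * np.exp(-0.5 * ((t[m] - st - 0.25) / 0.3) ** 2)
    return pd.DataFrame({"t_s": t, "diameter_au": np.maximum(diameter, 0.5)})


# ---------------------------------------------------------------------------
# full session


def _draw_k(rng: np.random.Generator, p: float) -> int:
    """Truncated 1 + Geometric(p) on {1..8}."""
    k = 1 + rng.geometric(p)
    return int(min(k, 8))


def generate_session(spec: SessionSpec, config: TaskConfig | None = None) -> SyntheticSession:
    """Compose a full synthetic session with ground truth.

    Fully reproducible from (spec, config): all randomness flows from the
    session seed through named substreams (blocks, quiescence, trials,
    traces, spikes, pupil).
    """
    cfg = config or TaskConfig()
    policy = spec.wiggle_policy or DEFAULT_WIGGLE_POLICY
    ss = np.random.SeedSequence(spec.seed)
    rng_blocks, rng_quies, rng_trials, rng_traces, rng_spikes, rng_pupil = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    n = spec.n_trials
    p_left = generate_block_sequence(n, rng_blocks)
    quiescence = sample_quiescence_duration(n, rng_quies, cfg)
    rts = _reaction_times(n, spec.p_false_start, rng_trials)

    levels = np.asarray(cfg.contrast_set)
    rows, gt_rows = [], []
    wheel: dict[int, WheelTrace] = {}
    t_cursor = 2.0
    for i in range(n):
        level = float(levels[rng_trials.integers(levels.size)])
        side = -1 if rng_trials.random() < p_left[i] else 1
        c_signed = side * level
        choice, correct = generate_choice(
            c_signed, p_left[i], spec.psychometric, rng_trials,
            bias_shift_pct=spec.bias_shift_pct, stim_side=side,
        )
        pol = policy[min(policy, key=lambda c: abs(c - level))]
        wiggle = rng_trials.random() < pol["p_wiggle"]
        if wiggle:
            k_true = _draw_k(rng_trials, spec.k_geometric_p)
            amp = pol["amp_scale"] * rng_trials.uniform(0.7, 1.3)
            amp = max(amp, 1.1 * cfg.wheel_deg_per_35_visual_deg / (k_true + 1))
            move_dur = (k_true + 1) * pol["seg_dur"] * rng_trials.uniform(0.8, 1.2)
        else:
            k_true, amp = 0, float("nan")
            move_dur = rng_trials.uniform(0.18, 0.32)

        stim_on = t_cursor + quiescence[i]
        rt = rts[i]
        onset = stim_on + rt
        feedback = onset + move_dur

        if spec.make_traces:
            wheel[i] = generate_wheel_trace(
                k_true, choice, stim_on, rt, move_dur,
                amplitude_deg=None if k_true == 0 else amp,
                config=cfg, seed=rng_traces, noise_frac=spec.noise_frac,
            )

        rows.append(
            dict(trial_id=i, contrast_signed_pct=c_signed, p_left=p_left[i],
                 choice=choice, correct=correct, rt_s=rt, stim_on_s=stim_on,
                 go_cue_s=stim_on, feedback_s=feedback, quiescence_s=quiescence[i],
                 response_duration_s=feedback - stim_on)
        )
        gt_rows.append(
            dict(trial_id=i, k_true=k_true, wiggle_true=int(wiggle),
                 block_p_left_true=p_left[i], stimulus_side_true=side,
                 quiescence_true=quiescence[i], amplitude_true=amp,
                 move_duration_s=move_dur)
        )
        iti = 0.5 if correct else 2.0
        t_cursor = max(feedback + iti, stim_on + 1.6)

    trials = pd.DataFrame(rows)
    ground_truth = pd.DataFrame(gt_rows)

    spikes = None
    if spec.n_neurons:
        window = (-0.5, 1.0)
        tensor = generate_spike_tensor(
            ground_truth["stimulus_side_true"].to_numpy(), spec.n_neurons,
            spec.coding_strength, rng_spikes, window=window,
        )
        spikes = _tensor_to_events(tensor, trials["stim_on_s"].to_numpy(), rng_spikes)

    pupil = None
    if spec.pupil_coupling is not None:
        gt = ground_truth
        speed_proxy = np.where(
            gt["k_true"] > 0,
            gt["k_true"] * gt["amplitude_true"] / gt["move_duration_s"],
            np.nan,
        )
        pupil = generate_pupil_trace(
            trials["stim_on_s"].to_numpy(), speed_proxy, spec.pupil_coupling,
            rng_pupil, t_end=float(trials["feedback_s"].iloc[-1]) + 5.0,
        )

    return SyntheticSession(
        trials=trials, ground_truth=ground_truth, wheel=wheel,
        spikes=spikes, pupil=pupil, spec=spec, config=cfg,
    )


def _tensor_to_events(
    tensor: SpikeTensor, stim_times: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Spread tensor counts uniformly within their 20 ms bins to produce a
    (t_s, cluster_id) event list; re-binning the events with the tensor's
    window reproduces the counts exactly."""
    N, T, K = tensor.counts.shape
    times, clusters = [], []
    bin_start = tensor.window[0] + np.arange(T) * tensor.bin_width
    for k in range(K):
        for nrn in range(N):
            c = tensor.counts[nrn, :, k]
            tot = int(c.sum())
            if tot == 0:
                continue
            offs = np.repeat(bin_start, c) + rng.random(tot) * tensor.bin_width
            times.append(stim_times[k] + offs)
            clusters.append(np.full(tot, nrn))
    if not times:
        return pd.DataFrame({"t_s": [], "cluster_id": []})
    t = np.concatenate(times)
    cl = np.concatenate(clusters).astype(int)
    order = np.argsort(t, kind="stable")
    return pd.DataFrame({"t_s": t[order], "cluster_id": cl[order]})


def generate_k_accuracy_table(
    n_trials: int,
    slope_per_bin: float,
    seed,
    base_accuracy: float = 0.6,
    contrast_pct: float = 6.25,
    k_probs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Trial table with a planted linear k-accuracy coupling.

    P(correct) = base_accuracy + slope_per_bin * min(k, 4), clipped to
    [0.02, 0.98]; k is drawn from ``k_probs`` over {0..6} (default weights
    mimicking the heavy-zero empirical k distribution).  Used to test the
    session/mouse classification pipeline against known coupling signs.
    """
    rng = _rng(seed)
    if k_probs is None:
        k_probs = np.array([0.45, 0.18, 0.12, 0.09, 0.07, 0.05, 0.04])
    k_probs = np.asarray(k_probs, dtype=float)
    k_probs = k_probs / k_probs.sum()
    k = rng.choice(np.arange(k_probs.size), size=n_trials, p=k_probs)
    p = np.clip(base_accuracy + slope_per_bin * np.minimum(k, 4), 0.02, 0.98)
    correct = (rng.random(n_trials) < p).astype(int)
    side = np.where(rng.random(n_trials) < 0.5, -1, 1)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "contrast_signed_pct": side * contrast_pct,
            "k": k,
            "is_wiggle": (k > 0).astype(int),
            "correct": correct,
            "choice": np.where(correct.astype(bool), side, -side),
        }
    )
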