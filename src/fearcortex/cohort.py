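"""Synthetic cohorts for differential fear conditioning analyses.

Generates per-mouse, per-session trial-response tables with the statistical
structure the analysis pipeline assumes: neurons carry Gaussian tuning
curves on the log2-frequency axis, trial responses are the tuning mean plus
additive Gaussian noise (in dF/F_std units), and tuning drifts across
sessions as a random walk of best frequency (octaves) and multiplicative
gain. A per-mouse ``discriminability_gradient`` g in [0, 1] programs how
strongly the population separates the CS+ (15 kHz) and CS- (11.4 kHz)
tones, by placing a fraction of neurons with narrow tuning exactly at the
CS frequencies. Ground-truth learning specificity is a saturating
(logistic-shaped) function of the programmed population separation plus
noise for conditioned mice, and pure noise around zero for
pseudo-conditioned mice.

The same module generates two-state (freeze/move) motion-index traces whose
scoring by the behavior module recovers the programmed freezing fractions,
and synthetic ROI scenes with known geometry for the tracking module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import BASELINE, CS_MINUS, CS_PLUS, MotionTrace
from .decoding import PopulationTrials
from .responses import CS_MINUS_HZ, CS_PLUS_HZ, TrialResponseMatrix
from .tracking import RoiSet, TransformModel

__all__ = [
    "CohortConfig",
    "MouseData",
    "SyntheticCohort",
    "default_frequencies",
    "generate_cohort",
    "generate_motion_trace",
    "generate_roi_scene",
    "build_retrieval_schedule",
]


def default_frequencies(n: int = 12, lo: float = 5000.0, hi: float = 32000.0) -> tuple[float, ...]:
    """Log-spaced stimulus grid from 5 to 32 kHz, snapped to contain the
    exact CS+ (15 kHz) and CS- (11.4 kHz) frequencies."""
    grid = lo * 2.0 ** np.linspace(0.0, math.log2(hi / lo), n)
    for target in (CS_MINUS_HZ, CS_PLUS_HZ):
        k = int(np.argmin(np.abs(np.log2(grid / target))))
        grid[k] = target
    grid = np.unique(grid)
    return tuple(float(f) for f in grid)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for a synthetic cohort."""

    n_conditioned: int = 14
    n_pseudo: int = 9
    neurons_per_mouse: tuple[int, int] = (60, 120)
    frequencies: tuple[float, ...] = field(default_factory=default_frequencies)
    repeats_per_frequency: int = 25
    n_sessions: int = 8
    n_pre_sessions: int = 4            # sessions 1..n_pre are pre-DFC
    tuning_width_octaves: tuple[float, float] = (0.25, 1.5)
    amplitude_range: tuple[float, float] = (1.0, 3.0)
    noise_sd: float = 1.0              # trial noise, dF/F_std units
    discriminability_gradient: tuple[float, ...] | None = None
    selective_fraction_max: float = 0.6
    ls_noise_sd: float = 0.05
    ls_max: float = 0.65
    ls_slope: float = 1.3
    drift_rate: float = 0.1            # per-session BF perturbation SD, octaves
    seed: int = 0
    include_motion: bool = True
    include_rois: bool = False
    n_rois_per_session: int = 60

    def __post_init__(self) -> None:
        if self.repeats_per_frequency < 2:
            raise ValueError("repeats_per_frequency must be at least 2")
        freqs = np.asarray(self.frequencies, dtype=float)
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.n_conditioned < 0 or self.n_pseudo < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.neurons_per_mouse[0] > self.neurons_per_mouse[1]:
            raise ValueError("neurons_per_mouse range must be ordered")
        if self.n_pre_sessions > self.n_sessions:
            raise ValueError("n_pre_sessions cannot exceed n_sessions")

    @property
    def gradients(self) -> np.ndarray:
        if self.discriminability_gradient is not None:
            g = np.asarray(self.discriminability_gradient, dtype=float)
            if g.size != self.n_conditioned:
                raise ValueError("one gradient per conditioned mouse required")
            return g
        if self.n_conditioned == 1:
            return np.array([1.0])
        return np.linspace(0.0, 1.0, self.n_conditioned)


@dataclass
class MouseData:
    """All synthetic data of one mouse."""

    mouse_id: str
    group: str                      # "conditioned" | "pseudo"
    gradient: float
    ls_true: float
    bf_log2: np.ndarray             # sessions x neurons, log2 Hz
    gain: np.ndarray                # sessions x neurons
    width_octaves: np.ndarray       # neurons
    amplitude: np.ndarray           # neurons
    responses: list[np.ndarray]     # per session: neurons x freqs x repeats
    motion: dict[int, MotionTrace] = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.responses[0].shape[0]


@dataclass
class SyntheticCohort:
    config: CohortConfig
    mice: list[MouseData]
    roi_scenes: dict[int, tuple[RoiSet, RoiSet, tuple[np.ndarray, np.ndarray]]] = field(
        default_factory=dict
    )

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.config.frequencies)

    def conditioned(self) -> list[MouseData]:
        return [m for m in self.mice if m.group == "conditioned"]

    def trial_matrix(self, mouse: MouseData, session: int, neuron: int) -> TrialResponseMatrix:
        """Single-neuron TrialResponseMatrix for a (1-based) session."""
        return TrialResponseMatrix(
            responses=mouse.responses[session - 1][neuron],
            frequencies=self.frequencies,
            neuron_id=neuron,
            session_id=session,
        )

    def cs_repeats(self, mouse: MouseData, session: int) -> tuple[np.ndarray, np.ndarray]:
        """(r_CS+, r_CS-) arrays of shape neurons x repeats."""
        freqs = self.frequencies
        i_plus = int(np.argmin(np.abs(freqs - CS_PLUS_HZ)))
        i_minus = int(np.argmin(np.abs(freqs - CS_MINUS_HZ)))
        resp = mouse.responses[session - 1]
        return resp[:, i_plus, :], resp[:, i_minus, :]

    def population(self, mouse: MouseData, session: int) -> PopulationTrials:
        """Single-trial CS+/CS- population responses (trials x neurons)."""
        r_plus, r_minus = self.cs_repeats(mouse, session)
        X = np.vstack([r_plus.T, r_minus.T])
        y = np.concatenate([
            np.ones(r_plus.shape[1], dtype=int),
            -np.ones(r_minus.shape[1], dtype=int),
        ])
        return PopulationTrials(
            X=X, y=y, session_id=session, mouse_id=mouse.mouse_id
        )

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mouse_id": [m.mouse_id for m in self.mice],
                "group": [m.group for m in self.mice],
                "gradient": [m.gradient for m in self.mice],
                "ls_true": [m.ls_true for m in self.mice],
                "n_neurons": [m.n_neurons for m in self.mice],
            }
        )


# distance between the CS tones, octaves (|log2(15000/11400)| ~ 0.396)
_CS_DISTANCE_OCT = abs(math.log2(CS_PLUS_HZ / CS_MINUS_HZ))


def _expected_separation(config: CohortConfig, gradient: float) -> float:
    """Programmed CS+/CS- population separation for a gradient value.

    A fraction ``selective_fraction_max * g`` of neurons is narrowly tuned
    at one of the CS frequencies; each contributes an expected |response
    difference| of A_mean * (1 - exp(-d_cs^2 / (2 w_min^2))).
    """
    w_min = config.tuning_width_octaves[0]
    a_mean = float(np.mean(config.amplitude_range))
    delta = a_mean * (1.0 - math.exp(-(_CS_DISTANCE_OCT**2) / (2 * w_min**2)))
    return config.selective_fraction_max * gradient * delta


def _ground_truth_ls(config: CohortConfig, gradient: float, rng: np.random.Generator) -> float:
    sep = _expected_separation(config, gradient)
    ls = config.ls_max * math.tanh(config.ls_slope * sep)
    ls += rng.normal(0.0, config.ls_noise_sd) if config.ls_noise_sd > 0 else 0.0
    return float(np.clip(ls, -1.0, 1.0))


def _make_mouse(
    config: CohortConfig,
    mouse_id: str,
    group: str,
    gradient: float,
    rng: np.random.Generator,
) -> MouseData:
    lo, hi = config.neurons_per_mouse
    n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    freqs_log2 = np.log2(np.asarray(config.frequencies))
    lo_f, hi_f = freqs_log2.min(), freqs_log2.max()
    w_lo, w_hi = config.tuning_width_octaves

    p_sel = config.selective_fraction_max * gradient if group == "conditioned" else 0.0
    selective = rng.random(n) < p_sel
    bf0 = rng.uniform(lo_f, hi_f, size=n)
    width = rng.uniform(w_lo, w_hi, size=n)
    amplitude = rng.uniform(*config.amplitude_range, size=n)
    # CS-selective neurons sit exactly on one CS tone with the narrowest tuning
    cs_choice = rng.random(n) < 0.5
    bf0[selective] = np.where(
        cs_choice[selective], math.log2(CS_PLUS_HZ), math.log2(CS_MINUS_HZ)
    )
    width[selective] = w_lo

    n_sessions = config.n_sessions
    bf = np.empty((n_sessions, n))
    gain = np.empty((n_sessions, n))
    bf[0] = bf0
    gain[0] = 1.0
    for s in range(1, n_sessions):
        bf[s] = bf[s - 1] + rng.normal(0.0, config.drift_rate, size=n)
        gain[s] = gain[s - 1] * np.exp(rng.normal(0.0, config.drift_rate / 2, size=n))

    responses = []
    for s in range(n_sessions):
        mu = (
            amplitude[:, None]
            * gain[s][:, None]
            * np.exp(-((freqs_log2[None, :] - bf[s][:, None]) ** 2) / (2 * width[:, None] ** 2))
        )
        trials = mu[:, :, None] + rng.normal(
            0.0, config.noise_sd, size=(n, freqs_log2.size, config.repeats_per_frequency)
        )
        responses.append(trials)

    ls_true = (
        _ground_truth_ls(config, gradient, rng)
        if group == "conditioned"
        else float(np.clip(rng.normal(0.0, config.ls_noise_sd), -1.0, 1.0))
    )
    return MouseData(
        mouse_id=mouse_id,
        group=group,
        gradient=gradient,
        ls_true=ls_true,
        bf_log2=bf,
        gain=gain,
        width_octaves=width,
        amplitude=amplitude,
        responses=responses,
    )


def build_retrieval_schedule(
    rng: np.random.Generator,
    n_trials_per_cs: int = 4,
    stimulus_s: float = 30.0,
    baseline_s: float = 30.0,
    iti_range: tuple[float, float] = (70.0, 110.0),
    start_s: float = 60.0,
) -> list[tuple[str, float, float]]:
    """Interleaved CS+/CS- retrieval-session windows with baselines.

    Stimuli occupy a minority of the session so that the session-wide
    12.5th-percentile movement threshold stays above the freezing state.
    """
    windows: list[tuple[str, float, float]] = []
    t = start_s
    for k in range(2 * n_trials_per_cs):
        label = CS_PLUS if k % 2 == 0 else CS_MINUS
        windows.append((BASELINE, t - baseline_s, t))
        windows.append((label, t, t + stimulus_s))
        t += stimulus_s + float(rng.uniform(*iti_range))
    return windows


def generate_motion_trace(
    schedule: list[tuple[tuple[float, float], float]],
    frame_rate: float = 3.75,
    noise_sd: float = 0.6,
    seed: int | np.random.Generator = 0,
    labels: list[str] | None = None,
    moving_level: float = 1.0,
    moving_floor: float = 0.5,
    freezing_level: float = 0.02,
    tail_s: float = 30.0,
) -> MotionTrace:
    """Two-state motion-index trace realizing scheduled freezing fractions.

    ``schedule`` lists ``((start_s, end_s), freeze_fraction)`` windows;
    within each window a contiguous freezing bout occupies the requested
    fraction of frames. Moving samples are Gaussian around
    ``moving_level`` clipped below at ``moving_floor`` (a camera noise
    floor), freezing samples sit near ``freezing_level`` — far below the
    floor, so the session percentile threshold separates the two states.
    """
    if not schedule:
        raise ValueError("empty schedule")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for (_start, _end), frac in schedule:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("freeze_fraction must lie in [0, 1]")
    duration = max(end for (_s, end), _f in schedule) + tail_s
    n = int(round(duration * frame_rate))
    samples = np.maximum(rng.normal(moving_level, noise_sd, size=n), moving_floor)
    for (start, end), frac in schedule:
        i0, i1 = int(round(start * frame_rate)), int(round(end * frame_rate))
        n_win = i1 - i0
        n_freeze = int(round(frac * n_win))
        if n_freeze == 0:
            continue
        offset = int(rng.integers(0, n_win - n_freeze + 1))
        sl = slice(i0 + offset, i0 + offset + n_freeze)
        samples[sl] = np.abs(rng.normal(freezing_level, freezing_level / 2, size=n_freeze))
    windows = []
    if labels is not None:
        if len(labels) != len(schedule):
            raise ValueError("labels must match schedule length")
        windows = [
            (lab, float(start), float(end))
            for lab, ((start, end), _f) in zip(labels, schedule)
        ]
    return MotionTrace(samples=samples, frame_rate=frame_rate, windows=windows)


def _retrieval_motion(
    config: CohortConfig, mouse: MouseData, rng: np.random.Generator
) -> dict[int, MotionTrace]:
    """One motion trace per retrieval session (after each post-DFC imaging
    session), with CS+ freezing elevated by the mouse's ground-truth LS."""
    traces: dict[int, MotionTrace] = {}
    f_base, f_minus = 0.02, 0.08
    f_plus = float(np.clip(f_minus + mouse.ls_true, 0.0, 0.85))
    for session in range(config.n_pre_sessions + 1, config.n_sessions + 1):
        windows = build_retrieval_schedule(rng)
        schedule, labels = [], []
        for label, start, end in windows:
            frac = {CS_PLUS: f_plus, CS_MINUS: f_minus, BASELINE: f_base}[label]
            schedule.append(((start, end), frac))
            labels.append(label)
        traces[session] = generate_motion_trace(
            schedule, seed=rng, labels=labels
        )
    return traces


def _disk_mask(cx: float, cy: float, radius: int) -> np.ndarray:
    span = np.arange(-radius, radius + 1)
    xs, ys = np.meshgrid(span, span)
    keep = xs**2 + ys**2 <= radius**2
    return np.column_stack([np.round(cx + xs[keep]), np.round(cy + ys[keep])]).astype(int)


def generate_roi_scene(
    n_rois: int,
    transform: TransformModel,
    jitter_px: float = 0.0,
    seed: int | np.random.Generator = 0,
    image_size: int = 512,
    radius_range: tuple[int, int] = (4, 6),
    min_separation: float = 14.0,
    n_landmarks: int = 4,
) -> tuple[RoiSet, RoiSet, tuple[np.ndarray, np.ndarray]]:
    """Reference ROI set, its transformed-and-jittered counterpart, and
    exact landmark pairs.

    Moved centroids are ``transform(reference) + N(0, jitter_px)``; the
    landmark pairs are exact under the transform, as in a well-annotated
    imaging field.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    margin = 40
    centroids: list[np.ndarray] = []
    attempts = 0
    while len(centroids) < n_rois:
        attempts += 1
        if attempts > 200 * n_rois:
            raise RuntimeError("could not place ROIs with requested separation")
        p = rng.uniform(margin, image_size - margin, size=2)
        if all(np.linalg.norm(p - q) >= min_separation for q in centroids):
            centroids.append(p)
    cents = np.array(centroids)
    radii = rng.integers(radius_range[0], radius_range[1] + 1, size=n_rois)
    ids = list(range(n_rois))
    ref = RoiSet(
        ids=ids,
        masks=[_disk_mask(c[0], c[1], r) for c, r in zip(cents, radii)],
        centroids=cents,
        image_size=(image_size, image_size),
    )
    moved_cents = transform.apply(cents)
    if jitter_px > 0:
        moved_cents = moved_cents + rng.normal(0.0, jitter_px, size=moved_cents.shape)
    moved = RoiSet(
        ids=ids,
        masks=[_disk_mask(c[0], c[1], r) for c, r in zip(moved_cents, radii)],
        centroids=moved_cents,
        image_size=(image_size, image_size),
    )
    lm_ref = rng.uniform(margin, image_size - margin, size=(n_landmarks, 2))
    lm_moved = transform.apply(lm_ref)
    return ref, moved, (lm_ref, lm_moved)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic for a given config."""
    rng = np.random.default_rng(config.seed)
    mice: list[MouseData] = []
    for k, g in enumerate(config.gradients):
        mice.append(_make_mouse(config, f"c{k:02d}", "conditioned", float(g), rng))
    for k in range(config.n_pseudo):
        mice.append(_make_mouse(config, f"p{k:02d}", "pseudo", 0.0, rng))
    if config.include_motion:
        for mouse in mice:
            mouse.motion = _retrieval_motion(config, mouse, rng)
    scenes = {}
    if config.include_rois:
        for session in range(2, config.n_sessions + 1):
            angle = math.radians(rng.uniform(-5.0, 5.0))
            A = np.array(
                [[math.cos(angle), -math.sin(angle)], [math.sin(angle), math.cos(angle)]]
            )
            shift = rng.uniform(-10.0, 10.0, size=2)
            tf = TransformModel(A=A, b=shift)
            scenes[session] = generate_roi_scene(
                config.n_rois_per_session, tf, jitter_px=1.0, seed=rng
            )
    return SyntheticCohort(config=config, mice=mice, roi_scenes=scenes)
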