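"""Freezing behavior: motion-index scoring and learning specificity.

Freezing is scored from a video-derived motion index (mean inter-frame
grayscale difference). A mouse counts as freezing whenever the motion index
falls strictly below a session-wide threshold, defined as the 12.5th
percentile of all motion samples in that session. Learning specificity (LS)
is the mean freezing fraction during CS+ trials minus the mean freezing
fraction during CS- trials; LS near 1 indicates fear specialized to the
shock-paired tone, LS near 0 generalized (or absent) fear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotionTrace",
    "FreezingRecord",
    "motion_index",
    "freezing_threshold",
    "percent_freezing",
    "learning_specificity",
    "classify_learner",
    "score_session",
    "split_window",
]

#: window labels understood by the scoring helpers
CS_PLUS = "CS+"
CS_MINUS = "CS-"
BASELINE = "baseline"


@dataclass
class MotionTrace:
    """Motion-index time series with labelled stimulus windows.

    Parameters
    ----------
    samples
        Motion index per frame transition (arbitrary units).
    frame_rate
        Acquisition rate in Hz.
    windows
        ``(label, start_s, end_s)`` triples; labels are ``"CS+"``, ``"CS-"``
        or ``"baseline"``.
    """

    samples: np.ndarray
    frame_rate: float
    windows: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        dur = self.duration
        for label, start, end in self.windows:
            if not (0 <= start < end <= dur + 1.0 / self.frame_rate):
                raise ValueError(
                    f"window {label!r} [{start}, {end}] outside trace of {dur:.2f} s"
                )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.frame_rate

    def window_samples(self, start: float, end: float) -> np.ndarray:
        i0 = int(np.floor(start * self.frame_rate))
        i1 = int(np.ceil(end * self.frame_rate))
        return self.samples[i0:i1]


@dataclass
class FreezingRecord:
    """Per-trial freezing fractions for the two CS conditions and baseline."""

    fr_cs_plus: list[float]
    fr_cs_minus: list[float]
    fr_baseline: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fr_cs_plus or not self.fr_cs_minus:
            raise ValueError("both CS trial lists must be non-empty")
        for name in ("fr_cs_plus", "fr_cs_minus", "fr_baseline"):
            vals = getattr(self, name)
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise ValueError(f"{name} contains fractions outside [0, 1]")


def motion_index(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Mean inter-frame grayscale difference.

    ``sample[n] = mean(frame[n+1] - frame[n])`` over pixels; the output has
    one fewer entry than the number of frames.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    arrs = [np.asarray(f, dtype=float) for f in frames]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs[1:]):
        raise ValueError("all frames must share the same dimensions")
    stack = np.stack(arrs)
    return np.diff(stack, axis=0).mean(axis=tuple(range(1, stack.ndim)))


def freezing_threshold(trace: MotionTrace) -> float:
    """Session-wide movement threshold: 12.5th percentile of all samples.

    Uses linear interpolation between order statistics (numpy's default
    percentile definition).
    """
    if trace.samples.size == 0:
        raise ValueError("empty trace")
    if trace.samples.size < 8:
        raise ValueError("need at least 8 samples for a stable percentile")
    return float(np.percentile(trace.samples, 12.5))


def percent_freezing(
    trace: MotionTrace, window: tuple[float, float], threshold: float
) -> float:
    """Fraction of window samples strictly below ``threshold``.

    Ties with the threshold count as movement, so a constant trace scores 0.
    """
    samples = trace.window_samples(*window)
    if samples.size == 0:
        raise ValueError("empty window")
    return float(np.mean(samples < threshold))


def learning_specificity(record: FreezingRecord) -> float:
    """LS = mean per-trial CS+ freezing minus mean per-trial CS- freezing."""
    return float(np.mean(record.fr_cs_plus) - np.mean(record.fr_cs_minus))


def split_window(
    window: tuple[float, float], n_parts: int = 4
) -> list[tuple[float, float]]:
    """Divide a long stimulus window into equal sub-trials.

    Mirrors the handling of extended (60-120 s) tone presentations, which are
    scored as ``n_parts`` independent trials.
    """
    start, end = window
    edges = np.linspace(start, end, n_parts + 1)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def score_session(
    trace: MotionTrace,
    threshold: float | None = None,
    split_long_trials: int | None = None,
) -> FreezingRecord:
    """Score every labelled window of a session into a FreezingRecord.

    ``threshold`` defaults to the session's own 12.5th-percentile threshold.
    ``split_long_trials`` optionally divides each stimulus window into that
    many equal sub-trials before scoring.
    """
    if threshold is None:
        threshold = freezing_threshold(trace)
    by_label: dict[str, list[float]] = {CS_PLUS: [], CS_MINUS: [], BASELINE: []}
    for label, start, end in trace.windows:
        if label not in by_label:
            raise ValueError(f"unknown window label {label!r}")
        windows = [(start, end)]
        if split_long_trials and label != BASELINE:
            windows = split_window((start, end), split_long_trials)
        for w in windows:
            by_label[label].append(percent_freezing(trace, w, threshold))
    return FreezingRecord(
        fr_cs_plus=by_label[CS_PLUS],
        fr_cs_minus=by_label[CS_MINUS],
        fr_baseline=by_label[BASELINE],
    )


def classify_learner(
    records: Sequence[FreezingRecord], alpha: float = 0.05
) -> tuple[str, dict[str, float]]:
    """Learner / non-learner classification via per-mouse two-way ANOVA.

    Freezing scores from all retrieval sessions enter a two-way ANOVA with
    factors ``stimulus`` (CS+/CS-) and ``period`` (stimulus presentation vs
    pre-stimulus baseline). Baseline trials are split evenly between the two
    stimulus levels so the design is crossed. A mouse is a learner if the
    main effect of period or the period-by-stimulus interaction is
    significant at ``alpha``.

    Returns the label and the ANOVA p-values
    (``{"stimulus", "period", "interaction"}``).
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rows: list[tuple[float, str, str]] = []
    for rec in records:
        if len(rec.fr_cs_plus) < 2 or len(rec.fr_cs_minus) < 2:
            raise ValueError("need at least 2 trials per cell")
        rows += [(v, "plus", "stim") for v in rec.fr_cs_plus]
        rows += [(v, "minus", "stim") for v in rec.fr_cs_minus]
        base = rec.fr_baseline
        if not base:
            raise ValueError("baseline trials required for learner ANOVA")
        half = len(base) // 2
        rows += [(v, "plus", "base") for v in base[:half]]
        rows += [(v, "minus", "base") for v in base[half:]]
    df = pd.DataFrame(rows, columns=["freezing", "stimulus", "period"])
    model = ols("freezing ~ C(stimulus) * C(period)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    pvals = {
        "stimulus": float(table.loc["C(stimulus)", "PR(>F)"]),
        "period": float(table.loc["C(period)", "PR(>F)"]),
        "interaction": float(table.loc["C(stimulus):C(period)", "PR(>F)"]),
    }
    learner = pvals["period"] < alpha or pvals["interaction"] < alpha
    return ("learner" if learner else "non_learner"), pvals
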