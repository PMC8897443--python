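"""Single-neuron response statistics for two-photon calcium imaging.

Converts fluorescence traces to trial-evoked scalars (mean dF/F_std over the
2 s after tone onset), tests responsiveness, summarizes frequency tuning
(frequency response function, best frequency, sparseness), and quantifies
CS+/CS- discriminability with the Z_diff statistic and its permutation null.

Z_diff for a neuron is

    Z_diff = |mean(r_CS+) - mean(r_CS-)| / sqrt(sd(r_CS+) * sd(r_CS-))

where r are single-trial mean responses. Significance is assessed against
250 label-shuffled recomputations: a score is significant when it exceeds the
95th percentile of the shuffled distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FluorescenceTrace",
    "TrialResponseMatrix",
    "FrequencyResponseFunction",
    "ZdiffResult",
    "dff_zscore",
    "trial_response",
    "is_responsive",
    "frequency_response_function",
    "sparseness",
    "zdiff",
    "zdiff_significance",
    "interpolate_at_frequency",
    "normalize_frf",
    "frf_percent_change",
    "bf_distance_octaves",
    "resample_by_bf_bin",
]

CS_PLUS_HZ = 15000.0
CS_MINUS_HZ = 11400.0


class DegenerateResponseError(ValueError):
    """Raised when a statistic is undefined (zero trial-to-trial variance)."""


@dataclass
class FluorescenceTrace:
    """Neuropil-corrected fluorescence with stimulus onset annotations."""

    F: np.ndarray
    frame_rate: float
    stimulus_onsets: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        dur = len(self.F) / self.frame_rate
        for t, _hz in self.stimulus_onsets:
            if not 0 <= t <= dur:
                raise ValueError("stimulus onset outside trace")


@dataclass
class TrialResponseMatrix:
    """Per-neuron scalar evoked responses, frequency x repeat.

    ``responses[i, k]`` is the mean dF/F_std response of this neuron to the
    k-th repeat of frequency ``frequencies[i]``.
    """

    responses: np.ndarray
    frequencies: np.ndarray
    neuron_id: int | str = 0
    session_id: int | str = 0

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be 2-D (frequency x repeat)")
        if self.responses.shape[0] != self.frequencies.size:
            raise ValueError("rows must match number of frequencies")
        if self.responses.shape[1] < 2:
            raise ValueError("need at least 2 repeats per frequency")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def repeats_at(self, hz: float) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.frequencies, hz))[0]
        if idx.size != 1:
            raise KeyError(f"frequency {hz} Hz not present")
        return self.responses[idx[0]]


@dataclass
class FrequencyResponseFunction:
    """Mean response per frequency with derived tuning summaries."""

    mean_response: np.ndarray
    frequencies: np.ndarray
    best_frequency: float
    sparseness: float | None
    a: float | None


@dataclass
class ZdiffResult:
    zdiff: float
    null_scores: np.ndarray
    null_95th: float
    significant: bool


def dff_zscore(
    trace: FluorescenceTrace,
    onset_s: float,
    baseline_s: float = 1.0,
    response_s: float = 2.0,
) -> np.ndarray:
    """dF/F_std around one stimulus presentation.

    Baseline mean and SD come from the ``baseline_s`` seconds before onset;
    returns ``(F - F_baseline) / F_std`` for the window from onset-baseline_s
    to onset+response_s.

    Raises :class:`DegenerateResponseError` when the baseline SD is zero, so
    degenerate presentations can be excluded rather than propagate infinities.
    """
    fr = trace.frame_rate
    i_on = int(round(onset_s * fr))
    i0 = i_on - int(round(baseline_s * fr))
    i1 = i_on + int(round(response_s * fr))
    if i0 < 0 or i1 > len(trace.F):
        raise ValueError("insufficient pre/post context around onset")
    base = trace.F[i0:i_on]
    f_baseline = base.mean()
    f_std = base.std(ddof=1)
    if f_std == 0:
        raise DegenerateResponseError("zero baseline SD")
    return (trace.F[i0:i1] - f_baseline) / f_std


def trial_response(zscored: np.ndarray) -> float:
    """Scalar trial response: mean dF/F_std over the post-onset window."""
    zscored = np.asarray(zscored, dtype=float)
    if zscored.size == 0:
        raise ValueError("empty segment")
    return float(zscored.mean())


def _one_sample_p(values: np.ndarray) -> float:
    """Two-sided one-sample t-test p-value vs 0, with the zero-variance
    convention: constant non-zero responses are maximally significant,
    constant zero responses are not."""
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.0 if values.mean() != 0 else 1.0
    return float(stats.ttest_1samp(values, 0.0).pvalue)


def is_responsive(matrix: TrialResponseMatrix, alpha: float = 0.05) -> bool:
    """Sound-responsiveness: any frequency's response differs from zero.

    One-sample t-tests per frequency, Holm-Bonferroni corrected over the
    number of frequencies tested.
    """
    from statsmodels.stats.multitest import multipletests

    pvals = np.array([_one_sample_p(row) for row in matrix.responses])
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return bool(reject.any())


def frequency_response_function(matrix: TrialResponseMatrix) -> FrequencyResponseFunction:
    """Mean response per frequency; BF is the argmax (ties -> lowest Hz)."""
    means = matrix.responses.mean(axis=1)
    bf = float(matrix.frequencies[int(np.argmax(means))])
    s, a = _sparseness_from_means(means)
    return FrequencyResponseFunction(
        mean_response=means,
        frequencies=matrix.frequencies.copy(),
        best_frequency=bf,
        sparseness=s,
        a=a,
    )


def _sparseness_from_means(means: np.ndarray) -> tuple[float | None, float | None]:
    n = means.size
    denom = np.sum(means**2) / n
    if denom == 0:
        return None, None
    a = (np.sum(means) / n) ** 2 / denom
    s = (1 - a) / (1 - 1 / n)
    return float(s), float(a)


def sparseness(frf: FrequencyResponseFunction | np.ndarray) -> float | None:
    """Lifetime sparseness of a frequency response function.

    a = (sum(r_i)/N)^2 / (sum(r_i^2)/N);  S = (1 - a) / (1 - 1/N).

    0 for a flat positive response function, 1 for a one-hot one. Negative
    mean responses are kept as-is, so S > 1 is possible and simply reported.
    Returns None for an all-zero response function (0/0).
    """
    means = frf.mean_response if isinstance(frf, FrequencyResponseFunction) else np.asarray(frf, float)
    s, _ = _sparseness_from_means(means)
    return s


def zdiff(r_plus: np.ndarray, r_minus: np.ndarray) -> float:
    """Z-scored CS+/CS- response difference (single-neuron discriminability).

    Uses sample SD (ddof=1). Raises :class:`DegenerateResponseError` when
    either SD is zero (the neuron is excluded downstream).
    """
    r_plus = np.asarray(r_plus, dtype=float)
    r_minus = np.asarray(r_minus, dtype=float)
    if r_plus.size < 2 or r_minus.size < 2:
        raise ValueError("need at least 2 repeats per stimulus")
    sp = r_plus.std(ddof=1)
    sm = r_minus.std(ddof=1)
    if sp == 0 or sm == 0:
        raise DegenerateResponseError("zero response SD")
    return float(abs(r_plus.mean() - r_minus.mean()) / math.sqrt(sp * sm))


def zdiff_significance(
    r_plus: np.ndarray,
    r_minus: np.ndarray,
    n_shuffles: int = 250,
    seed: int | np.random.Generator = 0,
) -> ZdiffResult:
    """Permutation test for Z_diff.

    The null pools the 2N trials and relabels them into two groups of the
    original sizes ``n_shuffles`` times; the observed score is significant
    when it exceeds (strictly) the null's 95th percentile.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = zdiff(r_plus, r_minus)
    r_plus = np.asarray(r_plus, dtype=float)
    r_minus = np.asarray(r_minus, dtype=float)
    n_plus = r_plus.size
    pooled = np.concatenate([r_plus, r_minus])
    # vectorized permutations: argsort of uniforms gives independent shuffles
    order = np.argsort(rng.random((n_shuffles, pooled.size)), axis=1)
    shuffled = pooled[order]
    a, b = shuffled[:, :n_plus], shuffled[:, n_plus:]
    sa = a.std(axis=1, ddof=1)
    sb = b.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        null = np.abs(a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sa * sb)
    null = null[np.isfinite(null)]
    null_95 = float(np.percentile(null, 95))
    return ZdiffResult(
        zdiff=observed,
        null_scores=null,
        null_95th=null_95,
        significant=bool(observed > null_95),
    )


def interpolate_at_frequency(
    frf: FrequencyResponseFunction, target_hz: float
) -> float:
    """Mean response linearly interpolated at ``target_hz``.

    Interpolation is linear on the log2-frequency axis, matching the
    log-spaced stimulus grid and octave-based distance measures. Used when
    the CS frequencies themselves were not presented.
    """
    freqs = np.asarray(frf.frequencies, dtype=float)
    if not (freqs.min() <= target_hz <= freqs.max()):
        raise ValueError("target frequency outside the tested range")
    return float(np.interp(np.log2(target_hz), np.log2(freqs), frf.mean_response))


def normalize_frf(frf: FrequencyResponseFunction) -> FrequencyResponseFunction:
    """Divide the mean response function by its maximum (peak becomes 1)."""
    peak = frf.mean_response.max()
    if peak == 0:
        raise DegenerateResponseError("cannot normalize an FRF with zero peak")
    means = frf.mean_response / peak
    s, a = _sparseness_from_means(means)
    return FrequencyResponseFunction(
        mean_response=means,
        frequencies=frf.frequencies.copy(),
        best_frequency=frf.best_frequency,
        sparseness=s,
        a=a,
    )


def frf_percent_change(
    pre: FrequencyResponseFunction,
    post: FrequencyResponseFunction,
    eps: float = 1e-9,
) -> np.ndarray:
    """Per-frequency percent change between normalized response functions.

    100 * (post - pre) / |pre|; entries where |pre| < eps are NaN. This is a
    relative measure: swapping pre and post does not merely change its sign.
    """
    if not np.array_equal(pre.frequencies, post.frequencies):
        raise ValueError("pre and post must share the frequency grid")
    p = pre.mean_response
    q = post.mean_response
    out = np.full(p.shape, np.nan)
    ok = np.abs(p) >= eps
    out[ok] = 100.0 * (q[ok] - p[ok]) / np.abs(p[ok])
    return out


def bf_distance_octaves(bf_hz: float, reference_hz: float = CS_PLUS_HZ) -> float:
    """Absolute distance of a best frequency from a reference, in octaves."""
    if bf_hz <= 0 or reference_hz <= 0:
        raise ValueError("frequencies must be positive")
    return abs(math.log2(bf_hz / reference_hz))


def resample_by_bf_bin(
    neurons: list,
    bfs_hz: np.ndarray,
    n_bins: int = 12,
    seed: int | np.random.Generator = 0,
    freq_range: tuple[float, float] | None = None,
) -> list:
    """Equal-count resampling (with replacement) per log-spaced BF bin.

    Flattens the best-frequency distribution so that tuning-change
    comparisons between groups are not confounded by different pre-existing
    BF distributions. Empty bins are skipped. Deterministic under ``seed``.
    """
    import warnings

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    bfs = np.asarray(bfs_hz, dtype=float)
    if len(neurons) != bfs.size:
        raise ValueError("neurons and bfs_hz must have equal length")
    lo, hi = freq_range if freq_range else (bfs.min(), bfs.max())
    edges = np.logspace(np.log2(lo), np.log2(hi), n_bins + 1, base=2.0)
    idx = np.clip(np.digitize(bfs, edges) - 1, 0, n_bins - 1)
    per_bin = [np.nonzero(idx == b)[0] for b in range(n_bins)]
    occupied = [m for m in per_bin if m.size > 0]
    if len(occupied) < len(per_bin):
        warnings.warn(
            f"{len(per_bin) - len(occupied)} empty BF bin(s) skipped",
            stacklevel=2,
        )
    if not occupied:
        raise ValueError("no neurons to resample")
    count = max(m.size for m in occupied)
    out = []
    for members in occupied:
        take = rng.choice(members, size=count, replace=True)
        out.extend(neurons[i] for i in take)
    return out
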