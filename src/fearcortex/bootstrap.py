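"""Rank correlations with bootstrap confidence intervals.

Confidence intervals for a correlation are obtained by resampling the
(x, y) pairs with replacement 1000 times and taking the 2.5th/97.5th
percentiles of the bootstrap correlation distribution. Two correlations are
compared by differencing their bootstrap distributions (paired over
replicates when both correlations are computed on the same subjects); the
difference is significant when its 95% CI excludes zero.

The correlation recomputed inside the bootstrap defaults to Spearman for
internal consistency with the point estimate; a Pearson mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedSample",
    "spearman",
    "bootstrap_corr_ci",
    "corr_difference_test",
]


@dataclass
class PairedSample:
    """Paired per-subject observations (e.g., mean Z_diff vs LS)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.y.size:
            raise ValueError("x and y must have equal length")
        if self.x.size < 4:
            raise ValueError("need at least 4 pairs")

    @property
    def n(self) -> int:
        return self.x.size


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    return float(stats.spearmanr(x, y).statistic)


def _corr(x: np.ndarray, y: np.ndarray, flavor: str) -> float:
    if flavor == "spearman":
        return spearman(x, y)
    if flavor == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown correlation flavor {flavor!r}")


def _boot_distribution(
    sample: PairedSample,
    n_boot: int,
    rng: np.random.Generator,
    flavor: str,
) -> np.ndarray:
    """Bootstrap correlation distribution; degenerate resamples (constant x
    or y) are dropped."""
    n = sample.n
    out = np.empty(n_boot)
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = sample.x[idx], sample.y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            continue
        out[kept] = _corr(xb, yb, flavor)
        kept += 1
    if kept == 0:
        raise ValueError("all bootstrap resamples degenerate")
    return out[:kept]


def bootstrap_corr_ci(
    sample: PairedSample,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    flavor: str = "spearman",
) -> tuple[float, float, float, np.ndarray]:
    """Correlation point estimate with a percentile bootstrap 95% CI.

    Returns ``(r_point, ci_low, ci_high, boot_distribution)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    r_point = _corr(sample.x, sample.y, flavor)
    boot = _boot_distribution(sample, n_boot, rng, flavor)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return r_point, float(lo), float(hi), boot


def corr_difference_test(
    sample_a: PairedSample,
    sample_b: PairedSample,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    flavor: str = "spearman",
    paired: bool | None = None,
) -> tuple[float, tuple[float, float], float]:
    """Bootstrap test for the difference between two correlations.

    The difference distribution is ``boot_r(a) - boot_r(b)``. When
    ``paired`` (default if the samples have equal n, as when both
    correlations are computed on the same mice) the same resample indices
    drive both correlations in each replicate; otherwise the two bootstrap
    distributions are drawn independently.

    Returns ``(delta_r, (ci_low, ci_high), p)`` with the two-sided
    ``p = 2 * min(P(delta <= 0), P(delta >= 0))`` clipped to 1.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if paired is None:
        paired = sample_a.n == sample_b.n
    delta_point = _corr(sample_a.x, sample_a.y, flavor) - _corr(
        sample_b.x, sample_b.y, flavor
    )
    if paired:
        if sample_a.n != sample_b.n:
            raise ValueError("paired comparison requires equal sample sizes")
        deltas = []
        for _ in range(n_boot):
            idx = rng.integers(0, sample_a.n, size=sample_a.n)
            xa, ya = sample_a.x[idx], sample_a.y[idx]
            xb, yb = sample_b.x[idx], sample_b.y[idx]
            if min(np.ptp(xa), np.ptp(ya), np.ptp(xb), np.ptp(yb)) == 0:
                continue
            deltas.append(_corr(xa, ya, flavor) - _corr(xb, yb, flavor))
        deltas = np.asarray(deltas)
    else:
        boot_a = _boot_distribution(sample_a, n_boot, rng, flavor)
        boot_b = _boot_distribution(sample_b, n_boot, rng, flavor)
        m = min(boot_a.size, boot_b.size)
        deltas = boot_a[:m] - boot_b[:m]
    if deltas.size == 0:
        raise ValueError("all bootstrap replicates degenerate")
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    p = 2 * min(np.mean(deltas <= 0), np.mean(deltas >= 0))
    return float(delta_point), (float(lo), float(hi)), float(min(p, 1.0))
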