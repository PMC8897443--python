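"""Rate-based MGB -> AC -> BLA model of differential fear conditioning.

Ten frequency channels feed a thalamic (MGB) population with narrow Gaussian
tuning (sigma_mgb = 0.8 channels); the cortical (AC) population reads the
thalamic activity through a broader Gaussian kernel with a subtractive broad
inhibitory term (I_ctx = 0.9, gain 1/1.8) and feeds back to MGB channel by
channel. Both populations project to a single BLA unit whose input weights
are potentiated by a Delta rule (dw_i = alpha * x_i * shock, alpha = 0.1,
weights clipped to [0, 1], initialized at 0.1) during 10 conditioning steps
pairing the CS+ channel with a shock. Freezing to a tone is the BLA activity
normalized by its value with all weights at 1; model learning specificity is
freezing(CS+) - freezing(CS-). After conditioning, the cortical tuning width
sigma_ctx performs a bounded random walk (steps uniform in +-0.25, clipped
to [4, 20]) for 10,000 time-steps, modelling representational drift.

Tuning kernels use the conventional Gaussian form exp(-d^2 / (2 sigma^2)) on
the circular channel distance; ``exponent="linear"`` switches to a variant
with sigma entering the exponent unsquared, exp(-d^2 / (2 sigma)), for
sensitivity checks (see the methods note for why the squared form is the
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CircuitParams",
    "CircuitState",
    "Stimulus",
    "ExperimentResult",
    "circular_distance",
    "tuning_matrix",
    "forward",
    "delta_update",
    "freezing_response",
    "model_learning_specificity",
    "drift_step",
    "run_experiment",
    "tuning_ls_correlation_over_time",
    "sweep_tuning",
]

MANIPULATIONS = (
    "control",
    "reduced_inhibition",
    "ac_off_conditioning",
    "ac_off_recall",
)


@dataclass(frozen=True)
class CircuitParams:
    """Model constants. Channel indices are 1-based, as in the protocol
    description (CS+ = channel 3, CS- = channel 6)."""

    n_channels: int = 10
    sigma_mgb: float = 0.8
    sigma_ctx_init: float = 3.0       # 3 narrow | 10 broad
    inhibition_ctx: float = 0.9
    ctx_gain: float = 1.0 / 1.8
    alpha: float = 0.1
    w_init: float = 0.1
    w_bounds: tuple[float, float] = (0.0, 1.0)
    drift_amplitude: float = 0.25
    sigma_ctx_bounds: tuple[float, float] = (4.0, 20.0)
    n_conditioning_steps: int = 10
    n_drift_steps: int = 10_000
    cs_plus_channel: int = 3
    cs_minus_channel: int = 6
    exponent: str = "conventional"    # "conventional" (2 sigma^2) | "linear" (2 sigma)
    feedback: str = "matched"         # "matched" (channel-wise) | "summed"

    def __post_init__(self) -> None:
        if self.n_channels < 2 or self.n_conditioning_steps < 1:
            raise ValueError("counts must be positive")
        if self.w_bounds[0] >= self.w_bounds[1] or self.sigma_ctx_bounds[0] >= self.sigma_ctx_bounds[1]:
            raise ValueError("bounds must be ordered")
        if self.exponent not in ("conventional", "linear"):
            raise ValueError("exponent must be 'conventional' or 'linear'")
        if self.feedback not in ("matched", "summed"):
            raise ValueError("feedback must be 'matched' or 'summed'")


@dataclass
class CircuitState:
    """Mutable simulation state: BLA input weights and current AC width."""

    w_mgb: np.ndarray
    w_ctx: np.ndarray
    sigma_ctx: float
    rng: np.random.Generator

    @classmethod
    def initial(cls, params: CircuitParams, seed: int | np.random.Generator = 0) -> "CircuitState":
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        n = params.n_channels
        return cls(
            w_mgb=np.full(n, params.w_init),
            w_ctx=np.full(n, params.w_init),
            sigma_ctx=params.sigma_ctx_init,
            rng=rng,
        )


@dataclass
class Stimulus:
    """Channel activities plus the shock (teaching) signal."""

    s: np.ndarray
    shock: int = 0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if not np.isfinite(self.s).all():
            raise ValueError("stimulus must be finite")
        if self.shock not in (0, 1):
            raise ValueError("shock must be 0 or 1")

    @classmethod
    def tone(cls, channel_1based: int, n: int = 10, shock: int = 0) -> "Stimulus":
        s = np.zeros(n)
        s[channel_1based - 1] = 1.0
        return cls(s=s, shock=shock)


@dataclass
class ExperimentResult:
    manipulation: str
    tuning: str
    ls_at_conditioning: float
    ls_after_drift: float
    freezing: dict[str, float] = field(default_factory=dict)
    sigma_ctx_final: float = float("nan")


def circular_distance(i: int, j: int, n: int) -> int:
    """Ring distance between channels (input 1 and input n are neighbors)."""
    d = abs(i - j)
    return min(d, n - d)


def tuning_matrix(
    sigma: float,
    inhibition: float = 0.0,
    gain: float = 1.0,
    n: int = 10,
    exponent: str = "conventional",
) -> np.ndarray:
    """Rectified circular-Gaussian tuning kernel.

    T_ij = gain * [exp(-d(i,j)^2 / (2 sigma^2)) - inhibition]_+  with d the
    circular channel distance. The MGB kernel uses gain 1, no inhibition;
    the cortical kernel uses gain 1/1.8 and the broad inhibitory term.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    d = np.minimum(d, n - d)
    denom = 2 * sigma**2 if exponent == "conventional" else 2 * sigma
    return gain * np.maximum(np.exp(-(d.astype(float) ** 2) / denom) - inhibition, 0.0)


def forward(
    params: CircuitParams,
    state: CircuitState,
    stim: Stimulus,
    inhibition: float | None = None,
    ac_off: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One feedforward-then-feedback pass through MGB and AC.

    x0 = T_mgb s; x_ctx = T_ctx x0; x_mgb = x0 + feedback, where the
    feedback is x_ctx channel-wise ("matched", tonotopically organized) or
    its sum broadcast to every channel ("summed"). ``ac_off`` silences the
    cortex (x_ctx = 0, no feedback).
    """
    inhib = params.inhibition_ctx if inhibition is None else inhibition
    t_mgb = tuning_matrix(
        params.sigma_mgb, 0.0, 1.0, params.n_channels, params.exponent
    )
    x0 = t_mgb @ stim.s
    if ac_off:
        x_ctx = np.zeros(params.n_channels)
    else:
        t_ctx = tuning_matrix(
            state.sigma_ctx, inhib, params.ctx_gain, params.n_channels, params.exponent
        )
        x_ctx = t_ctx @ x0
    fb = np.full(params.n_channels, x_ctx.sum()) if params.feedback == "summed" else x_ctx
    return x0 + fb, x_ctx


def delta_update(
    params: CircuitParams,
    state: CircuitState,
    x_mgb: np.ndarray,
    x_ctx: np.ndarray,
    shock: int,
) -> CircuitState:
    """Delta-rule weight update: w <- clip(w + alpha * x * shock)."""
    if shock:
        lo, hi = params.w_bounds
        state.w_mgb = np.clip(state.w_mgb + params.alpha * x_mgb, lo, hi)
        state.w_ctx = np.clip(state.w_ctx + params.alpha * x_ctx, lo, hi)
    return state


def freezing_response(
    params: CircuitParams,
    state: CircuitState,
    stim: Stimulus,
    ac_off: bool = False,
) -> float:
    """Normalized BLA activity to an auditory input (no shock).

    y = w_mgb . x_mgb + w_ctx . x_ctx, divided by the same quantity with all
    weights at 1. ``ac_off`` zeroes the cortical activity in both numerator
    and normalizer.
    """
    x_mgb, x_ctx = forward(params, state, stim, ac_off=ac_off)
    y = state.w_mgb @ x_mgb + state.w_ctx @ x_ctx
    y_max = x_mgb.sum() + x_ctx.sum()
    if y_max == 0:
        raise ZeroDivisionError("zero normalizer: no activity reaches BLA")
    return float(y / y_max)


def model_learning_specificity(
    params: CircuitParams, state: CircuitState, ac_off: bool = False
) -> float:
    """freezing(CS+) - freezing(CS-)."""
    n = params.n_channels
    f_plus = freezing_response(params, state, Stimulus.tone(params.cs_plus_channel, n), ac_off)
    f_minus = freezing_response(params, state, Stimulus.tone(params.cs_minus_channel, n), ac_off)
    return f_plus - f_minus


def drift_step(params: CircuitParams, state: CircuitState) -> CircuitState:
    """One tuning-drift step: sigma_ctx += U(-a, a), clipped to its bounds.

    Weights are untouched; no plasticity occurs without a shock.
    """
    a = params.drift_amplitude
    lo, hi = params.sigma_ctx_bounds
    state.sigma_ctx = float(np.clip(state.sigma_ctx + state.rng.uniform(-a, a), lo, hi))
    return state


def _condition(
    params: CircuitParams,
    state: CircuitState,
    inhibition: float | None,
    ac_off: bool,
) -> CircuitState:
    stim = Stimulus.tone(params.cs_plus_channel, params.n_channels, shock=1)
    for _ in range(params.n_conditioning_steps):
        x_mgb, x_ctx = forward(params, state, stim, inhibition=inhibition, ac_off=ac_off)
        state = delta_update(params, state, x_mgb, x_ctx, stim.shock)
    return state


def run_experiment(
    params: CircuitParams,
    manipulation: str = "control",
    seed: int | np.random.Generator = 0,
) -> ExperimentResult:
    """Conditioning, readout, drift, readout — under one manipulation.

    * ``control``: plain protocol.
    * ``reduced_inhibition``: I_ctx = 0.45 during conditioning (half the
      normal level); readout and normalizer use the intact I_ctx = 0.9.
    * ``ac_off_conditioning``: cortex silenced (activity and feedback)
      during conditioning only.
    * ``ac_off_recall``: cortex silenced during every freezing readout
      (numerator and normalizer), conditioning intact.

    LS is measured immediately after the 10 conditioning steps and again
    after the 10,000-step tuning drift. The drift runs at the clipped
    sigma bounds; conditioning runs at the unclipped initial value.
    """
    if manipulation not in MANIPULATIONS:
        raise ValueError(f"unknown manipulation {manipulation!r}")
    state = CircuitState.initial(params, seed)
    cond_inhib = 0.45 if manipulation == "reduced_inhibition" else None
    cond_ac_off = manipulation == "ac_off_conditioning"
    recall_ac_off = manipulation == "ac_off_recall"
    state = _condition(params, state, cond_inhib, cond_ac_off)

    ls_t0 = model_learning_specificity(params, state, ac_off=recall_ac_off)
    n = params.n_channels
    freezing = {
        "cs_plus_t0": freezing_response(params, state, Stimulus.tone(params.cs_plus_channel, n), recall_ac_off),
        "cs_minus_t0": freezing_response(params, state, Stimulus.tone(params.cs_minus_channel, n), recall_ac_off),
    }
    for _ in range(params.n_drift_steps):
        state = drift_step(params, state)
    ls_t1 = model_learning_specificity(params, state, ac_off=recall_ac_off)
    freezing.update(
        cs_plus_drift=freezing_response(params, state, Stimulus.tone(params.cs_plus_channel, n), recall_ac_off),
        cs_minus_drift=freezing_response(params, state, Stimulus.tone(params.cs_minus_channel, n), recall_ac_off),
    )
    tuning = "narrow" if params.sigma_ctx_init <= 5 else "broad"
    return ExperimentResult(
        manipulation=manipulation,
        tuning=tuning,
        ls_at_conditioning=ls_t0,
        ls_after_drift=ls_t1,
        freezing=freezing,
        sigma_ctx_final=state.sigma_ctx,
    )


def tuning_ls_correlation_over_time(
    params: CircuitParams,
    n_model_mice: int = 20,
    sigma_range: tuple[float, float] = (3.0, 10.0),
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Correlation between AC discriminability and LS, at t=0 and post-drift.

    Simulates model subjects with heterogeneous initial sigma_ctx and
    correlates inverse tuning width (discriminability) with LS immediately
    after conditioning and after the drift period. Returns
    ``(r_t0, r_after_drift)`` (Pearson).
    """
    from scipy import stats

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sigmas = np.linspace(*sigma_range, n_model_mice)
    ls0, ls1 = [], []
    for sig in sigmas:
        p = replace(params, sigma_ctx_init=float(sig))
        res = run_experiment(p, "control", seed=rng)
        ls0.append(res.ls_at_conditioning)
        ls1.append(res.ls_after_drift)
    inv_width = 1.0 / sigmas
    r0 = float(stats.pearsonr(inv_width, ls0).statistic)
    r1 = float(stats.pearsonr(inv_width, ls1).statistic)
    return r0, r1


def sweep_tuning(
    params: CircuitParams,
    sigma_grid: np.ndarray,
    seed: int | np.random.Generator = 0,
    normalize: bool = True,
) -> dict[str, np.ndarray]:
    """LS as a function of initial AC tuning width, pre- and post-drift.

    When ``normalize`` is set, both curves are divided by the maximum LS
    across the whole sweep.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    ls0 = np.empty(sigma_grid.size)
    ls1 = np.empty(sigma_grid.size)
    for k, sig in enumerate(sigma_grid):
        res = run_experiment(replace(params, sigma_ctx_init=float(sig)), "control", seed=rng)
        ls0[k] = res.ls_at_conditioning
        ls1[k] = res.ls_after_drift
    if normalize:
        peak = max(ls0.max(), ls1.max())
        if peak > 0:
            ls0, ls1 = ls0 / peak, ls1 / peak
    return {"sigma_ctx": sigma_grid, "ls_post_conditioning": ls0, "ls_post_drift": ls1}
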