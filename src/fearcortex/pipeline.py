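"""End-to-end orchestration on synthetic cohorts.

Simulate a cohort, score behavior, compute single-neuron and population
discriminability per mouse and session, correlate neural measures with
learning specificity (with bootstrap confidence intervals), and run the
circuit-model experiments — producing the figure-level tables of a
differential-fear-conditioning imaging study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from .bootstrap import PairedSample, bootstrap_corr_ci, corr_difference_test, spearman
from .circuit import MANIPULATIONS, CircuitParams, run_experiment
from .cohort import CohortConfig, MouseData, SyntheticCohort, generate_cohort
from .decoding import resampled_metric, svm_cv_performance

__all__ = [
    "RunConfig",
    "mean_zdiff_per_mouse",
    "svm_per_mouse",
    "behavioral_ls",
    "model_panel",
    "run_full_pipeline",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic-cohort analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_resamples: int = 20       # neuron resamples for per-mouse SVM metrics
    svm_folds: int = 10
    n_boot: int = 1000
    model_seeds: int = 20
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.cohort.n_pre_sessions > self.cohort.n_sessions:
            raise ValueError("session groupings exceed n_sessions")

    @property
    def pre_sessions(self) -> tuple[int, ...]:
        return tuple(range(1, self.cohort.n_pre_sessions + 1))

    @property
    def post_sessions(self) -> tuple[int, ...]:
        return tuple(range(self.cohort.n_pre_sessions + 1, self.cohort.n_sessions + 1))


def _zdiff_vector(r_plus: np.ndarray, r_minus: np.ndarray) -> np.ndarray:
    """Z_diff for every neuron at once (NaN where a SD is zero)."""
    sp = r_plus.std(axis=1, ddof=1)
    sm = r_minus.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(r_plus.mean(axis=1) - r_minus.mean(axis=1)) / np.sqrt(sp * sm)
    z[(sp == 0) | (sm == 0)] = np.nan
    return z


def _holm_any_reject(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Row-wise Holm-Bonferroni: does any test in the row survive?

    Vectorized equivalent of the per-neuron responsiveness call; the Holm
    criterion rejects anything iff min_i (m - i) * p_(i) ... the step-down
    procedure stops at the first non-rejection, so 'any reject' reduces to
    the smallest p-value beating alpha / m.
    """
    m = pvals.shape[1]
    return pvals.min(axis=1) * m < alpha


def _responsive_mask(responses: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Sound-responsiveness for all neurons of a session (neurons x freq x
    repeat), one-sample t-tests with Holm correction over frequencies."""
    from scipy import stats

    res = stats.ttest_1samp(responses, 0.0, axis=2)
    pvals = np.asarray(res.pvalue)
    means = responses.mean(axis=2)
    sds = responses.std(axis=2, ddof=1)
    pvals = np.where(sds == 0, np.where(means != 0, 0.0, 1.0), pvals)
    return _holm_any_reject(pvals, alpha)


def mean_zdiff_per_mouse(
    cohort: SyntheticCohort,
    sessions: tuple[int, ...],
    responsive_only: bool = True,
) -> pd.DataFrame:
    """Mean Z_diff of (responsive) neurons per mouse, averaged over sessions."""
    rows = []
    for mouse in cohort.mice:
        per_session = []
        for s in sessions:
            r_plus, r_minus = cohort.cs_repeats(mouse, s)
            z = _zdiff_vector(r_plus, r_minus)
            if responsive_only:
                mask = _responsive_mask(mouse.responses[s - 1])
                z = z[mask]
            z = z[np.isfinite(z)]
            if z.size:
                per_session.append(z.mean())
        rows.append(
            (mouse.mouse_id, mouse.group, mouse.ls_true,
             float(np.mean(per_session)) if per_session else np.nan)
        )
    return pd.DataFrame(rows, columns=["mouse_id", "group", "ls_true", "mean_zdiff"])


def svm_per_mouse(
    cohort: SyntheticCohort,
    sessions: tuple[int, ...],
    n_resamples: int = 20,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-mouse linear-SVM CS+/CS- accuracy under min-neuron resampling,
    averaged over the requested sessions."""
    rng = np.random.default_rng(seed)
    per_mouse: dict[str, list[float]] = {m.mouse_id: [] for m in cohort.mice}
    for s in sessions:
        pops = {m.mouse_id: cohort.population(m, s) for m in cohort.mice}
        fold_seed = int(rng.integers(2**31))
        res = resampled_metric(
            pops,
            lambda pop, _rng: svm_cv_performance(pop, folds=folds, seed=fold_seed),
            n_resamples=n_resamples,
            seed=rng,
        )
        for mouse_id, (mean_acc, _sd) in res.items():
            per_mouse[mouse_id].append(mean_acc)
    rows = [
        (m.mouse_id, m.group, m.ls_true, float(np.mean(per_mouse[m.mouse_id])))
        for m in cohort.mice
    ]
    return pd.DataFrame(rows, columns=["mouse_id", "group", "ls_true", "svm_accuracy"])


def behavioral_ls(cohort: SyntheticCohort) -> pd.DataFrame:
    """Score every retrieval-session motion trace into LS per mouse/session."""
    rows = []
    for mouse in cohort.mice:
        for session, trace in sorted(mouse.motion.items()):
            record = bh.score_session(trace)
            rows.append(
                (
                    mouse.mouse_id,
                    mouse.group,
                    session,
                    bh.learning_specificity(record),
                    float(np.mean(record.fr_baseline)) if record.fr_baseline else np.nan,
                )
            )
    return pd.DataFrame(
        rows, columns=["mouse_id", "group", "session", "ls", "baseline_freezing"]
    )


def model_panel(
    params: CircuitParams | None = None,
    n_seeds: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Circuit-model manipulation table (both tunings, all manipulations)."""
    params = params or CircuitParams()
    rows = []
    root = np.random.SeedSequence(seed)
    for sig, tuning in ((3.0, "narrow"), (10.0, "broad")):
        p = replace(params, sigma_ctx_init=sig)
        for manip in MANIPULATIONS:
            for k, child in enumerate(root.spawn(n_seeds)):
                res = run_experiment(p, manip, seed=np.random.default_rng(child))
                rows.append(
                    (manip, tuning, k, res.ls_at_conditioning, res.ls_after_drift)
                )
    return pd.DataFrame(
        rows, columns=["manipulation", "tuning", "seed", "ls_t0", "ls_after_drift"]
    )


def _corr_block(x: np.ndarray, y: np.ndarray, n_boot: int, seed: int) -> dict:
    sample = PairedSample(x=x, y=y)
    r, lo, hi, _ = bootstrap_corr_ci(sample, n_boot=n_boot, seed=seed)
    return {"r": r, "ci_low": lo, "ci_high": hi, "n": sample.n}


def run_full_pipeline(config: RunConfig) -> dict:
    """Simulate, analyse, and report. Deterministic for a fixed config.

    Returns a report dict with per-mouse tables, the correlation analyses
    (pre-DFC neural measures vs learning specificity), and the
    circuit-model manipulation panel. If ``config.outdir`` is set, tables
    are also written as CSV.
    """
    cohort = generate_cohort(config.cohort)
    seed = config.cohort.seed

    zdiff_pre = mean_zdiff_per_mouse(cohort, config.pre_sessions)
    zdiff_post = (
        mean_zdiff_per_mouse(cohort, config.post_sessions)
        if config.post_sessions
        else None
    )
    zdiff_last_pre = mean_zdiff_per_mouse(cohort, (config.pre_sessions[-1],))
    svm_pre = svm_per_mouse(
        cohort, config.pre_sessions, config.n_resamples, config.svm_folds, seed
    )
    ls_table = behavioral_ls(cohort) if config.cohort.include_motion else None

    cond = zdiff_pre["group"] == "conditioned"
    x_z = zdiff_pre.loc[cond, "mean_zdiff"].to_numpy()
    x_zlast = zdiff_last_pre.loc[cond, "mean_zdiff"].to_numpy()
    x_svm = svm_pre.loc[cond, "svm_accuracy"].to_numpy()
    y_ls = zdiff_pre.loc[cond, "ls_true"].to_numpy()

    correlations = {
        "zdiff_pre_vs_ls": _corr_block(x_z, y_ls, config.n_boot, seed + 1),
        "zdiff_last_pre_vs_ls": _corr_block(x_zlast, y_ls, config.n_boot, seed + 2),
        "svm_pre_vs_ls": _corr_block(x_svm, y_ls, config.n_boot, seed + 3),
        "svm_vs_zdiff": _corr_block(x_svm, x_z, config.n_boot, seed + 4),
    }
    delta, ci, p = corr_difference_test(
        PairedSample(x=x_z, y=y_ls),
        PairedSample(x=x_zlast, y=y_ls),
        n_boot=config.n_boot,
        seed=seed + 5,
    )
    correlations["zdiff_pre_minus_last_pre"] = {
        "delta_r": delta, "ci_low": ci[0], "ci_high": ci[1], "p": p
    }

    panel = model_panel(n_seeds=config.model_seeds, seed=seed + 6)

    report = {
        "manifest": cohort.manifest(),
        "zdiff_pre": zdiff_pre,
        "zdiff_post": zdiff_post,
        "svm_pre": svm_pre,
        "behavior_ls": ls_table,
        "correlations": correlations,
        "model_panel": panel,
        "spearman_zdiff_ls": spearman(x_z, y_ls),
        "spearman_svm_zdiff": spearman(x_svm, x_z),
        "seed": seed,
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("manifest", "zdiff_pre", "zdiff_post", "svm_pre", "behavior_ls", "model_panel"):
            tbl = report[name]
            if tbl is not None:
                tbl.to_csv(out / f"{name}.csv", index=False)
        pd.DataFrame(correlations).T.to_csv(out / "correlations.csv")
    return report
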