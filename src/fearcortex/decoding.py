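"""Population decoding of CS+ vs CS- with a linear support-vector machine.

Single-trial population response vectors are classified with a linear-kernel
SVM under stratified 10-fold cross-validation; features are standardized
inside each training fold only. Because mice contribute different neuron
counts, per-mouse metrics are computed on populations repeatedly resampled
(with replacement) down to the smallest neuron count in the cohort.

Cross-session decoder transfer (train on one day, test the same tracked
neurons on another day) and the session-pair correlation of per-neuron
Z_diff scores quantify representational drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "PopulationTrials",
    "svm_cv_performance",
    "resampled_metric",
    "cross_session_svm",
    "zdiff_similarity",
]


@dataclass
class PopulationTrials:
    """Single-trial population responses with CS labels.

    ``X`` is trials x neurons; ``y`` holds the labels (+1 for CS+, -1 for
    CS-, any two distinct values work). ``neuron_ids`` allows restriction to
    tracked neurons across sessions.
    """

    X: np.ndarray
    y: np.ndarray
    neuron_ids: np.ndarray | None = None
    session_id: int | str = 0
    mouse_id: int | str = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be trials x neurons, aligned with y")
        if np.unique(self.y).size < 2:
            raise ValueError("both stimulus classes must be present")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing entries")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.X.shape[1])
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
            if self.neuron_ids.size != self.X.shape[1]:
                raise ValueError("neuron_ids must match the number of columns")

    @property
    def n_neurons(self) -> int:
        return self.X.shape[1]

    def subset(self, columns: np.ndarray) -> "PopulationTrials":
        return PopulationTrials(
            X=self.X[:, columns],
            y=self.y.copy(),
            neuron_ids=np.asarray(self.neuron_ids)[columns],
            session_id=self.session_id,
            mouse_id=self.mouse_id,
        )


def _linear_svm(C: float = 1.0):
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))


def svm_cv_performance(
    pop: PopulationTrials,
    folds: int = 10,
    seed: int | np.random.Generator = 0,
    C: float = 1.0,
) -> float:
    """Mean held-out accuracy of a linear SVM over stratified folds."""
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**31))
    _, counts = np.unique(pop.y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"need at least {folds} trials per class")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in cv.split(pop.X, pop.y):
        clf = _linear_svm(C)
        clf.fit(pop.X[train], pop.y[train])
        accs.append(clf.score(pop.X[test], pop.y[test]))
    return float(np.mean(accs))


def resampled_metric(
    populations: Mapping[object, PopulationTrials],
    metric: Callable[[PopulationTrials, np.random.Generator], float],
    n_resamples: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict[object, tuple[float, float]]:
    """Per-mouse metric under neuron resampling at the cohort minimum.

    For every mouse, ``n_resamples`` populations of ``n*`` neurons (the
    smallest neuron count across mice) are drawn with replacement and the
    metric is averaged. Returns ``{mouse: (mean, sd)}``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_star = min(p.n_neurons for p in populations.values())
    out: dict[object, tuple[float, float]] = {}
    for mouse, pop in populations.items():
        vals = []
        for _ in range(n_resamples):
            cols = rng.integers(0, pop.n_neurons, size=n_star)
            vals.append(metric(pop.subset(cols), rng))
        out[mouse] = (float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
    return out


def cross_session_svm(
    train: PopulationTrials,
    test: PopulationTrials,
    tracked_ids: np.ndarray,
    folds: int = 10,
    seed: int | np.random.Generator = 0,
    C: float = 1.0,
) -> tuple[float, float, float]:
    """Decoder transfer across sessions on tracked neurons.

    Fits the SVM on the training session restricted to ``tracked_ids`` (the
    internal cross-validated accuracy is ``train_perf``), then freezes a
    decoder fit on all training trials and scores it on the same neurons'
    trials from the test session. Returns
    ``(train_perf, test_perf, deficit)`` with ``deficit = train - test``.
    """
    tracked_ids = np.asarray(tracked_ids)

    def columns(pop: PopulationTrials) -> np.ndarray:
        ids = list(np.asarray(pop.neuron_ids))
        try:
            return np.array([ids.index(t) for t in tracked_ids])
        except ValueError as err:
            raise ValueError("tracked id missing from session") from err

    tr = train.subset(columns(train))
    te = test.subset(columns(test))
    train_perf = svm_cv_performance(tr, folds=folds, seed=seed, C=C)
    clf = _linear_svm(C)
    clf.fit(tr.X, tr.y)
    test_perf = float(clf.score(te.X, te.y))
    return train_perf, test_perf, train_perf - test_perf


def zdiff_similarity(
    session_a_zdiffs: Mapping[object, float],
    session_b_zdiffs: Mapping[object, float],
    tracked_ids: np.ndarray | None = None,
) -> float:
    """Pearson correlation of per-neuron Z_diff between two sessions.

    Only neurons with a finite Z_diff in both sessions enter; at least 3 are
    required.
    """
    if tracked_ids is None:
        tracked_ids = np.array(
            sorted(set(session_a_zdiffs) & set(session_b_zdiffs), key=str)
        )
    a, b = [], []
    for t in tracked_ids:
        va = session_a_zdiffs.get(t)
        vb = session_b_zdiffs.get(t)
        if va is not None and vb is not None and np.isfinite(va) and np.isfinite(vb):
            a.append(va)
            b.append(vb)
    if len(a) < 3:
        raise ValueError("need at least 3 tracked neurons with valid Z_diff")
    return float(stats.pearsonr(a, b).statistic)
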