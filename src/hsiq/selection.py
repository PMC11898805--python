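"""Wavelength selection: interval random frog (iRF) and VCPA.

Both selectors search for the small set of bands that carries the chemical
signal, scoring candidate subsets with a cross-validated latent-variable
fit (RMSECV for content targets, CV misclassification for class targets;
lower is fitter).

*iRF* runs a reversible-jump pseudo-MCMC chain over subsets of contiguous
wavelength intervals: each step proposes adding or removing one interval,
accepts outright if the candidate is fitter and otherwise with probability
equal to the (current/candidate) objective ratio clipped to [0, 1].  A
band's score is the chain visitation frequency of the best interval
covering it.

*VCPA* repeatedly draws random variable combinations by binary matrix
sampling, keeps the fittest fraction, and shrinks the retained pool along
an exponentially decreasing function (EDF) down to a small final pool that
is searched exhaustively ("survival of the fittest").
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold

from .pls import PLS1

REGRESSION = "regression"
CLASSIFICATION = "classification"


@dataclass(frozen=True)
class FitnessSpec:
    """Cross-validated fitness for subset scoring.

    ``task='regression'`` scores RMSECV of a PLS fit; ``'classification'``
    scores the CV misclassification fraction of its discriminant variant
    (PLS-DA: regress a 0/1 coding, threshold at 0.5).
    """

    task: str = REGRESSION
    max_latent: int = 10
    folds: int = 5

    def __post_init__(self) -> None:
        if self.task not in (REGRESSION, CLASSIFICATION):
            raise ValueError(f"unknown task {self.task!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.max_latent < 1:
            raise ValueError("max_latent must be >= 1")


@dataclass(frozen=True)
class IntervalSet:
    """Half-open [start, end) index intervals over a wavelength grid."""

    intervals: tuple[tuple[int, int], ...]
    width: int
    step: int

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("need at least one interval")
        starts = [s for s, _ in self.intervals]
        if starts != sorted(starts):
            raise ValueError("intervals must be ordered by start")
        for s, e in self.intervals:
            if not (0 <= s < e):
                raise ValueError(f"bad interval ({s}, {e})")

    def __len__(self) -> int:
        return len(self.intervals)

    def indices(self, which: int) -> np.ndarray:
        s, e = self.intervals[which]
        return np.arange(s, e)

    def union_indices(self, members: set[int] | list[int]) -> np.ndarray:
        idx: set[int] = set()
        for m in members:
            s, e = self.intervals[m]
            idx.update(range(s, e))
        return np.array(sorted(idx), dtype=int)


@dataclass
class SelectionResult:
    """Outcome of one selection run.

    ``scores`` holds a per-wavelength value in [0, 1] (chain selection
    probability for iRF, final-population inclusion frequency for VCPA);
    ``selected`` the chosen band indices; ``trace`` per-iteration
    diagnostics (chain model size for iRF, (retained count, best fitness)
    per EDF run for VCPA).
    """

    method: str
    scores: np.ndarray
    selected: np.ndarray
    trace: list
    config: dict
    seed: int
    data_fingerprint: str = ""

    def to_json(self, path: str | Path, wavelengths_nm: np.ndarray | None = None) -> None:
        if wavelengths_nm is not None:
            scores = {f"{wavelengths_nm[i]:.4f}": float(s)
                      for i, s in enumerate(self.scores)}
            selected = [float(wavelengths_nm[i]) for i in self.selected]
        else:
            scores = {str(i): float(s) for i, s in enumerate(self.scores)}
            selected = [int(i) for i in self.selected]
        payload = {
            "method": self.method,
            "config": self.config,
            "seed": self.seed,
            "data_fingerprint": self.data_fingerprint,
            "scores": scores,
            "selected": selected,
            "selected_indices": [int(i) for i in self.selected],
            "trace": self.trace,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def data_fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    """Stable hash of the (X, y) a selection was computed on (leakage guard)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.asarray(X, dtype=float)).tobytes())
    h.update(np.ascontiguousarray(np.asarray(y)).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Fitness


def _encode_target(y: np.ndarray, fitness: FitnessSpec) -> np.ndarray:
    y = np.asarray(y)
    if fitness.task == CLASSIFICATION:
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(
                f"classification fitness needs exactly 2 classes, got {classes.size}"
            )
        return (y == classes[1]).astype(float)
    y = y.astype(float)
    if np.ptp(y) == 0:
        raise ValueError("constant target: fitness undefined")
    return y


def fitness_cv(
    X_subset: np.ndarray,
    y: np.ndarray,
    fitness: FitnessSpec,
    seed: int = 0,
) -> float:
    """Mean CV objective of the internal latent-variable model on a subset.

    Returns RMSECV for regression or the pooled CV misclassification
    fraction for classification; deterministic for a given seed.
    """
    X_subset = np.asarray(X_subset, dtype=float)
    if X_subset.ndim == 1:
        X_subset = X_subset[:, None]
    n, p = X_subset.shape
    if p == 0:
        raise ValueError("empty wavelength subset")
    if fitness.folds > n:
        raise ValueError(f"folds ({fitness.folds}) exceed sample count ({n})")
    y_enc = _encode_target(y, fitness)

    kf = KFold(n_splits=fitness.folds, shuffle=True, random_state=seed % (2**31))
    sq_err = 0.0
    n_wrong = 0
    for train_idx, test_idx in kf.split(X_subset):
        cap = min(fitness.max_latent, p, max(1, train_idx.size - 1))
        model = PLS1(n_components=cap).fit(X_subset[train_idx], y_enc[train_idx])
        pred = model.predict(X_subset[test_idx])
        if fitness.task == REGRESSION:
            sq_err += float(np.sum((pred - y_enc[test_idx]) ** 2))
        else:
            n_wrong += int(np.sum((pred >= 0.5) != (y_enc[test_idx] >= 0.5)))
    if fitness.task == REGRESSION:
        return float(np.sqrt(sq_err / n))
    return n_wrong / n


# ---------------------------------------------------------------------------
# Interval random frog


def make_intervals(
    grid_len: int, width: int, step: int, include_partial: bool = False
) -> IntervalSet:
    """Tile [0, grid_len) with [k*step, k*step + width) windows.

    A trailing partial window (shorter than ``width``) is appended only
    when ``include_partial`` is set.
    """
    if not (1 <= width <= grid_len):
        raise ValueError(f"width {width} outside [1, {grid_len}]")
    if step < 1:
        raise ValueError("step must be >= 1")
    intervals = []
    k = 0
    while k * step + width <= grid_len:
        intervals.append((k * step, k * step + width))
        k += 1
    if include_partial and k * step < grid_len:
        intervals.append((k * step, grid_len))
    return IntervalSet(intervals=tuple(intervals), width=width, step=step)


def _validate_xy(X: np.ndarray, y: np.ndarray, fitness: FitnessSpec) -> tuple:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x bands)")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    if X.shape[0] < 2 * fitness.folds:
        raise ValueError("need at least 2 samples per CV fold")
    _encode_target(y, fitness)  # raises on constant / non-binary targets
    return X, y


def irf_select(
    X: np.ndarray,
    y: np.ndarray,
    intervals: IntervalSet,
    fitness: FitnessSpec,
    n_iterations: int = 1000,
    n_keep: int = 10,
    seed: int = 0,
    acceptance_sharpness: float = 10.0,
    burn_in: float = 0.2,
) -> SelectionResult:
    """Random-frog chain over interval subsets.

    The chain state is a non-empty subset of intervals.  Each iteration
    proposes a dimension jump (add or remove one interval, chosen uniformly
    among the legal moves); a fitter candidate is always accepted, a worse
    one with probability (current/candidate objective) raised to
    ``acceptance_sharpness``.  Cross-validated objectives differ by only a
    few percent between informative and diluted subsets, so the exponent
    (Metropolis sampling of pi(S) proportional to obj(S)^-sharpness) is
    what turns those small ratios into decisive accept/reject decisions;
    sharpness 1 recovers the plain ratio rule.  An interval's selection
    probability is its post-burn-in visitation frequency; the union of the
    ``n_keep`` most-visited intervals is returned as the selected
    wavelength set (frequency ties broken by ascending start).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if acceptance_sharpness <= 0:
        raise ValueError("acceptance_sharpness must be positive")
    if not 0.0 <= burn_in < 1.0:
        raise ValueError("burn_in fraction must lie in [0, 1)")
    X, y = _validate_xy(X, y, fitness)
    m = len(intervals)
    n_keep = min(n_keep, m)
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31))  # one CV assignment for the whole chain

    cache: dict[frozenset, float] = {}

    def objective(members: frozenset) -> float:
        if members not in cache:
            cols = intervals.union_indices(members)
            cache[members] = fitness_cv(X[:, cols], y, fitness, seed=cv_seed)
        return cache[members]

    # start small: a handful of intervals mixes far faster than half the set
    state = frozenset(np.flatnonzero(rng.random(m) < min(0.5, 4.0 / m)))
    if not state:
        state = frozenset({int(rng.integers(m))})
    cur_obj = objective(state)

    n_burn = int(burn_in * n_iterations)
    counts = np.zeros(m)
    trace: list[int] = []
    for it in range(n_iterations):
        moves = []
        if len(state) < m:
            moves.append("add")
        if len(state) > 1:
            moves.append("remove")
        if moves:
            move = moves[int(rng.integers(len(moves)))]
            if move == "add":
                pool = [i for i in range(m) if i not in state]
                cand = state | {pool[int(rng.integers(len(pool)))]}
            else:
                pool = sorted(state)
                cand = state - {pool[int(rng.integers(len(pool)))]}
            cand_obj = objective(cand)
            if cand_obj <= cur_obj:
                accept = True
            else:
                ratio = cur_obj / cand_obj if cand_obj > 0 else 0.0
                accept = rng.random() < min(1.0, ratio) ** acceptance_sharpness
            if accept:
                state, cur_obj = cand, cand_obj
        if it >= n_burn:
            counts[list(state)] += 1
        trace.append(len(state))

    probs = counts / max(1, n_iterations - n_burn)

    scores = np.zeros(X.shape[1])
    for i, (s, e) in enumerate(intervals.intervals):
        scores[s:e] = np.maximum(scores[s:e], probs[i])

    order = sorted(range(m), key=lambda i: (-probs[i], intervals.intervals[i][0]))
    selected = intervals.union_indices(order[:n_keep])

    return SelectionResult(
        method="iRF",
        scores=scores,
        selected=selected,
        trace=trace,
        config={
            "n_iterations": n_iterations,
            "n_keep": n_keep,
            "acceptance_sharpness": acceptance_sharpness,
            "burn_in": burn_in,
            "width": intervals.width,
            "step": intervals.step,
            "fitness": {"task": fitness.task, "max_latent": fitness.max_latent,
                        "folds": fitness.folds},
            "interval_probabilities": [float(p) for p in probs],
        },
        seed=seed,
        data_fingerprint=data_fingerprint(X, y),
    )


# ---------------------------------------------------------------------------
# VCPA


def edf_schedule(p: int, final_pool: int, n_runs: int) -> list[int]:
    """Retained-variable counts N_i = round(p * exp(-k*i)), i = 1..n_runs,
    with k chosen so the last run retains exactly ``final_pool`` variables."""
    if not (1 <= final_pool <= p):
        raise ValueError("need 1 <= final_pool <= p")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    k = np.log(p / final_pool) / n_runs
    sched = [int(round(p * np.exp(-k * i))) for i in range(1, n_runs + 1)]
    sched[-1] = final_pool
    return sched


def vcpa_select(
    X: np.ndarray,
    y: np.ndarray,
    fitness: FitnessSpec,
    n_edf_runs: int = 50,
    n_bms: int = 1000,
    keep_ratio: float = 0.1,
    final_pool: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Variable combination population analysis.

    Each EDF run draws ``n_bms`` random combinations of the currently
    retained variables (binary matrix sampling, inclusion probability 0.5),
    scores them, computes inclusion frequencies among the best
    ``keep_ratio`` fraction, and shrinks the pool to the EDF-scheduled
    count, keeping the highest-frequency variables (frequency ties broken
    by ascending index).  The final pool of at most 14 variables is then
    searched exhaustively; the fitness-minimising subset is returned
    (ties: smaller subset, then lexicographic order).
    """
    X, y = _validate_xy(X, y, fitness)
    p = X.shape[1]
    if not (1 <= final_pool <= min(p, 14)):
        raise ValueError("final_pool must be in [1, min(p, 14)]")
    if not (0 < keep_ratio <= 1):
        raise ValueError("keep_ratio must be in (0, 1]")
    if n_bms < 2:
        raise ValueError("n_bms must be >= 2")

    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31))
    schedule = edf_schedule(p, final_pool, n_edf_runs)

    retained = np.arange(p)
    scores = np.zeros(p)
    trace: list[tuple[int, float]] = []
    for target_count in schedule:
        combos = rng.random((n_bms, retained.size)) < 0.5
        empty = ~combos.any(axis=1)
        if empty.any():
            combos[empty, rng.integers(retained.size, size=int(empty.sum()))] = True
        objs = np.array([
            fitness_cv(X[:, retained[row]], y, fitness, seed=cv_seed)
            for row in combos
        ])
        n_best = max(1, int(round(keep_ratio * n_bms)))
        best_rows = np.argsort(objs, kind="stable")[:n_best]
        freq = combos[best_rows].mean(axis=0)

        scores[:] = 0.0
        scores[retained] = freq
        trace.append((int(target_count), float(objs[best_rows[0]])))

        if retained.size > target_count:
            order = np.lexsort((retained, -freq))  # high freq first, low index ties
            retained = np.sort(retained[order[:target_count]])

    # exhaustive search over the final pool
    best: tuple[float, int, tuple[int, ...]] | None = None
    for size in range(1, retained.size + 1):
        for combo in combinations(range(retained.size), size):
            cols = retained[list(combo)]
            obj = fitness_cv(X[:, cols], y, fitness, seed=cv_seed)
            key = (obj, size, tuple(int(c) for c in cols))
            if best is None or key < best:
                best = key
    selected = np.array(best[2], dtype=int)

    return SelectionResult(
        method="VCPA",
        scores=scores,
        selected=selected,
        trace=trace,
        config={
            "n_edf_runs": n_edf_runs,
            "n_bms": n_bms,
            "keep_ratio": keep_ratio,
            "final_pool": final_pool,
            "final_pool_indices": [int(i) for i in retained],
            "cv_seed": cv_seed,
            "fitness": {"task": fitness.task, "max_latent": fitness.max_latent,
                        "folds": fitness.folds},
            "final_objective": float(best[0]),
        },
        seed=seed,
        data_fingerprint=data_fingerprint(X, y),
    )
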