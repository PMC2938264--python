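"""Repeated cross-validation SVM classification with a t-test feature
filter recomputed inside every training fold.

The procedure mirrors the screening study design: 100 repetitions of
stratified 10-fold cross-validation; in each fold the s most significant
miRNAs are selected on the training part only (no held-out sample ever
influences feature selection), a kernel SVM is trained on those features
and the held-out part is predicted.  Held-out predictions are pooled per
pass, so accuracy = (sens * n_case + spec * n_control) / n exactly.
Permutation runs re-execute the full pipeline — fold assignment, per-fold
feature ranking, training, prediction — under randomly permuted class
labels to estimate chance-level performance and detect overtraining.

The kernel classifier itself is an off-the-shelf max-margin learner
(sklearn's SVC) behind this module's surface; the bespoke machinery here
is the resampling, filtering and permutation logic.  Features are
standardised using training-fold statistics only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .diffexp import welch_ttest
from .errors import ConfigurationError, FoldDegeneracyError
from .preprocess import ExpressionMatrix
from .simulate import CASE_LABEL, CONTROL_LABEL

__all__ = [
    "CVConfig",
    "SubsetResult",
    "CVReport",
    "PermutationReport",
    "LeakageProbeResult",
    "assign_folds",
    "rank_features_on_training",
    "evaluate_subset",
    "run_repeated_cv",
    "run_permutation",
    "leakage_probe",
]

KERNELS = ("linear", "polynomial", "sigmoid", "radial")
_SKLEARN_KERNEL = {
    "linear": "linear",
    "polynomial": "poly",
    "sigmoid": "sigmoid",
    "radial": "rbf",
}
_REDRAW_ATTEMPTS = 5


@dataclass(frozen=True)
class CVConfig:
    """Grid and resampling design of the repeated cross-validation.

    Defaults are the full study design: 10-fold CV repeated 100 times,
    all four kernels, cost sampled from 0.01 to 10 in decimal powers.
    """

    n_folds: int = 10
    n_repeats: int = 100
    subset_sizes: tuple[int, ...] = (10, 20, 40, 60, 100, 200)
    kernels: tuple[str, ...] = KERNELS
    cost_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if not self.subset_sizes or any(s < 1 for s in self.subset_sizes):
            raise ConfigurationError("subset_sizes must be positive")
        if list(self.subset_sizes) != sorted(self.subset_sizes):
            raise ConfigurationError("subset_sizes must be ascending")
        unknown = set(self.kernels) - set(KERNELS)
        if unknown:
            raise ConfigurationError(f"unknown kernels: {sorted(unknown)}")
        if not self.cost_grid or any(c <= 0 for c in self.cost_grid):
            raise ConfigurationError("cost_grid must be positive")


def _as_xy(matrix, labels=None):
    """Coerce input to (X samples x features, y bool case, tiebreak ranks)."""
    if isinstance(matrix, ExpressionMatrix):
        X = matrix.values.T
        if labels is None:
            labels = matrix.labels
        tiebreak = np.argsort(np.argsort(np.asarray(matrix.probe_ids)))
    else:
        X = np.asarray(matrix, dtype=float)
        tiebreak = np.arange(X.shape[1])
    if labels is None:
        raise ConfigurationError("class labels required for bare array input")
    labels = np.asarray(labels)
    if labels.shape != (X.shape[0],):
        raise ConfigurationError("need one class label per sample")
    y = labels == CASE_LABEL
    return X, y, labels, tiebreak


def assign_folds(
    labels, n_folds: int = 10, stratified: bool = True, seed: int = 0
) -> np.ndarray:
    """Deterministic fold index per sample, sizes as even as possible.

    Stratified assignment keeps per-fold class ratios within one sample of
    the cohort ratio; it requires every class to have at least ``n_folds``
    members.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    if n_folds > n:
        raise ConfigurationError("more folds than samples")
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < n_folds:
            raise ConfigurationError(
                f"stratified {n_folds}-fold CV needs >= {n_folds} samples per class"
            )
        splitter = StratifiedKFold(n_folds, shuffle=True, random_state=int(seed))
        split = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_folds, shuffle=True, random_state=int(seed))
        split = splitter.split(np.zeros(n))
    folds = np.empty(n, dtype=int)
    for k, (_, test_idx) in enumerate(split):
        folds[test_idx] = k
    return folds


def _rank_features(X_train, y_train, tiebreak, method="welch") -> np.ndarray:
    """Feature indices ordered by ascending t-test p on the training part.

    Ties broken by larger |t|, then probe order.  Seeing only training
    samples is the caller's responsibility and this function's contract.
    """
    if y_train.all() or not y_train.any():
        raise FoldDegeneracyError("training fold contains a single class")
    t, p = welch_ttest(X_train[y_train].T, X_train[~y_train].T, method=method)
    return np.lexsort((tiebreak, -np.abs(t), p))


def rank_features_on_training(
    matrix, labels=None, train_idx=None, method: str = "welch"
) -> list[str] | np.ndarray:
    """Probe ids (or indices for bare arrays) ranked on the training samples.

    ``train_idx`` restricts the view to the training fold; test-fold
    columns are never touched.
    """
    X, y, _, tiebreak = _as_xy(matrix, labels)
    if train_idx is None:
        train_idx = np.arange(X.shape[0])
    order = _rank_features(X[train_idx], y[train_idx], tiebreak, method=method)
    if isinstance(matrix, ExpressionMatrix):
        return [matrix.probe_ids[i] for i in order]
    return order


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _grid_pass(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    subset_sizes,
    kernels,
    costs,
    feature_order: np.ndarray | None = None,
    tiebreak: np.ndarray | None = None,
) -> dict[tuple, tuple[float, float, float]]:
    """One CV pass over the whole grid; ranking computed once per fold.

    ``feature_order`` bypasses per-fold ranking (used only by the leakage
    probe to demonstrate selection bias).  Returns per-cell pooled
    (accuracy, sensitivity, specificity).
    """
    cells = [(s, k, c) for s in subset_sizes for k in kernels for c in costs]
    preds = {cell: np.zeros(len(y), dtype=bool) for cell in cells}
    for f in np.unique(folds):
        test_mask = folds == f
        train_mask = ~test_mask
        order = (
            feature_order
            if feature_order is not None
            else _rank_features(X[train_mask], y[train_mask], tiebreak)
        )
        Xtr, Xte = _standardize(X[train_mask], X[test_mask])
        ytr = y[train_mask]
        for s in subset_sizes:
            cols = order[:s]
            for k in kernels:
                for c in costs:
                    clf = SVC(kernel=_SKLEARN_KERNEL[k], C=c, gamma="scale")
                    clf.fit(Xtr[:, cols], ytr)
                    preds[(s, k, c)][test_mask] = clf.predict(Xte[:, cols])
    out = {}
    n_case = int(y.sum())
    n_control = int((~y).sum())
    for cell, pred in preds.items():
        sens = float((pred & y).sum() / n_case)
        spec = float((~pred & ~y).sum() / n_control)
        acc = float((pred == y).mean())
        out[cell] = (acc, sens, spec)
    return out


def evaluate_subset(
    matrix,
    labels,
    folds: np.ndarray,
    subset_size: int,
    kernel: str,
    cost: float,
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) of a single CV pass.

    Per fold: rank features on the training part, keep the top
    ``subset_size``, train the SVM, predict the held-out part; held-out
    predictions are pooled over folds.
    """
    if kernel not in KERNELS:
        raise ConfigurationError(f"unknown kernel {kernel!r}")
    if cost <= 0:
        raise ConfigurationError("cost must be positive")
    X, y, _, tiebreak = _as_xy(matrix, labels)
    if subset_size < 1 or subset_size > X.shape[1]:
        raise ConfigurationError("subset_size must be in 1..n_probes")
    result = _grid_pass(X, y, np.asarray(folds), (subset_size,), (kernel,), (cost,),
                        tiebreak=tiebreak)
    return result[(subset_size, kernel, cost)]


@dataclass
class SubsetResult:
    """Per-repeat CV metrics of one (subset size, kernel, cost) cell."""

    subset_size: int
    kernel: str
    cost: float
    accuracies: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.sensitivities.mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.specificities.mean())


SELECTION_RULE = (
    "maximize mean accuracy; ties: smaller subset size, kernel order as "
    "configured, smaller cost"
)


@dataclass
class CVReport:
    """All grid cells of a repeated-CV run plus the selected best cell."""

    results: list[SubsetResult]
    best: SubsetResult
    selection_rule: str
    config: CVConfig

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset_size": [r.subset_size for r in self.results],
                "kernel": [r.kernel for r in self.results],
                "cost": [r.cost for r in self.results],
                "mean_accuracy": [r.mean_accuracy for r in self.results],
                "mean_sensitivity": [r.mean_sensitivity for r in self.results],
                "mean_specificity": [r.mean_specificity for r in self.results],
            }
        )

    def per_repeat_frame(self) -> pd.DataFrame:
        """Long-format per-repeat metrics, ready for box-plot rendering."""
        rows = []
        for r in self.results:
            for i in range(len(r.accuracies)):
                rows.append(
                    {
                        "subset_size": r.subset_size,
                        "kernel": r.kernel,
                        "cost": r.cost,
                        "repeat": i,
                        "accuracy": r.accuracies[i],
                        "sensitivity": r.sensitivities[i],
                        "specificity": r.specificities[i],
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "selection_rule": self.selection_rule,
            "config": {
                "n_folds": self.config.n_folds,
                "n_repeats": self.config.n_repeats,
                "subset_sizes": list(self.config.subset_sizes),
                "kernels": list(self.config.kernels),
                "cost_grid": list(self.config.cost_grid),
                "stratified": self.config.stratified,
                "seed": self.config.seed,
            },
            "best": {
                "subset_size": self.best.subset_size,
                "kernel": self.best.kernel,
                "cost": self.best.cost,
                "mean_accuracy": self.best.mean_accuracy,
                "mean_sensitivity": self.best.mean_sensitivity,
                "mean_specificity": self.best.mean_specificity,
            },
            "results": [
                {
                    "subset_size": r.subset_size,
                    "kernel": r.kernel,
                    "cost": r.cost,
                    "mean_accuracy": r.mean_accuracy,
                    "mean_sensitivity": r.mean_sensitivity,
                    "mean_specificity": r.mean_specificity,
                    "accuracies": r.accuracies.tolist(),
                    "sensitivities": r.sensitivities.tolist(),
                    "specificities": r.specificities.tolist(),
                }
                for r in self.results
            ],
        }
        return json.dumps(payload, indent=2)


def _repeat_seeds(seed: int, n: int, salt: int = 0) -> np.ndarray:
    return np.random.SeedSequence([int(seed), salt]).generate_state(n) % (2**31)


def _folds_with_redraw(labels, config: CVConfig, seed: int) -> np.ndarray:
    for attempt in range(_REDRAW_ATTEMPTS):
        folds = assign_folds(labels, config.n_folds, config.stratified,
                             int(seed) + attempt)
        # verify every training set sees both classes
        ok = all(
            len(np.unique(np.asarray(labels)[folds != f])) == 2
            for f in np.unique(folds)
        )
        if ok:
            return folds
    raise FoldDegeneracyError(
        f"could not draw non-degenerate folds in {_REDRAW_ATTEMPTS} attempts "
        f"(n_folds={config.n_folds}, stratified={config.stratified})"
    )


def run_repeated_cv(matrix, labels=None, config: CVConfig | None = None) -> CVReport:
    """Repeated k-fold CV over the full (subset x kernel x cost) grid.

    Each repeat draws a fresh seed-derived fold assignment; per-repeat
    pooled metrics are aggregated per grid cell and the best cell is
    selected by mean accuracy with a deterministic tie-break.  Bit
    reproducible from ``config.seed``.
    """
    config = config or CVConfig()
    X, y, labels, tiebreak = _as_xy(matrix, labels)
    if max(config.subset_sizes) > X.shape[1]:
        raise ConfigurationError(
            f"largest subset size {max(config.subset_sizes)} exceeds "
            f"{X.shape[1]} probes"
        )
    cells = [
        (s, k, c)
        for s in config.subset_sizes
        for k in config.kernels
        for c in config.cost_grid
    ]
    acc = {cell: np.empty(config.n_repeats) for cell in cells}
    sens = {cell: np.empty(config.n_repeats) for cell in cells}
    spec = {cell: np.empty(config.n_repeats) for cell in cells}

    for r, fold_seed in enumerate(_repeat_seeds(config.seed, config.n_repeats)):
        folds = _folds_with_redraw(labels, config, fold_seed)
        pass_metrics = _grid_pass(
            X, y, folds, config.subset_sizes, config.kernels, config.cost_grid,
            tiebreak=tiebreak,
        )
        for cell, (a, se, sp) in pass_metrics.items():
            acc[cell][r] = a
            sens[cell][r] = se
            spec[cell][r] = sp

    results = [
        SubsetResult(s, k, c, acc[(s, k, c)], sens[(s, k, c)], spec[(s, k, c)])
        for (s, k, c) in cells
    ]
    kernel_order = {k: i for i, k in enumerate(config.kernels)}
    best = min(
        results,
        key=lambda r: (-r.mean_accuracy, r.subset_size, kernel_order[r.kernel], r.cost),
    )
    return CVReport(results=results, best=best, selection_rule=SELECTION_RULE,
                    config=config)


@dataclass
class PermutationReport:
    """Chance-level calibration: observed best-cell metrics vs the metric
    distribution over label-permuted full-pipeline runs."""

    n_permutation_runs: int
    permuted_accuracy: np.ndarray
    permuted_sensitivity: np.ndarray
    permuted_specificity: np.ndarray
    observed: dict[str, float]
    exceedance: dict[str, float]

    def summary(self) -> str:
        lines = ["Permutation-null validation"]
        for m in ("accuracy", "sensitivity", "specificity"):
            perm = getattr(self, f"permuted_{m}")
            lines.append(
                f"  {m:>12}: observed {self.observed[m]:.3f} | permuted "
                f"mean {perm.mean():.3f} | exceedance {self.exceedance[m]:.4f}"
            )
        return "\n".join(lines)


def run_permutation(
    matrix,
    labels=None,
    config: CVConfig | None = None,
    n_permutation_runs: int = 100,
    perm_config: CVConfig | None = None,
) -> PermutationReport:
    """Full-pipeline permutation test.

    Each run draws one random label permutation (class sizes preserved)
    and re-executes fold assignment, per-fold feature ranking, training
    and prediction under the permuted labels, collecting the best-cell
    metrics.  ``perm_config`` may scale down the per-run grid/repeats; by
    default the observed config is reused.  Exceedance fractions use the
    add-one estimator (#{permuted >= observed} + 1) / (runs + 1).
    """
    config = config or CVConfig()
    if n_permutation_runs < 1:
        raise ConfigurationError("n_permutation_runs must be >= 1")
    _, _, labels, _ = _as_xy(matrix, labels)

    observed_best = run_repeated_cv(matrix, labels, config).best
    observed = {
        "accuracy": observed_best.mean_accuracy,
        "sensitivity": observed_best.mean_sensitivity,
        "specificity": observed_best.mean_specificity,
    }

    base = perm_config or config
    run_seeds = _repeat_seeds(config.seed, n_permutation_runs, salt=1)
    perm = {m: np.empty(n_permutation_runs) for m in observed}
    for i, s in enumerate(run_seeds):
        rng = np.random.default_rng(int(s))
        permuted = rng.permutation(labels)
        best = run_repeated_cv(matrix, permuted, replace(base, seed=int(s))).best
        perm["accuracy"][i] = best.mean_accuracy
        perm["sensitivity"][i] = best.mean_sensitivity
        perm["specificity"][i] = best.mean_specificity

    exceedance = {
        m: float((np.count_nonzero(perm[m] >= observed[m]) + 1)
                 / (n_permutation_runs + 1))
        for m in observed
    }
    return PermutationReport(
        n_permutation_runs=n_permutation_runs,
        permuted_accuracy=perm["accuracy"],
        permuted_sensitivity=perm["sensitivity"],
        permuted_specificity=perm["specificity"],
        observed=observed,
        exceedance=exceedance,
    )


@dataclass
class LeakageProbeResult:
    """Paired accuracies of the correct and the deliberately leaky CV."""

    correct_accuracy: float
    leaky_accuracy: float

    @property
    def selection_bias(self) -> float:
        return self.leaky_accuracy - self.correct_accuracy


def leakage_probe(matrix, labels=None, config: CVConfig | None = None) -> LeakageProbeResult:
    """Self-test of the engine: filter-inside-fold vs filter-before-CV.

    The leaky variant ranks features once on ALL samples (held-out ones
    included) before cross-validating; on effect-free data its accuracy
    exceeds the correct variant's, demonstrating the selection bias the
    fold-internal filter avoids.
    """
    config = config or CVConfig()
    X, y, labels, tiebreak = _as_xy(matrix, labels)
    if max(config.subset_sizes) > X.shape[1]:
        raise ConfigurationError("subset size exceeds number of probes")

    global_order = _rank_features(X, y, tiebreak)
    cells = [
        (s, k, c)
        for s in config.subset_sizes
        for k in config.kernels
        for c in config.cost_grid
    ]
    acc = {variant: {cell: np.empty(config.n_repeats) for cell in cells}
           for variant in ("correct", "leaky")}
    for r, fold_seed in enumerate(_repeat_seeds(config.seed, config.n_repeats)):
        folds = _folds_with_redraw(labels, config, fold_seed)
        for variant, order in (("correct", None), ("leaky", global_order)):
            metrics = _grid_pass(
                X, y, folds, config.subset_sizes, config.kernels,
                config.cost_grid, feature_order=order, tiebreak=tiebreak,
            )
            for cell, (a, _, _) in metrics.items():
                acc[variant][cell][r] = a

    def best_mean(per_cell):
        return max(float(v.mean()) for v in per_cell.values())

    return LeakageProbeResult(
        correct_accuracy=best_mean(acc["correct"]),
        leaky_accuracy=best_mean(acc["leaky"]),
    )
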