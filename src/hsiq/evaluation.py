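"""Data splitting, the study's metrics, and the model x band-set benchmark.

Regression quality is reported as Pearson's R, its square R2, mean
absolute error and root mean squared error between measured and predicted
contents; classification as percentage accuracy.  The benchmark trains
every model (SVM, CNN, LSTM, CLSTM) on every band group (full grid, iRF
selection, VCPA selection) under one shared stratified split, which is the
grid layout the study reports.

Wavelength selection must have been computed on the training partition
only; :func:`run_benchmark` verifies each selection's data fingerprint
against the training matrix and refuses to evaluate leaked selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .models import (
    ArchitectureConfig,
    TrainedModel,
    TrainingConfig,
    build_model,
    predict,
    records_xy,
    train,
)
from .selection import SelectionResult, data_fingerprint
from .synthetic import Dataset

BAND_GROUPS = ("Full", "iRF", "VCPA")
MODEL_ORDER = ("SVM", "CNN", "LSTM", "CLSTM")


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.3
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class MetricsReport:
    """Metrics for one model x band-group cell."""

    task: str
    n: int
    train_accuracy: float | None = None   # percent
    test_accuracy: float | None = None    # percent
    r: float | None = None
    r2: float | None = None
    mae: float | None = None
    rmse: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def stratified_split(dataset: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """Disjoint, exhaustive train/test split, class-balanced when stratified."""
    labels = dataset.labels()
    if spec.stratify:
        classes, counts = np.unique(labels, return_counts=True)
        if classes.size < 2 or counts.min() < 2:
            raise ValueError("stratified split needs >= 2 members in each class")
        strat = labels
    else:
        strat = None
    idx = np.arange(len(dataset))
    tr, te = train_test_split(
        idx, test_size=spec.test_fraction, stratify=strat, random_state=spec.seed
    )
    return dataset.subset(np.sort(tr)), dataset.subset(np.sort(te))


def regression_metrics(actual: np.ndarray, predicted: np.ndarray) -> MetricsReport:
    """R, R2 (= R squared), MAE and RMSE between measured and predicted."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.ndim != 1:
        raise ValueError("actual and predicted must be equal-length 1-D")
    if actual.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(actual) == 0:
        raise ValueError("constant actual values: Pearson R undefined")
    resid = predicted - actual
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    if np.ptp(predicted) == 0:
        r = 0.0  # degenerate constant prediction: no linear association
    else:
        r = float(stats.pearsonr(actual, predicted).statistic)
    return MetricsReport(
        task="regression", n=actual.size, r=r, r2=r * r, mae=mae, rmse=rmse
    )


def classification_accuracy(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Percentage of matching labels."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError("label vectors differ in length")
    if actual.size == 0:
        raise ValueError("empty label vectors")
    return float(100.0 * np.mean(actual == predicted))


@dataclass
class BenchmarkTable:
    """Complete band-group x model grid of metric reports."""

    task: str
    target: str
    cells: dict[tuple[str, str], MetricsReport] = field(default_factory=dict)
    predictions: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    configs: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (group, model), report in self.cells.items():
            rows.append({"group": group, "model": model, **report.as_dict()})
        return pd.DataFrame(rows)

    def is_complete(self, groups=BAND_GROUPS, models=MODEL_ORDER) -> bool:
        return all((g, m) in self.cells for g in groups for m in models)


_MIN_GROUP_BANDS = 4  # two stride-2 convolutions need at least 4 positions


def _band_indices(
    group: str, n_bands: int, selections: dict[str, SelectionResult | None]
) -> np.ndarray:
    if group == "Full":
        return np.arange(n_bands)
    sel = selections.get(group)
    if sel is None:
        raise ValueError(f"no selection result provided for band group {group!r}")
    if sel.selected.size == 0:
        raise ValueError(f"band group {group!r} is empty")
    bands = sel.selected
    if bands.size < _MIN_GROUP_BANDS:
        # a very aggressive selection is topped up from its own score ranking
        # so the convolutional models remain buildable on the group
        order = np.argsort(-sel.scores, kind="stable")
        extra = [i for i in order if i not in set(bands.tolist())]
        bands = np.sort(np.concatenate(
            [bands, extra[: _MIN_GROUP_BANDS - bands.size]]
        ).astype(int))
    return bands


def run_benchmark(
    dataset: Dataset,
    selections: dict[str, SelectionResult | None],
    target: str,
    training: TrainingConfig | None = None,
    split: SplitSpec | None = None,
    models: tuple[str, ...] = MODEL_ORDER,
    arch_overrides: dict | None = None,
) -> BenchmarkTable:
    """Train/evaluate every model on every band group under one split.

    ``selections`` maps group names ("iRF", "VCPA") to their
    :class:`SelectionResult`; "Full" needs none.  Selections must carry the
    fingerprint of this split's training data — a mismatch (e.g. selection
    run on the full dataset) is treated as information leakage and raises.
    """
    split = split or SplitSpec()
    training = training or TrainingConfig()
    task = "classification" if target == "label" else "regression"
    train_set, test_set = stratified_split(dataset, split)

    X_tr, y_tr = records_xy(train_set, target)
    expected_fp = data_fingerprint(X_tr, y_tr)
    for group, sel in selections.items():
        if sel is not None and sel.data_fingerprint and sel.data_fingerprint != expected_fp:
            raise ValueError(
                f"selection for {group!r} was not computed on this benchmark's "
                "training partition (leakage guard)"
            )

    groups = tuple(g for g in BAND_GROUPS if g == "Full" or g in selections)
    table = BenchmarkTable(task=task, target=target)
    table.configs = {
        "split": split.__dict__,
        "training": training.__dict__,
        "target": target,
        "groups": list(groups),
    }

    n_bands = len(dataset.grid)
    for group in groups:
        bands = _band_indices(group, n_bands, selections)
        tr_sub = _restrict_bands(train_set, bands)
        te_sub = _restrict_bands(test_set, bands)
        for name in models:
            arch = ArchitectureConfig(
                kind=name.lower(), task=task, **(arch_overrides or {})
            )
            model = build_model(arch, n_bands=bands.size, seed=training.seed)
            train(model, tr_sub, target, training)
            report = _evaluate_cell(model, tr_sub, te_sub, target, task)
            table.cells[(group, name)] = report
            table.predictions[(group, name)] = _prediction_frame(
                model, te_sub, target, task
            )
    return table


def _restrict_bands(dataset: Dataset, bands: np.ndarray) -> Dataset:
    from .grid import WavelengthGrid
    from .synthetic import SampleRecord

    grid = WavelengthGrid(
        centers=dataset.grid.centers[bands],
        sensor_tags=tuple(dataset.grid.sensor_tags[i] for i in bands),
    )
    records = [
        SampleRecord(
            spectrum=r.spectrum[bands],
            label=r.label,
            contents=r.contents,
            sample_id=r.sample_id,
        )
        for r in dataset.records
    ]
    return Dataset(records=records, grid=grid, provenance=dataset.provenance)


def _evaluate_cell(
    model: TrainedModel, train_set: Dataset, test_set: Dataset, target: str, task: str
) -> MetricsReport:
    if task == "classification":
        tr_pred = _labels(predict(model, train_set))
        te_pred = _labels(predict(model, test_set))
        return MetricsReport(
            task=task,
            n=len(test_set),
            train_accuracy=classification_accuracy(train_set.labels(), tr_pred),
            test_accuracy=classification_accuracy(test_set.labels(), te_pred),
        )
    te_pred = predict(model, test_set)
    report = regression_metrics(test_set.contents(target), te_pred)
    return report


def _labels(prediction) -> np.ndarray:
    return prediction[0] if isinstance(prediction, tuple) else prediction


def _prediction_frame(
    model: TrainedModel, test_set: Dataset, target: str, task: str
) -> pd.DataFrame:
    ids = [r.sample_id for r in test_set.records]
    if task == "classification":
        labels, probs = predict(model, test_set)
        return pd.DataFrame(
            {"sample_id": ids, "actual": test_set.labels(), "predicted": labels,
             "p_class1": probs[:, 1]}
        )
    values = predict(model, test_set)
    return pd.DataFrame(
        {"sample_id": ids, "actual": test_set.contents(target), "predicted": values}
    )
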