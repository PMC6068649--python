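"""Cross-validated evaluation: confusion matrix, micro counts, metrics.

Performance of the three-class stenosis classifier is summarised by pooling
each evaluation run's held-out predictions into a single 3x3 confusion
matrix C (rows = actual class, columns = predicted class) and collapsing it
into micro-aggregated counts

    TP = C11 + C22 + C33
    FP = (C21 + C31) + (C12 + C32) + (C13 + C23)
    FN = (C12 + C13) + (C21 + C23) + (C31 + C32)
    TN = (C22+C23+C32+C33) + (C11+C13+C31+C33) + (C11+C12+C21+C22)

from which ACC, REC (sensitivity), SPE (specificity), PPV (precision) and
GM = sqrt(REC*SPE) are computed, in percent.  For three classes these
definitions force the identities FP = FN, TN = N + TP, hence REC = PPV,
ACC = (1 + 2*REC)/3 and SPE = (1 + REC)/2 (rates as fractions); they are
asserted on every evaluation.

Model selection uses repeated stratified 5-fold cross-validation (10
repeats by default): per repeat the cohort is shuffled into stratified
folds, the network is trained on k-1 folds and predicts the held-out fold
by arg-max, predictions are pooled over folds into one confusion matrix,
and the metrics are reported as mean +/- SD (n-1) across repeats.  With
only two severe-class subjects some folds necessarily lack a class; pooling
predictions across folds before computing metrics makes this benign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .labels import one_hot
from .mlp import init_weights, predict_classes
from .trainers import TrainConfig, TrainResult, train

__all__ = [
    "ConfusionMatrix3",
    "AggregateCounts",
    "MetricsReport",
    "confusion_matrix",
    "aggregate_counts",
    "metrics",
    "cross_validate",
]

N_CLASSES = 3


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 confusion matrix; counts[i, j] = #(actual i+1, predicted j+1)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (N_CLASSES, N_CLASSES) or (counts < 0).any():
            raise ValueError("confusion matrix must be 3x3 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AggregateCounts:
    TP: int
    FP: int
    FN: int
    TN: int


@dataclass
class MetricsReport:
    """Percent metrics (mean over one pooled evaluation)."""

    acc: float
    rec: float
    spe: float
    ppv: float
    gm: float


def confusion_matrix(actual: Sequence[int], predicted: Sequence[int]) -> ConfusionMatrix3:
    """Count actual-vs-predicted label pairs; labels must be in {1, 2, 3}."""
    actual = np.asarray(actual, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    for name, labels in (("actual", actual), ("predicted", predicted)):
        bad = labels[(labels < 1) | (labels > N_CLASSES)]
        if bad.size:
            raise ValueError(f"{name} labels outside 1..{N_CLASSES}: {sorted(set(bad))}")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(counts, (actual - 1, predicted - 1), 1)
    return ConfusionMatrix3(counts)


def aggregate_counts(cm: ConfusionMatrix3) -> AggregateCounts:
    """Micro-aggregated TP/FP/FN/TN of the three per-class 2x2 tables."""
    C = cm.counts
    tp = int(np.trace(C))
    fp = int(C.sum() - np.trace(C))  # off-diagonal cells grouped by predicted class
    fn = int(C.sum() - np.trace(C))  # off-diagonal cells grouped by actual class
    # per-class true negatives: the 2x2 block excluding class i's row and column
    others = [[j for j in range(N_CLASSES) if j != i] for i in range(N_CLASSES)]
    tn = int(sum(C[np.ix_(rows, rows)].sum() for rows in others))
    counts = AggregateCounts(TP=tp, FP=fp, FN=fn, TN=tn)
    n = cm.total
    assert counts.FP == counts.FN, "micro aggregation identity FP == FN violated"
    assert counts.TN == n + counts.TP, "micro aggregation identity TN == N + TP violated"
    return counts


def metrics(counts: AggregateCounts) -> MetricsReport:
    """ACC/REC/SPE/PPV/GM in percent from micro-aggregated counts."""
    denoms = {
        "acc": counts.TP + counts.TN + counts.FP + counts.FN,
        "rec": counts.TP + counts.FN,
        "spe": counts.TN + counts.FP,
        "ppv": counts.TP + counts.FP,
    }
    for name, denom in denoms.items():
        if denom == 0:
            raise ZeroDivisionError(f"metric {name.upper()} undefined: zero denominator")
    acc = (counts.TP + counts.TN) / denoms["acc"]
    rec = counts.TP / denoms["rec"]
    spe = counts.TN / denoms["spe"]
    ppv = counts.TP / denoms["ppv"]
    gm = float(np.sqrt(rec * spe))
    assert abs(rec - ppv) < 1e-12, "micro aggregation identity REC == PPV violated"
    assert abs(acc - (1 + 2 * rec) / 3) < 1e-12, "identity ACC == (1+2*REC)/3 violated"
    assert abs(spe - (1 + rec) / 2) < 1e-12, "identity SPE == (1+REC)/2 violated"
    return MetricsReport(acc=100 * acc, rec=100 * rec, spe=100 * spe, ppv=100 * ppv, gm=100 * gm)


@dataclass
class CrossValidationReport:
    """Mean +/- SD metrics over repeated stratified k-fold evaluation."""

    algorithm: str
    mean: MetricsReport
    sd: MetricsReport
    confusions: list[ConfusionMatrix3]
    per_repeat: list[MetricsReport]
    train_time_mean: float
    predict_time_mean: float
    epochs_mean: float
    epochs_sd: float
    mse_mean: float
    mse_sd: float

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            **{
                k: {"mean": getattr(self.mean, k), "sd": getattr(self.sd, k)}
                for k in ("acc", "rec", "spe", "ppv", "gm")
            },
            "tnt_s": self.train_time_mean,
            "tt_s": self.predict_time_mean,
            "epochs": {"mean": self.epochs_mean, "sd": self.epochs_sd},
            "mse": {"mean": self.mse_mean, "sd": self.mse_sd},
        }


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled stratified fold assignment; classes dealt round-robin.

    Class proportions are preserved as far as integer counts allow; classes
    with fewer members than folds simply miss from some folds.
    """
    n = labels.size
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
        offset += idx.size  # stagger so small classes rotate across folds
    return [np.array(sorted(f), dtype=int) for f in folds]


def _default_fit_predict(
    x_train: np.ndarray,
    t_train: np.ndarray,
    x_test: np.ndarray,
    seed: int,
    config: TrainConfig,
    hidden_dim: int,
) -> tuple[np.ndarray, TrainResult]:
    model = init_weights(
        input_dim=x_train.shape[1], hidden_dim=hidden_dim, output_dim=N_CLASSES, seed=seed
    )
    result = train(model, x_train, t_train, config)
    return predict_classes(result.model, x_test), result


def cross_validate(
    x: np.ndarray,
    labels: Sequence[int],
    config: TrainConfig | None = None,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    hidden_dim: int = 35,
    fit_predict: Callable | None = None,
) -> CrossValidationReport:
    """Repeated stratified k-fold evaluation of the MLP classifier.

    ``fit_predict(x_train, t_train, x_test, seed) -> (labels, TrainResult|None)``
    may be supplied to evaluate a different classifier under the identical
    protocol (used for baselines and tests); by default a fresh seeded
    4-35-3 network is trained per fold with ``config``.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if x.shape[0] != n:
        raise ValueError("feature matrix and labels disagree in length")
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    config = config or TrainConfig()

    root = np.random.SeedSequence(seed)
    repeat_seeds = root.spawn(repeats)
    confusions: list[ConfusionMatrix3] = []
    per_repeat: list[MetricsReport] = []
    train_times, predict_times, epoch_counts, mses = [], [], [], []
    targets = np.stack([one_hot(c) for c in labels])

    for rep, seq in enumerate(repeat_seeds):
        rng = np.random.default_rng(seq)
        fold_idx = _stratified_folds(labels, k, rng)
        predicted = np.zeros(n, dtype=int)
        seen = np.zeros(n, dtype=bool)
        for fold_no, test_idx in enumerate(fold_idx):
            if test_idx.size == 0:
                continue
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            fold_seed = int(rng.integers(2**31 - 1))
            if fit_predict is not None:
                pred, result = fit_predict(x[train_mask], targets[train_mask], x[test_idx], fold_seed)
            else:
                pred, result = _default_fit_predict(
                    x[train_mask], targets[train_mask], x[test_idx], fold_seed, config, hidden_dim
                )
            predicted[test_idx] = pred
            seen[test_idx] = True
            if result is not None:
                train_times.append(result.train_time)
                predict_times.append(result.predict_time_per_sample * test_idx.size)
                epoch_counts.append(result.epochs)
                mses.append(result.final_mse)
        assert seen.all(), "every sample must be predicted exactly once per repeat"
        cm = confusion_matrix(labels, predicted)
        confusions.append(cm)
        per_repeat.append(metrics(aggregate_counts(cm)))

    def _agg(attr: str) -> tuple[float, float]:
        vals = np.array([getattr(m, attr) for m in per_repeat])
        return float(vals.mean()), float(vals.std(ddof=1)) if repeats > 1 else 0.0

    mean = MetricsReport(*(_agg(a)[0] for a in ("acc", "rec", "spe", "ppv", "gm")))
    sd = MetricsReport(*(_agg(a)[1] for a in ("acc", "rec", "spe", "ppv", "gm")))
    return CrossValidationReport(
        algorithm=config.algorithm,
        mean=mean,
        sd=sd,
        confusions=confusions,
        per_repeat=per_repeat,
        train_time_mean=float(np.mean(train_times)) if train_times else 0.0,
        predict_time_mean=float(np.mean(predict_times)) if predict_times else 0.0,
        epochs_mean=float(np.mean(epoch_counts)) if epoch_counts else 0.0,
        epochs_sd=float(np.std(epoch_counts, ddof=1)) if len(epoch_counts) > 1 else 0.0,
        mse_mean=float(np.mean(mses)) if mses else 0.0,
        mse_sd=float(np.std(mses, ddof=1)) if len(mses) > 1 else 0.0,
    )
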