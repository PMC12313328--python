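"""Train and evaluate phenotype classifiers.

Three model families, in increasing order of expressive power:
tabular models (random forest, SVM) on the derived mechanotyping
features; a GRU on the per-frame scalar sequences; and a CNN-GRU on the
mask-image sequences.  All share the same protocol: shuffle, split
70:15:15 into train/validation/test, standardize using statistics from
the training partition only, select hyperparameters / the best epoch on
validation accuracy, and report on the held-out test partition.
Confusion matrices are row-normalized by true-label count and accuracy
is the mean of the normalized diagonal, so class imbalance cannot
inflate it.

Feature attributions are exact interventional Shapley values computed
by subset enumeration (Monte-Carlo permutation sampling above 12
features), satisfying the efficiency identity per sample.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .nn import CNNGRUClassifier, GRUClassifier, MaskCNNClassifier


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.ratios), 1.0, abs_tol=1e-9):
            raise ValueError("split ratios must sum to 1")


@dataclass
class ClassifierReport:
    """Evaluation summary of a fitted classifier."""

    confusion: np.ndarray          # row-normalized by true-label count
    counts: np.ndarray             # raw confusion counts
    accuracy: float                # mean of the normalized diagonal
    tpr: float                     # recall of the positive class (1)
    fpr: float                     # 1 − recall of the negative class (0)
    n_test: int
    fold_accuracies: list[float] | None = None
    fold_sem: float | None = None

    def to_dict(self) -> dict:
        out = {
            "confusion": self.confusion.tolist(),
            "counts": self.counts.tolist(),
            "accuracy": self.accuracy,
            "tpr": self.tpr, "fpr": self.fpr, "n_test": self.n_test,
        }
        if self.fold_accuracies is not None:
            out["fold_accuracies"] = self.fold_accuracies
            out["fold_sem"] = self.fold_sem
        return out


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray
                         ) -> ClassifierReport:
    """Row-normalized confusion matrix and balanced accuracy."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty test set")
    counts = np.zeros((2, 2))
    for t, p in zip(y_true, y_pred):
        counts[t, p] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    confusion = np.divide(counts, row_sums, where=row_sums > 0,
                          out=np.zeros_like(counts))
    present = row_sums[:, 0] > 0
    accuracy = float(confusion[np.nonzero(present)[0],
                               np.nonzero(present)[0]].mean())
    tpr = float(confusion[1, 1]) if present[1] else float("nan")
    fpr = float(confusion[0, 1]) if present[0] else float("nan")
    return ClassifierReport(confusion=confusion, counts=counts,
                            accuracy=accuracy, tpr=tpr, fpr=fpr,
                            n_test=int(y_true.size))


def evaluate(model, x_test, y_test) -> ClassifierReport:
    """Evaluate any fitted model exposing predict on this test set."""
    if isinstance(x_test, tuple):
        y_pred = model.predict(*x_test)
    else:
        y_pred = model.predict(x_test)
    return evaluate_predictions(y_test, y_pred)


# ------------------------------------------------------------------ splits

def _allocate(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation of n into parts ∝ ratios."""
    raw = [n * r for r in ratios]
    base = [int(math.floor(v)) for v in raw]
    rem = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i],
                   reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


def split_indices(labels: np.ndarray, spec: SplitSpec
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded, stratified train/validation/test index partition."""
    labels = np.asarray(labels)
    n = labels.size
    if n < 20:
        raise ValueError("need at least 20 samples to split")
    rng = np.random.default_rng(spec.seed)
    parts: list[list[int]] = [[], [], []]
    if spec.stratified:
        # floor quota per class, then hand out leftovers to whichever
        # partition lags its global target most — exact global counts
        # with near-exact per-class stratification
        global_targets = _allocate(n, spec.ratios)
        classes = list(np.unique(labels))
        shuffled = {cls: rng.permutation(np.nonzero(labels == cls)[0])
                    for cls in classes}
        sizes = {cls: [int(math.floor(len(shuffled[cls]) * r))
                       for r in spec.ratios] for cls in classes}
        filled = [sum(sizes[cls][j] for cls in classes) for j in range(3)]
        for cls in classes:
            leftovers = len(shuffled[cls]) - sum(sizes[cls])
            for _ in range(leftovers):
                deficits = [global_targets[j] - filled[j] for j in range(3)]
                j = int(np.argmax(deficits))
                sizes[cls][j] += 1
                filled[j] += 1
        for cls in classes:
            if any(s == 0 for s in sizes[cls]):
                raise ValueError(
                    f"class {cls} absent from one partition; "
                    "more samples needed")
            idx = shuffled[cls]
            stops = np.cumsum(sizes[cls])
            parts[0].extend(idx[:stops[0]])
            parts[1].extend(idx[stops[0]:stops[1]])
            parts[2].extend(idx[stops[1]:])
    else:
        idx = rng.permutation(n)
        sizes = _allocate(n, spec.ratios)
        stops = np.cumsum(sizes)
        parts = [list(idx[:stops[0]]), list(idx[stops[0]:stops[1]]),
                 list(idx[stops[1]:])]
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


@dataclass
class Standardizer:
    """Per-feature mean/SD computed on the training partition only."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x_train: np.ndarray) -> "Standardizer":
        sd = x_train.std(axis=0)
        return cls(mean=x_train.mean(axis=0),
                   sd=np.where(sd > 0, sd, 1.0))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


def split_dataset(x: np.ndarray, labels: np.ndarray, spec: SplitSpec
                  ) -> dict:
    """Split and standardize; returns partitions plus the scaler."""
    tr, va, te = split_indices(labels, spec)
    scaler = Standardizer.fit(x[tr])
    return {
        "train": (scaler.transform(x[tr]), labels[tr]),
        "val": (scaler.transform(x[va]), labels[va]),
        "test": (scaler.transform(x[te]), labels[te]),
        "indices": (tr, va, te),
        "scaler": scaler,
    }


# ----------------------------------------------------------------- tabular

RF_GRID = [{"max_depth": d, "min_samples_leaf": leaf}
           for d in (None, 8) for leaf in (1, 3)]
SVM_GRID = [{"C": c} for c in (0.5, 1.0, 10.0)]


@dataclass
class TabularResult:
    model: object
    report: ClassifierReport
    split: dict
    best_hyper: dict
    kind: str


def _build_tabular(kind: str, hyper: dict, seed: int):
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=300, random_state=seed,
                                      n_jobs=1, **hyper)
    if kind == "svm":
        return SVC(kernel="rbf", gamma="scale", random_state=seed,
                   **hyper)
    raise ValueError(f"unknown model kind {kind!r}")


def train_tabular(x: np.ndarray, labels: np.ndarray,
                  model_kind: str = "random_forest",
                  spec: SplitSpec | None = None,
                  grid: list[dict] | None = None,
                  seed: int = 0) -> TabularResult:
    """Fit a tabular classifier with validation-based model selection.

    Hyperparameters are chosen on the validation partition; the reported
    numbers come from the untouched test partition.
    """
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("need two classes")
    spec = spec or SplitSpec(seed=seed)
    split = split_dataset(np.asarray(x, dtype=float), labels, spec)
    x_tr, y_tr = split["train"]
    x_va, y_va = split["val"]
    x_te, y_te = split["test"]
    grid = grid or (RF_GRID if model_kind == "random_forest" else SVM_GRID)
    best_acc, best_model, best_hyper = -1.0, None, None
    for hyper in grid:
        model = _build_tabular(model_kind, hyper, seed)
        model.fit(x_tr, y_tr)
        acc = float((model.predict(x_va) == y_va).mean())
        if acc > best_acc:
            best_acc, best_model, best_hyper = acc, model, hyper
    report = evaluate(best_model, x_te, y_te)
    return TabularResult(model=best_model, report=report, split=split,
                         best_hyper=best_hyper, kind=model_kind)


# ------------------------------------------------------ Shapley attribution

@dataclass
class ImportanceReport:
    """Per-feature mean absolute Shapley attribution, descending."""

    names: list[str]
    mean_abs: np.ndarray           # aligned with names, descending
    phi: np.ndarray                # (n_samples, n_features) signed values
    base_value: float

    def ranking(self) -> list[tuple[str, float]]:
        return list(zip(self.names, self.mean_abs))


def _predict_fn(model):
    if hasattr(model, "predict_proba"):
        return lambda x: model.predict_proba(x)[:, 1]
    if hasattr(model, "decision_function"):
        return lambda x: model.decision_function(x)
    return lambda x: model.predict(x).astype(float)


def shapley_values(model, background: np.ndarray, samples: np.ndarray,
                   max_exact: int = 12, n_permutations: int = 256,
                   seed: int = 0) -> tuple[np.ndarray, float]:
    """Interventional Shapley values of model output per sample.

    The value of a coalition S is the model output with features in S
    taken from the sample and the rest replaced by background rows,
    averaged over the background.  Up to ``max_exact`` features all 2^d
    coalitions are enumerated (exact); beyond that, permutation
    sampling.  Returns (phi [n_samples, d], base_value).
    """
    if not hasattr(model, "predict"):
        raise ValueError("model must be fitted and expose predict")
    f = _predict_fn(model)
    background = np.asarray(background, dtype=float)
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n, d = samples.shape
    nb = background.shape[0]
    base = float(f(background).mean())

    if d <= max_exact:
        subsets = list(itertools.chain.from_iterable(
            itertools.combinations(range(d), k) for k in range(d + 1)))
        # value of every coalition for every sample
        v = np.empty((len(subsets), n))
        for si, s in enumerate(subsets):
            z = np.repeat(background[None, :, :], n, axis=0)  # (n, nb, d)
            if s:
                z[:, :, s] = samples[:, None, s]
            v[si] = f(z.reshape(n * nb, d)).reshape(n, nb).mean(axis=1)
        index = {s: i for i, s in enumerate(subsets)}
        phi = np.zeros((n, d))
        fact = [math.factorial(k) for k in range(d + 1)]
        for s in subsets:
            k = len(s)
            if k == d:
                continue
            weight = fact[k] * fact[d - k - 1] / fact[d]
            vs = v[index[s]]
            for i in range(d):
                if i in s:
                    continue
                s_with = tuple(sorted(s + (i,)))
                phi[:, i] += weight * (v[index[s_with]] - vs)
        return phi, base

    rng = np.random.default_rng(seed)
    phi = np.zeros((n, d))
    for _ in range(n_permutations):
        perm = rng.permutation(d)
        z = np.repeat(background[None, :, :], n, axis=0)
        prev = f(z.reshape(n * nb, d)).reshape(n, nb).mean(axis=1)
        for i in perm:
            z[:, :, i] = samples[:, None, i]
            cur = f(z.reshape(n * nb, d)).reshape(n, nb).mean(axis=1)
            phi[:, i] += cur - prev
            prev = cur
    return phi / n_permutations, base


def feature_importance(model, background: np.ndarray,
                       samples: np.ndarray,
                       feature_names: list[str] | None = None,
                       **kwargs) -> ImportanceReport:
    """Mean |Shapley value| per feature, sorted descending."""
    phi, base = shapley_values(model, background, samples, **kwargs)
    mean_abs = np.abs(phi).mean(axis=0)
    d = phi.shape[1]
    names = feature_names or [f"f{i}" for i in range(d)]
    order = np.argsort(mean_abs)[::-1]
    return ImportanceReport(
        names=[names[i] for i in order],
        mean_abs=mean_abs[order],
        phi=phi, base_value=base)


# --------------------------------------------------------- sequence models

@dataclass
class SequenceResult:
    model: object
    report: ClassifierReport
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    scaler: "SequenceStandardizer | None"


@dataclass
class SequenceStandardizer:
    """Per-channel mean/SD over the valid timesteps of the train split."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray, valid: np.ndarray) -> "SequenceStandardizer":
        vals = x[valid]                       # (n_valid_steps, channels)
        sd = vals.std(axis=0)
        return cls(mean=vals.mean(axis=0), sd=np.where(sd > 0, sd, 1.0))

    def transform(self, x: np.ndarray, valid: np.ndarray) -> np.ndarray:
        out = (x - self.mean) / self.sd
        out[~valid] = 0.0
        return out


def train_gru(sequences: np.ndarray, valid: np.ndarray,
              labels: np.ndarray, units: int = 24, epochs: int = 175,
              lr: float = 1e-2, spec: SplitSpec | None = None,
              seed: int = 0) -> SequenceResult:
    """GRU on scalar shape sequences with the standard protocol."""
    labels = np.asarray(labels, dtype=int)
    spec = spec or SplitSpec(seed=seed)
    tr, va, te = split_indices(labels, spec)
    scaler = SequenceStandardizer.fit(sequences[tr], valid[tr])
    xs = scaler.transform(sequences, valid)
    model = GRUClassifier(n_channels=sequences.shape[-1], units=units,
                          epochs=epochs, lr=lr, seed=seed)
    model.fit(xs[tr], valid[tr], labels[tr],
              xs[va], valid[va], labels[va])
    report = evaluate(model, (xs[te], valid[te]), labels[te])
    return SequenceResult(model=model, report=report, indices=(tr, va, te),
                          scaler=scaler)


def train_cnn_gru(mask_sequences: np.ndarray, valid: np.ndarray,
                  labels: np.ndarray, units: int = 24, epochs: int = 30,
                  lr: float = 3e-3, spec: SplitSpec | None = None,
                  seed: int = 0, **hyper) -> SequenceResult:
    """CNN-GRU on two-channel mask-image sequences."""
    labels = np.asarray(labels, dtype=int)
    if mask_sequences.ndim != 5:
        raise ValueError("mask sequences must be (n, T, H, W, C)")
    spec = spec or SplitSpec(seed=seed)
    tr, va, te = split_indices(labels, spec)
    model = CNNGRUClassifier(units=units, epochs=epochs, lr=lr, seed=seed,
                             **hyper)
    model.fit(mask_sequences[tr], valid[tr], labels[tr],
              mask_sequences[va], valid[va], labels[va])
    report = evaluate(model, (mask_sequences[te], valid[te]), labels[te])
    return SequenceResult(model=model, report=report, indices=(tr, va, te),
                          scaler=None)


def train_mask_cnn(masks: np.ndarray, labels: np.ndarray,
                   epochs: int = 30, lr: float = 3e-3,
                   spec: SplitSpec | None = None, seed: int = 0,
                   **hyper) -> SequenceResult:
    """Static CNN on single mask images (morphology-only control)."""
    labels = np.asarray(labels, dtype=int)
    spec = spec or SplitSpec(seed=seed)
    tr, va, te = split_indices(labels, spec)
    model = MaskCNNClassifier(epochs=epochs, lr=lr, seed=seed, **hyper)
    model.fit(masks[tr], labels[tr], masks[va], labels[va])
    report = evaluate(model, masks[te], labels[te])
    return SequenceResult(model=model, report=report, indices=(tr, va, te),
                          scaler=None)


# ---------------------------------------------------------- cross-validation

def cross_validate(model_builder, samples, labels: np.ndarray, k: int = 5,
                   seed: int = 0) -> dict:
    """Stratified k-fold cross-validation, each fold trained from scratch.

    ``model_builder()`` must return a fresh estimator with
    fit(X, y) / predict(X); ``samples`` may be an array or a tuple of
    aligned arrays (e.g. sequences plus validity masks), in which case
    fit and predict receive the indexed tuple elements as leading
    arguments.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    rng = np.random.default_rng(seed)
    folds: list[np.ndarray] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = rng.permutation(np.nonzero(labels == cls)[0])
        if idx.size < k:
            raise ValueError(f"class {cls} has fewer samples than folds")
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    folds = [np.sort(np.array(f)) for f in folds]

    def take(idx):
        if isinstance(samples, tuple):
            return tuple(s[idx] for s in samples)
        return samples[idx]

    accs = []
    for i in range(k):
        test_idx = folds[i]
        train_idx = np.sort(np.concatenate(
            [folds[j] for j in range(k) if j != i]))
        model = model_builder()
        xtr, xte = take(train_idx), take(test_idx)
        if isinstance(samples, tuple):
            model.fit(*xtr, labels[train_idx])
            y_pred = model.predict(*xte)
        else:
            model.fit(xtr, labels[train_idx])
            y_pred = model.predict(xte)
        accs.append(float((y_pred == labels[test_idx]).mean()))
    accs_arr = np.array(accs)
    sem = float(accs_arr.std(ddof=1) / math.sqrt(k)) if k > 1 else 0.0
    return {"fold_accuracies": accs, "mean": float(accs_arr.mean()),
            "sem": sem, "fold_sizes": [len(f) for f in folds]}
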