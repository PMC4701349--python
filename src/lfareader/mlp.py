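"""Tansig multilayer perceptrons with a reject option, sklearn-style.

Classification of a preprocessed lateral histogram runs through a fixed
five-step chain, all of whose statistics come from the training split only:

1. per-bin z-scoring against the training mean and standard deviation,
2. an affine map sending the training minimum/maximum of each bin to -1/+1,
3. a fully-connected network in which *every* neuron, hidden and output,
   applies the hyperbolic-tangent sigmoid to its weighted input plus bias,
4. a reverse affine map of each output back to the training-target scale
   (class indicators on [0, 1]),
5. thresholding: the argmax output wins only if its reverse-mapped score
   reaches that class's confidence threshold, otherwise the classifier
   answers ``"undetermined"``.

Three fixed architectures are used by the reader: 62-5-2 for alcohol
strips, 31-1-2 for control lines and 31-7-7-5 for test lines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .config import TrainerParams
from .errors import DataError
from .synthetic import TEST_LINE_CLASSES

UNDETERMINED = "undetermined"

# kind -> (input slice of the 62-bin profile, hidden layer sizes, class order)
ARCHITECTURES: dict[str, tuple[slice, tuple[int, ...], tuple[str, ...]]] = {
    "alcohol": (slice(0, 62), (5,), ("positive", "negative")),
    "control": (slice(0, 31), (1,), ("valid", "invalid")),
    "testline": (slice(31, 62), (7, 7), TEST_LINE_CLASSES),
}


# ---------------------------------------------------------------------------
# the five chain steps as plain functions (unit-testable in isolation)
# ---------------------------------------------------------------------------

def normalize(X: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    """Per-bin z-score against training statistics."""
    return (np.asarray(X, float) - mean) / std


def map_input(X_normalized: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Affine map sending the training min to -1 and max to +1 per bin.

    Out-of-range inputs map outside [-1, 1]; no clipping is applied.
    """
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    if np.any(hi <= lo):
        raise DataError("degenerate mapping bounds (max <= min)")
    return 2.0 * (np.asarray(X_normalized, float) - lo) / (hi - lo) - 1.0


def mlp_forward(X_mapped: np.ndarray, weights: list[np.ndarray],
                biases: list[np.ndarray]) -> np.ndarray:
    """Layered tansig evaluation; outputs lie in (-1, 1)."""
    a = np.atleast_2d(np.asarray(X_mapped, float))
    if a.shape[1] != weights[0].shape[0]:
        raise DataError(
            f"input width {a.shape[1]} != network input {weights[0].shape[0]}")
    for W, b in zip(weights, biases):
        a = np.tanh(a @ W + b)
    return a


def reverse_map(Y_nn: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Inverse affine map from (-1, 1) network outputs to the target scale."""
    return (np.asarray(Y_nn, float) + 1.0) / 2.0 * (np.asarray(hi, float)
                                                    - np.asarray(lo, float)) + lo


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class TansigMLPClassifier(ClassifierMixin, BaseEstimator):
    """Small all-tansig MLP with confidence thresholding ("undetermined").

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Neurons per hidden layer.
    threshold : float or sequence of float
        Per-class confidence threshold on the reverse-mapped [0, 1] scale.
        Predictions whose winning score falls below it become
        ``"undetermined"``.
    class_order : sequence of str, optional
        Explicit label order (meaningful for ordinal class sets); defaults
        to the sorted unique training labels.
    learning_rate, max_epochs, patience, l2, class_weight
        Full-batch Adam settings; training minimizes (optionally
        class-balanced) squared error against +-1 encoded targets, with an
        L2 weight penalty and early stopping on validation success (or
        training loss when no validation split is given).
    random_state : int
        Seeds weight initialization; training is deterministic given it.

    Attributes
    ----------
    classes_ : ndarray of training labels in model order.
    norm_mean_, norm_std_ : per-bin training statistics.
    map_min_, map_max_ : per-bin bounds of the [-1, 1] input map.
    reverse_min_, reverse_max_ : per-output bounds of the reverse map.
    coefs_, intercepts_ : layer weights and biases.
    n_iter_ : epochs actually run.
    """

    def __init__(self, hidden_layer_sizes=(5,), threshold=0.9,
                 class_order=None, learning_rate=0.02, max_epochs=4000,
                 patience=300, l2=1e-4, class_weight="balanced",
                 random_state=0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.threshold = threshold
        self.class_order = class_order
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.l2 = l2
        self.class_weight = class_weight
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = check_X_y(X, np.asarray(y, dtype=object))
        if self.class_order is not None:
            classes = np.asarray(self.class_order, dtype=object)
            unknown = set(y) - set(classes)
            if unknown:
                raise DataError(f"labels {unknown} not in class_order")
        else:
            classes = np.unique(y)
        self.classes_ = classes
        counts = pd.Series(y).value_counts()
        if (counts.reindex(classes).fillna(0) < 2).any():
            raise DataError("every class needs at least 2 training samples")

        self.norm_mean_ = X.mean(axis=0)
        self.norm_std_ = X.std(axis=0, ddof=0)
        if np.any(self.norm_std_ < 1e-12):
            raise DataError("a histogram bin is constant over the training set")
        Xn = normalize(X, self.norm_mean_, self.norm_std_)
        self.map_min_ = Xn.min(axis=0)
        self.map_max_ = Xn.max(axis=0)
        Xm = map_input(Xn, self.map_min_, self.map_max_)

        # class-indicator targets on [0, 1]; the network trains against
        # their +-1 remapping
        class_index = {c: k for k, c in enumerate(classes)}
        T01 = np.zeros((len(y), len(classes)))
        T01[np.arange(len(y)), [class_index[c] for c in y]] = 1.0
        self.reverse_min_ = T01.min(axis=0)
        self.reverse_max_ = T01.max(axis=0)
        T = 2.0 * T01 - 1.0

        if self.class_weight == "balanced":
            freq = T01.mean(axis=0)
            sample_weight = 1.0 / (len(classes) * freq[T01.argmax(axis=1)])
        elif self.class_weight is None:
            sample_weight = np.ones(len(y))
        else:
            raise DataError(f"unsupported class_weight {self.class_weight!r}")

        if X_val is not None:
            X_val = check_array(X_val)
            y_val = np.asarray(y_val, dtype=object)

        self._fit_network(Xm, T, sample_weight, X_val, y_val)
        return self

    def _init_layers(self, n_in: int, rng: np.random.Generator):
        sizes = [n_in, *self.hidden_layer_sizes, len(self.classes_)]
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            r = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-r, r, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return weights, biases

    def _fit_network(self, Xm, T, sample_weight, X_val, y_val):
        rng = np.random.default_rng(self.random_state)
        W, b = self._init_layers(Xm.shape[1], rng)
        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(v) for v in b]
        vb = [np.zeros_like(v) for v in b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate
        n = Xm.shape[0]

        best = (-np.inf, np.inf)   # (validation success, -ish; loss)
        best_Wb = None
        since_best = 0
        self.loss_curve_ = []
        for epoch in range(1, self.max_epochs + 1):
            # forward with cached activations
            acts = [Xm]
            for Wl, bl in zip(W, b):
                acts.append(np.tanh(acts[-1] @ Wl + bl))
            out = acts[-1]
            err = (out - T) * sample_weight[:, None]
            loss = float(((out - T) ** 2).mean())
            self.loss_curve_.append(loss)

            # backprop of (weighted) mean squared error through tanh layers
            delta = 2.0 * err / err.size * (1.0 - out ** 2)
            for layer in range(len(W) - 1, -1, -1):
                gW = acts[layer].T @ delta + self.l2 * W[layer]
                gb = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ W[layer].T) * (1.0 - acts[layer] ** 2)
                # Adam update
                mW[layer] = beta1 * mW[layer] + (1 - beta1) * gW
                vW[layer] = beta2 * vW[layer] + (1 - beta2) * gW ** 2
                mb[layer] = beta1 * mb[layer] + (1 - beta1) * gb
                vb[layer] = beta2 * vb[layer] + (1 - beta2) * gb ** 2
                t = epoch
                mW_h = mW[layer] / (1 - beta1 ** t)
                vW_h = vW[layer] / (1 - beta2 ** t)
                mb_h = mb[layer] / (1 - beta1 ** t)
                vb_h = vb[layer] / (1 - beta2 ** t)
                W[layer] -= lr * mW_h / (np.sqrt(vW_h) + eps)
                b[layer] -= lr * mb_h / (np.sqrt(vb_h) + eps)

            self.coefs_, self.intercepts_ = W, b
            if X_val is not None and len(X_val):
                score = (self.predict(X_val) == y_val).mean()
            else:
                score = 0.0
            key = (score, -loss)
            if best_Wb is None or key > best:
                best = key
                best_Wb = ([w.copy() for w in W], [v.copy() for v in b])
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break

        self.coefs_, self.intercepts_ = best_Wb
        self.n_iter_ = epoch
        if X_val is not None and len(X_val):
            self.best_validation_success_ = float(best[0])
        return self

    # -- inference ---------------------------------------------------------

    def _thresholds(self) -> np.ndarray:
        thr = np.asarray(self.threshold, dtype=float)
        if thr.ndim == 0:
            thr = np.full(len(self.classes_), float(thr))
        if thr.size != len(self.classes_):
            raise DataError("threshold must be scalar or one per class")
        return thr

    def predict_scores(self, X) -> np.ndarray:
        """Reverse-mapped class scores (the Eq-chain output before Eq. 8)."""
        check_is_fitted(self, "coefs_")
        X = check_array(X)
        Xm = map_input(normalize(X, self.norm_mean_, self.norm_std_),
                       self.map_min_, self.map_max_)
        Y = mlp_forward(Xm, self.coefs_, self.intercepts_)
        return reverse_map(Y, self.reverse_min_, self.reverse_max_)

    def predict(self, X) -> np.ndarray:
        """Class labels, or ``"undetermined"`` below the confidence threshold.

        Argmax ties resolve toward the lowest class index.
        """
        scores = self.predict_scores(X)
        thr = self._thresholds()
        winners = scores.argmax(axis=1)
        confident = scores[np.arange(len(scores)), winners] >= thr[winners]
        labels = self.classes_[winners].astype(object)
        labels[~confident] = UNDETERMINED
        return labels


def classify(h_x: np.ndarray, model: TansigMLPClassifier) -> str:
    """Single-histogram convenience wrapper around :meth:`predict`."""
    return str(model.predict(np.atleast_2d(h_x))[0])


# ---------------------------------------------------------------------------
# evaluation and training protocol
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Success rate and confusion matrix for one data split.

    The confusion matrix has one row per true class and one predicted
    column per class plus ``undetermined``; success counts exact matches
    only, so rejected samples are failures.
    """

    split: str
    success_rate: float        # percent
    confusion: pd.DataFrame

    def __str__(self) -> str:
        return (f"{self.split}: success {self.success_rate:.3f}%\n"
                f"{self.confusion.to_string()}")


def evaluate(model: TansigMLPClassifier, X, y, split: str = "test"
             ) -> EvaluationReport:
    y = np.asarray(y, dtype=object)
    unknown = set(y) - set(model.classes_)
    if unknown:
        raise DataError(f"labels {unknown} unknown to the model")
    pred = model.predict(X)
    cols = list(model.classes_) + [UNDETERMINED]
    confusion = pd.DataFrame(0, index=list(model.classes_), columns=cols)
    for truth, guess in zip(y, pred):
        confusion.loc[truth, guess] += 1
    success = 100.0 * float((pred == y).mean())
    return EvaluationReport(split=split, success_rate=success,
                            confusion=confusion)


def _feature_matrix(dataset: pd.DataFrame, kind: str) -> np.ndarray:
    cols = [c for c in dataset.columns if c.startswith("bin_")]
    if len(cols) != 62:
        raise DataError(f"expected 62 bin_* columns, found {len(cols)}")
    X = dataset[sorted(cols)].to_numpy(dtype=float)
    return X[:, ARCHITECTURES[kind][0]]


def train(dataset: pd.DataFrame, kind: str,
          split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
          trainer_params: TrainerParams | None = None, seed: int = 0,
          threshold: float = 0.9):
    """Train one of the three strip classifiers on a labeled histogram table.

    The data are split stratified-by-class into training/validation/test
    subsets (default 70/15/15); normalization, mapping and reverse-mapping
    bounds come from the training subset only; the network is fitted with
    early stopping on validation success.  Returns the fitted model and an
    :class:`EvaluationReport` per split.
    """
    if kind not in ARCHITECTURES:
        raise DataError(f"unknown classifier kind {kind!r}")
    if not np.isclose(sum(split_ratios), 1.0):
        raise DataError("split_ratios must sum to 1")
    tp = trainer_params or TrainerParams()
    _, hidden, class_order = ARCHITECTURES[kind]

    X = _feature_matrix(dataset, kind)
    y = dataset["label"].to_numpy(dtype=object)
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise DataError("every class needs at least 2 samples")

    holdout = split_ratios[1] + split_ratios[2]
    X_tr, X_rest, y_tr, y_rest = train_test_split(
        X, y, test_size=holdout, stratify=y, random_state=seed)
    X_val, X_te, y_val, y_te = train_test_split(
        X_rest, y_rest, test_size=split_ratios[2] / holdout,
        stratify=y_rest, random_state=seed + 1)

    model = TansigMLPClassifier(
        hidden_layer_sizes=hidden, threshold=threshold,
        class_order=class_order, learning_rate=tp.learning_rate,
        max_epochs=tp.max_epochs, patience=tp.patience, l2=tp.l2,
        class_weight=tp.class_weight, random_state=seed)
    model.fit(X_tr, y_tr, X_val=X_val, y_val=y_val)
    model.kind_ = kind

    reports = {
        "training": evaluate(model, X_tr, y_tr, "training"),
        "validation": evaluate(model, X_val, y_val, "validation"),
        "test": evaluate(model, X_te, y_te, "test"),
    }
    return model, reports


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(model: TansigMLPClassifier, path: str | Path) -> None:
    check_is_fitted(model, "coefs_")
    payload = {
        "kind": getattr(model, "kind_", None),
        "hidden_layer_sizes": list(model.hidden_layer_sizes),
        "threshold": np.asarray(model.threshold).tolist(),
        "classes": list(map(str, model.classes_)),
        "norm_mean": model.norm_mean_.tolist(),
        "norm_std": model.norm_std_.tolist(),
        "map_min": model.map_min_.tolist(),
        "map_max": model.map_max_.tolist(),
        "reverse_min": model.reverse_min_.tolist(),
        "reverse_max": model.reverse_max_.tolist(),
        "weights": [w.tolist() for w in model.coefs_],
        "biases": [v.tolist() for v in model.intercepts_],
        "random_state": model.random_state,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TansigMLPClassifier:
    payload = json.loads(Path(path).read_text())
    model = TansigMLPClassifier(
        hidden_layer_sizes=tuple(payload["hidden_layer_sizes"]),
        threshold=payload["threshold"],
        class_order=payload["classes"],
        random_state=payload.get("random_state", 0))
    model.classes_ = np.asarray(payload["classes"], dtype=object)
    model.norm_mean_ = np.asarray(payload["norm_mean"])
    model.norm_std_ = np.asarray(payload["norm_std"])
    model.map_min_ = np.asarray(payload["map_min"])
    model.map_max_ = np.asarray(payload["map_max"])
    model.reverse_min_ = np.asarray(payload["reverse_min"])
    model.reverse_max_ = np.asarray(payload["reverse_max"])
    model.coefs_ = [np.asarray(w) for w in payload["weights"]]
    model.intercepts_ = [np.asarray(v) for v in payload["biases"]]
    if payload.get("kind"):
        model.kind_ = payload["kind"]
    return model
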