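"""Optimization with validation stopping, accuracy evaluation, and the
band-power logistic-regression baseline.

The decoder is trained by minimizing cross-entropy with Adam (learning rate
1e-3, default moments), batch size 32, for a fixed number of epochs; the
parameters from the epoch with the lowest validation loss are restored before
the test set is touched.  The spatial-filter rows are projected back inside
the unit max-norm ball after every optimizer step.

The baseline is a binary logistic regression on 40 log band-power features
(10 regions x 4 bands: delta 2-4, theta 4-8, alpha 8-13, beta 15-32 Hz),
trained by full-batch gradient descent with the same best-validation
selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .data_model import CLASSES, CVSplit, WindowSample
from .model import InteractionDecoder

#: Baseline feature bands, region-major ordering (region, then band).
BASELINE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 2.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 15.0, 32.0),
)

LOG_FLOOR = 1e-12


@dataclass
class TrainReport:
    best_epoch: int
    val_loss_curve: list[float]
    test_accuracy: float
    fold_id: int = -1
    participant_id: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.val_loss_curve:
            assert self.best_epoch == int(np.argmin(self.val_loss_curve))
        assert 0.0 <= self.test_accuracy <= 1.0


@dataclass
class BaselineModel:
    """Logistic regression over the 40 (region, band) log-power features."""

    weights: np.ndarray  # (40,)
    intercept: float
    feature_mean: np.ndarray = field(default_factory=lambda: np.zeros(40))
    feature_std: np.ndarray = field(default_factory=lambda: np.ones(40))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X) - self.feature_mean) / self.feature_std
        return 1.0 / (1.0 + np.exp(-(Z @ self.weights + self.intercept)))


def _labels_to_int(labels) -> np.ndarray:
    return np.array([CLASSES.index(l) for l in labels], dtype=int)


def split_windows(
    windows: list[WindowSample], split: CVSplit
) -> tuple[list[WindowSample], list[WindowSample], list[WindowSample]]:
    """Partition windows by a fold's id sets (trial ids within, participant
    ids across)."""
    key = (lambda w: w.trial_id) if split.scope == "within" else (lambda w: w.participant_id)
    tr = [w for w in windows if key(w) in split.train_ids]
    va = [w for w in windows if key(w) in split.val_ids]
    te = [w for w in windows if key(w) in split.test_ids]
    return tr, va, te


class Adam:
    """Standard Adam over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for k, gk in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            params[k] -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def _stack(windows: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([w.data for w in windows])
    y = _labels_to_int([w.label for w in windows])
    return X, y


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return -float(np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))


def _eval_loss(model: InteractionDecoder, X: np.ndarray, y: np.ndarray,
               batch_size: int = 128) -> float:
    losses, ns = [], []
    for i in range(0, len(y), batch_size):
        probs = model.forward(X[i : i + batch_size])
        losses.append(cross_entropy(probs, y[i : i + batch_size]) * len(y[i : i + batch_size]))
        ns.append(len(y[i : i + batch_size]))
    return float(np.sum(losses) / np.sum(ns))


def train_decoder(
    model: InteractionDecoder,
    split: CVSplit,
    windows: list[WindowSample],
    epochs: int = 200,
    batch_size: int = 32,
    seed: int = 0,
    lr: float = 1e-3,
) -> TrainReport:
    """Train the decoder on a fold and report held-out test accuracy.

    Runs all epochs, recording the validation loss after each; the parameters
    of the best-validation epoch are restored before accuracy is computed on
    the test windows (which are never otherwise touched).  Window order is
    reshuffled every epoch from the seeded generator; dropout draws from the
    same generator, so identical seeds give identical runs.
    """
    train_w, val_w, test_w = split_windows(windows, split)
    if not (train_w and val_w and test_w):
        raise ValueError("split produced an empty train/val/test window set")
    Xtr, ytr = _stack(train_w)
    Xva, yva = _stack(val_w)
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=lr)
    val_curve: list[float] = []
    best_state = model.state_dict()
    best_loss = np.inf
    n = len(ytr)
    for _epoch in range(epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            _, grads = model.loss_and_grads(Xtr[idx], ytr[idx], rng)
            opt.step(model.params, grads)
            model.project_maxnorm()
        vloss = _eval_loss(model, Xva, yva)
        val_curve.append(vloss)
        if vloss < best_loss:
            best_loss = vloss
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    acc = evaluate_accuracy(model, test_w)
    return TrainReport(
        best_epoch=int(np.argmin(val_curve)),
        val_loss_curve=val_curve,
        test_accuracy=acc,
        fold_id=split.fold_id,
        participant_id=test_w[0].participant_id,
        seed=seed,
    )


def evaluate_accuracy(model: InteractionDecoder, windows: list[WindowSample],
                      batch_size: int = 128) -> float:
    """Fraction of windows whose argmax class probability matches the label."""
    if not windows:
        raise ValueError("need at least one window")
    X, y = _stack(windows)
    hits = 0
    for i in range(0, len(y), batch_size):
        probs = model.forward(X[i : i + batch_size])
        hits += int(np.sum(np.argmax(probs, axis=1) == y[i : i + batch_size]))
    return hits / len(y)


# ---------------------------------------------------------------------------
# Band-power logistic baseline
# ---------------------------------------------------------------------------

def bandpower_features(data: np.ndarray, fs: float = 64.0) -> np.ndarray:
    """40 log band-power features from a 30 x T enhanced trial or window.

    Per region, the Welch power spectra of the region's three enhanced
    channels are averaged (channel signs are arbitrary after
    eigendecomposition, so spectra — not signals — are combined), then
    averaged inside each of the four baseline bands; features are
    log10-scaled with a small floor and ordered region-major, band-minor.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.shape[0] != 30:
        raise ValueError(f"expected 30 channels, got {data.shape[0]}")
    T = data.shape[1]
    lowest = min(b[1] for b in BASELINE_BANDS)
    if T < 2 * fs / lowest:
        raise ValueError(
            f"window of {T} samples shorter than 2 periods of {lowest} Hz"
        )
    feats = np.empty(10 * len(BASELINE_BANDS))
    nperseg = min(T, 128)
    for r in range(10):
        freqs, psd = scipy.signal.welch(data[3 * r : 3 * r + 3], fs=fs, nperseg=nperseg)
        psd = psd.mean(axis=0)
        for b, (_code, lo, hi) in enumerate(BASELINE_BANDS):
            sel = (freqs >= lo) & (freqs <= hi)
            feats[r * len(BASELINE_BANDS) + b] = np.log10(psd[sel].mean() + LOG_FLOOR)
    return feats


@dataclass
class FeatureSample:
    """A baseline feature vector with the provenance needed for splitting."""

    features: np.ndarray
    label: str
    trial_id: int
    block_id: int = -1
    participant_id: str = ""


def windows_to_features(windows: list[WindowSample], fs: float = 64.0) -> list[FeatureSample]:
    return [
        FeatureSample(
            features=bandpower_features(w.data, fs),
            label=w.label,
            trial_id=w.trial_id,
            block_id=w.block_id,
            participant_id=w.participant_id,
        )
        for w in windows
    ]


def train_baseline(
    samples: list[FeatureSample],
    split: CVSplit,
    seed: int = 0,
    lr: float = 0.05,
    n_iter: int = 2000,
) -> tuple[BaselineModel, TrainReport]:
    """Gradient-descent logistic regression with best-validation selection.

    Full-batch gradient descent on binary cross-entropy; features are
    standardized with training-set statistics.  The weight/intercept state
    from the iteration with the lowest validation loss is returned, and
    accuracy is reported on the test partition only.
    """
    key = (lambda s: s.trial_id) if split.scope == "within" else (lambda s: s.participant_id)
    tr = [s for s in samples if key(s) in split.train_ids]
    va = [s for s in samples if key(s) in split.val_ids]
    te = [s for s in samples if key(s) in split.test_ids]
    if not (tr and va and te):
        raise ValueError("split produced an empty train/val/test feature set")

    def xy(group):
        X = np.stack([s.features for s in group])
        y = _labels_to_int([s.label for s in group]).astype(float)
        return X, y

    Xtr, ytr = xy(tr)
    Xva, yva = xy(va)
    Xte, yte = xy(te)
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    Ztr = (Xtr - mu) / sd
    Zva = (Xva - mu) / sd

    rng = np.random.default_rng(seed)
    w = rng.normal(0, 0.01, size=Xtr.shape[1])
    b = 0.0
    best = (w.copy(), b)
    best_loss = np.inf
    curve = []

    def bce(Z, y, w, b):
        p = 1.0 / (1.0 + np.exp(-(Z @ w + b)))
        return -float(np.mean(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12)))

    n = len(ytr)
    for _it in range(n_iter):
        p = 1.0 / (1.0 + np.exp(-(Ztr @ w + b)))
        err = p - ytr
        w -= lr * (Ztr.T @ err) / n
        b -= lr * float(err.mean())
        vloss = bce(Zva, yva, w, b)
        curve.append(vloss)
        if vloss < best_loss:
            best_loss = vloss
            best = (w.copy(), b)
    w, b = best
    mdl = BaselineModel(weights=w, intercept=b, feature_mean=mu, feature_std=sd)
    pred = (mdl.predict_proba(Xte) > 0.5).astype(int)
    acc = float(np.mean(pred == yte.astype(int)))
    return mdl, TrainReport(
        best_epoch=int(np.argmin(curve)),
        val_loss_curve=curve,
        test_accuracy=acc,
        fold_id=split.fold_id,
        participant_id=te[0].participant_id,
        seed=seed,
    )
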