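"""Training: class-weighted cross-entropy, step-decayed SGD, early stopping,
stratified cross-validation and a pluggable hyperparameter search.

Class imbalance is handled with the "balanced" inverse-frequency weighting
``w_j = total / (n_classes * count_j)`` applied as per-sample loss
multipliers (no resampling, no augmentation).  The learning rate follows a
step schedule ``eta = eta0 * 0.1^floor(epoch/30)``; training stops early
when validation accuracy has not improved for ``patience`` epochs, restoring
the best weights seen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classes import N_CLASSES
from .nn.model import DualBranchModel

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """Aligned model inputs: segments, spectral vectors, one-hot labels."""

    inputs1: np.ndarray  # (n, 1201)
    inputs2: np.ndarray  # (n, 292)
    labels: np.ndarray   # (n, 4) one-hot
    groups: np.ndarray   # (n,) record ids

    def __post_init__(self) -> None:
        n = self.inputs1.shape[0]
        if not (self.inputs2.shape[0] == n == self.labels.shape[0] == len(self.groups)):
            raise ValueError("inputs1, inputs2, labels and groups must align on n")
        row_sums = self.labels.sum(axis=1)
        if self.labels.size and not np.all(row_sums == 1):
            raise ValueError("labels must be one-hot rows")

    def __len__(self) -> int:
        return self.inputs1.shape[0]

    @property
    def y(self) -> np.ndarray:
        """Integer class indices."""
        return self.labels.argmax(axis=1)

    def subset(self, idx) -> "Dataset":
        return Dataset(self.inputs1[idx], self.inputs2[idx],
                       self.labels[idx], np.asarray(self.groups)[idx])

    @staticmethod
    def from_indices(inputs1, inputs2, y, groups) -> "Dataset":
        labels = np.zeros((len(y), N_CLASSES))
        labels[np.arange(len(y)), y] = 1.0
        return Dataset(np.asarray(inputs1), np.asarray(inputs2), labels,
                       np.asarray(groups))


@dataclass
class TrainConfig:
    eta0: float = 0.01
    decay_factor: float = 0.1
    decay_every: int = 30
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    momentum: float = 0.0
    seed: int = 0
    class_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if min(self.eta0, self.decay_factor, self.decay_every,
               self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("all TrainConfig scalars must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


def class_weights(counts) -> np.ndarray:
    """Balanced inverse-frequency weights: ``w_j = total / (4 * count_j)``."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} class counts")
    if (counts <= 0).any():
        raise ValueError("every class must have at least one example")
    return counts.sum() / (N_CLASSES * counts)


def weighted_cross_entropy(y: np.ndarray, y_hat: np.ndarray,
                           weights=None, clamp: float = 1e-7) -> float:
    """Mean class-weighted cross-entropy over a one-hot batch.

    ``-(1/k) * sum_i w_class(i) * log(y_hat_i[class(i)])``; with unit
    weights this is the plain categorical cross-entropy.  Probabilities at
    the true class are clamped at ``clamp`` (and the event logged) rather
    than propagating -inf.
    """
    y = np.atleast_2d(y)
    y_hat = np.atleast_2d(y_hat)
    cls = y.argmax(axis=1)
    p = y_hat[np.arange(len(cls)), cls]
    if (p < clamp).any():
        logger.warning("clamped %d near-zero probabilities in loss", int((p < clamp).sum()))
        p = np.maximum(p, clamp)
    w = np.ones(N_CLASSES) if weights is None else np.asarray(weights, dtype=float)
    if w.ndim == 0:
        w = np.full(N_CLASSES, float(w))
    return float(-(w[cls] * np.log(p)).mean())


def lr_at_epoch(n: int, cfg: TrainConfig) -> float:
    """Step-decay schedule: ``eta0 * decay_factor ** floor(n / decay_every)``."""
    if n < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.eta0 * cfg.decay_factor ** (n // cfg.decay_every)


def stratified_folds(labels, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Disjoint, exhaustive, per-class-balanced fold index lists.

    Per-class counts across folds differ by at most 1; deterministic under
    ``seed``.  A class with fewer than ``k`` members is an error.
    """
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels.argmax(axis=1)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls} has {idx.size} members, fewer than k={k}")
        rng.shuffle(idx)
        # rotate the starting fold so remainders spread across folds
        for i, j in enumerate(idx):
            folds[(start + i) % k].append(int(j))
        start += idx.size % k
    return [np.array(sorted(f)) for f in folds]


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -1.0
    stopped_early: bool = False


def history_to_csv(hist: "TrainHistory", path) -> None:
    """Per-epoch training history (epoch, lr, loss, validation accuracy)."""
    lines = ["epoch,lr,train_loss,val_accuracy"]
    for e, lr, loss, acc in zip(hist.epochs, hist.lr, hist.train_loss,
                                hist.val_accuracy):
        lines.append(f"{e},{lr:g},{loss:.6f},{acc:.6f}")
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def _accuracy(model: DualBranchModel, data: Dataset, batch_size: int = 64) -> float:
    pred = model.predict(data.inputs1, data.inputs2, batch_size)
    return float((pred == data.y).mean())


def train(model: DualBranchModel, train_data: Dataset, val_data: Dataset,
          cfg: TrainConfig) -> TrainHistory:
    """Mini-batch SGD with the step-decay schedule and early stopping.

    Class weights enter as per-sample multipliers on the cross-entropy
    gradient; early stopping monitors unweighted validation accuracy and
    restores the best weights.  Divergence (NaN loss) aborts.
    """
    rng = np.random.default_rng(cfg.seed)
    w = (np.ones(N_CLASSES) if cfg.class_weights is None
         else np.asarray(cfg.class_weights, dtype=float))
    n = len(train_data)
    hist = TrainHistory()
    best_snapshot = model.get_weights()
    since_best = 0
    velocity = None

    for epoch in range(cfg.max_epochs):
        lr = lr_at_epoch(epoch, cfg)
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            x1, x2 = train_data.inputs1[idx], train_data.inputs2[idx]
            y = train_data.labels[idx]
            p = model.forward(x1, x2, train=True)
            losses.append(weighted_cross_entropy(y, p, w))
            # d(loss)/d(probabilities) for the weighted NLL
            cls = y.argmax(axis=1)
            wi = w[cls][:, None]
            p_safe = np.maximum(p, 1e-7)
            dp = -(wi * y / p_safe) / len(idx)
            model.backward(dp)
            if cfg.momentum > 0:
                if velocity is None:
                    velocity = [{k: np.zeros_like(g) for k, g in l.grads.items()}
                                for l in model.layers]
                for l, v in zip(model.layers, velocity):
                    for name, g in l.grads.items():
                        v[name] = cfg.momentum * v[name] - lr * g
                        l.params[name] += v[name]
            else:
                model.sgd_step(lr)
        epoch_loss = float(np.mean(losses))
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (loss = {epoch_loss})"
            )
        val_acc = _accuracy(model, val_data)
        hist.epochs.append(epoch)
        hist.lr.append(lr)
        hist.train_loss.append(epoch_loss)
        hist.val_accuracy.append(val_acc)
        if val_acc > hist.best_val_accuracy:
            hist.best_val_accuracy = val_acc
            hist.best_epoch = epoch
            best_snapshot = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                hist.stopped_early = True
                break
        logger.debug("epoch %d lr %.2g loss %.4f val_acc %.4f",
                     epoch, lr, epoch_loss, val_acc)
    model.set_weights(best_snapshot)
    return hist


# ---------------------------------------------------------------------------
# Hyperparameter search


@dataclass
class SearchSpace:
    """Named choice sets (lists) and continuous ranges (lo, hi tuples)."""

    params: dict[str, object]

    def __post_init__(self) -> None:
        for name, spec in self.params.items():
            if isinstance(spec, (list, tuple)) and len(spec) == 0:
                raise ValueError(f"empty choice set for {name!r}")

    def sample(self, rng: np.random.Generator) -> dict:
        out = {}
        for name, spec in self.params.items():
            if isinstance(spec, list):
                out[name] = spec[rng.integers(len(spec))]
            else:
                lo, hi = spec
                out[name] = float(rng.uniform(lo, hi))
        return out

    def encode(self, config: dict) -> np.ndarray:
        """Normalized numeric vector for the surrogate model."""
        vec = []
        for name, spec in self.params.items():
            v = config[name]
            if isinstance(spec, list):
                vec.append(spec.index(v) / max(len(spec) - 1, 1))
            else:
                lo, hi = spec
                vec.append((v - lo) / (hi - lo))
        return np.array(vec)


def hyperparameter_search(space: SearchSpace, objective, budget: int,
                          strategy: str = "random", seed: int = 0):
    """Sequential search for the config maximizing a validation objective.

    ``random`` draws i.i.d. configurations; ``model_based`` is a sequential
    model-based strategy that fits a Gaussian-process surrogate to the
    observed (config, score) pairs and proposes the candidate with maximal
    expected improvement.  A failing objective scores ``-inf`` and the
    trial is still logged.  Returns ``(best_config, trials)``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if strategy not in ("random", "model_based"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    trials: list[tuple[dict, float]] = []

    def evaluate(config: dict) -> float:
        try:
            score = float(objective(config))
        except Exception as exc:  # noqa: BLE001 - objective failures are data
            logger.warning("objective failed on %s: %s", config, exc)
            score = -np.inf
        trials.append((config, score))
        return score

    n_init = budget if strategy == "random" else min(max(5, budget // 5), budget)
    for _ in range(n_init):
        evaluate(space.sample(rng))

    if strategy == "model_based" and len(trials) < budget:
        from scipy.stats import norm
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern, WhiteKernel

        while len(trials) < budget:
            X = np.array([space.encode(c) for c, s in trials if np.isfinite(s)])
            ys = np.array([s for _, s in trials if np.isfinite(s)])
            if len(ys) < 2:
                evaluate(space.sample(rng))
                continue
            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5) + WhiteKernel(1e-6),
                normalize_y=True,
                random_state=int(rng.integers(2**31)),
            )
            gp.fit(X, ys)
            cands = [space.sample(rng) for _ in range(256)]
            Xc = np.array([space.encode(c) for c in cands])
            mu, sigma = gp.predict(Xc, return_std=True)
            best = ys.max()
            sigma = np.maximum(sigma, 1e-12)
            z = (mu - best) / sigma
            ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
            evaluate(cands[int(np.argmax(ei))])

    best_config, _ = max(trials, key=lambda t: t[1])
    return best_config, trials
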