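"""Training and evaluation protocol.

The evaluation convention is ten independent stratified 80/10/10
resamples with distinct seeds; each run trains with Adam and early
stopping on validation accuracy (patience 50, ties broken by lower
validation loss), restores the best-validation parameters and reports
the test accuracy of that model.  Mean and standard deviation over the
repeats are the headline numbers.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import train_test_split

from .autodiff import Adam
from .graph_data import GraphDataset, batch_dense
from .model import HierarchicalGNN, ModelConfig, total_loss

__all__ = ["TrainConfig", "EvalReport", "split_dataset", "train_once", "run_protocol", "evaluate"]


@dataclass
class TrainConfig:
    """Optimization and protocol settings (reference defaults)."""

    lr: float = 5e-4
    weight_decay: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 500
    patience: int = 50
    repeats: int = 10
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seeds: tuple[int, ...] = tuple(range(10))
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


@dataclass
class EvalReport:
    """Per-repeat accuracies with their mean and std, plus training curves."""

    accuracies: list[float] = field(default_factory=list)
    curves: list[list[dict]] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    last_model: "HierarchicalGNN | None" = None  # model of the final repeat

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def std(self) -> float:
        return float(np.std(self.accuracies))

    def to_dict(self) -> dict:
        return {"accuracies": self.accuracies, "mean": self.mean, "std": self.std,
                "config": self.config}


def split_dataset(dataset: GraphDataset, seed: int,
                  ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/val/test index split, deterministic under `seed`.

    Sizes are floor(r_train * n) and floor(r_val * n); the remainder is
    the test set.  Falls back to an unstratified split (with a warning)
    when some class has fewer than 3 members.
    """
    if len(dataset) < 10:
        raise ValueError("need at least 10 graphs to split")
    labels = dataset.labels()
    n = len(dataset)
    n_train, n_val = int(ratios[0] * n), int(ratios[1] * n)

    counts = np.bincount(labels)
    stratify: np.ndarray | None = labels
    if (counts[counts > 0] < 3).any():
        warnings.warn("a class has fewer than 3 graphs; splitting without stratification")
        stratify = None

    indices = np.arange(n)
    train, rest = train_test_split(indices, train_size=n_train, random_state=seed,
                                   stratify=stratify)
    val, test = train_test_split(rest, train_size=n_val, random_state=seed,
                                 stratify=None if stratify is None else labels[rest])
    return np.sort(train), np.sort(val), np.sort(test)


def _iterate_minibatches(indices: np.ndarray, batch_size: int, rng: np.random.Generator):
    shuffled = rng.permutation(indices)
    for i in range(0, len(shuffled), batch_size):
        yield shuffled[i:i + batch_size]


def evaluate(model: HierarchicalGNN, dataset: GraphDataset, indices: np.ndarray,
             batch_size: int = 128) -> tuple[float, float]:
    """(accuracy, mean total loss) on `indices`, eval mode (no dropout)."""
    correct, losses, total = 0, [], 0
    for chunk in np.array_split(indices, max(1, int(np.ceil(len(indices) / batch_size)))):
        if len(chunk) == 0:
            continue
        batch = batch_dense([dataset[i] for i in chunk])
        res = model.forward(batch, training=False, rng=np.random.default_rng(0))
        pred = res.probs.data.argmax(axis=1)
        correct += int((pred == batch.labels).sum())
        loss = total_loss(res.probs, batch.labels, res.mi_losses, model.config.mi_weight)
        losses.append(float(loss.data) * len(chunk))
        total += len(chunk)
    return correct / total, float(np.sum(losses) / total)


def train_once(model: HierarchicalGNN, config: TrainConfig, dataset: GraphDataset,
               splits: tuple[np.ndarray, np.ndarray, np.ndarray], seed: int = 0
               ) -> tuple[float, list[dict]]:
    """Train with early stopping; return (test accuracy, per-epoch curve).

    Model selection reads only validation accuracy/loss; the test split
    is touched once, after the best parameters are restored.
    """
    train_idx, val_idx, test_idx = splits
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(seed)

    best = (-1.0, np.inf)  # (val accuracy, val loss); higher acc, then lower loss
    best_snap = model.snapshot()
    since_improve = 0
    curve: list[dict] = []

    for epoch in range(config.max_epochs):
        t0 = time.time()
        epoch_losses = []
        for chunk in _iterate_minibatches(train_idx, config.batch_size, rng):
            batch = batch_dense([dataset[i] for i in chunk])
            res = model.forward(batch, training=True, rng=rng)
            loss = total_loss(res.probs, batch.labels, res.mi_losses, model.config.mi_weight)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        val_acc, val_loss = evaluate(model, dataset, val_idx, config.batch_size)
        curve.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                      "val_acc": val_acc, "val_loss": val_loss,
                      "seconds": time.time() - t0})
        if config.verbose:
            print(f"epoch {epoch:4d}  loss {np.mean(epoch_losses):.4f}  "
                  f"val acc {val_acc:.4f}  val loss {val_loss:.4f}")

        if val_acc > best[0] or (val_acc == best[0] and val_loss < best[1]):
            best = (val_acc, val_loss)
            best_snap = model.snapshot()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break

    model.restore(best_snap)
    test_acc, _ = evaluate(model, dataset, test_idx, config.batch_size)
    return test_acc, curve


def run_protocol(dataset: GraphDataset, train_config: TrainConfig,
                 model_config: ModelConfig) -> EvalReport:
    """Repeat split/train/test with distinct seeds and aggregate."""
    report = EvalReport(config={"train": asdict(train_config), "model": asdict(model_config)})
    seeds = train_config.seeds[: train_config.repeats]
    if len(seeds) < train_config.repeats:
        raise ValueError("not enough seeds for the requested repeats")
    for seed in seeds:
        splits = split_dataset(dataset, seed, train_config.ratios)
        ref_nodes = max(dataset[i].n for i in splits[0])
        cfg_kwargs = asdict(model_config)
        cfg_kwargs.update(ref_nodes=ref_nodes, seed=seed,
                          feature_dim=dataset.feature_dim, num_classes=dataset.num_classes)
        cfg_kwargs["mlp_hidden"] = tuple(cfg_kwargs["mlp_hidden"])
        model = HierarchicalGNN(ModelConfig(**cfg_kwargs))
        acc, curve = train_once(model, train_config, dataset, splits, seed=seed)
        report.accuracies.append(acc)
        report.curves.append(curve)
        report.last_model = model
    return report
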