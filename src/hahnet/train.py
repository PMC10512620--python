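"""Training loop, checkpointing and checkpoint evaluation.

Optimisation follows the published recipe: Adam at learning rate 5e-4
with weight decay 1e-5 (classic L2, folded into the gradient; a decoupled
variant is available), cross-entropy on the logits, batch size 64.  After
every epoch the model is evaluated in eval mode; the checkpoint returned
is the one from the epoch with the highest selection metric (eval
accuracy by default, macro precision optionally), earliest epoch on ties.

A checkpoint is a single ``.npz`` container holding every parameter and
buffer plus a JSON header (format version, config echo, best epoch,
history), so any run is reproducible from its own artifacts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import records_to_arrays
from .errors import ConfigError
from .metrics import MetricsReport, multiclass_report
from .model import HAHNet, ModelConfig, build_model
from .nn import Adam, functional as F

__all__ = [
    "TrainConfig", "TrainHistory", "train", "save_checkpoint",
    "load_checkpoint", "evaluate_checkpoint", "evaluate_model",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    weight_decay: float = 1e-5
    epochs: int = 250
    batch_size: int = 64
    seed: int = 0
    device: str = "cpu"
    decoupled_weight_decay: bool = False
    select_metric: str = "accuracy"          # or "macro_precision"
    normalize: bool = False                  # channel standardization
    #: stop once training accuracy reaches this level (None = never)
    early_stop_train_acc: float | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.device != "cpu":
            raise ConfigError("only device='cpu' is supported")
        if self.select_metric not in ("accuracy", "macro_precision"):
            raise ConfigError("select_metric must be accuracy or macro_precision")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainHistory:
    """Per-epoch curves plus the index of the retained epoch."""

    train_loss: list = field(default_factory=list)
    test_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    test_accuracy: list = field(default_factory=list)
    best_epoch: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self.train_loss)),
            "train_loss": self.train_loss,
            "test_loss": self.test_loss,
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
        })

    def to_csv(self, path):
        self.to_frame().assign(best_epoch=self.best_epoch).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrainHistory":
        df = pd.read_csv(path)
        return cls(
            train_loss=df["train_loss"].tolist(),
            test_loss=df["test_loss"].tolist(),
            train_accuracy=df["train_accuracy"].tolist(),
            test_accuracy=df["test_accuracy"].tolist(),
            best_epoch=int(df["best_epoch"].iloc[0]),
        )


def _iterate_minibatches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _eval_pass(model: HAHNet, xs, ys, batch_size):
    """Eval-mode loss, accuracy and probabilities over a dataset."""
    model.eval()
    losses, probs = [], []
    for start in range(0, len(xs), batch_size):
        xb, yb = xs[start:start + batch_size], ys[start:start + batch_size]
        logits = model(xb)
        losses.append(F.cross_entropy(logits, yb).data * len(xb))
        probs.append(F.softmax(logits.data, axis=1))
    probs = np.concatenate(probs)
    loss = float(np.sum(losses) / len(xs))
    acc = float((probs.argmax(axis=1) == ys).mean())
    return loss, acc, probs


def _selection_value(metric: str, acc: float, probs, ys) -> float:
    if metric == "accuracy":
        return acc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = multiclass_report(ys, probs.argmax(axis=1), probs,
                                   probs.shape[1])
    return report.precision


def train(model: HAHNet, train_records, eval_records, cfg: TrainConfig):
    """Train ``model``; returns ``(checkpoint_state, history)``.

    ``checkpoint_state`` is the state dict captured at the best epoch (by
    ``cfg.select_metric`` on the eval set, ties to the earliest epoch);
    the model is left loaded with those best weights.
    """
    if not train_records or not eval_records:
        raise ValueError("train and eval sets must be non-empty")
    classes_present = {r.label for r in train_records}
    if len(classes_present) < 2:
        raise ValueError("training set must contain at least two classes")

    size = model.cfg.input_size
    x_tr, y_tr = records_to_arrays(train_records, size, normalize=cfg.normalize)
    x_ev, y_ev = records_to_arrays(eval_records, size, normalize=cfg.normalize)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay,
               decoupled=cfg.decoupled_weight_decay)

    history = TrainHistory()
    best_value = -np.inf
    best_state = None

    for epoch in range(cfg.epochs):
        model.train()
        epoch_loss = 0.0
        correct = 0
        for idx in _iterate_minibatches(len(x_tr), cfg.batch_size, rng):
            xb, yb = x_tr[idx], y_tr[idx]
            logits = model(xb)
            loss = F.cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}; "
                    "reduce the learning rate or check the input data")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(xb)
            correct += int((logits.data.argmax(axis=1) == yb).sum())

        train_loss = epoch_loss / len(x_tr)
        train_acc = correct / len(x_tr)
        test_loss, test_acc, probs = _eval_pass(model, x_ev, y_ev, cfg.batch_size)

        history.train_loss.append(train_loss)
        history.test_loss.append(test_loss)
        history.train_accuracy.append(train_acc)
        history.test_accuracy.append(test_acc)

        value = _selection_value(cfg.select_metric, test_acc, probs, y_ev)
        if value > best_value:   # strict: ties keep the earliest epoch
            best_value = value
            best_state = model.state_dict()
            history.best_epoch = epoch

        if (cfg.early_stop_train_acc is not None
                and train_acc >= cfg.early_stop_train_acc):
            break

    model.load_state_dict(best_state)
    return best_state, history


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, model: HAHNet, history: TrainHistory | None = None,
                    train_cfg: TrainConfig | None = None):
    header = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "model_config": model.cfg.to_dict(),
        "train_config": train_cfg.to_dict() if train_cfg else None,
        "history": asdict(history) if history else None,
        "best_epoch": history.best_epoch if history else None,
    }
    arrays = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez_compressed(path, header=json.dumps(header), **arrays)


def load_checkpoint(path):
    """Returns ``(model, header)`` with the model in eval mode."""
    with np.load(path, allow_pickle=False) as archive:
        header = json.loads(str(archive["header"]))
        if header.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format {header.get('format_version')}")
        state = {k[len("state/"):]: archive[k]
                 for k in archive.files if k.startswith("state/")}
    model = build_model(ModelConfig.from_dict(header["model_config"]))
    model.load_state_dict(state)
    return model.eval(), header


def evaluate_model(model: HAHNet, records, *, batch_size: int = 64,
                   normalize: bool = False) -> MetricsReport:
    """Full metrics report of a model on a record list."""
    labels = {r.label for r in records}
    k = model.cfg.num_classes
    if max(labels) >= k:
        raise ValueError(f"dataset has labels {sorted(labels)} but the model "
                         f"predicts {k} classes")
    xs, ys = records_to_arrays(records, model.cfg.input_size, normalize=normalize)
    _, _, probs = _eval_pass(model, xs, ys, batch_size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # small sets may miss classes
        return multiclass_report(ys, probs.argmax(axis=1), probs, k)


def evaluate_checkpoint(path, records, **kw) -> MetricsReport:
    model, _ = load_checkpoint(path)
    return evaluate_model(model, records, **kw)
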