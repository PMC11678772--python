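"""Optimization protocol: MSE objective, Adam, early stopping on validation.

Networks are trained for at most ``max_epochs`` epochs (default 300) and
stopped once ``patience`` epochs (default 25) pass without a new *strictly*
better validation loss; the parameters from the best validation epoch are
restored before returning.  Ties never reset the patience counter.

Inputs are taken as-is — the generator's fixed amplitude convention already
puts all spectra on one consistent scale.  An optional max-scaling toggle
(:func:`max_scale`) is provided for experiments; the comparison suite uses
it to keep losses well inside float32 range, recording the factor in its
manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from ._nn import Adam, Module, mse_value_and_grad
from .spectral_core import ValidationError

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "mse_loss",
    "train_model",
    "predict",
    "evaluate_mse",
    "max_scale",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run."""

    max_epochs: int = 300
    patience: int = 25
    batch_size: int = 16
    learning_rate: float = 1e-3   # conventional Adam default
    seed: int = 0
    task: str = "conversion"      # or "quantification"; informational

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValidationError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.patience < 1:
            raise ValidationError(f"patience must be >= 1, got {self.patience}")
        if self.batch_size < 1:
            raise ValidationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.task not in ("conversion", "quantification"):
            raise ValidationError(f"unknown task {self.task!r}")


@dataclass
class TrainHistory:
    """Per-epoch losses plus where and why training stopped.

    ``best_epoch`` is a 0-based index into the loss lists; ``val_loss`` at
    that index is the minimum over all recorded epochs.
    """

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_reason: str = ""

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch]


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over all elements of squared differences."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred.astype(np.float64) - target.astype(np.float64)
    return float(np.mean(diff * diff))


def max_scale(*arrays: np.ndarray) -> float:
    """Maximum absolute value across arrays (a simple normalization factor)."""
    return max(float(np.max(np.abs(a))) for a in arrays if a.size)


def _model_dtype(network: Module):
    params = network.parameters()
    return params[0].value.dtype if params else np.float64


def predict(network: Module, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Run the network in inference mode (dropout off), batched."""
    x = np.asarray(x, dtype=_model_dtype(network))
    single = x.ndim == 1
    if single:
        x = x[None, :]
    # copy each batch: layers may return reused internal buffers
    outs = [network.forward(x[i:i + batch_size], train=False).astype(np.float64)
            for i in range(0, x.shape[0], batch_size)]
    y = np.concatenate(outs, axis=0)
    return y[0] if single else y


def evaluate_mse(network: Module, x: np.ndarray, y: np.ndarray,
                 batch_size: int = 16) -> float:
    """Exact dataset MSE in inference mode (batched accumulation)."""
    return mse_loss(predict(network, x, batch_size=batch_size), y)


def train_model(
    network: Module,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[Module, TrainHistory]:
    """Train with MSE + Adam under the early-stopping protocol.

    ``train_set`` and ``val_set`` are ``(inputs, targets)`` pairs: LF and HF
    spectra for the conversion task, spectra and concentration vectors for
    quantification.  Returns the network carrying the parameters of the best
    validation epoch, plus the complete history.
    """
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValidationError("empty dataset")
    if len(x_tr) != len(y_tr) or len(x_va) != len(y_va):
        raise ValidationError("inputs and targets must have equal counts")
    dtype = _model_dtype(network)
    x_tr = np.asarray(x_tr, dtype=dtype)
    y_tr = np.asarray(y_tr, dtype=dtype)
    x_va = np.asarray(x_va, dtype=dtype)
    y_va = np.asarray(y_va, dtype=dtype)

    rng = np.random.default_rng(cfg.seed)  # per-epoch shuffling stream
    opt = Adam(network.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    best_state: list[np.ndarray] | None = None
    since_best = 0

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(x_tr))
        sq_sum = 0.0
        n_elem = 0
        for start in range(0, len(perm), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            pred = network.forward(xb, train=True)
            loss, grad = mse_value_and_grad(pred, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            network.zero_grad()
            network.backward(grad.astype(dtype))
            opt.step()
            sq_sum += loss * pred.size
            n_elem += pred.size
        train_loss = sq_sum / n_elem
        # validate at the training batch size so conv work buffers are reused
        val_loss = evaluate_mse(network, x_va, y_va, batch_size=cfg.batch_size)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)

        if history.best_epoch < 0 or val_loss < history.val_loss[history.best_epoch]:
            history.best_epoch = len(history.val_loss) - 1
            best_state = network.state_arrays()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                history.stopped_reason = "early_stop"
                break
    if not history.stopped_reason:
        history.stopped_reason = "max_epochs"
    if best_state is not None:
        network.load_state_arrays(best_state)
    return network, history
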