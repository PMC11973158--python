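"""Training and inference for the unrolled reconstruction models.

Training optimizes the complex L1 loss between the *backbone* output and the
fully sampled ground truth — the data-consistency step is deliberately not
part of the training graph; it is applied at inference only.  The optimizer
is Adam with a stepped learning-rate schedule (the reference recipe: initial
rate 1e-4 decayed by a factor of 10 after every 50 epochs, batch size 1,
betas 0.9/0.999, eps 1e-9, 100 epochs; desk-scale profiles shrink this).

Data consistency replaces the predicted k-space with the measured samples at
every acquired location:

    k_out = mask * measured + (1 - mask) * FFT(prediction),
    result = iFFT(k_out),

so the final image agrees with the acquisition exactly where data exist and
is idempotent.  Because unrolled networks are scale sensitive, each sample
is normalized by the magnitude peak of its zero-filled reconstruction before
the network and de-normalized afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam
from .complexnn import complex_l1_loss_t
from .kspace import SamplingMask, fft2c, ifft2c, undersample
from .models import FourierPD, ReconModelConfig

__all__ = [
    "TrainConfig",
    "MeasuredSample",
    "make_measured_sample",
    "data_consistency",
    "learning_rate_at",
    "train",
    "reconstruct",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe.

    The reference profile is ``TrainConfig()`` (100 epochs, batch 1, initial
    learning rate 1e-4 decayed by ``lr_decay_factor`` = 10 after every
    ``lr_decay_every`` = 50 epochs, betas 0.9/0.999, eps 1e-9).  Use
    :meth:`desk_scale` for fast CPU-size experiments.
    """

    epochs: int = 100
    batch_size: int = 1
    lr: float = 1e-4
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 50
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-9
    seed: int = 0
    validate_every: int = 1

    def __post_init__(self):
        for name in ("epochs", "batch_size", "lr", "lr_decay_factor", "lr_decay_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def desk_scale(cls, epochs: int = 50, lr: float = 1e-3, seed: int = 0) -> "TrainConfig":
        """Small-problem profile: fewer epochs, larger initial rate."""
        return cls(epochs=epochs, lr=lr, seed=seed)


@dataclass(frozen=True)
class MeasuredSample:
    """One retrospectively undersampled training pair."""

    measured_k: np.ndarray  # zero-filled undersampled k-space
    mask: SamplingMask
    target: np.ndarray  # fully sampled complex ground truth

    def __post_init__(self):
        off = np.abs(self.measured_k * (1 - self.mask.grid))
        if off.size and off.max() > 0:
            raise ValueError("measured_k carries energy off the mask")


def make_measured_sample(target: np.ndarray, mask: SamplingMask) -> MeasuredSample:
    """Retrospectively undersample a fully sampled complex image."""
    measured = undersample(fft2c(target), mask)
    return MeasuredSample(measured_k=measured, mask=mask, target=np.asarray(target, dtype=np.complex128))


def data_consistency(
    predicted: np.ndarray, measured_k: np.ndarray, mask: SamplingMask | np.ndarray
) -> np.ndarray:
    """Overwrite predicted k-space with measured samples where acquired."""
    grid = mask.grid if isinstance(mask, SamplingMask) else np.asarray(mask)
    predicted = np.asarray(predicted, dtype=np.complex128)
    measured_k = np.asarray(measured_k, dtype=np.complex128)
    if predicted.shape[-2:] != grid.shape or measured_k.shape[-2:] != grid.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape}, measured {measured_k.shape}, mask {grid.shape}"
        )
    k_out = grid * measured_k + (1 - grid) * fft2c(predicted)
    return ifft2c(k_out)


def learning_rate_at(epoch: int, config: TrainConfig) -> float:
    """Stepped schedule: lr / decay^floor((epoch-1) / decay_every), 1-based.

    Epochs 1-50 run at the initial rate, 51-100 at a tenth, 101-150 at a
    hundredth (with the reference settings).
    """
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return config.lr / config.lr_decay_factor ** ((epoch - 1) // config.lr_decay_every)


def _normalizer(measured_k: np.ndarray) -> float:
    peak = np.abs(ifft2c(measured_k)).max()
    return peak if peak > 0 else 1.0


@dataclass
class TrainResult:
    """Loss history and best-validation weights of one training run."""

    loss_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)
    best_val: float = np.inf
    best_arrays: list[np.ndarray] | None = None


def train(
    model: FourierPD,
    dataset: list[MeasuredSample],
    config: TrainConfig,
    val_dataset: list[MeasuredSample] | None = None,
    callback=None,
) -> TrainResult:
    """Optimize the backbone with complex L1 loss and the stepped Adam schedule.

    Samples are visited in a seed-reproducible shuffled order each epoch.
    When ``val_dataset`` is given, the weights with the best validation
    complex L1 loss are kept in the result (and restored into the model at
    the end).  Raises on an empty dataset and aborts on a non-finite loss.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    opt = Adam(model.parameters, lr=config.lr, beta1=config.beta1, beta2=config.beta2, eps=config.eps)
    rng = np.random.default_rng(config.seed)
    result = TrainResult()

    for epoch in range(1, config.epochs + 1):
        opt.lr = learning_rate_at(epoch, config)
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        for idx in order:
            s = dataset[idx]
            scale = _normalizer(s.measured_k)
            yr, yi = model.forward(s.measured_k / scale, s.mask)
            tgt = (s.target / scale)[None, None]
            loss = complex_l1_loss_t(yr, yi, tgt.real, tgt.imag)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} (sample {idx}); "
                    "reduce the learning rate or check the inputs"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        result.loss_history.append(epoch_loss / len(dataset))

        if val_dataset and epoch % config.validate_every == 0:
            val = np.mean([_eval_loss(model, s) for s in val_dataset])
            result.val_history.append(float(val))
            if val < result.best_val:
                result.best_val = float(val)
                result.best_arrays = model.state_arrays()
        if callback is not None:
            callback(epoch, result)

    if result.best_arrays is not None:
        model.load_state_arrays(result.best_arrays)
    return result


def _eval_loss(model: FourierPD, s: MeasuredSample) -> float:
    scale = _normalizer(s.measured_k)
    yr, yi = model.forward(s.measured_k / scale, s.mask)
    tgt = (s.target / scale)[None, None]
    return float(
        np.mean(np.abs(yr.data - tgt.real) + np.abs(yi.data - tgt.imag))
    )


def reconstruct(
    model: FourierPD, measured_k: np.ndarray, mask: SamplingMask | np.ndarray
) -> np.ndarray:
    """Full inference: normalized backbone pass followed by data consistency.

    At every acquired k-space location the output's spectrum equals the
    measured data to floating-point round-off.
    """
    measured_k = np.asarray(measured_k, dtype=np.complex128)
    scale = _normalizer(measured_k)
    pred = model.predict(measured_k / scale, mask) * scale
    return data_consistency(pred, measured_k, mask)


def save_checkpoint(
    path: str | Path, model: FourierPD, mask: SamplingMask | None = None, extra: dict | None = None
) -> None:
    """Write weights + model config (+ mask metadata) to an .npz checkpoint."""
    path = Path(path)
    meta = {"model": model.config.to_dict(), "extra": extra or {}}
    if mask is not None:
        meta["mask"] = mask.to_dict()
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[FourierPD, dict]:
    """Rebuild a model (and its metadata) from :func:`save_checkpoint` output."""
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        keys = sorted(k for k in data.files if k.startswith("param_"))
        arrays = [data[k] for k in keys]
    model = FourierPD(ReconModelConfig(**meta["model"]))
    model.load_state_arrays(arrays)
    return model, meta
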