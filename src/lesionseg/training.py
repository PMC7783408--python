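"""Training protocol: Adam on the composite loss, full-volume steps.

The reference protocol optimizes the network with Adam
(beta1 0.9, beta2 0.999, eps 1e-8) at a constant learning rate of 1e-5
for 700 epochs on normalized full volumes, and repeats the whole run
three times from independent random initializations for later
majority-vote ensembling.  Those values are the defaults here; small
phantom studies typically scale epochs down and the learning rate up
(see the package docs for the desk-scale protocol).

Every epoch logs the training loss components and the validation Dice.
Both the final-epoch weights and the best-validation-Dice weights are
retained; inference defaults to the latter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from lesionseg.engine import Adam
from lesionseg.errors import InvalidConfigError, LesionSegError
from lesionseg.losses import DEFAULT_SMOOTHING, loss_and_logit_grad
from lesionseg.network import NetworkConfig, RatLesNetV2, build_network
from lesionseg.volume_io import SegmentationMask, VolumeImage

__all__ = ["TrainConfig", "TrainResult", "train", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    learning_rate: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    epochs: int = 700
    batch_size: int = 1
    seed: int = 0
    loss_smoothing: float = DEFAULT_SMOOTHING

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise InvalidConfigError("learning_rate must be >= 0")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise InvalidConfigError("betas must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidConfigError("epochs and batch_size must be >= 1")


@dataclass
class TrainResult:
    """Outcome of one training run."""

    model: RatLesNetV2
    log: pd.DataFrame  # epoch, train_bce, train_dice_loss, train_total, val_dice
    final_state: dict = field(repr=False, default_factory=dict)
    best_state: dict = field(repr=False, default_factory=dict)
    best_epoch: int = -1
    best_val_dice: float = float("nan")

    def use_best(self) -> RatLesNetV2:
        """Load the best-validation-Dice weights into the model and return it."""
        if self.best_state:
            self.model.load_state_dict(self.best_state)
        return self.model

    def use_final(self) -> RatLesNetV2:
        self.model.load_state_dict(self.final_state)
        return self.model


def _as_array(v) -> np.ndarray:
    return v.data if isinstance(v, (VolumeImage, SegmentationMask)) else np.asarray(v)


def _val_dice(model: RatLesNetV2, val_set) -> float:
    from lesionseg.metrics import dice as dice_metric
    from lesionseg.volume_io import SegmentationMask

    scores = []
    for vol, mask in val_set:
        probs = model.predict_probs(_as_array(vol), training=False)
        pred = (probs[1] > 0.5).astype(np.uint8)
        spacing = getattr(vol, "spacing", (1.0, 1.0, 1.0))
        scores.append(
            dice_metric(
                SegmentationMask(data=pred, spacing=spacing),
                SegmentationMask(data=_as_array(mask), spacing=spacing),
            )
        )
    return float(np.mean(scores)) if scores else float("nan")


def train(
    model: RatLesNetV2 | NetworkConfig,
    train_set,
    val_set=(),
    config: TrainConfig | None = None,
) -> TrainResult:
    """Optimize a network on (volume, mask) pairs.

    Parameters
    ----------
    model
        A built network, or a :class:`NetworkConfig` to instantiate with
        ``config.seed`` (so independent runs differ only by seed).
    train_set, val_set
        Sequences of ``(VolumeImage, SegmentationMask)`` pairs (plain
        arrays are accepted too).  Volumes are expected normalized.
    config
        Optimization hyperparameters; defaults to :class:`TrainConfig`.

    Returns
    -------
    TrainResult
        Per-epoch log plus final and best-validation weights.

    Raises
    ------
    InvalidConfigError
        For an empty training set.
    LesionSegError
        If the loss becomes non-finite.
    """
    config = config or TrainConfig()
    if isinstance(model, NetworkConfig):
        model = build_network(model, seed=config.seed)
    train_set = list(train_set)
    val_set = list(val_set)
    if not train_set:
        raise InvalidConfigError("training set is empty")

    params = model.parameters()
    opt = Adam(
        params,
        lr=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        eps=config.epsilon,
    )
    rng = np.random.default_rng(config.seed)

    rows = []
    best_state: dict = {}
    best_epoch, best_val = -1, -np.inf
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            for idx in batch:
                vol, mask = train_set[idx]
                x = _as_array(vol).astype(np.float32)
                t = _as_array(mask).astype(np.float64)
                logits = model.forward_logits(x, training=True)
                value, grad = loss_and_logit_grad(
                    t, logits, smoothing=config.loss_smoothing
                )
                if not np.isfinite(value.total):
                    raise LesionSegError(
                        f"non-finite loss at epoch {epoch} "
                        f"(bce={value.bce}, dice={value.dice})"
                    )
                model.backward(grad / len(batch))
                losses.append(value)
            opt.step()

        val_dice = _val_dice(model, val_set)
        rows.append(
            {
                "epoch": epoch,
                "train_bce": float(np.mean([l.bce for l in losses])),
                "train_dice_loss": float(np.mean([l.dice for l in losses])),
                "train_total": float(np.mean([l.total for l in losses])),
                "val_dice": val_dice,
            }
        )
        if val_set and val_dice >= best_val:
            best_val, best_epoch = val_dice, epoch
            best_state = model.state_dict()

    final_state = model.state_dict()
    if not best_state:
        best_state, best_epoch, best_val = final_state, config.epochs, float("nan")
    return TrainResult(
        model=model,
        log=pd.DataFrame(rows),
        final_state=final_state,
        best_state=best_state,
        best_epoch=best_epoch,
        best_val_dice=float(best_val),
    )


def save_checkpoint(
    result: TrainResult,
    path: str | Path,
    which: str = "best",
    extra: dict | None = None,
) -> Path:
    """Write weights (npz) plus a JSON manifest next to them."""
    path = Path(path)
    state = result.best_state if which == "best" else result.final_state
    np.savez(path, **state)
    manifest = {
        "network_config": asdict(result.model.config),
        "config_hash": result.model.config.config_hash(),
        "init_seed": result.model.seed,
        "which": which,
        "best_epoch": result.best_epoch,
        "best_val_dice": result.best_val_dice,
        "epochs": int(result.log["epoch"].max()) if len(result.log) else 0,
    }
    if extra:
        manifest.update(extra)
    manifest_path = path.with_suffix(".json")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> RatLesNetV2:
    """Rebuild a network from an npz checkpoint and its JSON manifest."""
    path = Path(path)
    manifest_path = path.with_suffix(".json")
    manifest = json.loads(manifest_path.read_text())
    config = NetworkConfig(**manifest["network_config"])
    model = build_network(config, seed=manifest.get("init_seed", 0))
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
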