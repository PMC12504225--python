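"""Two-stage training: masked-reconstruction pre-training, layer-frozen
supervised fine-tuning, and the from-scratch baseline.

Pre-training reconstructs masked patches of 18-channel angle windows,
minimizing MSE over the masked positions (an all-positions mode is a
config flag). Fine-tuning adapts a pre-trained encoder to one joint's
left/right angle pair, freezing the embedding and the first
`n_frozen_blocks` blocks, with a reduce-on-plateau schedule and early
stopping on validation loss. The baseline trains the identical
architecture from random initialization with the pre-training optimizer
settings (Adam, cosine annealing).

Reference settings follow the study protocol: Adam lr 1e-4 (pre-training)
and 1e-6 (fine-tuning, 100x smaller), batch size 64, weight decay 1e-5,
dropout 0.1, 2000/500 epochs, early-stopping patience 20. Desk-scale runs
override epochs/learning rate through the same specs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Adam, Tensor
from .errors import InvalidArgumentError, SchemaError
from .model import (
    MaskSpec,
    ModelSpec,
    TransformerAutoencoder,
    freeze_prefix,
    sample_mask,
)
from .preprocess import WindowSet
from .synthetic import substream

# ---------------------------------------------------------------------------
# Specs and logs
# ---------------------------------------------------------------------------


@dataclass
class PretrainSpec:
    """Masked-reconstruction pre-training configuration."""

    lr: float = 1e-4
    batch_size: int = 64
    epochs: int = 2000
    schedule: str = "cosine"
    weight_decay: float = 1e-5
    mask: MaskSpec = field(default_factory=MaskSpec)
    loss_on: str = "masked"  # "masked" | "all"
    channel_subsampling: bool = False
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1:
            raise InvalidArgumentError("lr must be positive and epochs >= 1")
        if self.loss_on not in ("masked", "all"):
            raise InvalidArgumentError("loss_on must be 'masked' or 'all'")


@dataclass
class FinetuneSpec:
    """Supervised fine-tuning configuration (plateau schedule + early stop)."""

    lr: float = 1e-6
    batch_size: int = 64
    epochs: int = 500
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    early_stopping_patience: int = 20
    n_frozen_blocks: int = 6
    weight_decay: float = 1e-5
    label_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1:
            raise InvalidArgumentError("lr must be positive and epochs >= 1")
        if self.early_stopping_patience < 1 or self.plateau_patience < 1:
            raise InvalidArgumentError("patience must be >= 1")
        if not 0 < self.label_fraction <= 1:
            raise InvalidArgumentError("label_fraction must be in (0, 1]")


@dataclass
class TrainLog:
    """Per-epoch record of losses and learning rate, plus the stop verdict."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "lr": self.lr,
            }
        )


# ---------------------------------------------------------------------------
# Pre-training
# ---------------------------------------------------------------------------


def _masked_mse(out: Tensor, target: np.ndarray, weight: np.ndarray) -> Tensor:
    w = Tensor(weight)
    return ((out - Tensor(target)).square() * w).sum() / float(weight.sum())


def _patch_weight(mask: np.ndarray, patch_length: int, n_channels: int) -> np.ndarray:
    """Expand a (B, n_patches) patch mask to per-(time, channel) weights."""
    w = np.repeat(mask, patch_length, axis=1)[..., None]
    return np.broadcast_to(w, (*w.shape[:2], n_channels)).astype(np.float32)


def pretrain(
    windows: WindowSet,
    model_spec: ModelSpec,
    spec: PretrainSpec,
) -> tuple[TransformerAutoencoder, TrainLog]:
    """Masked-reconstruction pre-training on unlabeled angle windows.

    Uses the entire window set (no held-out split): evaluation happens
    exclusively on the downstream task. The reconstruction loss is the MSE
    between model output and the original values, restricted to masked
    positions by default.
    """
    if windows.inputs.shape[2] != model_spec.n_channels_in:
        raise SchemaError(
            f"window set has {windows.inputs.shape[2]} channels, model expects {model_spec.n_channels_in}"
        )
    if spec.loss_on == "masked" and spec.mask.n_masked(model_spec.n_patches) == 0:
        raise InvalidArgumentError("mask ratio yields zero masked patches; the masked-only loss is undefined")

    model = TransformerAutoencoder(model_spec, seed=spec.seed)
    opt = Adam(model.parameters(), lr=spec.lr, weight_decay=spec.weight_decay)
    shuffle_rng = substream(spec.seed, "shuffle")
    mask_rng = substream(spec.seed, "mask")
    drop_rng = substream(spec.seed, "dropout")
    x_all = windows.inputs.astype(np.float32)
    n = x_all.shape[0]
    log = TrainLog()
    for epoch in range(spec.epochs):
        opt.lr = _cosine_lr(spec.lr, epoch, spec.epochs) if spec.schedule == "cosine" else spec.lr
        order = shuffle_rng.permutation(n) if spec.shuffle else np.arange(n)
        losses = []
        for i in range(0, n, spec.batch_size):
            xb = x_all[order[i : i + spec.batch_size]]
            x_in = xb
            if spec.channel_subsampling:
                # train the encoder on random channel subsets (zeroed-out
                # channels, i.e. at their standardized mean) so downstream
                # fine-tuning on a 2-channel joint pair stays in
                # distribution; the reconstruction target remains the full
                # channel set
                x_in = xb * _channel_keep(xb.shape, mask_rng)
            mask = sample_mask(xb.shape[0], model_spec.n_patches, spec.mask, mask_rng)
            out = model.forward(x_in, head="reconstruct", mask=mask, train=True, rng=drop_rng)
            if spec.loss_on == "masked":
                weight = _patch_weight(mask, model_spec.patch_length, model_spec.n_channels_in)
            else:
                weight = np.ones_like(xb, dtype=np.float32)
            loss = _masked_mse(out, xb, weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.train_loss.append(float(np.mean(losses)))
        log.val_loss.append(float("nan"))
        log.lr.append(opt.lr)
    log.stop_reason = "epoch budget"
    log.best_epoch = int(np.argmin(log.train_loss))
    return model, log


def _cosine_lr(lr0: float, epoch: int, total: int) -> float:
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / max(total, 1)))


def _channel_keep(shape: tuple, rng: np.random.Generator) -> np.ndarray:
    """Per-window channel-keep mask: the number of visible channels is
    uniform on {2, ..., C} and the subset is uniform, so small subsets
    (down to a single joint pair) are well represented."""
    b, _, c = shape
    keep = np.zeros((b, 1, c), dtype=np.float32)
    n_keep = rng.integers(2, c + 1, size=b)
    order = rng.random((b, c)).argsort(axis=1)
    for w in range(b):  # vectorizing this is possible but not worth it
        keep[w, 0, order[w, : n_keep[w]]] = 1.0
    return keep


# ---------------------------------------------------------------------------
# Label subsampling
# ---------------------------------------------------------------------------


def subsample_labels(labeled: WindowSet, fraction: float, seed: int) -> WindowSet:
    """Uniform subsample of round(fraction * n) training windows.

    Implemented as a prefix of one fixed seeded permutation, so smaller
    fractions are nested subsets of larger ones under the same seed.
    Applies to the training partition only — validation/test stay fixed.
    """
    if not 0 < fraction <= 1:
        raise InvalidArgumentError("fraction must be in (0, 1]")
    n = len(labeled)
    k = round(fraction * n)
    if k < 1:
        raise InvalidArgumentError(f"fraction {fraction} yields zero windows out of {n}")
    perm = substream(seed, "labels").permutation(n)
    return labeled.subset(np.sort(perm[:k]))


# ---------------------------------------------------------------------------
# Supervised training (shared by fine-tuning and the baseline)
# ---------------------------------------------------------------------------


def _eval_supervised(model: TransformerAutoencoder, ws: WindowSet, batch_size: int = 256) -> float:
    pred = model.predict(ws.inputs.astype(np.float32), head="regress", batch_size=batch_size)
    return float(np.mean((pred - ws.targets) ** 2))


def _train_supervised(
    model: TransformerAutoencoder,
    train: WindowSet,
    val: WindowSet,
    *,
    lr: float,
    epochs: int,
    batch_size: int,
    weight_decay: float,
    schedule: str,
    plateau_factor: float = 0.5,
    plateau_patience: int = 10,
    early_stopping_patience: int | None = None,
    seed: int = 0,
) -> tuple[TransformerAutoencoder, TrainLog]:
    if train.targets is None or val.targets is None:
        raise SchemaError("supervised training requires windows with moment targets")
    opt = Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    shuffle_rng = substream(seed, "shuffle")
    drop_rng = substream(seed, "dropout")
    x_all = train.inputs.astype(np.float32)
    y_all = train.targets.astype(np.float32)
    n = x_all.shape[0]
    log = TrainLog()
    best_val = np.inf
    best_state = [a.copy() for a in model.state_arrays()]
    since_best = 0
    since_plateau = 0
    current_lr = lr
    log.stop_reason = "epoch budget"
    for epoch in range(epochs):
        opt.lr = _cosine_lr(lr, epoch, epochs) if schedule == "cosine" else current_lr
        order = shuffle_rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            out = model.forward(x_all[idx], head="regress", train=True, rng=drop_rng)
            loss = ((out - Tensor(y_all[idx])).square()).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_loss = _eval_supervised(model, val)
        log.train_loss.append(float(np.mean(losses)))
        log.val_loss.append(val_loss)
        log.lr.append(opt.lr)
        # improvements below 1e-6 (N·m/kg)² are noise-level; they neither
        # reset the early-stopping clock nor delay the plateau decay
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = [a.copy() for a in model.state_arrays()]
            log.best_epoch = epoch
            since_best = 0
            since_plateau = 0
        else:
            since_best += 1
            since_plateau += 1
        if schedule == "plateau" and since_plateau >= plateau_patience:
            current_lr *= plateau_factor
            since_plateau = 0
        if early_stopping_patience is not None and since_best >= early_stopping_patience:
            log.stop_reason = f"early stopping at epoch {epoch}"
            break
    model.load_state_arrays(best_state)
    return model, log


def finetune(
    checkpoint: TransformerAutoencoder | tuple[TransformerAutoencoder, dict] | str,
    train: WindowSet,
    val: WindowSet,
    spec: FinetuneSpec,
    pretrain_channels: tuple[str, ...] | None = None,
) -> tuple[TransformerAutoencoder, TrainLog]:
    """Layer-frozen supervised fine-tuning from a pre-trained checkpoint.

    If the labeled windows carry fewer channels than the pre-trained model,
    a fresh input projection is created, warm-started from the pre-trained
    embedding rows of the corresponding channels; `pretrain_channels` names
    the pre-training channel order (defaults to the canonical 18-channel
    set). No masking is applied; loss is MSE on the moment outputs in
    N·m/kg.
    """
    from .synthetic import CHANNELS  # local import to avoid cycle at module load

    if isinstance(checkpoint, str):
        from .model import load_checkpoint

        model0, meta = load_checkpoint(checkpoint)
    elif isinstance(checkpoint, tuple):
        model0, meta = checkpoint
    else:
        model0, meta = checkpoint, {"stage": "pretrain"}
    if meta.get("stage") != "pretrain":
        raise SchemaError(f"fine-tuning requires a pretrain-stage checkpoint, got stage={meta.get('stage')!r}")
    if train.targets is None:
        raise SchemaError("fine-tuning requires labeled windows (moment targets)")

    n_out = train.targets.shape[2]
    adapted = train.inputs.shape[2] != model0.spec.n_channels_in
    if adapted:
        names = pretrain_channels or CHANNELS
        try:
            idx = [names.index(c) for c in train.channel_names]
        except ValueError as e:
            raise SchemaError(f"labeled channel not present in the pre-trained channel set: {e}") from e
    else:
        idx = list(range(model0.spec.n_channels_in))
    model = model0.adapt_channels(idx, n_out, seed=spec.seed)
    if n_out == len(idx) and model0.spec.patch_length == 1:
        # warm-start the regression head from the reconstruction head's
        # columns for the selected channels: its output already tracks the
        # joint angle, a strong prior for the (near-proportional) moment
        model.head_regress.w.data = model0.head_reconstruct.w.data[:, idx].copy()
        model.head_regress.b.data = model0.head_reconstruct.b.data[idx].copy()

    # A freshly created input projection carries no pre-trained knowledge,
    # so it always stays trainable; a verbatim-copied embedding is frozen
    # with the prefix blocks.
    freeze_prefix(model, spec.n_frozen_blocks, freeze_embedding=not adapted)
    labeled = train if spec.label_fraction == 1.0 else subsample_labels(train, spec.label_fraction, spec.seed)
    return _train_supervised(
        model,
        labeled,
        val,
        lr=spec.lr,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        weight_decay=spec.weight_decay,
        schedule="plateau",
        plateau_factor=spec.plateau_factor,
        plateau_patience=spec.plateau_patience,
        early_stopping_patience=spec.early_stopping_patience,
        seed=spec.seed,
    )


def train_baseline(
    train: WindowSet,
    val: WindowSet,
    model_spec: ModelSpec,
    spec: PretrainSpec,
    label_fraction: float = 1.0,
    seed: int | None = None,
) -> tuple[TransformerAutoencoder, TrainLog]:
    """From-scratch supervised baseline: identical architecture, pre-training
    optimizer settings (Adam + cosine annealing), no SSL initialization."""
    if train.targets is None:
        raise SchemaError("baseline training requires labeled windows")
    run_seed = spec.seed if seed is None else seed
    model_spec_out = model_spec
    if (
        model_spec.n_channels_in != train.inputs.shape[2]
        or model_spec.n_channels_out != train.targets.shape[2]
    ):
        import dataclasses

        model_spec_out = dataclasses.replace(
            model_spec,
            n_channels_in=train.inputs.shape[2],
            n_channels_out=train.targets.shape[2],
        )
    model = TransformerAutoencoder(model_spec_out, seed=run_seed)
    labeled = train if label_fraction == 1.0 else subsample_labels(train, label_fraction, run_seed)
    return _train_supervised(
        model,
        labeled,
        val,
        lr=spec.lr,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        weight_decay=spec.weight_decay,
        schedule="cosine",
        seed=run_seed,
    )
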