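"""Transformer auto-encoder for gait windows, with reconstruction and
regression heads.

Each window of W time steps is cut into W/patch_length patches, linearly
embedded into d_model dimensions, optionally masked (a learnable mask token
replaces the embedding of masked patches, BERT-style, before positional
encoding is added), passed through a stack of post-norm self-attention
blocks, and linearly projected back — either to the input channels
(reconstruction pre-training) or to joint-moment channels (regression
fine-tuning).

The reference configuration is 8 blocks, 12 heads, d_model 24, 2048
feedforward units, ReLU, dropout 0.1, layer-norm eps 1e-5, window 64 with
patch length 1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Parameter, Tensor
from .errors import InvalidArgumentError, SchemaError
from .synthetic import substream

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the auto-encoder and its heads."""

    window: int = 64
    patch_length: int = 1
    n_channels_in: int = 18
    d_model: int = 24
    n_blocks: int = 8
    n_heads: int = 12
    ffn_dim: int = 2048
    dropout: float = 0.1
    layernorm_eps: float = 1e-5
    activation: str = "relu"
    n_channels_out: int | None = None  # None -> n_channels_in (reconstruction)

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise InvalidArgumentError("d_model must be divisible by n_heads")
        if self.window % self.patch_length:
            raise InvalidArgumentError("patch_length must divide the window length")
        if not 0 <= self.dropout < 1:
            raise InvalidArgumentError("dropout must be in [0, 1)")
        if self.activation != "relu":
            raise InvalidArgumentError("only ReLU activation is supported")

    @property
    def n_patches(self) -> int:
        return self.window // self.patch_length

    @property
    def out_channels(self) -> int:
        return self.n_channels_out if self.n_channels_out is not None else self.n_channels_in

    def digest(self) -> str:
        return hashlib.sha1(json.dumps(dataclasses.asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def desk_spec(n_channels_in: int = 18, n_channels_out: int | None = None) -> ModelSpec:
    """Scaled-down architecture for CPU-sized experiments: window 32,
    4 blocks of d_model 16 / 4 heads / 64 ffn units. Freezing 3 of 4
    blocks preserves the reference configuration's 75% frozen fraction."""
    return ModelSpec(
        window=32,
        d_model=16,
        n_blocks=4,
        n_heads=4,
        ffn_dim=64,
        n_channels_in=n_channels_in,
        n_channels_out=n_channels_out,
    )


@dataclass(frozen=True)
class MaskSpec:
    """Random masking policy: a fixed round(ratio * n_patches) patches per
    window are replaced by the learnable mask token."""

    ratio: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.ratio < 1:
            raise InvalidArgumentError("mask ratio must be in [0, 1)")

    def n_masked(self, n_patches: int) -> int:
        n = round(self.ratio * n_patches)
        if n >= n_patches:
            raise InvalidArgumentError("mask ratio leaves no visible patch")
        return n


# ---------------------------------------------------------------------------
# Positional encoding
# ---------------------------------------------------------------------------


def positional_encoding(n_positions: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional encoding.

    PE(pos, 2i) = sin(pos / 10000^(2i/d)), PE(pos, 2i+1) = cos(...); all
    entries lie in [-1, 1] and the map is deterministic.
    """
    if d_model % 2:
        raise InvalidArgumentError("d_model must be even for sinusoidal encoding")
    pos = np.arange(n_positions)[:, None].astype(float)
    i = np.arange(d_model // 2)[None, :].astype(float)
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.empty((n_positions, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

_DTYPE = np.float32


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.w = Parameter(rng.uniform(-bound, bound, size=(d_in, d_out)).astype(_DTYPE))
        self.b = Parameter(np.zeros(d_out, dtype=_DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self):
        return [self.w, self.b]


class _LayerNorm:
    def __init__(self, d: int, eps: float):
        self.gamma = Parameter(np.ones(d, dtype=_DTYPE))
        self.beta = Parameter(np.zeros(d, dtype=_DTYPE))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return _nn.layer_norm(x, self.gamma, self.beta, self.eps)

    def parameters(self):
        return [self.gamma, self.beta]


class _MultiHeadAttention:
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        self.h = n_heads
        self.dh = d_model // n_heads
        self.q = _Linear(d_model, d_model, rng)
        self.k = _Linear(d_model, d_model, rng)
        self.v = _Linear(d_model, d_model, rng)
        self.o = _Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape

        def heads(z: Tensor) -> Tensor:
            return z.reshape(b, t, self.h, self.dh).transpose(0, 2, 1, 3)

        q, k, v = heads(self.q(x)), heads(self.k(x)), heads(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
        attn = _nn.softmax(scores)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.o(out)

    def parameters(self):
        return self.q.parameters() + self.k.parameters() + self.v.parameters() + self.o.parameters()


class _Block:
    """Post-norm transformer block: LN(x + Drop(MHA(x))), LN(x + Drop(FFN(x)))."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        self.attn = _MultiHeadAttention(spec.d_model, spec.n_heads, rng)
        self.ffn1 = _Linear(spec.d_model, spec.ffn_dim, rng)
        self.ffn2 = _Linear(spec.ffn_dim, spec.d_model, rng)
        self.ln1 = _LayerNorm(spec.d_model, spec.layernorm_eps)
        self.ln2 = _LayerNorm(spec.d_model, spec.layernorm_eps)
        self.dropout = spec.dropout

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        x = self.ln1(x + _nn.dropout(self.attn(x), self.dropout, rng))
        x = self.ln2(x + _nn.dropout(self.ffn2(_nn.relu(self.ffn1(x))), self.dropout, rng))
        return x

    def parameters(self):
        return (
            self.attn.parameters()
            + self.ffn1.parameters()
            + self.ffn2.parameters()
            + self.ln1.parameters()
            + self.ln2.parameters()
        )


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class TransformerAutoencoder:
    """The full auto-encoder: patch embedding, mask token, positional
    encoding, encoder stack, and one head per task."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = substream(seed, "init")
        patch_in = spec.patch_length * spec.n_channels_in
        patch_out = spec.patch_length * spec.out_channels
        self.embed = _Linear(patch_in, spec.d_model, rng)
        self.mask_token = Parameter(rng.normal(0.0, 0.02, size=spec.d_model).astype(_DTYPE))
        self.blocks = [_Block(spec, rng) for _ in range(spec.n_blocks)]
        self.head_reconstruct = _Linear(spec.d_model, patch_in, rng)
        self.head_regress = _Linear(spec.d_model, patch_out, rng)
        self.pe = positional_encoding(spec.n_patches, spec.d_model).astype(_DTYPE)

    # -- parameter bookkeeping ------------------------------------------

    def embedding_parameters(self) -> list[Parameter]:
        return self.embed.parameters() + [self.mask_token]

    def encoder_parameters(self) -> list[Parameter]:
        return self.embedding_parameters() + [p for blk in self.blocks for p in blk.parameters()]

    def parameters(self) -> list[Parameter]:
        return self.encoder_parameters() + self.head_reconstruct.parameters() + self.head_regress.parameters()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise SchemaError("checkpoint parameter count does not match the architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise SchemaError(f"checkpoint array shape {a.shape} != parameter shape {p.data.shape}")
            p.data = a.astype(p.data.dtype)

    # -- forward ----------------------------------------------------------

    def embed_patches(self, window: np.ndarray) -> Tensor:
        """Affine, position-shared patch embedding: (B, W, C) -> (B, n_patches, d)."""
        spec = self.spec
        if window.ndim == 2:
            window = window[None]
        if window.shape[1] != spec.window or window.shape[2] != spec.n_channels_in:
            raise SchemaError(
                f"expected windows of shape (., {spec.window}, {spec.n_channels_in}), got {window.shape}"
            )
        b = window.shape[0]
        patches = window.reshape(b, spec.n_patches, spec.patch_length * spec.n_channels_in)
        return self.embed(Tensor(patches.astype(_DTYPE)))

    def apply_mask(self, tokens: Tensor, mask: np.ndarray) -> Tensor:
        """Replace masked token embeddings by the learnable mask token.

        `mask` is a boolean (B, n_patches) array; the replacement happens
        before positional encoding so the encoder knows where a masked
        patch sits but nothing about its content.
        """
        m = mask[..., None].astype(_DTYPE)
        return tokens * Tensor(1.0 - m) + self.mask_token * Tensor(m)

    def forward(
        self,
        window: np.ndarray,
        head: str = "reconstruct",
        mask: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Run the full model; returns (B, W, C_out) in the head's units."""
        if head not in ("reconstruct", "regress"):
            raise InvalidArgumentError("head must be 'reconstruct' or 'regress'")
        tok = self.embed_patches(window)
        if mask is not None:
            tok = self.apply_mask(tok, mask)
        tok = tok + Tensor(self.pe)
        drop_rng = rng if train else None
        for blk in self.blocks:
            tok = blk(tok, drop_rng)
        head_layer = self.head_reconstruct if head == "reconstruct" else self.head_regress
        out = head_layer(tok)
        b = out.shape[0]
        c_out = self.spec.n_channels_in if head == "reconstruct" else self.spec.out_channels
        return out.reshape(b, self.spec.window, c_out)

    def predict(self, window: np.ndarray, head: str = "regress", batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode forward pass over an array of windows."""
        outs = []
        for i in range(0, window.shape[0], batch_size):
            outs.append(self.forward(window[i : i + batch_size], head=head).data)
        return np.concatenate(outs)

    # -- channel adaptation -----------------------------------------------

    def adapt_channels(self, channel_idx: list[int], n_channels_out: int, seed: int = 0) -> "TransformerAutoencoder":
        """New model for a channel subset, warm-started from this one.

        Encoder blocks, layer norms and the mask token are copied verbatim.
        The fresh input projection reuses the pre-trained embedding rows of
        the selected channels (exact for patch_length 1, one row per
        channel); for longer patches the per-position rows of the selected
        channels are extracted the same way. The regression head is fresh.
        """
        spec = dataclasses.replace(
            self.spec, n_channels_in=len(channel_idx), n_channels_out=n_channels_out
        )
        new = TransformerAutoencoder(spec, seed=seed)
        p = self.spec.patch_length
        rows = np.concatenate([[pos * self.spec.n_channels_in + c for c in channel_idx] for pos in range(p)])
        new.embed.w.data = self.embed.w.data[rows].copy()
        new.embed.b.data = self.embed.b.data.copy()
        new.mask_token.data = self.mask_token.data.copy()
        for nb, ob in zip(new.blocks, self.blocks):
            for np_, op_ in zip(nb.parameters(), ob.parameters()):
                np_.data = op_.data.copy()
        return new


# ---------------------------------------------------------------------------
# Masking and freezing helpers
# ---------------------------------------------------------------------------


def sample_mask(
    n_windows: int, n_patches: int, mask_spec: MaskSpec, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_windows, n_patches) mask with exactly round(ratio *
    n_patches) True entries per row, positions uniform without replacement."""
    k = mask_spec.n_masked(n_patches)
    mask = np.zeros((n_windows, n_patches), dtype=bool)
    if k:
        order = rng.random((n_windows, n_patches)).argsort(axis=1)
        np.put_along_axis(mask, order[:, :k], True, axis=1)
    return mask


def apply_mask(
    model: TransformerAutoencoder, window: np.ndarray, mask_spec: MaskSpec
) -> tuple[Tensor, np.ndarray]:
    """Embed a batch of windows and mask it; returns (masked tokens, mask).

    The index set (as a boolean array) records which patches were replaced;
    no position is masked twice and the count per window is exact.
    """
    if window.ndim == 2:
        window = window[None]
    tok = model.embed_patches(window)
    rng = substream(mask_spec.seed, "mask")
    mask = sample_mask(window.shape[0], model.spec.n_patches, mask_spec, rng)
    return model.apply_mask(tok, mask), mask


def freeze_prefix(model: TransformerAutoencoder, n_frozen_blocks: int, freeze_embedding: bool = True) -> float:
    """Freeze the patch embedding and the first `n_frozen_blocks` encoder
    blocks; heads always stay trainable. Returns the frozen fraction of
    encoder parameters."""
    if not 0 <= n_frozen_blocks <= model.spec.n_blocks:
        raise InvalidArgumentError(f"n_frozen_blocks must be in [0, {model.spec.n_blocks}]")
    for p in model.parameters():
        p.trainable = True
    if freeze_embedding and n_frozen_blocks > 0:
        for p in model.embedding_parameters():
            p.trainable = False
    for blk in model.blocks[:n_frozen_blocks]:
        for p in blk.parameters():
            p.trainable = False
    enc = model.encoder_parameters()
    frozen = sum(p.data.size for p in enc if not p.trainable)
    return frozen / sum(p.data.size for p in enc)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: TransformerAutoencoder, path, *, stage: str, seed: int, extra: dict | None = None) -> None:
    """Single self-describing archive: spec + weights + provenance."""
    meta = {
        "spec": dataclasses.asdict(model.spec),
        "stage": stage,
        "seed": seed,
        "extra": extra or {},
    }
    arrays = {f"p{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[TransformerAutoencoder, dict]:
    try:
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]))
            arrays = [z[f"p{i:04d}"] for i in range(len(z.files) - 1)]
    except (OSError, KeyError, ValueError, EOFError, json.JSONDecodeError) as e:
        raise SchemaError(f"corrupt or unreadable checkpoint {path}: {e}") from e
    spec = ModelSpec(**meta["spec"])
    model = TransformerAutoencoder(spec, seed=meta.get("seed", 0))
    model.load_state_arrays(arrays)
    return model, meta
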