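"""The asymmetric attention masked autoencoder and classification head.

Pipeline: each event's ``L x w`` subsequence matrix is linearly projected to a
``d``-dimensional token sequence with learned positional embeddings; an
``n_layers``-deep multi-head self-attention encoder processes the visible and
the masked tokens as two separate sequences; the decoder sees all ``L``
positions, with a shared learned mask token standing in for hidden content,
and must predict the encoder's (gradient-isolated) representation of the true
masked subsequences.  Fine-tuning runs the encoder over the full sequence,
global-average-pools positions into one event embedding ``z`` and applies a
two-layer classifier.

A drop-in convolutional backbone (kernel-3 residual blocks in place of the
attention sublayer, feedforward sublayer kept) is provided for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._autograd import Parameter, Tensor, concat, gelu, set_at, softmax
from .preprocess import MaskPlan

__all__ = [
    "ModelConfig",
    "ClassifierConfig",
    "LatentBatch",
    "MaskedAutoencoder",
    "Classifier",
    "mse_latent_loss",
    "count_parameters",
]

_LN_EPS = 1e-5


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the published recipe)."""

    d: int = 64  # embedding dim
    d_k: int = 64  # per-head key/query dim
    d_v: int = 64  # per-head value dim
    n_layers: int = 8  # attention layers in encoder and in decoder
    h: int = 4  # heads per layer
    p1: float = 0.2  # dropout in the feedforward sublayer
    ffn_dim: int | None = None  # feedforward hidden width, default 4*d
    w: int = 12  # subsequence length
    backbone: str = "attention"  # {"attention", "cnn"}

    def __post_init__(self) -> None:
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.d
        for name in ("d", "d_k", "d_v", "n_layers", "h", "ffn_dim", "w"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.p1 < 1.0:
            raise ValueError("p1 must lie in [0, 1)")
        if self.backbone not in ("attention", "cnn"):
            raise ValueError(f"unknown backbone {self.backbone!r}")


@dataclass
class ClassifierConfig:
    """Classification-head hyperparameters."""

    M: int  # number of classes
    d_c: int = 256  # hidden width of the first layer
    p2: float = 0.2  # classifier dropout

    def __post_init__(self) -> None:
        if self.d_c < 1:
            raise ValueError("d_c must be >= 1")
        if self.M < 2:
            raise ValueError("need at least 2 classes")
        if not 0.0 <= self.p2 < 1.0:
            raise ValueError("p2 must lie in [0, 1)")


@dataclass
class LatentBatch:
    """Per-position latent representations for a batch of events.

    ``values`` is a ``(B, L', d)`` tensor; ``positions`` records, per event,
    which original subsequence index each of the ``L'`` columns came from.
    """

    values: Tensor
    positions: np.ndarray
    stage: str  # {"projected", "encoded", "decoder_input", "decoded"}

    @property
    def array(self) -> np.ndarray:
        return self.values.data

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        B, Lp, _ = self.values.shape
        if self.positions.shape != (B, Lp):
            raise ValueError("positions must be shaped (B, L')")
        for row in self.positions:
            if np.unique(row).size != row.size:
                raise ValueError("positions must be unique per event")


def _plan_arrays(plan, B: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a MaskPlan / sequence of MaskPlans / pair of index arrays."""
    if isinstance(plan, MaskPlan):
        plan = [plan] * B
    if isinstance(plan, tuple) and len(plan) == 2:
        masked, visible = (np.asarray(a, dtype=np.int64) for a in plan)
    else:
        plans = list(plan)
        if len(plans) != B:
            raise ValueError(f"need one mask plan per event ({B}), got {len(plans)}")
        masked = np.stack([p.masked_idx for p in plans])
        visible = np.stack([p.visible_idx for p in plans])
    if masked.ndim != 2 or visible.ndim != 2 or masked.shape[0] != B:
        raise ValueError("mask plan arrays must be (B, m) and (B, L-m)")
    return masked, visible


class _Module:
    """Minimal parameter container with named state."""

    def named_parameters(self) -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                out.append((name, val))
            elif isinstance(val, _Module):
                out.extend((f"{name}.{sub}", p) for sub, p in val.named_parameters())
            elif isinstance(val, list) and val and isinstance(val[0], _Module):
                for i, mod in enumerate(val):
                    out.extend((f"{name}.{i}.{sub}", p) for sub, p in mod.named_parameters())
        return out

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state mismatch for keys: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class _Linear(_Module):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = Parameter(_glorot(rng, n_in, n_out, (n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class _LayerNorm(_Module):
    def __init__(self, d: int):
        self.gain = Parameter(np.ones(d))
        self.bias = Parameter(np.zeros(d))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + _LN_EPS) ** 0.5) * self.gain + self.bias


class _Dropout:
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, owner: "MaskedAutoencoder | Classifier"):
        self.p = p
        self.owner = owner

    def __call__(self, x: Tensor) -> Tensor:
        if self.p <= 0.0 or not self.owner.training:
            return x
        keep = self.owner._dropout_rng.random(x.shape) >= self.p
        return x * Tensor(keep / (1.0 - self.p))


class _MultiHeadAttention(_Module):
    def __init__(self, rng: np.random.Generator, cfg: ModelConfig):
        d, h, dk, dv = cfg.d, cfg.h, cfg.d_k, cfg.d_v
        self.h, self.d_k, self.d_v = h, dk, dv
        self.Wq = _Linear(rng, d, h * dk)
        self.Wk = _Linear(rng, d, h * dk)
        self.Wv = _Linear(rng, d, h * dv)
        self.Wo = _Linear(rng, h * dv, d)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        h, dk, dv = self.h, self.d_k, self.d_v

        def split(t: Tensor, dh: int) -> Tensor:
            return t.reshape(B, L, h, dh).swapaxes(1, 2)  # (B, h, L, dh)

        q, k, v = split(self.Wq(x), dk), split(self.Wk(x), dk), split(self.Wv(x), dv)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, L, h * dv)
        return self.Wo(ctx)


class _Conv3(_Module):
    """Kernel-3 1-D convolution over the position axis via shifted matmuls."""

    def __init__(self, rng: np.random.Generator, d: int):
        self.W_prev = Parameter(_glorot(rng, 3 * d, d, (d, d)))
        self.W_self = Parameter(_glorot(rng, 3 * d, d, (d, d)))
        self.W_next = Parameter(_glorot(rng, 3 * d, d, (d, d)))
        self.b = Parameter(np.zeros(d))

    def __call__(self, x: Tensor) -> Tensor:
        B, L, d = x.shape
        zero = Tensor(np.zeros((B, 1, d)))
        prev = concat([zero, x[:, :-1, :]], axis=1) if L > 1 else zero
        nxt = concat([x[:, 1:, :], zero], axis=1) if L > 1 else zero
        return prev @ self.W_prev + x @ self.W_self + nxt @ self.W_next + self.b


class _Block(_Module):
    """Post-norm residual block: mixing sublayer + feedforward sublayer."""

    def __init__(self, rng: np.random.Generator, cfg: ModelConfig, owner):
        if cfg.backbone == "attention":
            self.mix = _MultiHeadAttention(rng, cfg)
        else:
            self.mix = _Conv3(rng, cfg.d)
        self.ln1 = _LayerNorm(cfg.d)
        self.ln2 = _LayerNorm(cfg.d)
        self.ffn1 = _Linear(rng, cfg.d, cfg.ffn_dim)
        self.ffn2 = _Linear(rng, cfg.ffn_dim, cfg.d)
        self._drop = _Dropout(cfg.p1, owner)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.mix(x))
        y = self.ffn2(self._drop(gelu(self.ffn1(x))))
        return self.ln2(x + y)


class MaskedAutoencoder(_Module):
    """Input projection + positional table + encoder/decoder stacks.

    Parameters
    ----------
    cfg : ModelConfig
    n_positions : int
        Maximum sequence length ``L`` (size of the positional table, which is
        shared between encoder and decoder).
    seed : int
        Initialization (and dropout-stream) seed.
    """

    def __init__(self, cfg: ModelConfig, n_positions: int, seed: int = 0):
        self.cfg = cfg
        self.n_positions = int(n_positions)
        self.training = True
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.proj = _Linear(rng, cfg.w, cfg.d)
        self.pos = Parameter(rng.normal(0.0, 0.02, size=(self.n_positions, cfg.d)))
        self.mask_token = Parameter(rng.normal(0.0, 0.02, size=(cfg.d,)))
        self.encoder = [_Block(rng, cfg, self) for _ in range(cfg.n_layers)]
        self.decoder = [_Block(rng, cfg, self) for _ in range(cfg.n_layers)]

    # -- mode switches ---------------------------------------------------
    def train(self) -> "MaskedAutoencoder":
        self.training = True
        return self

    def eval(self) -> "MaskedAutoencoder":
        self.training = False
        return self

    # -- forward operations ------------------------------------------------
    def project(self, segments: np.ndarray | Sequence) -> LatentBatch:
        """Affine-map each length-``w`` subsequence to ``d`` dims and add its
        positional embedding."""
        segments = np.asarray(segments, dtype=np.float64)
        if segments.ndim == 2:  # single event
            segments = segments[None]
        if segments.ndim != 3:
            raise ValueError("segments must be (B, L, w) — ragged batches are not allowed")
        B, L, w = segments.shape
        if w != self.cfg.w:
            raise ValueError(f"subsequence length {w} != model w={self.cfg.w}")
        if L > self.n_positions:
            raise ValueError(f"L={L} exceeds positional table size {self.n_positions}")
        x = self.proj(Tensor(segments)) + self.pos[:L]
        positions = np.broadcast_to(np.arange(L), (B, L)).copy()
        return LatentBatch(values=x, positions=positions, stage="projected")

    def _select(self, lat: LatentBatch, idx: np.ndarray) -> LatentBatch:
        B = lat.values.shape[0]
        vals = lat.values[np.arange(B)[:, None], idx]
        pos = np.take_along_axis(lat.positions, idx, axis=1)
        return LatentBatch(values=vals, positions=pos, stage=lat.stage)

    def encode(self, latents: LatentBatch, mode: str = "full", plan=None) -> LatentBatch:
        """Run the encoder stack over all, only visible, or only masked columns."""
        if latents.stage != "projected":
            raise ValueError("encode expects projected latents")
        if mode not in ("full", "visible_only", "masked_only"):
            raise ValueError(f"unknown encode mode {mode!r}")
        if mode == "full":
            sel = latents
        else:
            if plan is None:
                raise ValueError(f"mode {mode!r} requires a mask plan")
            masked, visible = _plan_arrays(plan, latents.values.shape[0])
            sel = self._select(latents, masked if mode == "masked_only" else visible)
        x = sel.values
        for block in self.encoder:
            x = block(x)
        return LatentBatch(values=x, positions=sel.positions, stage="encoded")

    def build_decoder_input(self, encoded_visible: LatentBatch, plan) -> LatentBatch:
        """Scatter visible-token encodings into a full-length sequence whose
        masked columns carry the shared mask token plus positional embedding."""
        if encoded_visible.stage != "encoded":
            raise ValueError("build_decoder_input expects encoder output")
        B, nv, d = encoded_visible.values.shape
        masked, visible = _plan_arrays(plan, B)
        if visible.shape != (B, nv) or not np.array_equal(visible, encoded_visible.positions):
            raise ValueError("encoded_visible must cover exactly the plan's visible indices")
        L = nv + masked.shape[1]
        base = Tensor(np.zeros((B, L, d))) + self.mask_token.reshape(1, 1, d) + self.pos[
            :L
        ].reshape(1, L, d)
        full = set_at(base, (np.arange(B)[:, None], visible), encoded_visible.values)
        positions = np.broadcast_to(np.arange(L), (B, L)).copy()
        return LatentBatch(values=full, positions=positions, stage="decoder_input")

    def decode(self, decoder_input: LatentBatch) -> LatentBatch:
        """Run the decoder stack over the entire (visible + mask-token) input."""
        if decoder_input.stage != "decoder_input":
            raise ValueError("decode expects build_decoder_input output")
        x = decoder_input.values
        for block in self.decoder:
            x = block(x)
        return LatentBatch(values=x, positions=decoder_input.positions.copy(), stage="decoded")

    @staticmethod
    def pretrain_targets(latents_masked: LatentBatch) -> LatentBatch:
        """Gradient-isolate the encoder's masked-token representations, the
        regression target of the pretext task."""
        if latents_masked.stage != "encoded":
            raise ValueError("pretrain_targets expects encoder output")
        return LatentBatch(
            values=latents_masked.values.detach(),
            positions=latents_masked.positions.copy(),
            stage="encoded",
        )

    def decoded_at(self, decoded: LatentBatch, masked: np.ndarray) -> LatentBatch:
        """Extract the decoder's predictions at the masked positions."""
        return self._select(decoded, np.asarray(masked, dtype=np.int64))

    def embed_event(self, segments: np.ndarray) -> Tensor:
        """Full-sequence encoding pooled over positions: ``z = mean_L H^n``."""
        encoded = self.encode(self.project(segments), mode="full")
        return encoded.values.mean(axis=1)


class Classifier(_Module):
    """Two-layer head: ``d -> d_c`` with GELU and dropout ``p2``, then ``d_c -> M``."""

    def __init__(self, cfg: ClassifierConfig, d: int, seed: int = 0):
        self.cfg = cfg
        self.training = True
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.lin1 = _Linear(rng, d, cfg.d_c)
        self.lin2 = _Linear(rng, cfg.d_c, cfg.M)
        self._drop = _Dropout(cfg.p2, self)

    def train(self) -> "Classifier":
        self.training = True
        return self

    def eval(self) -> "Classifier":
        self.training = False
        return self

    def __call__(self, z: Tensor | np.ndarray) -> Tensor:
        z = z if isinstance(z, Tensor) else Tensor(z)
        return self.lin2(self._drop(gelu(self.lin1(z))))

    classify = __call__


def mse_latent_loss(Fm: LatentBatch | Tensor, Hm: LatentBatch | Tensor) -> Tensor:
    """Mean squared error between decoder predictions and encoder targets,
    averaged over all masked positions and embedding dimensions."""
    f = Fm.values if isinstance(Fm, LatentBatch) else Fm
    h = Hm.values if isinstance(Hm, LatentBatch) else Hm
    if f.shape != h.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {h.shape}")
    diff = f - h
    return (diff * diff).mean()


def count_parameters(module: _Module) -> int:
    return int(sum(p.data.size for p in module.parameters()))
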