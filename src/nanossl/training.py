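"""Pretraining and fine-tuning loops, optimizers, schedules, checkpoints.

Pretraining is self-supervised: labels are stripped before the loop, each
event gets a fresh random mask plan every epoch (seeded stream), and the
latent-reconstruction MSE is minimized with Adam.  Fine-tuning optimizes
cross-entropy over pooled full-event embeddings with AdamW and a cosine
learning-rate schedule decaying to ``lr * lr_floor_fraction`` by the final
epoch.  Passing ``init=None`` to :func:`finetune` gives the supervised-only
baseline ("ZeroTrain"): identical recipe, randomly initialized encoder.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._autograd import Parameter, log_softmax, softmax
from .event_io import EventSet
from .mae_model import (
    Classifier,
    ClassifierConfig,
    MaskedAutoencoder,
    ModelConfig,
    mse_latent_loss,
)
from .preprocess import n_masked, segment_matrix

__all__ = [
    "TrainConfig",
    "TrainLog",
    "Checkpoint",
    "Adam",
    "AdamW",
    "cosine_lr",
    "pretrain",
    "finetune",
    "predict",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published recipe)."""

    epochs_pretrain: int = 300
    epochs_finetune: int = 300
    batch_size: int = 128
    lr: float = 1e-3
    weight_decay: float = 1e-4  # fine-tuning (AdamW) only
    lr_floor_fraction: float = 0.01
    optimizer_pretrain: str = "adam"
    optimizer_finetune: str = "adamw"
    schedule_finetune: str = "cosine_to_floor"  # or "none"
    seed: int = 0
    mask_ratio: float = 0.6
    grad_clip: float | None = None
    freeze_encoder: bool = False
    lr_pretrain: float | None = None  # pretraining lr override (defaults to lr)

    def __post_init__(self) -> None:
        for name in ("epochs_pretrain", "epochs_finetune", "batch_size", "lr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.lr_floor_fraction <= 1.0:
            raise ValueError("lr_floor_fraction must lie in (0, 1]")
        if not 0.0 < self.mask_ratio < 1.0:
            raise ValueError("mask_ratio must lie in (0, 1)")
        if self.optimizer_pretrain != "adam":
            raise ValueError("pretraining uses Adam")
        if self.optimizer_finetune != "adamw":
            raise ValueError("fine-tuning uses AdamW")
        if self.schedule_finetune not in ("cosine_to_floor", "none"):
            raise ValueError(f"unknown schedule {self.schedule_finetune!r}")


@dataclass
class TrainLog:
    stage: str  # {"pretrain", "finetune"}
    epochs: list[dict] = field(default_factory=list)

    def record(self, epoch: int, loss: float, lr: float, seconds: float) -> None:
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        self.epochs.append(
            {"epoch": epoch, "loss": float(loss), "lr": float(lr), "seconds": float(seconds)}
        )

    def losses(self) -> np.ndarray:
        return np.array([e["loss"] for e in self.epochs])


@dataclass
class Checkpoint:
    """Weights plus every config needed to verify compatibility downstream."""

    state: dict[str, np.ndarray]
    model_config: ModelConfig
    classifier_config: ClassifierConfig | None = None
    preprocess: dict = field(default_factory=dict)  # {"F": ..., "w": ..., "standardize": ...}
    class_names: list[str] = field(default_factory=list)

    def save(self, path) -> None:
        """Write ``<path>.npz`` (weights) and ``<path>.json`` (configs)."""
        path = Path(path)
        base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
        np.savez(str(base) + ".npz", **self.state)
        meta = {
            "model_config": asdict(self.model_config),
            "classifier_config": asdict(self.classifier_config)
            if self.classifier_config
            else None,
            "preprocess": self.preprocess,
            "class_names": self.class_names,
        }
        with open(str(base) + ".json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        path = Path(path)
        base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
        with np.load(str(base) + ".npz") as npz:
            state = {k: npz[k].copy() for k in npz.files}
        with open(str(base) + ".json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        ccfg = meta["classifier_config"]
        return cls(
            state=state,
            model_config=ModelConfig(**meta["model_config"]),
            classifier_config=ClassifierConfig(**ccfg) if ccfg else None,
            preprocess=meta["preprocess"],
            class_names=meta["class_names"],
        )


class Adam:
    """Adam with conventional betas (0.9, 0.999)."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _decay(self, p: Parameter) -> None:
        if self.weight_decay:
            # L2 penalty folded into the gradient (classic Adam)
            p.grad = p.grad + self.weight_decay * p.data

    def step(self, clip: float | None = None) -> None:
        self.t += 1
        if clip is not None:
            total = np.sqrt(sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None))
            if total > clip:
                scale = clip / (total + 1e-12)
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self._decay(p)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class AdamW(Adam):
    """Adam with decoupled weight decay."""

    def _decay(self, p: Parameter) -> None:
        if self.weight_decay:
            p.data = p.data - self.lr * self.weight_decay * p.data


def cosine_lr(epoch: int, total_epochs: int, lr: float, floor_fraction: float) -> float:
    """Cosine annealing from ``lr`` (epoch 0) to ``lr * floor_fraction`` (last epoch)."""
    floor = lr * floor_fraction
    if total_epochs <= 1:
        return lr
    t = epoch / (total_epochs - 1)
    return floor + 0.5 * (lr - floor) * (1.0 + np.cos(np.pi * t))


def _prepare_segments(events: EventSet, w: int) -> np.ndarray:
    if events.fixed_length is None:
        raise ValueError("events must be preprocessed to a fixed length first")
    if len(events) == 0:
        raise ValueError("empty event set")
    return segment_matrix(events.trace_matrix(), w)


def pretrain(
    events: EventSet, mcfg: ModelConfig, tcfg: TrainConfig
) -> tuple[Checkpoint, TrainLog]:
    """Self-supervised pretraining of projection + encoder (+ decoder).

    Labels are never read: only the trace matrix enters the loop.  Each event
    receives a fresh uniformly random mask plan every epoch from a stream
    seeded by ``tcfg.seed``.
    """
    segments = _prepare_segments(events, mcfg.w)  # labels stripped here
    B, L, _ = segments.shape
    if L < 2:
        raise ValueError(f"need at least 2 subsequences per event, got L={L}")
    m = n_masked(L, tcfg.mask_ratio)

    lr = tcfg.lr_pretrain if tcfg.lr_pretrain is not None else tcfg.lr
    model = MaskedAutoencoder(mcfg, n_positions=L, seed=tcfg.seed).train()
    opt = Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, 0x5EED]))
    log = TrainLog(stage="pretrain")

    for epoch in range(tcfg.epochs_pretrain):
        t0 = time.perf_counter()
        order = rng.permutation(B)
        losses, weights = [], []
        for start in range(0, B, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            batch = segments[idx]
            b = batch.shape[0]
            # fresh per-event mask plans
            ranks = np.argsort(rng.random((b, L)), axis=1)
            masked = np.sort(ranks[:, :m], axis=1)
            visible = np.sort(ranks[:, m:], axis=1)

            X = model.project(batch)
            Hv = model.encode(X, "visible_only", (masked, visible))
            Hm = model.encode(X, "masked_only", (masked, visible))
            targets = model.pretrain_targets(Hm)
            Fdec = model.decode(model.build_decoder_input(Hv, (masked, visible)))
            Fm = model.decoded_at(Fdec, masked)
            loss = mse_latent_loss(Fm, targets)

            opt.zero_grad()
            loss.backward()
            opt.step(clip=tcfg.grad_clip)
            losses.append(loss.item())
            weights.append(b)
        log.record(epoch, np.average(losses, weights=weights), lr,
                   time.perf_counter() - t0)

    ckpt = Checkpoint(
        state=model.state_dict(),
        model_config=mcfg,
        preprocess={"F": int(events.fixed_length), "w": int(mcfg.w)},
    )
    return ckpt, log


def _class_indices(events: EventSet) -> tuple[np.ndarray, list[str]]:
    names = list(events.class_names)
    lookup = {c: i for i, c in enumerate(names)}
    y = np.empty(len(events), dtype=np.int64)
    for i, ev in enumerate(events):
        if not ev.label:
            raise ValueError(f"event {ev.id!r} is unlabeled; fine-tuning requires labels")
        y[i] = lookup[ev.label]
    return y, names


def finetune(
    events: EventSet,
    init: Checkpoint | None,
    mcfg: ModelConfig,
    ccfg: ClassifierConfig,
    tcfg: TrainConfig,
) -> tuple[Checkpoint, TrainLog]:
    """Supervised fine-tuning (or the ZeroTrain baseline when ``init`` is None)."""
    y, class_names = _class_indices(events)
    if ccfg.M != len(class_names):
        raise ValueError(f"classifier M={ccfg.M} but data has {len(class_names)} classes")
    segments = _prepare_segments(events, mcfg.w)
    B, L, _ = segments.shape

    model = MaskedAutoencoder(mcfg, n_positions=L, seed=tcfg.seed).train()
    if init is not None:
        ic = init.model_config
        if (ic.d, ic.w, ic.n_layers, ic.backbone) != (mcfg.d, mcfg.w, mcfg.n_layers, mcfg.backbone):
            raise ValueError("pretrained checkpoint is incompatible with the model config")
        if init.preprocess.get("F") != int(events.fixed_length):
            raise ValueError(
                f"checkpoint was pretrained at F={init.preprocess.get('F')}, "
                f"data has F={events.fixed_length}"
            )
        model.load_state_dict(init.state)
    clf = Classifier(ccfg, mcfg.d, seed=tcfg.seed + 1).train()

    params = clf.parameters() if tcfg.freeze_encoder else model.parameters() + clf.parameters()
    opt = AdamW(params, lr=tcfg.lr, weight_decay=tcfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, 0xF17E]))
    log = TrainLog(stage="finetune")

    for epoch in range(tcfg.epochs_finetune):
        t0 = time.perf_counter()
        if tcfg.schedule_finetune == "cosine_to_floor":
            lr_e = cosine_lr(epoch, tcfg.epochs_finetune, tcfg.lr, tcfg.lr_floor_fraction)
        else:
            lr_e = tcfg.lr
        opt.lr = lr_e
        order = rng.permutation(B)
        losses, weights = [], []
        for start in range(0, B, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            z = model.embed_event(segments[idx])
            logits = clf(z)
            logp = log_softmax(logits, axis=-1)
            nll = -logp[np.arange(idx.size), y[idx]].mean()
            opt.zero_grad()
            nll.backward()
            opt.step(clip=tcfg.grad_clip)
            losses.append(nll.item())
            weights.append(idx.size)
        log.record(epoch, np.average(losses, weights=weights), lr_e,
                   time.perf_counter() - t0)

    state = {f"model.{k}": v for k, v in model.state_dict().items()}
    state.update({f"clf.{k}": v for k, v in clf.state_dict().items()})
    ckpt = Checkpoint(
        state=state,
        model_config=mcfg,
        classifier_config=ccfg,
        preprocess={"F": int(events.fixed_length), "w": int(mcfg.w)},
        class_names=class_names,
    )
    return ckpt, log


def _split_state(state: dict[str, np.ndarray]) -> tuple[dict, dict]:
    model_state = {k[6:]: v for k, v in state.items() if k.startswith("model.")}
    clf_state = {k[4:]: v for k, v in state.items() if k.startswith("clf.")}
    return model_state, clf_state


def load_finetuned(ckpt: Checkpoint, L: int) -> tuple[MaskedAutoencoder, Classifier]:
    """Rebuild model + classifier from a fine-tuned checkpoint, in eval mode."""
    if ckpt.classifier_config is None:
        raise ValueError("checkpoint has no classifier head")
    model_state, clf_state = _split_state(ckpt.state)
    model = MaskedAutoencoder(ckpt.model_config, n_positions=L, seed=0).eval()
    model.load_state_dict(model_state)
    clf = Classifier(ckpt.classifier_config, ckpt.model_config.d, seed=0).eval()
    clf.load_state_dict(clf_state)
    return model, clf


def predict(events: EventSet, ckpt: Checkpoint, batch_size: int = 256) -> pd.DataFrame:
    """Per-event class probabilities (softmax rows summing to 1).

    Returns a DataFrame with columns ``id``, ``true_label``, ``pred_label``
    and one probability column ``p_<class>`` per class.
    """
    if events.fixed_length is None:
        raise ValueError("events must be fixed-length")
    if ckpt.preprocess.get("F") != int(events.fixed_length):
        raise ValueError(
            f"checkpoint expects F={ckpt.preprocess.get('F')}, data has F={events.fixed_length}"
        )
    segments = _prepare_segments(events, ckpt.model_config.w)
    B, L, _ = segments.shape
    model, clf = load_finetuned(ckpt, L)
    probs = np.empty((B, ckpt.classifier_config.M))
    for start in range(0, B, batch_size):
        z = model.embed_event(segments[start : start + batch_size])
        probs[start : start + batch_size] = softmax(clf(z), axis=-1).data
    classes = ckpt.class_names
    pred = [classes[i] for i in probs.argmax(axis=1)]
    out = {
        "id": [ev.id for ev in events],
        "true_label": [ev.label for ev in events],
        "pred_label": pred,
    }
    for j, c in enumerate(classes):
        out[f"p_{c}"] = probs[:, j]
    return pd.DataFrame(out)
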