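"""Metrics, cross-validation and the experiment runners.

Headline precision/recall are macro-averaged (unweighted over classes) and the
headline F1 is the harmonic mean of the macro precision and macro recall;
per-class F1 values are also emitted.  ``run_cv`` performs stratified k-fold
cross-validation of the full pretrain+finetune pipeline (pretraining sees only
the training partition of each fold); ``scarcity_experiment`` and
``mask_ratio_sweep`` wrap it into the data-scarcity and mask-ratio protocols,
and ``export_embeddings`` dumps pooled event embeddings for projection tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .event_io import EventSet
from .mae_model import ClassifierConfig, MaskedAutoencoder, ModelConfig
from .preprocess import segment_matrix
from .training import Checkpoint, TrainConfig, finetune, predict, pretrain

__all__ = [
    "MetricReport",
    "FoldAssignment",
    "ExperimentConfig",
    "CVResult",
    "cross_entropy",
    "compute_metrics",
    "kfold",
    "run_cv",
    "scarcity_experiment",
    "mask_ratio_sweep",
    "export_embeddings",
]


def cross_entropy(probs, true_class: int) -> float:
    """``-log p_true`` for a single predicted distribution (one-hot target)."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 1:
        raise ValueError("probs must be a single distribution")
    if not 0 <= true_class < probs.size:
        raise IndexError(f"class index {true_class} out of range for M={probs.size}")
    if not math.isclose(probs.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("probabilities must sum to 1")
    return float(-np.log(max(probs[true_class], 1e-12)))


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str
    confusion: np.ndarray  # rows = true, columns = predicted
    n: int
    class_names: list[str]
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_f1: np.ndarray


def compute_metrics(
    preds, truth, averaging: str = "macro", class_names: list[str] | None = None
) -> MetricReport:
    """Accuracy, averaged precision/recall/F1 and the confusion matrix.

    Classes in ``class_names`` that appear in neither truth nor predictions
    contribute zero precision/recall and are counted in the macro average.
    """
    preds, truth = list(preds), list(truth)
    if len(preds) != len(truth):
        raise ValueError("preds and truth must have equal length")
    if not preds:
        raise ValueError("cannot compute metrics on empty input")
    if averaging not in ("macro", "micro"):
        raise ValueError(f"unknown averaging {averaging!r}")
    if class_names is None:
        class_names = []
        for lab in truth + preds:
            if lab not in class_names:
                class_names.append(lab)
    lookup = {c: i for i, c in enumerate(class_names)}
    M, n = len(class_names), len(preds)
    confusion = np.zeros((M, M), dtype=np.int64)
    for t, p in zip(truth, preds):
        confusion[lookup[t], lookup[p]] += 1

    diag = np.diag(confusion).astype(float)
    col = confusion.sum(axis=0).astype(float)  # predicted counts
    row = confusion.sum(axis=1).astype(float)  # true counts
    with np.errstate(divide="ignore", invalid="ignore"):
        prec_c = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
        rec_c = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
        denom = prec_c + rec_c
        f1_c = np.where(denom > 0, 2 * prec_c * rec_c / np.maximum(denom, 1e-300), 0.0)

    accuracy = float(diag.sum() / n)
    if averaging == "macro":
        precision, recall = float(prec_c.mean()), float(rec_c.mean())
    else:
        precision = recall = accuracy
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return MetricReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=float(f1),
        averaging=averaging,
        confusion=confusion,
        n=n,
        class_names=list(class_names),
        per_class_precision=prec_c,
        per_class_recall=rec_c,
        per_class_f1=f1_c,
    )


@dataclass
class FoldAssignment:
    k: int
    fold_of: dict[str, int]  # event id -> fold
    seed: int
    stratified: bool

    def test_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_of.items() if f == fold]


def kfold(events: EventSet, k: int, seed: int, stratified: bool = True) -> FoldAssignment:
    """Deterministic (stratified) k-fold assignment; per-class fold sizes
    differ by at most one when stratified."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    if stratified:
        by_class: dict[str, list[str]] = {}
        for ev in events:
            by_class.setdefault(ev.label, []).append(ev.id)
        for label, ids in by_class.items():
            if len(ids) < k:
                raise ValueError(
                    f"class {label!r} has {len(ids)} events, fewer than k={k}"
                )
            order = rng.permutation(len(ids))
            for j, pos in enumerate(order):
                fold_of[ids[pos]] = j % k
    else:
        ids = [ev.id for ev in events]
        order = rng.permutation(len(ids))
        for j, pos in enumerate(order):
            fold_of[ids[pos]] = j % k
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed, stratified=stratified)


@dataclass
class ExperimentConfig:
    """Everything needed to train and evaluate one pipeline variant."""

    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    d_c: int = 256
    p2: float = 0.2
    pretrain: bool = True  # False = ZeroTrain baseline

    def classifier(self, M: int) -> ClassifierConfig:
        return ClassifierConfig(M=M, d_c=self.d_c, p2=self.p2)

    @classmethod
    def scaled_down(cls, seed: int = 0, pretrain: bool = True) -> "ExperimentConfig":
        """The desk-scale protocol used throughout the docs and examples.

        A small model (d=32, 2 layers, 2 heads) trained for 30+30 epochs.
        Because a few hundred events at batch 16 give only a few hundred
        optimizer steps, the fine-tuning learning rate is raised to 3e-3
        (pretraining keeps the reference 1e-3, where the pretext task is
        well-behaved) and gradients are norm-clipped at 1.0.
        """
        return cls(
            model=ModelConfig(d=32, d_k=16, d_v=16, n_layers=2, h=2, w=12),
            train=TrainConfig(
                epochs_pretrain=30,
                epochs_finetune=30,
                batch_size=16,
                lr=3e-3,
                lr_pretrain=1e-3,
                grad_clip=1.0,
                seed=seed,
            ),
            d_c=64,
            pretrain=pretrain,
        )


@dataclass
class CVResult:
    folds: list[MetricReport]
    fold_assignment: FoldAssignment

    def mean_sd(self, metric: str) -> tuple[float, float]:
        vals = np.array([getattr(r, metric) for r in self.folds])
        return float(vals.mean()), float(vals.std(ddof=1) if vals.size > 1 else 0.0)

    @property
    def accuracy(self) -> float:
        return self.mean_sd("accuracy")[0]

    @property
    def f1(self) -> float:
        return self.mean_sd("f1")[0]


def _train_and_eval(
    train_set: EventSet, test_set: EventSet, cfg: ExperimentConfig, class_names: list[str]
) -> MetricReport:
    ccfg = cfg.classifier(M=len(train_set.class_names))
    init = None
    if cfg.pretrain:
        init, _ = pretrain(train_set, cfg.model, cfg.train)
    ckpt, _ = finetune(train_set, init, cfg.model, ccfg, cfg.train)
    df = predict(test_set, ckpt)
    return compute_metrics(df["pred_label"], df["true_label"], class_names=class_names)


def run_cv(events: EventSet, k: int, cfg: ExperimentConfig, seed: int = 0) -> CVResult:
    """Stratified k-fold CV of the full pipeline; pretraining (when enabled)
    sees only each fold's training partition."""
    fa = kfold(events, k, seed=seed, stratified=True)
    class_names = list(events.class_names)
    reports = []
    for fold in range(k):
        train_idx = [i for i, ev in enumerate(events) if fa.fold_of[ev.id] != fold]
        test_idx = [i for i, ev in enumerate(events) if fa.fold_of[ev.id] == fold]
        reports.append(
            _train_and_eval(events.subset(train_idx), events.subset(test_idx), cfg, class_names)
        )
    return CVResult(folds=reports, fold_assignment=fa)


def _stratified_subsample(events: EventSet, fraction: float, rng: np.random.Generator) -> EventSet:
    if fraction >= 1.0:
        return events
    by_class: dict[str, list[int]] = {}
    for i, ev in enumerate(events):
        by_class.setdefault(ev.label, []).append(i)
    keep: list[int] = []
    for label, idx in by_class.items():
        n = int(round(fraction * len(idx)))
        if n < 1:
            raise ValueError(
                f"fraction {fraction} leaves no events of class {label!r}"
            )
        chosen = rng.choice(len(idx), size=n, replace=False)
        keep.extend(idx[j] for j in chosen)
    return events.subset(sorted(keep))


def scarcity_experiment(
    events: EventSet,
    fractions: list[float],
    variants: list[str],
    seeds: list[int],
    cfg: ExperimentConfig,
    k: int = 2,
) -> pd.DataFrame:
    """Data-scarcity protocol: per CV fold, fine-tune on stratified subsamples
    of the training split while evaluating on the fixed held-out fold.

    Labels are the scarce resource: the ``pretrained`` variant is pretrained
    once per fold on the *full* (label-stripped) training split and then
    fine-tuned on the subsample, while ``zerotrain`` trains from scratch on
    the subsample.  Returns a tidy table
    (fraction, variant, seed, fold, accuracy, f1).
    """
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
    for v in variants:
        if v not in ("pretrained", "zerotrain"):
            raise ValueError(f"unknown variant {v!r}")
    class_names = list(events.class_names)
    rows = []
    for seed in seeds:
        fa = kfold(events, k, seed=seed, stratified=True)
        for fold in range(k):
            train_idx = [i for i, ev in enumerate(events) if fa.fold_of[ev.id] != fold]
            test_idx = [i for i, ev in enumerate(events) if fa.fold_of[ev.id] == fold]
            train_all, test_set = events.subset(train_idx), events.subset(test_idx)
            tcfg = replace(cfg.train, seed=seed)
            init = None
            if "pretrained" in variants:
                init, _ = pretrain(train_all, cfg.model, tcfg)
            for fraction in fractions:
                sub_rng = np.random.default_rng(
                    np.random.SeedSequence([seed, fold, int(round(fraction * 1e6))])
                )
                train_sub = _stratified_subsample(train_all, fraction, sub_rng)
                ccfg = cfg.classifier(M=len(train_sub.class_names))
                for variant in variants:
                    ckpt, _ = finetune(
                        train_sub,
                        init if variant == "pretrained" else None,
                        cfg.model,
                        ccfg,
                        tcfg,
                    )
                    df = predict(test_set, ckpt)
                    rep = compute_metrics(
                        df["pred_label"], df["true_label"], class_names=class_names
                    )
                    rows.append(
                        {
                            "fraction": fraction,
                            "variant": variant,
                            "seed": seed,
                            "fold": fold,
                            "accuracy": rep.accuracy,
                            "f1": rep.f1,
                        }
                    )
    return pd.DataFrame(rows)


def mask_ratio_sweep(
    events: EventSet, ratios: list[float], seeds: list[int], cfg: ExperimentConfig
) -> pd.DataFrame:
    """Full pretrain+finetune per mask ratio per seed on a stratified 50/50
    split; tidy table (ratio, seed, accuracy)."""
    class_names = list(events.class_names)
    rows = []
    for ratio in ratios:
        for seed in seeds:
            fa = kfold(events, 2, seed=seed, stratified=True)
            train_idx = [i for i, ev in enumerate(events) if fa.fold_of[ev.id] != 0]
            test_idx = [i for i, ev in enumerate(events) if fa.fold_of[ev.id] == 0]
            vcfg = replace(
                cfg,
                pretrain=True,
                train=replace(cfg.train, mask_ratio=ratio, seed=seed),
            )
            rep = _train_and_eval(
                events.subset(train_idx), events.subset(test_idx), vcfg, class_names
            )
            rows.append({"ratio": ratio, "seed": seed, "accuracy": rep.accuracy})
    return pd.DataFrame(rows)


def export_embeddings(
    events: EventSet,
    checkpoint: Checkpoint | None,
    stage: str,
    path=None,
    mcfg: ModelConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled event embeddings ``z`` as a table (id, label, z1..zd).

    ``stage`` is recorded for provenance: ``random_init`` builds a freshly
    seeded untrained encoder; the other stages (``pretrained``, ``zerotrain``,
    ``finetuned``) embed with the supplied checkpoint.
    """
    if events.fixed_length is None:
        raise ValueError("events must be fixed-length")
    if stage == "random_init":
        mcfg = mcfg or (checkpoint.model_config if checkpoint else ModelConfig())
        segments = segment_matrix(events.trace_matrix(), mcfg.w)
        model = MaskedAutoencoder(mcfg, n_positions=segments.shape[1], seed=seed).eval()
    else:
        if checkpoint is None:
            raise ValueError(f"stage {stage!r} requires a checkpoint")
        mcfg = checkpoint.model_config
        segments = segment_matrix(events.trace_matrix(), mcfg.w)
        model = MaskedAutoencoder(mcfg, n_positions=segments.shape[1], seed=seed).eval()
        state = checkpoint.state
        if any(key.startswith("model.") for key in state):
            state = {k[6:]: v for k, v in state.items() if k.startswith("model.")}
        model.load_state_dict(state)
    zs = []
    for start in range(0, segments.shape[0], 256):
        zs.append(model.embed_event(segments[start : start + 256]).data)
    z = np.concatenate(zs, axis=0) if zs else np.empty((0, mcfg.d))
    df = pd.DataFrame({"id": [ev.id for ev in events], "label": [ev.label for ev in events]})
    for j in range(mcfg.d):
        df[f"z{j + 1}"] = z[:, j]
    if path is not None:
        with open(Path(path), "w", encoding="utf-8") as fh:
            fh.write(f"# stage={stage}\tseed={seed}\n")
            df.to_csv(fh, sep="\t", index=False)
    return df
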