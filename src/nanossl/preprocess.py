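"""Fixed-length conversion, segmentation and mask planning.

The model consumes events as ``L`` non-overlapping subsequences of length
``w`` cut from a fixed-length trace: variable-length events are first brought
to a common length ``F`` either by linear interpolation (peptide-sequencing
style, F = 500) or by centered padding (barcode-carrier style, F = 700), then
segmented, and during pretraining a random subset of subsequences at mask
ratio ``r`` is hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .event_io import EventRecord, EventSet

__all__ = [
    "FixedTrace",
    "SegmentedEvent",
    "MaskPlan",
    "resample_linear",
    "pad_center",
    "standardize",
    "standardize_events",
    "segment",
    "make_mask",
    "preprocess_events",
    "segment_matrix",
]


@dataclass
class FixedTrace:
    """A trace of exactly ``F`` points, with padding provenance."""

    values: np.ndarray
    origin: str  # {"interpolated", "padded"}
    pad_mask: np.ndarray  # bool, True where value is padding

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.pad_mask = np.asarray(self.pad_mask, dtype=bool)
        if self.values.shape != self.pad_mask.shape:
            raise ValueError("values and pad_mask must have equal length")
        if self.origin == "interpolated" and self.pad_mask.any():
            raise ValueError("interpolated traces cannot carry padding")


@dataclass
class SegmentedEvent:
    """An ``L x w`` matrix of non-overlapping subsequences of a fixed trace."""

    subsequences: np.ndarray
    w: int
    L: int
    tail_pad: int

    def concatenate(self) -> np.ndarray:
        """Invert segmentation: rows joined, tail padding dropped."""
        flat = self.subsequences.reshape(-1)
        return flat[: flat.size - self.tail_pad]


@dataclass
class MaskPlan:
    """Visible/masked partition of subsequence indices at ratio ``r``."""

    masked_idx: np.ndarray
    visible_idx: np.ndarray
    r: float
    seed: int

    def __post_init__(self) -> None:
        self.masked_idx = np.asarray(self.masked_idx, dtype=np.int64)
        self.visible_idx = np.asarray(self.visible_idx, dtype=np.int64)
        union = np.concatenate([self.masked_idx, self.visible_idx])
        L = union.size
        if np.intersect1d(self.masked_idx, self.visible_idx).size:
            raise ValueError("masked and visible indices must be disjoint")
        if not np.array_equal(np.sort(union), np.arange(L)):
            raise ValueError("masked and visible indices must partition 0..L-1")


def n_masked(L: int, r: float) -> int:
    """Mask count: round(r*L) half-up, clamped to [1, L-1]."""
    return int(min(max(int(math.floor(r * L + 0.5)), 1), L - 1))


def resample_linear(event: EventRecord, F: int) -> FixedTrace:
    """Resample a trace to ``F`` points by linear interpolation.

    Output position ``j`` is the piecewise-linear interpolant of the input
    evaluated at ``j * (T-1) / (F-1)``; the endpoints are preserved exactly.
    """
    trace = event.trace
    T = trace.size
    if T < 2:
        raise ValueError(f"event {event.id!r}: need at least 2 points to interpolate")
    if F < 2:
        raise ValueError("F must be >= 2")
    if F == T:
        values = trace.copy()
    else:
        values = np.interp(np.arange(F) * (T - 1) / (F - 1), np.arange(T), trace)
        values[0], values[-1] = trace[0], trace[-1]
    return FixedTrace(values=values, origin="interpolated", pad_mask=np.zeros(F, dtype=bool))


def pad_center(event: EventRecord, F: int, pad_value: float = 0.0) -> FixedTrace:
    """Place the trace centrally in an ``F``-vector, padding both sides."""
    trace = event.trace
    T = trace.size
    if T > F:
        raise ValueError(
            f"event {event.id!r}: length {T} exceeds F={F}; resample or truncate first"
        )
    left = (F - T) // 2
    values = np.full(F, float(pad_value))
    values[left : left + T] = trace
    pad_mask = np.ones(F, dtype=bool)
    pad_mask[left : left + T] = False
    return FixedTrace(values=values, origin="padded", pad_mask=pad_mask)


def standardize(trace: FixedTrace, mode: str = "zscore") -> FixedTrace:
    """Amplitude normalization over non-pad values; pad values are untouched."""
    if mode == "none":
        return FixedTrace(trace.values.copy(), trace.origin, trace.pad_mask.copy())
    if mode != "zscore":
        raise ValueError(f"unknown standardization mode {mode!r}")
    values = trace.values.copy()
    real = ~trace.pad_mask
    mu = values[real].mean()
    sd = values[real].std()
    if sd < 1e-12:
        sd = 1.0
    values[real] = (values[real] - mu) / sd
    return FixedTrace(values=values, origin=trace.origin, pad_mask=trace.pad_mask.copy())


def standardize_events(events: EventSet, mode: str = "zscore_global") -> EventSet:
    """Standardize a whole fixed-length EventSet.

    ``none`` and ``zscore`` apply :func:`standardize` per trace.
    ``zscore_global`` subtracts one scalar mean and divides by one scalar
    standard deviation computed over every value in the set — the analog of
    calibrating all events against a common open-pore current, which centers
    the data for optimization while preserving between-event amplitude
    differences.
    """
    if events.fixed_length is None:
        raise ValueError("standardize_events requires a fixed-length EventSet")
    if mode == "zscore_global":
        X = events.trace_matrix()
        mu = float(X.mean())
        sd = float(X.std())
        if sd < 1e-12:
            sd = 1.0
        new = [
            EventRecord(
                id=ev.id,
                trace=(ev.trace - mu) / sd,
                label=ev.label,
                source=ev.source,
                duration_points=ev.duration_points,
            )
            for ev in events
        ]
    elif mode in ("none", "zscore"):
        new = []
        for ev in events:
            ft = standardize(
                FixedTrace(ev.trace, "interpolated", np.zeros(ev.trace.size, bool)), mode
            )
            new.append(
                EventRecord(
                    id=ev.id,
                    trace=ft.values,
                    label=ev.label,
                    source=ev.source,
                    duration_points=ev.duration_points,
                )
            )
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    return EventSet.from_events(new, fixed_length=events.fixed_length)


def segment(trace: FixedTrace | np.ndarray, w: int) -> SegmentedEvent:
    """Cut a fixed-length trace into ``L = ceil(F/w)`` subsequences of length ``w``.

    The final subsequence is tail-padded with its own last real value so no
    artificial step edge is created; ``tail_pad`` records how many values to
    drop when reconstructing.
    """
    if w < 1:
        raise ValueError("subsequence length w must be >= 1")
    values = trace.values if isinstance(trace, FixedTrace) else np.asarray(trace, float)
    F = values.size
    L = -(-F // w)
    tail_pad = L * w - F
    padded = np.concatenate([values, np.full(tail_pad, values[-1])]) if tail_pad else values
    return SegmentedEvent(subsequences=padded.reshape(L, w).copy(), w=w, L=L, tail_pad=tail_pad)


def make_mask(L: int, r: float, seed: int) -> MaskPlan:
    """Uniformly random visible/masked partition, deterministic given ``seed``."""
    if L < 2:
        raise ValueError("need L >= 2 subsequences to define a mask")
    if not 0.0 < r < 1.0:
        raise ValueError("mask ratio r must lie in (0, 1)")
    m = n_masked(L, r)
    rng = np.random.default_rng(seed)
    masked = np.sort(rng.choice(L, size=m, replace=False))
    visible = np.setdiff1d(np.arange(L), masked, assume_unique=True)
    return MaskPlan(masked_idx=masked, visible_idx=visible, r=float(r), seed=int(seed))


def preprocess_events(
    events: EventSet,
    mode: str,
    F: int,
    standardize_mode: str = "none",
    pad_value: float = 0.0,
) -> EventSet:
    """Bring every event to length ``F`` (``mode`` in {"interp", "pad"}) and
    standardize (per-trace {"none", "zscore"} or dataset-level "zscore_global")."""
    if mode not in ("interp", "pad"):
        raise ValueError(f"unknown preprocessing mode {mode!r}")
    out = []
    for ev in events:
        ft = resample_linear(ev, F) if mode == "interp" else pad_center(ev, F, pad_value)
        if standardize_mode in ("none", "zscore"):
            ft = standardize(ft, standardize_mode)
        out.append(
            EventRecord(
                id=ev.id,
                trace=ft.values,
                label=ev.label,
                source=ev.source,
                duration_points=ev.duration_points,
            )
        )
    fixed = EventSet.from_events(out, fixed_length=F)
    if standardize_mode == "zscore_global":
        fixed = standardize_events(fixed, "zscore_global")
    elif standardize_mode not in ("none", "zscore"):
        raise ValueError(f"unknown standardization mode {standardize_mode!r}")
    return fixed


def segment_matrix(traces: np.ndarray, w: int) -> np.ndarray:
    """Vectorized segmentation of a (B, F) trace matrix into (B, L, w).

    Same tail-padding rule as :func:`segment` (replicate each trace's last
    value).
    """
    traces = np.asarray(traces, dtype=np.float64)
    B, F = traces.shape
    L = -(-F // w)
    tail_pad = L * w - F
    if tail_pad:
        tail = np.repeat(traces[:, -1:], tail_pad, axis=1)
        traces = np.concatenate([traces, tail], axis=1)
    return traces.reshape(B, L, w).copy()
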