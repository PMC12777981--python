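"""Reading and writing nanopore translocation-event datasets.

Events are variable-length 1-D relative current-blockade traces with a class
label.  The canonical on-disk format is NDJSON (one event object per line),
which round-trips arbitrary-length traces bit-stably because floats are
serialized as shortest round-trip decimals.  A rectangular tab-separated
dialect (``matrix_tsv``) is provided for fixed-length, post-preprocessing
datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["EventRecord", "EventSet", "read_events", "write_events"]

FORMATS = ("ndjson", "matrix_tsv")


@dataclass
class EventRecord:
    """One raw translocation event.

    Parameters
    ----------
    id : str
        Unique event identifier.
    trace : numpy.ndarray
        Relative current blockade samples (arbitrary units), length ``T >= 1``.
    label : str
        Class name; empty string for unlabeled events.
    source : str
        Provenance tag (e.g. pore id).
    duration_points : int
        Raw event length before any resampling; defaults to ``len(trace)``.
    """

    id: str
    trace: np.ndarray
    label: str = ""
    source: str = ""
    duration_points: int | None = None

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=np.float64)
        if self.trace.ndim != 1 or self.trace.size == 0:
            raise ValueError(f"event {self.id!r}: trace must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.trace)):
            raise ValueError(f"event {self.id!r}: trace contains non-finite values")
        if self.duration_points is None:
            self.duration_points = int(self.trace.size)
        if self.duration_points < 1:
            raise ValueError(f"event {self.id!r}: duration_points must be >= 1")


@dataclass
class EventSet:
    """An ordered collection of events plus label bookkeeping."""

    events: list[EventRecord] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)
    fixed_length: int | None = None

    @classmethod
    def from_events(
        cls, events: Iterable[EventRecord], fixed_length: int | None = None
    ) -> "EventSet":
        events = list(events)
        seen: set[str] = set()
        class_names: list[str] = []
        ids: set[str] = set()
        for ev in events:
            if ev.id in ids:
                raise ValueError(f"duplicate event id {ev.id!r}")
            ids.add(ev.id)
            if ev.label and ev.label not in seen:
                seen.add(ev.label)
                class_names.append(ev.label)
        if fixed_length is not None:
            for ev in events:
                if ev.trace.size != fixed_length:
                    raise ValueError(
                        f"event {ev.id!r} has length {ev.trace.size}, "
                        f"expected fixed_length={fixed_length}"
                    )
        return cls(events=events, class_names=class_names, fixed_length=fixed_length)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def labels(self) -> list[str]:
        return [ev.label for ev in self.events]

    def subset(self, indices: Sequence[int]) -> "EventSet":
        return EventSet.from_events(
            [self.events[i] for i in indices], fixed_length=self.fixed_length
        )

    def trace_matrix(self) -> np.ndarray:
        """Stack traces into a (n_events, fixed_length) array."""
        if self.fixed_length is None:
            raise ValueError("trace_matrix requires a fixed-length EventSet")
        return np.stack([ev.trace for ev in self.events]) if self.events else np.empty(
            (0, self.fixed_length)
        )


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def _read_ndjson(path: Path) -> EventSet:
    events: list[EventRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON at line {lineno}: {exc}") from exc
            if not isinstance(obj, dict) or "id" not in obj or "trace" not in obj:
                raise ValueError(f"{path}: line {lineno}: object must have 'id' and 'trace'")
            trace = obj["trace"]
            if not isinstance(trace, list) or not trace:
                raise ValueError(f"{path}: line {lineno}: 'trace' must be a non-empty array")
            if any(not isinstance(v, (int, float)) or not math.isfinite(v) for v in trace):
                raise ValueError(
                    f"{path}: non-finite or non-numeric value in record {obj['id']!r}"
                )
            events.append(
                EventRecord(
                    id=str(obj["id"]),
                    trace=np.asarray(trace, dtype=np.float64),
                    label=str(obj.get("label", "")),
                    source=str(obj.get("source", "")),
                    duration_points=int(obj.get("duration_points", len(trace))),
                )
            )
    return EventSet.from_events(events)


def _read_matrix_tsv(path: Path) -> EventSet:
    events: list[EventRecord] = []
    width: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 3 or cols[0] != "id" or cols[1] != "label":
            raise ValueError(f"{path}: line 1: expected header 'id\\tlabel\\tt0...'")
        width = len(cols) - 2
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != width + 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected {width + 2} columns, got {len(parts)}"
                )
            ev_id, label = parts[0], parts[1]
            try:
                trace = np.array([float(v) for v in parts[2:]], dtype=np.float64)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if not np.all(np.isfinite(trace)):
                raise ValueError(f"{path}: non-finite value in record {ev_id!r}")
            events.append(EventRecord(id=ev_id, trace=trace, label=label))
    return EventSet.from_events(events, fixed_length=width)


def read_events(path, format: str = "ndjson") -> EventSet:
    """Read an event dataset, preserving record order and labels verbatim."""
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    return _read_ndjson(path) if format == "ndjson" else _read_matrix_tsv(path)


def write_events(events: EventSet, path, format: str = "ndjson") -> None:
    """Write an event dataset; ``read_events`` of the result is an exact round-trip."""
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "ndjson":
        with open(path, "w", encoding="utf-8") as fh:
            for ev in events:
                trace = "[" + ", ".join(_fmt(v) for v in ev.trace) + "]"
                fh.write(
                    "{"
                    + f'"id": {json.dumps(ev.id)}, "trace": {trace}, '
                    + f'"label": {json.dumps(ev.label)}, "source": {json.dumps(ev.source)}, '
                    + f'"duration_points": {int(ev.duration_points)}'
                    + "}\n"
                )
        return
    if events.fixed_length is None:
        raise ValueError("matrix_tsv requires a fixed-length EventSet")
    width = events.fixed_length
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\t" + "\t".join(f"t{i}" for i in range(width)) + "\n")
        for ev in events:
            if ev.trace.size != width:
                raise ValueError(
                    f"event {ev.id!r} has length {ev.trace.size}, expected {width}"
                )
            fh.write(ev.id + "\t" + ev.label + "\t" + "\t".join(_fmt(v) for v in ev.trace) + "\n")
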