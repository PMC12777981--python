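"""Seeded simulator of nanopore-like translocation events.

Two event families with the statistical structure the learning method
exploits — localized, class-discriminative amplitude patterns embedded in
noisy variable-duration traces — so the whole pipeline is exercisable with no
external dataset:

* **Barcode-carrier events**: a flat carrier blockade with downward current
  spikes at equally spaced sites encoding bits (8 classes for 3 bits), plus an
  optional protein-binding spike in the latter half of the event (the binary
  bound/unbound task).
* **Peptide events**: a 42-residue chain read residue-by-residue; residue
  ``i`` occupies a gamma-distributed dwell at a blockade depth proportional to
  its volume (deeper = more negative), so single-residue mutations and
  PTM-style local volume changes shift the signal only inside one dwell
  window.  Traces are linearly resampled to a fixed length, as in peptide
  sequencing practice.

The default 42-mer is the canonical human amyloid-beta 1-42 sequence, used
here as a synthetic surrogate: positions 22 (E22G), 37 (G37R) and 26
(phosphoserine) line up with the named variants.  Residue volumes come from a
vendored published table; the crystallographic local volume deltas of the
variants (0.0887, 0.1357 and 0.0565 nm^3) are exposed as constants and can be
applied directly through ``volume_deltas``.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .event_io import EventRecord, EventSet
from . import preprocess

__all__ = [
    "AB42_SEQUENCE",
    "DELTA_VOLUME_E22G",
    "DELTA_VOLUME_G37R",
    "DELTA_VOLUME_PHOSPHO",
    "BarcodeSimParams",
    "PeptideSimParams",
    "load_volume_table",
    "simulate_barcode_event",
    "simulate_peptide_event",
    "barcode_template",
    "peptide_template",
    "mutate_sequence",
    "generate_dataset",
    "template_oracle_predict",
    "template_oracle_accuracy",
    "load_recipe",
    "dataset_from_recipe",
]

# Canonical human amyloid-beta 1-42 (surrogate fixture sequence; E at 22,
# S at 26, G at 37, 1-based).
AB42_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA"

# Local volume changes (nm^3) of the named variants, from crystallography.
DELTA_VOLUME_E22G = 0.0887
DELTA_VOLUME_G37R = 0.1357
DELTA_VOLUME_PHOSPHO = 0.0565


def load_volume_table() -> dict[str, float]:
    """Residue -> volume (nm^3) from the vendored published table."""
    table: dict[str, float] = {}
    text = (
        importlib.resources.files("nanossl").joinpath("data/aa_volumes.tsv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, vol = line.split("\t")
        table[code] = float(vol)
    return table


@dataclass
class BarcodeSimParams:
    """Geometry and noise of DNA barcode-carrier events."""

    n_bits: int = 3
    carrier_level: float = -0.2  # baseline blockade (negative = blocked)
    spike_amp: float = 0.15  # additional depth of a bit spike
    spike_width_points: int = 24
    event_len_range: tuple[int, int] = (420, 650)
    noise_sd: float = 0.02
    binding_site: str = "none"  # {"none", "unbound", "bound"}
    binding_amp: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.binding_site not in ("none", "unbound", "bound"):
            raise ValueError(f"unknown binding_site {self.binding_site!r}")
        lo = self.event_len_range[0]
        # all bit sites live in the first half; each needs a full spike window
        if self.spike_width_points * (self.n_bits + 1) > lo // 2:
            raise ValueError("spike windows do not fit inside the shortest event")


def barcode_template(barcode: str, params: BarcodeSimParams, length: int) -> np.ndarray:
    """Deterministic noiseless trace for a barcode at a given event length."""
    if len(barcode) != params.n_bits or any(c not in "01" for c in barcode):
        raise ValueError(f"barcode {barcode!r} must be {params.n_bits} binary digits")
    trace = np.full(length, params.carrier_level)
    half = length // 2
    w = params.spike_width_points
    for i, bit in enumerate(barcode):
        if bit == "1":
            center = int(round(half * (i + 1) / (params.n_bits + 1)))
            trace[max(0, center - w // 2) : center + w - w // 2] -= params.spike_amp
    if params.binding_site == "bound":
        center = int(round(length * 0.75))
        trace[center - w // 2 : center + w - w // 2] -= params.binding_amp
    return trace


def simulate_barcode_event(
    barcode: str,
    params: BarcodeSimParams,
    seed: int | None = None,
    event_id: str = "",
    label: str | None = None,
) -> EventRecord:
    """One noisy barcode-carrier event; deterministic given the seed."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    lo, hi = params.event_len_range
    length = int(rng.integers(lo, hi + 1))
    trace = barcode_template(barcode, params, length)
    if params.noise_sd > 0:
        trace = trace + rng.normal(0.0, params.noise_sd, size=length)
    if label is None:
        label = barcode if params.binding_site == "none" else params.binding_site
    return EventRecord(id=event_id or f"bc-{barcode}", trace=trace, label=label,
                       source="sim-barcode", duration_points=length)


@dataclass
class PeptideSimParams:
    """Residue-by-residue peptide translocation events.

    Blockade sign convention: larger residue volume -> deeper blockade ->
    more negative value.  ``volume_deltas`` adds a local volume change
    (nm^3, 1-based position) without altering the sequence — the PTM
    mechanism.
    """

    sequence: str = AB42_SEQUENCE
    volume_table: dict[str, float] | None = None
    volume_deltas: dict[int, float] = field(default_factory=dict)
    depth_per_volume: float = 3.0  # blockade units per nm^3
    dwell_mean_points: float = 12.0
    dwell_shape: float = 200.0  # gamma shape; large = near-constant translocation velocity
    noise_sd: float = 0.1
    out_len: int = 500
    drift_sd: float = 0.0  # optional per-point random-walk drift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.volume_table is None:
            self.volume_table = load_volume_table()
        missing = sorted(set(self.sequence) - set(self.volume_table))
        if missing:
            raise ValueError(f"no volume entry for residues {missing}")
        if self.out_len < 2:
            raise ValueError("out_len must be >= 2")
        for pos in self.volume_deltas:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"volume_deltas position {pos} outside sequence")
        if self.noise_sd < 0 or self.dwell_shape <= 0 or self.dwell_mean_points <= 0:
            raise ValueError("noise_sd >= 0 and positive dwell parameters required")


def _residue_depths(params: PeptideSimParams) -> np.ndarray:
    vols = np.array([params.volume_table[c] for c in params.sequence])
    for pos, delta in params.volume_deltas.items():
        vols[pos - 1] += delta
    return -params.depth_per_volume * vols


def peptide_template(params: PeptideSimParams) -> np.ndarray:
    """Deterministic noiseless trace: mean dwell per residue, resampled."""
    depths = _residue_depths(params)
    n = len(params.sequence)
    bounds = np.round(np.arange(n + 1) * params.dwell_mean_points).astype(int)
    raw = np.repeat(depths, np.diff(bounds))
    return np.interp(
        np.arange(params.out_len) * (raw.size - 1) / (params.out_len - 1),
        np.arange(raw.size),
        raw,
    )


def simulate_peptide_event(
    params: PeptideSimParams,
    seed: int | None = None,
    event_id: str = "",
    label: str = "",
) -> EventRecord:
    """One noisy peptide event; deterministic given the seed.

    Residue ``i`` occupies a gamma(dwell_shape) dwell with mean
    ``dwell_mean_points``; the piecewise-constant latent signal gets Gaussian
    noise (and optional random-walk drift) before linear resampling to
    ``out_len`` points.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    depths = _residue_depths(params)
    n = len(params.sequence)
    dwells = rng.gamma(
        shape=params.dwell_shape,
        scale=params.dwell_mean_points / params.dwell_shape,
        size=n,
    )
    counts = np.maximum(1, np.round(dwells).astype(int))
    raw = np.repeat(depths, counts)
    if params.noise_sd > 0:
        raw = raw + rng.normal(0.0, params.noise_sd, size=raw.size)
    if params.drift_sd > 0:
        raw = raw + np.cumsum(rng.normal(0.0, params.drift_sd, size=raw.size))
    duration = raw.size
    rec = EventRecord(id=event_id or "pep", trace=raw, label=label,
                      source="sim-peptide", duration_points=duration)
    fixed = preprocess.resample_linear(rec, params.out_len)
    return EventRecord(id=rec.id, trace=fixed.values, label=label,
                       source="sim-peptide", duration_points=duration)


def mutate_sequence(sequence: str, position_1based: int, new_residue: str) -> str:
    """Single-residue substitution at a 1-based position."""
    if not 1 <= position_1based <= len(sequence):
        raise ValueError(
            f"position {position_1based} outside sequence of length {len(sequence)}"
        )
    if len(new_residue) != 1:
        raise ValueError("new_residue must be a single one-letter code")
    i = position_1based - 1
    return sequence[:i] + new_residue + sequence[i + 1 :]


def default_peptide_classes(params: PeptideSimParams) -> list[tuple[str, str, dict]]:
    """Native / E22G / G37R class definitions on the reference sequence."""
    seq = params.sequence
    return [
        ("native", seq, {}),
        ("E22G", mutate_sequence(seq, 22, "G"), {}),
        ("G37R", mutate_sequence(seq, 37, "R"), {}),
    ]


def generate_dataset(
    task: str,
    n_per_class: int = 200,
    seed: int = 0,
    barcode_params: BarcodeSimParams | None = None,
    peptide_params: PeptideSimParams | None = None,
    class_defs: list[tuple[str, str, dict]] | None = None,
    class_counts: dict[str, int] | None = None,
) -> tuple[EventSet, dict]:
    """Labeled synthetic dataset plus a manifest of every parameter and seed.

    ``task`` is one of ``barcode8`` (2**n_bits barcode classes), ``binding2``
    (bound/unbound) or ``peptide`` (``class_defs`` = list of
    ``(label, sequence, volume_deltas)``, default native/E22G/G37R).
    ``class_counts`` overrides ``n_per_class`` per label for imbalanced sets.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    root = np.random.SeedSequence(seed)
    events: list[EventRecord] = []

    def count(label: str) -> int:
        return (class_counts or {}).get(label, n_per_class)

    if task == "barcode8":
        params = barcode_params or BarcodeSimParams()
        labels = [format(i, f"0{params.n_bits}b") for i in range(2**params.n_bits)]
        children = root.spawn(len(labels))
        for barcode, child in zip(labels, children):
            seeds = child.generate_state(count(barcode)).tolist()
            for j, s in enumerate(seeds):
                events.append(
                    simulate_barcode_event(
                        barcode, params, seed=s, event_id=f"barcode8-{barcode}-{j:04d}"
                    )
                )
        manifest_params = asdict(params)
    elif task == "binding2":
        base = barcode_params or BarcodeSimParams()
        labels = ["unbound", "bound"]
        children = root.spawn(2)
        for label, child in zip(labels, children):
            from dataclasses import replace

            params = replace(base, binding_site=label)
            barcode = "1" * params.n_bits  # fixed carrier barcode
            seeds = child.generate_state(count(label)).tolist()
            for j, s in enumerate(seeds):
                events.append(
                    simulate_barcode_event(
                        barcode, params, seed=s, event_id=f"binding2-{label}-{j:04d}",
                        label=label,
                    )
                )
        manifest_params = asdict(base)
    elif task == "peptide":
        params = peptide_params or PeptideSimParams()
        defs = class_defs or default_peptide_classes(params)
        children = root.spawn(len(defs))
        from dataclasses import replace

        for (label, sequence, deltas), child in zip(defs, children):
            cparams = replace(
                params, sequence=sequence, volume_deltas=dict(deltas),
                volume_table=dict(params.volume_table),
            )
            seeds = child.generate_state(count(label)).tolist()
            for j, s in enumerate(seeds):
                events.append(
                    simulate_peptide_event(
                        cparams, seed=s, event_id=f"peptide-{label}-{j:04d}", label=label
                    )
                )
        manifest_params = asdict(params)
        manifest_params["class_defs"] = [
            {"label": lab, "sequence": seq, "volume_deltas": deltas}
            for lab, seq, deltas in defs
        ]
    else:
        raise ValueError(f"unknown task {task!r}")

    fixed = params.out_len if task == "peptide" else None
    evset = EventSet.from_events(events, fixed_length=fixed)
    manifest = {
        "task": task,
        "seed": seed,
        "n_per_class": n_per_class,
        "class_counts": {c: sum(1 for e in events if e.label == c) for c in evset.class_names},
        "params": json.loads(json.dumps(manifest_params, default=str)),
        "sign_convention": "larger volume -> deeper blockade -> more negative value",
    }
    return evset, manifest


# -- independent nearest-template oracle -------------------------------------


def template_oracle_predict(
    events: EventSet,
    task: str,
    barcode_params: BarcodeSimParams | None = None,
    peptide_params: PeptideSimParams | None = None,
    class_defs: list[tuple[str, str, dict]] | None = None,
) -> list[str]:
    """Nearest-template classification, independent of any learned model.

    Events are matched in the time domain against noiseless class templates;
    barcode/binding templates are rebuilt at each event's observed length,
    peptide templates live on the fixed resampled grid.
    """
    preds: list[str] = []
    if task in ("barcode8", "binding2"):
        params = barcode_params or BarcodeSimParams()
        if task == "barcode8":
            from dataclasses import replace

            labels = [format(i, f"0{params.n_bits}b") for i in range(2**params.n_bits)]
            variants = [(lab, replace(params, binding_site="none"), lab) for lab in labels]
        else:
            from dataclasses import replace

            barcode = "1" * params.n_bits
            variants = [
                (lab, replace(params, binding_site=lab), barcode)
                for lab in ("unbound", "bound")
            ]
        for ev in events:
            dists = [
                np.sum((ev.trace - barcode_template(bc, p, ev.trace.size)) ** 2)
                for _, p, bc in variants
            ]
            preds.append(variants[int(np.argmin(dists))][0])
    elif task == "peptide":
        params = peptide_params or PeptideSimParams()
        defs = class_defs or default_peptide_classes(params)
        from dataclasses import replace

        templates = []
        for label, sequence, deltas in defs:
            cparams = replace(
                params, sequence=sequence, volume_deltas=dict(deltas),
                volume_table=dict(params.volume_table),
            )
            templates.append((label, peptide_template(cparams)))
        for ev in events:
            dists = [np.sum((ev.trace - t) ** 2) for _, t in templates]
            preds.append(templates[int(np.argmin(dists))][0])
    else:
        raise ValueError(f"unknown task {task!r}")
    return preds


def template_oracle_accuracy(events: EventSet, task: str, **kwargs) -> float:
    preds = template_oracle_predict(events, task, **kwargs)
    truth = events.labels()
    return float(np.mean([p == t for p, t in zip(preds, truth)]))


# -- checked-in fixture recipes ----------------------------------------------


def load_recipe(name: str) -> dict:
    """Load a named fixture recipe (checked-in YAML config)."""
    path = importlib.resources.files("nanossl").joinpath(f"recipes/{name}.yaml")
    if not path.is_file():
        raise FileNotFoundError(f"no recipe named {name!r}")
    return yaml.safe_load(path.read_text())


def dataset_from_recipe(
    name: str, seed: int | None = None, n_per_class: int | None = None, **overrides
) -> tuple[EventSet, dict]:
    """Generate the dataset a recipe describes (seed/size overridable)."""
    recipe = load_recipe(name)
    task = recipe.pop("task")
    recipe.update(overrides)
    if seed is not None:
        recipe["seed"] = seed
    if n_per_class is not None:
        recipe["n_per_class"] = n_per_class
    if "peptide_params" in recipe:
        recipe["peptide_params"] = PeptideSimParams(**recipe["peptide_params"])
    if "barcode_params" in recipe:
        bp = recipe["barcode_params"]
        if "event_len_range" in bp:
            bp["event_len_range"] = tuple(bp["event_len_range"])
        recipe["barcode_params"] = BarcodeSimParams(**bp)
    return generate_dataset(task, **recipe)
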