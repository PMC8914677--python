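"""Seeded synthetic inertial datasets shaped like smartphone HAR data.

Two kinds of activity are emulated: *static* classes (near-constant signal
around a per-channel baseline, e.g. standing still with gravity on one
accelerometer axis) and *dynamic* classes (a per-channel sinusoid at a
class-specific stride frequency with a random per-window phase, e.g.
walking or jumping). Gaussian i.i.d. noise is added per sample. This is the
minimal structure the classifier must exploit — per-class baselines and
frequencies — not a biomechanical IMU simulation.

The ``desk`` preset (4 classes, 50-step windows, 200 windows per class) is
sized for minutes-scale CPU training; ``ku_har_synthetic_spec`` mirrors the
18-class manifest and per-class counts of the reference smartphone dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import (
    ActivityClassManifest,
    SignalWindow,
    WindowDataset,
    ku_har_manifest,
)

__all__ = [
    "SyntheticClassSpec",
    "SyntheticDatasetSpec",
    "generate_window",
    "generate_dataset",
    "desk_preset",
    "ku_har_synthetic_spec",
    "load_spec_yaml",
]


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Signal recipe for one activity class."""

    class_id: int
    name: str
    kind: str  # "static" | "dynamic"
    offsets: tuple[float, ...]  # per-channel baseline, m/s^2 or rad/s
    noise_sd: float = 0.5
    frequency: float | None = None  # Hz, dynamic only
    amplitudes: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("static", "dynamic"):
            raise ValueError(f"kind must be static or dynamic, got {self.kind!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.kind == "dynamic":
            if self.frequency is None or self.amplitudes is None:
                raise ValueError("dynamic classes need frequency and amplitudes")
        object.__setattr__(self, "offsets", tuple(self.offsets))
        if self.amplitudes is not None:
            object.__setattr__(self, "amplitudes", tuple(self.amplitudes))


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    classes: tuple[SyntheticClassSpec, ...]
    counts: tuple[int, ...]
    n_steps: int = 50
    n_channels: int = 6
    sampling_rate: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if len(self.classes) != len(self.counts):
            raise ValueError("one count per class required")
        if any(c <= 0 for c in self.counts):
            raise ValueError("counts must be positive")
        for spec in self.classes:
            if len(spec.offsets) != self.n_channels:
                raise ValueError(
                    f"class {spec.name!r} has {len(spec.offsets)} offsets for "
                    f"{self.n_channels} channels"
                )
            if spec.kind == "dynamic":
                if not 0 < spec.frequency < self.sampling_rate / 2:
                    raise ValueError(
                        f"class {spec.name!r} frequency {spec.frequency} outside "
                        f"(0, {self.sampling_rate / 2})"
                    )

    def manifest(self) -> ActivityClassManifest:
        return ActivityClassManifest.from_counts(
            [c.name for c in self.classes], self.counts
        )


def generate_window(
    spec: SyntheticClassSpec,
    n_steps: int,
    n_channels: int,
    sampling_rate: float,
    seed: int | np.random.Generator,
) -> SignalWindow:
    """One seeded window of the class.

    Static: ``offset_c + noise``. Dynamic:
    ``offset_c + amplitude_c * sin(2 pi f t / rate + phase) + noise`` with a
    per-window random phase. Labels are all ``spec.class_id``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_steps)[:, None]
    base = np.broadcast_to(np.asarray(spec.offsets, float), (n_steps, n_channels))
    if spec.kind == "dynamic":
        if not 0 < spec.frequency < sampling_rate / 2:
            raise ValueError(
                f"frequency {spec.frequency} outside (0, {sampling_rate / 2})"
            )
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave = np.asarray(spec.amplitudes, float) * np.sin(
            2.0 * np.pi * spec.frequency * t / sampling_rate + phase
        )
        base = base + wave
    noise = rng.normal(0.0, spec.noise_sd, size=(n_steps, n_channels))
    values = base + noise
    labels = np.full(n_steps, spec.class_id, dtype=int)
    return SignalWindow(values, labels, window_id=spec.name)


def generate_dataset(spec: SyntheticDatasetSpec) -> WindowDataset:
    """Per-class counts exactly as specified; deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    windows: list[SignalWindow] = []
    for cls, count in zip(spec.classes, spec.counts):
        for j in range(count):
            w = generate_window(
                cls, spec.n_steps, spec.n_channels, spec.sampling_rate, rng
            )
            windows.append(
                SignalWindow(w.values, w.labels, window_id=f"{cls.name}-{j:05d}")
            )
    return WindowDataset(tuple(windows), spec.manifest(), spec.sampling_rate)


def desk_preset(seed: int = 0, windows_per_class: int = 200) -> SyntheticDatasetSpec:
    """Small 4-class preset: two static and two dynamic activities,
    50-step windows, 6 channels at 100 Hz.

    Noise sd is comparable to the baseline separation so a single sample is
    an unreliable classifier and temporal pooling pays off.
    """
    g = 9.81
    classes = (
        SyntheticClassSpec(
            0, "still", "static",
            offsets=(0.0, 0.0, g, 0.0, 0.0, 0.0), noise_sd=0.8,
        ),
        SyntheticClassSpec(
            1, "lean", "static",
            offsets=(1.8, -1.2, g - 1.5, 0.4, -0.3, 0.2), noise_sd=0.8,
        ),
        SyntheticClassSpec(
            2, "walk", "dynamic",
            offsets=(0.0, 0.3, g, 0.1, 0.0, 0.0), noise_sd=0.8,
            frequency=4.0, amplitudes=(1.6, 1.0, 2.2, 0.8, 0.5, 0.4),
        ),
        SyntheticClassSpec(
            3, "run", "dynamic",
            offsets=(0.4, -0.2, g + 0.8, -0.2, 0.3, 0.1), noise_sd=0.8,
            frequency=10.0, amplitudes=(3.0, 2.0, 4.0, 1.5, 1.2, 0.9),
        ),
    )
    return SyntheticDatasetSpec(
        classes=classes,
        counts=(windows_per_class,) * 4,
        n_steps=50,
        n_channels=6,
        sampling_rate=100.0,
        seed=seed,
    )


def ku_har_synthetic_spec(seed: int = 0) -> SyntheticDatasetSpec:
    """18 synthetic classes mirroring the reference manifest's names and
    per-class counts (total 20,750); static/dynamic assigned by activity."""
    manifest = ku_har_manifest()
    dynamic = {
        "Stand-sit", "Lay-stand", "Pick", "Jump", "Push-up", "Sit-up",
        "Walk", "Walk-backward", "Walk-circle", "Run", "Stair-up",
        "Stair-down", "Table-tennis",
    }
    freqs = {name: 1.0 + 0.5 * i for i, name in enumerate(sorted(dynamic))}
    rng = np.random.default_rng(20750)
    classes = []
    for cid, name, _count in manifest.classes:
        offsets = tuple(np.round(rng.normal(0.0, 2.0, size=6), 3))
        if name in dynamic:
            classes.append(
                SyntheticClassSpec(
                    cid, name, "dynamic", offsets=offsets, noise_sd=0.8,
                    frequency=freqs[name],
                    amplitudes=tuple(np.round(rng.uniform(0.5, 3.0, size=6), 3)),
                )
            )
        else:
            classes.append(
                SyntheticClassSpec(cid, name, "static", offsets=offsets, noise_sd=0.8)
            )
    return SyntheticDatasetSpec(
        classes=tuple(classes),
        counts=manifest.counts,
        n_steps=300,
        n_channels=6,
        sampling_rate=100.0,
        seed=seed,
    )


def load_spec_yaml(text: str) -> SyntheticDatasetSpec:
    """Dataset spec from YAML (``preset: desk`` or an explicit class list)."""
    import yaml

    payload = yaml.safe_load(text) or {}
    preset = payload.pop("preset", None)
    if preset is not None:
        seed = payload.pop("seed", 0)
        if preset == "desk":
            return desk_preset(seed=seed, **payload)
        if preset in ("ku-har", "ku-har-manifest"):
            return ku_har_synthetic_spec(seed=seed)
        raise ValueError(f"unknown preset {preset!r}")
    classes = tuple(
        SyntheticClassSpec(
            class_id=c["class_id"], name=c["name"], kind=c["kind"],
            offsets=tuple(c["offsets"]), noise_sd=c.get("noise_sd", 0.5),
            frequency=c.get("frequency"),
            amplitudes=tuple(c["amplitudes"]) if "amplitudes" in c else None,
        )
        for c in payload["classes"]
    )
    return SyntheticDatasetSpec(
        classes=classes,
        counts=tuple(payload["counts"]),
        n_steps=payload.get("n_steps", 50),
        n_channels=payload.get("n_channels", 6),
        sampling_rate=payload.get("sampling_rate", 100.0),
        seed=payload.get("seed", 0),
    )
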