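"""Windowed multichannel inertial signals: containers, CSV I/O, splitting.

A *window* is a fixed-length segment of a 6-channel inertial recording
(accelerometer x/y/z in m/s^2, gyroscope x/y/z in rad/s), 300 steps at
100 Hz by default, carrying one activity label per timestep so that
two-activity windows produced by augmentation can be represented.

The on-disk format is CSV, one row per window: ``T*C`` signal values in
timestep-major, channel-minor order (flat index ``t*C + c``) followed by
either a single class column (single-activity window) or ``T`` label
columns (per-timestep labels).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "ActivityClassManifest",
    "SignalWindow",
    "WindowDataset",
    "CsvLayout",
    "read_dataset_csv",
    "write_dataset_csv",
    "stratified_split",
    "manifest_total",
    "ku_har_manifest",
]

DEFAULT_WINDOW_LENGTH = 300
DEFAULT_CHANNELS = 6
DEFAULT_SAMPLING_RATE = 100.0

# float formatting that survives a write/read round trip bit-for-bit
_FLOAT_FMT = "%.17g"


class DatasetFormatError(ValueError):
    """Raised for malformed dataset files or inconsistent containers."""


@dataclass(frozen=True)
class ActivityClassManifest:
    """Ordered activity classes with per-class example counts.

    Class ids must be the consecutive integers ``0..K-1`` and names unique;
    ``total()`` is the number of examples the manifest accounts for.
    """

    classes: tuple[tuple[int, str, int], ...]

    def __post_init__(self) -> None:
        ids = [c[0] for c in self.classes]
        if ids != list(range(len(ids))):
            raise DatasetFormatError(
                f"class ids must be consecutive from 0, got {ids}"
            )
        names = [c[1] for c in self.classes]
        if len(set(names)) != len(names):
            raise DatasetFormatError("class names must be unique")
        for _, name, count in self.classes:
            if count < 0:
                raise DatasetFormatError(f"negative count for class {name!r}")

    @classmethod
    def from_counts(
        cls, names: Sequence[str], counts: Sequence[int]
    ) -> "ActivityClassManifest":
        if len(names) != len(counts):
            raise DatasetFormatError("names and counts must align")
        return cls(tuple((i, n, int(c)) for i, (n, c) in enumerate(zip(names, counts))))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c[1] for c in self.classes)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(c[2] for c in self.classes)

    def total(self) -> int:
        return sum(self.counts)

    def class_id(self, name: str) -> int:
        for cid, cname, _ in self.classes:
            if cname == name:
                return cid
        raise KeyError(f"unknown class name {name!r}")

    def count_of(self, name_or_id: str | int) -> int:
        cid = name_or_id if isinstance(name_or_id, int) else self.class_id(name_or_id)
        return self.classes[cid][2]

    def with_counts(self, counts: Sequence[int]) -> "ActivityClassManifest":
        return ActivityClassManifest.from_counts(self.names, counts)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_classes": self.n_classes,
                "total": self.total(),
                "classes": [
                    {"class_id": i, "name": n, "count": c}
                    for i, n, c in self.classes
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ActivityClassManifest":
        payload = json.loads(text)
        return cls(
            tuple(
                (entry["class_id"], entry["name"], entry["count"])
                for entry in payload["classes"]
            )
        )


def manifest_total(manifest: ActivityClassManifest) -> int:
    """Sum of per-class example counts."""
    return manifest.total()


def ku_har_manifest() -> ActivityClassManifest:
    """The 18-class KU-HAR manifest (class names, ids and example counts)."""
    text = resources.files("harformer.data").joinpath("ku_har_manifest.csv").read_text()
    rows = list(csv.DictReader(text.splitlines()))
    return ActivityClassManifest(
        tuple((int(r["class_id"]), r["name"], int(r["count"])) for r in rows)
    )


@dataclass(frozen=True)
class SignalWindow:
    """A ``T x C`` block of sensor values with a per-timestep label track."""

    values: np.ndarray
    labels: np.ndarray
    window_id: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if values.ndim != 2:
            raise DatasetFormatError("values must be a T x C matrix")
        if labels.shape != (values.shape[0],):
            raise DatasetFormatError(
                f"labels length {labels.shape} does not match T={values.shape[0]}"
            )
        if not np.all(np.isfinite(values)):
            raise DatasetFormatError(f"non-finite values in window {self.window_id!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def is_single_activity(self) -> bool:
        return bool(np.all(self.labels == self.labels[0]))

    def stratum(self) -> tuple[int, int]:
        """Key used for stratified splitting: (first label, last label).

        Reduces to the class itself for single-activity windows and keeps
        two-activity pair windows grouped by their ordered pair.
        """
        return int(self.labels[0]), int(self.labels[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalWindow):
            return NotImplemented
        return (
            self.window_id == other.window_id
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.labels, other.labels)
        )


@dataclass(frozen=True)
class WindowDataset:
    """A sequence of :class:`SignalWindow` plus the class manifest."""

    windows: tuple[SignalWindow, ...]
    manifest: ActivityClassManifest
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(self.windows))
        k = self.manifest.n_classes
        for w in self.windows:
            if w.labels.min(initial=0) < 0 or w.labels.max(initial=0) >= k:
                raise DatasetFormatError(
                    f"window {w.window_id!r} has labels outside 0..{k - 1}"
                )

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[SignalWindow]:
        return iter(self.windows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WindowDataset):
            return NotImplemented
        return (
            self.sampling_rate == other.sampling_rate
            and self.manifest == other.manifest
            and self.windows == other.windows
        )

    @property
    def n_steps(self) -> int:
        if not self.windows:
            raise DatasetFormatError("empty dataset has no window length")
        return self.windows[0].n_steps

    @property
    def n_channels(self) -> int:
        if not self.windows:
            raise DatasetFormatError("empty dataset has no channel count")
        return self.windows[0].n_channels

    def observed_counts(self) -> tuple[int, ...]:
        """Windows per class, a single-activity window counted under its
        class and a mixed window under its first-timestep class."""
        counts = [0] * self.manifest.n_classes
        for w in self.windows:
            counts[int(w.labels[0])] += 1
        return tuple(counts)

    def with_windows(self, windows: Iterable[SignalWindow]) -> "WindowDataset":
        windows = tuple(windows)
        counts = [0] * self.manifest.n_classes
        for w in windows:
            counts[int(w.labels[0])] += 1
        return WindowDataset(
            windows, self.manifest.with_counts(counts), self.sampling_rate
        )

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into ``X`` of shape (n, T, C) and ``Y`` of shape (n, T)."""
        if not self.windows:
            t = DEFAULT_WINDOW_LENGTH
            return np.zeros((0, t, DEFAULT_CHANNELS)), np.zeros((0, t), dtype=int)
        x = np.stack([w.values for w in self.windows])
        y = np.stack([w.labels for w in self.windows])
        return x, y


@dataclass(frozen=True)
class CsvLayout:
    """Dialect of the one-row-per-window CSV format.

    ``label_mode`` is ``"window"`` (one trailing class column, broadcast to
    every timestep on read) or ``"timestep"`` (``T`` trailing label columns).
    """

    n_steps: int = DEFAULT_WINDOW_LENGTH
    n_channels: int = DEFAULT_CHANNELS
    label_mode: str = "window"
    header: bool = True
    class_names: tuple[str, ...] | None = None
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        if self.label_mode not in ("window", "timestep"):
            raise DatasetFormatError(f"unknown label_mode {self.label_mode!r}")
        if self.n_steps <= 0 or self.n_channels <= 0:
            raise DatasetFormatError("n_steps and n_channels must be positive")
        if self.class_names is not None:
            object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def n_value_fields(self) -> int:
        return self.n_steps * self.n_channels

    @property
    def n_label_fields(self) -> int:
        return 1 if self.label_mode == "window" else self.n_steps

    def column_names(self) -> list[str]:
        cols = [
            f"v{t}_{c}" for t in range(self.n_steps) for c in range(self.n_channels)
        ]
        if self.label_mode == "window":
            cols.append("label")
        else:
            cols.extend(f"label{t}" for t in range(self.n_steps))
        return cols

    @classmethod
    def from_yaml(cls, text: str) -> "CsvLayout":
        import yaml

        payload = yaml.safe_load(text) or {}
        return cls(**payload)


def write_dataset_csv(dataset: WindowDataset, path, layout: CsvLayout) -> None:
    """Write a dataset in the flat CSV dialect described by ``layout``."""
    t, c = layout.n_steps, layout.n_channels
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if layout.header:
            writer.writerow(layout.column_names())
        for w in dataset.windows:
            if w.values.shape != (t, c):
                raise DatasetFormatError(
                    f"window {w.window_id!r} shape {w.values.shape} does not "
                    f"match layout ({t}, {c})"
                )
            row = [_FLOAT_FMT % v for v in w.values.reshape(-1)]
            if layout.label_mode == "window":
                if not w.is_single_activity:
                    raise DatasetFormatError(
                        f"window {w.window_id!r} is multi-activity; use "
                        "label_mode='timestep'"
                    )
                row.append(str(int(w.labels[0])))
            else:
                row.extend(str(int(v)) for v in w.labels)
            writer.writerow(row)


def read_dataset_csv(path, layout: CsvLayout) -> WindowDataset:
    """Read a dataset written in the flat CSV dialect.

    Rows with the wrong field count, non-numeric values or out-of-range
    labels raise :class:`DatasetFormatError` naming the offending row
    (1-based, counted after any header).
    """
    t, c = layout.n_steps, layout.n_channels
    expected = layout.n_value_fields + layout.n_label_fields
    windows: list[SignalWindow] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = iter(reader)
        if layout.header:
            next(rows, None)
        for i, row in enumerate(rows, start=1):
            if not row:
                continue
            if len(row) != expected:
                raise DatasetFormatError(
                    f"row {i}: expected {expected} fields "
                    f"({layout.n_value_fields} values + "
                    f"{layout.n_label_fields} labels), got {len(row)}"
                )
            try:
                values = np.array(row[: t * c], dtype=float).reshape(t, c)
            except ValueError as exc:
                raise DatasetFormatError(f"row {i}: non-numeric value ({exc})") from exc
            try:
                raw_labels = np.array(row[t * c :], dtype=int)
            except ValueError as exc:
                raise DatasetFormatError(f"row {i}: non-integer label ({exc})") from exc
            labels = (
                np.full(t, raw_labels[0], dtype=int)
                if layout.label_mode == "window"
                else raw_labels
            )
            windows.append(SignalWindow(values, labels, window_id=f"w{i - 1:06d}"))

    if layout.class_names is not None:
        names = layout.class_names
    else:
        k = int(max((int(w.labels.max()) for w in windows), default=-1)) + 1
        names = tuple(f"class_{j}" for j in range(k))
    counts = [0] * len(names)
    for i, w in enumerate(windows, start=1):
        if w.labels.max(initial=0) >= len(names) or w.labels.min(initial=0) < 0:
            raise DatasetFormatError(
                f"row {i}: label outside 0..{len(names) - 1}"
            )
        counts[int(w.labels[0])] += 1
    manifest = ActivityClassManifest.from_counts(names, counts)
    return WindowDataset(tuple(windows), manifest, layout.sampling_rate)


def stratified_split(
    dataset: WindowDataset,
    ratios: tuple[float, float, float],
    seed: int,
) -> tuple[WindowDataset, WindowDataset, WindowDataset]:
    """Split into (train, validation, test) preserving class proportions.

    Windows are grouped by stratum (class for single-activity windows,
    ordered label pair for augmented ones), shuffled with a generator seeded
    by ``seed``, and sliced contiguously; per-stratum remainders after the
    floor allocation are assigned train-first. Per stratum the partition
    sizes differ from ``count * ratio`` by at most 1, partitions are
    disjoint, and their union is the dataset.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be three non-negative proportions")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")

    strata: dict[tuple[int, int], list[int]] = {}
    for idx, w in enumerate(dataset.windows):
        strata.setdefault(w.stratum(), []).append(idx)

    n_nonzero = sum(1 for r in ratios if r > 0)
    rng = np.random.default_rng(seed)
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for key in sorted(strata):
        members = np.array(strata[key])
        if len(members) < n_nonzero:
            raise ValueError(
                f"stratum {key} has {len(members)} windows, fewer than the "
                f"{n_nonzero} non-empty partitions requested"
            )
        rng.shuffle(members)
        n = len(members)
        sizes = [int(np.floor(n * r)) for r in ratios]
        remainder = n - sum(sizes)
        for j in range(3):
            if remainder == 0:
                break
            if ratios[j] > 0:
                sizes[j] += 1
                remainder -= 1
        start = 0
        for j, size in enumerate(sizes):
            parts[j].extend(members[start : start + size].tolist())
            start += size

    out = []
    for indices in parts:
        indices.sort()
        out.append(dataset.with_windows(dataset.windows[i] for i in indices))
    return out[0], out[1], out[2]
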