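"""Reading and writing single-channel EEG segments and dataset manifests.

Segments follow the plain-text dialect of the public Bonn epilepsy
collection: one amplitude sample per line, ASCII decimal, no header, no
embedded sampling rate.  The sampling rate is metadata supplied out of
band (manifest or call site) and defaults to 173.61 Hz, the rate of that
collection.  Amplitudes are treated as microvolts but never rescaled on
read; units are metadata only.

A dataset manifest is a small YAML or JSON document listing, per
segment, its file path, class label and sampling rate.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .exceptions import ConfigError, EmptyInputError, ParseError

#: Sampling rate (Hz) of the Bonn-dialect recordings; used when none is given.
DEFAULT_FS = 173.61

#: Canonical class tags: A/B normal (eyes open/closed), C/D interictal, E ictal.
BONN_LABELS = ("A", "B", "C", "D", "E")
STATE_LABELS = ("normal", "interictal", "ictal")


@dataclass
class EegSegment:
    """One labeled single-channel EEG recording.

    Parameters
    ----------
    samples:
        Amplitude series in microvolts; finite floats, length >= 2.
    fs:
        Sampling rate in Hz, > 0.
    label:
        Optional class tag (``A``–``E`` or ``normal``/``interictal``/``ictal``).
    segment_id:
        Opaque identifier, unique within a dataset.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    label: str | None = None
    segment_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise EmptyInputError(
                f"segment needs at least 2 samples, got {self.samples.size}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Segment duration in seconds, ``n_samples / fs``."""
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "EegSegment":
        """Copy of this segment with new samples, metadata preserved."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class ManifestEntry:
    path: str
    label: str | None = None
    fs: float = DEFAULT_FS
    segment_id: str | None = None


@dataclass
class DatasetManifest:
    """Mapping of segment files to labels and sampling rates."""

    entries: list[ManifestEntry] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        ids = [e.segment_id for e in self.entries if e.segment_id is not None]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate segment_ids in manifest")

    @property
    def labels(self) -> list[str | None]:
        return [e.label for e in self.entries]


def read_segment(
    path: str | Path,
    fs: float = DEFAULT_FS,
    label: str | None = None,
    segment_id: str | None = None,
) -> EegSegment:
    """Read a one-sample-per-line text file (Bonn dialect) or single-column CSV.

    Blank lines are ignored.  A single non-numeric first line is treated
    as a CSV header; any other non-numeric line raises :class:`ParseError`
    naming the offending line.  Decimal separator is always ``.``
    regardless of locale.
    """
    path = Path(path)
    values: list[float] = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            token = line.split(",")[0].strip() if "," in line else line
            try:
                values.append(float(token))
            except ValueError:
                if lineno == 1 and not values:
                    continue  # tolerate a single CSV header line
                raise ParseError(
                    f"{path}: line {lineno} is not numeric: {line!r}"
                ) from None
    if not values:
        raise EmptyInputError(f"{path}: no samples found")
    if segment_id is None:
        segment_id = path.stem
    return EegSegment(np.asarray(values), fs=fs, label=label, segment_id=segment_id)


def write_segment(segment: EegSegment, path: str | Path) -> Path:
    """Write one sample per line as decimal text; round-trips bit-exactly."""
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        for v in segment.samples:
            fh.write(f"{_fmt(v)}\n")
    return path


def _fmt(v: float) -> str:
    # repr of a Python float round-trips exactly and prints "1.5", "-2.0".
    return repr(float(v))


def read_csv_multichannel(path: str | Path, fs: float = DEFAULT_FS) -> list[EegSegment]:
    """Read a multi-channel CSV (one column per channel, header optional).

    Each column becomes its own :class:`EegSegment`; channel names come
    from the header when present, else ``ch0``, ``ch1``, ...
    """
    path = Path(path)
    with open(path, "r", encoding="ascii") as fh:
        rows = [r for r in csv.reader(fh) if any(c.strip() for c in r)]
    if not rows:
        raise EmptyInputError(f"{path}: empty file")
    try:
        [float(c) for c in rows[0]]
        names = [f"ch{i}" for i in range(len(rows[0]))]
        data_rows = rows
    except ValueError:
        names = [c.strip() for c in rows[0]]
        data_rows = rows[1:]
    if not data_rows:
        raise EmptyInputError(f"{path}: header but no samples")
    data = np.array([[float(c) for c in r] for r in data_rows], dtype=float)
    return [
        EegSegment(data[:, j], fs=fs, segment_id=f"{path.stem}:{names[j]}")
        for j in range(data.shape[1])
    ]


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    """Serialize a manifest to YAML or JSON depending on the extension."""
    path = Path(path)
    doc = {
        "note": manifest.note,
        "entries": [
            {"path": e.path, "label": e.label, "fs": e.fs, "segment_id": e.segment_id}
            for e in manifest.entries
        ],
    }
    with open(path, "w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    entries = [
        ManifestEntry(
            path=e["path"],
            label=e.get("label"),
            fs=float(e.get("fs", DEFAULT_FS)),
            segment_id=e.get("segment_id"),
        )
        for e in doc.get("entries", [])
    ]
    return DatasetManifest(entries=entries, note=doc.get("note", ""))


def load_dataset(
    manifest: DatasetManifest, root: str | Path | None = None
) -> list[EegSegment]:
    """Read every segment listed in a manifest.

    Relative entry paths are resolved against ``root`` when given.
    """
    segments = []
    for e in manifest.entries:
        p = Path(e.path)
        if root is not None and not p.is_absolute():
            p = Path(root) / p
        segments.append(
            read_segment(p, fs=e.fs, label=e.label, segment_id=e.segment_id)
        )
    return segments


def normalize_label(label: str) -> str:
    """Map a Bonn subset tag to its clinical state name.

    A/B -> normal, C/D -> interictal, E -> ictal; state names pass through.
    """
    table = {"A": "normal", "B": "normal", "C": "interictal", "D": "interictal",
             "E": "ictal"}
    if label in table:
        return table[label]
    if label in STATE_LABELS:
        return label
    raise ConfigError(f"unknown class label {label!r}")


def segments_to_arrays(segments: Sequence[EegSegment]) -> tuple[np.ndarray, list[str]]:
    """Stack equally long segments into an (n_segments, n_samples) array."""
    lengths = {s.n_samples for s in segments}
    if len(lengths) != 1:
        raise ConfigError(f"segments have differing lengths: {sorted(lengths)}")
    data = np.stack([s.samples for s in segments])
    labels = [s.label if s.label is not None else "" for s in segments]
    return data, labels
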