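"""Core containers: sleep-stage labels, 30 s epochs, per-subject
recordings, and the prepared-dataset archive format."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

SFREQ = 100.0           # Hz, the expected polysomnography sampling rate
EPOCH_SECONDS = 30.0
EPOCH_SAMPLES = int(SFREQ * EPOCH_SECONDS)  # 3000


class StageLabel(IntEnum):
    """The five AASM sleep stages with fixed integer codes."""

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4


STAGE_NAMES = tuple(s.name for s in StageLabel)


@dataclass
class Epoch:
    """One 30 s two-modality sample: EEG and EOG vectors plus its stage."""

    eeg: np.ndarray
    eog: np.ndarray
    label: StageLabel
    subject_id: str
    index_in_night: int

    def __post_init__(self):
        self.eeg = np.asarray(self.eeg, dtype=np.float32)
        self.eog = np.asarray(self.eog, dtype=np.float32)
        if self.eeg.shape != self.eog.shape or self.eeg.ndim != 1:
            raise ValueError(
                f"EEG/EOG must be equal-length vectors, got "
                f"{self.eeg.shape} and {self.eog.shape}")
        self.label = StageLabel(self.label)

    @property
    def signal(self) -> np.ndarray:
        """(2, n_samples) array, EEG first."""
        return np.stack([self.eeg, self.eog])


@dataclass
class Recording:
    """An ordered sequence of labelled epochs for one subject-night."""

    subject_id: str
    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self):
        idx = [e.index_in_night for e in self.epochs]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("epoch indices must be strictly increasing")
        if any(e.subject_id != self.subject_id for e in self.epochs):
            raise ValueError("all epochs must share the recording's subject_id")

    def __len__(self) -> int:
        return len(self.epochs)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(n, 2, n_samples) signals and (n,) integer labels."""
        if not self.epochs:
            n = EPOCH_SAMPLES
            return (np.empty((0, 2, n), dtype=np.float32),
                    np.empty(0, dtype=np.int64))
        x = np.stack([e.signal for e in self.epochs])
        y = np.array([int(e.label) for e in self.epochs], dtype=np.int64)
        return x, y

    @classmethod
    def from_arrays(cls, subject_id: str, x: np.ndarray,
                    y: np.ndarray) -> "Recording":
        epochs = [
            Epoch(eeg=x[i, 0], eog=x[i, 1], label=StageLabel(int(y[i])),
                  subject_id=subject_id, index_in_night=i)
            for i in range(len(y))
        ]
        return cls(subject_id=subject_id, epochs=epochs)

    def label_histogram(self) -> np.ndarray:
        hist = np.zeros(len(StageLabel), dtype=np.int64)
        for e in self.epochs:
            hist[int(e.label)] += 1
        return hist


def zscore_epochs(x: np.ndarray) -> np.ndarray:
    """Standardise each epoch per channel (zero mean, unit variance), so
    spectral shape rather than absolute µV scale carries information."""
    return ((x - x.mean(axis=-1, keepdims=True))
            / (x.std(axis=-1, keepdims=True) + 1e-8))


def zscore_recordings(recordings: list[Recording]) -> list[Recording]:
    out = []
    for rec in recordings:
        x, y = rec.to_arrays()
        out.append(Recording.from_arrays(rec.subject_id, zscore_epochs(x), y))
    return out


def class_histogram(recordings: list[Recording]) -> np.ndarray:
    hist = np.zeros(len(StageLabel), dtype=np.int64)
    for rec in recordings:
        hist += rec.label_histogram()
    return hist


# ---------------------------------------------------------------------------
# prepared-dataset archive: one signals + one labels array per subject,
# plus a JSON manifest with subject ids, class histogram and flags.


def save_dataset(recordings: list[Recording], outdir: str | Path,
                 preprocessing: dict | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects = []
    for rec in recordings:
        x, y = rec.to_arrays()
        np.save(outdir / f"{rec.subject_id}_signals.npy", x.astype(np.float32))
        np.save(outdir / f"{rec.subject_id}_labels.npy", y)
        subjects.append(rec.subject_id)
    manifest = {
        "subjects": subjects,
        "stage_names": list(STAGE_NAMES),
        "class_histogram": class_histogram(recordings).tolist(),
        "preprocessing": preprocessing or {},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def load_dataset(datadir: str | Path) -> list[Recording]:
    datadir = Path(datadir)
    manifest = json.loads((datadir / "manifest.json").read_text())
    recordings = []
    for sid in manifest["subjects"]:
        x = np.load(datadir / f"{sid}_signals.npy")
        y = np.load(datadir / f"{sid}_labels.npy")
        recordings.append(Recording.from_arrays(sid, x, y))
    return recordings
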