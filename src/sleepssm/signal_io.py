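"""Reading polysomnography, stage-label mapping, wake trimming, and
segmentation into labelled 30 s epochs.

The preprocessing follows the conventions used with the Sleep-EDF
cassette recordings: signals are EEG Fpz-Cz and EOG horizontal at
100 Hz; hypnograms are R&K-scored, with N4 merged into N3 under the
AASM five-stage scheme; MOVEMENT and UNKNOWN epochs are excluded; and
only the wakefulness within half an hour before sleep onset and after
the final sleep epoch is kept, so the night is not dominated by
pre/post-bed wake.

EDF signal files are read through MNE; headers are parsed directly
beforehand so that a missing channel or an off-spec sampling rate is a
hard, named error rather than a silent resample.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import (EPOCH_SAMPLES, EPOCH_SECONDS, SFREQ, Epoch, Recording,
                   StageLabel)
from .edfwrite import read_edf_header

DEFAULT_CHANNELS = ("EEG Fpz-Cz", "EOG horizontal")

#: R&K hypnogram vocabulary -> AASM stage (None = excluded from analysis)
_RAW_LABEL_MAP: dict[str, StageLabel | None] = {
    "W": StageLabel.W,
    "1": StageLabel.N1,
    "2": StageLabel.N2,
    "3": StageLabel.N3,
    "4": StageLabel.N3,  # AASM merges R&K N4 into N3
    "R": StageLabel.REM,
    "N1": StageLabel.N1,
    "N2": StageLabel.N2,
    "N3": StageLabel.N3,
    "N4": StageLabel.N3,
    "REM": StageLabel.REM,
    "M": None,
    "MOVEMENT": None,
    "MOVEMENT TIME": None,
    "?": None,
    "UNKNOWN": None,
}


@dataclass
class RawRecording:
    """Signals plus the ordered stage-annotation list for one night."""

    subject_id: str
    night_id: str
    channels: dict[str, np.ndarray]  # channel name -> µV samples
    sampling_rate: float
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self):
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal channel lengths: {sorted(lengths)}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        onsets = [a[0] for a in self.annotations]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("annotations must be ordered by onset")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


def _normalise_raw_label(raw: str) -> str:
    s = raw.strip()
    s = re.sub(r"(?i)^sleep stage\s*", "", s)
    return s.upper()


def map_stage_labels(raw_labels: list[str]) -> list[StageLabel | None]:
    """Map R&K hypnogram strings to AASM stages; MOVEMENT/UNKNOWN map to
    None (excluded).  Accepts bare codes ("4", "R") and the EDF+ form
    ("Sleep stage 4")."""
    out = []
    for raw in raw_labels:
        key = _normalise_raw_label(raw)
        if key not in _RAW_LABEL_MAP:
            raise ValueError(f"unrecognised stage label: {raw!r}")
        out.append(_RAW_LABEL_MAP[key])
    return out


def trim_wake_margin(labels: list[StageLabel | None],
                     margin_epochs: int = 60) -> tuple[int, int]:
    """Index range [start, end) keeping at most ``margin_epochs`` of wake
    before the first and after the last sleep epoch (60 epochs = 30 min).

    Excluded (None) entries never count as sleep.  If the night contains
    no sleep at all, the full range is returned with a warning.
    """
    if not labels:
        raise ValueError("empty label sequence")
    if margin_epochs < 0:
        raise ValueError("margin_epochs must be >= 0")
    sleep_idx = [i for i, lab in enumerate(labels)
                 if lab is not None and lab != StageLabel.W]
    if not sleep_idx:
        warnings.warn("recording contains no sleep epochs; keeping full range")
        return 0, len(labels)
    start = max(0, sleep_idx[0] - margin_epochs)
    end = min(len(labels), sleep_idx[-1] + 1 + margin_epochs)
    return start, end


def expand_annotations(annotations: list[tuple[float, float, str]],
                       epoch_seconds: float = EPOCH_SECONDS,
                       ) -> tuple[list[float], list[str]]:
    """Unroll (onset, duration, label) annotations to one label per 30 s
    window, anchored at annotation onsets; a trailing partial window is
    dropped."""
    onsets, labels = [], []
    for onset, duration, label in annotations:
        for k in range(int(duration // epoch_seconds)):
            onsets.append(onset + k * epoch_seconds)
            labels.append(label)
    return onsets, labels


def load_recording(psg_path: str | Path, hyp_path: str | Path,
                   channel_names: list[str] = list(DEFAULT_CHANNELS),
                   ) -> RawRecording:
    """Read an EDF signal file plus its EDF+ hypnogram.

    The requested channels must exist and be sampled at 100 Hz; anything
    else raises (no silent resampling).  Channels not requested are
    dropped.  Signals are returned in µV.
    """
    import mne

    psg_path, hyp_path = Path(psg_path), Path(hyp_path)
    header = read_edf_header(psg_path)
    for name in channel_names:
        if name not in header.channel_names:
            raise ValueError(
                f"channel not found: {name!r} (file has "
                f"{header.channel_names})")
        rate = header.sampling_rate(name)
        if abs(rate - SFREQ) > 1e-9:
            raise ValueError(
                f"channel {name!r} sampled at {rate:g} Hz, expected "
                f"{SFREQ:g} Hz (no silent resampling)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(psg_path, include=list(channel_names),
                                  preload=True, verbose="error")
        data = raw.get_data(picks=list(channel_names)) * 1e6  # V -> µV
        ann = mne.read_annotations(hyp_path)
    annotations = [(float(on), float(du), str(desc))
                   for on, du, desc in zip(ann.onset, ann.duration,
                                           ann.description)]
    annotations.sort(key=lambda a: a[0])
    stem = psg_path.stem
    m = re.match(r"(SC4\d\d)(\d)", stem)
    subject_id, night_id = (m.group(1), m.group(2)) if m else (stem, "0")
    return RawRecording(
        subject_id=subject_id, night_id=night_id,
        channels={name: data[i] for i, name in enumerate(channel_names)},
        sampling_rate=SFREQ, annotations=annotations)


def segment_epochs(raw: RawRecording,
                   mapped_labels: list[StageLabel | None] | None = None,
                   margin_epochs: int = 60,
                   zscore: bool = True) -> Recording:
    """Cut the recording into labelled, non-overlapping 30 s epochs.

    Wake trimming runs on the mapped label sequence first; excluded
    (MOVEMENT/UNKNOWN) windows inside the kept range are then dropped.
    With ``zscore`` (default) each epoch is standardised per channel, so
    stage information is carried by waveform shape rather than absolute
    µV scale.
    """
    onsets, raw_labels = expand_annotations(raw.annotations)
    if mapped_labels is None:
        mapped_labels = map_stage_labels(raw_labels)
    if len(mapped_labels) != len(onsets):
        raise ValueError(
            f"label/annotation mismatch: {len(mapped_labels)} labels for "
            f"{len(onsets)} annotation windows")
    start, end = trim_wake_margin(mapped_labels, margin_epochs)
    names = list(raw.channels)
    if len(names) != 2:
        raise ValueError(f"expected 2 channels (EEG, EOG), got {names}")
    sig = np.stack([raw.channels[n] for n in names])
    epochs = []
    spe = int(round(raw.sampling_rate * EPOCH_SECONDS))
    for i in range(start, end):
        lab = mapped_labels[i]
        if lab is None:
            continue
        s0 = int(round(onsets[i] * raw.sampling_rate))
        s1 = s0 + spe
        if s1 > sig.shape[1]:
            raise ValueError(
                f"annotation window [{s0}, {s1}) exceeds signal length "
                f"{sig.shape[1]}")
        w = sig[:, s0:s1].astype(np.float32)
        if zscore:
            w = (w - w.mean(axis=1, keepdims=True)) / (
                w.std(axis=1, keepdims=True) + 1e-8)
        epochs.append(Epoch(eeg=w[0], eog=w[1], label=lab,
                            subject_id=raw.subject_id,
                            index_in_night=i))
    return Recording(subject_id=raw.subject_id, epochs=epochs)


def prepare_recording(psg_path, hyp_path,
                      channel_names: list[str] = list(DEFAULT_CHANNELS),
                      margin_epochs: int = 60,
                      zscore: bool = True) -> Recording:
    """load_recording + label mapping + trimming + segmentation."""
    raw = load_recording(psg_path, hyp_path, channel_names)
    return segment_epochs(raw, margin_epochs=margin_epochs, zscore=zscore)


def pair_sleep_edf_files(directory: str | Path) -> list[tuple[Path, Path]]:
    """Match SC4ssNE0-PSG.edf signal files with their SC4ssNE?-Hypnogram
    companions by the shared subject-night prefix."""
    def pair_key(path: Path) -> str:
        base = re.sub(r"-(PSG|Hypnogram)$", "", path.stem)
        # Sleep-EDF pairs share the subject-night prefix SC4ssN but
        # differ in the trailing scorer/version characters
        return base[:6] if re.match(r"SC4\d\d\d", base) else base

    directory = Path(directory)
    psgs = sorted(directory.glob("*-PSG.edf"))
    hyps = {pair_key(h): h for h in directory.glob("*-Hypnogram.edf")}
    pairs = []
    for psg in psgs:
        key = pair_key(psg)
        if key in hyps:
            pairs.append((psg, hyps[key]))
        else:
            warnings.warn(f"no hypnogram found for {psg.name}")
    return pairs


def export_recording_edf(rec: Recording, psg_path: str | Path,
                         hyp_path: str | Path | None = None,
                         channel_names: list[str] = list(DEFAULT_CHANNELS),
                         ) -> None:
    """Write a Recording back out as an EDF signal file (+ optional EDF+
    hypnogram), mainly for round-trip testing of the reading path."""
    from .edfwrite import write_edf, write_hypnogram_edf

    x, y = rec.to_arrays()
    flat = x.transpose(1, 0, 2).reshape(2, -1)
    write_edf(psg_path, {channel_names[0]: flat[0],
                         channel_names[1]: flat[1]}, sfreq=SFREQ)
    if hyp_path is not None:
        anns = [(i * EPOCH_SECONDS, EPOCH_SECONDS,
                 f"Sleep stage {_STAGE_TO_RAW[StageLabel(int(lab))]}")
                for i, lab in enumerate(y)]
        write_hypnogram_edf(hyp_path, anns,
                            total_seconds=len(y) * EPOCH_SECONDS)


_STAGE_TO_RAW = {
    StageLabel.W: "W",
    StageLabel.N1: "1",
    StageLabel.N2: "2",
    StageLabel.N3: "3",
    StageLabel.REM: "R",
}
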