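"""Minimal EDF / EDF+ writing and header inspection.

Covers exactly what this package needs: writing two-channel 100 Hz
signal files and EDF+ hypnogram annotation files (so synthetic
recordings can be exported and round-tripped through the same reading
path used for real polysomnography), plus a lightweight header parse
used to verify channel names and per-channel sampling rates before
loading data.  Signals are stored as 16-bit integers with per-channel
physical scaling, i.e. the standard EDF quantisation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_ANNOT_LABEL = "EDF Annotations"


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


@dataclass
class EdfChannelHeader:
    label: str
    dimension: str
    physical_min: float
    physical_max: float
    digital_min: int
    digital_max: int
    samples_per_record: int


@dataclass
class EdfHeader:
    n_records: int
    record_seconds: float
    channels: list[EdfChannelHeader]

    @property
    def channel_names(self) -> list[str]:
        return [c.label for c in self.channels]

    def sampling_rate(self, name: str) -> float:
        for c in self.channels:
            if c.label == name:
                return c.samples_per_record / self.record_seconds
        raise KeyError(name)


def read_edf_header(path: str | Path) -> EdfHeader:
    """Parse the fixed and per-channel EDF header fields."""
    with open(path, "rb") as f:
        fixed = f.read(256)
        if len(fixed) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(fixed[236:244].decode("ascii").strip())
        record_seconds = float(fixed[244:252].decode("ascii").strip())
        ns = int(fixed[252:256].decode("ascii").strip())
        per = f.read(256 * ns)

    def col(width: int, offset: int) -> list[str]:
        base = offset * ns
        return [per[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)]

    labels = col(16, 0)
    # per-channel fields are stored column-major: all labels, then all
    # transducers (80), dimensions (8), phys min/max (8+8), dig min/max
    # (8+8), prefilter (80), samples per record (8)
    offsets = {"dim": 16 + 80, "pmin": 16 + 80 + 8, "pmax": 16 + 80 + 16,
               "dmin": 16 + 80 + 24, "dmax": 16 + 80 + 32,
               "spr": 16 + 80 + 40 + 80}

    def colw(key: str, width: int) -> list[str]:
        base = offsets[key] * ns
        return [per[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)]

    dims = colw("dim", 8)
    pmins = colw("pmin", 8)
    pmaxs = colw("pmax", 8)
    dmins = colw("dmin", 8)
    dmaxs = colw("dmax", 8)
    sprs = colw("spr", 8)
    channels = [
        EdfChannelHeader(labels[i], dims[i], float(pmins[i]), float(pmaxs[i]),
                         int(dmins[i]), int(dmaxs[i]), int(sprs[i]))
        for i in range(ns)
    ]
    return EdfHeader(n_records=n_records, record_seconds=record_seconds,
                     channels=channels)


def _write_header(f, *, n_records: int, record_seconds: float,
                  channels: list[EdfChannelHeader], reserved: str = "",
                  start: _dt.datetime | None = None,
                  patient: str = "X", recording: str = "X") -> None:
    start = start or _dt.datetime(2000, 1, 1, 0, 0, 0)
    ns = len(channels)
    header_bytes = 256 * (1 + ns)
    rec_sec = (f"{record_seconds:g}")
    f.write(_field("0", 8))
    f.write(_field(patient, 80))
    f.write(_field(recording, 80))
    f.write(_field(start.strftime("%d.%m.%y"), 8))
    f.write(_field(start.strftime("%H.%M.%S"), 8))
    f.write(_field(str(header_bytes), 8))
    f.write(_field(reserved, 44))
    f.write(_field(str(n_records), 8))
    f.write(_field(rec_sec, 8))
    f.write(_field(str(ns), 4))
    for width, get in (
        (16, lambda c: c.label),
        (80, lambda c: ""),                       # transducer
        (8, lambda c: c.dimension),
        (8, lambda c: f"{c.physical_min:g}"[:8]),
        (8, lambda c: f"{c.physical_max:g}"[:8]),
        (8, lambda c: str(c.digital_min)),
        (8, lambda c: str(c.digital_max)),
        (80, lambda c: ""),                       # prefiltering
        (8, lambda c: str(c.samples_per_record)),
        (32, lambda c: ""),                       # reserved
    ):
        for c in channels:
            f.write(_field(get(c), width))


def write_edf(path: str | Path, signals: dict[str, np.ndarray],
              sfreq: float, dimension: str = "uV",
              record_seconds: float = 30.0,
              start: _dt.datetime | None = None) -> Path:
    """Write channels (µV) as a plain EDF file with 16-bit quantisation.

    All channels must share length, and the length must be a whole
    number of ``record_seconds`` records.
    """
    path = Path(path)
    names = list(signals)
    arrs = [np.asarray(signals[n], dtype=np.float64) for n in names]
    n_samp = len(arrs[0])
    if any(len(a) != n_samp for a in arrs):
        raise ValueError("all channels must have equal length")
    spr = int(round(sfreq * record_seconds))
    if n_samp % spr != 0:
        raise ValueError(
            f"signal length {n_samp} is not a whole number of "
            f"{record_seconds}s records ({spr} samples)")
    n_records = n_samp // spr
    channels = []
    scaled = []
    for name, a in zip(names, arrs):
        lim = max(1e-6, float(np.abs(a).max()))
        ch = EdfChannelHeader(label=name, dimension=dimension,
                              physical_min=-lim, physical_max=lim,
                              digital_min=-32767, digital_max=32767,
                              samples_per_record=spr)
        channels.append(ch)
        # header fields are ASCII-truncated, so recompute the gain the
        # same way a reader will see it
        pmin = float(f"{ch.physical_min:g}"[:8])
        pmax = float(f"{ch.physical_max:g}"[:8])
        gain = (pmax - pmin) / (ch.digital_max - ch.digital_min)
        dig = np.clip(np.round(a / gain), -32767, 32767).astype("<i2")
        scaled.append(dig)
    with open(path, "wb") as f:
        _write_header(f, n_records=n_records, record_seconds=record_seconds,
                      channels=channels, start=start)
        for r in range(n_records):
            for dig in scaled:
                f.write(dig[r * spr:(r + 1) * spr].tobytes())
    return path


def write_hypnogram_edf(path: str | Path,
                        annotations: list[tuple[float, float, str]],
                        total_seconds: float | None = None,
                        start: _dt.datetime | None = None) -> Path:
    """Write stage annotations as an EDF+C file with a single
    'EDF Annotations' channel (one data record holding all time-stamped
    annotation lists)."""
    path = Path(path)
    if total_seconds is None:
        total_seconds = max((on + du) for on, du, _ in annotations)
    tals = b"+0\x14\x14\x00"  # record onset timestamp
    for onset, duration, text in annotations:
        tals += (f"+{onset:g}\x15{duration:g}\x14{text}\x14\x00"
                 .encode("ascii"))
    # pad to an even number of bytes (stored as 2-byte integers)
    if len(tals) % 2:
        tals += b"\x00"
    spr = len(tals) // 2
    ch = EdfChannelHeader(label=_ANNOT_LABEL, dimension="",
                          physical_min=-1, physical_max=1,
                          digital_min=-32768, digital_max=32767,
                          samples_per_record=spr)
    with open(path, "wb") as f:
        _write_header(f, n_records=1, record_seconds=float(total_seconds),
                      channels=[ch], reserved="EDF+C", start=start)
        f.write(tals)
    return path
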