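"""Recording / hypnogram I/O and montage definitions.

Recordings are kept in microvolts throughout the pipeline.  Two on-disk
formats are supported: EDF (read through :mod:`mne`, written by a minimal
16-bit writer) and a plain "matrix + sidecar" pair — a CSV of samples
(rows = time, columns = channels) next to a JSON header carrying labels,
sampling rate and units.
"""

from __future__ import annotations

import csv
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: The eight scalp channels consumed by the pipeline, in fixed
#: anterior-to-posterior order.
FCPO_CHANNELS = ("F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2")

#: Named electrode subsets: full set, minus occipital, minus parietal,
#: frontal+central only, and frontal pair only.
MONTAGES = {
    "FCPO": FCPO_CHANNELS,
    "FCP": ("F3", "F4", "C3", "C4", "P3", "P4"),
    "FCO": ("F3", "F4", "C3", "C4", "O1", "O2"),
    "FC": ("F3", "F4", "C3", "C4"),
    "F": ("F3", "F4"),
}

STAGE_VOCAB = ("W", "N1", "N2", "N3", "REM", "artifact")


class MissingChannelError(KeyError):
    """Requested channel labels absent from a recording."""

    def __init__(self, missing, available):
        self.missing = list(missing)
        self.available = list(available)
        super().__init__(
            f"channels not present: {sorted(self.missing)}; "
            f"available: {sorted(self.available)}"
        )


class UnknownUnitsError(ValueError):
    pass


class HypnogramParseError(ValueError):
    pass


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is a (n_channels, n_samples) float array; sample ``i`` on any
    channel is at time ``start_time + i / sampling_rate`` seconds.
    """

    subject_id: str
    channels: tuple
    sampling_rate: float
    data: np.ndarray
    start_time: float = 0.0

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise MissingChannelError([label], self.channels) from None

    def get(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def pick(self, channels) -> "EEGRecording":
        """Restrict to the given channels (in the given order)."""
        channels = tuple(channels)
        missing = [c for c in channels if c not in self.channels]
        if missing:
            raise MissingChannelError(missing, self.channels)
        idx = [self.channels.index(c) for c in channels]
        return EEGRecording(
            self.subject_id, channels, self.sampling_rate,
            self.data[idx], self.start_time,
        )


@dataclass
class Hypnogram:
    """Sleep stage per fixed-length epoch (default 30 s)."""

    stages: tuple
    epoch_length: float = 30.0

    def __post_init__(self):
        self.stages = tuple(self.stages)
        bad = [s for s in self.stages if s not in STAGE_VOCAB]
        if bad:
            raise HypnogramParseError(f"unknown stage codes: {sorted(set(bad))}")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")

    @property
    def duration(self) -> float:
        return len(self.stages) * self.epoch_length

    def stage_at(self, t: float):
        """Stage containing time ``t`` (seconds), or None if unstaged.

        Samples past the last epoch are unstaged and excluded from
        detection downstream.
        """
        if t < 0:
            return None
        i = int(t // self.epoch_length)
        if i >= len(self.stages):
            return None
        return self.stages[i]

    def stage_per_sample(self, n_samples: int, rate: float) -> np.ndarray:
        """Stage label per sample ('' where unstaged)."""
        t = np.arange(n_samples) / rate
        idx = (t // self.epoch_length).astype(int)
        out = np.full(n_samples, "", dtype=object)
        valid = idx < len(self.stages)
        stages_arr = np.asarray(self.stages, dtype=object)
        out[valid] = stages_arr[idx[valid]]
        return out


@dataclass
class MontageConfig:
    name: str
    channels: tuple = field(default=None)

    def __post_init__(self):
        if self.name not in MONTAGES:
            raise ValueError(
                f"unknown montage {self.name!r}; valid names: {sorted(MONTAGES)}"
            )
        if self.channels is None:
            self.channels = MONTAGES[self.name]
        self.channels = tuple(self.channels)
        if self.channels != MONTAGES[self.name]:
            raise ValueError(
                f"montage {self.name} must use channels {MONTAGES[self.name]}"
            )

    def __len__(self):
        return len(self.channels)


def resolve_montage(name: str) -> MontageConfig:
    """Return the named electrode subset (FCPO, FCP, FCO, FC or F)."""
    return MontageConfig(name=name)


# ---------------------------------------------------------------------------
# matrix + sidecar format

def save_matrix(rec: EEGRecording, path) -> None:
    """Write a recording as ``<path>.csv`` + ``<path>.json`` sidecar."""
    path = Path(path)
    header = {
        "subject_id": rec.subject_id,
        "channels": list(rec.channels),
        "sampling_rate": rec.sampling_rate,
        "units": "uV",
        "start_time": rec.start_time,
        "n_samples": rec.n_samples,
        "layout": "rows=samples,cols=channels",
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    np.savetxt(path.with_suffix(".csv"), rec.data.T, delimiter=",", fmt="%.6f")


_UNIT_SCALE = {"uv": 1.0, "µv": 1.0, "μv": 1.0, "mv": 1000.0, "v": 1e6}


def load_matrix(path, channels=None) -> EEGRecording:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    units = str(header.get("units", "")).lower()
    if units not in _UNIT_SCALE:
        raise UnknownUnitsError(
            f"cannot resolve units {header.get('units')!r} to microvolts"
        )
    data = np.loadtxt(path.with_suffix(".csv"), delimiter=",", ndmin=2).T
    data = data * _UNIT_SCALE[units]
    rec = EEGRecording(
        subject_id=header.get("subject_id", path.stem),
        channels=header["channels"],
        sampling_rate=float(header["sampling_rate"]),
        data=data,
        start_time=float(header.get("start_time", 0.0)),
    )
    if channels is not None:
        rec = rec.pick(channels)
    return rec


# ---------------------------------------------------------------------------
# EDF

def save_edf(rec: EEGRecording, path) -> None:
    """Write a minimal EDF file (one data record, 16-bit little-endian).

    Physical range is taken from the data; digital range is the full
    16-bit span, so quantization error is (phys range)/65534 per sample.
    """
    path = Path(path)
    ns = len(rec.channels)
    n_samp = rec.n_samples
    dur = rec.duration

    def pad(s, n):
        s = str(s)[:n]
        return s + " " * (n - len(s))

    pmins, pmaxs, digitized = [], [], []
    for row in rec.data:
        pmin, pmax = float(np.min(row)), float(np.max(row))
        if pmax <= pmin:
            pmax = pmin + 1.0
        pmins.append(pmin)
        pmaxs.append(pmax)
        scale = (pmax - pmin) / 65534.0
        dig = np.round((row - pmin) / scale).astype(np.int64) - 32767
        digitized.append(np.clip(dig, -32768, 32767).astype("<i2"))

    hdr = b""
    hdr += pad("0", 8).encode()
    hdr += pad(rec.subject_id, 80).encode()
    hdr += pad("recording", 80).encode()
    hdr += pad("01.01.00", 8).encode()
    hdr += pad("00.00.00", 8).encode()
    hdr += pad(str(256 + ns * 256), 8).encode()
    hdr += pad("", 44).encode()
    hdr += pad("1", 8).encode()          # one data record
    hdr += pad(f"{dur:.6g}", 8).encode()
    hdr += pad(str(ns), 4).encode()
    for c in rec.channels:
        hdr += pad(c, 16).encode()
    hdr += pad("", 80).encode() * ns      # transducer
    for _ in rec.channels:
        hdr += pad("uV", 8).encode()
    for v in pmins:
        hdr += pad(f"{v:.6g}", 8).encode()
    for v in pmaxs:
        hdr += pad(f"{v:.6g}", 8).encode()
    hdr += pad("-32768", 8).encode() * ns
    hdr += pad("32767", 8).encode() * ns
    hdr += pad("", 80).encode() * ns      # prefiltering
    hdr += pad(str(n_samp), 8).encode() * ns
    hdr += pad("", 32).encode() * ns      # reserved

    with open(path, "wb") as f:
        f.write(hdr)
        for dig in digitized:
            f.write(dig.tobytes())


def load_edf(path, channels=None, subject_id=None) -> EEGRecording:
    """Read an EDF recording (via mne), restricted to ``channels``, in μV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = list(raw.ch_names)
    if channels is not None:
        missing = [c for c in channels if c not in available]
        if missing:
            raise MissingChannelError(missing, available)
        raw.pick(list(channels))
        order = tuple(channels)
    else:
        order = tuple(available)
    data = raw.get_data(picks=list(order)) * 1e6  # mne uses volts internally
    return EEGRecording(
        subject_id=subject_id or Path(path).stem,
        channels=order,
        sampling_rate=float(raw.info["sfreq"]),
        data=data,
    )


def load_recording(path, format="matrix", channels=None, subject_id=None) -> EEGRecording:
    """Load a recording from EDF or matrix+sidecar, in microvolts."""
    if format == "edf":
        return load_edf(path, channels=channels, subject_id=subject_id)
    if format in ("matrix", "matrix+sidecar"):
        rec = load_matrix(path, channels=channels)
        if subject_id is not None:
            rec.subject_id = subject_id
        return rec
    raise ValueError(f"unknown format {format!r}; use 'edf' or 'matrix'")


# ---------------------------------------------------------------------------
# hypnogram

def save_hypnogram(hyp: Hypnogram, path) -> None:
    path = Path(path)
    lines = [f"epoch_length_s={hyp.epoch_length:g}"]
    lines += list(hyp.stages)
    path.write_text("\n".join(lines) + "\n")


def load_hypnogram(path, epoch_length: float = 30.0) -> Hypnogram:
    """Read a single-column stage file; optional ``epoch_length_s=`` header."""
    path = Path(path)
    stages = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        tok = line.strip().strip(",")
        if not tok:
            continue
        if tok.lower().startswith("epoch_length_s"):
            epoch_length = float(tok.split("=", 1)[1])
            continue
        if tok not in STAGE_VOCAB:
            raise HypnogramParseError(f"unknown stage token {tok!r} at row {i}")
        stages.append(tok)
    return Hypnogram(stages=tuple(stages), epoch_length=epoch_length)


def save_events_csv(events, path) -> None:
    """Write detected events (with optional labels) to CSV."""
    fields = [
        "subject_id", "channel", "stage", "t_zc1", "t_trough", "t_zc2",
        "t_zc3", "trough_amp", "peak_amp",
    ]
    extra = []
    if events and getattr(events[0], "cluster_index", None) is not None:
        extra = ["cluster_index", "so_type"]
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(fields + extra)
        for ev in events:
            row = [getattr(ev, k) for k in fields]
            row += [getattr(ev, k, "") for k in extra]
            w.writerow(row)
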