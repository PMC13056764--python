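"""Slow-oscillation event detection from zero-crossing anatomy.

An SO is a negative half-wave followed by a positive half-wave on the
0.1–4 Hz trace: three consecutive zero crossings (down, up, down) where
the first two are 0.3–1.0 s apart, the full event spans at most 10 s, the
trough reaches at most −80 μV, the peak-to-trough range is at least
80 μV, and the whole event lies inside a single N2 or N3 epoch and inside
artifact-free samples.  Candidates deeper than 4 standard deviations of
the per-channel trough magnitude are pruned afterwards as artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import bandpass


@dataclass
class DetectionParams:
    filter_band: tuple = (0.1, 4.0)
    neg_halfwave_bounds: tuple = (0.3, 1.0)
    max_event_span: float = 10.0
    trough_max: float = -80.0        # μV; trough must be <= this
    min_peak_to_trough: float = 80.0  # μV
    outlier_sd: float = 4.0

    def __post_init__(self):
        lo, hi = self.neg_halfwave_bounds
        if not (0 < lo < hi):
            raise ValueError("neg_halfwave_bounds must be positive and ordered")
        if self.trough_max >= 0:
            raise ValueError("trough_max must be negative")
        if self.min_peak_to_trough <= 0 or self.max_event_span <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class SOEvent:
    """One detected trough on one channel."""

    subject_id: str
    channel: str
    t_zc1: float
    t_trough: float
    t_zc2: float
    t_zc3: float
    trough_amp: float   # μV, negative
    peak_amp: float     # μV, positive peak within [zc2, zc3]
    stage: str
    cluster_index: int = field(default=None)
    so_type: str = field(default=None)

    def __post_init__(self):
        if not (self.t_zc1 < self.t_trough < self.t_zc2 < self.t_zc3):
            raise ValueError("zero crossings must bracket the trough in order")


def _zero_crossings(x):
    """(index, sign) of sign changes between consecutive samples.

    sign = -1 for a downward (pos→neg) crossing at fractional index
    interpolated linearly between samples.  Samples exactly at zero take
    the sign of the following excursion.
    """
    s = np.sign(x)
    # propagate the previous nonzero sign through exact zeros
    nz = s != 0
    if not nz.any():
        return np.empty(0), np.empty(0)
    idx = np.where(nz, np.arange(len(s)), 0)
    np.maximum.accumulate(idx, out=idx)
    s_filled = s[idx]
    change = np.flatnonzero(s_filled[1:] * s_filled[:-1] < 0)
    frac = x[change] / (x[change] - x[change + 1])
    times = change + frac
    direction = np.sign(x[change + 1] - x[change])
    return times, direction


def detect_sos_channel(filtered, rate, hypnogram=None, mask=None,
                       params: DetectionParams = None, channel: str = "",
                       subject_id: str = "") -> list:
    """Detect SO events on one channel of the 0.1–4 Hz filtered trace.

    ``filtered`` must already be band-limited to ``params.filter_band``.
    Boundary comparisons are inclusive (a trough of exactly −80 μV and a
    range of exactly 80 μV both pass).
    """
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    params = params or DetectionParams()
    x = np.asarray(filtered, dtype=float)
    zc_idx, zc_dir = _zero_crossings(x)
    events = []
    lo, hi = params.neg_halfwave_bounds

    stages = (hypnogram.stage_per_sample(len(x), rate)
              if hypnogram is not None else None)
    usable = np.asarray(mask, dtype=bool) if mask is not None else None

    down = np.flatnonzero(zc_dir < 0)
    for k in down:
        if k + 2 >= len(zc_idx):
            break
        i1, i2, i3 = zc_idx[k], zc_idx[k + 1], zc_idx[k + 2]
        t1, t2, t3 = i1 / rate, i2 / rate, i3 / rate
        if not (lo <= t2 - t1 <= hi):
            continue
        if t3 - t1 > params.max_event_span:
            continue
        a, b = int(np.ceil(i1)), int(np.floor(i2)) + 1
        c, d = int(np.ceil(i2)), int(np.floor(i3)) + 1
        neg_seg = x[a:b]
        pos_seg = x[c:d]
        if neg_seg.size == 0 or pos_seg.size == 0:
            continue
        trough_rel = int(np.argmin(neg_seg))
        trough_amp = float(neg_seg[trough_rel])
        peak_amp = float(np.max(pos_seg))
        if trough_amp > params.trough_max:
            continue
        if peak_amp - trough_amp < params.min_peak_to_trough:
            continue
        t_trough = (a + trough_rel) / rate
        lo_samp = int(np.floor(i1))
        hi_samp = min(int(np.ceil(i3)) + 1, len(x))
        if stages is not None:
            seg = stages[lo_samp:hi_samp]
            if seg[0] not in ("N2", "N3") or not (seg == seg[0]).all():
                continue
            stage = seg[0]
        else:
            stage = "N3"
        if usable is not None and not usable[lo_samp:hi_samp].all():
            continue
        events.append(SOEvent(
            subject_id=subject_id, channel=channel,
            t_zc1=t1, t_trough=t_trough, t_zc2=t2, t_zc3=t3,
            trough_amp=trough_amp, peak_amp=peak_amp, stage=stage,
        ))
    events.sort(key=lambda e: e.t_trough)
    return events


def prune_amplitude_outliers(events, params: DetectionParams = None) -> list:
    """Drop events whose |trough| exceeds mean + k·SD of per-channel |trough|.

    Applied once (no iteration); channels with fewer than 3 candidates are
    left untouched since the SD estimate is unreliable.
    """
    params = params or DetectionParams()
    if len(events) < 3:
        return list(events)
    amps = np.array([abs(e.trough_amp) for e in events])
    sd = amps.std(ddof=0)
    if sd == 0:
        return list(events)
    cutoff = amps.mean() + params.outlier_sd * sd
    return [e for e, a in zip(events, amps) if a <= cutoff]


def detect_sos(recording, hypnogram=None, masks=None,
               params: DetectionParams = None) -> dict:
    """Detect and prune SOs on every channel of a recording.

    Returns {channel: [SOEvent, ...]}.  The recording is band-filtered to
    ``params.filter_band`` internally.
    """
    params = params or DetectionParams()
    out = {}
    for ch in recording.channels:
        filt = bandpass(recording.get(ch), recording.sampling_rate,
                        *params.filter_band)
        mask = masks.get(ch) if masks else None
        ev = detect_sos_channel(
            filt, recording.sampling_rate, hypnogram, mask, params,
            channel=ch, subject_id=recording.subject_id)
        out[ch] = prune_amplitude_outliers(ev, params)
    return out
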