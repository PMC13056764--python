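"""The 35-feature-per-channel bank around each SO trough.

Each detected SO is cut as a 2-s epoch (±1 s around the trough) on every
montage channel, downsampled to 200 Hz.  Per channel the bank holds:

* 6 base waveform coordinates — amplitude and time offset of the trough,
  the last peak before the trough and the first peak after it, read from
  the 0.1–4 Hz trace (time offsets are measured from the detection
  channel's trough, so they are generally nonzero off that channel);
* 7 mean power-spectral-density values (Welch) in delta 1–4, SWA 0.1–4,
  theta 5–8, alpha 9–12, sigma 13–15, beta 16–30 and low-gamma 31–48 Hz;
* 7 mean absolute amplitudes of the trace band-filtered to the same bands;
* 13 complexity scores (Lempel-Ziv, sign changes, the three Hjorth
  parameters, permutation / SVD / sample entropies, Petrosian / Katz /
  Higuchi fractal dimensions, the DFA exponent, lag-1 autocorrelation);
* 2 descriptive values — integer code of the detection electrode and a
  binary spindle-presence flag.

Trough amplitudes stay negative; no feature is normalized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import bandpass, resample_epoch

logger = logging.getLogger(__name__)

EPOCH_RATE = 200.0
EPOCH_HALF_S = 1.0
EPOCH_SAMPLES = 400

BANDS = {
    "delta": (1.0, 4.0),
    "swa": (0.1, 4.0),
    "theta": (5.0, 8.0),
    "alpha": (9.0, 12.0),
    "sigma": (13.0, 15.0),
    "beta": (16.0, 30.0),
    "lowgamma": (31.0, 48.0),
}

BASE_FEATURES = (
    "trough_amp", "trough_dt", "pre_peak_amp", "pre_peak_dt",
    "post_peak_amp", "post_peak_dt",
)
COMPLEXITY_FEATURES = (
    "lziv", "sign_changes", "hjorth_activity", "hjorth_mobility",
    "hjorth_complexity", "perm_entropy", "svd_entropy", "samp_entropy",
    "petrosian_fd", "katz_fd", "higuchi_fd", "dfa", "autocorr_lag1",
)
FEATURE_NAMES = (
    BASE_FEATURES
    + tuple(f"pow_{b}" for b in BANDS)
    + tuple(f"amp_{b}" for b in BANDS)
    + COMPLEXITY_FEATURES
    + ("detection_node", "spindle_present")
)
assert len(FEATURE_NAMES) == 35

META_COLUMNS = ("subject_id", "stage", "so_type", "detection_channel",
                "t_trough")


@dataclass
class SOEpoch:
    """2-s multichannel cutout at 200 Hz, t = 0 at the detected trough."""

    event: object
    channels: tuple
    traces: np.ndarray        # broadband, (n_channels, 400)
    slow_traces: np.ndarray   # 0.1–4 Hz filtered, (n_channels, 400)

    def __post_init__(self):
        self.channels = tuple(self.channels)
        for arr in (self.traces, self.slow_traces):
            if arr.shape != (len(self.channels), EPOCH_SAMPLES):
                raise ValueError("traces must be (n_channels, 400)")


class _PreparedRecording:
    """Continuous recording resampled to 200 Hz once, broadband + slow."""

    def __init__(self, recording, montage, slow_band=(0.1, 4.0)):
        self.channels = tuple(montage.channels)
        rec = recording.pick(self.channels)
        rate = rec.sampling_rate
        self.broad = resample_epoch(rec.data, rate, EPOCH_RATE)
        slow = np.vstack([bandpass(rec.data[i], rate, *slow_band)
                          for i in range(len(self.channels))])
        self.slow = resample_epoch(slow, rate, EPOCH_RATE)
        self.n = self.broad.shape[1]

    def cut(self, t_trough):
        c = int(round(t_trough * EPOCH_RATE))
        a, b = c - EPOCH_SAMPLES // 2, c + EPOCH_SAMPLES // 2
        if a < 0 or b > self.n:
            return None
        return self.broad[:, a:b], self.slow[:, a:b]


def extract_epoch(recording, event, montage, _prepared=None):
    """Cut the 2-s epoch around an event's trough; None if too close to an edge."""
    prep = _prepared or _PreparedRecording(recording, montage)
    cut = prep.cut(event.t_trough)
    if cut is None:
        logger.info("skipping event at t=%.3fs: within 1 s of a recording edge",
                    event.t_trough)
        return None
    broad, slow = cut
    return SOEpoch(event=event, channels=prep.channels,
                   traces=broad, slow_traces=slow)


# ---------------------------------------------------------------------------
# base waveform coordinates

def _local_maxima(x):
    return np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])) + 1


def base_features(trace, rate=EPOCH_RATE):
    """(trough_amp, trough_dt, pre_peak_amp, pre_peak_dt, post_peak_amp,
    post_peak_dt) of a trough-centered trace.

    The trough is the global minimum; the pre/post peaks are the local
    maxima nearest before/after t = 0, falling back to the half-window
    maximum when no interior local maximum exists.
    """
    x = np.asarray(trace, dtype=float)
    center = len(x) // 2
    t = (np.arange(len(x)) - center) / rate
    i_tr = int(np.argmin(x))
    maxima = _local_maxima(x)
    pre = maxima[maxima < center]
    post = maxima[maxima >= center]
    i_pre = int(pre[-1]) if pre.size else int(np.argmax(x[:center]))
    i_post = int(post[0]) if post.size else center + int(np.argmax(x[center:]))
    return (float(x[i_tr]), float(t[i_tr]),
            float(x[i_pre]), float(t[i_pre]),
            float(x[i_post]), float(t[i_post]))


# ---------------------------------------------------------------------------
# spectral features

def band_power_features(trace, rate=EPOCH_RATE):
    """Mean Welch PSD (1-s Hann segments, 50% overlap) per band, closed bins."""
    x = np.asarray(trace, dtype=float)
    nper = int(rate)
    freqs, psd = sps.welch(x, fs=rate, nperseg=min(nper, len(x)),
                           noverlap=min(nper, len(x)) // 2, window="hann")
    out = []
    for lo, hi in BANDS.values():
        sel = (freqs >= lo) & (freqs <= hi)
        out.append(float(psd[sel].mean()) if sel.any() else 0.0)
    return tuple(out)


@lru_cache(maxsize=64)
def _band_sos(rate, lo, hi):
    nyq = rate / 2.0
    return sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")


def band_amplitude_features(trace, rate=EPOCH_RATE):
    """Mean |band-filtered trace| per band, μV."""
    x = np.asarray(trace, dtype=float)
    out = []
    for lo, hi in BANDS.values():
        sos = _band_sos(rate, lo, hi)
        filt = sps.sosfiltfilt(sos, x)
        out.append(float(np.abs(filt).mean()))
    return tuple(out)


# ---------------------------------------------------------------------------
# complexity scores

def lziv_complexity(x):
    """LZ76 phrase count of the median-binarized trace, normalized by
    n / log2(n)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return 0.0
    s = (x > np.median(x)).astype(np.uint8).tobytes()
    c = _lz76_phrases(s)
    return float(c * np.log2(n) / n)


def _lz76_phrases(s):
    """Number of phrases in the LZ76 parsing of a symbol sequence."""
    n = len(s)
    i, c = 0, 0
    while i < n:
        length = 1
        # longest prefix of s[i:] occurring in s[:i+length-1]
        while i + length <= n and s[i:i + length] in s[:i + length - 1]:
            length += 1
        c += 1
        i += length
    return c


def sign_changes(x):
    """Zero crossings of the mean-centered trace."""
    y = np.asarray(x, dtype=float)
    y = y - y.mean()
    s = np.sign(y)
    s[s == 0] = 1
    return int(np.sum(s[1:] != s[:-1]))


def hjorth_params(x):
    """(activity, mobility, complexity); mobility/complexity 0 on constants."""
    x = np.asarray(x, dtype=float)
    var = x.var()
    if var == 0:
        return 0.0, 0.0, 0.0
    d1 = np.diff(x)
    v1 = d1.var()
    mobility = np.sqrt(v1 / var)
    if v1 == 0:
        return float(var), 0.0, 0.0
    d2 = np.diff(d1)
    complexity = np.sqrt(d2.var() / v1) / mobility
    return float(var), float(mobility), float(complexity)


def _embed(x, order, delay=1):
    n = len(x) - (order - 1) * delay
    return np.array([x[i * delay: i * delay + n] for i in range(order)]).T


def permutation_entropy(x, order=3, delay=1):
    """Normalized Shannon entropy of ordinal patterns (0 for a ramp)."""
    x = np.asarray(x, dtype=float)
    if len(x) < (order - 1) * delay + 1:
        return 0.0
    emb = _embed(x, order, delay)
    patterns = np.argsort(emb, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log2(p)).sum()
    return float(h / np.log2(math.factorial(order)))


def svd_entropy(x, order=3, delay=1):
    """Normalized entropy of the embedding matrix's singular-value spectrum."""
    x = np.asarray(x, dtype=float)
    if x.var() == 0 or len(x) < (order - 1) * delay + 1:
        return 0.0
    emb = _embed(x, order, delay)
    sv = np.linalg.svd(emb, compute_uv=False)
    sv = sv / sv.sum()
    sv = sv[sv > 0]
    h = -(sv * np.log2(sv)).sum()
    return float(h / np.log2(order))


def sample_entropy(x, m=2, r_factor=0.2):
    """Sample entropy, Chebyshev distance, tolerance 0.2·SD, self-matches
    excluded; 0 when either template count vanishes (constant input).

    Template counts use all n−m+1 (resp. n−m) windows of each length; the
    Chebyshev maxima are built incrementally from the scalar distance
    matrix rather than by embedding.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1 or x.std(ddof=0) == 0:
        return 0.0
    r = r_factor * x.std(ddof=0)
    d = np.abs(x[:, None] - x[None, :])
    cheb = d
    for mm in range(2, m + 2):
        k = n - mm + 1
        cheb = np.maximum(cheb[:k, :k], d[mm - 1:, mm - 1:])
        if mm == m:
            b = int((cheb <= r).sum()) - k
    a = int((cheb <= r).sum()) - (n - m)
    if m == 1:
        b = int((d <= r).sum()) - n
    if a == 0 or b == 0:
        return 0.0
    return float(-np.log(a / b))


def petrosian_fd(x):
    x = np.asarray(x, dtype=float)
    n = len(x)
    d = np.diff(x)
    s = np.sign(d)
    s[s == 0] = 1
    nd = int(np.sum(s[1:] != s[:-1]))
    if nd == 0:
        return 1.0
    return float(np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * nd))))


def katz_fd(x):
    x = np.asarray(x, dtype=float)
    dists = np.abs(np.diff(x))
    ll = dists.sum()
    if ll == 0:
        return 1.0
    a = dists.mean()
    d = np.abs(x - x[0]).max()
    if d == 0:
        return 1.0
    ln = np.log10(ll / a)
    return float(ln / (ln + np.log10(d / ll)))


def higuchi_fd(x, k_max=10):
    x = np.asarray(x, dtype=float)
    n = len(x)
    if x.var() == 0:
        return 1.0
    lk = []
    ks = []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            seg = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((len(idx) - 1) * k)
            lengths.append(seg * norm / k)
        if lengths:
            lk.append(np.log(np.mean(lengths)))
            ks.append(np.log(1.0 / k))
    slope = np.polyfit(ks, lk, 1)[0]
    return float(slope)


def dfa_exponent(x, min_window=4, max_window=100, n_windows=10):
    """Detrended-fluctuation scaling exponent, linear detrend, log-spaced
    windows of 4–100 samples; 0 on constant input."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if x.var() == 0 or n < 2 * min_window:
        return 0.0
    y = np.cumsum(x - x.mean())
    max_window = min(max_window, n // 2)
    sizes = np.unique(np.geomspace(min_window, max_window,
                                   n_windows).astype(int))
    flucts = []
    for w in sizes:
        k = n // w
        seg = y[: k * w].reshape(k, w)
        t = np.arange(w)
        # per-segment linear fit residual RMS, vectorized
        tm = t - t.mean()
        beta = (seg @ tm) / (tm @ tm)
        resid = seg - seg.mean(axis=1, keepdims=True) - np.outer(beta, tm)
        flucts.append(np.sqrt((resid ** 2).mean()))
    flucts = np.asarray(flucts)
    ok = flucts > 0
    if ok.sum() < 2:
        return 0.0
    slope = np.polyfit(np.log(sizes[ok]), np.log(flucts[ok]), 1)[0]
    return float(slope)


def autocorr_lag1(x):
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = (x ** 2).sum()
    if denom == 0:
        return 0.0
    return float((x[1:] * x[:-1]).sum() / denom)


def complexity_features(trace, rate=EPOCH_RATE):
    """The 13 complexity scores, in :data:`COMPLEXITY_FEATURES` order."""
    x = np.asarray(trace, dtype=float)
    act, mob, comp = hjorth_params(x)
    return (
        lziv_complexity(x),
        float(sign_changes(x)),
        act, mob, comp,
        permutation_entropy(x),
        svd_entropy(x),
        sample_entropy(x),
        petrosian_fd(x),
        katz_fd(x),
        higuchi_fd(x),
        dfa_exponent(x),
        autocorr_lag1(x),
    )


# ---------------------------------------------------------------------------
# spindles and descriptive features

def detect_spindle(trace, rate=EPOCH_RATE, band=(11.0, 16.0),
                   rms_window_s=0.25, factor=3.0, min_duration_s=0.5,
                   min_amp=5.0):
    """Default sigma-burst detector on one epoch trace.

    The sigma-band moving RMS (250 ms boxcar) must exceed ``factor`` times
    its own median (the epoch background) and an absolute floor of
    ``min_amp`` μV RMS for at least 0.5 s contiguously.  The floor keeps
    large slow waves with negligible sigma content from triggering on
    filter residue.  Returns 1/0.
    """
    x = np.asarray(trace, dtype=float)
    sos = _band_sos(rate, *band)
    sigma = sps.sosfiltfilt(sos, x)
    w = max(int(round(rms_window_s * rate)), 1)
    kernel = np.ones(w) / w
    mov_rms = np.sqrt(np.convolve(sigma ** 2, kernel, mode="same"))
    background = np.median(mov_rms)
    if background == 0:
        return 0
    above = (mov_rms > factor * background) & (mov_rms > min_amp)
    need = int(round(min_duration_s * rate))
    run = 0
    for flag in above:
        run = run + 1 if flag else 0
        if run >= need:
            return 1
    return 0


def descriptive_features(event, epoch: SOEpoch, montage,
                         spindle_detector=detect_spindle):
    """(detection_node, spindle_present) per channel.

    The detection-node code (index of the detecting electrode in fixed
    montage order) is replicated across channels so the per-channel
    feature count stays constant.
    """
    channels = tuple(montage.channels)
    if event.channel not in channels:
        raise ValueError(f"detection channel {event.channel} not in montage")
    node = channels.index(event.channel)
    out = []
    for i, _ch in enumerate(channels):
        spin = spindle_detector(epoch.traces[i], EPOCH_RATE)
        out.append((float(node), float(spin)))
    return out


# ---------------------------------------------------------------------------
# table assembly

@dataclass
class FeatureTable:
    """Events × (35 × n_channels) predictors plus per-event metadata."""

    data: pd.DataFrame          # feature columns only, "<channel>__<feature>"
    meta: pd.DataFrame          # META_COLUMNS
    montage: object = None

    def __post_init__(self):
        if len(self.data) != len(self.meta):
            raise ValueError("data and meta must have equal row counts")

    @property
    def feature_columns(self):
        return list(self.data.columns)

    def __len__(self):
        return len(self.data)

    def restrict(self, montage, feature_mode="full"):
        """Column subset for a smaller montage and/or base-only features."""
        keep_feats = BASE_FEATURES if feature_mode == "base" else FEATURE_NAMES
        cols = [f"{ch}__{f}" for ch in montage.channels for f in keep_feats]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"table lacks columns: {missing[:5]}...")
        return FeatureTable(self.data[cols].copy(), self.meta.copy(), montage)

    def to_csv(self, path):
        pd.concat([self.meta, self.data], axis=1).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, montage=None):
        frame = pd.read_csv(path)
        meta = frame[list(META_COLUMNS)]
        data = frame.drop(columns=list(META_COLUMNS))
        return cls(data, meta, montage)


def _band_power_matrix(traces, rate=EPOCH_RATE):
    """Per-channel band powers of an epoch matrix, (n_channels, 7)."""
    nper = min(int(rate), traces.shape[-1])
    freqs, psd = sps.welch(traces, fs=rate, nperseg=nper,
                           noverlap=nper // 2, window="hann", axis=-1)
    cols = []
    for lo, hi in BANDS.values():
        sel = (freqs >= lo) & (freqs <= hi)
        cols.append(psd[:, sel].mean(axis=1) if sel.any()
                    else np.zeros(len(traces)))
    return np.column_stack(cols)


def _band_amplitude_matrix(traces, rate=EPOCH_RATE):
    cols = []
    for lo, hi in BANDS.values():
        filt = sps.sosfiltfilt(_band_sos(rate, lo, hi), traces, axis=-1)
        cols.append(np.abs(filt).mean(axis=1))
    return np.column_stack(cols)


def feature_vector(event, epoch: SOEpoch, montage,
                   spindle_detector=detect_spindle):
    """One event's 35 × n_channels values, ordered channel-major."""
    desc = descriptive_features(event, epoch, montage, spindle_detector)
    pows = _band_power_matrix(epoch.traces)
    amps = _band_amplitude_matrix(epoch.traces)
    values = []
    for i in range(len(epoch.channels)):
        base = base_features(epoch.slow_traces[i])
        cplx = complexity_features(epoch.traces[i])
        values.extend(base + tuple(pows[i]) + tuple(amps[i]) + cplx + desc[i])
    return values


def feature_schema(montage):
    return [f"{ch}__{f}" for ch in montage.channels for f in FEATURE_NAMES]


def assemble_feature_table(recording, events, montage,
                           spindle_detector=detect_spindle) -> FeatureTable:
    """Build the raw (unnormalized) feature table for labeled events.

    Events without an ``so_type`` label and events within 1 s of a
    recording edge are excluded (logged).
    """
    prep = _PreparedRecording(recording, montage)
    cols = feature_schema(montage)
    rows, meta = [], []
    for ev in events:
        if getattr(ev, "so_type", None) is None:
            logger.info("excluding unlabeled event at t=%.3fs", ev.t_trough)
            continue
        epoch = extract_epoch(recording, ev, montage, _prepared=prep)
        if epoch is None:
            continue
        rows.append(feature_vector(ev, epoch, montage, spindle_detector))
        meta.append((ev.subject_id, ev.stage, ev.so_type, ev.channel,
                     ev.t_trough))
    data = pd.DataFrame(rows, columns=cols, dtype=float)
    meta = pd.DataFrame(meta, columns=list(META_COLUMNS))
    return FeatureTable(data, meta, montage)


def concat_tables(tables):
    """Stack per-subject feature tables into one cohort table."""
    tables = list(tables)
    data = pd.concat([t.data for t in tables], ignore_index=True)
    meta = pd.concat([t.meta for t in tables], ignore_index=True)
    return FeatureTable(data, meta, tables[0].montage)
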