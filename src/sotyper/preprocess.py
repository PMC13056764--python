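"""Filtering, epoch resampling and artifact-bin rejection.

Two muscle-artifact screens are applied per channel before event
detection: a local one (26.25–32 Hz power per 4-s bin against the median
of the surrounding 45 bins, factor 4) and a global one (4–50 Hz power per
5-s bin against the median over all bins, factor 6).  Both mark whole
bins unusable; the combined mask is the AND of the two rules plus any
hypnogram "artifact" epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass
class ArtifactParams:
    brunner_band: tuple = (26.25, 32.0)
    brunner_bin: float = 4.0
    brunner_factor: float = 4.0
    brunner_window_bins: int = 45
    wang_band: tuple = (4.0, 50.0)
    wang_bin: float = 5.0
    wang_factor: float = 6.0

    def __post_init__(self):
        for lo, hi in (self.brunner_band, self.wang_band):
            if not (0 < lo < hi):
                raise ValueError("band must satisfy 0 < low < high")
        if min(self.brunner_bin, self.wang_bin, self.brunner_factor,
               self.wang_factor) <= 0 or self.brunner_window_bins <= 0:
            raise ValueError("artifact parameters must be positive")


def bandpass(x, rate, low, high, order: int = 4):
    """Zero-phase Butterworth band-pass (low-pass when ``low == 0``).

    Applied forward-backward so trough timing is not shifted.
    """
    x = np.asarray(x, dtype=float)
    nyq = rate / 2.0
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    if low < 0 or low >= high:
        raise ValueError("need 0 <= low < high")
    if low == 0:
        sos = sps.butter(order, high / nyq, btype="low", output="sos")
    else:
        sos = sps.butter(order, [low / nyq, high / nyq], btype="band",
                         output="sos")
    padlen = min(x.shape[-1] - 1, max(3 * int(rate / max(low, 0.1)), 100))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def resample_epoch(epoch, from_rate, to_rate):
    """Anti-aliased downsampling of per-channel traces (polyphase)."""
    if to_rate > from_rate:
        raise ValueError("upsampling is out of scope (to_rate > from_rate)")
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if to_rate == from_rate:
        out = epoch
    else:
        from fractions import Fraction

        frac = Fraction(int(round(to_rate * 1000)),
                        int(round(from_rate * 1000)))
        out = sps.resample_poly(epoch, frac.numerator, frac.denominator,
                                axis=-1)
    return out[0] if np.asarray(epoch).ndim == 1 else out


def _bin_power(x, rate, band, bin_s):
    """Mean squared band-filtered signal per bin; drops a trailing partial bin."""
    n_bin = int(round(bin_s * rate))
    n_full = len(x) // n_bin
    if n_full == 0:
        return np.empty(0), n_bin
    filt = bandpass(x[: n_full * n_bin], rate, band[0], band[1])
    power = (filt.reshape(n_full, n_bin) ** 2).mean(axis=1)
    return power, n_bin


def _expand(keep_bins, n_bin, n_samples):
    mask = np.ones(n_samples, dtype=bool)
    for i, keep in enumerate(keep_bins):
        if not keep:
            mask[i * n_bin: (i + 1) * n_bin] = False
    return mask


def artifact_mask_brunner(x, rate, params: ArtifactParams = None):
    """Per-sample usable mask from the local-median high-beta power rule.

    A 4-s bin is rejected when its 26.25–32 Hz power exceeds 4x the median
    of the 45 bins centered on it (window truncated at recording edges).
    """
    params = params or ArtifactParams()
    x = np.asarray(x, dtype=float)
    power, n_bin = _bin_power(x, rate, params.brunner_band, params.brunner_bin)
    n = len(power)
    keep = np.ones(n, dtype=bool)
    half = params.brunner_window_bins // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        med = np.median(power[lo:hi])
        if power[i] > params.brunner_factor * med:
            keep[i] = False
    return _expand(keep, n_bin, len(x))


def artifact_mask_wang(x, rate, params: ArtifactParams = None):
    """Per-sample usable mask from the global-median broadband power rule.

    A 5-s bin is rejected when its 4–50 Hz power exceeds 6x the median
    power over all bins.
    """
    params = params or ArtifactParams()
    x = np.asarray(x, dtype=float)
    power, n_bin = _bin_power(x, rate, params.wang_band, params.wang_bin)
    if len(power) == 0:
        return np.ones(len(x), dtype=bool)
    med = np.median(power)
    keep = power <= params.wang_factor * med
    return _expand(keep, n_bin, len(x))


def combined_mask(x, rate, hypnogram=None, params: ArtifactParams = None):
    """AND of both artifact rules and the hypnogram artifact stage."""
    mask = artifact_mask_brunner(x, rate, params) & artifact_mask_wang(
        x, rate, params)
    if hypnogram is not None:
        stages = hypnogram.stage_per_sample(len(x), rate)
        mask &= stages != "artifact"
    return mask


def mask_intervals(mask, rate):
    """Masked (unusable) stretches as (start_s, end_s) pairs."""
    bad = ~np.asarray(mask, dtype=bool)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    return [(s / rate, e / rate) for s, e in zip(edges[::2], edges[1::2])]
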