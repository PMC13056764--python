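"""Synthetic sleep-EEG cohorts with planted SO events of known type.

Each recording is 1/f background noise on every montage channel with SO
waveforms of three space-time archetypes added at known times:

* **Global** — deep troughs on all eight channels, traveling
  anterior→posterior with a fixed per-step lag, depth maximal centrally;
* **Frontal** — moderate troughs restricted to F3/F4 (occasionally
  extending to the central pair at reduced depth);
* **Local** — a single moderately supra-threshold trough on one random
  channel.

Waveforms are a small positive pre-peak, a negative half-sine (0.45–0.85
s) reaching the drawn trough depth, and a positive rebound, so every
planted event satisfies the detector's zero-crossing, duration and
amplitude criteria by construction.  Optional sigma-band spindle bursts
are planted near troughs with a per-type coupling probability, and
optional broadband artifact bursts exercise the artifact masks.  All
randomness comes from one seeded generator with per-subject substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EEGRecording, Hypnogram, MontageConfig, resolve_montage

_REGION_SCALE = {"F": 0.85, "C": 1.0, "P": 0.90, "O": 0.78}


@dataclass
class SyntheticSpec:
    """Cohort recipe; defaults are the reference study conditions."""

    n_subjects: int = 12
    duration: float = 600.0            # seconds per subject
    sampling_rate: float = 200.0
    montage: MontageConfig = None
    stage_plan: tuple = (("N3", 300.0), ("N2", 300.0))  # cycled block plan
    epoch_length: float = 30.0
    # events per minute of staged (N2/N3) sleep, by archetype
    rates: dict = field(default_factory=lambda: {
        "Global": 1.0, "Frontal": 1.0, "Local": 1.0})
    # trough depth ranges (μV, negative); Global deepest on average but the
    # ranges overlap, as real SO amplitude distributions do, so amplitude
    # alone cannot identify the type
    depth_ranges: dict = field(default_factory=lambda: {
        "Global": (-200.0, -140.0),
        "Frontal": (-155.0, -110.0),
        "Local": (-130.0, -90.0)})
    travel_lag: float = 0.030          # s per anterior→posterior step
    frontal_central_prob: float = 0.15  # Frontal events extending to C3/C4
    spindle_prob: dict = field(default_factory=lambda: {
        "Global": 0.3, "Frontal": 0.2, "Local": 0.1})
    spindle_freq: float = 13.0
    spindle_duration: float = 0.7
    spindle_amp: float = 25.0
    noise_exponent: float = 1.0
    noise_rms: float = 15.0
    artifact_rate: float = 0.0         # bursts per minute
    min_gap: float = 3.5               # s between planted troughs
    seed: int = 0

    def __post_init__(self):
        if self.montage is None:
            self.montage = resolve_montage("FCPO")
        d = self.depth_ranges
        if not (d["Global"][0] < d["Frontal"][0] < d["Local"][0]):
            raise ValueError("depth ranges must order Global < Frontal < Local")
        if any(r < 0 for r in self.rates.values()) or self.travel_lag < 0:
            raise ValueError("rates and travel lag must be non-negative")


@dataclass
class GroundTruth:
    subject_id: str
    events: list      # dicts: type, seed_channel, channel_troughs {ch: (t, depth)}
    spindles: list    # dicts: channel, onset, duration
    artifacts: list   # dicts: channel, start, end

    def planted_troughs(self):
        """Flat [(channel, time, depth, type), ...] over all events."""
        out = []
        for ev in self.events:
            for ch, (t, d) in ev["channel_troughs"].items():
                out.append((ch, t, d, ev["type"]))
        return out


def _pink_noise(rng, n_channels, n, rate, exponent, rms):
    """Spectrally shaped Gaussian noise, 1/f^exponent power above 0.5 Hz."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.ones_like(freqs)
    floor = 0.5
    pos = freqs > 0
    shape[pos] = np.maximum(freqs[pos], floor) ** (-exponent / 2.0)
    shape[0] = 0.0
    spec *= shape
    x = np.fft.irfft(spec, n=n, axis=1)
    x *= rms / x.std(axis=1, keepdims=True)
    return x


from functools import lru_cache


@lru_cache(maxsize=256)
def _halfsine_attenuation(n_samples, rate):
    """Trough attenuation of a negative half-sine through the 0.1–4 Hz
    zero-phase detection filter.

    Planted depths are divided by this ratio so the drawn depth is the
    trough the detector actually sees (up to background noise).
    """
    from .preprocess import bandpass

    pad = int(5 * rate)
    x = np.zeros(2 * pad + n_samples)
    x[pad:pad + n_samples] = -np.sin(np.pi * np.arange(n_samples) / n_samples)
    return float(-bandpass(x, rate, 0.1, 4.0).min())


def _so_waveform(rng, depth):
    """(offsets_s, durations) for pre-peak / negative / rebound half-sines."""
    neg_dur = rng.uniform(0.45, 0.85)
    pre_dur = rng.uniform(0.3, 0.5)
    pre_amp = rng.uniform(0.15, 0.3) * abs(depth)
    reb_dur = rng.uniform(0.5, 1.0)
    reb_amp = rng.uniform(0.3, 0.5) * abs(depth)
    return neg_dur, pre_dur, pre_amp, reb_dur, reb_amp


def _add_half_sine(data, rate, t_start, duration, amplitude):
    n = data.shape[-1]
    i0 = int(round(t_start * rate))
    length = max(int(round(duration * rate)), 2)
    i1 = min(i0 + length, n)
    if i0 < 0 or i0 >= n:
        return
    u = np.arange(i1 - i0)
    data[i0:i1] += amplitude * np.sin(np.pi * u / length)


def _build_hypnogram(spec: SyntheticSpec) -> Hypnogram:
    stages = []
    t = 0.0
    bi = 0
    while t < spec.duration:
        stage, block = spec.stage_plan[bi % len(spec.stage_plan)]
        n_ep = max(int(round(block / spec.epoch_length)), 1)
        for _ in range(n_ep):
            if t >= spec.duration:
                break
            stages.append(stage)
            t += spec.epoch_length
        bi += 1
    return Hypnogram(stages=tuple(stages), epoch_length=spec.epoch_length)


def _stage_blocks(hyp: Hypnogram):
    """Contiguous (stage, start_s, end_s) runs of the hypnogram."""
    blocks = []
    for i, s in enumerate(hyp.stages):
        t0, t1 = i * hyp.epoch_length, (i + 1) * hyp.epoch_length
        if blocks and blocks[-1][0] == s and blocks[-1][2] == t0:
            blocks[-1] = (s, blocks[-1][1], t1)
        else:
            blocks.append((s, t0, t1))
    return blocks


def _draw_times(rng, blocks, duration, n_events, min_gap, margin=2.5,
                max_tries=2000):
    """Trough times inside N2/N3 blocks, separated and away from edges."""
    usable = [(max(b1 + margin, margin), min(b2 - margin, duration - margin))
              for s, b1, b2 in blocks if s in ("N2", "N3")]
    usable = [(a, b) for a, b in usable if b > a]
    if not usable:
        raise ValueError("stage plan leaves no usable N2/N3 interval")
    spans = np.array([b - a for a, b in usable])
    times = []
    tries = 0
    while len(times) < n_events:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place all events with the collision budget; "
                "lower the rates or min_gap")
        k = rng.choice(len(usable), p=spans / spans.sum())
        t = rng.uniform(*usable[k])
        if all(abs(t - u) >= min_gap for u in times):
            times.append(t)
    return sorted(times)


def _event_channels(rng, so_type, spec):
    """(channel, lag_s, depth_scale) per involved channel."""
    chans = spec.montage.channels
    if so_type == "Global":
        # regional profile (central max) with per-channel amplitude jitter:
        # traveling-wave expression varies across the scalp, so frontal and
        # central depths of a Global event overlap the Frontal range
        return [(ch, spec.travel_lag * i,
                 _REGION_SCALE[ch[0]] * rng.uniform(0.85, 1.0))
                for i, ch in enumerate(chans)]
    if so_type == "Frontal":
        out = [(ch, 0.005 * i, 1.0)
               for i, ch in enumerate(c for c in chans if c in ("F3", "F4"))]
        if rng.random() < spec.frontal_central_prob:
            for j, ch in enumerate(c for c in chans if c in ("C3", "C4")):
                out.append((ch, 0.02 + 0.005 * j, 0.9))
        return out
    ch = chans[rng.integers(len(chans))]
    return [(ch, 0.0, 1.0)]


def generate_recording(spec: SyntheticSpec, subject_index: int):
    """One subject's (EEGRecording, Hypnogram, GroundTruth)."""
    rng = np.random.default_rng([spec.seed, subject_index])
    rate = spec.sampling_rate
    n = int(round(spec.duration * rate))
    chans = spec.montage.channels
    data = _pink_noise(rng, len(chans), n, rate, spec.noise_exponent,
                       spec.noise_rms)
    hyp = _build_hypnogram(spec)
    blocks = _stage_blocks(hyp)
    staged_min = sum(b2 - b1 for s, b1, b2 in blocks
                     if s in ("N2", "N3")) / 60.0

    counts = {t: rng.poisson(r * staged_min) for t, r in spec.rates.items()}
    order = [t for t in ("Global", "Frontal", "Local")
             for _ in range(counts.get(t, 0))]
    rng.shuffle(order)
    times = _draw_times(rng, blocks, spec.duration, len(order), spec.min_gap)

    subject_id = f"synth{subject_index:03d}"
    truth_events, spindles = [], []
    for so_type, t0 in zip(order, times):
        lo, hi = spec.depth_ranges[so_type]
        depth = rng.uniform(lo, hi)
        involved = _event_channels(rng, so_type, spec)
        seed_channel = involved[0][0]
        channel_troughs = {}
        for ch, lag, scale in involved:
            d = depth * scale
            neg_dur, pre_dur, pre_amp, reb_dur, reb_amp = _so_waveform(rng, d)
            t_tr = t0 + lag
            row = data[chans.index(ch)]
            # compensate the detection filter's trough attenuation so the
            # drawn depth is realized on the 0.1-4 Hz trace
            atten = _halfsine_attenuation(
                max(int(round(neg_dur * rate)), 2), rate)
            _add_half_sine(row, rate, t_tr - neg_dur / 2 - pre_dur,
                           pre_dur, pre_amp)
            _add_half_sine(row, rate, t_tr - neg_dur / 2, neg_dur, d / atten)
            _add_half_sine(row, rate, t_tr + neg_dur / 2, reb_dur, reb_amp)
            channel_troughs[ch] = (t_tr, d)
        truth_events.append({"type": so_type, "seed_channel": seed_channel,
                             "channel_troughs": channel_troughs})
        if rng.random() < spec.spindle_prob.get(so_type, 0.0):
            onset = t0 + 0.25
            ci = chans.index(seed_channel)
            m = int(round(spec.spindle_duration * rate))
            i0 = int(round(onset * rate))
            if i0 + m < n:
                u = np.arange(m)
                burst = (spec.spindle_amp
                         * np.sin(2 * np.pi * spec.spindle_freq * u / rate)
                         * np.hanning(m))
                data[ci, i0:i0 + m] += burst
                spindles.append({"channel": seed_channel, "onset": onset,
                                 "duration": spec.spindle_duration})

    artifacts = []
    n_art = rng.poisson(spec.artifact_rate * spec.duration / 60.0)
    for _ in range(n_art):
        ci = rng.integers(len(chans))
        start = rng.uniform(0, spec.duration - 6)
        dur = rng.uniform(4.0, 6.0)
        i0, i1 = int(start * rate), int((start + dur) * rate)
        u = np.arange(i1 - i0)
        data[ci, i0:i1] += (10 * spec.noise_rms
                            * np.sin(2 * np.pi * 28.0 * u / rate))
        artifacts.append({"channel": chans[ci], "start": start,
                          "end": start + dur})

    rec = EEGRecording(subject_id=subject_id, channels=chans,
                       sampling_rate=rate, data=data)
    truth = GroundTruth(subject_id=subject_id, events=truth_events,
                        spindles=spindles, artifacts=artifacts)
    return rec, hyp, truth


def generate_cohort(spec: SyntheticSpec):
    """All subjects' (recording, hypnogram, truth) triples."""
    return [generate_recording(spec, i) for i in range(spec.n_subjects)]


def generative_types(meta, truths, tolerance: float = 0.4):
    """Per-row generative archetype for a feature table's events.

    ``meta`` needs subject_id / detection_channel / t_trough columns;
    ``truths`` maps subject_id → GroundTruth.  Rows with no planted trough
    on that channel within tolerance get None (false-positive detections).
    """
    lookup = {}
    for sid, truth in truths.items():
        for ch, t, _d, ty in truth.planted_troughs():
            lookup.setdefault((sid, ch), []).append((t, ty))
    out = []
    for sid, ch, t in zip(meta["subject_id"], meta["detection_channel"],
                          meta["t_trough"]):
        cands = lookup.get((sid, ch), [])
        best = None
        best_err = tolerance
        for tt, ty in cands:
            if abs(tt - t) <= best_err:
                best, best_err = ty, abs(tt - t)
        out.append(best)
    return out


def truth_match(detected, truth: GroundTruth, tolerance: float = 0.4):
    """Greedy one-to-one match of detections to planted troughs.

    ``detected`` is a flat list of SOEvent (any channels).  Returns a dict
    with precision, recall, mean absolute trough-time error, per-type
    label agreement (when detections carry ``so_type``), and a flag when
    precision is undefined (no detections) and reported as 1.
    """
    planted = truth.planted_troughs()
    det = sorted(detected, key=lambda e: e.t_trough)
    if not det:
        return {"precision": 1.0, "recall": 0.0, "n_matched": 0,
                "mean_time_error": float("nan"),
                "precision_undefined": True, "type_agreement": float("nan")}
    pairs = []
    for i, ev in enumerate(det):
        for j, (ch, t, _d, _ty) in enumerate(planted):
            if ev.channel == ch and abs(ev.t_trough - t) <= tolerance:
                pairs.append((abs(ev.t_trough - t), i, j))
    pairs.sort()
    used_d, used_p, matches = set(), set(), []
    for err, i, j in pairs:
        if i in used_d or j in used_p:
            continue
        used_d.add(i)
        used_p.add(j)
        matches.append((i, j, err))
    n_match = len(matches)
    agree = [1.0 for i, j, _ in matches
             if getattr(det[i], "so_type", None) == planted[j][3]]
    typed = [i for i, j, _ in matches
             if getattr(det[i], "so_type", None) is not None]
    return {
        "precision": n_match / len(det),
        "recall": n_match / len(planted) if planted else 1.0,
        "n_matched": n_match,
        "mean_time_error": (np.mean([e for _, _, e in matches])
                            if matches else float("nan")),
        "precision_undefined": False,
        "type_agreement": (len(agree) / len(typed) if typed else float("nan")),
    }
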