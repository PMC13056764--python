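import numpy as np
import pandas as pd
import pytest

from sotyper.detect import SOEvent
from sotyper.features import FEATURE_NAMES, FeatureTable, feature_schema
from sotyper.io import Hypnogram, resolve_montage


def make_so_signal(rate=200.0, total_s=30.0, t_trough=15.0, depth=-100.0,
                   neg_dur=0.6, reb_amp=30.0, reb_dur=0.8,
                   pre_amp=10.0, pre_dur=0.3, closing_amp=-8.0,
                   closing_dur=0.3):
    """Noise-free trace holding one SO-shaped waveform.

    Layout: small positive bump, negative half-sine reaching ``depth`` at
    ``t_trough``, positive rebound half-sine, then a small negative bump
    so the rebound ends on a third zero crossing.
    """
    n = int(round(total_s * rate))
    x = np.zeros(n)

    def add(t0, dur, amp):
        i0 = int(round(t0 * rate))
        m = max(int(round(dur * rate)), 2)
        u = np.arange(m)
        seg = amp * np.sin(np.pi * u / m)
        x[i0:i0 + m] += seg[: max(0, min(m, n - i0))]

    t_zc1 = t_trough - neg_dur / 2
    add(t_zc1 - pre_dur, pre_dur, pre_amp)
    add(t_zc1, neg_dur, depth)
    add(t_zc1 + neg_dur, reb_dur, reb_amp)
    add(t_zc1 + neg_dur + reb_dur, closing_dur, closing_amp)
    return x


@pytest.fixture
def so_signal():
    return make_so_signal


@pytest.fixture
def n3_hypnogram():
    def _make(total_s=30.0, stage="N3", epoch_length=30.0):
        n_ep = int(np.ceil(total_s / epoch_length))
        return Hypnogram(stages=(stage,) * n_ep, epoch_length=epoch_length)
    return _make


def synthetic_feature_table(n_subjects=20, rows_per_subject=30, montage="FCPO",
                            separation=3.0, seed=0, shuffle_labels=False):
    """Feature table with class means shifted on the trough-amp columns.

    ``separation`` is the between-class mean gap in units of the
    within-class SD; 0 gives pure noise (chance-level separability).
    """
    rng = np.random.default_rng(seed)
    mont = resolve_montage(montage)
    cols = feature_schema(mont)
    classes = ("Global", "Frontal", "Local")
    rows, meta = [], []
    for s in range(n_subjects):
        sid = f"subj{s:02d}"
        for _ in range(rows_per_subject):
            label = classes[rng.integers(3)]
            vec = rng.standard_normal(len(cols))
            shift = separation * (classes.index(label) - 1)
            for i, c in enumerate(cols):
                if c.endswith("__trough_amp"):
                    vec[i] += shift
            rows.append(vec)
            meta.append((sid, "N3", label, mont.channels[0], 100.0))
    data = pd.DataFrame(rows, columns=cols)
    meta = pd.DataFrame(
        meta, columns=["subject_id", "stage", "so_type",
                       "detection_channel", "t_trough"])
    if shuffle_labels:
        meta["so_type"] = rng.permutation(meta["so_type"].values)
    return FeatureTable(data, meta, mont)


@pytest.fixture
def feature_table_factory():
    return synthetic_feature_table


def make_event(channel="F3", t_trough=10.0, trough_amp=-100.0,
               subject_id="s0", stage="N3"):
    return SOEvent(subject_id=subject_id, channel=channel,
                   t_zc1=t_trough - 0.3, t_trough=t_trough,
                   t_zc2=t_trough + 0.3, t_zc3=t_trough + 1.0,
                   trough_amp=trough_amp, peak_amp=30.0, stage=stage)


@pytest.fixture
def event_factory():
    return make_event
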