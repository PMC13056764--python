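import math

import numpy as np
import pytest

import sotyper.features as F
from sotyper.features import (BANDS, BASE_FEATURES, COMPLEXITY_FEATURES,
                              FEATURE_NAMES, FeatureTable,
                              assemble_feature_table, base_features,
                              band_amplitude_features, band_power_features,
                              complexity_features, descriptive_features,
                              detect_spindle, extract_epoch, feature_schema)
from sotyper.io import EEGRecording, MONTAGES, resolve_montage
from conftest import make_event, make_so_signal, synthetic_feature_table

RATE = 200.0


# ---------------------------------------------------------------------------
# brute-force oracles (independent, naive implementations)

def naive_sample_entropy(x, m=2, r_factor=0.2):
    x = list(map(float, x))
    n = len(x)
    r = r_factor * float(np.std(x))

    def count(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        c = 0
        for i in range(len(templates)):
            for j in range(len(templates)):
                if i == j:
                    continue
                if max(abs(a - b) for a, b in
                       zip(templates[i], templates[j])) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return -math.log(a / b)


def naive_permutation_entropy(x, order=3):
    pats = {}
    for i in range(len(x) - order + 1):
        window = x[i:i + order]
        pat = tuple(sorted(range(order), key=lambda k: window[k]))
        pats[pat] = pats.get(pat, 0) + 1
    total = sum(pats.values())
    h = -sum((c / total) * math.log2(c / total) for c in pats.values())
    return h / math.log2(math.factorial(order))


def naive_svd_entropy(x, order=3):
    rows = [x[i:i + len(x) - order + 1] for i in range(order)]
    sv = np.linalg.svd(np.array(rows, dtype=float).T, compute_uv=False)
    sv = sv / sv.sum()
    sv = sv[sv > 0]
    return float(-(sv * np.log2(sv)).sum() / np.log2(order))


def naive_lz76(symbols):
    """Phrase count by explicit scan of all earlier substrings."""
    s = "".join(str(int(v)) for v in symbols)
    n = len(s)
    i, c = 0, 0
    while i < n:
        length = 1
        while i + length <= n:
            sub = s[i:i + length]
            hist = s[:i + length - 1]
            found = any(hist[j:j + length] == sub
                        for j in range(len(hist) - length + 1))
            if not found:
                break
            length += 1
        c += 1
        i += length
    return c


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("n", [20, 35, 50])
def test_sample_entropy_matches_bruteforce(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    assert F.sample_entropy(x) == pytest.approx(naive_sample_entropy(x),
                                                abs=1e-12)


@pytest.mark.parametrize("seed", [3, 4])
def test_permutation_entropy_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(50)
    assert F.permutation_entropy(x) == pytest.approx(
        naive_permutation_entropy(list(x)), abs=1e-12)


@pytest.mark.parametrize("seed", [5, 6])
def test_svd_entropy_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(40)
    assert F.svd_entropy(x) == pytest.approx(naive_svd_entropy(x), abs=1e-10)


@pytest.mark.parametrize("seed", [7, 8])
def test_lz76_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(50)
    sym = (x > np.median(x)).astype(int)
    expected = naive_lz76(sym) * np.log2(len(x)) / len(x)
    assert F.lziv_complexity(x) == pytest.approx(expected, abs=1e-12)


def test_lz76_periodic_below_random():
    periodic = np.tile([0.0, 1.0], 200)
    rng = np.random.default_rng(9)
    random = rng.random(400)
    assert F.lziv_complexity(periodic) <= F.lziv_complexity(random)


def test_ramp_closed_forms():
    ramp = np.arange(400, dtype=float)
    assert F.permutation_entropy(ramp) == 0.0
    assert F.sign_changes(ramp) == 1


def test_alternating_sequence_sign_changes():
    x = np.tile([1.0, -1.0], 200)
    assert F.sign_changes(x) == 399


def test_hjorth_activity_is_variance():
    rng = np.random.default_rng(10)
    x = rng.standard_normal(400) * 5.0
    act, mob, comp = F.hjorth_params(x)
    assert act == pytest.approx(x.var(), rel=1e-12)
    assert mob > 0 and comp > 0


def test_constant_input_fallbacks():
    x = np.full(400, 3.14)
    vals = dict(zip(COMPLEXITY_FEATURES, complexity_features(x)))
    assert vals["perm_entropy"] == 0.0
    assert vals["svd_entropy"] == 0.0
    assert vals["samp_entropy"] == 0.0
    assert vals["petrosian_fd"] == 1.0
    assert vals["katz_fd"] == 1.0
    assert vals["higuchi_fd"] == 1.0
    assert vals["dfa"] == 0.0
    assert vals["hjorth_mobility"] == 0.0
    assert vals["hjorth_complexity"] == 0.0


def test_entropies_and_fds_gain_invariant():
    rng = np.random.default_rng(11)
    x = rng.standard_normal(400) * 20.0
    a, b = complexity_features(x), complexity_features(x * 7.0)
    gain_invariant = ("lziv", "sign_changes", "hjorth_mobility",
                      "hjorth_complexity", "perm_entropy", "svd_entropy",
                      "samp_entropy", "petrosian_fd", "katz_fd",
                      "higuchi_fd", "dfa", "autocorr_lag1")
    for name in gain_invariant:
        i = COMPLEXITY_FEATURES.index(name)
        assert a[i] == pytest.approx(b[i], rel=1e-6, abs=1e-9), name


def test_amplitude_features_scale_linearly():
    rng = np.random.default_rng(12)
    x = rng.standard_normal(400) * 20.0
    a1 = np.array(band_amplitude_features(x))
    a2 = np.array(band_amplitude_features(2.0 * x))
    np.testing.assert_allclose(a2, 2.0 * a1, rtol=1e-9)
    b1 = np.array(base_features(x)[::2])  # the three amplitudes
    b2 = np.array(base_features(2.0 * x)[::2])
    np.testing.assert_allclose(b2, 2.0 * b1, rtol=1e-12)


# ---------------------------------------------------------------------------
# base waveform coordinates

def test_base_features_on_constructed_waveform():
    t = (np.arange(400) - 200) / RATE
    x = np.zeros(400)
    x += -90.0 * np.exp(-0.5 * (t / 0.15) ** 2)          # trough at t=0
    x += 30.0 * np.exp(-0.5 * ((t + 0.4) / 0.08) ** 2)   # peak at -0.4 s
    x += 30.0 * np.exp(-0.5 * ((t - 0.4) / 0.08) ** 2)   # peak at +0.4 s
    tr_a, tr_t, pre_a, pre_t, post_a, post_t = base_features(x)
    assert tr_a == pytest.approx(-90.0, abs=1.0)
    assert tr_t == pytest.approx(0.0, abs=0.01)
    # side peaks sit on the trough bump's tail (−2.6 μV at ±0.4 s)
    assert pre_a == pytest.approx(27.4, abs=1.0)
    assert pre_t == pytest.approx(-0.4, abs=0.02)
    assert post_a == pytest.approx(27.4, abs=1.0)
    assert post_t == pytest.approx(0.4, abs=0.02)


def test_base_features_offset_on_non_detection_channel():
    # trough shifted +0.1 s, as on a neighbor of the detection electrode
    t = (np.arange(400) - 200) / RATE
    x = -90.0 * np.exp(-0.5 * ((t - 0.1) / 0.15) ** 2)
    _, tr_t, *_ = base_features(x)
    assert tr_t == pytest.approx(0.1, abs=0.01)


def test_base_features_ramp_fallback():
    ramp = np.linspace(-1.0, 1.0, 400)
    tr_a, tr_t, pre_a, pre_t, post_a, post_t = base_features(ramp)
    assert tr_t == pytest.approx(-1.0)          # trough at left edge
    assert pre_t == pytest.approx(-1 / RATE, abs=1e-9)   # end of pre window
    assert post_t == pytest.approx((399 - 200) / RATE)   # right window end


# ---------------------------------------------------------------------------
# spectral features

def test_band_powers_zero_trace():
    assert band_power_features(np.zeros(400)) == (0.0,) * 7


def test_band_power_pure_delta_sine():
    t = np.arange(400) / RATE
    x = 50.0 * np.sin(2 * np.pi * 2.0 * t)
    vals = dict(zip(BANDS, band_power_features(x)))
    for other in ("theta", "alpha", "sigma", "beta", "lowgamma"):
        assert vals["delta"] >= 10 * vals[other]


def test_band_power_alpha_sine():
    t = np.arange(400) / RATE
    x = 50.0 * np.sin(2 * np.pi * 10.0 * t)
    vals = dict(zip(BANDS, band_power_features(x)))
    assert vals["alpha"] == max(vals[b] for b in
                                ("theta", "alpha", "sigma", "beta",
                                 "lowgamma"))


def test_band_amplitude_alpha_sine_mean_abs():
    t = np.arange(400) / RATE
    amp = 40.0
    x = amp * np.sin(2 * np.pi * 10.0 * t)
    vals = dict(zip(BANDS, band_amplitude_features(x)))
    assert vals["alpha"] == pytest.approx(2 * amp / np.pi, rel=0.1)


def test_band_amplitude_zero_trace():
    assert band_amplitude_features(np.zeros(400)) == (0.0,) * 7


# ---------------------------------------------------------------------------
# spindles and descriptive features

def _epoch_with_trace(traces):
    ev = make_event(channel="F3")
    mont = resolve_montage("FCPO")
    return F.SOEpoch(event=ev, channels=mont.channels, traces=traces,
                     slow_traces=np.zeros_like(traces))


def test_spindle_detected_on_planted_burst():
    rng = np.random.default_rng(13)
    x = rng.standard_normal(400) * 5.0
    t = np.arange(int(0.7 * RATE)) / RATE
    i0 = 260  # +0.3 s after the trough sample
    x[i0:i0 + len(t)] += 40.0 * np.sin(2 * np.pi * 13.0 * t)
    assert detect_spindle(x) == 1


def test_no_spindle_on_pure_delta():
    t = np.arange(400) / RATE
    x = 80.0 * np.sin(2 * np.pi * 1.0 * t)
    assert detect_spindle(x) == 0


def test_detection_node_code_replicated():
    traces = np.random.default_rng(14).standard_normal((8, 400))
    ev = make_event(channel="F3")
    mont = resolve_montage("FCPO")
    epoch = F.SOEpoch(event=ev, channels=mont.channels, traces=traces,
                      slow_traces=traces)
    desc = descriptive_features(ev, epoch, mont)
    assert [d[0] for d in desc] == [0.0] * 8
    ev2 = make_event(channel="O2")
    desc2 = descriptive_features(ev2, epoch, mont)
    assert [d[0] for d in desc2] == [7.0] * 8


# ---------------------------------------------------------------------------
# epoch extraction and table assembly

def _zero_recording(duration=120.0, rate=1000.0):
    n = int(duration * rate)
    return EEGRecording("s0", MONTAGES["FCPO"], rate, np.zeros((8, n)))


def test_extract_epoch_window_and_length():
    rec = _zero_recording()
    mont = resolve_montage("FCPO")
    ev = make_event(t_trough=100.0)
    epoch = extract_epoch(rec, ev, mont)
    assert epoch.traces.shape == (8, 400)
    assert epoch.slow_traces.shape == (8, 400)
    assert np.allclose(epoch.traces, 0.0)


def test_extract_epoch_skips_near_edge():
    rec = _zero_recording(duration=30.0)
    mont = resolve_montage("FCPO")
    assert extract_epoch(rec, make_event(t_trough=0.5), mont) is None


def test_feature_count_per_montage():
    for name, n in [("FCPO", 8), ("FCP", 6), ("FCO", 6), ("FC", 4), ("F", 2)]:
        assert len(feature_schema(resolve_montage(name))) == 35 * n


def test_assemble_table_shape_and_schema():
    rate = 500.0
    n = int(240 * rate)
    rng = np.random.default_rng(15)
    data = rng.standard_normal((8, n)) * 10.0
    rec = EEGRecording("s0", MONTAGES["FCPO"], rate, data)
    mont = resolve_montage("FCPO")
    events = []
    for i in range(5):
        ev = make_event(channel="C3", t_trough=20.0 + 40.0 * i)
        ev.so_type = "Global"
        ev.cluster_index = 0
        events.append(ev)
    unlabeled = make_event(channel="C3", t_trough=230.0)
    table = assemble_feature_table(rec, events + [unlabeled], mont)
    assert len(table) == 5            # unlabeled row excluded
    assert list(table.data.columns) == feature_schema(mont)
    assert table.data.shape[1] == 280
    assert (table.meta["so_type"] == "Global").all()


def test_assemble_empty_events_keeps_schema():
    rec = _zero_recording()
    table = assemble_feature_table(rec, [], resolve_montage("FC"))
    assert len(table) == 0
    assert list(table.data.columns) == feature_schema(resolve_montage("FC"))
    assert table.data.shape[1] == 140


def test_restrict_montage_and_base_mode():
    table = synthetic_feature_table(n_subjects=2, rows_per_subject=3)
    f_base = table.restrict(resolve_montage("F"), "base")
    assert f_base.data.shape[1] == 12
    fc_full = table.restrict(resolve_montage("FC"), "full")
    assert fc_full.data.shape[1] == 140


def test_features_follow_their_channel_under_reordering():
    # channel-permuted input recording yields identical per-channel values
    rate = 500.0
    rng = np.random.default_rng(16)
    data = rng.standard_normal((8, int(60 * rate))) * 15.0
    rec = EEGRecording("s0", MONTAGES["FCPO"], rate, data)
    perm_order = list(reversed(MONTAGES["FCPO"]))
    rec_perm = EEGRecording("s0", perm_order, rate,
                            data[[list(MONTAGES["FCPO"]).index(c)
                                  for c in perm_order]])
    mont = resolve_montage("FCPO")
    ev = make_event(channel="C3", t_trough=30.0)
    ev.so_type = "Global"
    t1 = assemble_feature_table(rec, [ev], mont)
    t2 = assemble_feature_table(rec_perm, [ev], mont)
    for col in t1.data.columns:
        assert t1.data[col].iloc[0] == pytest.approx(
            t2.data[col].iloc[0], rel=1e-9, abs=1e-9)


def test_table_csv_roundtrip(tmp_path):
    table = synthetic_feature_table(n_subjects=2, rows_per_subject=4)
    table.to_csv(tmp_path / "t.csv")
    back = FeatureTable.read_csv(tmp_path / "t.csv")
    assert list(back.data.columns) == list(table.data.columns)
    np.testing.assert_allclose(back.data.values, table.data.values,
                               rtol=1e-9)
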