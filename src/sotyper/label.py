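"""Space-time typing of SO events via co-detection clustering.

Each detection is one row of a binary events × channels matrix: entry
(i, c) is 1 when channel c carries a trough within ±400 ms of event i's
trough (closed interval).  K-means with k = 3 on the rows separates
widespread, frontally-restricted, and isolated co-detection footprints;
clusters are then named Global / Frontal / Local from their centroid
geometry (largest mean footprint → Global; of the rest, the more frontal
→ Frontal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

SO_TYPES = ("Global", "Frontal", "Local")
FRONTAL_CHANNELS = ("F3", "F4")


class ClusterTieError(ValueError):
    """Cluster naming is ambiguous; manual assignment required."""


@dataclass
class CoDetectionMatrix:
    events: list                 # flat list of SOEvent, one per row
    channels: tuple
    matrix: np.ndarray           # binary, rows = events, cols = channels
    delay: float = 0.4

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape != (len(self.events), len(self.channels)):
            raise ValueError("matrix shape must be (n_events, n_channels)")


def build_codetection_matrix(events_by_channel: dict, channels,
                             delay: float = 0.4) -> CoDetectionMatrix:
    """Binary co-detection matrix over all detections on all channels.

    Events are not merged: one physiological SO visible on several
    channels yields several rows with near-identical footprints.
    """
    if delay <= 0:
        raise ValueError("delay must be positive")
    channels = tuple(channels)
    flat = [e for ch in channels for e in events_by_channel.get(ch, [])]
    trough_by_channel = {
        ch: np.array(sorted(e.t_trough for e in events_by_channel.get(ch, [])))
        for ch in channels
    }
    mat = np.zeros((len(flat), len(channels)), dtype=np.int8)
    for i, ev in enumerate(flat):
        for j, ch in enumerate(channels):
            troughs = trough_by_channel[ch]
            if troughs.size == 0:
                continue
            k = np.searchsorted(troughs, ev.t_trough)
            for kk in (k - 1, k):
                # closed interval; epsilon guards float representation of
                # the boundary (|10.4 - 10.0| must count as <= 0.4)
                if 0 <= kk < troughs.size and \
                        abs(troughs[kk] - ev.t_trough) <= delay + 1e-9:
                    mat[i, j] = 1
                    break
    return CoDetectionMatrix(events=flat, channels=channels, matrix=mat,
                             delay=delay)


def cluster_so_types(matrix: CoDetectionMatrix, k: int = 3, seed: int = 0,
                     n_init: int = 50) -> np.ndarray:
    """K-means (Euclidean on binary rows) cluster index per event."""
    rows = matrix.matrix.astype(float)
    n_distinct = np.unique(rows, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(
            f"need at least {k} distinct co-detection rows, got {n_distinct}")
    km = KMeans(n_clusters=k, n_init=n_init, tol=1e-6, random_state=seed)
    return km.fit_predict(rows)


def name_clusters(assignments, matrix: CoDetectionMatrix,
                  tie_tol: float = 1e-3) -> dict:
    """Map the three cluster indices to Global / Frontal / Local.

    Global = largest mean row sum (footprint); of the remaining two the
    one with higher mean frontal (F3/F4) fraction = Frontal; the last is
    Local.  Near-ties raise :class:`ClusterTieError`.
    """
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if len(labels) != 3:
        raise ValueError(f"expected exactly 3 clusters, got {len(labels)}")
    rows = matrix.matrix.astype(float)
    frontal_cols = [i for i, c in enumerate(matrix.channels)
                    if c in FRONTAL_CHANNELS]
    row_sum = rows.sum(axis=1)
    mean_sum = {c: row_sum[assignments == c].mean() for c in labels}

    def _rel_close(a, b):
        denom = max(abs(a), abs(b), 1e-12)
        return abs(a - b) / denom < tie_tol

    ordered = sorted(labels, key=lambda c: -mean_sum[c])
    if _rel_close(mean_sum[ordered[0]], mean_sum[ordered[1]]):
        raise ClusterTieError(
            "two clusters have indistinguishable mean footprint; "
            "assign names manually")
    global_c = ordered[0]
    rest = ordered[1:]
    frac = {}
    for c in rest:
        sub = rows[assignments == c]
        with np.errstate(invalid="ignore"):
            frac[c] = (sub[:, frontal_cols].sum(axis=1)
                       / sub.sum(axis=1)).mean() if frontal_cols else 0.0
    if _rel_close(frac[rest[0]], frac[rest[1]]):
        raise ClusterTieError(
            "remaining clusters have indistinguishable frontal fraction; "
            "assign names manually")
    frontal_c = max(rest, key=lambda c: frac[c])
    local_c = next(c for c in rest if c != frontal_c)
    return {int(global_c): "Global", int(frontal_c): "Frontal",
            int(local_c): "Local"}


def label_events(events_by_channel: dict, channels, delay: float = 0.4,
                 seed: int = 0, n_init: int = 50):
    """Full labeling stage: matrix → k-means → names, written onto events.

    Returns (CoDetectionMatrix, assignments, name_map); every event in the
    matrix gains ``cluster_index`` and ``so_type`` attributes.
    """
    matrix = build_codetection_matrix(events_by_channel, channels, delay)
    assignments = cluster_so_types(matrix, seed=seed, n_init=n_init)
    names = name_clusters(assignments, matrix)
    for ev, c in zip(matrix.events, assignments):
        ev.cluster_index = int(c)
        ev.so_type = names[int(c)]
    return matrix, assignments, names
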