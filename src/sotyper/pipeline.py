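"""End-to-end orchestration: detect → label → featurize → train.

Co-detection rows from all subjects are pooled before k-means so the
three type labels are defined consistently across the cohort, then
written back onto each subject's events.
"""

from __future__ import annotations

import numpy as np

from . import detect, features, label, model, preprocess, simulate


def detect_subject(recording, hypnogram=None, params=None,
                   artifact_params=None, apply_masks=True):
    """Artifact masks + per-channel SO detection for one recording."""
    params = params or detect.DetectionParams()
    masks = None
    if apply_masks:
        masks = {
            ch: preprocess.combined_mask(
                recording.get(ch), recording.sampling_rate, hypnogram,
                artifact_params)
            for ch in recording.channels
        }
    return detect.detect_sos(recording, hypnogram, masks, params)


def label_cohort(events_by_channel_per_subject, channels, delay=0.4,
                 seed=0, n_init=50):
    """Pool co-detection rows over subjects, cluster once, name, assign."""
    mats = [label.build_codetection_matrix(ebc, channels, delay)
            for ebc in events_by_channel_per_subject]
    rows = np.vstack([m.matrix for m in mats if len(m.events)])
    events = [e for m in mats for e in m.events]
    pooled = label.CoDetectionMatrix(events=events, channels=tuple(channels),
                                     matrix=rows, delay=delay)
    assignments = label.cluster_so_types(pooled, seed=seed, n_init=n_init)
    names = label.name_clusters(assignments, pooled)
    for ev, c in zip(events, assignments):
        ev.cluster_index = int(c)
        ev.so_type = names[int(c)]
    return pooled, assignments, names


def featurize_cohort(recordings, events_per_subject, montage):
    """One pooled FeatureTable over labeled events of all subjects."""
    tables = [features.assemble_feature_table(rec, evs, montage)
              for rec, evs in zip(recordings, events_per_subject)]
    return features.concat_tables(tables)


def run_synthetic_pipeline(spec=None, seed=0, settings=None,
                           apply_masks=False, params=None):
    """Simulate a cohort and run detect → label → featurize → fit.

    Artifact masking defaults off here because the generator plants no
    artifacts unless asked.  Returns a dict with the cohort, detections,
    the labeled feature table and the fitted :class:`SOTypeResults`.
    """
    spec = spec or simulate.SyntheticSpec(seed=seed)
    cohort = simulate.generate_cohort(spec)
    per_subject = []
    for rec, hyp, _truth in cohort:
        per_subject.append(detect_subject(rec, hyp, params=params,
                                          apply_masks=apply_masks))
    matrix, _assign, names = label_cohort(
        per_subject, spec.montage.channels, seed=seed)
    events_per_subject = [
        [e for ch_events in ebc.values() for e in ch_events]
        for ebc in per_subject
    ]
    table = featurize_cohort([rec for rec, _h, _t in cohort],
                             events_per_subject, spec.montage)
    clf = model.SOTypeClassifier(table, montage=spec.montage,
                                 settings=settings)
    results = clf.fit(seed=seed)
    return {
        "spec": spec,
        "cohort": cohort,
        "detections": per_subject,
        "codetection": matrix,
        "cluster_names": names,
        "table": table,
        "results": results,
    }
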