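"""Feature attribution for the trained ensemble.

Attributions are tree-path-dependent SHAP values on the margin (log-odds)
output of each booster, averaged over the five models of the ensemble.
Per model, the attributions plus the base value reproduce that model's
margin exactly (additivity).  Aggregations mirror the usual reporting:
per-(feature, class) signed means, per-feature mean absolute value across
classes, per-family means over the montage's channels, and per-channel
topographic values for a chosen family and class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb

from .features import FEATURE_NAMES
from .label import SO_TYPES


@dataclass
class ShapAttributions:
    """values: (n_records, n_classes, n_features); base: (n_records, n_classes)."""

    values: np.ndarray
    base_values: np.ndarray
    feature_columns: list
    class_order: tuple = SO_TYPES


def shap_attributions(ensemble, table) -> ShapAttributions:
    """Tree-SHAP margin attributions, averaged over the five models."""
    ensemble._check_schema(table)
    dmat = xgb.DMatrix(table.data.values,
                       feature_names=list(ensemble.feature_columns))
    per_model = []
    bases = []
    for booster in ensemble.boosters:
        contrib = booster.predict(dmat, pred_contribs=True)
        # (n, n_class, n_feat + 1); last column is the base value
        per_model.append(contrib[:, :, :-1])
        bases.append(contrib[:, :, -1])
    return ShapAttributions(
        values=np.mean(per_model, axis=0),
        base_values=np.mean(bases, axis=0),
        feature_columns=list(ensemble.feature_columns),
    )


@dataclass
class ShapSummary:
    signed_mean: pd.DataFrame       # rows = feature column, cols = class
    mean_abs: pd.Series             # per feature, mean |SHAP| across classes
    family_mean_abs: pd.Series      # per feature family, mean over channels
    by_channel: pd.DataFrame        # rows = (channel, family), cols = class

    def top_features(self, n=6):
        """Feature columns ranked by mean absolute attribution."""
        return list(self.mean_abs.sort_values(ascending=False).index[:n])

    def top_families(self, n=6):
        return list(self.family_mean_abs.sort_values(ascending=False).index[:n])

    def topography(self, family: str, class_name: str,
                   flip_trough_sign: bool = True) -> pd.Series:
        """Per-channel signed mean SHAP of one family for one class.

        Trough amplitude is stored negative, so its attribution sign is
        flipped by default to give large troughs a positive reading.
        """
        sel = self.by_channel.xs(family, level="family")[class_name]
        if flip_trough_sign and family == "trough_amp":
            sel = -sel
        return sel

    def to_frame(self) -> pd.DataFrame:
        out = self.signed_mean.copy()
        out.columns = [f"signed_mean_{c}" for c in out.columns]
        out["mean_abs"] = self.mean_abs
        return out


def _split_column(col):
    ch, feat = col.split("__", 1)
    return ch, feat


def aggregate_shap(attr: ShapAttributions, montage,
                   feature_columns=None) -> ShapSummary:
    """Reduce per-record attributions to the reporting aggregates."""
    cols = list(feature_columns or attr.feature_columns)
    classes = list(attr.class_order)
    vals = attr.values  # (n, n_class, n_feat)
    signed = pd.DataFrame(vals.mean(axis=0).T, index=cols, columns=classes)
    mean_abs = pd.Series(np.abs(vals).mean(axis=(0, 1)), index=cols)

    chans = [_split_column(c)[0] for c in cols]
    fams = [_split_column(c)[1] for c in cols]
    family_mean_abs = mean_abs.groupby(pd.Index(fams, name="family")).mean()
    # keep the fixed schema order for deterministic tie-breaks
    order = [f for f in FEATURE_NAMES if f in set(fams)]
    family_mean_abs = family_mean_abs.reindex(order)

    idx = pd.MultiIndex.from_arrays([chans, fams],
                                    names=["channel", "family"])
    by_channel = pd.DataFrame(vals.mean(axis=0).T, index=idx, columns=classes)
    return ShapSummary(signed_mean=signed, mean_abs=mean_abs,
                       family_mean_abs=family_mean_abs,
                       by_channel=by_channel)
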