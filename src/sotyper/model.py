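"""Subject-wise ensemble classification of SO type.

The classifier is an ensemble of five gradient-boosted tree models
(XGBoost, multiclass softmax-probability objective) trained on five
random 70–30 train/test splits taken at the *subject* level, so no
individual contributes events to both sides of any split.  Predicted
probabilities are the unweighted arithmetic mean across the five models.
Features enter raw (no normalization).

The public surface follows the Model/Results convention:
``SOTypeClassifier(table).fit(seed=0)`` returns an
:class:`SOTypeResults` carrying per-split held-out metrics, the pooled
confusion matrix, the analytic chance baseline and a ``summary()`` table;
prediction and SHAP attribution hang off the results object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .features import BASE_FEATURES, FEATURE_NAMES, FeatureTable
from .io import resolve_montage
from .label import SO_TYPES

CLASS_ORDER = SO_TYPES  # (Global, Frontal, Local); rows of confusion = true


@dataclass
class TrainingSettings:
    """XGBoost hyperparameters; defaults are deliberately untuned."""

    n_estimators: int = 500
    max_depth: int = 6
    learning_rate: float = 0.1
    tree_method: str = "hist"
    n_jobs: int = 1

    def to_params(self, seed):
        return dict(
            objective="multi:softprob",
            num_class=len(CLASS_ORDER),
            max_depth=self.max_depth,
            eta=self.learning_rate,
            tree_method=self.tree_method,
            nthread=self.n_jobs,
            seed=int(seed) % (2 ** 31),
        )


@dataclass
class SplitPlan:
    """Five random subject-level 70–30 partitions."""

    splits: list                 # [(train_subjects, test_subjects), ...]
    n_splits: int = 5
    train_fraction: float = 0.7
    seed: int = 0


def make_split_plan(subject_ids, n_splits=5, train_fraction=0.7,
                    seed=0) -> SplitPlan:
    """Random subject-level train/test partitions, reproducible by seed."""
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    subjects = sorted(set(subject_ids))
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for subject-wise splits")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(subjects)
        splits.append((set(perm[:n_train]), set(perm[n_train:])))
    return SplitPlan(splits=splits, n_splits=n_splits,
                     train_fraction=train_fraction, seed=seed)


class SchemaMismatchError(ValueError):
    def __init__(self, expected, got):
        missing = [c for c in expected if c not in got]
        extra = [c for c in got if c not in expected]
        super().__init__(
            f"feature schema mismatch; missing: {missing[:8]}, "
            f"unexpected: {extra[:8]}")


@dataclass
class EvalReport:
    accuracy: float
    log_loss: float
    confusion: np.ndarray        # 3×3 counts, rows = true in CLASS_ORDER
    chance_accuracy: float
    n_records: int

    def to_dict(self):
        return {
            "accuracy": self.accuracy,
            "log_loss": self.log_loss,
            "confusion": self.confusion.tolist(),
            "chance_accuracy": self.chance_accuracy,
            "n_records": self.n_records,
            "class_order": list(CLASS_ORDER),
        }


def evaluate(probabilities, true_labels) -> EvalReport:
    """Accuracy, multiclass log-loss, confusion counts and the Σp² chance
    baseline computed from the evaluated labels' proportions."""
    proba = np.asarray(probabilities, dtype=float)
    labels = list(true_labels)
    if len(labels) != len(proba):
        raise ValueError("probabilities and labels differ in length")
    unknown = set(labels) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"labels outside class vocabulary: {sorted(unknown)}")
    y = np.array([CLASS_ORDER.index(l) for l in labels])
    pred = proba.argmax(axis=1)
    acc = float((pred == y).mean())
    clipped = np.clip(proba, 1e-15, 1 - 1e-15)
    ll = float(-np.log(clipped[np.arange(len(y)), y]).mean())
    conf = np.zeros((3, 3), dtype=int)
    np.add.at(conf, (y, pred), 1)
    props = np.bincount(y, minlength=3) / len(y)
    chance = float((props ** 2).sum())
    return EvalReport(accuracy=acc, log_loss=ll, confusion=conf,
                      chance_accuracy=chance, n_records=len(y))


@dataclass
class TrainedEnsemble:
    """Five fitted boosters sharing one feature schema and class order."""

    boosters: list
    feature_columns: list
    montage_name: str
    feature_mode: str = "full"
    settings: TrainingSettings = field(default_factory=TrainingSettings)
    seed: int = 0

    def _check_schema(self, table: FeatureTable):
        if list(table.data.columns) != list(self.feature_columns):
            raise SchemaMismatchError(self.feature_columns,
                                      list(table.data.columns))

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        """Arithmetic mean of the five models' class probabilities."""
        self._check_schema(table)
        dmat = xgb.DMatrix(table.data.values,
                           feature_names=list(self.feature_columns))
        probs = [b.predict(dmat) for b in self.boosters]
        return np.mean(probs, axis=0)

    def predict(self, table: FeatureTable):
        proba = self.predict_proba(table)
        return [CLASS_ORDER[i] for i in proba.argmax(axis=1)]

    def save(self, directory):
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, b in enumerate(self.boosters):
            b.save_model(str(d / f"model_{i}.json"))
        (d / "schema.json").write_text(json.dumps({
            "feature_columns": list(self.feature_columns),
            "class_order": list(CLASS_ORDER),
        }, indent=1))
        (d / "metadata.json").write_text(json.dumps({
            "montage": self.montage_name,
            "feature_mode": self.feature_mode,
            "seed": self.seed,
            "n_estimators": self.settings.n_estimators,
            "max_depth": self.settings.max_depth,
            "learning_rate": self.settings.learning_rate,
        }, indent=1))

    @classmethod
    def load(cls, directory):
        d = Path(directory)
        schema = json.loads((d / "schema.json").read_text())
        meta = json.loads((d / "metadata.json").read_text())
        boosters = []
        for p in sorted(d.glob("model_*.json")):
            b = xgb.Booster()
            b.load_model(str(p))
            boosters.append(b)
        settings = TrainingSettings(
            n_estimators=meta["n_estimators"], max_depth=meta["max_depth"],
            learning_rate=meta["learning_rate"])
        return cls(boosters=boosters,
                   feature_columns=schema["feature_columns"],
                   montage_name=meta["montage"],
                   feature_mode=meta["feature_mode"],
                   settings=settings, seed=meta["seed"])


def train_ensemble(table: FeatureTable, plan: SplitPlan,
                   settings: TrainingSettings = None,
                   montage_name: str = "FCPO", feature_mode: str = "full"):
    """Fit one booster per split; returns (TrainedEnsemble, per-split reports).

    Per-split reports are EvalReports on each split's held-out subjects.
    """
    settings = settings or TrainingSettings()
    X = table.data.values
    y = np.array([CLASS_ORDER.index(l) for l in table.meta["so_type"]])
    subj = table.meta["subject_id"].values
    boosters, reports = [], []
    feature_names = list(table.data.columns)
    for si, (train_s, test_s) in enumerate(plan.splits):
        tr = np.isin(subj, list(train_s))
        te = np.isin(subj, list(test_s))
        present = set(np.unique(y[tr]))
        missing = [CLASS_ORDER[c] for c in range(3) if c not in present]
        if missing:
            raise ValueError(
                f"split {si}: class(es) {missing} absent from training side")
        dtrain = xgb.DMatrix(X[tr], label=y[tr], feature_names=feature_names)
        booster = xgb.train(settings.to_params(plan.seed + si), dtrain,
                            num_boost_round=settings.n_estimators)
        boosters.append(booster)
        if te.any():
            dtest = xgb.DMatrix(X[te], feature_names=feature_names)
            proba = booster.predict(dtest)
            reports.append(evaluate(
                proba, [CLASS_ORDER[c] for c in y[te]]))
        else:
            reports.append(None)
    ensemble = TrainedEnsemble(
        boosters=boosters, feature_columns=feature_names,
        montage_name=montage_name, feature_mode=feature_mode,
        settings=settings, seed=plan.seed)
    return ensemble, reports


def predict_proba(ensemble: TrainedEnsemble, table: FeatureTable):
    return ensemble.predict_proba(table)


# ---------------------------------------------------------------------------
# Model / Results surface

class SOTypeClassifier:
    """Multiclass SO-type model specification bound to a feature table.

    Parameters
    ----------
    table : FeatureTable
        Events × predictors with so_type / subject_id metadata.
    feature_mode : {"full", "base"}
        "base" keeps only the six waveform-coordinate features per channel.
    stage : optional {"N2", "N3"}
        Restrict training to events detected in one sleep stage.
    settings : TrainingSettings
    """

    def __init__(self, table: FeatureTable, montage=None, feature_mode="full",
                 stage=None, settings: TrainingSettings = None):
        self.montage = montage or table.montage or resolve_montage("FCPO")
        if feature_mode not in ("full", "base"):
            raise ValueError("feature_mode must be 'full' or 'base'")
        self.feature_mode = feature_mode
        self.stage = stage
        self.settings = settings or TrainingSettings()
        tbl = table
        if stage is not None:
            keep = (table.meta["stage"] == stage).values
            tbl = FeatureTable(table.data[keep].reset_index(drop=True),
                               table.meta[keep].reset_index(drop=True),
                               table.montage)
        expect = BASE_FEATURES if feature_mode == "base" else FEATURE_NAMES
        cols = [f"{ch}__{f}" for ch in self.montage.channels for f in expect]
        if list(tbl.data.columns) != cols:
            tbl = tbl.restrict(self.montage, feature_mode)
        self.table = tbl

    @classmethod
    def from_feature_table(cls, table, **kwargs):
        return cls(table, **kwargs)

    def fit(self, seed=0, n_splits=5, train_fraction=0.7, plan=None):
        """Train the five-split ensemble; returns :class:`SOTypeResults`."""
        plan = plan or make_split_plan(
            self.table.meta["subject_id"], n_splits=n_splits,
            train_fraction=train_fraction, seed=seed)
        ensemble, reports = train_ensemble(
            self.table, plan, self.settings,
            montage_name=self.montage.name, feature_mode=self.feature_mode)
        return SOTypeResults(self, ensemble, plan, reports)


class SOTypeResults:
    """Fitted ensemble with per-split held-out diagnostics."""

    def __init__(self, model: SOTypeClassifier, ensemble: TrainedEnsemble,
                 plan: SplitPlan, split_reports):
        self.model = model
        self.ensemble = ensemble
        self.plan = plan
        self.split_reports = split_reports

    # -- held-out (per-split) metrics ------------------------------------
    @property
    def heldout_accuracy(self):
        accs = [r.accuracy for r in self.split_reports if r is not None]
        return float(np.mean(accs))

    @property
    def heldout_log_loss(self):
        lls = [r.log_loss for r in self.split_reports if r is not None]
        return float(np.mean(lls))

    @property
    def confusion(self):
        """Pooled held-out confusion counts (rows = true)."""
        mats = [r.confusion for r in self.split_reports if r is not None]
        return np.sum(mats, axis=0)

    @property
    def chance_accuracy(self):
        y = self.model.table.meta["so_type"]
        props = y.value_counts(normalize=True).reindex(
            CLASS_ORDER).fillna(0.0).values
        return float((props ** 2).sum())

    def heldout_accuracy_against(self, labels):
        """Mean per-split held-out accuracy against an alternative label
        vector (e.g., generative archetypes); None entries are skipped."""
        labels = np.asarray(labels, dtype=object)
        X = self.model.table.data.values
        subj = self.model.table.meta["subject_id"].values
        cols = list(self.ensemble.feature_columns)
        accs = []
        for booster, (_tr, te_s) in zip(self.ensemble.boosters,
                                        self.plan.splits):
            te = np.isin(subj, list(te_s)) & (labels != None)  # noqa: E711
            if not te.any():
                continue
            dmat = xgb.DMatrix(X[te], feature_names=cols)
            pred = booster.predict(dmat).argmax(axis=1)
            true = np.array([CLASS_ORDER.index(l) for l in labels[te]])
            accs.append(float((pred == true).mean()))
        return float(np.mean(accs))

    # -- prediction on new tables ----------------------------------------
    def predict_proba(self, table: FeatureTable):
        return self.ensemble.predict_proba(table)

    def predict(self, table: FeatureTable):
        return self.ensemble.predict(table)

    def evaluate(self, table: FeatureTable) -> EvalReport:
        """Ensemble-averaged evaluation on an external table."""
        return evaluate(self.predict_proba(table),
                        list(table.meta["so_type"]))

    # -- explanation ------------------------------------------------------
    def shap_values(self, table: FeatureTable = None):
        from .explain import shap_attributions
        return shap_attributions(self.ensemble, table or self.model.table)

    def shap_summary(self, table: FeatureTable = None):
        from .explain import aggregate_shap, shap_attributions
        tbl = table or self.model.table
        attr = shap_attributions(self.ensemble, tbl)
        return aggregate_shap(attr, self.model.montage,
                              self.ensemble.feature_columns)

    def summary(self) -> str:
        conf = self.confusion
        lines = [
            "SO-type classification — subject-wise ensemble",
            "=" * 54,
            f"montage:            {self.model.montage.name} "
            f"({len(self.model.montage)} channels)",
            f"feature mode:       {self.model.feature_mode} "
            f"({len(self.ensemble.feature_columns)} predictors)",
            f"splits:             {self.plan.n_splits} x "
            f"{self.plan.train_fraction:.0%} train (subject-wise), "
            f"seed {self.plan.seed}",
            f"records:            {len(self.model.table)}",
            f"held-out accuracy:  {self.heldout_accuracy:.3f}",
            f"held-out log-loss:  {self.heldout_log_loss:.3f}",
            f"chance baseline:    {self.chance_accuracy:.3f}",
            "",
            "confusion (pooled held-out; rows = true "
            + "/".join(CLASS_ORDER) + "):",
        ]
        for i, row in enumerate(conf):
            lines.append(f"  {CLASS_ORDER[i]:<8}" +
                         "".join(f"{v:>8d}" for v in row))
        return "\n".join(lines)


def run_montage_battery(table: FeatureTable, montage_names=None,
                        feature_modes=("full", "base"), plan=None, seed=0,
                        settings: TrainingSettings = None) -> dict:
    """Retrain on every montage × feature-mode column subset of an
    FCPO-featurized table; returns {(montage, mode): SOTypeResults}."""
    montage_names = montage_names or ("FCPO", "FCP", "FCO", "FC", "F")
    results = {}
    for name in montage_names:
        montage = resolve_montage(name)
        for mode in feature_modes:
            sub = table.restrict(montage, mode)
            model = SOTypeClassifier(sub, montage=montage, feature_mode=mode,
                                     settings=settings)
            results[(name, mode)] = model.fit(seed=seed, plan=plan)
    return results
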