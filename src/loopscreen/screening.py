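"""Knowledge-based screening: curation, dataset assembly, model selection.

The curated interaction table pairs RNA motifs (joined miRNA-mRNA
sequences) with small molecules; every curated row is a "targeted"
positive.  Negatives are RNA x molecule combinations never observed as
paired, sampled uniformly without replacement at a 3:1 negative:positive
ratio.  Data are split 4/5 train : 1/5 test (stratified), and model
selection runs stratified 10-fold cross-validation over seven classifier
families, flagging a model when mean accuracy and ROC AUC exceed 0.8 with
standard deviations below 0.2.  The production model is a random forest
with the fixed hyperparameters below (entropy criterion, 200 trees,
random_state 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import (
    DEFAULT_MANIFEST,
    FeatureManifest,
    molecule_fingerprint,
    rna_feature_vector,
)
from .params import DEFAULT_MODEL, EnergyModel
from .sequences import RnaSequence, normalize

REQUIRED_COLUMNS = ("rna_id", "rna_sequence", "molecule_id", "smiles", "label")

#: the production random-forest hyperparameters, verbatim protocol constants
RF_HYPERPARAMETERS = {
    "bootstrap": True,
    "class_weight": None,
    "criterion": "entropy",
    "max_depth": None,
    "max_features": "auto",
    "max_leaf_nodes": None,
    "min_impurity_decrease": 0.0,
    "min_samples_leaf": 1,
    "min_samples_split": 2,
    "min_weight_fraction_leaf": 0.0,
    "n_estimators": 200,
    "n_jobs": 1,
    "oob_score": False,
    "random_state": 100,
    "verbose": 0,
    "warm_start": False,
}

SELECTION_MEAN_BOUND = 0.8
SELECTION_STD_BOUND = 0.2


class SchemaError(ValueError):
    """Interaction table does not match the documented schema."""


class DatasetError(ValueError):
    """Dataset construction failure."""


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def load_interaction_table(table) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Curate an interaction table (path or DataFrame).

    Removes rows whose RNA sequence is not valid RNA/DNA or whose SMILES
    does not parse; returns (curated table, rejection log).  The rejection
    log lists each removed row with its reason.
    """
    df = pd.read_csv(table) if not isinstance(table, pd.DataFrame) else table.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if df.empty:
        raise SchemaError("interaction table is empty")
    keep, rejected = [], []
    for idx, row in df.iterrows():
        reason = None
        try:
            normalize(str(row["rna_sequence"]))
        except Exception:
            reason = "invalid_sequence"
        if reason is None and Chem.MolFromSmiles(str(row["smiles"])) is None:
            reason = "invalid_smiles"
        if reason is None:
            keep.append(idx)
        else:
            rejected.append(
                {
                    "row": idx,
                    "rna_id": row["rna_id"],
                    "molecule_id": row["molecule_id"],
                    "reason": reason,
                }
            )
    curated = df.loc[keep].reset_index(drop=True)
    log = pd.DataFrame(rejected, columns=["row", "rna_id", "molecule_id", "reason"])
    return curated, log


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    records: pd.DataFrame  # rna_id, rna_sequence, molecule_id, smiles, label
    X: np.ndarray
    y: np.ndarray
    manifest: FeatureManifest
    seed: int
    split: np.ndarray | None = None  # "train"/"test" per record
    folds: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def train_indices(self) -> np.ndarray:
        if self.split is None:
            return np.arange(self.n)
        return np.flatnonzero(self.split == "train")

    @property
    def test_indices(self) -> np.ndarray:
        if self.split is None:
            return np.array([], dtype=int)
        return np.flatnonzero(self.split == "test")


class _FeatureCache:
    """Per-RNA fold/feature and per-molecule fingerprint caches."""

    def __init__(self, manifest: FeatureManifest, model: EnergyModel):
        self.manifest = manifest
        self.model = model
        self._rna: dict[str, np.ndarray] = {}
        self._mol: dict[str, np.ndarray] = {}

    def rna(self, rna_id: str, sequence: str) -> np.ndarray:
        if rna_id not in self._rna:
            seq = RnaSequence(id=rna_id, bases=sequence, kind="joined")
            self._rna[rna_id] = rna_feature_vector(seq, self.manifest, self.model).values
        return self._rna[rna_id]

    def mol(self, molecule_id: str, smiles: str) -> np.ndarray:
        if molecule_id not in self._mol:
            self._mol[molecule_id] = molecule_fingerprint(
                smiles, record_id=molecule_id
            ).bits
        return self._mol[molecule_id]

    def row(self, rna_id, sequence, molecule_id, smiles) -> np.ndarray:
        return np.concatenate([self.rna(rna_id, sequence), self.mol(molecule_id, smiles)])


def build_dataset(
    records: pd.DataFrame,
    neg_ratio: int = 3,
    seed: int = 0,
    manifest: FeatureManifest = DEFAULT_MANIFEST,
    model: EnergyModel = DEFAULT_MODEL,
) -> Dataset:
    """Label curated pairs as positives and sample unobserved negatives.

    Exactly ``neg_ratio`` negatives per positive, drawn uniformly without
    replacement from the unobserved RNA x molecule grid; reproducible under
    ``seed``.
    """
    positives = records.drop_duplicates(subset=["rna_id", "molecule_id"]).reset_index(
        drop=True
    )
    n_pos = len(positives)
    if n_pos == 0:
        raise DatasetError("no positive (targeted) records")
    rnas = positives.drop_duplicates("rna_id")[["rna_id", "rna_sequence"]]
    mols = positives.drop_duplicates("molecule_id")[["molecule_id", "smiles"]]
    observed = set(zip(positives["rna_id"], positives["molecule_id"]))
    universe = [
        (r.rna_id, r.rna_sequence, m.molecule_id, m.smiles)
        for r in rnas.itertuples()
        for m in mols.itertuples()
        if (r.rna_id, m.molecule_id) not in observed
    ]
    n_neg = neg_ratio * n_pos
    if n_neg > len(universe):
        feasible = len(universe) // n_pos
        raise DatasetError(
            f"cannot sample {n_neg} negatives from {len(universe)} unobserved pairs "
            f"(maximum feasible ratio {feasible})"
        )
    rng = np.random.default_rng(seed)
    chosen = [universe[i] for i in rng.choice(len(universe), size=n_neg, replace=False)]
    neg_df = pd.DataFrame(
        chosen, columns=["rna_id", "rna_sequence", "molecule_id", "smiles"]
    )
    neg_df["label"] = "non_targeted"
    pos_df = positives[["rna_id", "rna_sequence", "molecule_id", "smiles"]].copy()
    pos_df["label"] = "targeted"
    all_df = pd.concat([pos_df, neg_df], ignore_index=True)
    cache = _FeatureCache(manifest, model)
    X = np.vstack(
        [
            cache.row(r.rna_id, r.rna_sequence, r.molecule_id, r.smiles)
            for r in all_df.itertuples()
        ]
    )
    y = (all_df["label"] == "targeted").to_numpy(dtype=int)
    return Dataset(records=all_df, X=X, y=y, manifest=manifest, seed=seed)


def split_dataset(
    dataset: Dataset, train_fraction: float = 0.8, seed: int = 0
) -> Dataset:
    """Stratified train/test assignment (4/5 train by default), in place."""
    if dataset.n < 5:
        raise DatasetError("need at least 5 records to split")
    idx = np.arange(dataset.n)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        random_state=seed,
        stratify=dataset.y,
        shuffle=True,
    )
    split = np.empty(dataset.n, dtype=object)
    split[train_idx] = "train"
    split[test_idx] = "test"
    dataset.split = split
    return dataset


# ---------------------------------------------------------------------------
# model specs and comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    fingerprint: str = "morgan"


def rf_spec() -> ModelSpec:
    return ModelSpec(family="random_forest", hyperparameters=dict(RF_HYPERPARAMETERS))


def default_model_specs(fingerprint: str = "morgan") -> list[ModelSpec]:
    mk = lambda family, **hp: ModelSpec(family, hp, fingerprint)
    return [
        mk("logistic_regression", max_iter=2000, random_state=100),
        mk("linear_discriminant"),
        mk("k_nearest_neighbors"),
        mk("decision_tree", random_state=100),
        mk("naive_bayes"),
        mk("support_vector", random_state=100),
        rf_spec(),
    ]


_FAMILIES = {
    "logistic_regression": LogisticRegression,
    "linear_discriminant": LinearDiscriminantAnalysis,
    "k_nearest_neighbors": KNeighborsClassifier,
    "decision_tree": DecisionTreeClassifier,
    "naive_bayes": GaussianNB,
    "support_vector": SVC,
    "random_forest": RandomForestClassifier,
}


def build_estimator(spec: ModelSpec):
    if spec.family not in _FAMILIES:
        raise ValueError(f"unknown model family {spec.family!r}")
    hp = dict(spec.hyperparameters)
    if spec.family == "random_forest" and hp.get("max_features") == "auto":
        hp["max_features"] = "sqrt"  # classical "auto" for classification
    return _FAMILIES[spec.family](**hp)


def _continuous_scores(est, X) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


@dataclass
class ModelComparison:
    table: pd.DataFrame  # per family: mean/std of accuracy and roc_auc, flags
    fold_metrics: pd.DataFrame  # per (family, fold): accuracy, roc_auc

    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "family"])


def compare_models(
    dataset: Dataset,
    specs: list[ModelSpec] | None = None,
    k: int = 10,
    seed: int = 0,
) -> ModelComparison:
    """Stratified k-fold comparison of classifier families.

    A family is flagged as selected iff mean > 0.8 and STD < 0.2 for both
    accuracy and ROC AUC.  Families that fail to fit are recorded as
    failed, never silently dropped.
    """
    specs = specs or default_model_specs()
    idx = dataset.train_indices
    if k > len(idx):
        raise DatasetError(f"k={k} exceeds training size {len(idx)}")
    X, y = dataset.X[idx], dataset.y[idx]
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows, fold_rows = [], []
    for spec in specs:
        accs, aucs = [], []
        failed = False
        try:
            for fold, (tr, te) in enumerate(cv.split(X, y), start=1):
                est = build_estimator(spec)
                est.fit(X[tr], y[tr])
                acc = accuracy_score(y[te], est.predict(X[te]))
                auc = roc_auc_score(y[te], _continuous_scores(est, X[te]))
                accs.append(acc)
                aucs.append(auc)
                fold_rows.append(
                    {"family": spec.family, "fold": fold, "accuracy": acc, "roc_auc": auc}
                )
        except Exception as exc:  # noqa: BLE001 - recorded, not dropped
            failed = True
            error = str(exc)
        if failed:
            rows.append({"family": spec.family, "failed": True, "error": error})
            continue
        accs, aucs = np.array(accs), np.array(aucs)
        stats = {
            "family": spec.family,
            "failed": False,
            "error": "",
            "mean_accuracy": accs.mean(),
            "std_accuracy": accs.std(ddof=0),
            "mean_roc_auc": aucs.mean(),
            "std_roc_auc": aucs.std(ddof=0),
        }
        stats["selected"] = bool(
            stats["mean_accuracy"] > SELECTION_MEAN_BOUND
            and stats["std_accuracy"] < SELECTION_STD_BOUND
            and stats["mean_roc_auc"] > SELECTION_MEAN_BOUND
            and stats["std_roc_auc"] < SELECTION_STD_BOUND
        )
        rows.append(stats)
    table = pd.DataFrame(rows)
    if "selected" in table.columns:
        table["selected"] = table["selected"].fillna(False).astype(bool)
    return ModelComparison(table=table, fold_metrics=pd.DataFrame(fold_rows))


# ---------------------------------------------------------------------------
# training, prediction, importances
# ---------------------------------------------------------------------------

@dataclass
class ModelArtifact:
    estimator: object
    spec: ModelSpec
    manifest: FeatureManifest
    seed: int

    def feature_names(self) -> list[str]:
        from .features import FINGERPRINT_BITS

        return self.manifest.names + [f"fp_bit_{i}" for i in range(FINGERPRINT_BITS)]


def train_model(dataset: Dataset, spec: ModelSpec | None = None) -> ModelArtifact:
    """Fit on the train split (whole dataset if unsplit)."""
    spec = spec or rf_spec()
    idx = dataset.train_indices
    est = build_estimator(spec)
    n_expected = len(dataset.manifest) + 1024
    if dataset.X.shape[1] != n_expected:
        raise DatasetError(
            f"feature matrix width {dataset.X.shape[1]} != manifest {n_expected}"
        )
    est.fit(dataset.X[idx], dataset.y[idx])
    return ModelArtifact(estimator=est, spec=spec, manifest=dataset.manifest, seed=dataset.seed)


def save_model(artifact: ModelArtifact, path) -> None:
    joblib.dump(
        {
            "estimator": artifact.estimator,
            "spec": artifact.spec,
            "manifest_frame": artifact.manifest.to_frame(),
            "manifest_version": artifact.manifest.version,
            "seed": artifact.seed,
        },
        path,
    )


def load_model(path) -> ModelArtifact:
    bundle = joblib.load(path)
    manifest = FeatureManifest.from_frame(
        bundle["manifest_frame"], version=bundle["manifest_version"]
    )
    return ModelArtifact(
        estimator=bundle["estimator"],
        spec=bundle["spec"],
        manifest=manifest,
        seed=bundle["seed"],
    )


def predict_scores(
    artifact: ModelArtifact,
    candidates: pd.DataFrame,
    model: EnergyModel = DEFAULT_MODEL,
) -> pd.DataFrame:
    """Probability of "targeted" per candidate, ranked descending.

    ``candidates`` needs columns rna_id, rna_sequence, molecule_id, smiles.
    Ties break on molecule_id.
    """
    for c in ("rna_id", "rna_sequence", "molecule_id", "smiles"):
        if c not in candidates.columns:
            raise SchemaError(f"candidates missing column {c!r}")
    cache = _FeatureCache(artifact.manifest, model)
    X = np.vstack(
        [
            cache.row(r.rna_id, r.rna_sequence, r.molecule_id, r.smiles)
            for r in candidates.itertuples()
        ]
    )
    if X.shape[1] != getattr(artifact.estimator, "n_features_in_", X.shape[1]):
        raise DatasetError("candidate features do not match the trained model")
    probs = _continuous_scores(artifact.estimator, X)
    out = candidates.copy()
    out["probability"] = probs
    out = out.sort_values(
        ["probability", "molecule_id"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class FeatureImportanceReport:
    table: pd.DataFrame  # feature, category, importance (sorted desc)
    category_share: dict
    n_above_threshold: int
    threshold: float


def feature_importance(
    artifact: ModelArtifact, threshold: float = 0.001
) -> FeatureImportanceReport:
    """Ranked variable importances with RNA-vs-molecule aggregation."""
    est = artifact.estimator
    if not hasattr(est, "feature_importances_"):
        raise ValueError(f"{artifact.spec.family} exposes no feature importances")
    names = artifact.feature_names()
    imp = np.asarray(est.feature_importances_)
    cats = ["rna"] * len(artifact.manifest) + ["molecule"] * (len(names) - len(artifact.manifest))
    df = (
        pd.DataFrame({"feature": names, "category": cats, "importance": imp})
        .sort_values(["importance", "feature"], ascending=[False, True])
        .reset_index(drop=True)
    )
    share = df.groupby("category")["importance"].sum().to_dict()
    return FeatureImportanceReport(
        table=df,
        category_share=share,
        n_above_threshold=int((imp > threshold).sum()),
        threshold=threshold,
    )
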