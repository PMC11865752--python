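"""Family-specific active/decoy classifiers for fast first-stage screening.

For each inhibitor family a binary classifier separates family actives
from property-matched decoys.  The workflow: split the actives 80/20 into
train/test, generate ~50 decoys per active from a candidate pool
(property-matched but structurally dissimilar — a simplified stand-in for
DUDE-style decoy services), prune correlated molecular descriptors, shrink
the training decoys to one exemplar per k-means cluster (k = number of
training actives, so training is balanced), fit four algorithms (logistic
regression, SVM, decision tree, random forest) with cross-validated
hyperparameter search maximizing ROC-AUC, evaluate on the unbalanced test
library, and select one model by a four-term objective.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator

from .chemclust import MoleculeRecord
from .scoring import MetricReport, classification_metrics


@dataclass
class DescriptorTable:
    """Molecules × molecular descriptors, with optional active/decoy labels."""

    mol_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    labels: list[str] | None = None  # "active" | "decoy" per row

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.mol_ids), len(self.descriptor_names)):
            raise ValueError("values shape must be (n_mols, n_descriptors)")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("descriptor names must be unique")
        if np.isnan(v).any():
            raise ValueError("descriptor table contains missing values")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.mol_ids, columns=self.descriptor_names)
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def subset_columns(self, names: Sequence[str]) -> "DescriptorTable":
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorTable(
            mol_ids=list(self.mol_ids),
            descriptor_names=list(names),
            values=self.values[:, idx],
            labels=list(self.labels) if self.labels is not None else None,
        )


@dataclass
class SplitLibraries:
    train_actives: list[MoleculeRecord]
    test_actives: list[MoleculeRecord]
    train_decoys: list[MoleculeRecord] = field(default_factory=list)
    test_decoys: list[MoleculeRecord] = field(default_factory=list)
    seed: int = 0


@dataclass
class TrainedModel:
    algorithm: str  # logistic_regression | svm | decision_tree | random_forest
    estimator: object
    hyperparameters: dict
    retained_descriptors: list[str]
    cv_roc_auc: float
    seed: int
    test_metrics: MetricReport | None = None

    def predict_scores(self, table: DescriptorTable) -> np.ndarray:
        sub = table.subset_columns(self.retained_descriptors)
        return self.estimator.predict_proba(sub.values)[:, 1]


def split_actives(
    actives: Sequence[MoleculeRecord], test_fraction: float = 0.2, seed: int = 0
) -> SplitLibraries:
    """Uniform random 80/20 split; test size = floor(n × test_fraction)."""
    if len(actives) < 2:
        raise ValueError("need at least 2 actives to split")
    n_test = int(len(actives) * test_fraction)
    rng = random.Random(seed)
    idx = list(range(len(actives)))
    rng.shuffle(idx)
    test_idx = set(idx[:n_test])
    return SplitLibraries(
        train_actives=[a for i, a in enumerate(actives) if i not in test_idx],
        test_actives=[a for i, a in enumerate(actives) if i in test_idx],
        seed=seed,
    )


# physicochemical bin widths for property matching
DEFAULT_PROPERTY_BINS: dict[str, float] = {
    "mw": 25.0,         # g/mol
    "logp": 1.0,
    "hbd": 1.0,
    "hba": 1.0,
    "rotb": 2.0,
}


def _props(smiles: str) -> dict[str, float] | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return {
        "mw": Descriptors.MolWt(mol),
        "logp": Crippen.MolLogP(mol),
        "hbd": Lipinski.NumHDonors(mol),
        "hba": Lipinski.NumHAcceptors(mol),
        "rotb": Lipinski.NumRotatableBonds(mol),
    }


def generate_decoys(
    actives: Sequence[MoleculeRecord],
    pool: Sequence[MoleculeRecord],
    ratio: int = 50,
    property_bins: Mapping[str, float] = DEFAULT_PROPERTY_BINS,
    max_similarity: float = 0.4,
    seed: int = 0,
) -> tuple[list[MoleculeRecord], dict[str, int]]:
    """Property-matched, structurally dissimilar decoys from a pool.

    Per active, up to ``ratio`` pool molecules whose MW, logP, H-bond
    donor/acceptor and rotatable-bond counts fall within the configured
    bins of the active's values, and whose Morgan-fingerprint Tanimoto to
    EVERY active stays below ``max_similarity``.  Returns the decoy list
    and a per-active shortfall report (requested minus found).
    """
    if not pool:
        raise ValueError("empty decoy pool")
    active_ids = {a.mol_id for a in actives}
    if active_ids & {p.mol_id for p in pool}:
        raise ValueError("pool must be disjoint from actives")
    if not actives:
        return [], {}
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)

    def fp(smiles):
        mol = Chem.MolFromSmiles(smiles)
        return None if mol is None else gen.GetFingerprint(mol)

    active_fps = [f for f in (fp(a.structure) for a in actives) if f is not None]
    pool_props = {p.mol_id: _props(p.structure) for p in pool}
    rng = random.Random(seed)
    order = list(pool)
    rng.shuffle(order)

    chosen: list[MoleculeRecord] = []
    used: set[str] = set()
    shortfall: dict[str, int] = {}
    for act in actives:
        ap = _props(act.structure)
        found = 0
        if ap is not None:
            for cand in order:
                if found >= ratio:
                    break
                if cand.mol_id in used:
                    continue
                cp = pool_props[cand.mol_id]
                if cp is None:
                    continue
                if any(abs(cp[k] - ap[k]) > w for k, w in property_bins.items()):
                    continue
                cfp = fp(cand.structure)
                if cfp is None:
                    continue
                sims = DataStructs.BulkTanimotoSimilarity(cfp, active_fps)
                if max(sims) >= max_similarity:
                    continue
                chosen.append(cand)
                used.add(cand.mol_id)
                found += 1
        if found < ratio:
            shortfall[act.mol_id] = ratio - found
    return chosen, shortfall


def compute_descriptors(
    library: Sequence[MoleculeRecord], labels: Mapping[str, str] | None = None
) -> DescriptorTable:
    """RDKit physicochemical descriptor table for a molecule library."""
    names = [
        "MolWt", "MolLogP", "NumHDonors", "NumHAcceptors",
        "NumRotatableBonds", "TPSA", "RingCount", "NumAromaticRings",
        "FractionCSP3", "HeavyAtomCount",
    ]
    funcs = [
        Descriptors.MolWt, Crippen.MolLogP, Lipinski.NumHDonors,
        Lipinski.NumHAcceptors, Lipinski.NumRotatableBonds,
        Descriptors.TPSA, Descriptors.RingCount,
        Descriptors.NumAromaticRings, Lipinski.FractionCSP3,
        Descriptors.HeavyAtomCount,
    ]
    rows, ids = [], []
    for rec in library:
        mol = Chem.MolFromSmiles(rec.structure)
        if mol is None:
            raise ValueError(f"unparseable structure: {rec.mol_id}")
        rows.append([float(f(mol)) for f in funcs])
        ids.append(rec.mol_id)
    return DescriptorTable(
        mol_ids=ids,
        descriptor_names=names,
        values=np.array(rows),
        labels=[labels[i] for i in ids] if labels is not None else None,
    )


def prune_correlated(table: DescriptorTable, r_cut: float = 0.9) -> list[str]:
    """Correlation pruning of descriptors.

    Constant columns are dropped first.  Columns are min–max scaled, the
    Pearson correlation matrix is computed, pairs with |r| ≥ ``r_cut`` are
    grouped by transitive closure, and each group keeps its member with
    the highest scaled variance (ties → first in column order).  The
    retained set contains no pair at or above the cut.
    """
    if table.values.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    v = table.values
    keep_idx = [j for j in range(v.shape[1]) if np.ptp(v[:, j]) > 0]
    if len(keep_idx) < len(table.descriptor_names):
        dropped = [table.descriptor_names[j] for j in range(v.shape[1]) if j not in keep_idx]
        warnings.warn(f"constant descriptors dropped: {dropped}")
    if len(keep_idx) < 2:
        raise ValueError("fewer than 2 usable (non-constant) columns")
    x = v[:, keep_idx]
    scaled = (x - x.min(axis=0)) / (x.max(axis=0) - x.min(axis=0))
    var = scaled.var(axis=0, ddof=1)
    corr = np.corrcoef(x, rowvar=False)
    n = len(keep_idx)

    # union-find over |r| >= r_cut edges (transitive closure of pairwise rule)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if abs(corr[i, j]) >= r_cut:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    retained_local = []
    for members in groups.values():
        best = max(members, key=lambda j: (var[j], -j))
        retained_local.append(best)
    retained_local.sort()
    return [table.descriptor_names[keep_idx[j]] for j in retained_local]


def balance_decoys_kmeans(
    decoy_table: DescriptorTable, k: int, seed: int = 0
) -> list[str]:
    """One exemplar decoy per k-means cluster on scaled retained descriptors.

    k is set to the number of training actives so the resulting training
    set is balanced.  Per cluster the decoy nearest the centroid
    (Euclidean; ties → smallest mol_id) is returned; exactly k distinct
    decoys.
    """
    n = len(decoy_table.mol_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} decoys")
    x = decoy_table.values
    rng = x.max(axis=0) - x.min(axis=0)
    rng[rng == 0] = 1.0
    scaled = (x - x.min(axis=0)) / rng
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(scaled)
    out = []
    for c in range(k):
        members = np.flatnonzero(km.labels_ == c)
        dist = np.linalg.norm(scaled[members] - km.cluster_centers_[c], axis=1)
        ids = [decoy_table.mol_ids[m] for m in members]
        best = min(zip(dist, ids), key=lambda t: (t[0], t[1]))[1]
        out.append(best)
    return sorted(out)


# compact, fixed hyperparameter grids so a family trains in seconds
SEARCH_SPACES: dict[str, tuple[object, dict]] = {
    "logistic_regression": (
        LogisticRegression(max_iter=5000),
        {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    ),
    "svm": (
        # calibration wrapper gives the margin classifier a predict_proba
        CalibratedClassifierCV(SVC(), ensemble=False),
        {"clf__estimator__C": [0.1, 1.0, 10.0], "clf__estimator__gamma": ["scale", 0.1]},
    ),
    "decision_tree": (
        DecisionTreeClassifier(),
        {"clf__max_depth": [3, 5, None], "clf__min_samples_leaf": [1, 5]},
    ),
    "random_forest": (
        RandomForestClassifier(n_estimators=100),
        {"clf__max_depth": [3, None], "clf__max_features": ["sqrt", None]},
    ),
}


def train_models(
    balanced: DescriptorTable,
    cv_folds: int = 5,
    seed: int = 0,
    r_cut: float = 0.9,
) -> list[TrainedModel]:
    """Four classifiers with stratified-CV hyperparameter search on ROC-AUC.

    Correlated descriptors are pruned on the balanced training table; each
    algorithm's small fixed grid is searched with stratified ``cv_folds``-
    fold CV maximizing mean ROC-AUC, then refit on the full balanced set.
    """
    if balanced.labels is None:
        raise ValueError("balanced table must carry labels")
    y = np.array([lab == "active" for lab in balanced.labels])
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")
    retained = prune_correlated(balanced, r_cut=r_cut)
    sub = balanced.subset_columns(retained)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    models = []
    for name, (base, grid) in SEARCH_SPACES.items():
        est = clone(base)
        if "random_state" in est.get_params(deep=False):
            est.set_params(random_state=seed)
        pipe = Pipeline([("scale", StandardScaler()), ("clf", est)])
        search = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv, n_jobs=1)
        search.fit(sub.values, y)
        models.append(
            TrainedModel(
                algorithm=name,
                estimator=search.best_estimator_,
                hyperparameters={
                    k.removeprefix("clf__").removeprefix("estimator__"): v
                    for k, v in search.best_params_.items()
                },
                retained_descriptors=retained,
                cv_roc_auc=float(search.best_score_),
                seed=seed,
            )
        )
    return models


def evaluate_models(
    models: Sequence[TrainedModel], test_table: DescriptorTable
) -> list[TrainedModel]:
    """Score each model on the unbalanced test library; attach MetricReports."""
    if test_table.labels is None:
        raise ValueError("test table must carry labels")
    y = np.array([lab == "active" for lab in test_table.labels])
    out = []
    for m in models:
        missing = set(m.retained_descriptors) - set(test_table.descriptor_names)
        if missing:
            raise ValueError(f"test table lacks descriptors: {sorted(missing)}")
        scores = m.predict_scores(test_table)
        report = classification_metrics(scores, y, threshold=0.5)
        out.append(
            TrainedModel(
                algorithm=m.algorithm,
                estimator=m.estimator,
                hyperparameters=m.hyperparameters,
                retained_descriptors=m.retained_descriptors,
                cv_roc_auc=m.cv_roc_auc,
                seed=m.seed,
                test_metrics=report,
            )
        )
    return out


_TIE_ORDER = ["random_forest", "svm", "logistic_regression", "decision_tree"]


def select_model(
    candidates: Sequence[TrainedModel],
    extra_metrics: Mapping[str, tuple[float, float, float]],
) -> TrainedModel:
    """Pick the deployment model by a four-term objective.

    Objective = test specificity + true-negative fraction on the decoys
    excluded during balancing + family-active recall + non-family
    rejection rate, each in [0, 1], unweighted.  Ties break in the fixed
    order random forest > SVM > logistic regression > decision tree.
    """
    if not candidates:
        raise ValueError("no candidates")
    scored = []
    for m in candidates:
        if m.test_metrics is None:
            raise ValueError(f"{m.algorithm}: missing test metrics")
        if m.algorithm not in extra_metrics:
            raise ValueError(f"{m.algorithm}: missing extra metrics")
        terms = (m.test_metrics.specificity, *extra_metrics[m.algorithm])
        if any(not 0 <= t <= 1 for t in terms):
            raise ValueError(f"{m.algorithm}: objective terms must lie in [0,1]")
        scored.append((sum(terms), -_TIE_ORDER.index(m.algorithm), m))
    return max(scored, key=lambda t: (t[0], t[1]))[2]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_descriptor_csv(path: str | Path) -> DescriptorTable:
    """Read a descriptor CSV: ``mol_id`` first, optional ``label`` column."""
    df = pd.read_csv(path)
    labels = df["label"].tolist() if "label" in df.columns else None
    names = [c for c in df.columns if c not in ("mol_id", "label")]
    return DescriptorTable(
        mol_ids=df["mol_id"].astype(str).tolist(),
        descriptor_names=names,
        values=df[names].to_numpy(dtype=float),
        labels=labels,
    )


def write_descriptor_csv(table: DescriptorTable, path: str | Path) -> None:
    df = table.to_frame().reset_index(names="mol_id")
    df.to_csv(path, index=False)


MODEL_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "algorithm": model.algorithm,
            "estimator": model.estimator,
            "hyperparameters": model.hyperparameters,
            "retained_descriptors": model.retained_descriptors,
            "cv_roc_auc": model.cv_roc_auc,
            "seed": model.seed,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    doc = joblib.load(path)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("incompatible model artifact version")
    return TrainedModel(
        algorithm=doc["algorithm"],
        estimator=doc["estimator"],
        hyperparameters=doc["hyperparameters"],
        retained_descriptors=doc["retained_descriptors"],
        cv_roc_auc=doc["cv_roc_auc"],
        seed=doc["seed"],
    )
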