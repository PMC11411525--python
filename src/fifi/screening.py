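"""Virtual-screening workflows and evaluation.

Implements the comparison workflows around the fingerprints: Tanimoto
similarity search (ligand-based), docking-score ranking
(structure-based), the sequential top-1% hybrid (similarity filter,
then docking rank), the parallel consensus (elementwise product of two
model probabilities), ML classifiers over any fingerprint matrix, and
the evaluation utilities: AUPRC (average precision), IC50 quantile
binning into activity labels, and Bemis–Murcko scaffold diversity of
top-ranked actives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy import sparse
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

ML_ALGORITHMS = ("logistic", "svm_linear", "svm_rbf", "svm_tanimoto", "random_forest")

# Small hyperparameter grids used when tune=True (5-fold CV on training
# data only).
TUNING_GRIDS: dict[str, dict[str, list]] = {
    "logistic": {"C": [0.1, 1.0, 10.0]},
    "svm_linear": {"C": [0.1, 1.0, 10.0]},
    "svm_rbf": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01]},
    "svm_tanimoto": {"C": [0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [100, 300], "max_depth": [None, 10]},
}


@dataclass
class ScreeningSet:
    """A labeled compound set with its fingerprint matrix."""

    compound_ids: list[str]
    fingerprints: np.ndarray | sparse.spmatrix
    labels: np.ndarray  # 1 = active, 0 = inactive
    docking_scores: Optional[np.ndarray] = None  # lower = better
    role: str = "train"
    structures: Optional[list[str]] = None  # SMILES, for scaffold analysis

    def __post_init__(self) -> None:
        n = len(self.compound_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.fingerprints.shape[0] != n or len(self.labels) != n:
            raise ValueError("compound ids, fingerprints and labels must align")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")
        if self.docking_scores is not None:
            self.docking_scores = np.asarray(self.docking_scores, dtype=float)
            if len(self.docking_scores) != n:
                raise ValueError("docking scores must align with compounds")

    @property
    def n(self) -> int:
        return len(self.compound_ids)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())

    def subset(self, mask: np.ndarray, role: Optional[str] = None) -> "ScreeningSet":
        idx = np.flatnonzero(mask)
        return ScreeningSet(
            compound_ids=[self.compound_ids[i] for i in idx],
            fingerprints=self.fingerprints[idx],
            labels=self.labels[idx],
            docking_scores=None
            if self.docking_scores is None
            else self.docking_scores[idx],
            role=role or self.role,
            structures=None
            if self.structures is None
            else [self.structures[i] for i in idx],
        )


@dataclass(frozen=True)
class ScreenConfig:
    """Workflow parameters."""

    sequential_top_fraction: float = 0.01
    distinct_similarity_threshold: float = 0.2
    ml_algorithm: str = "random_forest"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sequential_top_fraction <= 1:
            raise ValueError("sequential_top_fraction must be in (0, 1]")
        if not 0 < self.distinct_similarity_threshold < 1:
            raise ValueError("distinct_similarity_threshold must be in (0, 1)")
        if self.ml_algorithm not in ML_ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.ml_algorithm!r}")


@dataclass(frozen=True)
class BinningConfig:
    """IC50 quantile-binning scheme: 25 equal-count bins, bin 1 = most
    potent; bins 1–7 active, 11–25 inactive, 8–10 dropped."""

    n_bins: int = 25
    active_bins: tuple[int, int] = (1, 7)
    inactive_bins: tuple[int, int] = (11, 25)

    def __post_init__(self) -> None:
        if self.active_bins[1] >= self.inactive_bins[0]:
            raise ValueError("active and inactive bin ranges must not overlap")
        if self.inactive_bins[1] != self.n_bins:
            raise ValueError("inactive bins must extend to the last bin")


def _dense(x) -> np.ndarray:
    if sparse.issparse(x):
        return np.asarray(x.todense())
    return np.asarray(x)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| on bit vectors; the
    empty/empty case is defined as 0."""
    a = np.asarray(a).ravel().astype(bool)
    b = np.asarray(b).ravel().astype(bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(A, B) -> np.ndarray:
    """Pairwise Tanimoto similarities between the rows of A and B."""
    A = _dense(A).astype(bool)
    B = _dense(B).astype(bool)
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint widths differ")
    inter = A.astype(np.int64) @ B.astype(np.int64).T
    card_a = A.sum(axis=1)[:, None]
    card_b = B.sum(axis=1)[None, :]
    union = card_a + card_b - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def nn_similarity(test_fps, train_fps) -> tuple[np.ndarray, np.ndarray]:
    """Per-test-row maximum Tanimoto similarity to any training row.

    Returns (max similarity, argmax train index) per test row.
    """
    sims = tanimoto_matrix(test_fps, train_fps)
    if sims.shape[1] == 0:
        raise ValueError("training set must be non-empty")
    return sims.max(axis=1), sims.argmax(axis=1)


def split_distinct(
    test: ScreeningSet, train: ScreeningSet, threshold: float = 0.2
) -> ScreeningSet:
    """Keep test compounds with nearest-training similarity strictly
    below ``threshold`` (the 'distinct' test set)."""
    best, _ = nn_similarity(test.fingerprints, train.fingerprints)
    mask = best < threshold
    if not mask.any():
        import warnings

        warnings.warn("distinct split removed every test compound", stacklevel=2)
    return test.subset(mask, role="test")


def sequential_screen(
    similarities: np.ndarray,
    docking_scores: np.ndarray,
    top_fraction: float = 0.01,
) -> np.ndarray:
    """Sequential hybrid ranking: similarity filter, then docking sort.

    Keeps the ceil(top_fraction * n) most similar compounds (stable
    input-order tie break), re-ranks the kept set ascending by docking
    score (lower = better), and appends the rest ordered by descending
    similarity.  Returns compound indices, best first.
    """
    similarities = np.asarray(similarities, dtype=float)
    docking_scores = np.asarray(docking_scores, dtype=float)
    if similarities.shape != docking_scores.shape:
        raise ValueError("similarities and docking scores must align")
    n = len(similarities)
    n_keep = math.ceil(top_fraction * n)
    order = np.argsort(-similarities, kind="stable")
    kept, rest = order[:n_keep], order[n_keep:]
    if np.isnan(docking_scores[kept]).any():
        raise ValueError("kept compounds must all have docking scores")
    kept_sorted = kept[np.argsort(docking_scores[kept], kind="stable")]
    return np.concatenate([kept_sorted, rest])


def consensus_score(p_ligand: np.ndarray, p_structure: np.ndarray) -> np.ndarray:
    """Parallel hybrid score: elementwise product of two probability
    vectors (ligand-based × structure-based)."""
    p_ligand = np.asarray(p_ligand, dtype=float)
    p_structure = np.asarray(p_structure, dtype=float)
    if p_ligand.shape != p_structure.shape:
        raise ValueError("probability vectors must align")
    for p in (p_ligand, p_structure):
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
    return p_ligand * p_structure


class TanimotoKernelSVC(BaseEstimator, ClassifierMixin):
    """SVC with a Tanimoto-similarity kernel on bit-vector inputs.

    The Gram matrix of pairwise Tanimoto similarities is passed to a
    precomputed-kernel SVC; training fingerprints are retained to build
    the test kernel.
    """

    def __init__(self, C: float = 1.0, random_state: Optional[int] = None):
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        self.X_train_ = _dense(X).astype(bool)
        gram = tanimoto_matrix(self.X_train_, self.X_train_)
        self.svc_ = SVC(
            kernel="precomputed",
            C=self.C,
            probability=True,
            random_state=self.random_state,
        )
        self.svc_.fit(gram, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "svc_")
        gram = tanimoto_matrix(_dense(X).astype(bool), self.X_train_)
        return self.svc_.predict_proba(gram)

    def predict(self, X):
        check_is_fitted(self, "svc_")
        gram = tanimoto_matrix(_dense(X).astype(bool), self.X_train_)
        return self.svc_.predict(gram)


def _make_model(algo: str, seed: int):
    if algo == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if algo == "svm_linear":
        return SVC(kernel="linear", probability=True, random_state=seed)
    if algo == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if algo == "svm_tanimoto":
        return TanimotoKernelSVC(random_state=seed)
    if algo == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    raise ValueError(f"unknown algorithm {algo!r}")


def train_classifier(
    train: ScreeningSet,
    algo: str = "random_forest",
    seed: int = 0,
    tune: bool = False,
):
    """Fit a seeded classifier with a predict_proba contract.

    ``tune=True`` runs a small 5-fold cross-validated grid search
    (grids in :data:`TUNING_GRIDS`) on the training set only.  Raises
    if the training labels contain a single class.
    """
    if algo not in ML_ALGORITHMS:
        raise ValueError(f"unknown algorithm {algo!r}")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set must contain both classes")
    X = _dense(train.fingerprints)
    model = _make_model(algo, seed)
    if tune:
        search = GridSearchCV(
            model,
            TUNING_GRIDS[algo],
            cv=5,
            scoring="average_precision",
            n_jobs=1,
        )
        search.fit(X, train.labels)
        return search.best_estimator_
    return model.fit(X, train.labels)


def predict_active_probability(model, fingerprints) -> np.ndarray:
    """Probability of the active (label 1) class per compound."""
    X = _dense(fingerprints)
    proba = model.predict_proba(X)
    col = list(model.classes_).index(1)
    return proba[:, col]


def auprc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision–recall curve, average-precision form.

    Ties are grouped (all items sharing a score enter together).
    Invariant under strictly monotone score transforms.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    uniq = set(np.unique(labels))
    if uniq != {0, 1}:
        raise ValueError("labels must contain both classes")
    return float(average_precision_score(labels, scores))


def bin_activity(
    ic50_values: Sequence[float], config: BinningConfig = BinningConfig()
) -> np.ndarray:
    """Quantile-bin IC50 values into active / inactive / dropped labels.

    Values are ranked (ties to the lower bin), split into ``n_bins``
    equal-count bins with bin 1 holding the lowest IC50 (most potent);
    labels follow the config's bin ranges.
    """
    values = np.asarray(ic50_values, dtype=float)
    if len(values) < config.n_bins:
        raise ValueError(f"need at least {config.n_bins} values")
    if (values <= 0).any() or not np.all(np.isfinite(values)):
        raise ValueError("IC50 values must be positive and finite")
    ranks = rankdata(values, method="min")  # ties share the lower rank
    bins = ((ranks - 1) * config.n_bins // len(values)).astype(int) + 1
    labels = np.full(len(values), "dropped", dtype=object)
    lo_a, hi_a = config.active_bins
    lo_i, hi_i = config.inactive_bins
    labels[(bins >= lo_a) & (bins <= hi_a)] = "active"
    labels[(bins >= lo_i) & (bins <= hi_i)] = "inactive"
    return labels


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis–Murcko framework SMILES ('' for acyclic)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable structure {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def scaffold_diversity(
    ranked_ids: Sequence[str],
    structures: dict[str, str],
    labels: dict[str, int],
    top_k: int = 100,
) -> int:
    """Number of unique Bemis–Murcko scaffolds among the true actives
    in the top ``top_k`` ranked compounds.

    Acyclic molecules share a single empty-scaffold class.
    """
    scaffolds: set[str] = set()
    for cid in list(ranked_ids)[:top_k]:
        if labels.get(cid, 0) != 1:
            continue
        scaffolds.add(murcko_scaffold(structures[cid]))
    return len(scaffolds)


def screening_report(
    train: ScreeningSet,
    test: ScreeningSet,
    methods: Sequence[str] = ("similarity", "docking", "sequential", "ml"),
    algo: str = "random_forest",
    seed: int = 0,
    top_fraction: float = 0.01,
) -> pd.DataFrame:
    """AUPRC of the requested workflows on one train/test pair.

    'similarity' ranks by nearest-active Tanimoto similarity;
    'docking' by docking score; 'sequential' filters the top fraction
    by similarity and re-ranks by docking; 'ml' fits a classifier on
    the training fingerprints.
    """
    rows = []
    actives = train.subset(train.labels == 1)
    best_sim, _ = nn_similarity(test.fingerprints, actives.fingerprints)
    for method in methods:
        if method == "similarity":
            scores = best_sim
        elif method == "docking":
            if test.docking_scores is None:
                raise ValueError("docking method needs docking scores")
            scores = -test.docking_scores
        elif method == "sequential":
            if test.docking_scores is None:
                raise ValueError("sequential method needs docking scores")
            order = sequential_screen(best_sim, test.docking_scores, top_fraction)
            scores = np.empty(test.n)
            scores[order] = -np.arange(test.n, dtype=float)  # rank as score
        elif method == "ml":
            model = train_classifier(train, algo=algo, seed=seed)
            scores = predict_active_probability(model, test.fingerprints)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"method": method, "auprc": auprc(test.labels, scores)})
    return pd.DataFrame(rows)
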