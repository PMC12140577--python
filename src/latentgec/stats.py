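"""Condition-level statistics on coupling ensembles and the task classifier.

Total connectivity summarises each mode's overall involvement (in- plus
out-strength); conditions are compared per mode with Wilcoxon rank-sum
tests under Benjamini-Hochberg FDR; thresholded directed graphs expose the
strong interactions; and a Gaussian-kernel one-versus-one multiclass SVM
tests whether coupling matrices are condition fingerprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .observables import _as_array


def total_connectivity(C) -> np.ndarray:
    """Per-node sum of incoming plus outgoing off-diagonal weights."""
    a = _as_array(C)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"need a square matrix, got shape {a.shape}")
    off = a - np.diag(np.diag(a))
    return off.sum(axis=1) + off.sum(axis=0)


def rank_sum_test(a, b, alternative: str = "two-sided"):
    """Wilcoxon rank-sum (Mann-Whitney) test; exact for small samples.

    Degenerate all-tied inputs yield p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations tied; rank-sum p set to 1", stacklevel=2)
        return 0.0, 1.0
    method = "exact" if (len(a) <= 20 and len(b) <= 20
                         and len(np.unique(pooled)) == len(pooled)) else "asymptotic"
    res = _stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ConditionComparison:
    """Per-network rank-sum statistics between two condition ensembles."""

    statistic: np.ndarray
    p: np.ndarray
    significant: np.ndarray


def compare_conditions(tc_a: np.ndarray, tc_b: np.ndarray,
                       alpha: float = 0.05) -> ConditionComparison:
    """Two-sided rank-sum per network column with BH correction across them."""
    tc_a = np.atleast_2d(np.asarray(tc_a, dtype=float))
    tc_b = np.atleast_2d(np.asarray(tc_b, dtype=float))
    if tc_a.shape[1] != tc_b.shape[1]:
        raise ValueError("condition samples must share the number of networks")
    if tc_a.shape[0] < 3 or tc_b.shape[0] < 3:
        raise ValueError("need at least 3 samples per condition")
    M = tc_a.shape[1]
    stat = np.zeros(M)
    p = np.ones(M)
    for m in range(M):
        stat[m], p[m] = rank_sum_test(tc_a[:, m], tc_b[:, m])
    rej, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return ConditionComparison(statistic=stat, p=p, significant=rej)


@dataclass
class ThresholdedGraph:
    """Directed edges ``(i, j)`` where ``C[i, j] > thr`` (strict)."""

    edges: list[tuple[int, int]]
    threshold: float

    @property
    def out_edges(self) -> dict[int, list[int]]:
        d: dict[int, list[int]] = {}
        for i, j in self.edges:
            d.setdefault(i, []).append(j)
        return d

    @property
    def in_edges(self) -> dict[int, list[int]]:
        d: dict[int, list[int]] = {}
        for i, j in self.edges:
            d.setdefault(j, []).append(i)
        return d


def threshold_graph(C, thr: float = 0.1) -> ThresholdedGraph:
    """Strictly-above-threshold directed edge list of a coupling matrix."""
    a = _as_array(C)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"need a square matrix, got shape {a.shape}")
    edges = [
        (int(i), int(j))
        for i, j in np.argwhere(a > thr)
        if i != j
    ]
    return ThresholdedGraph(edges=edges, threshold=thr)


def lgec_features(mats: list) -> np.ndarray:
    """Feature rows = all off-diagonal entries of each (asymmetric) matrix."""
    arrs = [_as_array(m) for m in mats]
    M = arrs[0].shape[0]
    mask = ~np.eye(M, dtype=bool)
    return np.vstack([a[mask] for a in arrs])


def fc_features(mats: list) -> np.ndarray:
    """Feature rows = upper-triangle entries of each symmetric matrix."""
    arrs = [_as_array(m) for m in mats]
    M = arrs[0].shape[0]
    iu = np.triu_indices(M, k=1)
    return np.vstack([a[iu] for a in arrs])


def scramble_labels(labels, seed: int = 0) -> np.ndarray:
    """Seeded uniform permutation of the label vector (multiset preserved)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(labels.size)]


@dataclass
class ClassifierConfig:
    """Gaussian-kernel one-vs-one SVM with repeated stratified 90/10 splits.

    ``gamma`` defaults to ``1/D`` (the sqrt(D) kernel-scale heuristic);
    ``box_c`` is the SVM regularisation constant.
    """

    train_frac: float = 0.9
    n_repeats: int = 100
    gamma: float | str = "auto"
    box_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class ClassifierReport:
    """Accuracy over repeats plus the pooled, row-normalized confusion matrix."""

    accuracy_mean: float
    accuracy_sd: float
    confusion: np.ndarray
    per_repeat: np.ndarray
    classes: np.ndarray = field(default_factory=lambda: np.array([]))


def train_task_classifier(features: np.ndarray, labels,
                          cfg: ClassifierConfig | None = None) -> ClassifierReport:
    """Repeatedly fit an RBF one-vs-one SVM on stratified shuffled splits.

    For each repeat the data are split 90/10 (stratified, seeded), the SVM
    fitted on the training side and scored on validation; confusion counts
    are pooled over repeats and then row-normalized.
    """
    cfg = cfg or ClassifierConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")

    splitter = StratifiedShuffleSplit(
        n_splits=cfg.n_repeats, train_size=cfg.train_frac,
        random_state=cfg.seed % (2**32),
    )
    accs = np.zeros(cfg.n_repeats)
    pooled = np.zeros((classes.size, classes.size))
    for rep, (tr, va) in enumerate(splitter.split(X, y)):
        clf = SVC(kernel="rbf", C=cfg.box_c, gamma=cfg.gamma,
                  decision_function_shape="ovo")
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[va])
        accs[rep] = np.mean(pred == y[va])
        pooled += confusion_matrix(y[va], pred, labels=classes)
    row_sums = pooled.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    return ClassifierReport(
        accuracy_mean=float(accs.mean()), accuracy_sd=float(accs.std(ddof=1)),
        confusion=pooled / row_sums, per_repeat=accs, classes=classes,
    )
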