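"""Task-state discovery and identification from window-wise FC.

Unsupervised: spectral and BIRCH clustering of vectorized FC patterns and a
t-SNE embedding for inspection.  Supervised: random-forest and RBF-SVM
task identification under stratified, time-separated K-fold
cross-validation.  Evaluation metrics follow their pair-counting /
information-theoretic definitions and are computed here from first
principles (scikit-learn serves as an independent cross-check in the test
suite, not as the implementation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import Birch, SpectralClustering
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.svm import SVC

from .dynamics import WindowedFC

__all__ = [
    "PairCounts", "EvaluationReport",
    "cluster_windows", "embed_tsne", "pair_counts",
    "clustering_metrics", "classify_tasks", "time_stratified_folds",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairCounts:
    """Pair-counting confusion over all unordered window pairs.

    TP: pairs co-clustered in both the prediction Y and the truth T;
    FP: co-clustered in T but not in Y; FN: co-clustered in Y but not in T;
    TN: separated in both.
    """

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class EvaluationReport:
    """Formula-defined evaluation metrics for a (Y, T) label comparison."""

    MI: float = math.nan
    FM: float = math.nan
    AR: float = math.nan
    RI: float = math.nan
    accuracy: float = math.nan
    BAS: float = math.nan
    per_class_precision: dict[str, float] = field(default_factory=dict)
    hamming_loss: float = math.nan
    mae: float = math.nan
    confusion: np.ndarray | None = None
    classes: list[str] = field(default_factory=list)
    notes: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in
               ("MI", "FM", "AR", "RI", "accuracy", "BAS",
                "hamming_loss", "mae")}
        out["per_class_precision"] = self.per_class_precision
        out["classes"] = self.classes
        if self.confusion is not None:
            out["confusion"] = self.confusion.tolist()
        out["notes"] = self.notes
        return out


# ---------------------------------------------------------------------------
# unsupervised
# ---------------------------------------------------------------------------

def _spectral_gamma(X: np.ndarray) -> float:
    """Gaussian-kernel width from the median pairwise distance heuristic."""
    d = pdist(X)
    med = np.median(d[d > 0]) if (d > 0).any() else 1.0
    return 1.0 / (2.0 * med ** 2)


def cluster_windows(wfc: WindowedFC, k: int, algorithm: str = "spectral",
                    seed: int = 0) -> np.ndarray:
    """Cluster non-mixed windows into k groups.

    "spectral": Gaussian similarity on Euclidean FC distance (median
    heuristic width), Laplacian eigenvectors, k-means.  "birch": clustering-
    feature tree agglomerated to k clusters.  Returns one integer label per
    non-mixed window.
    """
    sub = wfc.non_mixed()
    X = sub.vectorized()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds {X.shape[0]} windows")
    if algorithm == "spectral":
        gamma = _spectral_gamma(X)
        affinity = np.exp(-gamma * squareform(pdist(X, "sqeuclidean")))
        model = SpectralClustering(n_clusters=k, affinity="precomputed",
                                   n_init=10, random_state=seed)
        return model.fit_predict(affinity)
    if algorithm == "birch":
        model = Birch(n_clusters=k)
        return model.fit_predict(X)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def embed_tsne(wfc: WindowedFC, perplexity: float = 10.0,
               seed: int = 0) -> np.ndarray:
    """2-D t-SNE coordinates of non-mixed window FC patterns."""
    X = wfc.non_mixed().vectorized()
    if X.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {X.shape[0]} windows")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(X)


# ---------------------------------------------------------------------------
# formula-defined metrics
# ---------------------------------------------------------------------------

def pair_counts(Y: np.ndarray, T: np.ndarray) -> PairCounts:
    """Exhaustive pair-counting confusion over all W(W-1)/2 pairs."""
    Y = np.asarray(Y)
    T = np.asarray(T)
    if Y.shape != T.shape or Y.ndim != 1:
        raise ValueError("Y and T must be 1-D of equal length")
    same_y = Y[:, None] == Y[None, :]
    same_t = T[:, None] == T[None, :]
    upper = np.triu(np.ones((len(Y), len(Y)), dtype=bool), 1)
    tp = int((same_y & same_t & upper).sum())
    fp = int((same_t & ~same_y & upper).sum())
    fn = int((same_y & ~same_t & upper).sum())
    tn = int((~same_y & ~same_t & upper).sum())
    return PairCounts(tp, fp, fn, tn)


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _mutual_information(Y: np.ndarray, T: np.ndarray) -> float:
    n = len(Y)
    yu, yi = np.unique(Y, return_inverse=True)
    tu, ti = np.unique(T, return_inverse=True)
    cont = np.zeros((len(yu), len(tu)))
    np.add.at(cont, (yi, ti), 1.0)
    pxy = cont / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


def normalized_mutual_information(Y: np.ndarray, T: np.ndarray) -> float:
    """MI(Y, T) = 2 I(Y, T) / (H(Y) + H(T)).

    When both partitions are single-class the labelings are identical
    partitions and MI is defined as 1; if only one is single-class, 0.
    """
    hy, ht = _entropy(np.asarray(Y)), _entropy(np.asarray(T))
    if hy == 0.0 and ht == 0.0:
        return 1.0
    if hy == 0.0 or ht == 0.0:
        return 0.0
    return float(np.clip(2.0 * _mutual_information(Y, T) / (hy + ht), 0.0, 1.0))


def adjusted_rand(Y: np.ndarray, T: np.ndarray) -> float:
    """Rand index adjusted for chance via the hypergeometric expectation."""
    Y = np.asarray(Y)
    T = np.asarray(T)
    n = len(Y)
    yu, yi = np.unique(Y, return_inverse=True)
    tu, ti = np.unique(T, return_inverse=True)
    cont = np.zeros((len(yu), len(tu)), dtype=np.int64)
    np.add.at(cont, (yi, ti), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    a = comb2(cont.sum(axis=1)).sum()
    b = comb2(cont.sum(axis=0)).sum()
    total = comb2(n)
    expected = a * b / total if total > 0 else 0.0
    max_index = 0.5 * (a + b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def match_labels(Y: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, list, np.ndarray]:
    """Hungarian one-to-one matching of predicted to true labels.

    Returns (Y_matched, class list in T order, confusion matrix with rows =
    true classes, columns = matched predictions).
    """
    Y = np.asarray(Y)
    T = np.asarray(T)
    tu = list(np.unique(T))
    yu = list(np.unique(Y))
    size = max(len(tu), len(yu))
    cost = np.zeros((size, size))
    for yi, yv in enumerate(yu):
        for ti, tv in enumerate(tu):
            cost[yi, ti] = -np.sum((Y == yv) & (T == tv))
    rows, cols = linear_sum_assignment(cost)
    mapping = {}
    for r, c in zip(rows, cols):
        if r < len(yu):
            mapping[yu[r]] = tu[c] if c < len(tu) else f"_unmatched_{r}"
    Ym = np.array([mapping[v] for v in Y], dtype=object)
    classes = tu
    conf = np.zeros((len(tu), len(tu)), dtype=int)
    for ti, tv in enumerate(tu):
        for tj, pv in enumerate(tu):
            conf[ti, tj] = int(np.sum((T == tv) & (Ym == pv)))
    return Ym, classes, conf


def _confusion_metrics(conf: np.ndarray, classes: list) -> tuple[float, float, dict]:
    """(accuracy, balanced accuracy, per-class precision) from a confusion matrix.

    Balanced accuracy is the macro-average of per-class recall — the
    standard definition behind the named score.
    """
    n = conf.sum()
    acc = float(np.trace(conf) / n) if n else math.nan
    recalls = []
    precisions = {}
    for i, c in enumerate(classes):
        row = conf[i].sum()
        col = conf[:, i].sum()
        recalls.append(conf[i, i] / row if row else math.nan)
        precisions[str(c)] = float(conf[i, i] / col) if col else math.nan
    bas = float(np.nanmean(recalls))
    return acc, bas, precisions


def clustering_metrics(Y: np.ndarray, T: np.ndarray) -> EvaluationReport:
    """Full evaluation of a clustering Y against true labels T.

    Pair-counting metrics (FM, RI, AR) and normalized MI are invariant to
    cluster relabeling; accuracy, BAS and precision use Hungarian-matched
    labels.  RI and accuracy are reported separately (they coincide only
    when the matching is perfect on pairs).
    """
    Y = np.asarray(Y)
    T = np.asarray(T)
    pc = pair_counts(Y, T)
    fm_den = math.sqrt((pc.TP + pc.FP) * (pc.TP + pc.FN))
    fm = pc.TP / fm_den if fm_den > 0 else 0.0
    ri = (pc.TP + pc.TN) / pc.total if pc.total else math.nan
    Ym, classes, conf = match_labels(Y, T)
    acc, bas, prec = _confusion_metrics(conf, classes)
    return EvaluationReport(
        MI=normalized_mutual_information(Y, T),
        FM=float(fm), AR=adjusted_rand(Y, T), RI=float(ri),
        accuracy=acc, BAS=bas, per_class_precision=prec,
        hamming_loss=1.0 - acc,
        mae=math.nan,
        confusion=conf, classes=[str(c) for c in classes],
        notes={"accuracy": "after Hungarian label matching"},
    )


# ---------------------------------------------------------------------------
# supervised task identification
# ---------------------------------------------------------------------------

def time_stratified_folds(labels: list[str], K: int = 5) -> list[np.ndarray]:
    """Stratified, time-contiguous K-fold test index sets.

    Each class's windows (already in time order) are cut into K contiguous
    segments; fold f tests on segment f of every class.  This keeps fold
    class proportions within one window of the global proportions while the
    test windows of each class form a contiguous time span, so training
    never interleaves with testing in time.
    """
    labels_arr = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(K)]
    for cls in np.unique(labels_arr):
        idx = np.nonzero(labels_arr == cls)[0]
        if len(idx) < K:
            raise ValueError(f"class {cls!r} has {len(idx)} windows < K={K}")
        segments = np.array_split(idx, K)
        for f, seg in enumerate(segments):
            folds[f].extend(seg.tolist())
    return [np.array(sorted(f), dtype=int) for f in folds]


def _drop_overlapping(train_idx: np.ndarray, test_idx: np.ndarray,
                      windows: list[tuple[float, float]]) -> np.ndarray:
    """Remove training windows whose time span overlaps any test window."""
    test_iv = [windows[i] for i in test_idx]
    keep = []
    for i in train_idx:
        w0, w1 = windows[i]
        if all(w1 <= t0 + 1e-9 or w0 >= t1 - 1e-9 for t0, t1 in test_iv):
            keep.append(i)
    return np.array(keep, dtype=int)


def _make_classifier(model: str, seed: int):
    if model == "rfc":
        return RandomForestClassifier(n_estimators=500, random_state=seed,
                                      n_jobs=1)
    if model == "svm":
        return SVC(kernel="rbf", C=1.0, random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def classify_tasks(wfc: WindowedFC, model: str = "rfc", K: int = 5,
                   seed: int = 0,
                   shuffle_labels: bool = False) -> EvaluationReport:
    """Task identification from single-window FC with leakage-free folds.

    Features are the vectorized FC entries; per fold they are z-scored on
    the training split only.  Predictions are concatenated across folds
    into one confusion matrix (aggregated evaluation).  ``shuffle_labels``
    trains on permuted labels — the chance-level control.
    """
    sub = wfc.non_mixed()
    X = sub.vectorized()
    labels = list(sub.task_labels)
    rng = np.random.default_rng(seed)
    if shuffle_labels:
        labels = list(rng.permutation(labels))
    y = np.asarray(labels)
    folds = time_stratified_folds(labels, K)
    all_idx = np.arange(len(y))
    classes = list(dict.fromkeys(y))   # annotation (first-appearance) order
    enc = {c: i for i, c in enumerate(classes)}

    y_true_parts, y_pred_parts = [], []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_idx = _drop_overlapping(train_idx, test_idx, sub.windows)
        mu = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0)
        sd[sd < 1e-15] = 1.0
        clf = _make_classifier(model, seed + f)
        clf.fit((X[train_idx] - mu) / sd, y[train_idx])
        y_pred_parts.append(clf.predict((X[test_idx] - mu) / sd))
        y_true_parts.append(y[test_idx])

    y_true = np.concatenate(y_true_parts)
    y_pred = np.concatenate(y_pred_parts)
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[enc[t], enc[p]] += 1
    acc, bas, prec = _confusion_metrics(conf, classes)
    t_int = np.array([enc[v] for v in y_true])
    p_int = np.array([enc[v] for v in y_pred])
    return EvaluationReport(
        MI=normalized_mutual_information(y_pred, y_true),
        FM=math.nan, AR=math.nan, RI=math.nan,
        accuracy=acc, BAS=bas, per_class_precision=prec,
        hamming_loss=float(np.mean(y_true != y_pred)),
        mae=float(np.mean(np.abs(t_int - p_int))),
        confusion=conf, classes=[str(c) for c in classes],
        notes={"mae": "on integer-encoded labels in annotation order; "
                       "encoding-dependent"},
    )
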