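"""PCA-LDA classification of spectral fingerprints.

Pipeline: mean-centred PCA by SVD, component selection at >90% cumulative
explained variance, a two-class Fisher linear discriminant on the retained
scores, stratified ten-fold cross-validation (PCA refit and components
re-selected inside every training fold), ROC/AUC, a label-permutation
significance test, patient-level aggregation and confusion-matrix metrics.

Positive class convention: NR (non-remission); higher discriminant score
means more NR-like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import AlignmentError, DataError, LabelError, ParameterError
from .io import SpectraSet

POSITIVE_CLASS = "NR"


@dataclass
class PCAModel:
    mean_spectrum: np.ndarray
    loadings: np.ndarray              # components × channels, orthonormal rows
    explained_variance_ratio: np.ndarray

    def transform(self, matrix: np.ndarray, n_components: int | None = None) -> np.ndarray:
        L = self.loadings if n_components is None else self.loadings[:n_components]
        return (np.atleast_2d(matrix) - self.mean_spectrum) @ L.T


@dataclass
class LDAModel:
    weights: np.ndarray               # one discriminant axis for two classes
    threshold: float
    class_means: dict[str, float]     # projected class means
    classes: tuple[str, str]          # (negative, positive)

    def project(self, scores: np.ndarray) -> np.ndarray:
        return np.atleast_2d(scores) @ self.weights

    def predict(self, scores: np.ndarray) -> np.ndarray:
        proj = self.project(scores)
        neg, pos = self.classes
        return np.where(proj > self.threshold, pos, neg)


@dataclass
class PCALDAModel:
    pca: PCAModel
    n_components: int
    lda: LDAModel
    wavenumbers: np.ndarray | None = None


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class PermutationResult:
    observed_auc: float
    null_aucs: np.ndarray
    p_value: float


def _as_matrix(data) -> np.ndarray:
    return data.matrix if isinstance(data, SpectraSet) else np.atleast_2d(np.asarray(data, float))


def fit_pca(matrix) -> PCAModel:
    """Mean-centred PCA via SVD.

    Components are ordered by decreasing variance; each loading's
    largest-magnitude element is made positive (deterministic sign).
    """
    X = _as_matrix(matrix)
    if X.shape[0] < 2:
        raise DataError("PCA needs at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    evr = var / total if total > 0 else np.zeros_like(var)
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    return PCAModel(mean, Vt, evr)


def select_n_components(evr: np.ndarray, threshold: float = 0.90) -> int:
    """Smallest k whose cumulative explained-variance ratio exceeds threshold."""
    if not (0.0 < threshold < 1.0):
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    cum = np.cumsum(np.asarray(evr, dtype=float))
    above = np.nonzero(cum > threshold)[0]
    return int(above[0]) + 1 if above.size else int(cum.size)


def _binary_labels(labels) -> tuple[np.ndarray, tuple[str, str]]:
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise LabelError(f"need exactly 2 classes, got {classes}")
    # orientation: POSITIVE_CLASS last if present, else lexicographically last
    if POSITIVE_CLASS in classes:
        classes = [c for c in classes if c != POSITIVE_CLASS] + [POSITIVE_CLASS]
    return y, (classes[0], classes[1])


def fit_lda(scores: np.ndarray, labels) -> LDAModel:
    """Two-class Fisher discriminant with a midpoint decision threshold.

    Direction w ∝ Sw⁻¹(μ₊ − μ₋) maximizes the between/within scatter ratio;
    the within-class scatter is inverted via pseudo-inverse when singular.
    The threshold sits at the midpoint of the projected class means (equal
    priors); orientation is fixed so the positive class projects higher.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    y, (neg, pos) = _binary_labels(labels)
    Xn, Xp = X[y == neg], X[y == pos]
    if len(Xn) == 0 or len(Xp) == 0:
        raise LabelError("both classes must be present")
    mn, mp = Xn.mean(axis=0), Xp.mean(axis=0)
    Sw = np.zeros((X.shape[1], X.shape[1]))
    for Xi, mi in ((Xn, mn), (Xp, mp)):
        d = Xi - mi
        Sw += d.T @ d
    w = np.linalg.pinv(Sw) @ (mp - mn)
    nrm = np.linalg.norm(w)
    if nrm == 0:
        w = mp - mn
        nrm = np.linalg.norm(w)
    w = w / nrm if nrm > 0 else np.ones(X.shape[1]) / np.sqrt(X.shape[1])
    pn, pp = float(Xn.mean(axis=0) @ w), float(Xp.mean(axis=0) @ w)
    if pp < pn:
        w, pn, pp = -w, -pn, -pp
    return LDAModel(w, (pn + pp) / 2.0, {neg: pn, pos: pp}, (neg, pos))


def _pca_retained(X: np.ndarray, var_threshold: float) -> tuple[PCAModel, int]:
    """PCA keeping only the loadings needed at the variance threshold.

    When samples are fewer than channels the spectrum of the n × n Gram
    matrix gives the same eigenvalues as the SVD at a fraction of the cost,
    and only the retained right singular vectors are reconstructed.  The
    explained-variance-ratio vector is always the full spectrum.
    """
    if X.shape[0] < 2:
        raise DataError("PCA needs at least 2 samples")
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    if n > p:
        pca = fit_pca(X)
        return pca, select_n_components(pca.explained_variance_ratio, var_threshold)
    G = Xc @ Xc.T
    w, U = np.linalg.eigh(G)
    w = np.clip(w[::-1], 0.0, None)
    U = U[:, ::-1]
    total = w.sum()
    evr = w / total if total > 0 else np.zeros_like(w)
    k = select_n_components(evr, var_threshold)
    s = np.sqrt(w[:k])
    s_safe = np.where(s > 0, s, 1.0)
    V = (Xc.T @ U[:, :k]) / s_safe  # p × k, orthonormal columns
    L = V.T
    for i in range(k):
        j = int(np.argmax(np.abs(L[i])))
        if L[i, j] < 0:
            L[i] = -L[i]
    return PCAModel(mean, L, evr), k


def fit_pca_lda(dataset, labels, var_threshold: float = 0.90) -> PCALDAModel:
    """PCA on all rows, components kept at >threshold cumulative variance, LDA on the scores."""
    X = _as_matrix(dataset)
    pca, k = _pca_retained(X, var_threshold)
    lda = fit_lda(pca.transform(X, k), labels)
    wn = dataset.wavenumbers if isinstance(dataset, SpectraSet) else None
    return PCALDAModel(pca, k, lda, wn)


def decision_scores(model: PCALDAModel, dataset) -> np.ndarray:
    """LD1 projection of new spectra; higher score = more NR-like."""
    X = _as_matrix(dataset)
    if isinstance(dataset, SpectraSet) and model.wavenumbers is not None:
        if (
            dataset.wavenumbers.size != model.wavenumbers.size
            or not np.allclose(dataset.wavenumbers, model.wavenumbers)
        ):
            raise AlignmentError("dataset grid does not match the training grid")
    if X.shape[1] != model.pca.mean_spectrum.size:
        raise AlignmentError(
            f"dataset has {X.shape[1]} channels, model expects "
            f"{model.pca.mean_spectrum.size}"
        )
    return model.lda.project(model.pca.transform(X, model.n_components))


def predict(model: PCALDAModel, dataset) -> np.ndarray:
    scores = decision_scores(model, dataset)
    neg, pos = model.lda.classes
    return np.where(scores > model.lda.threshold, pos, neg)


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and AUC; AUC is the normalized Mann-Whitney U with half-credit ties."""
    s = np.asarray(scores, dtype=float).ravel()
    y, (neg, pos) = _binary_labels(labels)
    ybin = (y == pos).astype(int)
    n1, n0 = int(ybin.sum()), int((1 - ybin).sum())
    if n1 == 0 or n0 == 0:
        raise LabelError("both classes must be present for ROC analysis")
    # midranks give the tie-corrected U statistic
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(s.size, dtype=float)
    sorted_s = s[order]
    i = 0
    while i < s.size:
        j = i
        while j + 1 < s.size and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    r1 = ranks[ybin == 1].sum()
    auc = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thr = _sk_roc_curve(ybin, s)
    return ROCCurve(thr, tpr, fpr, float(auc))


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Accuracy/sensitivity/specificity from counts; zero denominators give NaN."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ParameterError(f"{name} must be >= 0")
    total = tp + fp + tn + fn
    if total == 0:
        raise ParameterError("at least one count must be positive")
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
    return ConfusionMetrics(tp, fp, tn, fn, acc, sens, spec)


def cross_validate(
    dataset,
    labels,
    folds: int = 10,
    seed: int = 0,
    var_threshold: float = 0.90,
) -> tuple[ConfusionMetrics, ROCCurve]:
    """Stratified k-fold CV of the PCA-LDA pipeline.

    The PCA and the component selection are refit inside every training fold
    (no selection leakage); pooled out-of-fold scores feed the metrics and
    the ROC curve.
    """
    X = _as_matrix(dataset)
    y, (neg, pos) = _binary_labels(labels)
    counts = {c: int((y == c).sum()) for c in (neg, pos)}
    if min(counts.values()) < folds:
        raise DataError(
            f"each class must have at least {folds} samples for {folds}-fold CV, "
            f"got {counts}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled_scores = np.empty(len(y))
    pooled_pred = np.empty(len(y), dtype=object)
    for train, test in skf.split(X, y):
        model = fit_pca_lda(X[train], y[train], var_threshold)
        sc = decision_scores(model, X[test])
        pooled_scores[test] = sc
        pooled_pred[test] = np.where(sc > model.lda.threshold, pos, neg)
    tp = int(np.sum((pooled_pred == pos) & (y == pos)))
    fp = int(np.sum((pooled_pred == pos) & (y == neg)))
    tn = int(np.sum((pooled_pred == neg) & (y == neg)))
    fn = int(np.sum((pooled_pred == neg) & (y == pos)))
    return confusion_metrics(tp, fp, tn, fn), roc_auc(pooled_scores, y)


def permutation_test(
    dataset,
    labels,
    n_permutations: int = 1000,
    seed: int = 0,
    folds: int = 10,
    var_threshold: float = 0.90,
) -> PermutationResult:
    """Label-permutation null distribution of the cross-validated AUC.

    Each permutation shuffles the labels, refits the full PCA-LDA CV and
    records its AUC; the p-value uses the add-one formula
    ``(1 + #{null ≥ observed}) / (1 + n_permutations)`` so it is never zero.
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    X = _as_matrix(dataset)
    y, _ = _binary_labels(labels)
    _, observed_roc = cross_validate(X, y, folds=folds, seed=seed, var_threshold=var_threshold)
    rng = np.random.default_rng(seed)
    null_aucs = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(len(y))
        _, roc = cross_validate(
            X, y[perm], folds=folds, seed=seed, var_threshold=var_threshold
        )
        null_aucs[b] = roc.auc
    p = (1.0 + np.sum(null_aucs >= observed_roc.auc)) / (1.0 + n_permutations)
    return PermutationResult(observed_roc.auc, null_aucs, float(p))


def patient_mean_spectra(dataset: SpectraSet) -> SpectraSet:
    """Average each patient's cells into one spectrum; group label inherited.

    A patient whose cells carry mixed group labels is a metadata error.
    """
    from .io import SampleMeta

    pids = dataset.patient_ids
    groups = dataset.groups
    order = list(dict.fromkeys(pids.tolist()))  # first-appearance order
    rows, meta = [], []
    for pid in order:
        mask = pids == pid
        g = set(groups[mask].tolist())
        if len(g) != 1:
            raise DataError(f"patient {pid} has mixed group labels {sorted(g)}")
        rows.append(dataset.matrix[mask].mean(axis=0))
        meta.append(SampleMeta(pid, pid, g.pop()))
    return SpectraSet(dataset.wavenumbers.copy(), np.array(rows), meta)


def ld1_pc_contributions(model: PCALDAModel) -> np.ndarray:
    """Per-PC share of the discriminant: |LD1 weights| normalized to sum to 1."""
    w = np.abs(model.lda.weights)
    return w / w.sum()
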