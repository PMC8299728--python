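"""Multi-kernel SVM classification under nested leave-one-out CV.

The classifier is a soft-margin SVM on the convex kernel combination
K(beta) = sum_m beta_m K_m with beta on the probability simplex
(sum_m beta_m = 1, beta_m >= 0) and per-modality linear kernels on
t-test-selected, z-scored edge features.  The dual

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(beta)_ij
    s.t.   sum_i a_i y_i = 0,   0 <= a_i <= C

is solved by LIBSVM (scikit-learn's precomputed-kernel SVC).  Model
selection runs a nested leave-one-out scheme: the outer loop holds out
one subject for performance estimation; an inner leave-one-out grid
search over C (powers of two, default 2**-5 .. 2**5) and beta (simplex
grid, default step 0.1) picks hyperparameters on each outer training
set.  Feature selection and scaling are refit inside every outer
training fold, so the held-out subject never influences them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.svm import SVC

from .selection import edge_ttest

__all__ = [
    "KernelSet",
    "MKSVMModel",
    "CVReport",
    "TrainingError",
    "linear_kernel",
    "combine_kernels",
    "simplex_grid",
    "default_c_grid",
    "train_mksvm",
    "dual_objective",
    "predict",
    "roc_auc",
    "nested_loocv",
    "selection_fold_masks",
]

SIMPLEX_TOL = 1e-9
KKT_TOL = 1e-6


class TrainingError(RuntimeError):
    """SVM training failed or produced an infeasible dual solution."""


def default_c_grid() -> np.ndarray:
    """Integer powers of two from 2**-5 to 2**5."""
    return 2.0 ** np.arange(-5, 6)


def linear_kernel(features: np.ndarray) -> np.ndarray:
    """Gram matrix <x_i, x_j> of the (selected, scaled) feature rows."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] < 1:
        raise ValueError("need at least one feature column")
    return x @ x.T


@dataclass
class KernelSet:
    """Per-modality kernel matrices over one shared sample set."""

    kernels: list[np.ndarray]
    modalities: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("empty kernel set")
        n = self.kernels[0].shape[0]
        for k in self.kernels:
            if k.shape != (n, n):
                raise ValueError("kernels have mismatched dimensions")
            if np.max(np.abs(k - k.T)) > 1e-8:
                raise ValueError("kernel not symmetric")
        if not self.modalities:
            self.modalities = [f"m{i}" for i in range(len(self.kernels))]

    @property
    def n_samples(self) -> int:
        return self.kernels[0].shape[0]

    @property
    def n_modalities(self) -> int:
        return len(self.kernels)


def _check_simplex(betas: np.ndarray, m: int) -> np.ndarray:
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (m,):
        raise ValueError(f"expected {m} kernel weights, got {betas.shape}")
    if (betas < -SIMPLEX_TOL).any() or abs(betas.sum() - 1.0) > SIMPLEX_TOL:
        raise ValueError(f"kernel weights must lie on the simplex, got {betas}")
    return np.clip(betas, 0.0, None)


def combine_kernels(kernels: list[np.ndarray], betas: np.ndarray) -> np.ndarray:
    """Convex combination sum_m beta_m K_m (PSD-preserving)."""
    betas = _check_simplex(np.asarray(betas, dtype=float), len(kernels))
    out = np.zeros_like(kernels[0], dtype=float)
    for b, k in zip(betas, kernels):
        if b != 0.0:
            out = out + b * k
    return out


def simplex_grid(m: int, step: float = 0.1) -> list[tuple[float, ...]]:
    """All simplex points with coordinates on a grid of the given step.

    Returned in lexicographic order, so deterministic tie-breaking picks
    the lexicographically smallest beta.
    """
    levels = int(round(1.0 / step))
    if abs(levels * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1 exactly")
    out: list[tuple[float, ...]] = []

    def rec(prefix: list[int], remaining: int) -> None:
        if len(prefix) == m - 1:
            out.append(tuple(k / levels for k in prefix + [remaining]))
            return
        for k in range(remaining + 1):
            rec(prefix + [k], remaining - k)

    rec([], levels)
    return sorted(out)


@dataclass
class MKSVMModel:
    """Trained multi-kernel SVM in dual form."""

    alphas: np.ndarray  # per training sample, in [0, C]
    bias: float
    betas: np.ndarray  # simplex kernel weights
    C: float
    y_train: np.ndarray
    support: np.ndarray  # indices with alpha > 0

    def __post_init__(self) -> None:
        if abs(float(np.dot(self.alphas, self.y_train))) > KKT_TOL * max(1.0, self.C):
            raise TrainingError("dual equality constraint sum(alpha*y)=0 violated")
        if (self.alphas < -KKT_TOL).any() or (self.alphas > self.C + KKT_TOL).any():
            raise TrainingError("dual box constraint 0<=alpha<=C violated")


def train_mksvm(
    kernels: list[np.ndarray],
    labels: np.ndarray,
    betas: np.ndarray,
    C: float,
    tol: float = 1e-9,
) -> MKSVMModel:
    """Fit the soft-margin SVM dual on the combined kernel.

    The quadratic programme is solved by LIBSVM; the returned model
    carries the full dual solution (alphas, bias) so predictions can be
    formed from per-modality cross-kernels.
    """
    labels = np.asarray(labels, dtype=float)
    if set(np.unique(labels)) != {-1.0, 1.0}:
        raise ValueError("labels must contain both +1 and -1")
    kc = combine_kernels(kernels, betas)
    svc = SVC(kernel="precomputed", C=C, tol=tol, shrinking=False)
    try:
        svc.fit(kc, labels)
    except Exception as exc:  # pragma: no cover - libsvm rarely fails here
        raise TrainingError(f"SVM solver failed: {exc}") from exc
    n = len(labels)
    alphas = np.zeros(n)
    # dual_coef_ stores alpha_i * y_i for support vectors
    alphas[svc.support_] = svc.dual_coef_[0] * labels[svc.support_]
    return MKSVMModel(
        alphas=alphas,
        bias=float(svc.intercept_[0]),
        betas=_check_simplex(np.asarray(betas, dtype=float), len(kernels)),
        C=float(C),
        y_train=labels.astype(int),
        support=svc.support_.copy(),
    )


def dual_objective(model: MKSVMModel, kernels: list[np.ndarray]) -> float:
    """Value of the dual objective at the trained solution."""
    kc = combine_kernels(kernels, model.betas)
    a, y = model.alphas, model.y_train.astype(float)
    return float(a.sum() - 0.5 * (a * y) @ kc @ (a * y))


def predict(
    model: MKSVMModel, cross_kernels: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Decision values and labels for test samples.

    ``cross_kernels[m]`` has shape (n_test, n_train): k_m(x_test, x_train).
    The decision function is
    f(x) = sum_i y_i alpha_i sum_m beta_m k_m(x_i, x) + b.
    """
    if len(cross_kernels) != len(model.betas):
        raise ValueError("cross-kernel count does not match kernel weights")
    n_train = len(model.alphas)
    for k in cross_kernels:
        if k.shape[1] != n_train:
            raise ValueError("cross-kernel has wrong training dimension")
    kc = np.zeros_like(cross_kernels[0], dtype=float)
    for b, k in zip(model.betas, cross_kernels):
        if b != 0.0:
            kc = kc + b * k
    dec = kc @ (model.alphas * model.y_train) + model.bias
    lab = np.where(dec >= 0, 1, -1)
    return dec, lab


def roc_auc(
    decision_values: np.ndarray, labels: np.ndarray
) -> tuple[float, list[tuple[float, float]]]:
    """AUC by the rank statistic (ties counted half) plus ROC points."""
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(d)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # ROC polyline over score thresholds (descending)
    order = np.argsort(-d, kind="stable")
    tp = fp = 0
    pts = [(0.0, 0.0)]
    k = 0
    while k < len(d):
        thr = d[order[k]]
        while k < len(d) and d[order[k]] == thr:
            if y[order[k]] == 1:
                tp += 1
            else:
                fp += 1
            k += 1
        pts.append((fp / n_neg, tp / n_pos))
    return float(auc), pts


@dataclass
class CVReport:
    """Outer-loop performance and per-fold bookkeeping of nested LOOCV."""

    accuracy: float  # percent
    sensitivity: float  # percent, patients (+1) positive
    specificity: float  # percent
    auc: float
    roc_points: list[tuple[float, float]]
    decision_values: np.ndarray
    predictions: np.ndarray
    y_true: np.ndarray
    fold_masks: dict[str, list[np.ndarray]]  # modality -> per-outer-fold masks
    chosen_params: list[tuple[float, tuple[float, ...]]]  # per fold (C, beta)

    def summary(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 2),
            "sensitivity": round(self.sensitivity, 2),
            "specificity": round(self.specificity, 2),
            "auc": round(self.auc, 4),
        }


def _fold_kernels(
    features: dict[str, np.ndarray],
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    alpha_select: float,
) -> tuple[list[np.ndarray], list[np.ndarray], dict[str, np.ndarray]]:
    """Select, scale and kernelise features inside one training fold."""
    y_tr = labels[train_idx]
    kernels, cross, masks = [], [], {}
    for mod, X in features.items():
        Xtr = X[train_idx]
        st = edge_ttest(Xtr[y_tr == 1], Xtr[y_tr == -1], alpha=alpha_select)
        mask = st.selected
        masks[mod] = mask
        if mask.any():
            mu = Xtr[:, mask].mean(axis=0)
            sd = Xtr[:, mask].std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Z = (Xtr[:, mask] - mu) / sd
            Zt = (X[test_idx][:, mask] - mu) / sd
            kernels.append(Z @ Z.T)
            cross.append(Zt @ Z.T)
        else:
            warnings.warn(
                f"no {mod} features selected at alpha={alpha_select}; "
                "falling back to an identity kernel",
                stacklevel=2,
            )
            kernels.append(np.eye(len(train_idx)))
            cross.append(np.zeros((len(test_idx), len(train_idx))))
    return kernels, cross, masks


def _inner_loo_accuracy(kc: np.ndarray, y: np.ndarray, C: float) -> float:
    """Leave-one-out accuracy of an SVM with a fixed precomputed kernel."""
    n = len(y)
    correct = 0
    counted = 0
    idx = np.arange(n)
    for v in range(n):
        tr = idx[idx != v]
        y_tr = y[tr]
        if len(np.unique(y_tr)) < 2:
            warnings.warn("inner fold skipped: one class absent", stacklevel=2)
            continue
        svc = SVC(kernel="precomputed", C=C, shrinking=False)
        svc.fit(kc[np.ix_(tr, tr)], y_tr)
        pred = svc.predict(kc[v : v + 1, tr])
        correct += int(pred[0] == y[v])
        counted += 1
    return correct / counted if counted else 0.0


def nested_loocv(
    features: dict[str, np.ndarray],
    labels: np.ndarray,
    C_grid: np.ndarray | None = None,
    beta_step: float = 0.1,
    alpha_select: float = 0.01,
) -> CVReport:
    """Nested leave-one-out cross-validation of the multi-kernel SVM.

    Outer folds hold out one subject each; inside every outer training
    set, edges are reselected (t-test, ``alpha_select``), z-scored, and
    an inner leave-one-out grid search over C x beta picks the
    hyperparameters (ties: higher accuracy, then smaller C, then
    lexicographically smallest beta).  The procedure is deterministic.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if n < 6 or (labels == 1).sum() < 3 or (labels == -1).sum() < 3:
        raise ValueError("need >= 6 subjects with >= 3 per class")
    if C_grid is None:
        C_grid = default_c_grid()
    modalities = list(features)
    betas_grid = (
        simplex_grid(len(modalities), beta_step)
        if len(modalities) > 1
        else [(1.0,)]
    )
    idx = np.arange(n)
    decisions = np.zeros(n)
    preds = np.zeros(n, dtype=int)
    fold_masks: dict[str, list[np.ndarray]] = {m: [] for m in modalities}
    chosen: list[tuple[float, tuple[float, ...]]] = []
    for t in range(n):
        train = idx[idx != t]
        kernels, cross, masks = _fold_kernels(
            features, labels, train, np.array([t]), alpha_select
        )
        for m in modalities:
            fold_masks[m].append(masks[m])
        y_tr = labels[train]
        best_key = None
        best = None
        for beta in betas_grid:
            kc = combine_kernels(kernels, np.array(beta))
            for C in C_grid:
                acc = _inner_loo_accuracy(kc, y_tr, C)
                key = (-acc, C, beta)
                if best_key is None or key < best_key:
                    best_key, best = key, (C, beta)
        C, beta = best
        model = train_mksvm(kernels, y_tr, np.array(beta), C)
        dec, lab = predict(model, cross)
        decisions[t] = dec[0]
        preds[t] = lab[0]
        chosen.append((float(C), beta))
    tp = int(((preds == 1) & (labels == 1)).sum())
    tn = int(((preds == -1) & (labels == -1)).sum())
    fn = int(((preds == -1) & (labels == 1)).sum())
    fp = int(((preds == 1) & (labels == -1)).sum())
    auc, pts = roc_auc(decisions, labels)
    return CVReport(
        accuracy=100.0 * (tp + tn) / n,
        sensitivity=100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        specificity=100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        auc=auc,
        roc_points=pts,
        decision_values=decisions,
        predictions=preds,
        y_true=labels.copy(),
        fold_masks=fold_masks,
        chosen_params=chosen,
    )


def selection_fold_masks(
    features: dict[str, np.ndarray],
    labels: np.ndarray,
    alpha_select: float = 0.01,
) -> dict[str, list[np.ndarray]]:
    """Per-outer-fold t-test selection masks of the leave-one-out scheme.

    This is exactly the selection stage of :func:`nested_loocv` (one
    mask per held-out subject, fitted on the remaining subjects), usable
    on its own when only consensus connections are needed.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    idx = np.arange(n)
    out: dict[str, list[np.ndarray]] = {m: [] for m in features}
    for t in range(n):
        train = idx[idx != t]
        y_tr = labels[train]
        for mod, X in features.items():
            st = edge_ttest(
                X[train][y_tr == 1], X[train][y_tr == -1], alpha=alpha_select
            )
            out[mod].append(st.selected)
    return out
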