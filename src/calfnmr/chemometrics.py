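"""Chemometrics: PCA, OPLS(-DA) and Monte Carlo cross-validation.

OPLS (orthogonal projections to latent structures) splits predictor variation
into a response-predictive part and a response-orthogonal part. Classes are
dummy-coded (one centered indicator column per class, "-DA"), orthogonal
components are extracted by the loading-filtering step — the loading of a
provisional predictive component minus its projection onto the column space
of X'Y — and deflated from X, after which an ordinary NIPALS-style PLS2 model
with ``n_pred`` components is fitted on the filtered matrix. With
``n_orth = 0`` the model reduces exactly to PLS2.

Orthogonal score vectors are response-orthogonal by construction: each
orthogonal weight is orthogonal to every column of X'Y, hence
``t_orth' Y = w_orth' (X'Y) = 0`` to machine precision, and the deflation
leaves X'Y unchanged.

Classifier accuracy is assessed with Monte Carlo cross-validation: repeated
stratified random 90/10 splits, accumulating one confusion matrix over all
iterations. Per-class accuracy is the class's sensitivity in the accumulated
matrix; "mean accuracy" is the overall fraction of correct test predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAResult", "pca", "OPLSModel", "fit_opls", "predict_opls",
           "CVReport", "mccv", "glog"]


def glog(X: np.ndarray, lam: float = 1e-6) -> np.ndarray:
    """Generalized log transform, ``log((x + sqrt(x² + λ))/2)``.

    Variance stabilization for bin intensities before projection methods:
    metabolite concentrations (and hence bin integrals) are approximately
    lognormal, so linear projections see heavy-tailed classes; the glog makes
    them near-Gaussian while remaining defined for the small negative values
    noise leaves in empty bins. ``λ`` sets the crossover scale below which
    the transform flattens out; any value well under typical peak-bin
    integrals behaves like a plain log.
    """
    X = np.asarray(X, dtype=float)
    if lam <= 0:
        raise ValueError("lam must be positive")
    return np.log((X + np.sqrt(X**2 + lam)) / 2.0)


# ---------------------------------------------------------------------------
# PCA

@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray              # (n_samples, n_components)
    loadings: np.ndarray            # (n_bins, n_components), orthonormal columns
    explained_variance: np.ndarray  # per-component sample-covariance eigenvalues
    mean: np.ndarray

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum() \
            if self.explained_variance.sum() > 0 else self.explained_variance


def pca(X: np.ndarray, n_components: int) -> PCAResult:
    """Principal component analysis of a column-mean-centered matrix via SVD."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2D with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    n, b = X.shape
    if n_components > min(n - 1, b):
        raise ValueError(f"n_components must be <= min(n-1, bins) = {min(n - 1, b)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading entry positive
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    k = n_components
    return PCAResult(
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T,
        explained_variance=s[:k] ** 2 / (n - 1),
        mean=mean,
    )


# ---------------------------------------------------------------------------
# OPLS(-DA)

@dataclass
class OPLSModel:
    classes: list[str]
    center_vector: np.ndarray       # per-bin training mean
    y_mean: np.ndarray              # dummy-column means
    pred_weights: np.ndarray        # (bins, n_pred)
    pred_loadings: np.ndarray       # (bins, n_pred)
    pred_scores: np.ndarray         # (train samples, n_pred)
    y_loadings: np.ndarray          # (classes, n_pred)
    orth_weights: np.ndarray        # (bins, n_orth)
    orth_loadings: np.ndarray       # (bins, n_orth)
    orth_scores: np.ndarray         # (train samples, n_orth)
    coef: np.ndarray                # (bins, classes) regression matrix
    n_pred: int
    n_orth: int


def _dummy(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y


def _dominant_weight(XtY: np.ndarray) -> np.ndarray:
    """Dominant left singular vector of X'Y with a deterministic sign."""
    U, _, _ = np.linalg.svd(XtY, full_matrices=False)
    w = U[:, 0]
    j = np.argmax(np.abs(w))
    if w[j] < 0:
        w = -w
    return w


def fit_opls(
    X: np.ndarray,
    class_labels,
    n_pred: int,
    n_orth: int,
) -> OPLSModel:
    """Fit an OPLS-DA model with ``n_pred`` predictive and ``n_orth``
    orthogonal components on dummy-coded class labels."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(class_labels)
    n, b = X.shape
    if len(labels) != n:
        raise ValueError("label length mismatch")
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    if n_pred < 1 or n_orth < 0 or n_pred + n_orth >= n:
        raise ValueError("need 1 <= n_pred and n_pred + n_orth < n_samples")

    center = X.mean(axis=0)
    Xc = X - center
    if not np.any(np.abs(Xc) > 1e-12 * max(1.0, np.abs(X).max())):
        raise ValueError("X is constant/singular: no variation to model")
    Ydum = _dummy(labels, classes)
    y_mean = Ydum.mean(axis=0)
    Y = Ydum - y_mean

    # orthonormal basis of the column space of X'Y (invariant under the
    # orthogonal deflation below)
    C = Xc.T @ Y
    Uc, sc, _ = np.linalg.svd(C, full_matrices=False)
    Wy = Uc[:, sc > max(1e-12 * sc[0], 1e-300)] if sc[0] > 0 else Uc[:, :0]

    Wo, Po, To = [], [], []
    for _ in range(n_orth):
        w = _dominant_weight(Xc.T @ Y)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        w_o = p - Wy @ (Wy.T @ p)
        norm = np.linalg.norm(w_o)
        if norm < 1e-12 * max(np.linalg.norm(p), 1.0):
            break  # no response-orthogonal variation left
        w_o = w_o / norm
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / (t_o @ t_o)
        Xc = Xc - np.outer(t_o, p_o)
        Wo.append(w_o)
        Po.append(p_o)
        To.append(t_o)

    # predictive PLS2 (NIPALS fixed point per component, X and Y deflated)
    Xd, Yd = Xc.copy(), Y.copy()
    W, P, T, Q = [], [], [], []
    for _ in range(n_pred):
        XtY = Xd.T @ Yd
        if np.linalg.norm(XtY) < 1e-14:
            break
        w = _dominant_weight(XtY)
        t = Xd @ w
        tt = t @ t
        if tt < 1e-300:
            break
        p = Xd.T @ t / tt
        q = Yd.T @ t / tt
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, q)
        W.append(w)
        P.append(p)
        T.append(t)
        Q.append(q)

    W = np.column_stack(W) if W else np.zeros((b, 0))
    P = np.column_stack(P) if P else np.zeros((b, 0))
    T = np.column_stack(T) if T else np.zeros((n, 0))
    Q = np.column_stack(Q) if Q else np.zeros((len(classes), 0))
    if W.shape[1]:
        coef = W @ np.linalg.solve(P.T @ W, Q.T)
    else:
        coef = np.zeros((b, len(classes)))

    return OPLSModel(
        classes=classes,
        center_vector=center,
        y_mean=y_mean,
        pred_weights=W,
        pred_loadings=P,
        pred_scores=T,
        y_loadings=Q,
        orth_weights=np.column_stack(Wo) if Wo else np.zeros((b, 0)),
        orth_loadings=np.column_stack(Po) if Po else np.zeros((b, 0)),
        orth_scores=np.column_stack(To) if To else np.zeros((n, 0)),
        coef=coef,
        n_pred=W.shape[1],
        n_orth=len(Wo),
    )


def predict_opls(model: OPLSModel, X_new: np.ndarray):
    """Predict class labels and per-class scores for new samples.

    New rows are centered with the training mean, stripped of the training
    orthogonal components, and pushed through the predictive regression.
    Ties in class scores resolve to the first class in label order.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.center_vector):
        raise ValueError(
            f"bin mismatch: model has {len(model.center_vector)} bins, "
            f"X_new has {X_new.shape[1]}"
        )
    Xc = X_new - model.center_vector
    for k in range(model.n_orth):
        t = Xc @ model.orth_weights[:, k]
        Xc = Xc - np.outer(t, model.orth_loadings[:, k])
    scores = Xc @ model.coef + model.y_mean
    labels = [model.classes[j] for j in np.argmax(scores, axis=1)]
    return labels, scores


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation

@dataclass
class CVReport:
    classes: list[str]
    confusion: np.ndarray            # (true class, predicted class) counts
    per_class_sensitivity: np.ndarray
    per_class_specificity: np.ndarray
    mean_accuracy: float
    per_iteration_accuracy: np.ndarray
    n_iterations: int
    train_fraction: float
    seed: int

    def format(self) -> str:
        """Human-readable confusion-matrix block with per-class rates."""
        width = max(6, max(len(c) for c in self.classes) + 1)
        lines = [
            f"MCCV report: {self.n_iterations} iterations, "
            f"train fraction {self.train_fraction:.2f}, seed {self.seed}",
            "confusion matrix (rows = true, cols = predicted):",
            " " * width + "".join(f"{c:>{width}}" for c in self.classes),
        ]
        for i, c in enumerate(self.classes):
            lines.append(
                f"{c:>{width}}" + "".join(f"{int(v):>{width}}" for v in self.confusion[i])
            )
        lines.append("per-class sensitivity / specificity:")
        for i, c in enumerate(self.classes):
            lines.append(
                f"  {c:>{width}}  {self.per_class_sensitivity[i]:.3f} / "
                f"{self.per_class_specificity[i]:.3f}"
            )
        lines.append(f"mean accuracy: {self.mean_accuracy:.3f}")
        return "\n".join(lines)


def mccv(
    X: np.ndarray,
    class_labels,
    n_iterations: int = 100,
    train_fraction: float = 0.9,
    n_pred: int = 6,
    n_orth: int = 4,
    seed: int = 0,
) -> CVReport:
    """Monte Carlo cross-validation of the OPLS-DA classifier.

    At each iteration a stratified random ``train_fraction`` of each class
    trains the model and the held-out remainder is predicted; confusion
    counts accumulate over all iterations. Stratification guarantees every
    class is represented in both halves (with only 10 healthy samples an
    unstratified 10% draw would often contain none). Deterministic given
    ``seed``: iteration ``i`` uses an independent substream derived from it.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(class_labels)
    classes = sorted(set(labels.tolist()))
    class_idx = {c: np.flatnonzero(labels == c) for c in classes}
    for c, idx in class_idx.items():
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        n_test = max(1, int(round((1.0 - train_fraction) * len(idx))))
        if len(idx) - n_test < 2:
            raise ValueError(
                f"train fraction {train_fraction} leaves class {c!r} with "
                "fewer than 2 training samples"
            )

    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)
    iter_acc = np.empty(n_iterations)
    for it in range(n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, it]))
        train, test = [], []
        for c in classes:
            idx = class_idx[c]
            perm = rng.permutation(idx)
            n_test = max(1, int(round((1.0 - train_fraction) * len(idx))))
            test.extend(perm[:n_test])
            train.extend(perm[n_test:])
        train = np.asarray(train)
        test = np.asarray(test)
        model = fit_opls(X[train], labels[train], n_pred=n_pred, n_orth=n_orth)
        pred, _ = predict_opls(model, X[test])
        hits = 0
        for true_lab, pred_lab in zip(labels[test], pred):
            i = classes.index(true_lab)
            j = classes.index(pred_lab)
            confusion[i, j] += 1
            hits += i == j
        iter_acc[it] = hits / len(test)

    row_tot = confusion.sum(axis=1)
    col_tot = confusion.sum(axis=0)
    total = confusion.sum()
    diag = np.diag(confusion)
    sens = np.where(row_tot > 0, diag / np.maximum(row_tot, 1), np.nan)
    # specificity: of all test appearances of other classes, fraction not
    # predicted as this class
    tn = total - row_tot - col_tot + diag
    spec = np.where(total - row_tot > 0, tn / np.maximum(total - row_tot, 1), np.nan)
    return CVReport(
        classes=classes,
        confusion=confusion,
        per_class_sensitivity=sens,
        per_class_specificity=spec,
        mean_accuracy=float(diag.sum() / total),
        per_iteration_accuracy=iter_acc,
        n_iterations=n_iterations,
        train_fraction=train_fraction,
        seed=seed,
    )
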