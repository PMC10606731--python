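"""Bilinear latent-variable models for discriminant chemometrics.

PCA, PLS-DA (sequential NIPALS-style components with per-component X and Y
deflation), OPLS-DA (orthogonal-variation filtering followed by a
predictive PLS fit), VIP scores, stratified cross-validation (Q2 / RMSECV),
and the standard metric suite (R2Y, RMSEE, RMSEP, classification accuracy).

The sequential-deflation (NIPALS) decomposition is used rather than a
kernel or SIMPLS solver because its per-component deflation gives exactly
the per-component explained-Y sums of squares that the VIP definition
weights by.  Each component's weight vector is the dominant left singular
vector of the residual cross-covariance X'Y — the exact fixed point of the
NIPALS inner iteration — computed directly, which avoids power-iteration
stagnation when late (noise) components sit on near-degenerate eigenpairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .prep import ScalingParams, scale

logger = logging.getLogger(__name__)

class ConvergenceError(RuntimeError):
    """A PLS component could not be extracted (degenerate residuals)."""


@dataclass
class LatentModel:
    """A fitted bilinear model (PCA, PLS-DA, or OPLS-DA).

    Scores/loadings follow the usual T/P/W/C notation: X ~ T P' (+ To Po'
    for the OPLS orthogonal part), Y_centered ~ T C'.  ``coefficients`` B
    satisfy Yhat_centered = X_scaled @ B on the (orthogonal-filtered)
    training matrix.
    """

    kind: str  # "PCA" | "PLSDA" | "OPLSDA"
    n_components: int
    x_scores: np.ndarray  # T, (n, A)
    x_loadings: np.ndarray  # P, (p, A)
    x_scaling: ScalingParams
    r2x_per_component: np.ndarray
    x_weights: np.ndarray | None = None  # W, (p, A); PLS/OPLS only
    y_loadings: np.ndarray | None = None  # C, (K, A)
    coefficients: np.ndarray | None = None  # B, (p, K)
    y_center: np.ndarray | None = None  # (K,)
    ssy_per_component: np.ndarray | None = None  # explained-Y SS per component
    r2y: float | None = None
    class_codes: list[str] = field(default_factory=list)
    orth_scores: np.ndarray | None = None  # (n, A_o)
    orth_loadings: np.ndarray | None = None  # (p, A_o)
    orth_weights: np.ndarray | None = None  # (p, A_o)
    r2x_orth_per_component: np.ndarray | None = None

    @property
    def n_orth(self) -> int:
        return 0 if self.orth_weights is None else self.orth_weights.shape[1]

    # -- prediction ----------------------------------------------------
    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new samples to (predictive) score space."""
        Xs = self.x_scaling.apply(np.asarray(X, dtype=float))
        Xs = self._remove_orthogonal(Xs)
        if self.kind == "PCA":
            return Xs @ self.x_loadings
        T = np.empty((Xs.shape[0], self.n_components))
        for a in range(self.n_components):
            t = Xs @ self.x_weights[:, a]
            T[:, a] = t
            Xs = Xs - np.outer(t, self.x_loadings[:, a])
        return T

    def _remove_orthogonal(self, Xs: np.ndarray) -> np.ndarray:
        if self.n_orth == 0:
            return Xs
        Xs = Xs.copy()
        for a in range(self.n_orth):
            t_o = Xs @ self.orth_weights[:, a]
            Xs = Xs - np.outer(t_o, self.orth_loadings[:, a])
        return Xs

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted indicator matrix Yhat (on the original, uncentered scale)."""
        if self.kind == "PCA":
            raise ValueError("PCA models have no response to predict")
        Xs = self.x_scaling.apply(np.asarray(X, dtype=float))
        Xs = self._remove_orthogonal(Xs)
        return Xs @ self.coefficients + self.y_center

    def predict_labels(self, X: np.ndarray) -> list[str]:
        """Class of the largest predicted indicator, per row."""
        Yhat = self.predict(X)
        return [self.class_codes[k] for k in np.argmax(Yhat, axis=1)]


# ---------------------------------------------------------------------------
# Class coding
# ---------------------------------------------------------------------------

def encode_classes(
    labels: list[str], class_codes: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """One-hot indicator matrix; columns ordered by sorted class code."""
    labels = list(labels)
    if class_codes is None:
        class_codes = sorted(set(labels))
        if len(class_codes) < 2:
            raise ValueError("need at least 2 distinct labels")
    index = {c: k for k, c in enumerate(class_codes)}
    unseen = [l for l in labels if l not in index]
    if unseen:
        raise ValueError(f"unseen label(s) {sorted(set(unseen))}")
    Y = np.zeros((len(labels), len(class_codes)))
    for i, l in enumerate(labels):
        Y[i, index[l]] = 1.0
    return Y, list(class_codes)


def decode_classes(Y: np.ndarray, class_codes: list[str]) -> list[str]:
    """Inverse of :func:`encode_classes` via row-wise argmax."""
    return [class_codes[k] for k in np.argmax(np.asarray(Y), axis=1)]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(X: np.ndarray, A: int, scaling: str = "mean-center") -> LatentModel:
    """Principal component analysis via SVD of the scaled matrix.

    Components maximise residual variance successively; the per-component
    explained-X fractions are therefore nonincreasing.  Loading signs are
    fixed so the largest-magnitude loading element is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A must be in [1, {min(n - 1, p)}]")
    Xs, params = scale(X, scaling)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    ss_total = float(np.sum(Xs**2))
    # deterministic sign: largest-|loading| element positive
    for a in range(A):
        jmax = np.argmax(np.abs(Vt[a]))
        if Vt[a, jmax] < 0:
            Vt[a] = -Vt[a]
            U[:, a] = -U[:, a]
    T = U[:, :A] * s[:A]
    P = Vt[:A].T
    r2x = (s[:A] ** 2) / ss_total if ss_total > 0 else np.zeros(A)
    return LatentModel(
        kind="PCA",
        n_components=A,
        x_scores=T,
        x_loadings=P,
        x_scaling=params,
        r2x_per_component=r2x,
    )


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS)
# ---------------------------------------------------------------------------

def _nipals_component(
    Xc: np.ndarray, Yc: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One PLS2 component (w, t, p, c) on the current residuals.

    w is the dominant left singular vector of Xc'Yc (the converged NIPALS
    weight), with a deterministic sign (largest-|w| element positive).
    """
    if float(np.sum(Yc**2)) <= 1e-300:
        raise ConvergenceError("response residual is numerically zero")
    S = Xc.T @ Yc  # (p, K) cross-covariance
    if float(np.sum(S**2)) <= 1e-300:
        raise ConvergenceError("response uncorrelated with X residual")
    U, _sv, _Vt = np.linalg.svd(S, full_matrices=False)
    w = U[:, 0]
    jmax = np.argmax(np.abs(w))
    if w[jmax] < 0:
        w = -w
    t = Xc @ w
    tt = t @ t
    if tt <= 1e-300:
        raise ConvergenceError("degenerate score vector")
    c = Yc.T @ t / tt
    p_vec = Xc.T @ t / tt
    return w, t, p_vec, c


def fit_plsda(
    X: np.ndarray,
    Y: np.ndarray,
    A: int,
    scaling: str = "mean-center",
    class_codes: list[str] | None = None,
) -> LatentModel:
    """PLS-DA by NIPALS with per-component deflation of X and Y.

    ``Y`` is the one-hot indicator matrix (see :func:`encode_classes`); it is
    column-centered internally.  Weights are unit-norm; the coefficient
    matrix B = W (P'W)^-1 C' maps scaled X to centered-Y predictions.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A must be in [1, {min(n - 1, p)}]")
    Xs, params = scale(X, scaling)
    y_center = Y.mean(axis=0)
    Yc = Y - y_center
    ssx_total = float(np.sum(Xs**2))
    ssy_total = float(np.sum(Yc**2))

    Xd, Yd = Xs.copy(), Yc.copy()
    W = np.empty((p, A))
    T = np.empty((n, A))
    P = np.empty((p, A))
    C = np.empty((Y.shape[1], A))
    r2x = np.empty(A)
    ssy = np.empty(A)
    for a in range(A):
        w, t, p_vec, c = _nipals_component(Xd, Yd)
        Xd -= np.outer(t, p_vec)
        Yd -= np.outer(t, c)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, p_vec, c
        tt = t @ t
        r2x[a] = tt * (p_vec @ p_vec) / ssx_total if ssx_total > 0 else 0.0
        ssy[a] = tt * (c @ c)
    B = W @ np.linalg.solve(P.T @ W, C.T)
    resid = Yc - Xs @ B
    r2y = 1.0 - float(np.sum(resid**2)) / ssy_total if ssy_total > 0 else 0.0
    return LatentModel(
        kind="PLSDA",
        n_components=A,
        x_scores=T,
        x_loadings=P,
        x_weights=W,
        y_loadings=C,
        coefficients=B,
        x_scaling=params,
        y_center=y_center,
        r2x_per_component=r2x,
        ssy_per_component=ssy,
        r2y=r2y,
        class_codes=list(class_codes) if class_codes else [],
    )


def fit_oplsda(
    X: np.ndarray,
    Y: np.ndarray,
    n_orth: int,
    n_predictive: int = 2,
    scaling: str = "mean-center",
    class_codes: list[str] | None = None,
) -> LatentModel:
    """OPLS-DA: strip Y-orthogonal X-variation, then fit the predictive part.

    Each orthogonal component takes the part of the current X-loading that is
    orthogonal to the predictive weight of a one-component PLS fit, scores it,
    and deflates X.  With ``n_orth = 0`` the model is exactly the PLS-DA fit
    with the same number of predictive components.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    Xs, params = scale(X, scaling)
    y_center = Y.mean(axis=0)
    Yc = Y - y_center
    ssx_total = float(np.sum(Xs**2))

    Xd = Xs.copy()
    Wo, To, Po, r2x_o = [], [], [], []
    for _ in range(n_orth):
        w, t, p_vec, _c = _nipals_component(Xd, Yc)
        w_o = p_vec - (w @ p_vec) * w  # loading part orthogonal to the weight
        nw = np.linalg.norm(w_o)
        if nw <= 1e-12:
            raise ConvergenceError("no Y-orthogonal X-variation left to extract")
        w_o /= nw
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd -= np.outer(t_o, p_o)
        Wo.append(w_o)
        To.append(t_o)
        Po.append(p_o)
        r2x_o.append((t_o @ t_o) * (p_o @ p_o) / ssx_total if ssx_total > 0 else 0.0)

    # predictive fit on the filtered matrix (scaling already applied)
    inner = fit_plsda(Xd, Y, n_predictive, scaling="none", class_codes=class_codes)
    # r2x of predictive components relative to the ORIGINAL scaled X
    tt_pp = np.einsum("ia,ia->a", inner.x_scores, inner.x_scores) * np.einsum(
        "ja,ja->a", inner.x_loadings, inner.x_loadings
    )
    r2x_pred = tt_pp / ssx_total if ssx_total > 0 else np.zeros(n_predictive)
    return LatentModel(
        kind="OPLSDA",
        n_components=n_predictive,
        x_scores=inner.x_scores,
        x_loadings=inner.x_loadings,
        x_weights=inner.x_weights,
        y_loadings=inner.y_loadings,
        coefficients=inner.coefficients,
        x_scaling=params,
        y_center=y_center,
        r2x_per_component=r2x_pred,
        ssy_per_component=inner.ssy_per_component,
        r2y=inner.r2y,
        class_codes=list(class_codes) if class_codes else [],
        orth_scores=np.column_stack(To) if To else None,
        orth_loadings=np.column_stack(Po) if Po else None,
        orth_weights=np.column_stack(Wo) if Wo else None,
        r2x_orth_per_component=np.array(r2x_o) if r2x_o else None,
    )


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def vip_scores(model: LatentModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) where
    SSY_a is the response sum of squares explained by component a.  The mean
    squared VIP is 1 by construction (sum VIP_j^2 = p).
    """
    if model.kind == "PCA" or model.x_weights is None:
        raise ValueError("VIP requires a discriminant (PLS/OPLS) model")
    W = model.x_weights
    ssy = model.ssy_per_component
    p = W.shape[0]
    wnorm2 = np.sum(W**2, axis=0)
    contrib = (W**2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / np.sum(ssy))


def screen_by_vip(
    model: LatentModel, threshold: float = 1.0, strict: bool = False
) -> np.ndarray:
    """Indices of variables whose VIP meets the screening threshold.

    The metabolite-screening convention is inclusive (VIP >= threshold);
    ``strict=True`` gives the strict-inequality variant used by the
    VIP-based fusion strategy.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    vip = vip_scores(model)
    mask = vip > threshold if strict else vip >= threshold
    return np.where(mask)[0]


# ---------------------------------------------------------------------------
# Cross-validation and metrics
# ---------------------------------------------------------------------------

def stratified_folds(labels: list[str], n_folds: int) -> np.ndarray:
    """Venetian-blind fold assignment within each class (deterministic)."""
    labels = list(labels)
    folds = np.empty(len(labels), dtype=int)
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        for pos, i in enumerate(idx):
            folds[i] = pos % n_folds
    return folds


def cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    A: int,
    n_folds: int = 7,
    scaling: str = "mean-center",
) -> tuple[float, float]:
    """(Q2, RMSECV) from class-stratified cross-validated PLS-DA refits.

    Scaling and Y-centering are re-estimated inside every fold; PRESS
    accumulates squared held-out prediction errors.  Q2 = 1 - PRESS/SSY with
    SSY the held-out deviation from each fold's training mean; RMSECV =
    sqrt(PRESS / (n K)).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    labels = [str(k) for k in np.argmax(Y, axis=1)]
    folds = stratified_folds(labels, n_folds)
    n, K = Y.shape
    press = 0.0
    ssy = 0.0
    for f in sorted(set(folds)):
        test = folds == f
        train = ~test
        train_classes = set(np.argmax(Y[train], axis=1))
        if len(train_classes) < len(set(np.argmax(Y, axis=1))):
            raise ValueError(f"fold {f} removes an entire class from training")
        model = fit_plsda(X[train], Y[train], A, scaling=scaling)
        Yhat = model.predict(X[test])
        press += float(np.sum((Y[test] - Yhat) ** 2))
        ssy += float(np.sum((Y[test] - Y[train].mean(axis=0)) ** 2))
    q2 = 1.0 - press / ssy if ssy > 0 else float("nan")
    rmsecv = float(np.sqrt(press / (n * K)))
    return q2, rmsecv


@dataclass
class ModelMetrics:
    """The standard discriminant-model report: capacity, fit, prediction."""

    n_components: int
    r2x: float
    r2y: float
    q2: float
    rmsee: float
    rmsecv: float
    rmsep: float
    accuracy_train: float  # %
    accuracy_test: float  # %

    def validate(self) -> None:
        if not (0 <= self.r2y <= 1 and 0 <= self.r2x <= 1):
            raise ValueError("R2X/R2Y must lie in [0, 1]")
        if self.q2 > 1:
            raise ValueError("Q2 cannot exceed 1")
        if min(self.rmsee, self.rmsep) < 0 or (
            not np.isnan(self.rmsecv) and self.rmsecv < 0
        ):
            raise ValueError("RMSE values must be >= 0")
        if not (0 <= self.accuracy_train <= 100 and 0 <= self.accuracy_test <= 100):
            raise ValueError("accuracies must be percentages")


def evaluate(
    model: LatentModel,
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    Y_test: np.ndarray,
    q2: float = float("nan"),
    rmsecv: float = float("nan"),
) -> ModelMetrics:
    """Training/test metric suite for a fitted discriminant model.

    R2Y = 1 - SSres/SStot on the training response; RMSEE/RMSEP are root
    mean squared errors over all n x K indicator entries; accuracy is the
    percentage of rows whose argmax class matches the label.
    """
    Y_train = np.asarray(Y_train, dtype=float)
    Y_test = np.asarray(Y_test, dtype=float)
    Yhat_tr = model.predict(X_train)
    Yhat_te = model.predict(X_test)
    if Yhat_tr.shape != Y_train.shape or Yhat_te.shape != Y_test.shape:
        raise ValueError("prediction/response dimension mismatch")
    ss_res = float(np.sum((Y_train - Yhat_tr) ** 2))
    ss_tot = float(np.sum((Y_train - Y_train.mean(axis=0)) ** 2))
    r2y = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    n_tr, K = Y_train.shape
    n_te = Y_test.shape[0]
    rmsee = float(np.sqrt(ss_res / (n_tr * K)))
    rmsep = float(np.sqrt(np.sum((Y_test - Yhat_te) ** 2) / (n_te * K)))
    acc_tr = 100.0 * float(
        np.mean(np.argmax(Yhat_tr, axis=1) == np.argmax(Y_train, axis=1))
    )
    acc_te = 100.0 * float(
        np.mean(np.argmax(Yhat_te, axis=1) == np.argmax(Y_test, axis=1))
    )
    r2x = float(np.sum(model.r2x_per_component))
    if model.r2x_orth_per_component is not None:
        r2x += float(np.sum(model.r2x_orth_per_component))
    r2x = min(r2x, 1.0)  # guard fp accumulation on rank-deficient fits
    metrics = ModelMetrics(
        n_components=model.n_components,
        r2x=r2x,
        r2y=max(0.0, r2y),
        q2=q2,
        rmsee=rmsee,
        rmsecv=rmsecv,
        rmsep=rmsep,
        accuracy_train=acc_tr,
        accuracy_test=acc_te,
    )
    metrics.validate()
    if not np.isnan(q2) and q2 > metrics.r2y:
        logger.warning("Q2 (%.3f) exceeds R2Y (%.3f)", q2, metrics.r2y)
    return metrics


def explained_two_components(r2x_per_component: np.ndarray | list[float]) -> float:
    """Percent variation explained by the first two components (score-plot axes)."""
    r2 = np.asarray(r2x_per_component, dtype=float)
    if r2.size < 2:
        raise ValueError("need at least two per-component fractions")
    if np.any((r2 < 0) | (r2 > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    return 100.0 * float(r2[0] + r2[1])
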