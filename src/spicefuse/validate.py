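"""Model validation and descriptive metabolomics summaries.

Label-permutation testing with R2/Q2 intercepts (the standard overfitting
diagnostic for discriminant PLS models), hierarchical clustering of samples
on z-scored metabolite contents with per-class upregulation counts, and
compound-class composition reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .dataio import MetaboliteTable
from .latent import cross_validate, encode_classes, fit_plsda

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    """Outcome of a label-permutation validation run.

    The intercepts are from least-squares lines through the permuted
    (|correlation|, R2) and (|correlation|, Q2) points plus the unpermuted
    model at correlation 1; a Q2 intercept well below the original Q2 (and
    near or below zero) indicates no overfitting.
    """

    n_permutations: int
    correlations: np.ndarray
    r2_values: np.ndarray
    q2_values: np.ndarray
    original_r2: float
    original_q2: float
    r2_intercept: float
    q2_intercept: float

    def __post_init__(self) -> None:
        for arr in (self.correlations, self.r2_values, self.q2_values):
            if len(arr) != self.n_permutations:
                raise ValueError("per-permutation arrays must match n_permutations")
        if np.any((self.correlations < 0) | (self.correlations > 1)):
            raise ValueError("correlations must lie in [0, 1]")
        if not np.isfinite([self.r2_intercept, self.q2_intercept]).all():
            raise ValueError("intercepts must be finite")


def _intercept(corrs: np.ndarray, values: np.ndarray) -> float:
    """Intercept at correlation 0 of the least-squares line through the points."""
    A = np.column_stack([corrs, np.ones_like(corrs)])
    slope_intercept, *_ = np.linalg.lstsq(A, values, rcond=None)
    return float(slope_intercept[1])


def permutation_test(
    X: np.ndarray,
    labels: list[str],
    A: int,
    n_perm: int = 200,
    seed: int = 0,
    n_folds: int = 7,
    scaling: str = "mean-center",
) -> PermutationResult:
    """Refit the PLS-DA under randomly permuted class labels.

    For each permutation the model is refit and (|corr|, R2Y, Q2) recorded,
    where |corr| is the absolute Pearson correlation between the vectorized
    permuted and original indicator matrices.  Deterministic under a fixed
    seed.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    if len(set(labels)) < 2:
        raise ValueError("degenerate label vector")
    Y, codes = encode_classes(labels)
    base = fit_plsda(X, Y, A, scaling=scaling, class_codes=codes)
    q2_orig, _ = cross_validate(X, Y, A, n_folds=n_folds, scaling=scaling)
    rng = np.random.default_rng(seed)
    y_flat = Y.ravel() - Y.mean()
    corrs = np.empty(n_perm)
    r2s = np.empty(n_perm)
    q2s = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(len(labels))
        Yp = Y[perm]
        yp_flat = Yp.ravel() - Yp.mean()
        denom = np.linalg.norm(y_flat) * np.linalg.norm(yp_flat)
        corrs[k] = abs(float(y_flat @ yp_flat) / denom) if denom > 0 else 0.0
        model = fit_plsda(X, Yp, A, scaling=scaling, class_codes=codes)
        r2s[k] = model.r2y
        q2s[k], _ = cross_validate(X, Yp, A, n_folds=n_folds, scaling=scaling)
    all_corr = np.append(corrs, 1.0)
    return PermutationResult(
        n_permutations=n_perm,
        correlations=corrs,
        r2_values=r2s,
        q2_values=q2s,
        original_r2=base.r2y,
        original_q2=q2_orig,
        r2_intercept=_intercept(all_corr, np.append(r2s, base.r2y)),
        q2_intercept=_intercept(all_corr, np.append(q2s, q2_orig)),
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering / heatmap summaries
# ---------------------------------------------------------------------------

def zscore_contents(table: MetaboliteTable) -> np.ndarray:
    """Per-metabolite z-scores across samples (population SD).

    Zero-variance metabolites get z = 0 with a logged warning.
    """
    X = table.contents
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd <= 0
    if np.any(zero):
        logger.warning(
            "%d zero-variance metabolite(s); z-scores set to 0", int(zero.sum())
        )
        sd = np.where(zero, 1.0, sd)
    Z = (X - mu) / sd
    Z[:, zero] = 0.0
    return Z


@dataclass
class HcaResult:
    """Agglomerative clustering of samples on z-scored metabolite contents."""

    linkage: np.ndarray  # scipy (n-1, 4) merge table
    leaf_order: np.ndarray
    zscores: np.ndarray  # samples x metabolites
    upregulated: dict[str, int]  # per-class upregulated-metabolite counts


def hca(
    table: MetaboliteTable,
    linkage_method: str = "ward",
    distance: str = "euclidean",
) -> HcaResult:
    """Hierarchical clustering heatmap summary.

    Samples are clustered on per-metabolite z-scored contents (Ward linkage
    on Euclidean distances by default); the per-class upregulation counts of
    :func:`upregulated_counts` are attached.
    """
    if table.n_samples < 2 or len(table.metabolite_names) < 1:
        raise ValueError("need >= 2 samples and >= 1 metabolite")
    Z = zscore_contents(table)
    link = hierarchy.linkage(Z, method=linkage_method, metric=distance)
    return HcaResult(
        linkage=link,
        leaf_order=hierarchy.leaves_list(link),
        zscores=Z,
        upregulated=upregulated_counts(table),
    )


def upregulated_counts(
    table: MetaboliteTable, labels: list[str] | None = None
) -> dict[str, int]:
    """Per-class counts of metabolites most elevated in that class.

    A metabolite counts as upregulated in the class whose mean z-score for
    it is the maximum over classes AND positive; each metabolite is
    assigned to at most one class, so counts sum to at most the number of
    metabolites.
    """
    labels = list(labels) if labels is not None else list(table.labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    Z = zscore_contents(table)
    class_mean = np.vstack(
        [Z[[i for i, l in enumerate(labels) if l == c]].mean(axis=0) for c in classes]
    )
    counts = {c: 0 for c in classes}
    winner = np.argmax(class_mean, axis=0)
    for j, c_idx in enumerate(winner):
        if class_mean[c_idx, j] > 0:
            counts[classes[c_idx]] += 1
    return counts


def compound_class_composition(
    table: MetaboliteTable, selected: np.ndarray | list[int] | None = None
) -> dict[str, float]:
    """Percent of (selected) metabolites per compound class, 2-decimal.

    "Terpenoids" aggregates Monoterpenes + Sesquiterpenes.  An empty
    selection returns an empty report.
    """
    names = table.metabolite_names
    if selected is not None:
        names = [names[i] for i in selected]
    if not names:
        return {}
    total = len(names)
    counts: dict[str, int] = {}
    for m in names:
        cls = table.compound_class[m]
        counts[cls] = counts.get(cls, 0) + 1
    pct = {cls: round(100.0 * c / total, 2) for cls, c in counts.items()}
    terp = counts.get("Monoterpenes", 0) + counts.get("Sesquiterpenes", 0)
    pct["Terpenoids"] = round(100.0 * terp / total, 2)
    return pct
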