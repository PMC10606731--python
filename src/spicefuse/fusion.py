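"""Multi-block NIR+MIR fusion strategies and the strategy-comparison harness.

Three ways of combining spectral blocks before a final PLS-DA:

* low-level   — concatenate the (block-scaled) full spectra;
* mid-level (VIP > 1) — per-block PLS-DA variable selection, concatenate the
  surviving channels;
* mid-level (latent variables) — per-block PLS-DA and PCA scores,
  concatenated.

Every selection/projection parameter is estimated on calibration rows only
and applied unchanged to validation rows, so the external validation stays
honest.  The same sample split is reused across strategies to keep the
comparison paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import SpectraBlock
from .latent import (
    LatentModel,
    ModelMetrics,
    cross_validate,
    encode_classes,
    evaluate,
    fit_pca,
    fit_plsda,
    vip_scores,
)
from .prep import SplitAssignment, scale, stratified_split
from .validate import PermutationResult, permutation_test

logger = logging.getLogger(__name__)

STRATEGIES = ("low_level", "mid_level_vip", "mid_level_lv")

#: Final-model latent-variable counts per strategy (the published capacities).
DEFAULT_FINAL_COMPONENTS = {"low_level": 23, "mid_level_vip": 22, "mid_level_lv": 12}


@dataclass
class FusionConfig:
    """Configuration of one fusion strategy run."""

    strategy: str
    vip_threshold: float = 1.0  # strict > for the VIP fusion strategy
    vip_model_components: int = 10  # per-block PLS-DA behind VIP selection
    components_per_block: int = 5  # PLS scores per block (mid_level_lv)
    pcs_per_block: int = 5  # PCA scores per block (mid_level_lv)
    block_scaling: str = "block-variance"  # or "none"
    final_model_components: int | None = None  # None -> published default
    cv_folds: int = 7
    n_permutations: int = 20  # 0 skips the permutation test
    permutation_seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.vip_threshold <= 0:
            raise ValueError("vip_threshold must be > 0")
        if min(self.components_per_block, self.pcs_per_block + 1) < 1:
            raise ValueError("component counts must be >= 1 (pcs may be 0)")
        if self.block_scaling not in ("block-variance", "none"):
            raise ValueError("block_scaling must be 'block-variance' or 'none'")

    def resolved_components(self) -> int:
        if self.final_model_components is not None:
            return self.final_model_components
        return DEFAULT_FINAL_COMPONENTS[self.strategy]


@dataclass
class FusedMatrices:
    """Row-aligned fused calibration/validation design matrices."""

    train: np.ndarray
    test: np.ndarray
    block_columns: list[int]  # fused columns contributed per block
    selected_per_block: list[np.ndarray] | None = None  # VIP strategy
    block_models: list[LatentModel] | None = None


@dataclass
class FusionResult:
    """One strategy's fused data, final model, metric suite, and validation."""

    config: FusionConfig
    fused: FusedMatrices
    model: LatentModel
    metrics: ModelMetrics
    permutation: PermutationResult | None = None
    class_codes: list[str] = field(default_factory=list)


def _check_blocks(blocks: list[SpectraBlock]) -> None:
    if not blocks:
        raise ValueError("need at least one block")
    ids = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ids:
            raise ValueError("blocks do not share sample_ids/ordering")


def _center_and_block_scale(
    X: np.ndarray, cal: np.ndarray, block_scaling: str
) -> tuple[np.ndarray, np.ndarray, float]:
    """Center by calibration means; optionally divide the whole block by the
    square root of its total calibration variance so no block dominates."""
    center = X[cal].mean(axis=0)
    Xc = X - center
    factor = 1.0
    if block_scaling == "block-variance":
        total_var = float(np.sum(Xc[cal] ** 2) / max(len(cal) - 1, 1))
        if total_var > 0:
            factor = 1.0 / np.sqrt(total_var)
    return Xc * factor, center, factor


def shared_split(
    blocks: list[SpectraBlock], labels: list[str], cal_fraction: float = 0.7
) -> SplitAssignment:
    """One Kennard-Stone split for all strategies, so comparisons are paired.

    Computed per class on the autoscaled low-level concatenation of all
    blocks; at 13 classes x 15 samples and 0.7 this gives the 143/52
    calibration/validation partition.
    """
    _check_blocks(blocks)
    X = np.hstack([b.intensities for b in blocks])
    Xs, _ = scale(X, "autoscale")
    return stratified_split(Xs, labels, cal_fraction)


def fuse_low_level(
    blocks: list[SpectraBlock],
    split: SplitAssignment,
    block_scaling: str = "block-variance",
) -> FusedMatrices:
    """Column-wise concatenation of the centered, block-scaled spectra."""
    _check_blocks(blocks)
    cal, val = split.calibration_indices, split.validation_indices
    train_parts, test_parts, widths = [], [], []
    for b in blocks:
        Xs, _, _ = _center_and_block_scale(b.intensities, cal, block_scaling)
        train_parts.append(Xs[cal])
        test_parts.append(Xs[val])
        widths.append(Xs.shape[1])
    return FusedMatrices(
        train=np.hstack(train_parts), test=np.hstack(test_parts), block_columns=widths
    )


def fuse_mid_level_vip(
    blocks: list[SpectraBlock],
    labels: list[str],
    split: SplitAssignment,
    threshold: float = 1.0,
    n_components: int = 10,
    block_scaling: str = "block-variance",
) -> FusedMatrices:
    """Per-block PLS-DA VIP selection (strict VIP > threshold), then concatenate.

    Selection is determined by calibration rows only and applied unchanged
    to validation rows.  A block in which no channel passes the threshold is
    an error naming the block.
    """
    _check_blocks(blocks)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    cal, val = split.calibration_indices, split.validation_indices
    labels = list(labels)
    Y_cal, codes = encode_classes([labels[i] for i in cal])
    train_parts, test_parts, widths, selected, models = [], [], [], [], []
    for b in blocks:
        X = b.intensities
        A = min(n_components, len(cal) - 1, X.shape[1])
        model = fit_plsda(X[cal], Y_cal, A, scaling="mean-center", class_codes=codes)
        vip = vip_scores(model)
        keep = np.where(vip > threshold)[0]
        if keep.size == 0:
            raise ValueError(
                f"no variable passes VIP > {threshold} in block {b.modality}"
            )
        Xs, _, _ = _center_and_block_scale(X[:, keep], cal, block_scaling)
        train_parts.append(Xs[cal])
        test_parts.append(Xs[val])
        widths.append(keep.size)
        selected.append(keep)
        models.append(model)
    return FusedMatrices(
        train=np.hstack(train_parts),
        test=np.hstack(test_parts),
        block_columns=widths,
        selected_per_block=selected,
        block_models=models,
    )


def fuse_mid_level_lv(
    blocks: list[SpectraBlock],
    labels: list[str],
    split: SplitAssignment,
    A_per_block: int = 5,
    pcs_per_block: int = 5,
) -> FusedMatrices:
    """Per-block [PLS-DA scores || PCA scores], fit on calibration rows only.

    The fused representation has sum_b (A_b + pcs_b) columns; calibration
    rows project exactly onto their training scores.
    """
    _check_blocks(blocks)
    if A_per_block < 1 or pcs_per_block < 0:
        raise ValueError("A_per_block >= 1 and pcs_per_block >= 0 required")
    cal, val = split.calibration_indices, split.validation_indices
    labels = list(labels)
    Y_cal, codes = encode_classes([labels[i] for i in cal])
    train_parts, test_parts, widths, models = [], [], [], []
    for b in blocks:
        X = b.intensities
        max_A = min(len(cal) - 1, X.shape[1])
        if A_per_block > max_A or pcs_per_block > max_A:
            raise ValueError(
                f"component count exceeds rank of block {b.modality} ({max_A})"
            )
        pls = fit_plsda(
            X[cal], Y_cal, A_per_block, scaling="mean-center", class_codes=codes
        )
        cols_tr = [pls.x_scores]
        cols_te = [pls.transform(X[val])]
        models.append(pls)
        if pcs_per_block > 0:
            pca = fit_pca(X[cal], pcs_per_block, scaling="mean-center")
            cols_tr.append(pca.x_scores)
            cols_te.append(pca.transform(X[val]))
            models.append(pca)
        train_parts.append(np.hstack(cols_tr))
        test_parts.append(np.hstack(cols_te))
        widths.append(A_per_block + pcs_per_block)
    return FusedMatrices(
        train=np.hstack(train_parts),
        test=np.hstack(test_parts),
        block_columns=widths,
        block_models=models,
    )


def run_strategy(
    blocks: list[SpectraBlock],
    labels: list[str],
    split: SplitAssignment,
    config: FusionConfig,
) -> FusionResult:
    """Fuse, fit the final PLS-DA, evaluate the full metric suite.

    Also runs the label-permutation validation when
    ``config.n_permutations > 0`` (>= 20 permutations required by the
    permutation routine).
    """
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("need at least two classes")
    if config.strategy == "low_level":
        fused = fuse_low_level(blocks, split, config.block_scaling)
    elif config.strategy == "mid_level_vip":
        fused = fuse_mid_level_vip(
            blocks,
            labels,
            split,
            threshold=config.vip_threshold,
            n_components=config.vip_model_components,
            block_scaling=config.block_scaling,
        )
    else:
        fused = fuse_mid_level_lv(
            blocks,
            labels,
            split,
            A_per_block=config.components_per_block,
            pcs_per_block=config.pcs_per_block,
        )
    cal, val = split.calibration_indices, split.validation_indices
    cal_labels = [labels[i] for i in cal]
    val_labels = [labels[i] for i in val]
    Y_cal, codes = encode_classes(cal_labels)
    Y_val, _ = encode_classes(val_labels, codes)
    A = config.resolved_components()
    max_A = min(fused.train.shape[0] - 1, fused.train.shape[1])
    if A > max_A:
        raise ValueError(
            f"final_model_components={A} exceeds fused capacity {max_A}"
        )
    model = fit_plsda(fused.train, Y_cal, A, scaling="mean-center", class_codes=codes)
    q2, rmsecv = cross_validate(
        fused.train, Y_cal, A, n_folds=config.cv_folds, scaling="mean-center"
    )
    metrics = evaluate(
        model, fused.train, Y_cal, fused.test, Y_val, q2=q2, rmsecv=rmsecv
    )
    perm = None
    if config.n_permutations > 0:
        perm = permutation_test(
            fused.train,
            cal_labels,
            A,
            n_perm=config.n_permutations,
            seed=config.permutation_seed,
            n_folds=config.cv_folds,
        )
    return FusionResult(
        config=config,
        fused=fused,
        model=model,
        metrics=metrics,
        permutation=perm,
        class_codes=codes,
    )


def report(results: list[FusionResult]) -> pd.DataFrame:
    """Strategy-comparison table in the standard column order."""
    names = {
        "low_level": "Low-level data fusion",
        "mid_level_vip": "Mid-level data fusion (VIP > 1)",
        "mid_level_lv": "Mid-level data fusion (latent variables)",
    }
    rows = []
    for i, res in enumerate(results):
        m = res.metrics
        rows.append(
            {
                "Model": f"Model {'I' * (i + 1) if i < 3 else i + 1}",
                "Data Fusion Strategy": names[res.config.strategy],
                "LV": m.n_components,
                "R2Y": round(m.r2y, 3),
                "Q2": round(m.q2, 3),
                "RMSEE": round(m.rmsee, 4),
                "RMSECV": round(m.rmsecv, 4),
                "RMSEP": round(m.rmsep, 4),
                "Accuracy of Training Set (%)": m.accuracy_train,
                "Accuracy of Test Set (%)": m.accuracy_test,
            }
        )
    return pd.DataFrame(rows)
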