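"""Preprocessing: replicate averaging, internal-standard normalization,
variable scaling, and Kennard-Stone calibration/validation partitioning."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .dataio import SpectraBlock

logger = logging.getLogger(__name__)

SCALING_MODES = ("mean-center", "autoscale", "pareto", "none")


@dataclass
class ScalingParams:
    """Per-variable centering/scaling; applying then inverting is the identity."""

    center: np.ndarray
    scale: np.ndarray
    mode: str

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def invert(self, X_scaled: np.ndarray) -> np.ndarray:
        return np.asarray(X_scaled, dtype=float) * self.scale + self.center


@dataclass
class SplitAssignment:
    """Disjoint calibration/validation index sets covering a sample collection."""

    calibration_indices: np.ndarray
    validation_indices: np.ndarray

    def __post_init__(self) -> None:
        self.calibration_indices = np.asarray(self.calibration_indices, dtype=int)
        self.validation_indices = np.asarray(self.validation_indices, dtype=int)
        cal, val = set(self.calibration_indices), set(self.validation_indices)
        if not cal or not val:
            raise ValueError("both calibration and validation must be non-empty")
        if cal & val:
            raise ValueError("calibration and validation sets overlap")

    @property
    def n_total(self) -> int:
        return len(self.calibration_indices) + len(self.validation_indices)

    def to_frame(self, sample_ids: list[str]) -> pd.DataFrame:
        """Two-column audit table (sample_id, set)."""
        rows = [(sample_ids[i], "calibration") for i in self.calibration_indices]
        rows += [(sample_ids[i], "validation") for i in self.validation_indices]
        return pd.DataFrame(rows, columns=["sample_id", "set"])


def average_replicates(block: SpectraBlock) -> SpectraBlock:
    """Arithmetic mean spectrum per sample_id over its instrument replicates.

    The acquisition protocol collects each sample three times and analyses
    the average spectrum; labels must agree across a sample's replicates.
    """
    if block.replicate_index is None:
        raise ValueError("block has no replicate_index; nothing to average")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(block.sample_ids):
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(i)
    labels = []
    means = np.empty((len(order), block.n_channels))
    for row, sid in enumerate(order):
        idx = groups[sid]
        lab = {block.labels[i] for i in idx}
        if len(lab) != 1:
            raise ValueError(f"sample {sid!r} has conflicting labels {sorted(lab)}")
        labels.append(lab.pop())
        means[row] = block.intensities[idx].mean(axis=0)
    return SpectraBlock(
        modality=block.modality,
        wavenumbers=block.wavenumbers,
        intensities=means,
        sample_ids=order,
        labels=labels,
        replicate_index=None,
    )


def internal_standard_normalize(
    peak_areas: np.ndarray, is_area: float, is_concentration: float = 100.0
) -> np.ndarray:
    """Relative content from peak areas via the spiked internal standard.

    content_i = (area_i / is_area) * is_concentration, the percent-scale
    relative content used throughout the metabolite tables.  The default
    concentration matches the 100 ug/mL 1,2-dichlorobenzene standard.
    """
    areas = np.asarray(peak_areas, dtype=float)
    if is_area <= 0:
        raise ValueError("internal-standard area must be > 0")
    if np.any(areas < 0):
        raise ValueError("peak areas must be >= 0")
    return areas / is_area * is_concentration


def scale(X: np.ndarray, mode: str = "autoscale") -> tuple[np.ndarray, ScalingParams]:
    """Column-wise scaling; returns the scaled matrix and invertible params.

    Zero-variance columns under autoscale/pareto get scale 1 (centered only)
    with a logged warning rather than an exception.
    """
    X = np.asarray(X, dtype=float)
    if mode not in SCALING_MODES:
        raise ValueError(f"unknown scaling mode {mode!r}")
    p = X.shape[1]
    if mode == "none":
        params = ScalingParams(np.zeros(p), np.ones(p), mode)
        return X.copy(), params
    center = X.mean(axis=0)
    if mode == "mean-center":
        s = np.ones(p)
    else:
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(p)
        zero = sd <= 0
        if np.any(zero):
            logger.warning(
                "%d zero-variance variable(s) under %s; scale set to 1",
                int(zero.sum()),
                mode,
            )
            sd = sd.copy()
            sd[zero] = 1.0
        s = sd if mode == "autoscale" else np.sqrt(sd)
    params = ScalingParams(center, s, mode)
    return params.apply(X), params


def apply_scaling(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    return params.apply(X)


def kennard_stone(X: np.ndarray, n_select: int) -> np.ndarray:
    """Deterministic greedy maximin selection of representative samples.

    Initialise with the pair at maximal Euclidean distance, then repeatedly
    add the candidate whose minimum distance to the selected set is largest;
    all ties break to the lowest index.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must be in [2, {n}], got {n_select}")
    D = cdist(X, X)
    i, j = np.unravel_index(np.argmax(D), D.shape)  # first max: lowest (i, j)
    selected = [min(i, j), max(i, j)]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_select:
        cand = np.where(remaining)[0]
        best = cand[np.argmax(min_dist[cand])]  # argmax takes first -> lowest index
        selected.append(int(best))
        remaining[best] = False
        min_dist = np.minimum(min_dist, D[best])
    return np.array(selected, dtype=int)


def stratified_split(
    X: np.ndarray, labels: list[str], cal_fraction: float = 0.7
) -> SplitAssignment:
    """Per-class Kennard-Stone split: ceil(cal_fraction x class size) per class.

    With 13 classes x 15 samples at 0.7 this yields ceil(10.5) = 11 per class,
    i.e. the published 143-calibration / 52-validation partition.  A class
    quota of 1 (possible on tiny classes) selects the sample nearest the
    class centroid, since the maximin rule needs at least two picks.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if not 0 < cal_fraction < 1:
        raise ValueError("cal_fraction must be in (0, 1)")
    cal: list[int] = []
    val: list[int] = []
    for lab in sorted(set(labels)):
        idx = np.array([i for i, l in enumerate(labels) if l == lab])
        if len(idx) < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 samples")
        k = int(np.ceil(cal_fraction * len(idx)))
        k = min(k, len(idx))
        if k == 1:
            centroid = X[idx].mean(axis=0)
            pick = np.array([np.argmin(np.linalg.norm(X[idx] - centroid, axis=1))])
        else:
            pick = kennard_stone(X[idx], k)
        chosen = set(idx[pick].tolist())
        cal.extend(sorted(chosen))
        val.extend(i for i in idx if i not in chosen)
    return SplitAssignment(np.sort(cal), np.sort(val))
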