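"""Shared fixtures: the full synthetic study and small toy datasets."""

from __future__ import annotations

import numpy as np
import pytest

import spicefuse as sf
from spicefuse.fusion import shared_split
from spicefuse.prep import average_replicates
from spicefuse.synthgen import (
    GeneratorConfig,
    default_class_specs,
    generate_metabolite_table,
    generate_spectra,
)

STUDY_SEED = 42  # the simulated-study realisation used by end-to-end tests


@pytest.fixture(scope="session")
def class_specs():
    return default_class_specs()


@pytest.fixture(scope="session")
def study(class_specs):
    """Full simulated design: 13 classes x 15 samples, averaged NIR+MIR blocks."""
    cfg = GeneratorConfig(seed=STUDY_SEED)
    table = generate_metabolite_table(class_specs, cfg)
    nir = average_replicates(generate_spectra(table, "NIR", cfg))
    mir = average_replicates(generate_spectra(table, "MIR", cfg))
    split = shared_split([nir, mir], nir.labels, 0.7)
    return {"config": cfg, "table": table, "nir": nir, "mir": mir, "split": split}


@pytest.fixture(scope="session")
def toy_classes():
    """Separable 4-class toy problem for model-level tests (fast)."""
    rng = np.random.default_rng(7)
    n_per, p = 10, 30
    centers = rng.normal(0, 3, size=(4, p))
    X = np.vstack([c + rng.normal(0, 0.5, size=(n_per, p)) for c in centers])
    labels = [c for c in "ABCD" for _ in range(n_per)]
    return X, labels
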