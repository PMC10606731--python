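"""Synthetic GC-MS metabolite tables and NIR/MIR spectra for thirteen spices.

The study design being emulated: 13 Zingiberaceae species x 15 powder
samples each (195 samples), three instrument replicates per sample for each
spectral modality.  Per-class metabolite relative contents are drawn from
the published mean +/- SD summary shipped with the package; spectra are sums
of Gaussian bands at the literature absorption positions, with band
amplitudes an affine function of the sample's metabolite contents so class
differences in composition propagate to class-specific band intensities.

The content->amplitude map is an artifact convention (the literature links
band-intensity differences to compositional differences without giving a
forward model); it uses a fixed seeded nonnegative loading matrix so the
map itself is identical across runs and configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import MetaboliteTable, SpectraBlock, load_main_metabolite_summary

#: Common absorption-band positions (cm^-1) reported for these spices.
NIR_BAND_CENTERS = (8330.0, 6803.0, 5696.0, 5179.0, 4693.0)
MIR_BAND_CENTERS = (3289.0, 2921.0, 2854.0, 1623.0, 1425.0, 1369.0, 1315.0, 1240.0, 1010.0)

#: Acquisition grids: range (high, low) and step, cm^-1.
NIR_GRID = (12000.0, 4000.0, 8.0)
MIR_GRID = (4000.0, 400.0, 16.0)

# The forward map from contents to band amplitudes is frozen: one fixed seed,
# independent of GeneratorConfig.seed, so the "instrument response" and the
# species' matrix signatures do not change between simulation runs.
_STRUCTURE_SEED = 136217
_AMPLITUDE_SCALE = 0.05
_BASELINE_AMPLITUDE = 0.05
# Species-specific bulk-matrix absorption per band (starch, cellulose,
# protein...): powder spectra are dominated by the non-volatile matrix, which
# is stable within a species and differs between species.  Uniform draws on
# [0, _CLASS_MATRIX_RANGE] absorbance units per (class, band).
_CLASS_MATRIX_RANGE = 0.6


@dataclass
class ClassSpec:
    """Per-species generative parameters.

    ``metabolite_means``/``metabolite_sds`` give the relative content (%) of
    each metabolite; metabolites absent from the species carry mean 0, SD 0.
    ``band_amplitudes`` records the expected (noise-free) band amplitude per
    modality implied by the class mean composition.
    """

    species_code: str
    species: str
    metabolite_means: dict[str, float]
    metabolite_sds: dict[str, float]
    band_amplitudes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mean in self.metabolite_means.items():
            sd = self.metabolite_sds.get(name)
            if sd is None:
                raise ValueError(f"metabolite {name!r} has a mean but no SD")
            if mean < 0 or sd < 0:
                raise ValueError(f"negative mean/SD for {name!r}")

    def mean(self, metabolite: str) -> float:
        """Mean relative content (%); absent metabolites are 0 by convention."""
        return self.metabolite_means.get(metabolite, 0.0)

    def sd(self, metabolite: str) -> float:
        return self.metabolite_sds.get(metabolite, 0.0)


@dataclass
class GeneratorConfig:
    """Simulation design: counts, noise levels (absorbance units), seed."""

    n_classes: int = 13
    n_samples_per_class: int = 15
    n_replicates: int = 3
    noise_sd: float = 0.005
    baseline_drift_sd: float = 0.01
    seed: int = 0
    nir_fwhm: float = 120.0  # Gaussian band FWHM, cm^-1
    mir_fwhm: float = 40.0

    def __post_init__(self) -> None:
        if min(self.n_classes, self.n_samples_per_class, self.n_replicates) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd < 0 or self.baseline_drift_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.nir_fwhm <= 0 or self.mir_fwhm <= 0:
            raise ValueError("band widths must be > 0")


def _metabolite_universe() -> tuple[list[str], dict[str, str]]:
    """All metabolites of the packaged summary, in first-appearance order,
    with one compound class per metabolite (majority over per-species rows)."""
    df = load_main_metabolite_summary()
    names: list[str] = []
    classes: dict[str, str] = {}
    votes: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        m = row["metabolite"]
        if m not in names:
            names.append(m)
        votes.setdefault(m, []).append(row["compound_class"])
    for m, vs in votes.items():
        # majority; ties resolved by first appearance
        classes[m] = max(sorted(set(vs), key=vs.index), key=vs.count)
    return names, classes


def default_compound_classes() -> dict[str, str]:
    """Compound class for every metabolite in the packaged summary."""
    return _metabolite_universe()[1]


def band_loading_matrix(modality: str, metabolite_names: list[str]) -> np.ndarray:
    """Fixed seeded nonnegative (n_bands x n_metabolites) loading matrix."""
    centers = NIR_BAND_CENTERS if modality == "NIR" else MIR_BAND_CENTERS
    rng = np.random.default_rng([_STRUCTURE_SEED, 0 if modality == "NIR" else 1])
    return rng.uniform(0.0, 1.0, size=(len(centers), len(metabolite_names)))


def class_matrix_amplitudes(species_code: str, modality: str) -> np.ndarray:
    """Fixed per-class bulk-matrix band amplitudes (absorbance units).

    Seeded from the class code string, so any code (not only A-M) maps to a
    stable species signature.
    """
    centers = NIR_BAND_CENTERS if modality == "NIR" else MIR_BAND_CENTERS
    key = [_STRUCTURE_SEED, 2 if modality == "NIR" else 3]
    key += [ord(ch) for ch in species_code]
    rng = np.random.default_rng(key)
    return rng.uniform(0.0, _CLASS_MATRIX_RANGE, size=len(centers))


def _band_amplitudes(
    contents: np.ndarray, modality: str, names: list[str], labels: list[str] | None = None
) -> np.ndarray:
    """baseline + species matrix signature + affine volatile-content term."""
    load = band_loading_matrix(modality, names)
    amps = _BASELINE_AMPLITUDE + _AMPLITUDE_SCALE * contents @ load.T
    if labels is not None:
        matrix = {c: class_matrix_amplitudes(c, modality) for c in set(labels)}
        amps = amps + np.vstack([matrix[l] for l in labels])
    return amps


def default_class_specs() -> list[ClassSpec]:
    """The thirteen species, parameterised by the packaged content summary.

    Each spec carries the six published main-metabolite means/SDs of its
    species; every other metabolite in the shared universe gets mean 0, SD 0.
    """
    df = load_main_metabolite_summary()
    names, _ = _metabolite_universe()
    specs: list[ClassSpec] = []
    for code, sub in df.groupby("code", sort=True):
        means = {m: 0.0 for m in names}
        sds = {m: 0.0 for m in names}
        for _, row in sub.iterrows():
            means[row["metabolite"]] = float(row["mean_pct"])
            sds[row["metabolite"]] = float(row["sd_pct"])
        mean_vec = np.array([means[m] for m in names])
        amps = {
            mod: _band_amplitudes(mean_vec[None, :], mod, names, [str(code)])[0]
            for mod in ("NIR", "MIR")
        }
        specs.append(
            ClassSpec(
                species_code=str(code),
                species=str(sub["species"].iloc[0]),
                metabolite_means=means,
                metabolite_sds=sds,
                band_amplitudes=amps,
            )
        )
    return specs


def generate_metabolite_table(
    specs: list[ClassSpec], config: GeneratorConfig
) -> MetaboliteTable:
    """Draw per-sample relative contents from each class's truncated normals.

    Contents are Normal(mean, sd) truncated at zero (relative contents are
    nonnegative); sd = 0 gives the mean exactly.  Bit-identical under a fixed
    (specs, config) pair.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if config.n_classes > len(specs):
        raise ValueError(
            f"config.n_classes={config.n_classes} exceeds {len(specs)} specs"
        )
    use = specs[: config.n_classes]
    names: list[str] = []
    for spec in use:
        for m in spec.metabolite_means:
            if m not in names:
                names.append(m)
    default_classes = default_compound_classes()
    compound_class = {m: default_classes.get(m, "other") for m in names}

    rng = np.random.default_rng([int(config.seed) % 2**31, 11])
    rows = []
    sample_ids = []
    labels = []
    for spec in use:
        means = np.array([spec.mean(m) for m in names])
        sds = np.array([spec.sd(m) for m in names])
        if np.any(sds < 0):
            raise ValueError(f"negative SD in spec {spec.species_code}")
        n = config.n_samples_per_class
        block = np.tile(means, (n, 1))
        pos = sds > 0
        if np.any(pos):
            a = (0.0 - means[pos]) / sds[pos]  # truncation at zero, in SD units
            draws = stats.truncnorm.rvs(
                a[None, :],
                np.inf,
                loc=means[None, pos],
                scale=sds[None, pos],
                size=(n, int(pos.sum())),
                random_state=rng,
            )
            block[:, pos] = draws
        rows.append(block)
        sample_ids.extend(f"{spec.species_code}{i + 1:03d}" for i in range(n))
        labels.extend([spec.species_code] * n)
    return MetaboliteTable(
        sample_ids=sample_ids,
        labels=labels,
        metabolite_names=names,
        compound_class=compound_class,
        contents=np.vstack(rows),
    )


def modality_grid(modality: str) -> np.ndarray:
    """Descending wavenumber grid for a modality (acquisition convention)."""
    if modality == "NIR":
        hi, lo, step = NIR_GRID
    elif modality == "MIR":
        hi, lo, step = MIR_GRID
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return np.arange(hi, lo - step / 2, -step)


def generate_spectra(
    table: MetaboliteTable, modality: str, config: GeneratorConfig
) -> SpectraBlock:
    """Simulate replicate absorbance spectra for every sample of ``table``.

    Each spectrum is a sum of Gaussian bands at the modality's published
    peak positions; band amplitudes are affine in the sample's metabolite
    contents, so composition differences become class-specific intensities.
    Replicates of a sample share its band amplitudes and differ only in the
    smooth random baseline and white noise realisations.
    """
    if modality not in ("NIR", "MIR"):
        raise ValueError(f"unknown modality {modality!r}")
    if table.n_samples == 0:
        raise ValueError("empty metabolite table")
    grid = modality_grid(modality)
    centers = np.array(NIR_BAND_CENTERS if modality == "NIR" else MIR_BAND_CENTERS)
    fwhm = config.nir_fwhm if modality == "NIR" else config.mir_fwhm
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    # (n_bands, n_channels) Gaussian profiles
    profiles = np.exp(-0.5 * ((grid[None, :] - centers[:, None]) / sigma) ** 2)
    amps = _band_amplitudes(
        table.contents, modality, table.metabolite_names, table.labels
    )
    clean = amps @ profiles  # (n_samples, n_channels)

    rng = np.random.default_rng(
        [int(config.seed) % 2**31, 21 if modality == "NIR" else 22]
    )
    n, p = clean.shape
    r = config.n_replicates
    x01 = np.linspace(0.0, 1.0, p)
    # 3 low-frequency cosine terms -> smooth per-replicate baseline drift
    cos_basis = np.cos(np.pi * np.arange(1, 4)[:, None] * x01[None, :])
    coeff = rng.normal(0.0, config.baseline_drift_sd, size=(n * r, 3))
    noise = rng.normal(0.0, config.noise_sd, size=(n * r, p))
    spectra = np.repeat(clean, r, axis=0) + coeff @ cos_basis + noise
    return SpectraBlock(
        modality=modality,
        wavenumbers=grid,
        intensities=spectra,
        sample_ids=list(np.repeat(table.sample_ids, r)),
        labels=list(np.repeat(table.labels, r)),
        replicate_index=np.tile(np.arange(r), n),
    )
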