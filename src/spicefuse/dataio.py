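"""Tabular I/O for spectra and metabolite tables, plus packaged reference data.

The canonical on-disk format is UTF-8 CSV with "." decimals and samples as
rows (everything downstream is samples x variables algebra).  Spectra files
carry the wavenumber grid as the header of the intensity columns; metabolite
files carry a second header row with the compound-class annotation of each
metabolite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Valid spectral modalities and their wavenumber ranges (cm^-1).
MODALITY_RANGES: dict[str, tuple[float, float]] = {
    "NIR": (4000.0, 12000.0),
    "MIR": (400.0, 4000.0),
}

#: Compound classes recognised in metabolite tables.
COMPOUND_CLASSES = (
    "Monoterpenes",
    "Sesquiterpenes",
    "Aldehydes",
    "Esters",
    "Acids",
    "Hydrocarbons",
    "other",
)

_META_COLS = ("sample_id", "label", "replicate")


class DataValidationError(ValueError):
    """A file or in-memory table violates a structural invariant."""


@dataclass
class SpectraBlock:
    """One modality's samples x channels absorbance matrix.

    Wavenumbers are stored strictly decreasing (high to low, the plotting
    convention of vibrational spectroscopy).  ``replicate_index`` is present
    while instrument replicates are still unaveraged.
    """

    modality: str
    wavenumbers: np.ndarray  # (p,), cm^-1, strictly decreasing
    intensities: np.ndarray  # (n, p), absorbance (a.u.)
    sample_ids: list[str]
    labels: list[str]
    replicate_index: np.ndarray | None = None  # (n,) ints, or None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.labels = list(self.labels)
        if self.replicate_index is not None:
            self.replicate_index = np.asarray(self.replicate_index, dtype=int)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def validate(self) -> None:
        if self.modality not in MODALITY_RANGES:
            raise DataValidationError(f"unknown modality {self.modality!r}")
        n, p = self.intensities.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise DataValidationError(
                "sample_ids/labels length does not match intensity rows"
            )
        if self.wavenumbers.shape != (p,):
            raise DataValidationError("wavenumber count does not match channels")
        if p > 1 and not np.all(np.diff(self.wavenumbers) < 0):
            raise DataValidationError("wavenumbers must be strictly decreasing")
        lo, hi = MODALITY_RANGES[self.modality]
        if self.wavenumbers.min() < lo or self.wavenumbers.max() > hi:
            raise DataValidationError(
                f"{self.modality} wavenumbers outside [{lo}, {hi}] cm^-1"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise DataValidationError("non-finite intensities")
        if self.replicate_index is not None and len(self.replicate_index) != n:
            raise DataValidationError("replicate_index length mismatch")


@dataclass
class MetaboliteTable:
    """Samples x metabolites relative-content (%) matrix with class annotation."""

    sample_ids: list[str]
    labels: list[str]
    metabolite_names: list[str]
    compound_class: dict[str, str]  # metabolite -> class
    contents: np.ndarray  # (n, m), relative content (%)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.labels = list(self.labels)
        self.metabolite_names = list(self.metabolite_names)
        self.contents = np.asarray(self.contents, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.contents.shape[0]

    def validate(self) -> None:
        n, m = self.contents.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise DataValidationError("sample_ids/labels length mismatch")
        if len(self.metabolite_names) != m:
            raise DataValidationError("metabolite name count mismatch")
        if len(set(self.metabolite_names)) != m:
            raise DataValidationError("duplicate metabolite names")
        if not np.all(np.isfinite(self.contents)) or np.any(self.contents < 0):
            raise DataValidationError("contents must be finite and >= 0")
        missing = [m_ for m_ in self.metabolite_names if m_ not in self.compound_class]
        if missing:
            raise DataValidationError(f"missing compound_class for {missing}")
        bad = {
            m_: c
            for m_, c in self.compound_class.items()
            if c not in COMPOUND_CLASSES
        }
        if bad:
            raise DataValidationError(f"unknown compound classes {bad}")


@dataclass(frozen=True)
class LabelLegend:
    """Bijection between single-letter species codes A-M and species names."""

    code_to_species: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.code_to_species) != 13:
            raise DataValidationError("legend must have exactly 13 entries")
        if len(set(self.code_to_species.values())) != 13:
            raise DataValidationError("legend must be bijective")

    def species(self, code: str) -> str:
        return self.code_to_species[code]

    def code(self, species: str) -> str:
        for c, s in self.code_to_species.items():
            if s == species:
                return c
        raise KeyError(species)


def species_legend() -> LabelLegend:
    """The thirteen Zingiberaceae species and their letter codes."""
    return LabelLegend(
        {
            "A": "Amomum koenigii",
            "B": "Amomum kravanh",
            "C": "Amomum longiligulare",
            "D": "Amomum tsaoko",
            "E": "Amomum villosum",
            "F": "Amomum maximum",
            "G": "Amomum paratsaoko",
            "H": "Alpinia galanga",
            "I": "Alpinia katsumadai",
            "J": "Alpinia zerumbet",
            "K": "Alpinia japonica",
            "L": "Alpinia oxyphylla",
            "M": "Zingiber striolatum",
        }
    )


def load_main_metabolite_summary() -> pd.DataFrame:
    """Published per-species main-metabolite summary (mean +/- SD, %).

    Returns the packaged 78-row table (13 species x 6 main volatile
    metabolites each) with columns ``code, species, metabolite,
    compound_class, mean_pct, sd_pct``.
    """
    ref = resources.files("spicefuse") / "data" / "species_main_metabolites.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df


# ---------------------------------------------------------------------------
# Spectra I/O
# ---------------------------------------------------------------------------

def write_spectra_matrix(block: SpectraBlock, path: str | Path) -> None:
    """Write a SpectraBlock as a wide CSV (sample_id, label, replicate, channels...)."""
    rep = (
        block.replicate_index
        if block.replicate_index is not None
        else np.zeros(block.n_samples, dtype=int)
    )
    df = pd.DataFrame(block.intensities, columns=[f"{w:.6g}" for w in block.wavenumbers])
    df.insert(0, "replicate", rep)
    df.insert(0, "label", block.labels)
    df.insert(0, "sample_id", block.sample_ids)
    df.to_csv(path, index=False)


def read_spectra_matrix(path: str | Path, modality: str) -> SpectraBlock:
    """Read a wide spectra CSV written by :func:`write_spectra_matrix`.

    Any violation of the SpectraBlock invariants (missing columns,
    non-numeric cells, out-of-range wavenumbers for the declared modality)
    raises :class:`DataValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in _META_COLS:
        if col not in df.columns:
            raise DataValidationError(f"missing required column {col!r}")
    channel_cols = [c for c in df.columns if c not in _META_COLS]
    try:
        wavenumbers = np.array([float(c) for c in channel_cols])
    except ValueError as exc:
        raise DataValidationError(f"non-numeric wavenumber header: {exc}") from exc
    values = df[channel_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise DataValidationError("non-numeric intensity cells")
    return SpectraBlock(
        modality=modality,
        wavenumbers=wavenumbers,
        intensities=values.astype(float),
        sample_ids=[str(s) for s in df["sample_id"]],
        labels=[str(x) for x in df["label"]],
        replicate_index=df["replicate"].to_numpy(dtype=int),
    )


# ---------------------------------------------------------------------------
# Metabolite table I/O
# ---------------------------------------------------------------------------

def write_metabolite_table(table: MetaboliteTable, path: str | Path) -> None:
    """Write a MetaboliteTable; the second row carries compound classes."""
    header = ["sample_id", "label", *table.metabolite_names]
    class_row = [
        "#compound_class",
        "",
        *[table.compound_class[m] for m in table.metabolite_names],
    ]
    body = pd.DataFrame(table.contents, columns=table.metabolite_names)
    body.insert(0, "label", table.labels)
    body.insert(0, "sample_id", table.sample_ids)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        pd.DataFrame([header]).to_csv(fh, index=False, header=False)
        pd.DataFrame([class_row]).to_csv(fh, index=False, header=False)
        body.to_csv(fh, index=False, header=False)


def read_metabolite_table(path: str | Path) -> MetaboliteTable:
    """Read a metabolite CSV written by :func:`write_metabolite_table`.

    Compound-class strings outside the recognised vocabulary are mapped to
    ``"other"`` with a logged warning; duplicate metabolite names are an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    header = list(raw.iloc[0])
    if header[:2] != ["sample_id", "label"]:
        raise DataValidationError("first header row must start sample_id,label")
    names = header[2:]
    class_row = list(raw.iloc[1])
    if class_row[0] != "#compound_class":
        raise DataValidationError("second row must be the #compound_class row")
    classes = class_row[2:]
    compound_class = {}
    for name, cls in zip(names, classes):
        if cls not in COMPOUND_CLASSES:
            logger.warning("unknown compound class %r for %r; using 'other'", cls, name)
            cls = "other"
        compound_class[name] = cls
    body = raw.iloc[2:]
    try:
        contents = body.iloc[:, 2:].to_numpy(dtype=float)
    except ValueError as exc:
        raise DataValidationError(f"non-numeric content cell: {exc}") from exc
    return MetaboliteTable(
        sample_ids=list(body.iloc[:, 0]),
        labels=list(body.iloc[:, 1]),
        metabolite_names=names,
        compound_class=compound_class,
        contents=contents,
    )
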