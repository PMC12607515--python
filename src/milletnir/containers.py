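"""Core in-memory containers shared across the pipeline.

``SpectrumSet`` (sample x wavelength reflectance) is the common currency
between instrument I/O, preprocessing, wavelength selection and modeling.
``ReferenceChemistry`` holds the wet-chemistry reference values the models
are calibrated against.  Both round-trip losslessly through plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS


@dataclass
class SpectrumSet:
    """A sample x wavelength matrix of reflectance (or processed) spectra.

    Attributes
    ----------
    sample_ids : list of str
        One identifier per row.
    reflectance : ndarray, shape (n_samples, n_bands)
    wavelengths : ndarray, shape (n_bands,)
        Band centers in nm, strictly increasing.
    metadata : dict
        Free-form provenance (applied preprocessing stages, generator
        parameters, ...).  Carried along by transformations.
    """

    sample_ids: list[str]
    reflectance: np.ndarray
    wavelengths: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be 2-D (samples x bands)")
        if self.reflectance.shape != (len(self.sample_ids), self.wavelengths.size):
            raise ValueError(
                f"shape mismatch: {self.reflectance.shape} vs "
                f"{len(self.sample_ids)} samples, {self.wavelengths.size} bands"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV: first column ``sample_id``, then one column per nm."""
        df = pd.DataFrame(
            self.reflectance,
            columns=[f"{w:.6g}" for w in self.wavelengths],
        )
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectrumSet":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id":
            raise ValueError(
                f"malformed spectra CSV {path}: first column must be "
                f"'sample_id', got '{df.columns[0]}'"
            )
        try:
            wavelengths = np.array([float(c) for c in df.columns[1:]])
        except ValueError as exc:
            raise ValueError(
                f"malformed spectra CSV {path}: non-numeric wavelength header"
            ) from exc
        return cls(
            sample_ids=[str(s) for s in df["sample_id"]],
            reflectance=df.iloc[:, 1:].to_numpy(dtype=float),
            wavelengths=wavelengths,
        )


@dataclass
class ReferenceChemistry:
    """Per-sample contents of the eight essential amino acids.

    ``contents`` columns follow :data:`milletnir.constants.AMINO_ACIDS`
    unless ``amino_acid_names`` says otherwise.  Units are percent of total
    protein (treated as arbitrary-but-consistent by the models).
    """

    sample_ids: list[str]
    contents: np.ndarray
    amino_acid_names: tuple[str, ...] = AMINO_ACIDS

    def __post_init__(self) -> None:
        self.contents = np.asarray(self.contents, dtype=float)
        if self.contents.ndim != 2:
            raise ValueError("contents must be 2-D (samples x analytes)")
        if self.contents.shape != (len(self.sample_ids), len(self.amino_acid_names)):
            raise ValueError("contents shape does not match ids/analyte names")
        if self.contents.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if np.any(self.contents < 0):
            raise ValueError("amino-acid contents must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.contents.shape[0]

    def column(self, analyte: str) -> np.ndarray:
        """Contents of one amino acid as a 1-D vector."""
        try:
            j = self.amino_acid_names.index(analyte)
        except ValueError as exc:
            raise KeyError(f"unknown analyte {analyte!r}") from exc
        return self.contents[:, j]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.contents, columns=list(self.amino_acid_names))
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceChemistry":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id":
            raise ValueError(
                f"malformed chemistry CSV {path}: first column must be 'sample_id'"
            )
        return cls(
            sample_ids=[str(s) for s in df["sample_id"]],
            contents=df.iloc[:, 1:].to_numpy(dtype=float),
            amino_acid_names=tuple(df.columns[1:]),
        )


def align(spectra: SpectrumSet, chem: ReferenceChemistry) -> None:
    """Validate that spectra and chemistry describe the same samples."""
    if spectra.sample_ids != chem.sample_ids:
        raise ValueError("spectra and chemistry sample_ids differ")
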