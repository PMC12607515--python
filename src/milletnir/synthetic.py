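"""Synthetic chemistry, spectra and raw cubes for the millet NIR pipeline.

The generator emulates a 217-sample single-variety study: amino-acid
contents are drawn from a truncated multivariate normal whose default means
match the typical millet protein composition, and reflectance spectra come
from a log10 Beer-Lambert forward model

    A(lam)  = sum_c conc_c * sum_bands amp * gauss(lam; center, width) + baseline(lam)
    R(lam)  = gain * 10**(-A(lam)) + offset + white noise

with Gaussian absorption bands placed at each amino acid's informative
wavelengths.  Multiplicative gain / additive offset emulate surface
scattering, the slow polynomial baseline emulates instrument drift, and the
white noise emulates sensor noise — exactly the interferences the
preprocessing chain (S-G, airPLS, SNV) is designed to remove.  Interferent
components ("moisture" O-H near 1450 nm, "carbohydrate" C-H near 1200 nm)
mask the low-concentration analytes as in real grain.

``generate_cube`` inverts the white/dark calibration so the instrument-I/O
stage can be exercised end to end without any instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .constants import (
    AMINO_ACIDS,
    EAA_MEAN_PERCENT,
    KEY_WAVELENGTHS_NM,
    default_wavelength_grid,
)
from .containers import ReferenceChemistry, SpectrumSet
from .instrument_io import CalibrationFrames, HyperCube

__all__ = [
    "GaussianBand",
    "SpectralComponent",
    "PureSpectraLibrary",
    "NoiseModel",
    "default_library",
    "default_means",
    "default_sds",
    "default_correlation",
    "generate_reference_chemistry",
    "generate_spectra",
    "generate_cube",
    "generate_dataset",
    "SyntheticCube",
]


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band: center (nm), width (Gaussian sigma, nm),
    amplitude (absorbance units per concentration unit)."""

    center: float
    width: float
    amplitude: float


@dataclass(frozen=True)
class SpectralComponent:
    """A pure component: an amino acid or an interferent.

    ``mean_concentration``/``concentration_cv`` are only used for
    interferents (components absent from the chemistry table), whose
    per-sample concentrations the generator draws itself.
    """

    name: str
    bands: tuple[GaussianBand, ...]
    mean_concentration: float = 1.0
    concentration_cv: float = 0.0


@dataclass
class PureSpectraLibrary:
    """Collection of pure-component spectra for the linear mixing model."""

    components: tuple[SpectralComponent, ...]

    def __post_init__(self) -> None:
        for comp in self.components:
            for b in comp.bands:
                if not (900.0 <= b.center <= 1700.0):
                    raise ValueError(
                        f"{comp.name}: band center {b.center} nm outside [900, 1700]"
                    )
                if b.width <= 0:
                    raise ValueError(f"{comp.name}: band width must be > 0")
                if b.amplitude < 0:
                    raise ValueError(f"{comp.name}: band amplitude must be >= 0")

    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def component(self, name: str) -> SpectralComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)


def default_library(
    band_width: float = 10.0,
    amplitude: float = 0.03,
    include_interferents: bool = True,
) -> PureSpectraLibrary:
    """Default library: each amino acid absorbs at its informative
    wavelengths; moisture and carbohydrate interferents add the broad O-H /
    C-H background that masks low-concentration analytes."""
    comps = [
        SpectralComponent(
            name=aa,
            bands=tuple(
                GaussianBand(center=c, width=band_width, amplitude=amplitude)
                for c in KEY_WAVELENGTHS_NM[aa]
            ),
        )
        for aa in AMINO_ACIDS
    ]
    if include_interferents:
        comps.append(
            SpectralComponent(
                name="moisture",
                bands=(GaussianBand(center=1450.0, width=45.0, amplitude=0.02),),
                mean_concentration=10.0,
                concentration_cv=0.10,
            )
        )
        comps.append(
            SpectralComponent(
                name="carbohydrate",
                bands=(GaussianBand(center=1200.0, width=45.0, amplitude=0.02),),
                mean_concentration=15.0,
                concentration_cv=0.06,
            )
        )
    return PureSpectraLibrary(components=tuple(comps))


@dataclass
class NoiseModel:
    """Instrumental/environmental artifact model.

    ``baseline_coeff_sds`` are the standard deviations of per-sample
    Legendre-style polynomial drift coefficients (absorbance units) on the
    normalized wavelength coordinate; ``scatter_gain_sigma`` is the sigma of
    a log-normal multiplicative gain (support strictly positive);
    ``scatter_offset_sd`` an additive reflectance offset;
    ``white_noise_sd`` i.i.d. sensor noise in reflectance units.
    """

    baseline_coeff_sds: tuple[float, ...] = (0.02, 0.01, 0.005)
    scatter_gain_sigma: float = 0.05
    scatter_offset_sd: float = 0.01
    white_noise_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_noise_sd < 0:
            raise ValueError("white_noise_sd must be >= 0")
        if self.scatter_gain_sigma < 0:
            raise ValueError("scatter_gain_sigma must be >= 0")

    @classmethod
    def off(cls, seed: int = 0) -> "NoiseModel":
        """Noise-free model: gain 1, offset 0, flat zero baseline."""
        return cls(
            baseline_coeff_sds=(),
            scatter_gain_sigma=0.0,
            scatter_offset_sd=0.0,
            white_noise_sd=0.0,
            seed=seed,
        )


def default_means() -> np.ndarray:
    """Default chemistry means, percent of total protein."""
    return np.array([EAA_MEAN_PERCENT[a] for a in AMINO_ACIDS])


def default_sds(cv: float = 0.05) -> np.ndarray:
    """Default standard deviations: a 5 % coefficient of variation around
    each mean, plausible for a single grain variety from one site."""
    return cv * default_means()


def default_correlation(rho: float = 0.3) -> np.ndarray:
    """Moderate positive equicorrelation among amino acids (default 0.3)."""
    n = len(AMINO_ACIDS)
    corr = np.full((n, n), rho)
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_reference_chemistry(
    n: int = 217,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
    correlation: np.ndarray | None = None,
    seed: int = 0,
) -> ReferenceChemistry:
    """Draw n samples of amino-acid contents from a truncated MVN.

    The marginal distributions are normal (matching the Shapiro-Wilk QC the
    pipeline applies downstream) and draws are clipped at zero.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    means = default_means() if means is None else np.asarray(means, dtype=float)
    sds = default_sds() if sds is None else np.asarray(sds, dtype=float)
    correlation = (
        default_correlation() if correlation is None else np.asarray(correlation, float)
    )
    k = means.size
    if sds.size != k or correlation.shape != (k, k):
        raise ValueError("means, sds and correlation sizes disagree")
    if np.any(sds < 0):
        raise ValueError("sds must be >= 0")
    if not np.allclose(correlation, correlation.T):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(correlation), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    eigs = np.linalg.eigvalsh(correlation)
    if eigs.min() < -1e-10:
        raise ValueError(
            f"correlation matrix not positive semi-definite (min eig {eigs.min():.3g})"
        )
    cov = correlation * np.outer(sds, sds)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(means, cov, size=n, method="svd")
    draws = np.clip(draws, 0.0, None)
    names = tuple(AMINO_ACIDS[:k]) if k <= len(AMINO_ACIDS) else tuple(
        f"c{i}" for i in range(k)
    )
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return ReferenceChemistry(sample_ids=ids, contents=draws, amino_acid_names=names)


def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def component_absorptivity(
    comp: SpectralComponent, grid: np.ndarray
) -> np.ndarray:
    """Unit-concentration absorbance spectrum of one component."""
    a = np.zeros_like(grid, dtype=float)
    for b in comp.bands:
        a += b.amplitude * _gauss(grid, b.center, b.width)
    return a


def absorbance_matrix(
    chem: ReferenceChemistry,
    library: PureSpectraLibrary,
    grid: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noise-free mixture absorbance, samples x bands.

    Components named in the chemistry use its concentrations; other library
    components (interferents) get per-sample log-normal concentrations drawn
    from ``rng`` (fixed at their mean when ``rng`` is None or cv == 0).
    """
    n = chem.n_samples
    A = np.zeros((n, grid.size))
    for comp in library.components:
        eps = component_absorptivity(comp, grid)
        if comp.name in chem.amino_acid_names:
            conc = chem.column(comp.name)
        else:
            if rng is not None and comp.concentration_cv > 0:
                sigma = np.sqrt(np.log1p(comp.concentration_cv**2))
                conc = comp.mean_concentration * rng.lognormal(
                    -0.5 * sigma**2, sigma, size=n
                )
            else:
                conc = np.full(n, comp.mean_concentration)
        A += np.outer(conc, eps)
    return A


def generate_spectra(
    chem: ReferenceChemistry,
    library: PureSpectraLibrary | None = None,
    grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
) -> SpectrumSet:
    """Forward-model reflectance spectra for a chemistry table."""
    library = default_library() if library is None else library
    grid = default_wavelength_grid() if grid is None else np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    noise = NoiseModel.off() if noise is None else noise
    rng = np.random.default_rng(noise.seed)
    n = chem.n_samples

    A = absorbance_matrix(chem, library, grid, rng=rng)

    # slow polynomial drift in absorbance, on u in [-1, 1]
    if noise.baseline_coeff_sds:
        u = (
            2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
            if grid.size > 1
            else np.zeros_like(grid)
        )
        sds = np.asarray(noise.baseline_coeff_sds)
        coeffs = rng.normal(0.0, 1.0, size=(n, sds.size)) * sds
        powers = np.vstack([u**k for k in range(sds.size)])  # (k, bands)
        A += coeffs @ powers

    gain = (
        rng.lognormal(0.0, noise.scatter_gain_sigma, size=n)
        if noise.scatter_gain_sigma > 0
        else np.ones(n)
    )
    offset = (
        rng.normal(0.0, noise.scatter_offset_sd, size=n)
        if noise.scatter_offset_sd > 0
        else np.zeros(n)
    )
    refl = gain[:, None] * 10.0 ** (-A) + offset[:, None]
    if noise.white_noise_sd > 0:
        refl = refl + rng.normal(0.0, noise.white_noise_sd, size=refl.shape)

    return SpectrumSet(
        sample_ids=list(chem.sample_ids),
        reflectance=refl,
        wavelengths=grid,
        metadata={
            "generator": "milletnir.synthetic.generate_spectra",
            "noise": asdict(noise),
            "library_components": library.names(),
        },
    )


@dataclass
class SyntheticCube:
    """Raw cube + calibration frames + where each sample's patch sits."""

    raw: HyperCube
    frames: CalibrationFrames
    placements: dict[str, tuple[int, int, int, int]]  # id -> (r0, c0, rows, cols)


def generate_cube(
    spectra: SpectrumSet,
    layout: tuple[int, int] = (8, 8),
    seed: int = 0,
    white_noise_sd: float = 0.0,
) -> SyntheticCube:
    """Invert the white/dark calibration to produce a raw-counts cube.

    Each sample occupies a ``layout`` = (rows, cols) rectangular patch;
    patches tile the image row-major.  Per-band white/dark reference vectors
    are returned such that calibrating the raw cube recovers the input
    reflectance up to the optional white noise.
    """
    pr, pc = layout
    if pr < 1 or pc < 1:
        raise ValueError("layout must be positive")
    n = spectra.n_samples
    grid_cols = int(np.ceil(np.sqrt(n)))
    grid_rows = int(np.ceil(n / grid_cols))
    rows, cols = grid_rows * pr, grid_cols * pc
    bands = spectra.n_bands
    if rows * cols < n * pr * pc:
        raise ValueError("layout too small to host all samples")

    rng = np.random.default_rng(seed)
    # smooth, band-dependent references as a real lamp/sensor pair would give
    dark = 100.0 + 10.0 * np.linspace(0, 1, bands)
    white = 4000.0 + 1500.0 * np.sin(np.linspace(0.3, 2.4, bands))

    refl = np.zeros((rows, cols, bands))
    placements: dict[str, tuple[int, int, int, int]] = {}
    for i, sid in enumerate(spectra.sample_ids):
        gr, gc = divmod(i, grid_cols)
        r0, c0 = gr * pr, gc * pc
        refl[r0 : r0 + pr, c0 : c0 + pc, :] = spectra.reflectance[i]
        placements[sid] = (r0, c0, pr, pc)
    if white_noise_sd > 0:
        refl = refl + rng.normal(0.0, white_noise_sd, size=refl.shape)

    raw = dark + refl * (white - dark)
    cube = HyperCube(data=raw, wavelengths=spectra.wavelengths.copy())
    return SyntheticCube(
        raw=cube,
        frames=CalibrationFrames(white=white, dark=dark),
        placements=placements,
    )


def generate_dataset(
    n: int = 217,
    seed: int = 0,
    library: PureSpectraLibrary | None = None,
    grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    sds: np.ndarray | None = None,
    correlation: np.ndarray | None = None,
) -> tuple[ReferenceChemistry, SpectrumSet]:
    """Convenience: chemistry + spectra under the default study conditions."""
    chem = generate_reference_chemistry(
        n=n, sds=sds, correlation=correlation, seed=seed
    )
    if noise is None:
        noise = NoiseModel(seed=seed + 1)
    spectra = generate_spectra(chem, library=library, grid=grid, noise=noise)
    return chem, spectra


def save_generation_config(path: str | Path, **params) -> None:
    """Log generator parameters as YAML for reproducibility."""
    clean = {}
    for k, v in params.items():
        if isinstance(v, np.ndarray):
            v = v.tolist()
        clean[k] = v
    Path(path).write_text(yaml.safe_dump(clean, sort_keys=True))
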