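"""Domain constants for the foxtail-millet NIR amino-acid pipeline.

The eight essential amino acids are handled in a fixed order throughout the
package so that chemistry matrices, model targets and reports line up without
name lookups.
"""

from __future__ import annotations

import numpy as np

#: Fixed analyte order used by every chemistry matrix in the package.
AMINO_ACIDS: tuple[str, ...] = (
    "Lys", "Phe", "Met", "Thr", "Ile", "Leu", "Val", "His",
)

#: Typical essential-amino-acid composition of foxtail millet protein,
#: in percent of total protein.  Used as the default means of the synthetic
#: chemistry generator.
EAA_MEAN_PERCENT: dict[str, float] = {
    "Lys": 1.892,
    "Phe": 7.918,
    "Met": 3.582,
    "Thr": 3.354,
    "Ile": 12.94,
    "Leu": 3.467,
    "Val": 4.001,
    "His": 1.787,
}

#: NIR band assignments (nm) used as each amino acid's informative
#: wavelengths in the default synthetic spectral library.  They fall in the
#: N-H / C-H / O-H overtone and combination region and double as the
#: ground-truth bands a wavelength selector should recover on synthetic data.
KEY_WAVELENGTHS_NM: dict[str, tuple[float, ...]] = {
    "Lys": (1172.0, 1242.0, 1252.0, 1388.0),
    "Phe": (955.0, 1280.0, 1398.0),
    "Met": (1082.0, 1129.0, 1176.0, 1544.0),
    "Thr": (1186.0, 1388.0, 1469.0, 1478.0, 1605.0),
    "Ile": (1143.0, 1228.0, 1398.0),
    "Leu": (997.0, 1134.0, 1186.0, 1242.0, 1318.0),
    "Val": (988.0, 1101.0, 1134.0, 1139.0, 1242.0, 1346.0, 1643.0),
    "His": (955.0, 969.0, 1176.0, 1223.0, 1412.0, 1431.0),
}

#: Modeling window in nm; sensor SNR degrades outside it.
MODELING_RANGE_NM: tuple[float, float] = (950.0, 1650.0)

#: Number of bands in the default modeling grid.
N_MODELING_BANDS: int = 148


def default_wavelength_grid() -> np.ndarray:
    """Default modeling grid: 148 evenly spaced bands on [950, 1650] nm."""
    lo, hi = MODELING_RANGE_NM
    return np.linspace(lo, hi, N_MODELING_BANDS)
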