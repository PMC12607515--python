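"""Spectral preprocessing: Savitzky-Golay smoothing, airPLS baseline
correction, and standard normal variate scatter correction.

All three stages operate per spectrum (SNV is by definition a single-sample
correction; the other two involve no cross-sample statistics), so the chain
is leakage-free: nothing is fitted on a training set.

The default chain is S-G (window 5, order 1) -> airPLS (lambda 1e4, 2nd
difference penalty) -> SNV, in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .containers import SpectrumSet

__all__ = [
    "PreprocessConfig",
    "sg_smooth",
    "airpls_baseline",
    "airpls_correct",
    "snv",
    "preprocess_pipeline",
]

_MAX_WEIGHT = 1e12  # cap against divergent exponential weights


@dataclass
class PreprocessConfig:
    """Parameters of the three-stage chain.

    sg_window must be odd and exceed sg_polyorder.  ``sg_frame_length`` is
    accepted for interface completeness but the filter is fully determined
    by window and polynomial order.  airPLS: ``airpls_lambda`` is the
    Whittaker smoothness penalty, ``airpls_diff_order`` the difference
    order, ``airpls_weight_exponent`` scales the exponential weight
    argument, ``airpls_neg_ratio`` is the stopping threshold on the L1 mass
    of negative residuals relative to the signal.
    """

    sg_window: int = 5
    sg_polyorder: int = 1
    sg_frame_length: int = 3
    airpls_lambda: float = 1e4
    airpls_diff_order: int = 2
    airpls_max_iter: int = 800
    airpls_weight_exponent: float = 0.1
    airpls_neg_ratio: float = 0.05
    pipeline_order: tuple[str, ...] = ("sg", "airpls", "snv")

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")
        if self.airpls_lambda <= 0:
            raise ValueError("airpls_lambda must be > 0")
        if self.airpls_max_iter < 1:
            raise ValueError("airpls_max_iter must be >= 1")
        unknown = set(self.pipeline_order) - {"sg", "airpls", "snv"}
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")


def sg_smooth(spectrum: np.ndarray, window: int = 5, polyorder: int = 1) -> np.ndarray:
    """Savitzky-Golay smoothing: local least-squares polynomial filtering.

    Edges are handled by evaluating the polynomial fitted to the terminal
    windows (``mode='interp'``), so a global polynomial of degree <=
    ``polyorder`` passes through unchanged.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > spectrum.size:
        raise ValueError("window larger than the spectrum")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    return savgol_filter(spectrum, window_length=window, polyorder=polyorder, mode="interp")


def _whittaker_solve(
    x: np.ndarray, w: np.ndarray, lam: float, d: int
) -> np.ndarray:
    n = x.size
    D = sparse.eye(n, format="csc")
    for _ in range(d):
        D = D[1:] - D[:-1]
    W = sparse.diags(w, 0, format="csc")
    A = W + lam * (D.T @ D)
    return spsolve(A, w * x)


def airpls_baseline(spectrum: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Adaptive iteratively reweighted penalized least-squares baseline.

    Fits a Whittaker-smooth baseline z minimizing
    ``sum_i w_i (x_i - z_i)^2 + lambda * ||D^d z||^2`` and re-weights each
    iteration t: points at or above the baseline get weight 0, points below
    get ``exp(t * weight_exponent_scaled |x_i - z_i| / |d-|_1)`` where d- is
    the vector of negative residuals.  Stops when the L1 mass of negative
    residuals drops below ``neg_ratio * |x|_1`` or at ``max_iter``.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(spectrum, dtype=float)
    n = x.size
    if n <= cfg.airpls_diff_order:
        raise ValueError("spectrum shorter than the difference order")
    x_l1 = np.abs(x).sum()
    if x_l1 == 0:
        return np.zeros_like(x)

    w = np.ones(n)
    z = x.copy()
    for t in range(1, cfg.airpls_max_iter + 1):
        z = _whittaker_solve(x, w, cfg.airpls_lambda, cfg.airpls_diff_order)
        d = x - z
        neg = d < 0
        dneg_l1 = float(np.abs(d[neg]).sum())
        if dneg_l1 < cfg.airpls_neg_ratio * x_l1 or not neg.any():
            break
        w = np.zeros(n)
        arg = t * cfg.airpls_weight_exponent * np.abs(d[neg]) / dneg_l1
        wneg = np.exp(arg)
        if np.any(wneg > _MAX_WEIGHT):
            warnings.warn("airPLS weights diverging; capping", RuntimeWarning)
            wneg = np.minimum(wneg, _MAX_WEIGHT)
        w[neg] = wneg
        # anchor the ends so the penalized system stays well-posed
        w[0] = w[-1] = 1.0
    return z


def airpls_correct(spectrum: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Baseline-corrected spectrum: input minus its airPLS baseline."""
    spectrum = np.asarray(spectrum, dtype=float)
    return spectrum - airpls_baseline(spectrum, cfg)


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and scale one spectrum to unit
    standard deviation (n-1 denominator)."""
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise ValueError("SNV needs at least 2 bands")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance spectrum: SNV undefined")
    return (x - x.mean()) / sd


def preprocess_pipeline(
    spectra: SpectrumSet, cfg: PreprocessConfig | None = None
) -> SpectrumSet:
    """Apply the configured stages per sample, in order.

    The applied stage order and parameters are recorded in the output
    metadata under ``"preprocess"``.
    """
    cfg = cfg or PreprocessConfig()
    out = spectra.reflectance.copy()
    for stage in cfg.pipeline_order:
        if stage == "sg":
            out = np.array(
                [sg_smooth(row, cfg.sg_window, cfg.sg_polyorder) for row in out]
            )
        elif stage == "airpls":
            out = np.array([airpls_correct(row, cfg) for row in out])
        elif stage == "snv":
            out = np.array([snv(row) for row in out])
    return SpectrumSet(
        sample_ids=list(spectra.sample_ids),
        reflectance=out,
        wavelengths=spectra.wavelengths.copy(),
        metadata={
            **spectra.metadata,
            "preprocess": {
                "stages": list(cfg.pipeline_order),
                "params": asdict(cfg),
            },
        },
    )
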