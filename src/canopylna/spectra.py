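"""Band simulation and multiangular reflectance bookkeeping.

Hyperspectral canopy reflectance (350-2500 nm at 1 nm, field-spectrometer
style) is convolved with per-band sensor spectral response functions (SRFs)
to simulate the six-band multispectral sensor (450, 530, 570, 675, 730 and
850 nm, 10 nm full width at half maximum). Band reflectance is the
SRF-weighted mean

    I_band = integral(I * SRF) / integral(SRF)

evaluated on the union grid of the spectrum and the SRF with linear
interpolation of both curves and exact integration of their product.

The view zenith angle (VZA) is carried as metadata: 0 deg is nadir and the
negative sign marks backward (solar-aligned azimuth) viewing. No BRDF
modelling is attempted here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BAND_CENTERS",
    "VZA_SET",
    "HyperSpectrum",
    "SpectralResponseFunction",
    "MultiBandReflectance",
    "gaussian_srf",
    "default_srf_set",
    "convolve_srf",
    "simulate_multispectral",
    "relative_change",
    "relative_change_table",
]

#: airphen-style band centers (nm)
BAND_CENTERS = (450, 530, 570, 675, 730, 850)
#: view zenith angles used throughout (deg; negative = backward viewing)
VZA_SET = (0, -30, -45)


class SpectraError(ValueError):
    """Invalid spectrum/SRF input or degenerate convolution."""


@dataclass(frozen=True)
class HyperSpectrum:
    """A reflectance curve on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", rf)
        if wl.shape != rf.shape or wl.ndim != 1:
            raise SpectraError("wavelengths and reflectance must be equal-"
                               "length 1-d arrays")
        if wl.size and np.any(np.diff(wl) <= 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(rf)):
            raise SpectraError("reflectance must be finite")


@dataclass(frozen=True)
class SpectralResponseFunction:
    """Per-band wavelength sensitivity curve; weights >= 0, not all zero."""

    band_name: str
    wavelengths: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "weights", w)
        if wl.shape != w.shape or wl.ndim != 1:
            raise SpectraError("SRF wavelengths/weights must be equal-length "
                               "1-d arrays")
        if wl.size > 1 and np.any(np.diff(wl) <= 0):
            raise SpectraError("SRF wavelengths must be strictly increasing")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise SpectraError("SRF weights must be finite and >= 0")
        if not np.any(w > 0):
            raise SpectraError("SRF must have at least one positive weight")


@dataclass(frozen=True)
class MultiBandReflectance:
    """Six-band reflectance vector tagged with its view zenith angle."""

    vza: float
    bands: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [b for b in BAND_CENTERS if b not in self.bands]
        if missing:
            raise SpectraError(f"missing bands {missing}")

    def band(self, center: int) -> float:
        return self.bands[center]


def gaussian_srf(center: float, fwhm: float = 10.0,
                 band_name: str | None = None,
                 step: float = 0.5) -> SpectralResponseFunction:
    """Gaussian SRF with the given FWHM, truncated at +/- 3 sigma."""
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    wl = np.arange(center - 3 * sigma, center + 3 * sigma + step / 2, step)
    w = np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return SpectralResponseFunction(band_name or f"b{int(center)}", wl, w)


def default_srf_set(fwhm: float = 10.0) -> dict[int, SpectralResponseFunction]:
    """Default Gaussian SRFs for the six sensor bands."""
    return {c: gaussian_srf(c, fwhm=fwhm) for c in BAND_CENTERS}


def convolve_srf(spectrum: HyperSpectrum,
                 srf: SpectralResponseFunction) -> float:
    """SRF-weighted mean reflectance over the band support.

    Both curves are linearly interpolated onto the union grid of spectrum
    and SRF nodes; on each interval the product of the two linear pieces
    is quadratic and is integrated exactly, so the quadrature is exact
    for the interpolants. The result is bounded by the spectrum's min/max
    over the SRF support. A single-node SRF degenerates to point
    evaluation of the (interpolated) spectrum.
    """
    s_wl, s_rf = spectrum.wavelengths, spectrum.reflectance
    lo = max(s_wl[0], srf.wavelengths[0])
    hi = min(s_wl[-1], srf.wavelengths[-1])
    if lo > hi:
        raise SpectraError(
            f"SRF support [{srf.wavelengths[0]}, {srf.wavelengths[-1]}] does "
            f"not overlap spectrum grid [{s_wl[0]}, {s_wl[-1]}]")

    if srf.wavelengths.size == 1:  # delta response: point sample
        return float(np.interp(srf.wavelengths[0], s_wl, s_rf))

    grid = np.union1d(s_wl, srf.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    i = np.interp(grid, s_wl, s_rf)
    w = np.interp(grid, srf.wavelengths, srf.weights, left=0.0, right=0.0)
    denom = np.trapezoid(w, grid)
    if denom <= 0:
        raise SpectraError("SRF integrates to zero over the overlap region")
    # exact integral of the product of the two piecewise-linear pieces:
    # per interval, int (I*w) = h/6 * (2 I0 w0 + I0 w1 + I1 w0 + 2 I1 w1)
    h = np.diff(grid)
    i0, i1 = i[:-1], i[1:]
    w0, w1 = w[:-1], w[1:]
    numer = np.sum(h / 6.0 * (2 * i0 * w0 + i0 * w1 + i1 * w0
                              + 2 * i1 * w1))
    return float(numer / denom)


def simulate_multispectral(spectrum: HyperSpectrum,
                           srf_set: dict[int, SpectralResponseFunction],
                           vza: float) -> MultiBandReflectance:
    """Convolve one spectrum with all six band SRFs, tagging the VZA."""
    missing = [b for b in BAND_CENTERS if b not in srf_set]
    if missing:
        raise SpectraError(f"missing SRF for band(s) {missing}")
    bands = {b: convolve_srf(spectrum, srf_set[b]) for b in BAND_CENTERS}
    return MultiBandReflectance(vza=vza, bands=bands)


def relative_change(vi_theta: float, vi_origin: float) -> float:
    """Relative VI change at an oblique VZA vs nadir: (VI_t - VI_0)/VI_0.

    Returns NaN (a flagged, excluded value) when the nadir VI is zero.
    """
    if vi_origin == 0:
        return float("nan")
    return (vi_theta - vi_origin) / vi_origin


def relative_change_table(vi_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(VI, VZA) mean |relative change| vs the nadir observation.

    ``vi_table`` is long format with columns plot_id, stage, vza, vi_name,
    value. Rows whose nadir VI is zero are excluded; the excluded count is
    reported per group in column ``n_excluded``.
    """
    nadir = (vi_table[vi_table["vza"] == 0]
             .set_index(["plot_id", "stage", "vi_name"])["value"])
    obl = vi_table[vi_table["vza"] != 0].copy()
    keys = list(zip(obl["plot_id"], obl["stage"], obl["vi_name"]))
    obl["vi_origin"] = [nadir.get(k, np.nan) for k in keys]
    obl["delta"] = [relative_change(v, o) if o == o and o != 0 else np.nan
                    for v, o in zip(obl["value"], obl["vi_origin"])]
    out = (obl.groupby(["vi_name", "vza"])
           .agg(mean_delta=("delta", "mean"),
                mean_abs_delta=("delta", lambda d: np.nanmean(np.abs(d))),
                n=("delta", lambda d: int(np.isfinite(d).sum())),
                n_excluded=("delta", lambda d: int((~np.isfinite(d)).sum())))
           .reset_index())
    return out
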