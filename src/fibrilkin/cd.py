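"""Circular-dichroism analysis of the coil-to-helix transition during assembly.

Far-UV CD distinguishes the disordered monomer (a strong negative band
near 198 nm) from the helical fibrillar state (negative bands near 208
and 222 nm).  Two readouts are provided:

* the band-intensity ratio |theta(222)| / |theta(198)|, a model-free
  tracker of helix content that grows as assembly proceeds, and
* a two-state least-squares decomposition of a spectrum into reference
  helix and coil spectra, yielding a helix fraction f in [0, 1].

A time series of spectra recorded during assembly can be reduced to
f_helix(t) and fitted with a single-exponential relaxation
(:func:`transition_kinetics`).

No experimental basis spectra ship with the package; :func:`default_basis`
builds synthetic Gaussian-band reference spectra with the canonical band
positions, which is sufficient for ratios and fractions in arbitrary
units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .curves import KineticCurve
from .errors import DomainError

__all__ = [
    "CDSpectrum",
    "BasisSet",
    "default_basis",
    "band_ratio",
    "decompose_two_state",
    "TwoStateFit",
    "transition_kinetics",
    "TransitionKineticsResult",
]

COIL_BAND_NM = 198.0
HELIX_BAND_NM = 222.0
BAND_WINDOW_NM = 2.0  # half-width of the averaging window around each band


@dataclass(frozen=True)
class CDSpectrum:
    """Ellipticity vs wavelength; units are arbitrary (mdeg in fixtures)."""

    wavelengths: np.ndarray
    ellipticity: np.ndarray
    time: Optional[float] = None  # minutes, for series members

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        el = np.asarray(self.ellipticity, dtype=float)
        if wl.ndim != 1 or wl.shape != el.shape:
            raise DomainError("wavelengths and ellipticity must be 1-D and equal length")
        if not np.all(np.diff(wl) > 0):
            raise DomainError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(el))):
            raise DomainError("spectrum must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "ellipticity", el)

    def interp(self, wl) -> np.ndarray:
        wl = np.asarray(wl, dtype=float)
        if wl.min() < self.wavelengths[0] or wl.max() > self.wavelengths[-1]:
            raise DomainError(
                f"requested wavelengths [{wl.min()}, {wl.max()}] outside the "
                f"measured range [{self.wavelengths[0]}, {self.wavelengths[-1]}]"
            )
        return np.interp(wl, self.wavelengths, self.ellipticity)

    def band_mean(self, center_nm: float, half_width_nm: float = BAND_WINDOW_NM) -> float:
        """Mean ellipticity over center +- half_width (linear interpolation)."""
        grid = np.linspace(center_nm - half_width_nm, center_nm + half_width_nm, 41)
        return float(np.mean(self.interp(grid)))


@dataclass(frozen=True)
class BasisSet:
    """Reference helix and coil spectra on a common wavelength grid."""

    helix_spectrum: CDSpectrum
    coil_spectrum: CDSpectrum

    def __post_init__(self):
        if not np.array_equal(self.helix_spectrum.wavelengths, self.coil_spectrum.wavelengths):
            raise DomainError("basis spectra must share one wavelength grid")
        if self.helix_spectrum.band_mean(HELIX_BAND_NM) >= 0:
            raise DomainError("helix basis must have a negative band near 222 nm")
        if self.coil_spectrum.band_mean(COIL_BAND_NM) >= 0:
            raise DomainError("coil basis must have a negative band near 198 nm")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.helix_spectrum.wavelengths

    def combine(self, f_helix: float) -> np.ndarray:
        """Ellipticity of the noiseless mixture f*helix + (1-f)*coil."""
        return (f_helix * self.helix_spectrum.ellipticity
                + (1.0 - f_helix) * self.coil_spectrum.ellipticity)


def _gauss(wl, center, sigma):
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def default_basis(wavelengths=None) -> BasisSet:
    """Synthetic Gaussian-band reference spectra (arbitrary mdeg scale).

    Coil: a single negative band at 198 nm.  Helix: the canonical
    exciton-split pattern — a positive band at 191 nm and negative bands
    at 208 and 222 nm.  The positive helix band is kept narrow so the
    helix signal in the 198 nm window stays negative, which keeps the
    222/198 band ratio finite and monotone along a coil-to-helix series.
    """
    if wavelengths is None:
        wavelengths = np.arange(185.0, 260.0 + 0.25, 0.5)
    wl = np.asarray(wavelengths, dtype=float)
    coil = -12.0 * _gauss(wl, 198.0, 7.0)
    helix = (15.0 * _gauss(wl, 191.0, 2.5)
             - 11.0 * _gauss(wl, 208.0, 6.0)
             - 11.0 * _gauss(wl, 222.0, 6.0))
    return BasisSet(CDSpectrum(wl, helix), CDSpectrum(wl, coil))


def band_ratio(spec: CDSpectrum) -> float:
    """Helix-to-coil band intensity ratio |theta(222)| / |theta(198)|.

    Each band value is the mean ellipticity over a +-2 nm window around
    the nominal wavelength.  The ratio is scale-invariant; it is < 1 for
    a pure coil spectrum and grows as helix content increases.
    """
    theta_coil = spec.band_mean(COIL_BAND_NM)
    theta_helix = spec.band_mean(HELIX_BAND_NM)
    if theta_coil == 0.0:
        raise DomainError("coil band intensity is exactly zero; ratio undefined")
    return abs(theta_helix) / abs(theta_coil)


@dataclass(frozen=True)
class TwoStateFit:
    f_helix: float
    residual_norm: float


def decompose_two_state(spec: CDSpectrum, basis: BasisSet) -> TwoStateFit:
    """Least-squares helix fraction under spec ~ f*helix + (1-f)*coil.

    The one-parameter linear problem is solved in closed form and f is
    clipped to [0, 1].  Raises :class:`DomainError` when the basis is
    degenerate (helix ~ coil), where f is unidentifiable.
    """
    y = spec.interp(basis.wavelengths)
    h = basis.helix_spectrum.ellipticity
    c = basis.coil_spectrum.ellipticity
    d = h - c
    dd = float(d @ d)
    scale = max(float(h @ h), float(c @ c))
    if dd <= 1e-12 * scale:
        raise DomainError("degenerate basis: helix and coil spectra are indistinguishable")
    f = float((y - c) @ d / dd)
    f = min(max(f, 0.0), 1.0)
    resid = y - (f * h + (1.0 - f) * c)
    return TwoStateFit(f_helix=f, residual_norm=float(np.linalg.norm(resid)))


@dataclass(frozen=True)
class TransitionKineticsResult:
    """Helix-fraction time course and its single-exponential relaxation fit.

    f(t) = f_inf + (f0 - f_inf) * exp(-k t); rate k in min^-1.
    ``nonmonotone`` flags a series whose f(t) decreases beyond noise.
    """

    f_curve: KineticCurve
    rate: float
    f0: float
    f_inf: float
    nonmonotone: bool


def transition_kinetics(series, basis: BasisSet,
                        noise_tolerance: float = 0.02) -> TransitionKineticsResult:
    """Reduce a timestamped CD series to f_helix(t) and fit its relaxation.

    Parameters
    ----------
    series : sequence of CDSpectrum
        At least 5 spectra, each with a ``time`` stamp in minutes.
    basis : BasisSet
    noise_tolerance : float
        Downward steps in f larger than this trigger the non-monotone
        warning flag (the fit is still returned).
    """
    if len(series) < 5:
        raise DomainError("need at least 5 time points for transition kinetics")
    if any(s.time is None for s in series):
        raise DomainError("every spectrum in the series needs a time stamp")
    order = np.argsort([s.time for s in series])
    times = np.array([series[i].time for i in order], dtype=float)
    f = np.array([decompose_two_state(series[i], basis).f_helix for i in order])
    curve = KineticCurve(times, f, label="helix fraction")

    nonmono = bool(np.any(np.diff(f) < -noise_tolerance))
    if nonmono:
        warnings.warn("helix fraction decreases beyond noise; exponential fit may be poor")

    amplitude = float(f[-1] - f[0])
    if abs(amplitude) < 1e-12:
        return TransitionKineticsResult(curve, rate=0.0, f0=float(f[0]),
                                        f_inf=float(f[-1]), nonmonotone=nonmono)

    def model(t, k, f0, f_inf):
        return f_inf + (f0 - f_inf) * np.exp(-k * t)

    t_span = times[-1] - times[0]
    k0 = 2.0 / t_span if t_span > 0 else 1.0
    popt, _ = curve_fit(model, times, f, p0=[k0, f[0], f[-1]],
                        bounds=([0.0, -0.5, -0.5], [np.inf, 1.5, 1.5]), maxfev=20000)
    return TransitionKineticsResult(curve, rate=float(popt[0]), f0=float(popt[1]),
                                    f_inf=float(popt[2]), nonmonotone=nonmono)
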