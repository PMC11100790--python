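"""Two-state photophysics of a fluorogenic glycan-binding dye.

A turn-on dye such as a boronic-acid-functionalized rhodamine exists in two
photophysical states: *unbound* (free in buffer) and *bound* (diol-engaged,
red-shifted and brighter).  Each state is described by an absorbance
spectrum, an emission spectrum, a molar extinction coefficient at peak, and
a fluorescence quantum yield.  The observed signal at a given microscope
configuration (one excitation line, one emission band) is a linear mixture
of the two state signals, weighted by the fraction of dye molecules bound.

The central quantity is the wavelength-specific excitation coefficient

    E(lambda_ex) = phi * (1 - 10 ** (-A(lambda_ex)))

which converts a quantum yield ``phi`` and an optical density ``A`` at the
excitation wavelength into the relative rate of emitted photons.  The
proportionality constant is taken as 1; every downstream quantity here is a
ratio of two such coefficients, so the constant cancels.

Fluorogenic contrast is reported as ``dF/F = (F_bound - F_unbound) /
F_unbound`` at a stated excitation/emission configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "Spectrum",
    "DyeStateParams",
    "TwoStateDyeModel",
    "AcquisitionSettings",
    "excitation_coefficient",
    "renormalize_emission",
    "state_signal",
    "signal_at_settings",
    "contrast_dff",
]

SPECTRUM_KINDS = ("absorbance", "excitation", "emission")


@dataclass(frozen=True)
class Spectrum:
    """A sampled optical spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelength samples in nanometres.
    values
        Nonnegative values: optical density for ``kind="absorbance"``,
        arbitrary intensity units for excitation/emission spectra.
    kind
        One of ``{"absorbance", "excitation", "emission"}``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if self.kind not in SPECTRUM_KINDS:
            raise TypeError(
                f"unknown spectrum kind {self.kind!r}; expected one of {SPECTRUM_KINDS}"
            )
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if w.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("spectrum values must be nonnegative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)

    # -- queries ---------------------------------------------------------

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated value at ``wavelength_nm``.

        Queries outside the stored grid raise ``ValueError``: extrapolating
        a measured spectrum would invent photophysics.
        """
        w = self.wavelengths_nm
        x = float(wavelength_nm)
        if x < w[0] or x > w[-1]:
            raise ValueError(
                f"wavelength {x} nm outside stored range [{w[0]}, {w[-1]}] nm"
            )
        return float(np.interp(x, w, self.values))

    def integrate_band(self, low_nm: float, high_nm: Optional[float] = None) -> float:
        """Trapezoidal integral of the spectrum over ``[low_nm, high_nm]``.

        The band is clipped to the stored grid; ``high_nm=None`` denotes a
        longpass band and integrates to the last stored wavelength.
        """
        w, v = self.wavelengths_nm, self.values
        lo = max(float(low_nm), float(w[0]))
        hi = float(w[-1]) if high_nm is None else min(float(high_nm), float(w[-1]))
        if lo >= hi:
            return 0.0
        inner = (w > lo) & (w < hi)
        xs = np.concatenate(([lo], w[inner], [hi]))
        ys = np.concatenate(([self.value_at(lo)], v[inner], [self.value_at(hi)]))
        return float(np.trapezoid(ys, xs))

    @property
    def peak_nm(self) -> float:
        """Wavelength of the maximum sampled value (lowest wavelength on ties)."""
        return float(self.wavelengths_nm[int(np.argmax(self.values))])


@dataclass(frozen=True)
class DyeStateParams:
    """Photophysical parameters of one dye state (bound or unbound).

    ``absorbance`` is stored for a stated reference condition (concentration
    and path length); in the Beer-Lambert regime scaling to another
    concentration is linear.
    """

    epsilon_peak: float  # molar extinction at peak, M^-1 cm^-1
    phi: float  # fluorescence quantum yield
    absorbance: Spectrum
    emission: Spectrum

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("quantum yield must be in [0, 1]")
        if self.epsilon_peak <= 0:
            raise ValueError("epsilon_peak must be positive")
        if self.absorbance.kind != "absorbance":
            raise TypeError("absorbance spectrum must have kind='absorbance'")
        if self.emission.kind != "emission":
            raise TypeError("emission spectrum must have kind='emission'")

    def absorbance_at(self, wavelength_nm: float) -> float:
        return self.absorbance.value_at(wavelength_nm)


@dataclass(frozen=True)
class TwoStateDyeModel:
    """Unbound and bound states of a fluorogenic dye."""

    unbound: DyeStateParams
    bound: DyeStateParams

    def __post_init__(self) -> None:
        for attr in ("absorbance", "emission"):
            a = getattr(self.unbound, attr).wavelengths_nm
            b = getattr(self.bound, attr).wavelengths_nm
            if max(a[0], b[0]) >= min(a[-1], b[-1]):
                raise ValueError(f"{attr} spectra of the two states do not overlap")


@dataclass(frozen=True)
class AcquisitionSettings:
    """One excitation line plus one emission band.

    ``emission_band`` is ``(low_nm, high_nm)``; ``high_nm=None`` denotes a
    longpass filter.
    """

    excitation_nm: float
    emission_band: Tuple[float, Optional[float]]

    def __post_init__(self) -> None:
        low, high = self.emission_band
        if high is not None and not (low < high):
            raise ValueError("emission band requires low_nm < high_nm")


def excitation_coefficient(phi: float, absorbance_at_ex: float) -> float:
    """Wavelength-specific excitation coefficient ``phi * (1 - 10**(-A))``.

    ``phi`` is the quantum yield, ``absorbance_at_ex`` the optical density at
    the excitation wavelength.  The result is dimensionless and bounded by
    ``phi``.
    """
    if not (0.0 <= phi <= 1.0):
        raise ValueError("phi must be in [0, 1]")
    if absorbance_at_ex < 0:
        raise ValueError("absorbance must be nonnegative")
    return float(phi * -np.expm1(-np.log(10.0) * absorbance_at_ex))


def renormalize_emission(emission: Spectrum, phi: float, absorbance_at_ex: float) -> Spectrum:
    """Scale an emission spectrum by the excitation coefficient.

    This renormalizes an emission shape to a chosen excitation wavelength, so
    that bound/unbound emission spectra become directly comparable at the
    acquisition settings actually used.
    """
    if emission.kind != "emission":
        raise TypeError("renormalize_emission requires an emission spectrum")
    coeff = excitation_coefficient(phi, absorbance_at_ex)
    return Spectrum(emission.wavelengths_nm, emission.values * coeff, "emission")


def state_signal(state: DyeStateParams, settings: AcquisitionSettings) -> float:
    """Detected signal of a single pure state at the given settings.

    Excitation coefficient at the laser line times the trapezoidal integral
    of the emission spectrum over the detection band.
    """
    coeff = excitation_coefficient(state.phi, state.absorbance_at(settings.excitation_nm))
    low, high = settings.emission_band
    return coeff * state.emission.integrate_band(low, high)


def signal_at_settings(
    model: TwoStateDyeModel, fraction_bound: float, settings: AcquisitionSettings
) -> float:
    """Signal of a two-state mixture: ``f * S_bound + (1 - f) * S_unbound``."""
    f = float(fraction_bound)
    if not (0.0 <= f <= 1.0):
        raise ValueError("fraction_bound must be in [0, 1]")
    s_b = state_signal(model.bound, settings)
    s_u = state_signal(model.unbound, settings)
    return f * s_b + (1.0 - f) * s_u


def contrast_dff(bound_signal: float, unbound_signal: float) -> float:
    """Fluorogenic contrast ``dF/F = (bound - unbound) / unbound``."""
    if unbound_signal <= 0:
        raise ValueError("unbound signal must be positive to define dF/F")
    return (bound_signal - unbound_signal) / unbound_signal
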