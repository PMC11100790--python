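"""Excitation-scan (hyperspectral) image cube analysis.

An excitation scan steps the laser wavelength over a grid (e.g. 500-566 nm
in 2 nm increments) at a fixed emission detection band, producing a cube in
which every pixel carries an excitation spectrum.  Because a bound,
red-shifted dye population peaks at a longer excitation wavelength than the
free dye, the per-pixel wavelength of maximal response ("spectral contrast"
image) separates bound from free dye spatially.

Peak wavelengths are grid-valued: the scan samples every 2 nm and no
sub-grid interpolation is performed.  Ties break toward the lowest
wavelength, so flat (noise-floor) pixels read maximally blue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .photophysics import Spectrum

__all__ = [
    "HyperspectralStack",
    "SpectralPeakMap",
    "roi_mean_spectrum",
    "spectral_peak_map",
    "intensity_image",
]


@dataclass(frozen=True)
class HyperspectralStack:
    """Excitation-scan cube ordered (excitation index, row, col)."""

    excitation_wavelengths_nm: np.ndarray
    data: np.ndarray
    emission_band: Tuple[float, float] = (575.0, 630.0)

    def __post_init__(self) -> None:
        w = np.asarray(self.excitation_wavelengths_nm, dtype=float)
        d = np.asarray(self.data, dtype=float)
        if w.ndim != 1 or not np.all(np.diff(w) > 0):
            raise ValueError("excitation wavelengths must be 1-D, strictly increasing")
        if d.ndim != 3 or d.shape[0] != w.size:
            raise ValueError("data must be 3-D with first dimension matching the grid")
        if np.any(d < 0):
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "excitation_wavelengths_nm", w)
        object.__setattr__(self, "data", d)

    @property
    def plane_shape(self) -> Tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass(frozen=True)
class SpectralPeakMap:
    """Per-pixel peak excitation wavelength with a validity mask."""

    peak_nm: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.peak_nm.shape != self.valid_mask.shape:
            raise ValueError("peak image and mask shapes differ")


def roi_mean_spectrum(stack: HyperspectralStack, roi_mask: np.ndarray) -> Spectrum:
    """Mean excitation spectrum over the pixels of a boolean ROI mask."""
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != stack.plane_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image plane {stack.plane_shape}"
        )
    if not mask.any():
        raise ValueError("ROI mask is empty")
    values = stack.data[:, mask].mean(axis=1)
    return Spectrum(stack.excitation_wavelengths_nm, values, "excitation")


def _block_mean(data: np.ndarray, binning: int) -> np.ndarray:
    """Mean over non-overlapping binning x binning blocks per plane.

    Trailing rows/columns that do not fill a block are dropped.
    """
    nlam, h, w = data.shape
    hb, wb = h // binning, w // binning
    if hb < 1 or wb < 1:
        raise ValueError("binning larger than the image plane")
    trimmed = data[:, : hb * binning, : wb * binning]
    return trimmed.reshape(nlam, hb, binning, wb, binning).mean(axis=(2, 4))


def spectral_peak_map(
    stack: HyperspectralStack,
    binning: int = 2,
    intensity_floor: float = 0.0,
) -> SpectralPeakMap:
    """Per-pixel peak-excitation-wavelength map after spatial binning.

    Pixels are first averaged over non-overlapping ``binning x binning``
    blocks, then each output pixel is assigned the grid wavelength of its
    spectrum's maximum (ties to the lowest wavelength).  Binned pixels whose
    total intensity falls below ``intensity_floor`` times the global maximum
    total are marked invalid; the default floor of 0 keeps the full field.
    """
    if int(binning) != binning or binning < 1:
        raise ValueError("binning must be a positive integer")
    binned = _block_mean(stack.data, int(binning))
    idx = np.argmax(binned, axis=0)  # argmax returns the first (lowest-wavelength) max
    peak = stack.excitation_wavelengths_nm[idx]
    total = binned.sum(axis=0)
    invalid = total < intensity_floor * total.max() if total.size else total > 0
    return SpectralPeakMap(peak_nm=peak, valid_mask=~invalid)


def intensity_image(stack: HyperspectralStack, excitation_nm: float) -> np.ndarray:
    """The single image plane acquired at one grid excitation wavelength."""
    grid = stack.excitation_wavelengths_nm
    match = np.isclose(grid, excitation_nm, rtol=0.0, atol=1e-9)
    if not match.any():
        raise ValueError(
            f"{excitation_nm} nm is not on the excitation grid {grid.tolist()}"
        )
    return stack.data[int(np.argmax(match))]
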