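"""Reflectance calibration, spectral denoising, and band binning.

Calibration divides every pixel's intensity spectrum by the mean spectrum of
the grey reference plate visible in the same cube and multiplies by the
plate's known flat reflectance (R = 0.1).  Because the plate sits in the same
illumination, water column, and optical path as the targets, the division
cancels the illumination spectrum, filter transmission envelope, channel
sensitivities, and exposure, leaving an intrinsic reflectance on an
instrument-independent scale.

Denoising is a Savitzky-Golay polynomial filter (order 2, window 9) applied
along the band axis only, followed by factor-5 band binning which takes the
default 225-point grid to the 45-band spectra the classifier consumes.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .hypercube import Hypercube

__all__ = [
    "calibrate_reflectance",
    "savgol_denoise",
    "bin_bands",
    "GREY_REFERENCE_REFLECTANCE",
]

GREY_REFERENCE_REFLECTANCE = 0.1


def calibrate_reflectance(
    cube: Hypercube,
    grey_region: np.ndarray,
    r_ref: float = GREY_REFERENCE_REFLECTANCE,
) -> Hypercube:
    """Convert an intensity cube to reflectance against the grey plate.

    Parameters
    ----------
    cube : Hypercube
        Pre-calibration intensities.
    grey_region : ndarray
        Boolean (rows, cols) mask of pixels on the grey reference plate.
        Saturated/invalid entries are excluded band-wise from the reference
        mean.
    r_ref : float
        Known flat reflectance of the plate.

    Per band ``b``: ``R(x, y, b) = r_ref * I(x, y, b) / mean_grey(b)``.  Bands
    whose grey reference mean is zero or has no valid pixel are masked
    invalid.
    """
    grey_region = np.asarray(grey_region, dtype=bool)
    if grey_region.shape != cube.values.shape[:2]:
        raise ValueError("grey_region mask must match the cube's spatial shape")
    if not grey_region.any():
        raise ValueError("grey region is empty")
    grey_vals = cube.values[grey_region]  # (n_grey, bands)
    grey_valid = cube.valid_mask[grey_region]
    counts = grey_valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.where(grey_valid, grey_vals, 0.0).sum(axis=0)
        grey_mean = np.divide(sums, counts, out=np.zeros(cube.n_bands), where=counts > 0)
    band_ok = (counts > 0) & (grey_mean > 0)
    values = np.full_like(cube.values, np.nan)
    values[..., band_ok] = (
        r_ref * cube.values[..., band_ok] / grey_mean[band_ok].astype(np.float32)
    )
    mask = cube.valid_mask & band_ok[None, None, :]
    values[~mask] = np.nan
    return Hypercube(values=values, band_centers=cube.band_centers, valid_mask=mask)


def savgol_denoise(cube: Hypercube, order: int = 2, window: int = 9) -> Hypercube:
    """Savitzky-Golay smoothing along the band axis only.

    The filter fits a polynomial of the given order in a sliding window, so
    spectra that *are* polynomials of that order (constants, quadratics) pass
    through unchanged.  Spatial dimensions are untouched.  Invalid bands are
    bridged by linear interpolation before filtering and re-masked after.
    """
    if window % 2 == 0:
        raise ValueError("window length must be odd")
    if window <= order:
        raise ValueError("window length must exceed the polynomial order")
    if cube.n_bands < window:
        raise ValueError(
            f"need at least {window} bands for a window-{window} filter"
        )
    values = cube.values
    if not cube.valid_mask.all():
        values = values.copy()
        flat = values.reshape(-1, cube.n_bands)
        ok = cube.valid_mask.reshape(-1, cube.n_bands)
        x = np.arange(cube.n_bands)
        for i in np.nonzero(~ok.all(axis=1))[0]:
            good = ok[i]
            if good.any():
                flat[i] = np.interp(x, x[good], flat[i][good])
            else:
                flat[i] = 0.0
    smooth = savgol_filter(values, window_length=window, polyorder=order, axis=2)
    smooth = smooth.astype(np.float32)
    smooth[~cube.valid_mask] = np.nan
    return Hypercube(
        values=smooth, band_centers=cube.band_centers, valid_mask=cube.valid_mask.copy()
    )


def bin_bands(cube: Hypercube, factor: int = 5) -> Hypercube:
    """Average consecutive groups of ``factor`` bands.

    New band centers are the means of the member centers.  A binned entry is
    valid if at least one member was valid; its value averages the valid
    members only.
    """
    if factor < 1:
        raise ValueError("binning factor must be >= 1")
    if factor == 1:
        return cube.copy()
    n = cube.n_bands
    if n % factor != 0:
        raise ValueError(
            f"band count {n} is not divisible by {factor}; adjust the "
            "interpolation grid so the counts divide evenly"
        )
    rows, cols, _ = cube.shape
    grouped = cube.values.reshape(rows, cols, n // factor, factor)
    gmask = cube.valid_mask.reshape(rows, cols, n // factor, factor)
    counts = gmask.sum(axis=3)
    sums = np.where(gmask, grouped, 0.0).sum(axis=3)
    with np.errstate(invalid="ignore"):
        values = np.divide(
            sums, counts, out=np.full(counts.shape, np.nan, dtype=np.float32),
            where=counts > 0,
        )
    centers = cube.band_centers.reshape(-1, factor).mean(axis=1)
    return Hypercube(
        values=values.astype(np.float32), band_centers=centers, valid_mask=counts > 0
    )
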