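"""Raw-scan to wavelength-indexed stack: de-shear and wavelength mapping.

A scanning-filter acquisition interleaves space and wavelength: within one
frame, each image row sees a different filter position and hence wavelength.
Reconstruction proceeds in five steps, all on the gamma-linearized stack:

1. *Shift estimation* -- cross-correlate the temporal intensity traces of two
   grey-plate pixels in the same column but different rows; the lag (in
   frames) divided by the row separation gives the shear slope in frames per
   row.  Because the filter gradient is linear and the stage speed constant,
   the shear is linear in the row index.
2. *De-shearing* -- re-order rows across frames so every output frame is
   monochromatic.
3. *Onset detection* -- on the grey-plate region of the de-sheared stack,
   find the frame where the blue channel first rises above a threshold and
   the frame where the red channel last stays above it.  These anchor the
   known filter wavelengths 436 nm and 642 nm.
4. *Wavelength map* -- a linear frame-to-wavelength function through the two
   anchors: ``lambda = m * frame + b`` with
   ``m = (642 - 436) / (f_red - f_blue)`` and ``b = 436 - m * f_blue``.
5. *Channel trim + summation and band interpolation* -- zero each RGB channel
   outside its usable window (R: 510-660, G: 465-620, B: 430-566 nm), sum the
   channels into a single intensity, and linearly interpolate from the
   frame-sampled wavelengths onto a uniform band grid (default 225 points on
   435-659 nm: inside the discard limits of 435/699 nm and the union of the
   trim windows, and chosen so factor-5 binning yields 45 bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d

from .hypercube import Hypercube

__all__ = [
    "ShiftModel",
    "WavelengthMap",
    "ChannelTrimWindows",
    "MonoStack",
    "estimate_row_shift",
    "fit_shift_model",
    "deshear_stack",
    "detect_onsets",
    "build_wavelength_map",
    "frames_to_wavelength",
    "trim_and_sum_channels",
    "interpolate_bands",
    "default_band_grid",
]

LAMBDA_BLUE = 436.0  # nm, filter wavelength at the blue-channel onset
LAMBDA_RED = 642.0  # nm, filter wavelength at the red-channel onset

BAND_MIN = 435.0  # nm, bands below are discarded (low SNR)
BAND_MAX = 699.0  # nm, bands above are discarded (low SNR)

# Default interpolation grid: 1 nm steps over the range where at least one
# trimmed channel still carries signal.  The red trim window ends at 660 nm,
# so bands beyond it would be empty; 225 points keep factor-5 binning at
# exactly 45 output bands.
DEFAULT_GRID_MIN = 435.0
DEFAULT_GRID_MAX = 659.0


@dataclass(frozen=True)
class ShiftModel:
    """Linear row shift: ``slope`` frames per row, zero at ``reference_row``."""

    slope: float
    reference_row: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("shift slope must be finite")

    def frame_offset(self, rows: int) -> np.ndarray:
        """Integer source-frame offset per row (nearest-frame rounding)."""
        y = np.arange(rows)
        return np.rint(self.slope * (y - self.reference_row)).astype(int)


@dataclass(frozen=True)
class WavelengthMap:
    """Linear frame-number to wavelength map anchored at two onsets."""

    m_lambda: float  # nm per frame
    b_lambda: float  # nm
    frame_blue_onset: float
    frame_red_onset: float

    def __call__(self, frame):
        return self.m_lambda * np.asarray(frame, dtype=float) + self.b_lambda


@dataclass(frozen=True)
class ChannelTrimWindows:
    """Usable wavelength window (nm) per RGB channel, outside which the
    channel's counts are baseline noise and are zeroed before summation."""

    red: tuple[float, float] = (510.0, 660.0)
    green: tuple[float, float] = (465.0, 620.0)
    blue: tuple[float, float] = (430.0, 566.0)

    def __post_init__(self) -> None:
        for name in ("red", "green", "blue"):
            lo, hi = getattr(self, name)
            if not (400.0 <= lo < hi <= 700.0):
                raise ValueError(f"{name} trim window must be non-empty in 400-700 nm")

    def as_tuple(self):
        # channel order (R, G, B), matching the stack's channel axis
        return (self.red, self.green, self.blue)


@dataclass
class MonoStack:
    """De-sheared (monochromatic-frame) stack.

    ``frame_indices`` holds the original frame numbers of the surviving
    output frames; the wavelength map is expressed in these numbers.
    """

    data: np.ndarray  # (n_valid, rows, cols, channels) or (n_valid, rows, cols)
    frame_indices: np.ndarray
    saturated: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def _xcorr_lag(ref: np.ndarray, other: np.ndarray) -> float:
    """Lag (frames) by which ``ref`` trails ``other``: other[f] ~ ref[f + lag].

    Integer lag at the maximum of the normalized cross-correlation (Pearson
    coefficient over the overlapping segment at each candidate lag, so
    baseline offsets and shrinking overlap do not tilt the peak), refined to
    sub-frame precision by a parabolic fit through the peak and its two
    neighbours.
    """
    a = np.asarray(ref, dtype=float)
    b = np.asarray(other, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("flat trace: cannot estimate a lag from zero variance")
    n = len(a)
    min_overlap = max(n // 4, 3)
    lags = np.arange(-(n - min_overlap), n - min_overlap + 1)
    r = np.full(len(lags), -np.inf)
    for i, k in enumerate(lags):
        # align a[f + k] with b[f]
        if k >= 0:
            seg_a, seg_b = a[k:], b[: n - k]
        else:
            seg_a, seg_b = a[: n + k], b[-k:]
        sa, sb = seg_a.std(), seg_b.std()
        if sa == 0 or sb == 0:
            continue
        r[i] = np.mean((seg_a - seg_a.mean()) * (seg_b - seg_b.mean())) / (sa * sb)
    i = int(np.argmax(r))
    lag = float(lags[i])
    if 0 < i < len(r) - 1 and np.isfinite(r[i - 1]) and np.isfinite(r[i + 1]):
        denom = r[i - 1] - 2.0 * r[i] + r[i + 1]
        if denom != 0:
            lag += 0.5 * (r[i - 1] - r[i + 1]) / denom
    return lag


def estimate_row_shift(
    linear_stack: np.ndarray, column: int, row_top: int, row_bottom: int
) -> float:
    """Cross-correlation lag in frames between two grey-plate pixels.

    Both pixels sit in ``column``; ``row_top`` < ``row_bottom``.  A positive
    lag means the top pixel observes any given wavelength ``lag`` frames
    after the bottom pixel (positive shear).  The lag is estimated per RGB
    channel and averaged over channels with usable variance.
    """
    lags = []
    n_ch = linear_stack.shape[3] if linear_stack.ndim == 4 else 1
    for c in range(n_ch):
        top = linear_stack[:, row_top, column, c].astype(float)
        bot = linear_stack[:, row_bottom, column, c].astype(float)
        try:
            lags.append(_xcorr_lag(top, bot))
        except ValueError:
            continue
    if not lags:
        raise ValueError("all channel traces are flat; cannot estimate shift")
    return float(np.mean(lags))


def fit_shift_model(
    lags: list[tuple[float, float]], reference_row: int = 0
) -> ShiftModel:
    """Least-squares line through (row separation, lag) pairs, constrained
    through the origin; the slope is the shear in frames per row."""
    if not lags:
        raise ValueError("need at least one (delta_row, lag) pair")
    dr = np.array([p[0] for p in lags], dtype=float)
    lg = np.array([p[1] for p in lags], dtype=float)
    denom = float(np.sum(dr * dr))
    if denom == 0:
        raise ValueError("all row separations are zero; slope is undefined")
    return ShiftModel(slope=float(np.sum(dr * lg) / denom), reference_row=reference_row)


def deshear_stack(
    linear_stack: np.ndarray,
    model: ShiftModel,
    saturated: np.ndarray | None = None,
) -> MonoStack:
    """Re-order rows across frames so each output frame is monochromatic.

    Output frame ``f'`` at row ``y`` takes the source frame in which row
    ``y`` saw the same filter position as the reference row sees at ``f'``;
    with positive shear lower rows lead, so the source frame is
    ``f' - round(slope * (y - reference_row))``.  Output frames for which any
    row's source falls outside the scan are dropped.
    """
    n_frames, rows = linear_stack.shape[0], linear_stack.shape[1]
    offset = model.frame_offset(rows)
    f0 = int(max(0, offset.max()))
    f1 = int(min(n_frames - 1, n_frames - 1 + offset.min()))
    if f1 < f0:
        raise ValueError("shift slope too large: no fully covered frame survives")
    out_frames = np.arange(f0, f1 + 1)
    src = out_frames[:, None] - offset[None, :]  # (n_valid, rows)
    rows_idx = np.arange(rows)[None, :]
    data = linear_stack[src, rows_idx]
    sat = saturated[src, rows_idx] if saturated is not None else None
    return MonoStack(data=data, frame_indices=out_frames, saturated=sat)


def detect_onsets(
    mono: MonoStack,
    grey_region: np.ndarray,
    threshold: float = 0.1,
) -> tuple[float, float]:
    """Blue and red onset frames on the grey reference region.

    ``grey_region`` is a boolean (rows, cols) mask of grey-plate pixels.
    The blue onset is the first frame where the blue-channel grey mean rises
    above ``threshold`` times that channel's maximum; the red onset is the
    last frame where the red-channel mean stays above the same fraction of
    its own maximum.  Frame numbers refer to the original scan.
    """
    if mono.data.ndim != 4 or mono.data.shape[3] != 3:
        raise ValueError("onset detection needs the RGB de-sheared stack")
    if not np.any(grey_region):
        raise ValueError("empty grey region")
    traces = mono.data[:, grey_region, :].mean(axis=1)  # (n_valid, 3)
    blue, red = traces[:, 2], traces[:, 0]
    onsets = []
    for trace, take_last in ((blue, False), (red, True)):
        peak = trace.max()
        if peak <= 0:
            raise ValueError("channel trace never rises above zero")
        above = trace > threshold * peak
        idx = np.nonzero(above)[0]
        if idx.size == 0:
            raise ValueError("channel trace never crosses the onset threshold")
        onsets.append(float(mono.frame_indices[idx[-1] if take_last else idx[0]]))
    return onsets[0], onsets[1]


def build_wavelength_map(onsets: tuple[float, float]) -> WavelengthMap:
    """Linear frame-to-wavelength map through the 436 nm / 642 nm anchors."""
    f_blue, f_red = onsets
    if f_red == f_blue:
        raise ZeroDivisionError("blue and red onsets coincide; slope undefined")
    if f_red < f_blue:
        raise ValueError("red onset precedes blue onset (negative dispersion)")
    m = (LAMBDA_RED - LAMBDA_BLUE) / (f_red - f_blue)
    b = LAMBDA_BLUE - m * f_blue
    return WavelengthMap(
        m_lambda=m, b_lambda=b, frame_blue_onset=f_blue, frame_red_onset=f_red
    )


def frames_to_wavelength(wmap: WavelengthMap, frame):
    """Wavelength (nm) of a frame number under the linear map."""
    return wmap(frame)


def trim_and_sum_channels(
    mono: MonoStack,
    wmap: WavelengthMap,
    windows: ChannelTrimWindows | None = None,
) -> MonoStack:
    """Zero each RGB channel outside its wavelength window, then sum channels.

    Each de-sheared frame is monochromatic, so trimming reduces to a per-frame
    channel weight: a channel contributes to a frame only if that frame's
    wavelength lies inside the channel's window.
    """
    if wmap is None:
        raise ValueError("wavelength map required: trim windows are in nm")
    windows = windows or ChannelTrimWindows()
    lam = wmap(mono.frame_indices)  # (n_valid,)
    weights = np.stack(
        [(lam >= lo) & (lam <= hi) for lo, hi in windows.as_tuple()], axis=1
    ).astype(mono.data.dtype)  # (n_valid, 3)
    data = np.einsum("fyxc,fc->fyx", mono.data, weights)
    sat = None
    if mono.saturated is not None:
        # a summed sample is compromised if any *active* channel saturated
        sat = np.einsum("fyxc,fc->fyx", mono.saturated.astype(np.uint8), weights) > 0
    return MonoStack(data=data, frame_indices=mono.frame_indices, saturated=sat)


def default_band_grid(n_points: int = 225) -> np.ndarray:
    """Uniform band-center grid: 225 points on 435-659 nm (1 nm steps).

    The grid stays inside the union of the channel trim windows (the red
    window ends at 660 nm, so no channel carries signal beyond it) and its
    length makes factor-5 binning produce exactly 45 output bands.
    """
    return np.linspace(DEFAULT_GRID_MIN, DEFAULT_GRID_MAX, n_points)


def interpolate_bands(
    summed: MonoStack, wmap: WavelengthMap, grid: np.ndarray | None = None
) -> Hypercube:
    """Linearly interpolate frame-sampled intensities onto a uniform band grid.

    Grid points outside the wavelength coverage of the de-sheared frames are
    marked invalid (NaN).  The grid must lie within the retained 435-699 nm
    range.
    """
    grid = default_band_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("band grid must be strictly increasing")
    if grid[0] < BAND_MIN or grid[-1] > BAND_MAX:
        raise ValueError(f"band grid must lie within [{BAND_MIN}, {BAND_MAX}] nm")
    lam = wmap(summed.frame_indices)
    if lam[0] > lam[-1]:  # descending map; flip to ascending for interpolation
        lam = lam[::-1]
        data = summed.data[::-1]
        sat = summed.saturated[::-1] if summed.saturated is not None else None
    else:
        data, sat = summed.data, summed.saturated
    covered = (grid >= lam[0]) & (grid <= lam[-1])
    if not covered.any():
        raise ValueError("band grid lies entirely outside the scan's coverage")
    fn = interp1d(lam, data, axis=0, bounds_error=False, fill_value=np.nan)
    values = np.moveaxis(fn(grid), 0, -1).astype(np.float32)  # (rows, cols, bands)
    mask = np.broadcast_to(covered, values.shape).copy()
    if sat is not None:
        # a band is compromised if either enclosing frame sample saturated
        sfn = interp1d(
            lam, sat.astype(float), axis=0, bounds_error=False, fill_value=1.0
        )
        mask &= ~(np.moveaxis(sfn(grid), 0, -1) > 0)
    values[~mask] = np.nan
    return Hypercube(values=values, band_centers=grid, valid_mask=mask)
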