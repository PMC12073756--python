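"""Forward model of a scanning linear-variable-filter hyperspectral camera.

The instrument couples a consumer RGB video camera to a linear variable
spectral bandpass filter (LVSBPF): a thin-film filter whose passband center
wavelength (CWL) varies linearly along its length (here 400-700 nm over
47.8 mm, bandwidth 3-9 nm FWHM).  Sweeping the filter across an intermediate
image plane while the camera records video multiplexes wavelength in time:
within one frame each image *row* looks through a different lateral filter
position and therefore a different wavelength, and successive frames shift
that mapping by a constant amount (the row shift, in frames per row).

This module renders synthetic raw scans of simple benthic scenes (macroalgae
patches on a flat grey reference plate) with full ground truth, so that the
entire reconstruction and classification pipeline can be exercised without
any real acquisition.  The forward chain per pixel is

    linear signal = gain * integral( illumination(l) * reflectance(l)
                    * filter_transmission(position, l) * sensitivity_c(l) dl )

followed by additive Gaussian sensor noise, the camera's forward gamma curve
and quantization to the sensor bit depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .radiometry import CHANNELS, GammaCurve, gamma_from_power_law

__all__ = [
    "FilterSpec",
    "CameraSpec",
    "SceneSpec",
    "ScanSpec",
    "RawScanStack",
    "Spectrum",
    "ChannelSensitivity",
    "filter_transmission",
    "reference_spectrum",
    "make_scene",
    "render_scan",
    "auto_gain",
    "default_camera",
    "default_channel_sensitivity",
    "spectral_response_fwhm",
    "REFERENCE_CLASSES",
]

# Gaussian half-width multiplier at which the profile drops to 10% of peak
_X10 = math.sqrt(2.0 * math.log(10.0))
_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

# integration grid for the spectral quadrature (1 nm step)
_WL_GRID = np.arange(350.0, 751.0, 1.0)


@dataclass(frozen=True)
class FilterSpec:
    """Linear variable bandpass filter parameters.

    CWL and FWHM vary linearly with the fractional position along the filter
    (0 = short-wavelength end, 1 = long-wavelength end).
    """

    length_mm: float = 47.8
    cwl_start: float = 400.0
    cwl_end: float = 700.0
    fwhm_start: float = 3.0
    fwhm_end: float = 9.0
    peak_transmittance: float = 1.0

    def __post_init__(self) -> None:
        if self.cwl_end == self.cwl_start:
            raise ValueError("CWL gradient must be strictly monotone")
        if min(self.fwhm_start, self.fwhm_end) <= 0:
            raise ValueError("FWHM must be positive everywhere")
        if not 0.0 <= self.peak_transmittance <= 1.0:
            raise ValueError("peak transmittance must lie in [0, 1]")

    def cwl(self, position_frac):
        """Center wavelength (nm) at fractional position along the filter."""
        p = np.asarray(position_frac, dtype=float)
        return self.cwl_start + (self.cwl_end - self.cwl_start) * p

    def fwhm(self, position_frac):
        """Bandwidth FWHM (nm) at fractional position along the filter."""
        p = np.asarray(position_frac, dtype=float)
        return self.fwhm_start + (self.fwhm_end - self.fwhm_start) * p


def filter_transmission(spec: FilterSpec, position_frac, wavelength):
    """Transmittance of the filter at a given position and wavelength.

    The passband is modeled as a Gaussian profile with position-dependent
    center and FWHM.  ``position_frac`` must lie in [0, 1]; wavelengths are
    meaningful over roughly 350-750 nm.
    """
    p = np.asarray(position_frac, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("position_frac must lie in [0, 1]")
    wl = np.asarray(wavelength, dtype=float)
    sigma = spec.fwhm(p) * _FWHM_TO_SIGMA
    z = (wl - spec.cwl(p)) / sigma
    return spec.peak_transmittance * np.exp(-0.5 * z * z)


class Spectrum:
    """A reflectance (or radiance) spectrum as a callable of wavelength in nm."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], name: str = ""):
        self._fn = fn
        self.name = name

    def __call__(self, wavelength) -> np.ndarray:
        wl = np.asarray(wavelength, dtype=float)
        return np.asarray(self._fn(wl), dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Spectrum({self.name!r})"


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _algal(name, base_lo, base_hi, rise_center, rise_width, dips) -> Spectrum:
    """Smooth algal reflectance: a red-rising baseline minus Gaussian
    pigment-absorption dips given as (center nm, sigma nm, depth)."""

    def fn(wl):
        r = base_lo + (base_hi - base_lo) * _expit((wl - rise_center) / rise_width)
        for center, sigma, depth in dips:
            r = r - depth * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        return np.clip(r, 0.005, 1.0)

    return Spectrum(fn, name)


# Reflectance models for the four macroalgae classes plus the grey reference
# plate.  The brown classes carry chlorophyll-a absorption minima at 445 and
# 641 nm plus lesser dips at 496 and 603 nm; the red classes dip at 440 and
# 639 nm with lesser, species-shifted dips in the 480-490 and ~600 nm region
# and are brighter overall, especially in the red.  Dip centers sit
# slightly red-ward of the target minima to pre-compensate the blue-ward shift
# that the rising baseline imposes on the realized local minimum.
_REFERENCE_PARAMS = {
    "brown_a": (0.055, 0.220, 672.0, 10.0,
                [(445.0, 11.0, 0.030), (496.0, 9.0, 0.010),
                 (603.0, 9.0, 0.010), (642.0, 9.0, 0.045)]),
    "brown_b": (0.052, 0.185, 672.0, 10.0,
                [(445.0, 11.0, 0.028), (496.0, 9.0, 0.009),
                 (603.0, 9.0, 0.009), (642.0, 9.0, 0.042)]),
    "red_a": (0.105, 0.380, 674.0, 11.0,
              [(440.0, 11.0, 0.045), (491.0, 9.0, 0.016),
               (603.0, 9.0, 0.018), (640.3, 9.0, 0.055)]),
    "red_b": (0.075, 0.280, 674.0, 11.0,
              [(440.0, 11.0, 0.036), (481.0, 9.0, 0.013),
               (598.0, 9.0, 0.015), (640.0, 9.0, 0.045)]),
}

REFERENCE_CLASSES = ("brown_a", "brown_b", "red_a", "red_b", "grey")

GREY_REFLECTANCE = 0.1


def reference_spectrum(class_name: str) -> Spectrum:
    """Reference reflectance spectrum for one of the built-in classes.

    ``brown_a``/``brown_b`` emulate two closely related brown macroalgae,
    ``red_a``/``red_b`` two red macroalgae, and ``grey`` the flat (R = 0.1)
    neutral background plate used for calibration.
    """
    if class_name == "grey":
        return Spectrum(lambda wl: np.full_like(wl, GREY_REFLECTANCE, dtype=float), "grey")
    try:
        params = _REFERENCE_PARAMS[class_name]
    except KeyError:
        raise KeyError(
            f"unknown class {class_name!r}; choose from {REFERENCE_CLASSES}"
        ) from None
    return _algal(class_name, *params)


@dataclass(frozen=True)
class ChannelSensitivity:
    """Per-channel spectral sensitivity as two-sided generalized Gaussians.

    Each RGB channel has a peak wavelength and, on each side, the half-width
    at which the response has dropped to 10% of the peak plus a shape
    exponent: ``S = peak * 10 ** (-|dl / w10| ** q)``.  ``q = 2`` is an
    ordinary Gaussian; smaller exponents give heavier shoulders, as real
    color-filter-array dyes show on their long-wavelength side.  Channel
    order is (R, G, B).
    """

    centers: tuple[float, float, float]
    w10_lo: tuple[float, float, float]
    w10_hi: tuple[float, float, float]
    q_lo: tuple[float, float, float] = (2.0, 2.0, 2.0)
    q_hi: tuple[float, float, float] = (2.0, 2.0, 2.0)
    peaks: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __call__(self, wavelength) -> np.ndarray:
        wl = np.asarray(wavelength, dtype=float)
        out = np.empty(wl.shape + (3,), dtype=float)
        for i in range(3):
            lo = wl < self.centers[i]
            w = np.where(lo, self.w10_lo[i], self.w10_hi[i])
            q = np.where(lo, self.q_lo[i], self.q_hi[i])
            z = np.abs(wl - self.centers[i]) / w
            out[..., i] = self.peaks[i] * 10.0 ** (-(z**q))
        return out


def default_channel_sensitivity() -> ChannelSensitivity:
    """Default RGB sensitivities.

    The 10%-of-peak crossings sit at the edges of each channel's usable
    window (R: 510-642, G: 465-620, B: 436-566 nm): in particular the blue
    channel rises through 10% at 436 nm and the red channel falls through
    10% at 642 nm -- the two wavelength anchors of the frame-to-wavelength
    map.  The red channel's long side uses a heavier shoulder (q = 1.32) so
    that its response reaches the ~2.5% noise floor only at the 660 nm trim
    edge rather than collapsing right after the onset anchor; likewise the
    blue short side reaches the floor near 430 nm.
    """
    return ChannelSensitivity(
        centers=(600.0, 540.0, 460.0),
        w10_lo=(90.0, 75.0, 24.0),
        w10_hi=(42.0, 80.0, 106.0),
        q_hi=(1.32, 2.0, 2.0),
    )


@dataclass
class CameraSpec:
    """Camera parameters: geometry, timing, gamma, and spectral response."""

    rows: int = 128
    cols: int = 160
    frame_rate: float = 240.0
    bit_depth: int = 8
    gamma: Mapping[str, GammaCurve] = field(default_factory=dict)
    channel_sensitivity: ChannelSensitivity = field(
        default_factory=default_channel_sensitivity
    )
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.rows < 2 or self.cols < 1:
            raise ValueError("sensor must have at least 2 rows and 1 column")
        if not self.gamma:
            self.gamma = {
                ch: gamma_from_power_law(1.0, channel=ch, full_scale=self.full_scale)
                for ch in CHANNELS
            }

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class SceneSpec:
    """A flat scene: integer class map plus per-class reflectance spectra.

    Class 0 is always the grey reference plate (flat reflectance, default
    0.1) which doubles as the calibration target; the simulator guarantees
    grey margin rows at the top and bottom of the frame.
    """

    label_map: np.ndarray
    class_spectra: dict[int, Spectrum]
    class_names: dict[int, str]
    illumination: Spectrum = field(
        default_factory=lambda: Spectrum(lambda wl: np.ones_like(wl), "flat")
    )
    grey_reflectance: float = GREY_REFLECTANCE

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=np.int16)
        if self.label_map.ndim != 2:
            raise ValueError("label_map must be 2-D (rows, cols)")
        present = set(np.unique(self.label_map).tolist())
        if 0 not in present:
            raise ValueError("scene must contain the class-0 grey background")
        missing = present - {0} - set(self.class_spectra)
        if missing:
            raise ValueError(f"no spectrum provided for classes {sorted(missing)}")
        if 0 not in self.class_spectra:
            self.class_spectra[0] = Spectrum(
                lambda wl: np.full_like(wl, self.grey_reflectance), "grey"
            )
            self.class_names.setdefault(0, "grey")
        for k, spec in self.class_spectra.items():
            r = spec(_WL_GRID)
            if np.any(r < 0) or np.any(r > 1):
                raise ValueError(f"class {k} reflectance leaves [0, 1]")

    @property
    def rows(self) -> int:
        return self.label_map.shape[0]

    @property
    def cols(self) -> int:
        return self.label_map.shape[1]


@dataclass(frozen=True)
class ScanSpec:
    """One full filter sweep: frame count, shear, noise, and RNG seed.

    ``shift_slope`` is the true row shift in frames per row: how many frames
    later the top of the image reaches the filter position the bottom saw.
    """

    n_frames: int = 240
    shift_slope: float = 0.2
    noise_sd: float = 0.005
    seed: int = 0
    exposure_blur: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("a sweep needs at least 2 frames")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class RawScanStack:
    """Raw scan: 4-D integer count stack (frame, row, col, RGB) + provenance."""

    counts: np.ndarray
    camera: CameraSpec
    scan: ScanSpec
    filter: FilterSpec = field(default_factory=FilterSpec)
    scene_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.ndim != 4 or c.shape[3] != 3:
            raise ValueError("counts must be (frame, row, col, 3)")
        if c.shape[0] != self.scan.n_frames:
            raise ValueError("frame count disagrees with scan metadata")
        if c.shape[1] != self.camera.rows or c.shape[2] != self.camera.cols:
            raise ValueError("spatial shape disagrees with camera metadata")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]


def _make_patches(rows, cols, margin, n_patches, rng):
    """Rectangular patch boxes (col_min, row_min, col_max, row_max) laid out
    on a 2-column grid inside the grey margins, with small seeded jitter."""
    top = margin + 4
    bottom = rows - margin - 4
    grid_rows = (n_patches + 1) // 2
    cell_h = (bottom - top) // grid_rows
    cell_w = (cols - 16) // 2
    boxes = []
    for i in range(n_patches):
        gr, gc = divmod(i, 2)
        r0 = top + gr * cell_h
        c0 = 8 + gc * cell_w
        jr = int(rng.integers(-2, 3))
        jc = int(rng.integers(-2, 3))
        h = int(cell_h * 0.72)
        w = int(cell_w * 0.72)
        rmin = np.clip(r0 + (cell_h - h) // 2 + jr, top, bottom - 2)
        cmin = np.clip(c0 + (cell_w - w) // 2 + jc, 1, cols - 2)
        rmax = min(rmin + h, bottom)
        cmax = min(cmin + w, cols - 1)
        boxes.append((int(cmin), int(rmin), int(cmax), int(rmax)))
    return boxes


def make_scene(
    layout="four_species",
    classes: Mapping[str, Spectrum] | None = None,
    seed: int = 1,
    rows: int = 128,
    cols: int = 160,
    margin: int = 16,
    illumination: Spectrum | None = None,
    flat_reflectance: float = 0.5,
) -> SceneSpec:
    """Build a synthetic scene.

    Parameters
    ----------
    layout : str or ndarray
        ``"four_species"`` -- four rectangular macroalgae patches on the grey
        plate; ``"flat_patch"`` -- one central patch of flat reflectance
        ``flat_reflectance``; or an explicit 2-D integer label map.
    classes : mapping, optional
        Class name -> :class:`Spectrum`, overriding the built-in reference
        spectra.  At least one non-background class is required.
    margin : int
        Grey-plate rows kept free at the top and bottom of the frame (needed
        by shift estimation and calibration).
    """
    rng = np.random.default_rng(seed)
    if isinstance(layout, np.ndarray):
        if classes is None or len(classes) == 0:
            raise ValueError("an explicit label map requires class spectra")
        names = list(classes)
        spectra = {i + 1: classes[n] for i, n in enumerate(names)}
        class_names = {0: "grey", **{i + 1: n for i, n in enumerate(names)}}
        scene = SceneSpec(layout, spectra, class_names)
    elif layout == "four_species":
        if classes is None:
            classes = {n: reference_spectrum(n) for n in REFERENCE_CLASSES[:4]}
        if len(classes) == 0:
            raise ValueError("need at least one non-background class")
        names = list(classes)
        label = np.zeros((rows, cols), dtype=np.int16)
        boxes = _make_patches(rows, cols, margin, len(names), rng)
        for i, (cmin, rmin, cmax, rmax) in enumerate(boxes):
            label[rmin:rmax, cmin:cmax] = i + 1
        spectra = {i + 1: classes[n] for i, n in enumerate(names)}
        class_names = {0: "grey", **{i + 1: n for i, n in enumerate(names)}}
        scene = SceneSpec(label, spectra, class_names)
    elif layout == "flat_patch":
        label = np.zeros((rows, cols), dtype=np.int16)
        h = max(rows - 2 * margin - 8, 4)
        w = max(cols - 32, 4)
        r0 = (rows - h) // 2 + int(rng.integers(-1, 2))
        c0 = (cols - w) // 2
        label[r0 : r0 + h, c0 : c0 + w] = 1
        if classes:
            name, spec = next(iter(classes.items()))
        else:
            r = float(flat_reflectance)
            name = "flat"
            spec = Spectrum(lambda wl: np.full_like(wl, r), "flat")
        scene = SceneSpec(label, {1: spec}, {0: "grey", 1: name})
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if illumination is not None:
        scene.illumination = illumination
    return scene


def _envelope(filt: FilterSpec, camera: CameraSpec, illumination: Spectrum,
              n_pos: int = 1025):
    """Per-channel scan envelope: signal of a perfect (R=1) reflector as a
    function of filter position.  Returns (pos_grid, env[(n_pos, 3)])."""
    wl = _WL_GRID
    pos = np.linspace(0.0, 1.0, n_pos)
    T = filter_transmission(filt, pos[:, None], wl[None, :])
    weight = illumination(wl)[:, None] * camera.channel_sensitivity(wl)
    return pos, T @ weight  # 1 nm quadrature step


def auto_gain(
    filt: FilterSpec,
    camera: CameraSpec,
    illumination: Spectrum | None = None,
    target_fill: float = 0.95,
    reference_reflectance: float = 0.5,
) -> float:
    """Exposure gain such that a target of the given reflectance peaks at
    ``target_fill`` of the linear full scale (exposure-setting surrogate)."""
    if illumination is None:
        illumination = Spectrum(lambda wl: np.ones_like(wl), "flat")
    _, env = _envelope(filt, camera, illumination)
    return target_fill / (reference_reflectance * float(env.max()))


def default_camera(
    rows: int = 128,
    cols: int = 160,
    gamma_exponent: float = 0.45,
    filt: FilterSpec | None = None,
) -> CameraSpec:
    """Camera with power-law gamma and exposure gain set for flat lighting."""
    cam = CameraSpec(
        rows=rows,
        cols=cols,
        gamma={
            ch: gamma_from_power_law(gamma_exponent, channel=ch) for ch in CHANNELS
        },
    )
    cam.gain = auto_gain(filt or FilterSpec(), cam)
    return cam


def render_scan(
    scene: SceneSpec,
    camera: CameraSpec | None = None,
    filt: FilterSpec | None = None,
    scan: ScanSpec | None = None,
) -> RawScanStack:
    """Render a raw video scan of a scene.

    For frame ``f`` and image row ``y`` the effective filter position is
    ``(f + shift_slope * y) / (n_frames - 1)`` clipped to [0, 1]: the filter
    sweeps its full length over one scan, and lower rows reach any given
    position earlier than upper rows (positive shear).  The per-pixel linear
    signal is the 1 nm-step quadrature of illumination x reflectance x filter
    transmission x channel sensitivity, scaled by the camera gain, plus
    Gaussian noise, then passed through the forward gamma curve and quantized.
    Deterministic for a fixed ``scan.seed``.
    """
    filt = filt or FilterSpec()
    camera = camera or default_camera(filt=filt)
    scan = scan or ScanSpec()
    if scene.rows != camera.rows or scene.cols != camera.cols:
        camera = replace(camera, rows=scene.rows, cols=scene.cols)

    wl = _WL_GRID
    pos_grid, _ = _envelope(filt, camera, scene.illumination)
    T = filter_transmission(filt, pos_grid[:, None], wl[None, :])
    base_weight = scene.illumination(wl)[:, None] * camera.channel_sensitivity(wl)

    f = np.arange(scan.n_frames, dtype=float)
    y = np.arange(scene.rows, dtype=float)
    posmat = (f[:, None] + scan.shift_slope * y[None, :]) / (scan.n_frames - 1)
    if scan.exposure_blur:
        # average the filter position over the exposure window (one frame's
        # worth of travel), approximated with a 3-point rule
        step = 1.0 / (scan.n_frames - 1)
        posmats = [posmat, posmat + 0.5 * step, posmat + step]
    else:
        posmats = [posmat]
    posmats = [np.clip(p, 0.0, 1.0) for p in posmats]

    linear = np.empty((scan.n_frames, scene.rows, scene.cols, 3), dtype=np.float32)
    for k in np.unique(scene.label_map):
        refl = scene.class_spectra[int(k)](wl)
        G = T @ (refl[:, None] * base_weight)  # (n_pos, 3)
        ys, xs = np.nonzero(scene.label_map == k)
        for c in range(3):
            sig = np.mean(
                [np.interp(p, pos_grid, G[:, c]) for p in posmats], axis=0
            )
            linear[:, ys, xs, c] = (camera.gain * sig[:, ys]).astype(np.float32)

    rng = np.random.default_rng(scan.seed)
    if scan.noise_sd > 0:
        linear += rng.normal(0.0, scan.noise_sd, size=linear.shape).astype(
            np.float32
        )
    np.clip(linear, 0.0, 1.0, out=linear)

    counts = np.empty(linear.shape, dtype=np.uint8 if camera.bit_depth <= 8 else np.uint16)
    p_grid = np.linspace(0.0, 1.0, 2049)
    for i, ch in enumerate(CHANNELS):
        c_grid = camera.gamma[ch].forward(p_grid)
        vals = np.interp(linear[..., i], p_grid, c_grid)
        counts[..., i] = np.clip(np.rint(vals), 0, camera.full_scale).astype(
            counts.dtype
        )
    return RawScanStack(
        counts=counts,
        camera=camera,
        scan=scan,
        filter=filt,
        scene_labels=scene.label_map.copy(),
    )


def spectral_response_fwhm(
    filt: FilterSpec, wavelength: float, n_pos: int = 20001
) -> float:
    """Spectral resolution probe: FWHM (nm) of the temporal response that a
    monochromatic target at ``wavelength`` produces during a scan, expressed
    on the wavelength axis via the filter's CWL gradient."""
    pos = np.linspace(0.0, 1.0, n_pos)
    profile = filter_transmission(filt, pos, wavelength)
    peak = profile.max()
    if peak <= 0:
        raise ValueError("wavelength outside the filter's range")
    above = profile >= 0.5 * peak
    idx = np.nonzero(above)[0]
    lo, hi = pos[idx[0]], pos[idx[-1]]
    return float(abs(filt.cwl(hi) - filt.cwl(lo)))
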