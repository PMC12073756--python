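"""End-to-end orchestration: simulate, reconstruct, label, train, evaluate.

This module wires the instrument simulator, radiometric linearization, cube
reconstruction, calibration, spectral library, and classifier into the
standard processing chains used by the command-line interface, the test
suite, and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration as calib
from . import cube as cube_mod
from .classifier import (
    ModelSpec,
    SpectralCNN,
    TrainConfig,
    TrainResult,
    build_model,
    train_model,
)
from .config import PipelineConfig
from .hypercube import Hypercube
from .instrument import (
    CameraSpec,
    FilterSpec,
    RawScanStack,
    ScanSpec,
    SceneSpec,
    default_camera,
    make_scene,
    render_scan,
)
from .library import Annotation, SpectralLibrary, extract_labeled_pixels
from .radiometry import GammaCurve, fit_gamma_table, linearize_stack

__all__ = [
    "PipelineResult",
    "simulate_scan",
    "simulate_gamma_measurements",
    "fitted_gamma_curves",
    "grey_margin_mask",
    "build_cube",
    "annotations_from_scene",
    "train_on_cubes",
]


def simulate_scan(
    config: PipelineConfig | None = None,
    layout: str = "four_species",
    seed: int = 1,
    rows: int | None = None,
    cols: int | None = None,
) -> tuple[RawScanStack, SceneSpec]:
    """Render a synthetic raw scan under the configured study conditions."""
    config = config or PipelineConfig()
    rows = rows or config.camera.rows
    cols = cols or config.camera.cols
    filt = FilterSpec(**config.filter.model_dump())
    camera = default_camera(
        rows=rows, cols=cols, gamma_exponent=config.camera.gamma_exponent, filt=filt
    )
    camera.frame_rate = config.camera.frame_rate
    camera.bit_depth = config.camera.bit_depth
    scan = ScanSpec(
        n_frames=config.scan.n_frames,
        shift_slope=config.scan.shift_slope,
        noise_sd=config.scan.noise_sd,
        seed=seed,
        exposure_blur=config.scan.exposure_blur,
    )
    scene = make_scene(
        layout=layout,
        seed=seed,
        rows=rows,
        cols=cols,
        margin=config.scene.margin,
        flat_reflectance=config.scene.flat_reflectance,
    )
    return render_scan(scene, camera, filt, scan), scene


def simulate_gamma_measurements(
    camera: CameraSpec, n_levels: int = 33
) -> pd.DataFrame:
    """Emulate the gamma characterization: per channel, record the digital
    count at a ladder of known relative power levels.

    The ladder follows Malus's law -- a rotating-polarizer attenuator at
    evenly spaced angles gives ``power = sin^2(theta)`` -- which concentrates
    levels near extinction where the camera's tone curve is steepest.
    """
    powers = np.sin(np.linspace(0.0, np.pi / 2.0, n_levels)) ** 2
    rows = []
    for ch, curve in camera.gamma.items():
        counts = np.rint(curve.forward(powers))
        for p, c in zip(powers, counts):
            rows.append({"channel": ch, "power": p, "count": c})
    return pd.DataFrame(rows)


def fitted_gamma_curves(camera: CameraSpec, n_levels: int = 21) -> dict[str, GammaCurve]:
    """Gamma curves re-fitted from simulated characterization measurements
    (the honest route: the reconstruction never sees the true curves)."""
    return fit_gamma_table(simulate_gamma_measurements(camera, n_levels))


def grey_margin_mask(rows: int, cols: int, margin: int) -> np.ndarray:
    """Mask of the grey-plate margin rows at the top and bottom of the frame."""
    mask = np.zeros((rows, cols), dtype=bool)
    mask[:margin] = True
    mask[rows - margin :] = True
    return mask


@dataclass
class PipelineResult:
    """Reconstruction outputs: final cube plus the estimated models."""

    cube: Hypercube
    shift_model: cube_mod.ShiftModel
    wavelength_map: cube_mod.WavelengthMap
    onsets: tuple[float, float]
    grey_region: np.ndarray
    intensity_cube: Hypercube | None = None
    lags: list[tuple[float, float]] = field(default_factory=list)


def build_cube(
    stack: RawScanStack,
    curves: dict[str, GammaCurve] | None = None,
    config: PipelineConfig | None = None,
    margin: int | None = None,
    keep_intensity: bool = False,
) -> PipelineResult:
    """Full raw-scan to reflectance-cube reconstruction.

    Steps: gamma linearization, shear estimation on the grey margins,
    de-shearing, onset detection, wavelength mapping, channel trimming and
    summation, band interpolation, grey-plate reflectance calibration,
    Savitzky-Golay denoising, and band binning.

    ``curves`` defaults to curves re-fitted from simulated characterization
    measurements of the stack's own camera.
    """
    config = config or PipelineConfig()
    margin = margin or config.scene.margin
    rows, cols = stack.camera.rows, stack.camera.cols
    curves = curves or fitted_gamma_curves(stack.camera)

    linear, saturated = linearize_stack(
        stack.counts, curves, bit_depth=stack.camera.bit_depth
    )

    # shear from grey-margin pixel pairs across several columns
    row_top = margin // 2
    row_bottom = rows - margin // 2 - 1
    columns = np.linspace(4, cols - 5, config.cube.n_shift_columns).astype(int)
    lags = []
    for col in columns:
        lag = cube_mod.estimate_row_shift(linear, int(col), row_top, row_bottom)
        lags.append((row_bottom - row_top, lag))
    shift_model = cube_mod.fit_shift_model(lags)

    mono = cube_mod.deshear_stack(linear, shift_model, saturated=saturated)
    grey_region = grey_margin_mask(rows, cols, margin)
    onsets = cube_mod.detect_onsets(
        mono, grey_region, threshold=config.cube.onset_threshold
    )
    wmap = cube_mod.build_wavelength_map(onsets)

    windows = cube_mod.ChannelTrimWindows(**config.cube.trim.model_dump())
    summed = cube_mod.trim_and_sum_channels(mono, wmap, windows)
    grid = np.linspace(
        config.cube.band_min, config.cube.band_max, config.cube.grid_points
    )
    intensity = cube_mod.interpolate_bands(summed, wmap, grid)

    reflectance = calib.calibrate_reflectance(
        intensity, grey_region, r_ref=config.calibration.grey_reflectance
    )
    smooth = calib.savgol_denoise(
        reflectance,
        order=config.calibration.savgol_order,
        window=config.calibration.savgol_window,
    )
    final = calib.bin_bands(smooth, factor=config.calibration.bin_factor)
    return PipelineResult(
        cube=final,
        shift_model=shift_model,
        wavelength_map=wmap,
        onsets=onsets,
        grey_region=grey_region,
        intensity_cube=intensity if keep_intensity else None,
        lags=lags,
    )


def annotations_from_scene(
    scene: SceneSpec,
    cube_id: str,
    margin: int | None = None,
    background: bool = True,
) -> list[Annotation]:
    """Derive bounding-box annotations from a simulated scene's label map.

    Each non-background class contributes its bounding rectangle (patches are
    rectangular, so the box contains only that class); the grey background
    contributes two strips inside the top and bottom margins.
    """
    anns = []
    labels = scene.label_map
    rows, cols = labels.shape
    for k in np.unique(labels):
        if k == 0:
            continue
        ys, xs = np.nonzero(labels == k)
        anns.append(
            Annotation(
                cube_id,
                scene.class_names[int(k)],
                (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1),
            )
        )
    if background:
        m = margin if margin is not None else 16
        name = scene.class_names.get(0, "grey")
        anns.append(Annotation(cube_id, name, (4, 2, cols - 4, min(m - 2, rows))))
        anns.append(Annotation(cube_id, name, (4, rows - m + 2, cols - 4, rows - 2)))
    return anns


@dataclass
class BenchmarkResult:
    """End-to-end synthetic classification benchmark outputs."""

    metrics: "object"  # ClassMetrics
    train_result: TrainResult
    library: SpectralLibrary
    coverage: dict[str, float]
    shift_slope: float
    cube: Hypercube


def run_synthetic_benchmark(
    seed: int = 0,
    epochs: int = 50,
    rows: int = 208,
    cols: int = 256,
    margin: int = 20,
    config: PipelineConfig | None = None,
) -> BenchmarkResult:
    """Simulate, reconstruct, train, and evaluate on a held-out cube.

    One training scene and one test scene (different layout seeds) are
    rendered with the four reference macroalgae classes on the grey plate
    (~5,000 labeled pixels per class at the default 208x256 sensor),
    reconstructed to 45-band reflectance cubes, and used to train and
    evaluate the 1-D CNN.  Fully deterministic for a fixed seed.
    """
    from .classifier import evaluate_segmentation, predict_cube

    config = config or PipelineConfig()
    config.scene.margin = margin
    stack_tr, scene_tr = simulate_scan(config, seed=seed + 11, rows=rows, cols=cols)
    stack_te, scene_te = simulate_scan(config, seed=seed + 99, rows=rows, cols=cols)
    result_tr = build_cube(stack_tr, config=config, margin=margin)
    result_te = build_cube(stack_te, config=config, margin=margin)
    ann_tr = annotations_from_scene(scene_tr, "train", margin=margin)
    ann_te = annotations_from_scene(scene_te, "test", margin=margin)
    class_names = ["grey", "brown_a", "brown_b", "red_a", "red_b"]
    train_result, library = train_on_cubes(
        {"train": result_tr.cube}, ann_tr, class_names, config,
        epochs=epochs, seed=seed,
    )
    pred = predict_cube(train_result.model, result_te.cube)
    metrics = evaluate_segmentation(pred, ann_te, "test")
    return BenchmarkResult(
        metrics=metrics,
        train_result=train_result,
        library=library,
        coverage=pred.coverage,
        shift_slope=result_tr.shift_model.slope,
        cube=result_te.cube,
    )


def train_on_cubes(
    cubes: dict[str, Hypercube],
    annotations: list[Annotation],
    class_names: list[str],
    config: PipelineConfig | None = None,
    epochs: int | None = None,
    seed: int = 0,
) -> tuple[TrainResult, SpectralLibrary]:
    """Extract a spectral library from annotated cubes and train the CNN."""
    config = config or PipelineConfig()
    library = extract_labeled_pixels(cubes, annotations)
    spec = ModelSpec(
        n_bands=config.model.n_bands,
        n_classes=len(class_names),
        conv1_filters=config.model.conv1_filters,
        conv2_filters=config.model.conv2_filters,
        kernel_size=config.model.kernel_size,
        pool_size=config.model.pool_size,
        dropout=config.model.dropout,
        dense_units=config.model.dense_units,
    )
    model = build_model(spec, class_names=class_names, seed=seed)
    tc = TrainConfig(
        epochs=epochs or config.training.epochs,
        batch_size=config.training.batch_size,
        learning_rate=config.training.learning_rate,
        train_fraction=config.training.train_fraction,
        seed=seed,
    )
    return train_model(model, library, tc), library
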