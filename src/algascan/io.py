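"""File formats: raw-scan containers, ENVI cubes, PNG frame import.

Raw scans travel as a compressed NumPy container (``.npz``) holding the count
stack plus ground-truth labels when simulated, with a JSON sidecar carrying
the acquisition metadata.  Reconstructed cubes are written as ENVI images --
a plain-text ``.hdr`` describing a band-sequential (BSQ) little-endian
float32 ``.img`` payload with the band-center wavelengths in the header --
the lingua franca of hyperspectral tooling.  Invalid cube entries are stored
as NaN, so masks survive the round trip.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np

from .hypercube import Hypercube
from .instrument import CameraSpec, FilterSpec, RawScanStack, ScanSpec, default_camera
from .radiometry import GammaCurve

__all__ = [
    "save_scan",
    "load_scan",
    "load_scan_frames",
    "write_envi",
    "read_envi",
]


def _scan_meta(stack: RawScanStack) -> dict:
    cam = dataclasses.asdict(stack.camera)
    cam.pop("channel_sensitivity", None)
    cam["gamma"] = {
        ch: {"power": c.power_knots.tolist(), "count": c.count_knots.tolist()}
        for ch, c in stack.camera.gamma.items()
    }
    return {
        "camera": cam,
        "scan": dataclasses.asdict(stack.scan),
        "filter": dataclasses.asdict(stack.filter),
    }


def save_scan(path, stack: RawScanStack) -> None:
    """Write a raw scan as ``path`` (.npz) plus a ``.json`` metadata sidecar."""
    path = Path(path)
    arrays = {"counts": stack.counts}
    if stack.scene_labels is not None:
        arrays["scene_labels"] = stack.scene_labels
    np.savez_compressed(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(_scan_meta(stack), indent=2))


def load_scan(path) -> RawScanStack:
    """Read a raw scan container written by :func:`save_scan`."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} is missing")
    meta = json.loads(sidecar.read_text())
    with np.load(path) as z:
        counts = z["counts"]
        labels = z["scene_labels"] if "scene_labels" in z else None
    camera = default_camera(
        rows=int(meta["camera"]["rows"]), cols=int(meta["camera"]["cols"])
    )
    camera.frame_rate = float(meta["camera"]["frame_rate"])
    camera.bit_depth = int(meta["camera"]["bit_depth"])
    camera.gain = float(meta["camera"]["gain"])
    camera.gamma = {
        ch: GammaCurve(ch, np.array(d["power"]), np.array(d["count"]))
        for ch, d in meta["camera"]["gamma"].items()
    }
    return RawScanStack(
        counts=counts,
        camera=camera,
        scan=ScanSpec(**meta["scan"]),
        filter=FilterSpec(**meta["filter"]),
        scene_labels=labels,
    )


def load_scan_frames(directory, camera: CameraSpec | None = None,
                     scan: ScanSpec | None = None) -> RawScanStack:
    """Import a raw scan from a directory of numbered PNG frames.

    Frames are sorted by the number embedded in each file name.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    files = sorted(
        directory.glob("*.png"),
        key=lambda p: int(re.sub(r"\D", "", p.stem) or 0),
    )
    if not files:
        raise FileNotFoundError(f"no PNG frames in {directory}")
    frames = np.stack([iio.imread(f)[..., :3] for f in files])
    n, rows, cols, _ = frames.shape
    camera = camera or default_camera(rows=rows, cols=cols)
    scan = scan or ScanSpec(n_frames=n)
    return RawScanStack(counts=frames, camera=camera, scan=scan)


_ENVI_TEMPLATE = """ENVI
description = {{ algascan reflectance hypercube }}
samples = {samples}
lines = {lines}
bands = {bands}
header offset = 0
file type = ENVI Standard
data type = 4
interleave = bsq
byte order = 0
wavelength units = Nanometers
wavelength = {{ {wavelengths} }}
"""


def write_envi(path, cube: Hypercube) -> None:
    """Write a cube as ENVI: text ``.hdr`` + float32 little-endian BSQ ``.img``.

    Masked entries are written as NaN and recovered as the validity mask on
    read.
    """
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix("")
    hdr = path.with_suffix(".hdr")
    img = path.with_suffix(".img")
    rows, cols, bands = cube.shape
    hdr.write_text(
        _ENVI_TEMPLATE.format(
            samples=cols,
            lines=rows,
            bands=bands,
            wavelengths=", ".join(f"{w:.4f}" for w in cube.band_centers),
        )
    )
    data = cube.values.copy()
    data[~cube.valid_mask] = np.nan
    # BSQ: band, line, sample
    np.ascontiguousarray(data.transpose(2, 0, 1).astype("<f4")).tofile(img)


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    # join brace-delimited multi-line values, then split on newlines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields = {}
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(path) -> Hypercube:
    """Read an ENVI cube written by :func:`write_envi` (with validation)."""
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix("")
    hdr = path.with_suffix(".hdr")
    img = path.with_suffix(".img")
    fields = _parse_envi_header(hdr.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field: {exc}") from None
    if dtype_code != 4 or interleave != "bsq":
        raise ValueError("only float32 BSQ ENVI cubes are supported")
    wl_match = re.search(r"\{([^}]*)\}", fields.get("wavelength", ""))
    if not wl_match:
        raise ValueError("ENVI header lacks a wavelength list")
    wavelengths = np.array(
        [float(w) for w in wl_match.group(1).split(",") if w.strip()]
    )
    if len(wavelengths) != bands:
        raise ValueError(
            f"header wavelength list has {len(wavelengths)} entries "
            f"for {bands} bands"
        )
    raw = np.fromfile(img, dtype="<f4")
    if raw.size != rows * cols * bands:
        raise ValueError(
            f"data size {raw.size} does not match header "
            f"{rows}x{cols}x{bands}"
        )
    values = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    return Hypercube(values=values, band_centers=wavelengths)
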