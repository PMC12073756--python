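"""Spectral libraries: labeled per-pixel spectra from annotated cubes.

Annotations are axis-aligned pixel boxes (0-based, half-open) drawn on a
reconstructed cube and tagged with a class label.  Extraction turns each box
into one record per pixel -- (cube id, row, col, class, reflectance vector) --
dropping pixels with any invalid band and de-duplicating pixels covered by
overlapping boxes.  Class summaries (band-wise mean and standard deviation)
and absorption-feature localization operate on the resulting library.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypercube import Hypercube

__all__ = [
    "Annotation",
    "SpectralLibrary",
    "extract_labeled_pixels",
    "class_mean_spectra",
    "find_absorption_minima",
    "read_annotations",
    "write_annotations",
]


@dataclass(frozen=True)
class Annotation:
    """A labeled pixel box: 0-based, half-open (col_min, row_min, col_max, row_max)."""

    cube_id: str
    class_label: str
    box: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        cmin, rmin, cmax, rmax = self.box
        if cmax <= cmin or rmax <= rmin:
            raise ValueError(f"annotation {self.cube_id}/{self.class_label}: empty box")

    @property
    def area(self) -> int:
        cmin, rmin, cmax, rmax = self.box
        return (cmax - cmin) * (rmax - rmin)


def write_annotations(path, annotations: list[Annotation]) -> None:
    """Write annotations as JSON lines."""
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(
                json.dumps(
                    {"cube_id": a.cube_id, "class": a.class_label, "box": list(a.box)}
                )
                + "\n"
            )


def read_annotations(path) -> list[Annotation]:
    """Read JSON-lines annotations."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            out.append(Annotation(d["cube_id"], d["class"], tuple(d["box"])))
    return out


@dataclass
class SpectralLibrary:
    """Labeled per-pixel spectra.

    ``spectra`` is (n_records, n_bands); ``labels`` the class per record;
    ``pixels`` a table with columns cube_id, row, col (no duplicates).
    """

    spectra: np.ndarray
    labels: np.ndarray
    pixels: pd.DataFrame
    band_centers: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        if self.spectra.ndim != 2 or len(self.labels) != len(self.spectra):
            raise ValueError("spectra must be (n_records, n_bands) matching labels")
        if self.pixels.duplicated(["cube_id", "row", "col"]).any():
            raise ValueError("duplicate (cube_id, row, col) records")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> list[str]:
        return sorted(np.unique(self.labels).tolist())

    def class_counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()

    def subset(self, index: np.ndarray) -> "SpectralLibrary":
        return SpectralLibrary(
            self.spectra[index],
            self.labels[index],
            self.pixels.iloc[index].reset_index(drop=True),
            self.band_centers,
        )

    def to_frame(self) -> pd.DataFrame:
        bands = [f"band_{c:.2f}" for c in self.band_centers]
        df = self.pixels.copy()
        df["class"] = self.labels
        return pd.concat(
            [df, pd.DataFrame(self.spectra, columns=bands, index=df.index)], axis=1
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectralLibrary":
        df = pd.read_csv(path)
        band_cols = [c for c in df.columns if c.startswith("band_")]
        centers = np.array([float(c.split("_", 1)[1]) for c in band_cols])
        return cls(
            df[band_cols].to_numpy(dtype=np.float32),
            df["class"].to_numpy(),
            df[["cube_id", "row", "col"]].reset_index(drop=True),
            centers,
        )

    def to_npz(self, path) -> None:
        np.savez_compressed(
            path,
            spectra=self.spectra,
            labels=self.labels.astype(str),
            cube_id=self.pixels["cube_id"].to_numpy(dtype=str),
            row=self.pixels["row"].to_numpy(),
            col=self.pixels["col"].to_numpy(),
            band_centers=self.band_centers,
        )

    @classmethod
    def from_npz(cls, path) -> "SpectralLibrary":
        with np.load(path, allow_pickle=False) as z:
            pixels = pd.DataFrame(
                {"cube_id": z["cube_id"], "row": z["row"], "col": z["col"]}
            )
            return cls(z["spectra"], z["labels"], pixels, z["band_centers"])


def extract_labeled_pixels(
    cubes: dict[str, Hypercube], annotations: list[Annotation]
) -> SpectralLibrary:
    """One record per annotated pixel, dropping masked and duplicate pixels.

    Overlapping boxes contribute each pixel once (first annotation wins; a
    conflicting class on the same pixel triggers a warning).
    """
    spectra, labels, rows_ = [], [], []
    seen: dict[tuple[str, int, int], str] = {}
    band_centers = None
    for ann in annotations:
        if ann.cube_id not in cubes:
            raise KeyError(f"annotation references unknown cube {ann.cube_id!r}")
        cube = cubes[ann.cube_id]
        if band_centers is None:
            band_centers = cube.band_centers
        cmin, rmin, cmax, rmax = ann.box
        nrows, ncols, _ = cube.shape
        if not (0 <= cmin < cmax <= ncols and 0 <= rmin < rmax <= nrows):
            raise ValueError(
                f"annotation {ann.cube_id}/{ann.class_label} box {ann.box} "
                f"exceeds cube bounds {(ncols, nrows)}"
            )
        block = cube.values[rmin:rmax, cmin:cmax]
        ok = cube.valid_mask[rmin:rmax, cmin:cmax].all(axis=2)
        if not ok.any():
            warnings.warn(
                f"annotation {ann.cube_id}/{ann.class_label} covers only "
                "masked pixels; no records extracted",
                stacklevel=2,
            )
            continue
        ys, xs = np.nonzero(ok)
        for y, x in zip(ys, xs):
            key = (ann.cube_id, rmin + int(y), cmin + int(x))
            if key in seen:
                if seen[key] != ann.class_label:
                    warnings.warn(
                        f"pixel {key} annotated as both {seen[key]!r} and "
                        f"{ann.class_label!r}; keeping the first",
                        stacklevel=2,
                    )
                continue
            seen[key] = ann.class_label
            spectra.append(block[y, x])
            labels.append(ann.class_label)
            rows_.append(key)
    if band_centers is None:
        raise ValueError("no annotations given")
    pixels = pd.DataFrame(rows_, columns=["cube_id", "row", "col"])
    return SpectralLibrary(
        np.asarray(spectra, dtype=np.float32),
        np.asarray(labels),
        pixels,
        band_centers,
    )


def class_mean_spectra(
    library: SpectralLibrary, classes: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Band-wise mean and standard deviation per class.

    Returns two DataFrames (mean, sd) indexed by class with one column per
    band center.
    """
    classes = classes or library.classes
    means, sds = {}, {}
    for cls in classes:
        sel = library.labels == cls
        if not sel.any():
            raise ValueError(f"no records for class {cls!r}")
        means[cls] = library.spectra[sel].mean(axis=0)
        sds[cls] = library.spectra[sel].std(axis=0)
    cols = library.band_centers
    return (
        pd.DataFrame(means, index=cols).T,
        pd.DataFrame(sds, index=cols).T,
    )


def find_absorption_minima(
    spectrum: np.ndarray,
    band_centers: np.ndarray,
    search_windows: list[tuple[float, float]],
) -> list[float | None]:
    """Locate reflectance minima (absorption features) within windows.

    A minimum is a sample strictly smaller than both neighbours.  Within each
    (lo, hi) nm window the deepest such minimum is returned (ties broken
    toward the shorter wavelength); ``None`` where a window has no local
    minimum.
    """
    r = np.asarray(spectrum, dtype=float)
    wl = np.asarray(band_centers, dtype=float)
    if r.ndim != 1 or r.size < 3:
        raise ValueError("spectrum must be 1-D with at least 3 samples")
    interior = np.arange(1, r.size - 1)
    is_min = (r[interior] < r[interior - 1]) & (r[interior] < r[interior + 1])
    min_idx = interior[is_min]
    out: list[float | None] = []
    for lo, hi in search_windows:
        cand = min_idx[(wl[min_idx] >= lo) & (wl[min_idx] <= hi)]
        if cand.size == 0:
            out.append(None)
            continue
        depths = r[cand]
        best = cand[np.lexsort((wl[cand], depths))][0]  # deepest, then shortest
        out.append(float(wl[best]))
    return out
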