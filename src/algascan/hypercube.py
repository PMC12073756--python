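"""The hypercube container: (row, col, band) values with band metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Hypercube"]


@dataclass
class Hypercube:
    """A 3-D spectral image: two spatial axes and one band axis.

    ``values`` holds intensity before calibration and reflectance after;
    invalid (band, pixel) entries are NaN and flagged False in ``valid_mask``
    so that statistics and model inputs can exclude them.
    """

    values: np.ndarray  # (rows, cols, bands), float
    band_centers: np.ndarray  # (bands,), nm, strictly ascending
    valid_mask: np.ndarray = field(default=None)  # (rows, cols, bands), bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("hypercube values must be (rows, cols, bands)")
        if self.band_centers.shape != (self.values.shape[2],):
            raise ValueError("band_centers length must equal the band axis")
        if np.any(np.diff(self.band_centers) <= 0):
            raise ValueError("band centers must be strictly ascending")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise ValueError("valid_mask shape must match values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def pixel_valid(self) -> np.ndarray:
        """(rows, cols) mask of pixels valid in every band."""
        return self.valid_mask.all(axis=2)

    def spectra(self, pixel_mask: np.ndarray) -> np.ndarray:
        """Per-pixel spectra (n, bands) for the pixels selected by a mask."""
        return self.values[pixel_mask]

    def copy(self) -> "Hypercube":
        return Hypercube(
            self.values.copy(), self.band_centers.copy(), self.valid_mask.copy()
        )
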