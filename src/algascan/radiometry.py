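"""Camera gamma characterization and radiometric linearization.

Consumer action cameras encode linear sensor irradiance through a strongly
non-linear opto-electronic transfer function ("gamma") before 8-bit
quantization.  For quantitative spectroscopy the recorded digital counts must
be mapped back to a scale proportional to incident power, per RGB channel.
This module represents an empirically measured gamma curve as a monotone
interpolant through (relative power, digital count) knots, fits such curves
from characterization measurements, and inverts them to linearize whole raw
video stacks.  Counts at the sensor's saturation ceiling carry no radiometric
information; they are clipped to full scale and flagged in a mask so that
downstream calibration can exclude them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "GammaCurve",
    "fit_gamma",
    "fit_gamma_table",
    "gamma_from_power_law",
    "linearize_stack",
    "read_gamma_csv",
    "write_gamma_csv",
]

CHANNELS = ("R", "G", "B")

# dense sampling used for numeric inversion of the forward curve
_INVERSE_GRID = 4096


@dataclass
class GammaCurve:
    """Monotone map between normalized linear power in [0, 1] and digital counts.

    Parameters
    ----------
    channel : str
        One of ``"R"``, ``"G"``, ``"B"``.
    power_knots, count_knots : ndarray
        Ordered knot pairs.  Powers are strictly increasing starting at 0;
        counts are non-decreasing with the first knot at (0, 0).
    """

    channel: str
    power_knots: np.ndarray
    count_knots: np.ndarray
    _forward: PchipInterpolator = field(init=False, repr=False)
    _inv_counts: np.ndarray = field(init=False, repr=False)
    _inv_powers: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.power_knots, dtype=float)
        c = np.asarray(self.count_knots, dtype=float)
        if p.ndim != 1 or p.shape != c.shape or p.size < 2:
            raise ValueError("gamma curve needs >= 2 matching knot pairs")
        if np.any(np.diff(p) <= 0):
            raise ValueError("power knots must be strictly increasing")
        if p[0] != 0.0 or c[0] != 0.0:
            raise ValueError("gamma curve must start at the (0, 0) knot")
        if np.any(np.diff(c) < 0):
            raise ValueError("count knots must be non-decreasing")
        self.power_knots = p
        self.count_knots = c
        self._forward = PchipInterpolator(p, c, extrapolate=False)
        # numeric inverse: dense forward samples, compressed to the first
        # occurrence of each count so plateaus (saturation) invert to the
        # lowest power reaching that count
        dense_p = np.linspace(0.0, p[-1], _INVERSE_GRID)
        dense_c = self._forward(dense_p)
        uniq_c, first = np.unique(dense_c, return_index=True)
        self._inv_counts = uniq_c
        self._inv_powers = dense_p[first]

    @property
    def max_count(self) -> float:
        """Largest count the curve reaches (saturation ceiling)."""
        return float(self.count_knots[-1])

    def forward(self, power: np.ndarray | float) -> np.ndarray:
        """Map linear power in [0, 1] to (real-valued) digital counts."""
        p = np.clip(np.asarray(power, dtype=float), 0.0, self.power_knots[-1])
        return self._forward(p)

    def inverse(self, count: np.ndarray | float) -> np.ndarray:
        """Map digital counts back to normalized linear power."""
        c = np.asarray(count, dtype=float)
        out = np.interp(c, self._inv_counts, self._inv_powers)
        return np.where(c >= self.max_count, 1.0, out)

    def lut(self, bit_depth: int = 8) -> np.ndarray:
        """Inverse lookup table over all integer counts of ``bit_depth``."""
        return self.inverse(np.arange(2**bit_depth, dtype=float))


def gamma_from_power_law(
    exponent: float = 0.45,
    channel: str = "R",
    full_scale: float = 255.0,
    n_knots: int = 33,
) -> GammaCurve:
    """Parametric encoding curve ``count = full_scale * power ** exponent``.

    ``exponent=1`` gives a perfectly linear (identity) sensor.  The sRGB-like
    default 0.45 mimics a consumer camera's tone curve.
    """
    p = np.linspace(0.0, 1.0, n_knots)
    return GammaCurve(channel, p, full_scale * p**exponent)


def fit_gamma(
    powers: np.ndarray,
    counts: np.ndarray,
    channel: str = "R",
    monotone_tol: float = 1.0,
) -> GammaCurve:
    """Fit a monotone gamma curve through measured (power, count) pairs.

    The pairs are sorted by power, projected onto the nearest non-decreasing
    sequence (isotonic regression) and interpolated with a monotone piecewise
    cubic.  A ``(0, 0)`` knot is prepended if the measurements do not include
    it, since zero incident power must read zero counts.

    Parameters
    ----------
    powers, counts : array-like
        At least three measurement pairs, powers in [0, 1].
    monotone_tol : float
        Count deviation beyond which the isotonic projection triggers a
        warning (measurement noise ordinarily stays below one count).
    """
    p = np.asarray(powers, dtype=float)
    c = np.asarray(counts, dtype=float)
    if p.size < 3:
        raise ValueError("gamma fit needs at least 3 measurement pairs")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("powers must lie in [0, 1]")
    order = np.argsort(p)
    p, c = p[order], c[order]
    # average duplicate power levels (repeat measurements)
    uniq_p, inv = np.unique(p, return_inverse=True)
    sum_c = np.bincount(inv, weights=c)
    mean_c = sum_c / np.bincount(inv)
    iso = IsotonicRegression(increasing=True)
    c_fit = iso.fit_transform(uniq_p, mean_c)
    if np.max(np.abs(c_fit - mean_c)) > monotone_tol:
        warnings.warn(
            f"channel {channel}: measurements are non-monotone beyond "
            f"{monotone_tol} counts; using isotonic projection",
            stacklevel=2,
        )
    if uniq_p[0] != 0.0:
        uniq_p = np.concatenate([[0.0], uniq_p])
        c_fit = np.concatenate([[0.0], c_fit])
    else:
        c_fit[0] = 0.0
    return GammaCurve(channel, uniq_p, c_fit)


def fit_gamma_table(table: pd.DataFrame) -> dict[str, GammaCurve]:
    """Fit one curve per channel from a long-format measurement table.

    Expects columns ``channel``, ``power``, ``count``.
    """
    required = {"channel", "power", "count"}
    if not required.issubset(table.columns):
        raise ValueError(f"gamma table must have columns {sorted(required)}")
    curves = {}
    for ch, grp in table.groupby("channel"):
        curves[str(ch)] = fit_gamma(
            grp["power"].to_numpy(), grp["count"].to_numpy(), channel=str(ch)
        )
    return curves


def linearize_stack(
    counts: np.ndarray,
    curves: dict[str, GammaCurve],
    bit_depth: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the per-channel gamma on a raw count stack.

    Parameters
    ----------
    counts : ndarray
        Integer stack whose last axis is the RGB channel (order R, G, B).
    curves : dict
        Gamma curve per channel letter; all three must be present.

    Returns
    -------
    linear : float32 ndarray
        Normalized linear intensity in [0, 1], same shape as ``counts``.
    saturated : bool ndarray
        True where the count sits at the curve's saturation ceiling; those
        entries are clipped to 1.0 and should be excluded from calibration.
    """
    missing = [ch for ch in CHANNELS if ch not in curves]
    if missing:
        raise ValueError(f"missing gamma curve(s) for channel(s) {missing}")
    if counts.shape[-1] != len(CHANNELS):
        raise ValueError("last axis of the stack must be the 3 RGB channels")
    linear = np.empty(counts.shape, dtype=np.float32)
    saturated = np.empty(counts.shape, dtype=bool)
    for i, ch in enumerate(CHANNELS):
        curve = curves[ch]
        lut = curve.lut(bit_depth).astype(np.float32)
        band = counts[..., i].astype(np.intp)
        linear[..., i] = lut[band]
        saturated[..., i] = band >= curve.max_count
        linear[..., i][saturated[..., i]] = 1.0
    return linear, saturated


def write_gamma_csv(path, measurements: pd.DataFrame) -> None:
    """Write a (channel, power, count) measurement table to CSV."""
    measurements[["channel", "power", "count"]].to_csv(path, index=False)


def read_gamma_csv(path) -> pd.DataFrame:
    """Read a (channel, power, count) measurement table from CSV."""
    df = pd.read_csv(path)
    required = {"channel", "power", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"gamma CSV must have columns {sorted(required)}")
    return df
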