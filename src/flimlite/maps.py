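"""Parameter maps, histograms with multi-Gaussian peak fits, scatter
tables and calibrated-quantity maps (e.g. membrane potential via V(tau)).

A :class:`ParameterMap` keeps an explicit "set" mask rather than a magic
value: CSV export writes empty fields for unset pixels, and every
operation counts only set values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import argrelmax

from .errors import ValidationError
from .roi import ROISet

__all__ = [
    "ParameterMap",
    "PeakFit",
    "map_from_rois",
    "histogram_map",
    "fit_peaks",
    "scatter_table",
    "map_through_curve",
    "colorize",
]


@dataclass
class ParameterMap:
    """A per-pixel scalar quantity with explicit unset state."""

    values: np.ndarray
    set_mask: np.ndarray
    name: str = "value"
    units: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.set_mask = np.asarray(self.set_mask, dtype=bool)
        if self.values.shape != self.set_mask.shape or self.values.ndim != 2:
            raise ValidationError("map values/mask must be matching 2-D arrays")
        if np.any(~np.isfinite(self.values[self.set_mask])):
            raise ValidationError("set map values must be finite")

    @classmethod
    def from_values(cls, values: np.ndarray, **kw) -> "ParameterMap":
        """Build from an array where NaN marks unset pixels."""
        values = np.asarray(values, dtype=float)
        return cls(values=values, set_mask=np.isfinite(values), **kw)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def set_values(self) -> np.ndarray:
        return self.values[self.set_mask]

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a DataFrame with empty cells for unset pixels."""
        out = self.values.astype(object)
        out[~self.set_mask] = ""
        return pd.DataFrame(out)


@dataclass
class PeakFit:
    """Sum-of-Gaussians fit of a histogram, peaks sorted by mean."""

    means: np.ndarray
    sigmas: np.ndarray
    areas: np.ndarray
    n_peaks: int
    chi2_reduced: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if not (len(self.means) == len(self.sigmas) == len(self.areas) == self.n_peaks):
            raise ValidationError("peak parameter lengths disagree")
        if np.any(self.sigmas <= 0) or np.any(self.areas <= 0):
            raise ValidationError("peak widths and areas must be positive")
        if np.any(np.diff(self.means) < 0):
            raise ValidationError("peak means must be sorted ascending")

    def model(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.zeros_like(x)
        for mu, sig, area in zip(self.means, self.sigmas, self.areas):
            y += area / (sig * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - mu) / sig) ** 2)
        return y


def map_from_rois(
    rs: ROISet, values: dict[int, float], shape: tuple[int, int] | None = None, **kw
) -> ParameterMap:
    """Paint one value per ROI into a map; background stays unset.

    Overlapping ROIs: the last-listed ROI wins and the overlap is flagged
    in the returned map's ``provenance``.
    """
    shape = shape or rs.shape
    out = np.full(shape, np.nan)
    painted = np.zeros(shape, dtype=bool)
    overlap = False
    for r in rs.rois:
        if r.id not in values:
            raise KeyError(f"no value for ROI {r.id}")
        ri, ci = r.indices()
        if np.any(painted[ri, ci]):
            overlap = True
        out[ri, ci] = values[r.id]
        painted[ri, ci] = True
    prov = kw.pop("provenance", "map_from_rois")
    if overlap:
        prov += " (overlapping ROIs: last-listed wins)"
    return ParameterMap.from_values(out, provenance=prov, **kw)


def histogram_map(
    m: ParameterMap, bins: "int | np.ndarray" = 32
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the set values; returns (edges, counts)."""
    vals = m.set_values()
    if vals.size == 0:
        raise ValidationError("cannot histogram a map with no set values")
    counts, edges = np.histogram(vals, bins=bins)
    return edges, counts


def _peak_init(centers: np.ndarray, counts: np.ndarray, n_peaks: int) -> np.ndarray:
    """Deterministic init from the n tallest local maxima (falling back to
    the tallest bins when the histogram has fewer strict local maxima)."""
    (locs,) = argrelmax(counts, mode="clip")
    if locs.size < n_peaks:
        order = np.argsort(counts)[::-1]
        locs = np.unique(np.concatenate([locs, order[: n_peaks]]))
    locs = locs[np.argsort(counts[locs])[::-1]][:n_peaks]
    locs = np.sort(locs)
    width = max(float(np.mean(np.diff(centers))), 1e-12)
    total = counts.sum()
    # moment-based width: robust for sparse histograms where a per-bin
    # guess would collapse onto a single tall bin
    mean_all = float(np.dot(counts, centers) / total)
    sd_all = float(np.sqrt(np.dot(counts, (centers - mean_all) ** 2) / total))
    sigma = max(sd_all / n_peaks, width)
    x0 = []
    for loc in locs:
        area = max(total / n_peaks, 1.0) * width
        mu = mean_all if n_peaks == 1 else centers[loc]
        x0.extend([mu, sigma, area])
    return np.asarray(x0)


def fit_peaks(
    hist: tuple[np.ndarray, np.ndarray],
    n_peaks: int = 1,
    init: np.ndarray | None = None,
) -> PeakFit:
    """Least-squares fit of a sum of Gaussians to a histogram.

    ``hist`` is (edges, counts) as returned by :func:`histogram_map`. Each
    peak is parameterized by (mean, sigma, area). Needs more than
    ``3 * n_peaks`` non-empty bins to be identifiable.
    """
    edges, counts = np.asarray(hist[0], float), np.asarray(hist[1], float)
    if n_peaks < 1:
        raise ValidationError("n_peaks must be >= 1")
    if edges.size != counts.size + 1:
        raise ValidationError("histogram edges/counts lengths inconsistent")
    if int((counts > 0).sum()) <= 3 * n_peaks:
        raise ValidationError(
            f"need more than {3 * n_peaks} non-empty bins to fit {n_peaks} peak(s)"
        )
    centers = 0.5 * (edges[:-1] + edges[1:])
    x0 = np.asarray(init, float) if init is not None else _peak_init(centers, counts, n_peaks)
    if x0.size != 3 * n_peaks:
        raise ValidationError("init must provide (mean, sigma, area) per peak")

    # means confined to the data range and widths to half the span: a
    # Gaussian centered beyond the histogram (a "half-Gaussian" ramp) is
    # never an acceptable summary of a parameter distribution
    span = float(edges[-1] - edges[0])
    binw = float(np.mean(np.diff(edges)))
    lo = np.tile([edges[0], binw / 2, 1e-300], n_peaks)
    hi = np.tile([edges[-1], span / 2, np.inf], n_peaks)

    def model(x: np.ndarray) -> np.ndarray:
        y = np.zeros_like(centers)
        for i in range(n_peaks):
            mu, sig, area = x[3 * i : 3 * i + 3]
            y += area / (sig * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((centers - mu) / sig) ** 2)
        return y

    res = least_squares(
        lambda x: model(x) - counts,
        np.clip(x0, lo, hi),
        bounds=(lo, hi),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-12,
    )
    p = res.x.reshape(n_peaks, 3)
    order = np.argsort(p[:, 0])
    p = p[order]
    dof = max(centers.size - 3 * n_peaks, 1)
    chi2 = float(np.sum((model(res.x) - counts) ** 2 / np.maximum(counts, 1.0))) / dof
    return PeakFit(
        means=p[:, 0],
        sigmas=p[:, 1],
        areas=p[:, 2],
        n_peaks=n_peaks,
        chi2_reduced=chi2,
        converged=bool(res.status > 0),
    )


def scatter_table(x: ParameterMap, y: ParameterMap) -> pd.DataFrame:
    """Rows (row, col, x, y) at pixels where both maps are set."""
    if x.shape != y.shape:
        raise ValidationError("scatter maps must share a shape")
    both = x.set_mask & y.set_mask
    rr, cc = np.nonzero(both)
    xn = x.name if x.name != y.name else f"{x.name}_x"
    yn = y.name if x.name != y.name else f"{y.name}_y"
    return pd.DataFrame(
        {"row": rr, "col": cc, xn: x.values[rr, cc], yn: y.values[rr, cc]}
    )


def map_through_curve(
    m: ParameterMap,
    curve: np.ndarray,
    monotone: bool = False,
    name: str = "converted",
    units: str = "",
) -> ParameterMap:
    """Convert map values through a calibration curve of (x, y) pairs.

    Piecewise-linear interpolation; values outside the curve's x-range are
    left unset (the count is recorded in ``provenance``). ``monotone=True``
    additionally asserts that y is monotone, as expected of a physical
    calibration curve such as V(tau).
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2 or curve.shape[0] < 2:
        raise ValidationError("curve must be an (n >= 2, 2) array of (x, y)")
    x, y = curve[:, 0], curve[:, 1]
    dx = np.diff(x)
    if np.all(dx < 0):
        x, y = x[::-1], y[::-1]
    elif not np.all(dx > 0):
        raise ValidationError("curve x values must be strictly monotone")
    if monotone:
        dy = np.diff(y)
        if not (np.all(dy >= 0) or np.all(dy <= 0)):
            raise ValidationError("curve y values are not monotone")
    out = np.full(m.shape, np.nan)
    sm = m.set_mask
    vals = m.values[sm]
    in_range = (vals >= x[0]) & (vals <= x[-1])
    interp = np.full(vals.shape, np.nan)
    interp[in_range] = np.interp(vals[in_range], x, y)
    out[sm] = interp
    n_out = int((~in_range).sum())
    return ParameterMap.from_values(
        out,
        name=name,
        units=units,
        provenance=f"map_through_curve({m.name}); {n_out} value(s) out of range",
    )


def colorize(
    m: ParameterMap, vmin: float, vmax: float, cmap: str = "viridis"
) -> np.ndarray:
    """Render a map to an RGB array with a linear ramp between vmin/vmax.

    Unset pixels come out black. This is the whole extent of "display"
    support: the package exports data, not figures.
    """
    import matplotlib

    if vmax <= vmin:
        raise ValidationError("vmax must exceed vmin")
    norm = np.clip((m.values - vmin) / (vmax - vmin), 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](norm)
    rgba[~m.set_mask] = 0.0
    return rgba[..., :3]
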