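"""Dataset conditioning: binning, background subtraction, pile-up, validity.

All operations return new :class:`~flimlite.core.FLIDataset` objects and
record what was done in ``meta`` so processing provenance survives a save.
"""

from __future__ import annotations

import numpy as np

from .core import FLIDataset, TimeAxis, ValidityMask
from .errors import SaturationError, ValidationError

__all__ = [
    "bin_spatial",
    "bin_temporal",
    "subtract_background",
    "correct_pileup",
    "validity_mask",
]


def bin_spatial(ds: FLIDataset, k: int) -> FLIDataset:
    """Sum non-overlapping k x k pixel blocks.

    Output dimensions are ``floor(dim / k)``; trailing partial rows/columns
    are dropped so every output pixel aggregates exactly k*k inputs.
    Total counts over the retained region are conserved exactly.
    """
    if k < 1:
        raise ValidationError("spatial binning factor must be >= 1")
    if k == 1:
        return FLIDataset(ds.counts.copy(), ds.time_axis, dict(ds.meta))
    t, r, c = ds.counts.shape
    rr, cc = r // k, c // k
    if rr < 1 or cc < 1:
        raise ValidationError(f"binning factor {k} exceeds image size {r}x{c}")
    trimmed = ds.counts[:, : rr * k, : cc * k]
    binned = trimmed.reshape(t, rr, k, cc, k).sum(axis=(2, 4))
    meta = dict(ds.meta)
    meta["bin_spatial"] = k
    return FLIDataset(binned, ds.time_axis, meta)


def bin_temporal(ds: FLIDataset, k: int) -> FLIDataset:
    """Sum groups of k consecutive time bins.

    New bin centers are the unweighted mean of the merged centers. If k does
    not divide the bin count the trailing bins are dropped and the drop is
    recorded in ``meta["bin_temporal_dropped"]``.
    """
    if k < 1:
        raise ValidationError("temporal binning factor must be >= 1")
    if k == 1:
        return FLIDataset(ds.counts.copy(), ds.time_axis, dict(ds.meta))
    t = ds.n_bins
    n_new = t // k
    if n_new < 1:
        raise ValidationError(f"binning factor {k} exceeds {t} time bins")
    dropped = t - n_new * k
    counts = ds.counts[: n_new * k]
    binned = counts.reshape(n_new, k, *ds.frame_shape).sum(axis=1)
    centers = ds.time_axis.bin_centers_ns[: n_new * k].reshape(n_new, k).mean(axis=1)
    axis = TimeAxis(n_bins=n_new, period_ns=ds.time_axis.period_ns, bin_centers_ns=centers)
    meta = dict(ds.meta)
    meta["bin_temporal"] = k
    if dropped:
        meta["bin_temporal_dropped"] = dropped
    return FLIDataset(binned, axis, meta)


def subtract_background(
    ds: FLIDataset,
    constant: float | None = None,
    from_bins: np.ndarray | list[int] | None = None,
) -> tuple[FLIDataset, np.ndarray]:
    """Subtract a per-bin background level from every pixel, clamping at 0.

    Exactly one of ``constant`` (a single level applied everywhere) or
    ``from_bins`` (time-bin indices of a pre-pulse window whose per-pixel
    mean estimates the background) must be given.

    Returns the corrected dataset and the per-pixel background estimate
    (a ``(row, col)`` array; constant mode broadcasts the scalar).
    """
    if (constant is None) == (from_bins is None):
        raise ValidationError("give exactly one of constant / from_bins")
    if constant is not None:
        if constant < 0:
            raise ValidationError("background constant must be >= 0")
        bg = np.full(ds.frame_shape, float(constant))
    else:
        idx = np.asarray(from_bins, dtype=int)
        if idx.size == 0:
            raise ValidationError("background window must not be empty")
        if idx.min() < 0 or idx.max() >= ds.n_bins:
            raise ValidationError("background window indices out of range")
        bg = ds.counts[idx].mean(axis=0).astype(float)
    corrected = np.clip(ds.counts.astype(float) - bg[None, :, :], 0.0, None)
    if constant is not None and float(constant).is_integer() and np.issubdtype(
        ds.counts.dtype, np.integer
    ):
        corrected = corrected.astype(ds.counts.dtype)
    meta = dict(ds.meta)
    meta["background_mode"] = "constant" if constant is not None else "from_bins"
    return FLIDataset(corrected, ds.time_axis, meta), bg


def correct_pileup(ds: FLIDataset, n_frames: int) -> FLIDataset:
    """Invert single-photon-per-frame saturation over ``n_frames`` exposures.

    With N frames and at most one count per frame per bin, an expected m
    photons per bin yields n = N (1 - e^(-m/N)) detected on average; the
    correction inverts this: ``m = -N ln(1 - n/N)``. Monotone, >= the raw
    counts, and ~identity when ``n/N`` is small.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    if np.any(ds.counts >= n_frames):
        where = np.argwhere(ds.counts >= n_frames)[0]
        raise SaturationError(
            f"counts at bin={where[0]}, pixel=({where[1]}, {where[2]}) "
            f"reach the frame count {n_frames}; correction undefined"
        )
    corrected = -float(n_frames) * np.log1p(-ds.counts / float(n_frames))
    meta = dict(ds.meta)
    meta["pileup_n_frames"] = int(n_frames)
    return FLIDataset(corrected, ds.time_axis, meta)


def validity_mask(ds: FLIDataset, min_counts: float) -> ValidityMask:
    """Flag pixels whose total counts reach ``min_counts``."""
    if min_counts < 0:
        raise ValidationError("min_counts must be >= 0")
    totals = ds.intensity_image()
    return ValidityMask(valid=totals >= min_counts, min_counts=float(min_counts))
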