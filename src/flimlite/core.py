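"""Core containers for time-resolved image data.

A fluorescence-lifetime dataset is a 3-D cube of photon counts indexed
``(time_bin, row, col)`` together with a :class:`TimeAxis` describing the
laser period and the temporal sampling grid. Decays extracted from pixels or
regions are :class:`DecayCurve` objects; integer label images and boolean
pixel-validity images get their own thin wrappers so shape contracts are
checked in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ValidationError

__all__ = [
    "TimeAxis",
    "FLIDataset",
    "DecayCurve",
    "LabelMask",
    "ValidityMask",
]


@dataclass(frozen=True)
class TimeAxis:
    """Temporal sampling grid of a pulsed-excitation measurement.

    Parameters
    ----------
    n_bins
        Number of time bins per laser period.
    period_ns
        Laser period ``T`` in nanoseconds; the repetition frequency is
        ``f = 1000 / T`` MHz.
    bin_centers_ns
        Strictly increasing bin-center times, all in ``[0, T)``. Stored as
        centers so no half-bin ambiguity leaks into phasor or fit math.
    """

    n_bins: int
    period_ns: float
    bin_centers_ns: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers_ns, dtype=float)
        object.__setattr__(self, "bin_centers_ns", centers)
        if self.n_bins < 1:
            raise ValidationError("TimeAxis needs at least one bin")
        if self.period_ns <= 0:
            raise ValidationError("laser period must be positive")
        if centers.shape != (self.n_bins,):
            raise ValidationError(
                f"expected {self.n_bins} bin centers, got shape {centers.shape}"
            )
        if self.n_bins > 1 and not np.all(np.diff(centers) > 0):
            raise ValidationError("bin centers must be strictly increasing")
        if centers[0] < 0 or centers[-1] >= self.period_ns:
            raise ValidationError("bin centers must lie in [0, period)")

    @classmethod
    def regular(cls, n_bins: int, period_ns: float) -> "TimeAxis":
        """Midpoint grid: bin k centered at ``(k + 1/2) T / n_bins``."""
        dt = period_ns / n_bins
        centers = (np.arange(n_bins) + 0.5) * dt
        return cls(n_bins=n_bins, period_ns=period_ns, bin_centers_ns=centers)

    @property
    def frequency_MHz(self) -> float:
        """Fundamental (laser repetition) frequency in MHz."""
        return 1000.0 / self.period_ns

    @property
    def bin_width_ns(self) -> float:
        """Nominal bin width ``T / n_bins``."""
        return self.period_ns / self.n_bins

    def is_regular(self, rtol: float = 1e-9) -> bool:
        if self.n_bins == 1:
            return True
        d = np.diff(self.bin_centers_ns)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=0.0))

    def omega(self, harmonic: int = 1) -> float:
        """Angular frequency ``2 pi n / T`` in rad/ns at the given harmonic."""
        if harmonic < 1:
            raise ValidationError("harmonic must be >= 1")
        return 2.0 * np.pi * harmonic / self.period_ns


@dataclass
class FLIDataset:
    """Photon-count cube ``counts[time_bin, row, col]`` plus its time axis.

    Counts are non-negative; integer for raw data, real-valued after
    corrections such as background subtraction or pile-up inversion.
    ``meta`` carries free-form provenance (source file, processing steps).
    """

    counts: np.ndarray
    time_axis: TimeAxis
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValidationError("counts must be a (time, row, col) cube")
        if self.counts.shape[0] != self.time_axis.n_bins:
            raise ValidationError(
                f"{self.counts.shape[0]} frames but time axis has "
                f"{self.time_axis.n_bins} bins"
            )
        if self.counts.shape[1] < 1 or self.counts.shape[2] < 1:
            raise ValidationError("image dimensions must be >= 1")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.counts.shape[1], self.counts.shape[2]

    def intensity_image(self) -> np.ndarray:
        """Per-pixel total counts, summed over all time bins."""
        return self.counts.sum(axis=0)

    def pixel_decay(self, row: int, col: int) -> "DecayCurve":
        return DecayCurve(
            time_ns=self.time_axis.bin_centers_ns.copy(),
            counts=self.counts[:, row, col].astype(float),
        )


@dataclass
class DecayCurve:
    """A single decay: counts per time bin at the stated bin centers."""

    time_ns: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.time_ns.ndim != 1 or self.counts.ndim != 1:
            raise ValidationError("decay time and counts must be 1-D")
        if self.time_ns.shape != self.counts.shape:
            raise ValidationError("decay time and counts lengths differ")
        if np.any(self.counts < 0):
            raise ValidationError("decay counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __len__(self) -> int:
        return self.time_ns.size


@dataclass
class LabelMask:
    """Integer label image; 0 is background, each positive label one region."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValidationError("label mask must be 2-D")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(np.equal(np.mod(labels, 1), 0)):
                raise ValidationError("label mask values must be integral")
            labels = labels.astype(np.int64)
        if np.any(labels < 0):
            raise ValidationError("label mask values must be >= 0")
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_values(self) -> np.ndarray:
        """Distinct non-zero labels, ascending."""
        vals = np.unique(self.labels)
        return vals[vals > 0]


@dataclass
class ValidityMask:
    """Boolean per-pixel validity flags and the threshold that produced them."""

    valid: np.ndarray
    min_counts: float = 0.0

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.ndim != 2:
            raise ValidationError("validity mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.valid.shape  # type: ignore[return-value]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def __and__(self, other: "ValidityMask") -> "ValidityMask":
        if self.shape != other.shape:
            raise ValidationError("validity mask shapes differ")
        return ValidityMask(self.valid & other.valid, self.min_counts)

    def __or__(self, other: "ValidityMask") -> "ValidityMask":
        if self.shape != other.shape:
            raise ValidationError("validity mask shapes differ")
        return ValidityMask(self.valid | other.valid, self.min_counts)
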