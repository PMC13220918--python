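"""Phasor analysis: transforms, calibration, universal-circle geometry.

The phasor of a decay is its normalized first (or n-th harmonic) Fourier
coefficient at the laser repetition frequency,

    g = sum_k c_k cos(w t_k) / sum_k c_k,   s = sum_k c_k sin(w t_k) / sum_k c_k,

with w = 2 pi n / T evaluated at the bin centers t_k. Single-exponential
decays of lifetime tau map onto the *universal circle* (UC), the circle of
center (1/2, 0) and radius 1/2:

    g = 1 / (1 + (w tau)^2),   s = w tau / (1 + (w tau)^2).

Mixtures fall inside the UC on the chord joining their components' UC
points, which is what makes two-component linear decomposition possible.

Instrument effects are removed by *calibration*: complex division of the
raw phasor by the phasor of a reference decay of known lifetime tau_ref
(an IRF acts as a tau_ref = 0 reference), followed by multiplication by
the UC phasor of tau_ref. Per-pixel calibration does the same division
pixel-wise, as needed for SPAD-camera data whose IRF varies across the
array.

The reference-finding algorithm takes a cloud of calibrated phasors,
computes its principal axis of inertia (major or minor), and intersects
that axis with the UC; the two intersections are single-exponential
*references* whose lifetimes bracket the cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from .core import DecayCurve, FLIDataset, TimeAxis, ValidityMask
from .errors import (
    DegenerateAxisError,
    DegenerateCalibrationError,
    EmptyDecayError,
    NoIntersectionError,
    NotOnCircleError,
    TangencyError,
    ValidationError,
)

__all__ = [
    "Phasor",
    "PhasorImage",
    "PhasorCalibration",
    "ReferencePair",
    "PhasorROI",
    "Decomposition",
    "decay_phasor",
    "phasor_image",
    "calibrate",
    "uc_phasor",
    "uc_lifetime",
    "phase_mod_lifetimes",
    "principal_axis_uc_references",
    "decompose",
    "amplitude_avg_lifetime",
    "phasor_select",
]

_UC_CENTER = np.array([0.5, 0.0])
_UC_RADIUS = 0.5


@dataclass(frozen=True)
class Phasor:
    """One point (g, s) in phasor space at a given harmonic/frequency."""

    g: float
    s: float
    harmonic: int = 1
    frequency_MHz: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g) and np.isfinite(self.s)):
            raise ValidationError("phasor coordinates must be finite")
        if self.harmonic < 1:
            raise ValidationError("harmonic must be >= 1")

    @property
    def z(self) -> complex:
        return complex(self.g, self.s)

    @property
    def modulus(self) -> float:
        return float(np.hypot(self.g, self.s))

    @property
    def phase(self) -> float:
        return float(np.arctan2(self.s, self.g))

    def omega(self) -> float:
        """Angular frequency in rad/ns, if the frequency is known."""
        if self.frequency_MHz is None:
            raise ValidationError("phasor carries no frequency")
        return 2.0 * np.pi * self.harmonic * self.frequency_MHz / 1000.0


@dataclass
class PhasorImage:
    """Per-pixel phasor coordinates with validity flags."""

    g: np.ndarray
    s: np.ndarray
    valid: ValidityMask
    harmonic: int = 1
    frequency_MHz: float | None = None

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.g.shape != self.s.shape or self.g.shape != self.valid.shape:
            raise ValidationError("phasor image g/s/valid shapes differ")
        bad = self.valid.valid & ~(np.isfinite(self.g) & np.isfinite(self.s))
        if np.any(bad):
            raise ValidationError("non-finite phasor at a valid pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.g.shape  # type: ignore[return-value]

    def valid_points(self) -> np.ndarray:
        """(n, 2) array of (g, s) at valid pixels, raster order."""
        m = self.valid.valid
        return np.column_stack([self.g[m], self.s[m]])


@dataclass
class PhasorCalibration:
    """Calibration reference: a phasor (or per-pixel phasor image) of a
    decay with known lifetime ``reference_lifetime_ns`` (0 for an IRF)."""

    mode: str  # "single" | "per_pixel"
    phasor: "Phasor | PhasorImage"
    reference_lifetime_ns: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("single", "per_pixel"):
            raise ValidationError("calibration mode must be single or per_pixel")
        if self.mode == "single" and not isinstance(self.phasor, Phasor):
            raise ValidationError("single mode needs a Phasor payload")
        if self.mode == "per_pixel" and not isinstance(self.phasor, PhasorImage):
            raise ValidationError("per_pixel mode needs a PhasorImage payload")
        if self.reference_lifetime_ns < 0:
            raise ValidationError("reference lifetime must be >= 0")


@dataclass
class ReferencePair:
    """Two single-exponential reference phasors on the UC, tau1 <= tau2."""

    p1: Phasor
    p2: Phasor
    tau1_ns: float
    tau2_ns: float
    message: str = ""

    def __post_init__(self) -> None:
        for p in (self.p1, self.p2):
            d = abs(np.hypot(p.g - 0.5, p.s) - 0.5)
            if d > 1e-6:
                raise ValidationError(f"reference phasor ({p.g}, {p.s}) off the UC by {d:g}")
        if self.tau1_ns > self.tau2_ns:
            raise ValidationError("references must satisfy tau1 <= tau2")


@dataclass
class PhasorROI:
    """A selection region in (g, s) space: polygon or disc."""

    vertices: np.ndarray | None = None
    center: tuple[float, float] | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.vertices is not None:
            self.vertices = np.asarray(self.vertices, dtype=float)
            if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
                raise ValidationError("polygon needs >= 3 (g, s) vertices")
            # degenerate (zero-area) polygons select nothing by construction
            v = self.vertices
            area2 = np.abs(
                np.dot(v[:, 0], np.roll(v[:, 1], -1)) - np.dot(v[:, 1], np.roll(v[:, 0], -1))
            )
            if area2 == 0.0:
                raise ValidationError("polygon has zero area")
        elif self.center is not None and self.radius is not None:
            if self.radius <= 0:
                raise ValidationError("disc radius must be > 0")
        else:
            raise ValidationError("give polygon vertices or center+radius")

    def contains(self, g: np.ndarray, s: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        s = np.asarray(s, dtype=float)
        pts = np.column_stack([g.ravel(), s.ravel()])
        if self.vertices is not None:
            inside = MplPath(self.vertices).contains_points(pts)
        else:
            cg, cs = self.center  # type: ignore[misc]
            inside = (pts[:, 0] - cg) ** 2 + (pts[:, 1] - cs) ** 2 <= self.radius**2
        return inside.reshape(g.shape)

    def describe(self) -> str:
        if self.vertices is not None:
            return f"polygon[{len(self.vertices)} vertices]"
        return f"disc[center=({self.center[0]:.4g}, {self.center[1]:.4g}), r={self.radius:.4g}]"


@dataclass
class Decomposition:
    """Two-component linear decomposition of a phasor onto a reference pair.

    ``f1``/``f2`` are *intensity* fractions (they weight emitted photons);
    ``residual`` is the perpendicular distance from the phasor to the
    reference chord, ``clamped`` flags projections outside [0, 1], and
    ``valid`` is cleared when the residual exceeds a confinement band.
    """

    f1: float
    f2: float
    residual: float
    clamped: bool = False
    valid: bool = True

    def __post_init__(self) -> None:
        if abs(self.f1 + self.f2 - 1.0) > 1e-12:
            raise ValidationError("fractions must sum to 1")
        if not (0.0 <= self.f1 <= 1.0):
            raise ValidationError("f1 must lie in [0, 1] after clamping")
        if self.residual < 0:
            raise ValidationError("residual must be >= 0")


def decay_phasor(d: DecayCurve, axis: TimeAxis, harmonic: int = 1) -> Phasor:
    """Raw (uncalibrated) phasor of a decay at the given harmonic."""
    total = d.counts.sum()
    if total <= 0:
        raise EmptyDecayError("cannot compute the phasor of an empty decay")
    w = axis.omega(harmonic)
    g = float(np.dot(d.counts, np.cos(w * d.time_ns)) / total)
    s = float(np.dot(d.counts, np.sin(w * d.time_ns)) / total)
    return Phasor(g=g, s=s, harmonic=harmonic, frequency_MHz=axis.frequency_MHz)


def phasor_image(
    ds: FLIDataset, harmonic: int = 1, mask: ValidityMask | None = None
) -> PhasorImage:
    """Per-pixel phasor transform of a dataset.

    Pixels outside ``mask`` (or with zero total counts) are flagged invalid
    and their coordinates left unset (NaN).
    """
    w = ds.time_axis.omega(harmonic)
    t = ds.time_axis.bin_centers_ns
    totals = ds.intensity_image().astype(float)
    valid = totals > 0
    if mask is not None:
        if mask.shape != ds.frame_shape:
            raise ValidationError("validity mask shape does not match dataset")
        valid &= mask.valid
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.tensordot(np.cos(w * t), ds.counts, axes=(0, 0)) / totals
        s = np.tensordot(np.sin(w * t), ds.counts, axes=(0, 0)) / totals
    g[~valid] = np.nan
    s[~valid] = np.nan
    return PhasorImage(
        g=g,
        s=s,
        valid=ValidityMask(valid, mask.min_counts if mask else 0.0),
        harmonic=harmonic,
        frequency_MHz=ds.time_axis.frequency_MHz,
    )


def _calibrate_z(raw: np.ndarray, cal: np.ndarray, target: complex) -> np.ndarray:
    mod = np.abs(cal)
    if np.any(mod < 1e-12):
        raise DegenerateCalibrationError("calibration phasor has zero modulus")
    return raw / cal * target


def calibrate(
    p: "Phasor | PhasorImage", cal: PhasorCalibration, omega: float | None = None
) -> "Phasor | PhasorImage":
    """Remove the instrument response from a raw phasor (or phasor image).

    calibrated = raw / cal * uc(tau_ref): complex division by the measured
    reference phasor (divides moduli, subtracts phases) followed by
    re-multiplication by the ideal UC phasor of the reference's lifetime.
    For an IRF reference (tau_ref = 0) the UC factor is 1.
    """
    if omega is None:
        omega = p.omega() if isinstance(p, Phasor) else _image_omega(p)
    target = uc_phasor(cal.reference_lifetime_ns, omega).z
    if isinstance(p, Phasor):
        if cal.mode != "single":
            raise ValidationError("per-pixel calibration needs a PhasorImage input")
        z = _calibrate_z(np.asarray(p.z), np.asarray(cal.phasor.z), target)
        return Phasor(float(z.real), float(z.imag), p.harmonic, p.frequency_MHz)
    raw = p.g + 1j * p.s
    if cal.mode == "single":
        calz = np.asarray(cal.phasor.z)
    else:
        img: PhasorImage = cal.phasor  # type: ignore[assignment]
        if img.shape != p.shape:
            raise ValidationError("per-pixel calibration shape does not match image")
        calz = np.where(img.valid.valid, img.g + 1j * img.s, np.nan)
    valid = p.valid.valid.copy()
    if cal.mode == "per_pixel":
        valid &= cal.phasor.valid.valid  # type: ignore[union-attr]
    z = np.full(p.g.shape, np.nan + 0j)
    z[valid] = _calibrate_z(raw[valid], np.broadcast_to(calz, p.g.shape)[valid], target)
    return PhasorImage(
        g=z.real,
        s=z.imag,
        valid=ValidityMask(valid, p.valid.min_counts),
        harmonic=p.harmonic,
        frequency_MHz=p.frequency_MHz,
    )


def _image_omega(pi: PhasorImage) -> float:
    if pi.frequency_MHz is None:
        raise ValidationError("phasor image carries no frequency")
    return 2.0 * np.pi * pi.harmonic * pi.frequency_MHz / 1000.0


def uc_phasor(tau_ns: float, omega: float) -> Phasor:
    """Universal-circle phasor of a single-exponential lifetime (rad/ns)."""
    if tau_ns < 0:
        raise ValidationError("lifetime must be >= 0")
    wt = omega * tau_ns
    denom = 1.0 + wt * wt
    return Phasor(g=1.0 / denom, s=wt / denom, frequency_MHz=1000.0 * omega / (2 * np.pi))


def uc_lifetime(p: Phasor, omega: float, tol: float = 1e-6) -> float:
    """Lifetime of a phasor on the universal circle: tau = s / (g w)."""
    d = abs(np.hypot(p.g - 0.5, p.s) - 0.5)
    if d > tol:
        raise NotOnCircleError(f"phasor is {d:g} off the universal circle (tol {tol:g})")
    if p.g <= 0:
        raise NotOnCircleError("phasor at the g=0 pole has infinite lifetime")
    return float(p.s / (p.g * omega))


def phase_mod_lifetimes(p: Phasor, omega: float) -> tuple[float, float | None]:
    """Phase and modulation lifetimes of an arbitrary phasor.

    tau_phi = tan(phase)/w, tau_m = sqrt(1/(g^2+s^2) - 1)/w. The two agree
    (and equal the UC lifetime) exactly on the universal circle; strictly
    inside it tau_m > tau_phi. A modulus above 1 is unphysical: tau_m is
    returned as None.
    """
    if p.g <= 0:
        raise ValidationError("phase lifetime undefined for g <= 0")
    tau_phi = float((p.s / p.g) / omega)
    m2 = p.g * p.g + p.s * p.s
    if m2 > 1.0 + 1e-9:
        return tau_phi, None
    tau_m = float(np.sqrt(max(1.0 / m2 - 1.0, 0.0)) / omega)
    return tau_phi, tau_m


def _collect_points(
    phasors: "PhasorImage | Sequence[Phasor] | np.ndarray",
) -> np.ndarray:
    if isinstance(phasors, PhasorImage):
        return phasors.valid_points()
    if isinstance(phasors, np.ndarray):
        pts = np.asarray(phasors, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("phasor array must have shape (n, 2)")
        return pts
    return np.array([[p.g, p.s] for p in phasors], dtype=float)


def principal_axis_uc_references(
    phasors: "PhasorImage | Sequence[Phasor] | np.ndarray",
    omega: float,
    use_major: bool = True,
    selection: Sequence[PhasorROI] | None = None,
    weights: np.ndarray | None = None,
) -> ReferencePair:
    """Find single-exponential references from a phasor cloud.

    The cloud's principal axis of inertia — the eigenvector of the 2x2
    second-moment matrix about the (optionally weighted) mean, major or
    minor per ``use_major`` — is intersected with the universal circle.
    The two intersections become the reference pair, ordered so that p1
    is the larger-g (shorter-lifetime) point.

    ``selection`` optionally restricts the cloud to phasors inside any of
    the given phasor-plot regions; the regions used are echoed in the
    returned pair's ``message``.
    """
    pts = _collect_points(phasors)
    if weights is not None:
        weights = np.asarray(weights, dtype=float).ravel()
        if isinstance(phasors, PhasorImage) and weights.size == phasors.g.size:
            weights = weights.reshape(phasors.g.shape)[phasors.valid.valid].ravel()
        if weights.size != len(pts):
            raise ValidationError("weights length does not match phasor count")
        if np.any(weights < 0):
            raise ValidationError("weights must be >= 0")
    message = "all valid phasors"
    if selection:
        inside = np.zeros(len(pts), dtype=bool)
        for region in selection:
            inside |= region.contains(pts[:, 0], pts[:, 1])
        pts = pts[inside]
        if weights is not None:
            weights = weights[inside]
        message = "restricted to " + " | ".join(r.describe() for r in selection)
    if len(pts) < 2 or np.unique(pts, axis=0).shape[0] < 2:
        raise ValidationError("need at least two distinct phasors for the axis")
    w = np.ones(len(pts)) if weights is None else weights
    wsum = w.sum()
    if wsum <= 0:
        raise ValidationError("all weights are zero")
    mean = (w[:, None] * pts).sum(axis=0) / wsum
    centered = pts - mean
    moment = (w[:, None, None] * (centered[:, :, None] * centered[:, None, :])).sum(axis=0) / wsum
    evals, evecs = np.linalg.eigh(moment)  # ascending eigenvalues
    scale = max(float(np.trace(moment)), 1e-300)
    if (evals[1] - evals[0]) / scale < 1e-9:
        raise DegenerateAxisError(
            "phasor cloud is isotropic; principal axes are not distinguishable"
        )
    direction = evecs[:, 1] if use_major else evecs[:, 0]

    # line mean + t * direction against circle |x - c| = r
    delta = mean - _UC_CENTER
    b = float(np.dot(direction, delta))
    c0 = float(np.dot(delta, delta) - _UC_RADIUS**2)
    disc = b * b - c0
    if disc < 1e-12:
        if disc > -1e-12:
            tangent = mean - b * direction
            raise TangencyError(
                "principal axis is tangent to the universal circle; "
                "the reference pair is degenerate",
                point=(float(tangent[0]), float(tangent[1])),
            )
        raise NoIntersectionError("principal axis does not intersect the universal circle")
    sq = float(np.sqrt(disc))
    points = [mean + (-b - sq) * direction, mean + (-b + sq) * direction]
    points.sort(key=lambda q: -q[0])  # p1 = larger g = shorter lifetime
    freq = 1000.0 * omega / (2 * np.pi)
    p1 = Phasor(float(points[0][0]), float(points[0][1]), frequency_MHz=freq)
    p2 = Phasor(float(points[1][0]), float(points[1][1]), frequency_MHz=freq)
    return ReferencePair(
        p1=p1,
        p2=p2,
        tau1_ns=uc_lifetime(p1, omega, tol=1e-6),
        tau2_ns=uc_lifetime(p2, omega, tol=1e-6),
        message=message,
    )


def decompose(
    p: Phasor, refs: ReferencePair, max_residual: float | None = None
) -> Decomposition:
    """Project a phasor onto the chord between the two references.

    f1 is the orthogonal-projection coordinate of p along p2 -> p1 (an
    intensity fraction); projections outside [0, 1] are clamped and
    flagged. The perpendicular distance to the chord is the residual; if
    ``max_residual`` is given and exceeded the decomposition is marked
    invalid (excluded from maps and histograms downstream).
    """
    v1 = np.array([refs.p1.g, refs.p1.s])
    v2 = np.array([refs.p2.g, refs.p2.s])
    chord = v1 - v2
    L2 = float(np.dot(chord, chord))
    if L2 < 1e-24:
        raise ValidationError("degenerate reference pair (coincident phasors)")
    q = np.array([p.g, p.s])
    raw_f1 = float(np.dot(q - v2, chord) / L2)
    foot = v2 + raw_f1 * chord
    residual = float(np.hypot(*(q - foot)))
    f1 = min(max(raw_f1, 0.0), 1.0)
    clamped = f1 != raw_f1
    valid = True if max_residual is None else residual <= max_residual
    return Decomposition(f1=f1, f2=1.0 - f1, residual=residual, clamped=clamped, valid=valid)


def amplitude_avg_lifetime(dec: Decomposition, refs: ReferencePair) -> float:
    """Amplitude-averaged lifetime of a decomposed phasor.

    Phasor fractions weight components by emitted intensity (a_i tau_i);
    converting to pre-exponential amplitude fractions a_i ~ f_i / tau_i
    gives <tau>_a = sum a_i tau_i / sum a_i = 1 / (f1/tau1 + f2/tau2),
    which always lies in [tau1, tau2].
    """
    if refs.tau1_ns <= 0 or refs.tau2_ns <= 0:
        raise ValidationError("reference lifetimes must be > 0")
    return 1.0 / (dec.f1 / refs.tau1_ns + dec.f2 / refs.tau2_ns)


def phasor_select(pi: PhasorImage, region: PhasorROI) -> ValidityMask:
    """Image mask of pixels whose phasor falls inside a phasor-plot region."""
    inside = np.zeros(pi.shape, dtype=bool)
    m = pi.valid.valid
    inside[m] = region.contains(pi.g[m], pi.s[m])
    return ValidityMask(valid=inside, min_counts=pi.valid.min_counts)
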