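"""Exponential decay fitting with iterative reconvolution.

The forward model is the steady-state response to periodic pulsed
excitation: a sum of wrapped exponentials

    D(t_k) = sum_i a_i exp(-t_k / tau_i) / (1 - exp(-T / tau_i)),

circularly convolved with the unit-normalized (and optionally time-shifted)
instrument response function sampled on the same grid, plus a flat
background B. Three objectives are supported:

* unweighted NLSF      : sum (n_k - m_k)^2
* weighted NLSF        : sum (n_k - m_k)^2 / max(n_k, 1)   (Neyman weights)
* Poisson MLE          : deviance 2 sum [m_k - n_k + n_k ln(n_k / m_k)]
                         (n_k = 0 terms contribute m_k)

All three are minimized with a bounded trust-region least-squares solver;
the Poisson deviance is expressed through signed square-root deviance
residuals, which are smooth near the optimum and whose squared sum is
exactly the deviance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln

from .core import DecayCurve, FLIDataset, TimeAxis, ValidityMask
from .errors import EmptyDecayError, ValidationError

__all__ = [
    "DecayModelParams",
    "FitResult",
    "FitImageResult",
    "model_decay",
    "fit_decay",
    "fit_image",
]

_METHODS = ("nlsf_unweighted", "nlsf_weighted", "mle")
TAU_BOUNDS_NS = (1e-3, 1e3)


@dataclass
class DecayModelParams:
    """Parameters of a 1- or 2-component reconvolution decay model.

    ``amplitudes`` are per-component pre-exponential factors on the
    counts-per-bin scale, ``lifetimes`` in ns (canonical order
    tau1 < tau2), ``background`` a flat counts-per-bin offset, and
    ``shift_ns`` the time offset of the IRF relative to the data.
    """

    amplitudes: tuple[float, ...]
    lifetimes: tuple[float, ...]
    background: float = 0.0
    shift_ns: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = tuple(float(a) for a in self.amplitudes)
        self.lifetimes = tuple(float(t) for t in self.lifetimes)
        if len(self.amplitudes) != len(self.lifetimes):
            raise ValidationError("one amplitude per lifetime required")
        if len(self.amplitudes) not in (1, 2):
            raise ValidationError("only 1- or 2-component models supported")
        if any(t <= 0 for t in self.lifetimes):
            raise ValidationError("lifetimes must be > 0")
        if any(a < 0 for a in self.amplitudes):
            raise ValidationError("amplitudes must be >= 0")
        if self.background < 0:
            raise ValidationError("background must be >= 0")

    @property
    def n_components(self) -> int:
        return len(self.lifetimes)

    def canonical(self) -> "DecayModelParams":
        """Sort components by ascending lifetime (tau1 < tau2)."""
        order = np.argsort(self.lifetimes)
        return DecayModelParams(
            amplitudes=tuple(self.amplitudes[i] for i in order),
            lifetimes=tuple(self.lifetimes[i] for i in order),
            background=self.background,
            shift_ns=self.shift_ns,
        )


@dataclass
class FitResult:
    params: DecayModelParams
    chi2_reduced: float
    neg_log_likelihood: float
    cov: np.ndarray | None
    n_iter: int
    converged: bool
    method: str
    param_names: tuple[str, ...] = ()


@dataclass
class FitImageResult:
    """Per-pixel fit output: one map per parameter plus status flags."""

    maps: dict[str, np.ndarray]
    converged: np.ndarray
    valid: np.ndarray
    results: dict[tuple[int, int], FitResult] = field(default_factory=dict)


def _shift_periodic(y: np.ndarray, shift_bins: float) -> np.ndarray:
    """Shift a periodic sequence later in index by a fractional amount,
    using periodic linear interpolation."""
    n = y.size
    i0 = int(np.floor(shift_bins))
    frac = shift_bins - i0
    rolled = np.roll(y, i0)
    if frac == 0.0:
        return rolled
    return (1.0 - frac) * rolled + frac * np.roll(y, i0 + 1)


def _circular_convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    fa = np.fft.rfft(a)
    fb = np.fft.rfft(b)
    return np.fft.irfft(fa * fb, n=a.size)


def model_decay(
    params: DecayModelParams, irf: DecayCurve, axis: TimeAxis
) -> np.ndarray:
    """Expected counts per bin of the reconvolution model.

    The IRF is unit-normalized and shifted by ``params.shift_ns`` (periodic
    linear interpolation), then circularly convolved with the wrapped
    multi-exponential. With a delta IRF at bin 0, zero shift and zero
    background the model is the wrapped exponential itself.
    """
    if irf.counts.sum() <= 0:
        raise ValidationError("IRF has zero total counts")
    if len(irf) != axis.n_bins:
        raise ValidationError("IRF must be sampled on the dataset time grid")
    if not axis.is_regular():
        raise ValidationError("reconvolution requires a regular time grid")
    t = axis.bin_centers_ns
    T = axis.period_ns
    decay = np.zeros(axis.n_bins)
    for a, tau in zip(params.amplitudes, params.lifetimes):
        decay += a * np.exp(-t / tau) / -np.expm1(-T / tau)
    irf_n = irf.counts / irf.counts.sum()
    irf_n = _shift_periodic(irf_n, params.shift_ns / axis.bin_width_ns)
    model = _circular_convolve(decay, irf_n) + params.background
    return np.maximum(model, 0.0)


def _initial_guess(
    d: DecayCurve, axis: TimeAxis, n_components: int
) -> DecayModelParams:
    """Deterministic starting point: background from the minimum bin, a
    log-linear tail regression for the lifetime, components split x/÷ 2."""
    counts = d.counts
    b0 = max(float(counts.min()), 0.0)
    peak = int(np.argmax(counts))
    tail = counts[peak:] - b0
    t_tail = d.time_ns[peak:]
    keep = tail > max(tail.max(initial=0.0) / 50.0, 0.0)
    if keep.sum() >= 3:
        slope, intercept = np.polyfit(t_tail[keep], np.log(tail[keep]), 1)
        tau0 = -1.0 / slope if slope < 0 else 2.0
        a0 = float(np.exp(intercept))
    else:
        tau0, a0 = 2.0, max(float(counts.max() - b0), 1.0)
    tau0 = float(np.clip(tau0, TAU_BOUNDS_NS[0] * 10, TAU_BOUNDS_NS[1] / 10))
    if n_components == 1:
        return DecayModelParams((a0,), (tau0,), background=b0, shift_ns=0.0)
    return DecayModelParams(
        (a0 / 2, a0 / 2), (tau0 / 2, tau0 * 2), background=b0, shift_ns=0.0
    )


def _residual_factory(method: str, n_obs: np.ndarray):
    if method == "nlsf_unweighted":
        def resid(m):
            return m - n_obs
    elif method == "nlsf_weighted":
        sig = np.sqrt(np.maximum(n_obs, 1.0))

        def resid(m):
            return (m - n_obs) / sig
    elif method == "mle":
        nz = n_obs > 0

        def resid(m):
            # signed sqrt deviance; delta - log1p(delta) evaluated by series
            # near 0 to avoid catastrophic cancellation on near-exact fits
            m = np.maximum(m, 1e-300)
            dev = 2.0 * m  # n = 0 term
            delta = (m[nz] - n_obs[nz]) / n_obs[nz]
            small = np.abs(delta) < 1e-3
            f = np.where(
                small,
                delta**2 * (0.5 + delta * (-1.0 / 3.0 + delta * (0.25 - 0.2 * delta))),
                delta - np.log1p(delta),
            )
            dev[nz] = 2.0 * n_obs[nz] * f
            return np.sign(n_obs - m) * np.sqrt(np.maximum(dev, 0.0))
    else:
        raise ValidationError(f"unknown fit method {method!r}; use one of {_METHODS}")
    return resid


def fit_decay(
    d: DecayCurve,
    irf: DecayCurve,
    axis: TimeAxis,
    n_components: int = 1,
    method: str = "mle",
    init: DecayModelParams | None = None,
    fit_range: tuple[int, int] | None = None,
    fit_shift: bool = True,
) -> FitResult:
    """Fit a 1- or 2-exponential reconvolution model to one decay.

    ``fit_range`` restricts the objective to bins [start, stop); the full
    period is still used to evaluate the periodic model. Non-convergence
    is reported through ``converged=False``, never as an exception.
    """
    if method not in _METHODS:
        raise ValidationError(f"unknown fit method {method!r}; use one of {_METHODS}")
    if n_components not in (1, 2):
        raise ValidationError("n_components must be 1 or 2")
    if d.counts.sum() <= 0:
        raise EmptyDecayError("cannot fit an empty decay")
    if init is not None and init.n_components != n_components:
        raise ValidationError("init has the wrong number of components")

    window = np.arange(axis.n_bins)
    if fit_range is not None:
        start, stop = fit_range
        if not (0 <= start < stop <= axis.n_bins):
            raise ValidationError("fit_range out of bounds")
        window = np.arange(start, stop)
    n_obs = d.counts[window]
    resid_of_model = _residual_factory(method, n_obs)

    p0 = init if init is not None else _initial_guess(d, axis, n_components)
    nc = n_components
    names = tuple(f"a{i+1}" for i in range(nc)) + tuple(f"tau{i+1}" for i in range(nc)) + (
        "background",
    ) + (("shift_ns",) if fit_shift else ())

    def unpack(x: np.ndarray) -> DecayModelParams:
        return DecayModelParams(
            amplitudes=tuple(x[:nc]),
            lifetimes=tuple(np.maximum(x[nc : 2 * nc], TAU_BOUNDS_NS[0])),
            background=float(x[2 * nc]),
            shift_ns=float(x[2 * nc + 1]) if fit_shift else p0.shift_ns,
        )

    x0 = list(p0.amplitudes) + list(p0.lifetimes) + [p0.background]
    lo = [0.0] * nc + [TAU_BOUNDS_NS[0]] * nc + [0.0]
    hi = [np.inf] * nc + [TAU_BOUNDS_NS[1]] * nc + [np.inf]
    if fit_shift:
        x0.append(p0.shift_ns)
        lo.append(-axis.period_ns / 2)
        hi.append(axis.period_ns / 2)
    x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)

    def objective(x: np.ndarray) -> np.ndarray:
        m = model_decay(unpack(x), irf, axis)[window]
        return resid_of_model(m)

    res = least_squares(
        objective,
        x0,
        bounds=(lo, hi),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-12,
        max_nfev=500 * (len(x0) + 1),
    )
    params = unpack(res.x).canonical()
    m_best = model_decay(params, irf, axis)[window]
    dof = max(n_obs.size - len(x0), 1)
    if method == "mle":
        chi2 = float(np.sum(resid_of_model(m_best) ** 2)) / dof  # deviance / dof
    else:
        chi2 = float(np.sum((n_obs - m_best) ** 2 / np.maximum(n_obs, 1.0))) / dof
    m_pos = np.maximum(m_best, 1e-300)
    nll = float(np.sum(m_pos - n_obs * np.log(m_pos) + gammaln(n_obs + 1.0)))

    cov = None
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.pinv(jtj)
        if method == "nlsf_unweighted":
            cov *= float(np.sum(res.fun**2)) / dof
    except np.linalg.LinAlgError:
        pass
    return FitResult(
        params=params,
        chi2_reduced=chi2,
        neg_log_likelihood=nll,
        cov=cov,
        n_iter=int(res.nfev),
        converged=bool(res.status > 0),
        method=method,
        param_names=names,
    )


def fit_image(
    ds: FLIDataset,
    irf: "DecayCurve | np.ndarray",
    axis: TimeAxis | None = None,
    n_components: int = 1,
    method: str = "mle",
    mask: ValidityMask | None = None,
    fit_shift: bool = True,
    keep_results: bool = False,
) -> FitImageResult:
    """Fit every valid pixel independently; collect parameter maps.

    ``irf`` may be a single :class:`DecayCurve` shared by all pixels or a
    ``(time, row, col)`` cube of per-pixel IRFs (SPAD-camera regime).
    Unset map entries are NaN; ``converged`` flags per-pixel success.
    """
    axis = axis or ds.time_axis
    per_pixel_irf = isinstance(irf, np.ndarray)
    if per_pixel_irf and irf.shape != ds.counts.shape:
        raise ValidationError("per-pixel IRF cube must match the dataset shape")
    valid = ds.intensity_image() > 0
    if mask is not None:
        if mask.shape != ds.frame_shape:
            raise ValidationError("validity mask shape does not match dataset")
        valid &= mask.valid
    names = (
        tuple(f"a{i+1}" for i in range(n_components))
        + tuple(f"tau{i+1}" for i in range(n_components))
        + ("background", "shift_ns", "chi2_reduced")
    )
    maps = {k: np.full(ds.frame_shape, np.nan) for k in names}
    converged = np.zeros(ds.frame_shape, dtype=bool)
    results: dict[tuple[int, int], FitResult] = {}
    t = axis.bin_centers_ns
    for r, c in zip(*np.nonzero(valid)):
        pixel_irf = (
            DecayCurve(time_ns=t, counts=irf[:, r, c]) if per_pixel_irf else irf
        )
        fr = fit_decay(
            ds.pixel_decay(r, c),
            pixel_irf,
            axis,
            n_components=n_components,
            method=method,
            fit_shift=fit_shift,
        )
        p = fr.params
        for i in range(n_components):
            maps[f"a{i+1}"][r, c] = p.amplitudes[i]
            maps[f"tau{i+1}"][r, c] = p.lifetimes[i]
        maps["background"][r, c] = p.background
        maps["shift_ns"][r, c] = p.shift_ns
        maps["chi2_reduced"][r, c] = fr.chi2_reduced
        converged[r, c] = fr.converged
        if keep_results:
            results[(int(r), int(c))] = fr
    return FitImageResult(maps=maps, converged=converged, valid=valid, results=results)
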