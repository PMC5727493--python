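"""Dual-input two-compartment distributed-parameter liver kinetics.

The liver receives blood from both the hepatic artery and the portal vein.
In this model the tissue contrast-concentration curve is the convolution of
a flow-weighted mixture of the two vascular input functions with a tissue
impulse residue function ``R(t)``:

    Ct(t) = F * [alpha * Ca(t - tau_a) + (1 - alpha) * Cp(t - tau_p)] (*) R(t)

``R(t)`` has two phases.  During the vascular transit phase the whole bolus
is still inside the sinusoidal (vascular) space, so ``R`` is 1 on the
half-open interval ``[0, t1)``.  At ``t1`` the intravascular tracer has been
washed out except for the fraction ``E = 1 - exp(-PS/F)`` that was extracted
into the interstitial space (the Space of Disse); the distributed-parameter
solution for the subsequent back-flux of that fraction involves the modified
Bessel function of the first kind ``I1``:

    R(t) = 1 - exp(-PS/F) * [1 + integral_0^(t - t1) exp(-(PS/v2) tau)
             * sqrt((PS/v2)(PS/F)/tau) * I1(2 sqrt((PS/v2)(PS/F) tau)) dtau]

for ``t >= t1``.  The back-flux phase is evaluated at the shifted time
``t - t1`` so that it begins when the vascular transit ends; this gives
``R(0) = 1`` and a jump from 1 down to ``E`` at ``t1``, as required for a
physically admissible residue function.

Units: flows ``F`` and the permeability-surface area product ``PS`` are
carried in mL/min/100 mL tissue, the convention of the clinical literature,
and converted internally to fractional per-second rates (divide by 100 and
by 60).  Times are in seconds, volumes are dimensionless fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import i1e

from .errors import GridMismatchError, InvalidArgumentError, InvalidParameterError

__all__ = [
    "FLOW_TO_PER_SECOND",
    "TimeGrid",
    "ConcentrationCurve",
    "ResidueCurve",
    "PerfusionParameters",
    "extraction_ratio",
    "vascular_phase",
    "backflux_integrand",
    "backflux_phase",
    "residue_function",
    "shift_curve",
    "tissue_curve",
    "derive_v1",
]

#: mL/min/100 mL tissue -> fractional volume per second
FLOW_TO_PER_SECOND = 1.0 / (100.0 * 60.0)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid: sample ``k`` lives at ``t0 + k * dt`` seconds."""

    n: int
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidParameterError(f"grid needs at least 2 samples, got n={self.n}")
        if not self.dt > 0:
            raise InvalidParameterError(f"temporal spacing must be positive, got dt={self.dt}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        """Time from first to last sample, ``(n - 1) * dt`` seconds."""
        return (self.n - 1) * self.dt


@dataclass(frozen=True)
class ConcentrationCurve:
    """A sampled contrast-concentration time course on a uniform grid."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.grid.n:
            raise GridMismatchError(
                f"curve has {values.size} samples but grid expects {self.grid.n}"
            )
        if not np.all(np.isfinite(values)):
            raise InvalidArgumentError("concentration values must be finite")

    def same_grid(self, other: "ConcentrationCurve") -> bool:
        return self.grid == other.grid


@dataclass(frozen=True)
class ResidueCurve:
    """Sampled tissue impulse residue function, dimensionless in [0, 1]."""

    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.grid.n:
            raise GridMismatchError(
                f"residue curve has {values.size} samples but grid expects {self.grid.n}"
            )


@dataclass(frozen=True)
class PerfusionParameters:
    """The six liver perfusion parameters plus the two input delays.

    Attributes
    ----------
    F : float
        Total blood flow, mL/min/100 mL tissue.
    alpha : float
        Arterial fraction of total flow, in [0, 1]; ``Fa = alpha * F`` and
        ``Fp = (1 - alpha) * F``.
    t1 : float
        Vascular mean transit time, seconds.
    v2 : float
        Fractional volume of the interstitial space, in (0, 1).
    PS : float
        Permeability-surface area product, mL/min/100 mL tissue.
    tau_a, tau_p : float
        Arrival delays of the arterial and portal input functions, seconds.
    """

    F: float
    alpha: float
    t1: float
    v2: float
    PS: float
    tau_a: float = 0.0
    tau_p: float = 0.0

    def __post_init__(self) -> None:
        if not self.F > 0:
            raise InvalidParameterError(f"total flow F must be positive, got {self.F}")
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParameterError(f"arterial fraction alpha must be in [0, 1], got {self.alpha}")
        if not self.t1 > 0:
            raise InvalidParameterError(f"vascular transit time t1 must be positive, got {self.t1}")
        if not 0.0 < self.v2 < 1.0:
            raise InvalidParameterError(f"interstitial volume v2 must be in (0, 1), got {self.v2}")
        if self.PS < 0:
            raise InvalidParameterError(f"PS must be non-negative, got {self.PS}")
        if self.tau_a < 0 or self.tau_p < 0:
            raise InvalidParameterError("arrival delays must be non-negative")

    @property
    def Fa(self) -> float:
        """Hepatic-arterial flow, mL/min/100 mL."""
        return self.alpha * self.F

    @property
    def Fp(self) -> float:
        """Portal-venous flow, mL/min/100 mL."""
        return (1.0 - self.alpha) * self.F

    @property
    def F_per_second(self) -> float:
        """Total flow as a fractional per-second rate."""
        return self.F * FLOW_TO_PER_SECOND

    def v1(self, hct: float | None = None) -> float:
        """Fractional vascular volume by the central-volume relation."""
        return derive_v1(self.F, self.t1, hct)

    def with_delays(self, tau_a: float, tau_p: float) -> "PerfusionParameters":
        return replace(self, tau_a=tau_a, tau_p=tau_p)


def extraction_ratio(PS: float, F: float) -> float:
    """First-pass extraction ratio ``E = 1 - exp(-PS/F)``.

    Fraction of tracer transferred from the vascular to the interstitial
    space during one vascular transit.  Strictly increasing in ``PS`` and
    decreasing in ``F``; saturates at 1 for ``PS >> F``.
    """
    PS_a = np.asarray(PS, dtype=float)
    F_a = np.asarray(F, dtype=float)
    if np.any(F_a <= 0):
        raise InvalidParameterError(f"total flow F must be positive, got {F}")
    if np.any(PS_a < 0):
        raise InvalidParameterError(f"PS must be non-negative, got {PS}")
    E = -np.expm1(-PS_a / F_a)
    return float(E) if E.ndim == 0 else E


def vascular_phase(t, t1: float):
    """Vascular transit phase ``u(t) - u(t - t1)``.

    1 on the half-open window ``[0, t1)``, 0 elsewhere.  The value at
    exactly ``t = t1`` is 0, making the residue function right-continuous
    at the jump.
    """
    if not t1 > 0:
        raise InvalidParameterError(f"vascular transit time t1 must be positive, got {t1}")
    t = np.asarray(t, dtype=float)
    out = np.where((t >= 0.0) & (t < t1), 1.0, 0.0)
    return float(out) if out.ndim == 0 else out


def backflux_integrand(tau, k_e: float, k_t: float):
    """Integrand of the back-flux phase integral.

    ``exp(-k_e tau) * sqrt(k_e k_t / tau) * I1(2 sqrt(k_e k_t tau))`` with
    ``k_e = PS/v2`` (per second) and ``k_t = PS/F`` (dimensionless).  The
    ``tau -> 0`` limit is ``k_e * k_t`` because ``I1(z) ~ z/2`` for small
    ``z``.  Evaluated through the exponentially scaled Bessel function to
    stay finite for large arguments.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise InvalidArgumentError("back-flux integration time tau must be non-negative")
    if k_e < 0 or k_t < 0:
        raise InvalidParameterError("rates k_e and k_t must be non-negative")
    scalar = tau.ndim == 0
    tau = np.atleast_1d(tau)
    out = np.empty_like(tau)
    zero = tau == 0.0
    out[zero] = k_e * k_t
    tz = tau[~zero]
    a = k_e * k_t
    z = 2.0 * np.sqrt(a * tz)
    # I1(z) = i1e(z) * exp(z); fold exp(z) into the decay term
    out[~zero] = np.exp(z - k_e * tz) * np.sqrt(a / tz) * i1e(z)
    return float(out[0]) if scalar else out


def _backflux_integral(t_rel: np.ndarray, k_e: float, k_t: float, qdt: float) -> np.ndarray:
    """Rectangular-method integral of the back-flux integrand from 0 to each t_rel.

    Midpoint rectangles of width ``qdt`` plus a partial final rectangle
    evaluated at its own midpoint.  The midpoint form keeps the
    rectangular-sum convention while converging at second order (halving
    the step moves the result by well under a percent at clinical settings),
    and the partial rectangle makes the result continuous in ``t_rel`` —
    important for the voxel fitter, which differentiates through it
    numerically.
    """
    t_rel = np.asarray(t_rel, dtype=float)
    if t_rel.size == 0:
        return np.zeros(0)
    j = np.floor(t_rel / qdt).astype(np.intp)
    jmax = int(j.max())
    mid = qdt * (np.arange(jmax + 1) + 0.5)
    f_mid = np.atleast_1d(backflux_integrand(mid, k_e, k_t))
    cum = np.concatenate(([0.0], np.cumsum(f_mid) * qdt))
    r = t_rel - j * qdt
    f_partial = np.atleast_1d(backflux_integrand(j * qdt + 0.5 * r, k_e, k_t))
    return cum[j] + f_partial * r


def backflux_phase(t_rel, params: PerfusionParameters, quadrature_dt: float):
    """Parenchyma back-flux phase at time ``t_rel`` after the vascular transit ends.

    ``1 - exp(-PS/F) * [1 + integral_0^t_rel integrand dtau]``, the integral
    taken by the rectangular method at step ``quadrature_dt``.  Equals the
    extraction ratio at ``t_rel = 0`` and decays monotonically to 0.
    """
    if not isinstance(params, PerfusionParameters):
        raise InvalidParameterError("params must be a PerfusionParameters instance")
    if not quadrature_dt > 0:
        raise InvalidArgumentError(f"quadrature step must be positive, got {quadrature_dt}")
    t_rel_arr = np.asarray(t_rel, dtype=float)
    if np.any(t_rel_arr < 0):
        raise InvalidArgumentError("back-flux time t_rel must be non-negative")
    scalar = t_rel_arr.ndim == 0
    t_rel_arr = np.atleast_1d(t_rel_arr)
    if params.PS == 0.0:
        out = np.zeros_like(t_rel_arr)
        return float(out[0]) if scalar else out
    k_t = params.PS / params.F
    k_e = params.PS * FLOW_TO_PER_SECOND / params.v2
    integral = _backflux_integral(t_rel_arr, k_e, k_t, quadrature_dt)
    out = 1.0 - np.exp(-k_t) * (1.0 + integral)
    np.clip(out, 0.0, 1.0, out=out)
    return float(out[0]) if scalar else out


def residue_function(
    grid: TimeGrid,
    params: PerfusionParameters,
    quadrature_dt: float | None = None,
) -> ResidueCurve:
    """Tissue impulse residue function sampled on ``grid``.

    ``R(t) = 1`` for ``0 <= t < t1`` (plug-flow vascular transit) and
    ``R(t) = backflux_phase(t - t1)`` for ``t >= t1``.  The quadrature step
    defaults to the grid spacing, matching the rectangular-method convention
    used for the convolution; a finer step may be supplied for
    high-accuracy reference evaluation.
    """
    qdt = grid.dt if quadrature_dt is None else quadrature_dt
    t = grid.times
    values = np.zeros(grid.n)
    vascular = (t >= 0.0) & (t < params.t1)
    values[vascular] = 1.0
    after = t >= params.t1
    if np.any(after):
        values[after] = backflux_phase(t[after] - params.t1, params, qdt)
    return ResidueCurve(grid=grid, values=values)


def shift_curve(curve: ConcentrationCurve, delay: float) -> ConcentrationCurve:
    """Translate a curve later in time by ``delay`` seconds.

    Fractional delays are realised by linear interpolation between the two
    neighbouring integer-sample shifts, which conserves total tracer mass
    and makes the output a continuous function of ``delay`` (so the fitter
    can optimise arrival delays smoothly).  The front is zero-padded.
    """
    if delay < 0:
        raise InvalidArgumentError(f"delay must be non-negative, got {delay}")
    if delay == 0.0:
        return ConcentrationCurve(grid=curve.grid, values=curve.values.copy())
    dt = curve.grid.dt
    m, frac = divmod(delay / dt, 1.0)
    m = int(m)
    n = curve.grid.n
    out = np.zeros(n)
    if m < n:
        out[m:] = (1.0 - frac) * curve.values[: n - m]
    if frac > 0.0 and m + 1 < n:
        out[m + 1 :] += frac * curve.values[: n - m - 1]
    return ConcentrationCurve(grid=curve.grid, values=out)


def tissue_curve(
    params: PerfusionParameters,
    Ca: ConcentrationCurve,
    Cp: ConcentrationCurve,
    grid: TimeGrid | None = None,
) -> ConcentrationCurve:
    """Forward model: tissue concentration from the dual vascular inputs.

    Computes ``F_frac * [alpha * Ca(t - tau_a) + (1 - alpha) * Cp(t - tau_p)]``
    convolved with ``R(t)`` by the rectangular method at the grid spacing,
    where ``F_frac`` is the total flow converted to per-second fractional
    units.
    """
    if grid is None:
        grid = Ca.grid
    if Ca.grid != grid or Cp.grid != grid:
        raise GridMismatchError("Ca, Cp and the output grid must be identical")
    Ca_d = shift_curve(Ca, params.tau_a)
    Cp_d = shift_curve(Cp, params.tau_p)
    mixed = params.alpha * Ca_d.values + (1.0 - params.alpha) * Cp_d.values
    R = residue_function(grid, params).values
    conv = np.convolve(mixed, R)[: grid.n]
    values = params.F_per_second * grid.dt * conv
    return ConcentrationCurve(grid=grid, values=values)


def derive_v1(F: float, t1: float, hct: float | None = None) -> float:
    """Fractional vascular volume from the central-volume relation.

    ``v1 = F_frac * t1`` where ``F_frac`` is the flow in fractional
    per-second units; with a haematocrit value, the result is scaled by
    ``(1 - hct)`` to express a plasma rather than whole-blood volume.  The
    default (no haematocrit scaling) treats all concentrations on the same
    whole-blood scale.
    """
    if not F > 0:
        raise InvalidParameterError(f"total flow F must be positive, got {F}")
    if not t1 > 0:
        raise InvalidParameterError(f"vascular transit time t1 must be positive, got {t1}")
    v1 = (F / 100.0) * (t1 / 60.0)
    if hct is not None:
        if not 0.0 <= hct < 1.0:
            raise InvalidArgumentError(f"haematocrit must be in [0, 1), got {hct}")
        v1 *= 1.0 - hct
    return v1
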