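"""Voxelwise nonlinear least-squares estimation of liver perfusion parameters.

Each voxel's tissue curve is fitted against the dual-input two-compartment
forward model by bounded trust-region least squares with finite-difference
gradients, restarted from a small set of deterministic starting points
spanning arterial-dominant/portal-dominant and fast/slow-exchange corners of
the parameter space (the objective is multi-modal in alpha, t1 and PS).
The arterial and portal arrival delays are fitted jointly with the kinetic
parameters as continuous variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import GridMismatchError, InvalidParameterError, MaskError
from .model import ConcentrationCurve, PerfusionParameters, TimeGrid, tissue_curve

__all__ = [
    "PARAM_NAMES",
    "MAP_NAMES",
    "FitConfig",
    "FitResult",
    "DynamicVolume",
    "ParameterMaps",
    "objective",
    "fit_voxel",
    "fit_volume",
    "extract_input_functions",
]

logger = logging.getLogger(__name__)

#: order of the free parameters in the optimisation vector
PARAM_NAMES = ("F", "alpha", "t1", "v2", "PS", "tau_a", "tau_p")

#: maps emitted by fit_volume (fitted parameters, derived v1, diagnostics)
MAP_NAMES = PARAM_NAMES[:5] + ("v1", "tau_a", "tau_p", "sse", "converged", "n_iter")

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "F": (1.0, 500.0),
    "alpha": (0.0, 1.0),
    "t1": (1.0, 120.0),
    "v2": (0.005, 0.8),
    "PS": (0.1, 300.0),
    "tau_a": (0.0, 30.0),
    "tau_p": (0.0, 30.0),
}


def _default_multistart() -> list[dict[str, float]]:
    """Six deterministic starts: four kinetic corners, one low-flow and one centre."""
    corners = []
    for alpha, label in ((0.8, "arterial"), (0.2, "portal")):
        for PS, t1, F, v2 in ((100.0, 10.0, 150.0, 0.1), (10.0, 40.0, 60.0, 0.3)):
            corners.append(
                {"F": F, "alpha": alpha, "t1": t1, "v2": v2, "PS": PS, "tau_a": 0.5, "tau_p": 0.5}
            )
    corners.append({"F": 40.0, "alpha": 0.4, "t1": 25.0, "v2": 0.2, "PS": 30.0, "tau_a": 0.5, "tau_p": 0.5})
    corners.append({"F": 100.0, "alpha": 0.5, "t1": 20.0, "v2": 0.15, "PS": 50.0, "tau_a": 0.5, "tau_p": 0.5})
    return corners


@dataclass
class FitConfig:
    """Settings for the per-voxel nonlinear fit.

    ``bounds`` are per-parameter (lower, upper) pairs; ``multistart`` is a
    list of starting points (dicts keyed by parameter name); ``baseline_n``
    is the number of pre-bolus samples used to estimate the noise floor for
    the enhancement guard, and ``enhancement_factor`` the multiple of the
    baseline SD the peak must exceed for a voxel to be fitted.
    """

    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    multistart: list[dict[str, float]] = field(default_factory=_default_multistart)
    max_iter: int = 200
    tol: float = 1e-12
    seed: int = 0
    baseline_n: int = 5
    enhancement_factor: float = 3.0
    fit_delays: bool = True
    t1_profile: bool = True
    profile_top: int = 3

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.bounds:
                raise InvalidParameterError(f"bounds missing parameter {name!r}")
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise InvalidParameterError(f"bounds for {name!r} must satisfy lower < upper")
        if not self.multistart:
            raise InvalidParameterError("multistart must list at least one starting point")
        for start in self.multistart:
            for name in PARAM_NAMES:
                lo, hi = self.bounds[name]
                if not lo <= start.get(name, lo) <= hi:
                    raise InvalidParameterError(
                        f"start value {start.get(name)} for {name!r} outside bounds [{lo}, {hi}]"
                    )

    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in PARAM_NAMES])

    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in PARAM_NAMES])

    def starts(self) -> list[np.ndarray]:
        return [np.array([s[n] for n in PARAM_NAMES]) for s in self.multistart]


@dataclass
class FitResult:
    """Outcome of one voxel fit."""

    params: PerfusionParameters | None
    sse: float
    converged: bool
    n_iter: int
    start_index: int
    message: str = ""


@dataclass
class DynamicVolume:
    """A 4D dynamic concentration dataset: x, y, z, time."""

    data: np.ndarray
    grid: TimeGrid
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise InvalidParameterError(f"dynamic data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] != self.grid.n:
            raise GridMismatchError(
                f"time dimension {self.data.shape[3]} does not match grid.n={self.grid.n}"
            )
        if self.mask.shape != self.data.shape[:3]:
            raise GridMismatchError("mask shape must equal the spatial shape of the data")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("dynamic data must be finite")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def curve_at(self, index: tuple[int, int, int]) -> ConcentrationCurve:
        return ConcentrationCurve(grid=self.grid, values=self.data[index])


@dataclass
class ParameterMaps:
    """Per-voxel fitted parameter maps plus fit diagnostics.

    One 3D float array per entry of :data:`MAP_NAMES`; voxels outside the
    mask or that failed the enhancement guard carry NaN (``converged`` is
    0.0 there).
    """

    maps: dict[str, np.ndarray]
    grid: TimeGrid | None = None
    affine: np.ndarray | None = None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return next(iter(self.maps.values())).shape

    @classmethod
    def empty(cls, shape: tuple[int, int, int], grid: TimeGrid | None = None,
              affine: np.ndarray | None = None) -> "ParameterMaps":
        maps = {name: np.full(shape, np.nan) for name in MAP_NAMES}
        maps["converged"] = np.zeros(shape)
        return cls(maps=maps, grid=grid, affine=affine)


def objective(
    theta: np.ndarray,
    Ct: ConcentrationCurve,
    Ca: ConcentrationCurve,
    Cp: ConcentrationCurve,
) -> float:
    """Sum of squared residuals between the measured and modelled tissue curve."""
    if not (Ct.grid == Ca.grid == Cp.grid):
        raise GridMismatchError("Ct, Ca and Cp must share one time grid")
    r = _residuals(np.asarray(theta, dtype=float), Ct, Ca, Cp)
    return float(np.dot(r, r))


def _params_from_vector(theta: np.ndarray) -> PerfusionParameters:
    return PerfusionParameters(**dict(zip(PARAM_NAMES, theta)))


def _residuals(theta, Ct, Ca, Cp):
    params = _params_from_vector(theta)
    model = tissue_curve(params, Ca, Cp)
    return model.values - Ct.values


def has_enhancement(Ct: ConcentrationCurve, baseline_n: int, factor: float) -> bool:
    """True when the curve's peak rises above the pre-bolus noise floor."""
    baseline = Ct.values[: max(1, baseline_n)]
    threshold = factor * float(np.std(baseline, ddof=0))
    peak = float(np.max(Ct.values) - np.mean(baseline))
    return peak > threshold


def fit_voxel(
    Ct: ConcentrationCurve,
    Ca: ConcentrationCurve,
    Cp: ConcentrationCurve,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the dual-input two-compartment model to one tissue curve.

    Runs bounded trust-region least squares from every configured start and
    returns the converged solution with the lowest sum of squared errors.
    Deterministic for a fixed configuration.  A curve without measurable
    enhancement, or for which every start fails, yields a non-converged
    result rather than an exception.
    """
    if config is None:
        config = FitConfig()
    if not (Ct.grid == Ca.grid == Cp.grid):
        raise GridMismatchError("Ct, Ca and Cp must share one time grid")
    if not has_enhancement(Ct, config.baseline_n, config.enhancement_factor):
        return FitResult(params=None, sse=float("inf"), converged=False,
                         n_iter=0, start_index=-1, message="no enhancement above noise floor")

    lower, upper = config.lower(), config.upper()
    if not config.fit_delays:
        upper = upper.copy()
        upper[5] = upper[6] = 1e-9
    max_nfev = config.max_iter * (len(PARAM_NAMES) + 1)
    n_iter_total = 0

    starts = config.starts()
    if config.t1_profile:
        profiled = _profile_t1(Ct, Ca, Cp, lower, upper, max_nfev, config.starts(),
                               config.profile_top)
        n_iter_total += sum(nfev for _, _, nfev in profiled)
        starts = [x for _, x, _ in profiled[: config.profile_top]] + starts

    best: FitResult | None = None
    for idx, x0 in enumerate(starts):
        x0 = np.clip(x0, lower, upper)
        try:
            sol = least_squares(
                _residuals,
                x0,
                bounds=(lower, upper),
                args=(Ct, Ca, Cp),
                method="trf",
                ftol=config.tol,
                xtol=config.tol,
                gtol=config.tol,
                max_nfev=max_nfev,
            )
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover - defensive
            logger.debug("start %d failed: %s", idx, exc)
            continue
        sse = float(2.0 * sol.cost)
        n_iter_total += int(sol.nfev)
        candidate = FitResult(
            params=_params_from_vector(sol.x),
            sse=sse,
            converged=bool(sol.success),
            n_iter=n_iter_total,
            start_index=idx,
            message=sol.message,
        )
        if candidate.converged and (best is None or not best.converged or sse < best.sse):
            best = candidate
        elif best is None:
            best = candidate
    if best is None:
        best = FitResult(params=None, sse=float("inf"), converged=False,
                         n_iter=n_iter_total, start_index=-1, message="all starts failed")
    else:
        best.n_iter = n_iter_total
    return best


def _interval_fit(Ct, Ca, Cp, lb, ub, x0, max_nfev):
    try:
        sol = least_squares(
            _residuals, np.clip(x0, lb, ub), bounds=(lb, ub), args=(Ct, Ca, Cp),
            method="trf", ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=max_nfev,
        )
    except (ValueError, FloatingPointError):  # pragma: no cover - defensive
        return None
    return float(2.0 * sol.cost), sol.x, int(sol.nfev)


def _profile_t1(Ct, Ca, Cp, lower, upper, max_nfev, corner_starts, top):
    """Coarse profile of the objective over vascular-transit-time intervals.

    The discretely sampled residue function changes branch whenever ``t1``
    crosses a grid time, so the least-squares objective is only piecewise
    smooth in ``t1`` and a single descent can stall in the wrong interval.
    Stage one fits all parameters from a centre start with ``t1`` confined
    to each grid-spacing interval in turn; stage two re-fits the best
    ``top`` intervals from every configured corner start (the objective is
    multi-modal in the remaining kinetic parameters even at fixed ``t1``).
    Returns candidate solutions sorted by sse, to seed the unconstrained
    joint fit.
    """
    dt = Ct.grid.dt
    horizon = min(upper[2], Ct.grid.duration)
    intervals = []
    k = int(np.floor(lower[2] / dt))
    while k * dt < horizon:
        lo_t1 = max(lower[2], k * dt + 1e-6)
        hi_t1 = min(upper[2], (k + 1) * dt - 1e-6)
        k += 1
        if hi_t1 > lo_t1:
            intervals.append((lo_t1, hi_t1))

    scan = []
    for lo_t1, hi_t1 in intervals:
        lb, ub = lower.copy(), upper.copy()
        lb[2], ub[2] = lo_t1, hi_t1
        x0 = np.array([100.0, 0.5, 0.5 * (lo_t1 + hi_t1), 0.15, 50.0, 0.5, 0.5])
        res = _interval_fit(Ct, Ca, Cp, lb, ub, x0, max_nfev)
        if res is not None:
            scan.append(((lo_t1, hi_t1), res))
    scan.sort(key=lambda r: r[1][0])

    results = [res for _, res in scan]
    for (lo_t1, hi_t1), _ in scan[:top]:
        lb, ub = lower.copy(), upper.copy()
        lb[2], ub[2] = lo_t1, hi_t1
        for corner in corner_starts:
            x0 = corner.copy()
            x0[2] = 0.5 * (lo_t1 + hi_t1)
            res = _interval_fit(Ct, Ca, Cp, lb, ub, x0, max_nfev)
            if res is not None:
                results.append(res)
    results.sort(key=lambda r: r[0])
    return results


def fit_volume(
    vol: DynamicVolume,
    Ca: ConcentrationCurve,
    Cp: ConcentrationCurve,
    config: FitConfig | None = None,
) -> ParameterMaps:
    """Fit every in-mask voxel of a dynamic volume and assemble parameter maps.

    Voxel fits are independent; results are identical to a serial
    voxel-by-voxel loop.  Non-mask and non-converged voxels carry NaN in
    the parameter maps and 0 in the convergence map.
    """
    if config is None:
        config = FitConfig()
    maps = ParameterMaps.empty(vol.spatial_shape, grid=vol.grid, affine=vol.affine)
    indices = np.argwhere(vol.mask)
    if indices.size == 0:
        logger.warning("fit_volume called with an empty mask; returning empty maps")
        return maps
    total = len(indices)
    for count, idx in enumerate(map(tuple, indices), start=1):
        result = fit_voxel(vol.curve_at(idx), Ca, Cp, config)
        maps["sse"][idx] = result.sse
        maps["converged"][idx] = float(result.converged)
        maps["n_iter"][idx] = result.n_iter
        if result.params is not None:
            p = result.params
            maps["F"][idx] = p.F
            maps["alpha"][idx] = p.alpha
            maps["t1"][idx] = p.t1
            maps["v2"][idx] = p.v2
            maps["PS"][idx] = p.PS
            maps["v1"][idx] = p.v1()
            maps["tau_a"][idx] = p.tau_a
            maps["tau_p"][idx] = p.tau_p
        if count % 50 == 0 or count == total:
            logger.info("fitted %d/%d voxels", count, total)
    return maps


def extract_input_functions(
    vol: DynamicVolume,
    aorta_mask: np.ndarray,
    portal_mask: np.ndarray,
) -> tuple[ConcentrationCurve, ConcentrationCurve]:
    """Mean arterial and portal input functions over vessel ROI masks."""
    curves = []
    for name, mask in (("aorta", aorta_mask), ("portal", portal_mask)):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.spatial_shape:
            raise MaskError(f"{name} mask shape {mask.shape} does not match volume {vol.spatial_shape}")
        if not mask.any():
            raise MaskError(f"{name} mask selects no voxels")
        curves.append(ConcentrationCurve(grid=vol.grid, values=vol.data[mask].mean(axis=0)))
    return curves[0], curves[1]
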