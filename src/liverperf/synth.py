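"""Synthetic dual-input DCE-MRI data: input functions, voxel curves, 4D phantoms.

No liver DCE dataset accompanies the model, so every pipeline stage is
exercised against synthetic data with the statistical structure of four
tissue classes — healthy volunteer parenchyma, cirrhotic parenchyma,
hepatocellular carcinoma (HCC) and metastatic adenocarcinoma — parameterised
by the class means and standard deviations of the perfusion parameters.

The arterial input function is a gamma-variate first pass plus a dispersed,
delayed recirculation tail; the portal input function is the arterial curve
convolved with a normalised exponential dispersion kernel and delayed,
reflecting transit through the splanchnic circulation.  Noise is additive
Gaussian on concentration, since the pipeline operates in concentration
space downstream of any MR signal conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .errors import InvalidParameterError, SpecificationError
from .fitting import DynamicVolume, ParameterMaps
from .model import (
    ConcentrationCurve,
    PerfusionParameters,
    TimeGrid,
    derive_v1,
    shift_curve,
    tissue_curve,
)

__all__ = [
    "InputFunctionModel",
    "TissueClassSpec",
    "PhantomSpec",
    "DEFAULT_INPUT_MODEL",
    "TISSUE_CLASSES",
    "default_grid",
    "generate_aif",
    "generate_pif",
    "sample_parameters",
    "generate_phantom",
    "simulate_cohort",
    "worked_example_parameters",
]

#: physical truncation bounds for cohort sampling, matching the fit bounds
SAMPLING_BOUNDS: dict[str, tuple[float, float]] = {
    "F": (1.0, 500.0),
    "alpha": (0.0, 1.0),
    "t1": (1.0, 120.0),
    "v1": (0.005, 0.9),
    "v2": (0.005, 0.8),
    "PS": (0.1, 300.0),
}


@dataclass(frozen=True)
class InputFunctionModel:
    """Parametric arterial/portal input-function pair.

    The first pass is a gamma variate
    ``A * ((t - t0)/scale)^shape * exp(-(t - t0)/scale)`` starting at the
    bolus arrival ``t0``; recirculation adds a delayed, exponentially
    dispersed copy carrying ``recirc_fraction`` of the first-pass area.
    The portal curve is the arterial curve dispersed (exponential kernel of
    width ``pif_dispersion``) and delayed by ``pif_delay``.
    """

    bolus_time: float = 10.0
    aif_amplitude: float = 4.0
    aif_shape: float = 3.0
    aif_scale: float = 2.5
    recirc_fraction: float = 0.35
    recirc_delay: float = 25.0
    recirc_dispersion: float = 30.0
    pif_delay: float = 15.0
    pif_dispersion: float = 25.0

    def __post_init__(self) -> None:
        if self.aif_amplitude < 0:
            raise InvalidParameterError("AIF amplitude must be non-negative")
        for name in ("bolus_time", "aif_shape", "aif_scale", "recirc_delay",
                     "recirc_dispersion", "pif_delay", "pif_dispersion"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.recirc_fraction < 0:
            raise InvalidParameterError("recirculation fraction must be non-negative")

    @property
    def first_pass_area(self) -> float:
        """Closed-form area of the gamma-variate first pass."""
        from scipy.special import gamma as gamma_fn

        return self.aif_amplitude * self.aif_scale * gamma_fn(self.aif_shape + 1.0)


DEFAULT_INPUT_MODEL = InputFunctionModel()


@dataclass(frozen=True)
class TissueClassSpec:
    """Per-parameter mean and SD describing one tissue class.

    Means and SDs are stored as ``{parameter: (mean, sd)}``; ``alpha``,
    ``v1`` and ``v2`` as fractions, flows in mL/min/100 mL, ``t1`` in
    seconds.  A class may omit ``t1`` (it is then derived per draw from the
    sampled ``v1`` and ``F`` through the central-volume relation) but must
    provide ``F``, ``alpha``, ``v2``, ``PS`` and at least one of ``t1`` or
    ``v1``.
    """

    name: str
    params: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for key, (mean, sd) in self.params.items():
            if key not in SAMPLING_BOUNDS:
                raise InvalidParameterError(f"unknown parameter {key!r} in class {self.name!r}")
            if sd < 0:
                raise InvalidParameterError(f"SD for {key!r} must be non-negative")
            lo, hi = SAMPLING_BOUNDS[key]
            if not lo <= mean <= hi:
                raise SpecificationError(
                    f"class {self.name!r}: mean {mean} for {key!r} outside bounds [{lo}, {hi}]"
                )
        required = {"F", "alpha", "v2", "PS"}
        missing = required - self.params.keys()
        if missing:
            raise SpecificationError(f"class {self.name!r} missing parameters {sorted(missing)}")
        if "t1" not in self.params and "v1" not in self.params:
            raise SpecificationError(f"class {self.name!r} must specify t1 or v1")


# Cohort defaults for the four tissue classes.  Values marked (literature)
# are not constrained by the reference cohort and are free defaults chosen
# from typical published liver perfusion ranges; see docs/methods.md.
TISSUE_CLASSES: dict[str, TissueClassSpec] = {
    "volunteer": TissueClassSpec(
        name="volunteer",
        params={
            "F": (123.6, 55.7),
            "alpha": (0.244, 0.080),
            "t1": (24.7, 6.8),
            "v1": (0.266, 0.055),
            "v2": (0.112, 0.030),
            "PS": (62.1, 19.6),
        },
    ),
    "cirrhosis": TissueClassSpec(
        name="cirrhosis",
        params={
            "F": (70.9, 9.5),
            "alpha": (0.41, 0.15),  # (literature) cirrhotic arterialisation
            "v1": (0.176, 0.025),
            "v2": (0.166, 0.056),
            "PS": (27.8, 6.9),
        },
    ),
    "hcc": TissueClassSpec(
        name="hcc",
        params={
            "F": (100.0, 30.0),  # (literature) hypervascular tumour flow
            "alpha": (0.732, 0.091),
            "t1": (17.8, 4.7),
            "v1": (0.211, 0.126),
            "v2": (0.168, 0.106),
            "PS": (40.0, 15.0),  # (literature)
        },
    ),
    "metastasis": TissueClassSpec(
        name="metastasis",
        params={
            "F": (80.0, 25.0),  # (literature)
            "alpha": (0.585, 0.201),
            "t1": (36.3, 15.7),
            "v1": (0.281, 0.100),
            "v2": (0.316, 0.073),
            "PS": (30.0, 10.0),  # (literature, below healthy parenchyma)
        },
    ),
}


def default_grid() -> TimeGrid:
    """Default acquisition grid: 120 volumes at 2.0 s temporal resolution."""
    return TimeGrid(n=120, dt=2.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise description of a synthetic 4D phantom.

    ``geometry`` is a 3D integer label map; ``labels`` assigns each nonzero
    label either a tissue class name or one of the vessel regions
    ``"aorta"`` / ``"portal"`` which carry the (noisy) input curves
    themselves.  Voxels labelled 0 stay at zero and are excluded from the
    mask.
    """

    geometry: np.ndarray
    labels: dict[int, str]
    grid: TimeGrid = field(default_factory=default_grid)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        geometry = np.asarray(self.geometry, dtype=int)
        object.__setattr__(self, "geometry", geometry)
        if geometry.ndim != 3:
            raise InvalidParameterError("phantom geometry must be a 3D label map")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise sigma must be non-negative")
        present = set(np.unique(geometry)) - {0}
        unknown = present - set(self.labels)
        if unknown:
            raise SpecificationError(f"geometry labels {sorted(unknown)} have no class assignment")


def _exponential_kernel(grid: TimeGrid, width: float) -> np.ndarray:
    """Discretely normalised causal exponential dispersion kernel."""
    t = grid.dt * np.arange(grid.n)
    kernel = np.exp(-t / width)
    return kernel / (kernel.sum() * grid.dt)


def generate_aif(grid: TimeGrid, model: InputFunctionModel | None = None) -> ConcentrationCurve:
    """Arterial input function: gamma-variate first pass plus recirculation tail."""
    if model is None:
        model = DEFAULT_INPUT_MODEL
    t = grid.times
    rel = np.maximum(t - model.bolus_time, 0.0) / model.aif_scale
    first_pass = model.aif_amplitude * rel**model.aif_shape * np.exp(-rel)
    first_pass[t <= model.bolus_time] = 0.0
    values = first_pass
    if model.recirc_fraction > 0:
        kernel = _exponential_kernel(grid, model.recirc_dispersion)
        dispersed = np.convolve(first_pass, kernel)[: grid.n] * grid.dt
        recirc = shift_curve(
            ConcentrationCurve(grid=grid, values=model.recirc_fraction * dispersed),
            model.recirc_delay,
        )
        values = first_pass + recirc.values
    return ConcentrationCurve(grid=grid, values=values)


def generate_pif(grid: TimeGrid, model: InputFunctionModel | None = None) -> ConcentrationCurve:
    """Portal input function: dispersed, delayed copy of the arterial input."""
    if model is None:
        model = DEFAULT_INPUT_MODEL
    aif = generate_aif(grid, model)
    kernel = _exponential_kernel(grid, model.pif_dispersion)
    dispersed = np.convolve(aif.values, kernel)[: grid.n] * grid.dt
    return shift_curve(ConcentrationCurve(grid=grid, values=dispersed), model.pif_delay)


def _truncnorm_location(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal whose *truncated* mean equals ``mean``.

    Plain truncation of N(mean, sd) to [lo, hi] shifts the realised mean
    away from ``mean`` when the bounds cut into the distribution; solving
    for the untruncated location removes that bias so cohort means match
    the class specification.
    """

    def truncated_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(sps.truncnorm.mean(a, b, loc=loc, scale=sd))

    span = 10.0 * sd
    try:
        return float(
            optimize.brentq(lambda loc: truncated_mean(loc) - mean, lo - span, hi + span, xtol=1e-10)
        )
    except ValueError as exc:
        raise SpecificationError(
            f"cannot moment-match truncated normal with mean {mean} on [{lo}, {hi}]"
        ) from exc


def _sample_truncated(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise SpecificationError(f"degenerate mean {mean} outside [{lo}, {hi}]")
        return np.full(n, mean)
    loc = _truncnorm_location(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return sps.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)


def sample_parameters(
    spec: TissueClassSpec,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[PerfusionParameters]:
    """Draw ``n`` independent parameter sets from a tissue-class distribution.

    Each parameter is an independent moment-matched truncated-normal draw.
    When the class specifies a transit time ``t1`` it is sampled directly
    and the vascular volume ``v1`` follows from the central-volume relation;
    when only ``v1`` is specified (cirrhosis), ``v1`` is sampled and ``t1``
    derived by inverting that relation, ``t1 = 6000 * v1 / F``.
    """
    if n < 1:
        raise InvalidParameterError(f"need at least one draw, got n={n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draw(key: str) -> np.ndarray:
        mean, sd = spec.params[key]
        lo, hi = SAMPLING_BOUNDS[key]
        return _sample_truncated(rng, mean, sd, lo, hi, n)

    F = draw("F")
    alpha = draw("alpha")
    v2 = draw("v2")
    PS = draw("PS")
    if "t1" in spec.params:
        t1 = draw("t1")
    else:
        v1 = draw("v1")
        t1 = np.clip(6000.0 * v1 / F, *SAMPLING_BOUNDS["t1"])
    return [
        PerfusionParameters(F=F[i], alpha=alpha[i], t1=t1[i], v2=v2[i], PS=PS[i])
        for i in range(n)
    ]


def generate_phantom(
    spec: PhantomSpec,
    classes: dict[str, TissueClassSpec] | None = None,
    ifm: InputFunctionModel | None = None,
) -> tuple[DynamicVolume, ParameterMaps, ConcentrationCurve, ConcentrationCurve]:
    """Build a 4D phantom with per-voxel ground truth.

    Every tissue-labelled voxel receives a tissue curve simulated from its
    own parameter draw plus independent Gaussian noise; aorta/portal
    labelled voxels carry the (noisy) input curves.  Returns the dynamic
    volume, the ground-truth parameter maps, and the clean arterial and
    portal input curves.
    """
    if classes is None:
        classes = TISSUE_CLASSES
    if ifm is None:
        ifm = DEFAULT_INPUT_MODEL
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    Ca = generate_aif(grid, ifm)
    Cp = generate_pif(grid, ifm)
    shape = spec.geometry.shape
    data = np.zeros(shape + (grid.n,))
    mask = np.zeros(shape, dtype=bool)
    truth = ParameterMaps.empty(shape, grid=grid)

    for label in sorted(set(np.unique(spec.geometry)) - {0}):
        region = spec.labels[label]
        voxels = np.argwhere(spec.geometry == label)
        if region in ("aorta", "portal"):
            source = Ca if region == "aorta" else Cp
            for idx in map(tuple, voxels):
                data[idx] = source.values
            continue
        if region not in classes:
            raise SpecificationError(f"unknown tissue class {region!r}")
        draws = sample_parameters(classes[region], len(voxels), rng)
        for idx, params in zip(map(tuple, voxels), draws):
            data[idx] = tissue_curve(params, Ca, Cp, grid).values
            mask[idx] = True
            truth["F"][idx] = params.F
            truth["alpha"][idx] = params.alpha
            truth["t1"][idx] = params.t1
            truth["v2"][idx] = params.v2
            truth["PS"][idx] = params.PS
            truth["v1"][idx] = params.v1()
            truth["tau_a"][idx] = params.tau_a
            truth["tau_p"][idx] = params.tau_p
            truth["converged"][idx] = 1.0
    if spec.noise_sigma > 0:
        noisy_region = spec.geometry != 0
        noise = rng.normal(0.0, spec.noise_sigma, size=data.shape)
        data[noisy_region] += noise[noisy_region]
    vol = DynamicVolume(data=data, grid=grid, mask=mask)
    return vol, truth, Ca, Cp


def simulate_cohort(
    sizes: dict[str, int],
    classes: dict[str, TissueClassSpec] | None = None,
    seed: int = 0,
):
    """Per-subject parameter tables for named tissue-class groups.

    Each subject (or lesion) contributes one independent draw from its
    class distribution; returns ``{group: DataFrame}`` with one row per
    subject and columns F, alpha, t1, v1, v2, PS — the unit of analysis for
    group-comparison statistics.
    """
    import pandas as pd

    if classes is None:
        classes = TISSUE_CLASSES
    rng = np.random.default_rng(seed)
    tables = {}
    for group, n in sizes.items():
        draws = sample_parameters(classes[group], n, rng)
        tables[group] = pd.DataFrame(
            {
                "F": [p.F for p in draws],
                "alpha": [p.alpha for p in draws],
                "t1": [p.t1 for p in draws],
                "v1": [p.v1() for p in draws],
                "v2": [p.v2 for p in draws],
                "PS": [p.PS for p in draws],
            }
        )
    return tables


def worked_example_parameters() -> PerfusionParameters:
    """The single-voxel volunteer worked-example parameter set.

    F = 81.0 mL/min/100 mL, alpha = 31.0 %, t1 = 23.3 s, v2 = 5.7 %,
    PS = 35.1 mL/min/100 mL, no arrival delays.  The implied vascular
    volume from the central-volume relation is v1 = F * t1 = 31.5 %
    (18.9 % after scaling by 1 - Hct with Hct = 0.4).
    """
    return PerfusionParameters(F=81.0, alpha=0.310, t1=23.3, v2=0.057, PS=35.1)
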