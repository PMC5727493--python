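"""NIfTI, CSV and config file I/O for the perfusion pipeline.

Dynamic volumes, masks and parameter maps travel as NIfTI; concentration
curves and comparison tables as CSV; configuration as YAML or JSON.  The
temporal spacing of a dynamic series is taken from the NIfTI header's
fourth pixdim unless a config override is supplied (dynamic headers are
unreliable in the wild, so the override wins).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .fitting import MAP_NAMES, DynamicVolume, ParameterMaps
from .model import ConcentrationCurve, TimeGrid

__all__ = [
    "read_dynamic",
    "write_dynamic",
    "read_mask",
    "write_mask",
    "read_curve_csv",
    "write_curve_csv",
    "read_maps",
    "write_maps",
    "load_config",
]

#: units written into map filenames/sidecar, per parameter
MAP_UNITS = {
    "F": "ml_per_min_per_100ml",
    "alpha": "fraction",
    "t1": "seconds",
    "v1": "fraction",
    "v2": "fraction",
    "PS": "ml_per_min_per_100ml",
    "tau_a": "seconds",
    "tau_p": "seconds",
    "sse": "concentration_sq",
    "converged": "flag",
    "n_iter": "count",
}


def read_dynamic(
    path: str | Path,
    dt_override: float | None = None,
    mask: np.ndarray | None = None,
) -> DynamicVolume:
    """Load a 4D dynamic NIfTI as a :class:`DynamicVolume`.

    The temporal spacing comes from the header (pixdim[4]) unless
    ``dt_override`` is given; a missing or zero header spacing without an
    override is a configuration error.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D dynamic series, got {data.ndim}D")
    zooms = img.header.get_zooms()
    dt = dt_override if dt_override is not None else (float(zooms[3]) if len(zooms) > 3 else 0.0)
    if not dt or dt <= 0:
        raise FormatError(
            f"{path}: temporal spacing missing from header and no override supplied"
        )
    grid = TimeGrid(n=data.shape[3], dt=float(dt))
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    voxel_size = tuple(float(z) for z in zooms[:3])
    return DynamicVolume(
        data=data.astype(float), grid=grid, mask=mask,
        voxel_size=voxel_size, affine=img.affine,
    )


def write_dynamic(path: str | Path, vol: DynamicVolume) -> None:
    """Write a dynamic volume as 4D NIfTI, recording dt in pixdim[4]."""
    affine = vol.affine if vol.affine is not None else np.eye(4)
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms(vol.voxel_size + (vol.grid.dt,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got {data.ndim}D")
    return data > 0


def write_mask(path: str | Path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine if affine is not None else np.eye(4))
    nib.save(img, str(path))


def read_curve_csv(path: str | Path) -> ConcentrationCurve:
    """Read a concentration curve from a two-column CSV (time_s, concentration).

    The time column must be strictly increasing and uniformly spaced
    (relative deviation below 1e-6).
    """
    frame = pd.read_csv(path)
    for col in ("time_s", "concentration"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    t = frame["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    dt = float(np.mean(steps))
    if np.max(np.abs(steps - dt)) > 1e-6 * dt:
        raise FormatError(f"{path}: time column is not uniformly spaced")
    grid = TimeGrid(n=t.size, dt=dt, t0=float(t[0]))
    return ConcentrationCurve(grid=grid, values=frame["concentration"].to_numpy(dtype=float))


def write_curve_csv(path: str | Path, curve: ConcentrationCurve) -> None:
    pd.DataFrame(
        {"time_s": curve.grid.times, "concentration": curve.values}
    ).to_csv(path, index=False, float_format="%.17g")


def write_maps(directory: str | Path, maps: ParameterMaps, prefix: str = "map") -> dict[str, Path]:
    """Write one NIfTI per parameter map plus a JSON sidecar with units.

    Returns the mapping from map name to written path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = maps.affine if maps.affine is not None else np.eye(4)
    written: dict[str, Path] = {}
    for name, volume in maps.maps.items():
        out = directory / f"{prefix}_{name}_{MAP_UNITS.get(name, 'unknown')}.nii"
        nib.save(nib.Nifti1Image(volume, affine), str(out))
        written[name] = out
    sidecar = {
        name: {"file": written[name].name, "units": MAP_UNITS.get(name, "unknown")}
        for name in maps.maps
    }
    (directory / f"{prefix}_maps.json").write_text(json.dumps(sidecar, indent=2))
    return written


def read_maps(directory: str | Path, prefix: str = "map") -> ParameterMaps:
    """Re-read a set of parameter maps written by :func:`write_maps`."""
    directory = Path(directory)
    sidecar_path = directory / f"{prefix}_maps.json"
    if not sidecar_path.exists():
        raise FormatError(f"{sidecar_path}: map sidecar not found")
    sidecar = json.loads(sidecar_path.read_text())
    maps: dict[str, np.ndarray] = {}
    affine = None
    for name, entry in sidecar.items():
        img = nib.load(str(directory / entry["file"]))
        maps[name] = np.asanyarray(img.dataobj).astype(float)
        affine = img.affine
    missing = set(MAP_NAMES) - maps.keys()
    if missing:
        raise FormatError(f"{directory}: maps missing {sorted(missing)}")
    return ParameterMaps(maps=maps, affine=affine)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return loaded
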