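"""ROI summaries and group-comparison statistics for perfusion parameters.

Group comparisons use the classical pooled-variance (Student) two-sample
t-test with a two-sided P value, significance at P < 0.05, and no
multiple-testing correction.  A Welch (unequal-variance) option is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidArgumentError, MaskError
from .fitting import ParameterMaps

__all__ = [
    "SUMMARY_PARAMETERS",
    "ROISummary",
    "GroupComparison",
    "roi_summary",
    "two_sample_t_test",
    "compare_groups",
]

#: parameters summarised over ROIs and compared between groups
SUMMARY_PARAMETERS = ("F", "alpha", "t1", "v1", "v2", "PS")

ALPHA_LEVEL = 0.05


@dataclass(frozen=True)
class ROISummary:
    """Per-parameter mean/SD over the converged voxels of one region."""

    name: str
    means: dict[str, float]
    sds: dict[str, float]
    count: int

    def as_series(self) -> pd.Series:
        data = {}
        for p in self.means:
            data[f"{p}_mean"] = self.means[p]
            data[f"{p}_sd"] = self.sds[p]
        data["n_voxels"] = self.count
        return pd.Series(data, name=self.name)


@dataclass(frozen=True)
class GroupComparison:
    """Pooled-variance t-test result for one parameter between two groups."""

    parameter: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA_LEVEL


def roi_summary(maps: ParameterMaps, mask: np.ndarray, name: str = "roi") -> ROISummary:
    """Mean and sample SD of each fitted parameter over an ROI mask.

    Only voxels flagged converged contribute; an ROI without any converged
    voxel is an error.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != maps.spatial_shape:
        raise MaskError(f"ROI mask shape {mask.shape} does not match maps {maps.spatial_shape}")
    selected = mask & (maps["converged"] > 0)
    count = int(selected.sum())
    if count == 0:
        raise MaskError(f"ROI {name!r} contains no converged voxels")
    means, sds = {}, {}
    for p in SUMMARY_PARAMETERS:
        values = maps[p][selected]
        means[p] = float(np.mean(values))
        sds[p] = float(np.std(values, ddof=1)) if count > 1 else 0.0
    return ROISummary(name=name, means=means, sds=sds, count=count)


def two_sample_t_test(
    a,
    b,
    parameter: str = "",
    group_a: str = "A",
    group_b: str = "B",
    welch: bool = False,
) -> GroupComparison:
    """Two-sided two-sample t-test on per-subject values.

    Pooled-variance (Student) by default with ``n_a + n_b - 2`` degrees of
    freedom; Welch's unequal-variance form when ``welch`` is set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("each group needs at least 2 values for a t-test")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        parameter=parameter,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sd_a=float(np.std(a, ddof=1)),
        sd_b=float(np.std(b, ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
        t=float(t),
        p=float(p),
    )


def compare_groups(
    groups: dict[str, pd.DataFrame],
    parameters: tuple[str, ...] = SUMMARY_PARAMETERS,
    welch: bool = False,
) -> pd.DataFrame:
    """All pairwise, all-parameter group comparisons as a tidy table.

    ``groups`` maps a group name to a per-subject table with one column per
    parameter (one row per subject or lesion).  Returns one row per
    (pair, parameter) with means, SDs, t, P and the significance flag.
    """
    if len(groups) < 2:
        raise InvalidArgumentError("need at least two groups to compare")
    rows = []
    for name_a, name_b in combinations(groups, 2):
        for param in parameters:
            if param not in groups[name_a] or param not in groups[name_b]:
                continue
            cmp_ = two_sample_t_test(
                groups[name_a][param].to_numpy(),
                groups[name_b][param].to_numpy(),
                parameter=param,
                group_a=name_a,
                group_b=name_b,
                welch=welch,
            )
            rows.append(
                {
                    "group_a": cmp_.group_a,
                    "group_b": cmp_.group_b,
                    "parameter": param,
                    "mean_a": cmp_.mean_a,
                    "sd_a": cmp_.sd_a,
                    "n_a": cmp_.n_a,
                    "mean_b": cmp_.mean_b,
                    "sd_b": cmp_.sd_b,
                    "n_b": cmp_.n_b,
                    "t": cmp_.t,
                    "p": cmp_.p,
                    "significant": cmp_.significant,
                }
            )
    return pd.DataFrame(rows)
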