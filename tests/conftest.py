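import numpy as np
import pytest

from liverperf import (
    TimeGrid,
    generate_aif,
    generate_pif,
    tissue_curve,
    worked_example_parameters,
)


@pytest.fixture(scope="session")
def grid():
    """Default acquisition grid: 120 volumes at 2.0 s."""
    return TimeGrid(n=120, dt=2.0)


@pytest.fixture(scope="session")
def inputs(grid):
    """Default synthetic arterial and portal input functions."""
    return generate_aif(grid), generate_pif(grid)


@pytest.fixture(scope="session")
def worked_truth():
    """Single-voxel volunteer worked-example parameter set."""
    return worked_example_parameters()


@pytest.fixture(scope="session")
def worked_curve(grid, inputs, worked_truth):
    """Noiseless tissue curve simulated from the worked-example truth."""
    Ca, Cp = inputs
    return tissue_curve(worked_truth, Ca, Cp, grid)


def naive_convolution_tissue_curve(params, Ca, Cp, grid):
    """Independent direct-sum oracle for the forward model.

    Re-implements the convolution as an explicit double sum over residue
    samples, separate from the pipeline's convolution path.
    """
    from liverperf import residue_function, shift_curve

    R = residue_function(grid, params).values
    mixed = (
        params.alpha * shift_curve(Ca, params.tau_a).values
        + (1.0 - params.alpha) * shift_curve(Cp, params.tau_p).values
    )
    n = grid.n
    out = np.zeros(n)
    for k in range(n):
        acc = 0.0
        for j in range(k + 1):
            acc += mixed[j] * R[k - j]
        out[k] = acc * params.F_per_second * grid.dt
    return out
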