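import numpy as np
import pytest

from permeapoly.core import Trajectory
from permeapoly.energy import NonbondedParams
from permeapoly.synthetic import (
    brownian_trajectory,
    ideal_gas_frames,
    lj_fluid_frames,
)

LJ_T_STAR = 1.5
LJ_RHO_STAR = 0.05


@pytest.fixture(scope="session")
def lj_traj():
    """Equilibrated dilute LJ fluid (reduced units, σ = 1 Å, ε = 1 kJ/mol)."""
    return lj_fluid_frames(
        64, LJ_T_STAR, LJ_RHO_STAR, n_frames=80, seed=11,
        sweeps_per_frame=25, burn_in_sweeps=300,
    )


@pytest.fixture(scope="session")
def lj_params(lj_traj):
    rc = lj_traj.metadata["ground_truth"].params["cutoff"]
    return NonbondedParams(
        types={"LJ": {"sigma": 1.0, "epsilon": 1.0},
               "probe": {"sigma": 1.0, "epsilon": 1.0}},
        cutoff=rc,
    )


@pytest.fixture(scope="session")
def ideal_gas_traj():
    return ideal_gas_frames(500, 30.0, 5, seed=101)


@pytest.fixture(scope="session")
def brownian_traj():
    """100 walkers, 10⁴ frames, D_true = 0.5 Å²/ps."""
    return brownian_trajectory(100, 0.5, 1.0, 10000, seed=42)


@pytest.fixture()
def hard_sphere_host():
    """One fixed hard sphere of radius 2 Å in a 10 Å cube."""
    traj = Trajectory(
        positions=np.full((1, 1, 3), 5.0),
        boxes=np.array([10.0, 10.0, 10.0]),
        elements=np.array(["HS"], dtype=object),
        masses=np.array([100.0]),
    )
    params = NonbondedParams(
        types={"HS": {"sigma": 1.0, "epsilon": 0.0, "hard_radius": 2.0},
               "point": {"sigma": 1.0, "epsilon": 0.0}},
        cutoff=4.9,
    )
    return traj, params
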