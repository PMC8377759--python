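import numpy as np
import pytest

from pbfield import (
    SolverConfig,
    build_grid,
    coulomb_constant,
    make_dimer,
    solve_pbe,
)
from pbfield.structures import Atom, Structure, load_charge_template


@pytest.fixture(scope="session")
def nucleotide_template():
    return load_charge_template("nucleotide_charges")


@pytest.fixture()
def dimer():
    return make_dimer(1.0, -1.0, 10.0)


@pytest.fixture()
def point_charge():
    """A bare +1 e point charge (no cavity) at the origin."""
    return Structure([Atom("Q", "ION", 1, "", np.zeros(3), 1.0, 0.0)])


@pytest.fixture(scope="session")
def uniform_water() -> SolverConfig:
    """Uniform dielectric 80, no salt: the Coulomb-oracle medium."""
    return SolverConfig(eps_in=80.0, eps_out=80.0, salt=0.0, tolerance=1e-6)


@pytest.fixture(scope="session")
def point_charge_solution(uniform_water):
    """+1 e in uniform eps 80, 65^3 nodes at 1.0 Å — shared analytic fixture."""
    s = Structure([Atom("Q", "ION", 1, "", np.zeros(3), 1.0, 0.0)])
    grid = build_grid(
        s, spacing=1.0, padding=30.0, dims=(65, 65, 65), center=np.zeros(3)
    )
    return s, solve_pbe(s, grid, uniform_water)


@pytest.fixture(scope="session")
def coulomb_kT():
    return coulomb_constant(300.0)
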