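import numpy as np
import pytest

import glkit as g


@pytest.fixture(scope="session")
def table1():
    """Reference kinetic constants of the glucokinase (µM, µmol/mg/min)."""
    return g.TABLE1_PARAMS


@pytest.fixture(scope="session")
def ordered_scheme(table1):
    return g.ordered_bibi_scheme(table1)


@pytest.fixture(scope="session")
def clean_velocity_data(table1):
    """Noise-free initial-rate dataset on the experimental grids."""
    return g.gen_velocity_data(g.VelocityDesign(), table1)


@pytest.fixture(scope="session")
def two_domain():
    spec = g.TwoDomainSpec(seed=11)
    open_m, closed_m, truth = g.gen_two_domain_model(spec)
    return spec, open_m, closed_m, truth


@pytest.fixture(scope="session")
def sphere31():
    """Lattice-filled solid sphere, R = 31 Å."""
    from glkit.synthetic import sphere_bead_model
    return sphere_bead_model(31.0, spacing=3.0)


def make_model(chains, resnums, resnames, atomnames, xyz, elements=None):
    """Handcrafted StructureModel helper for geometry fixtures."""
    n = len(chains)
    if elements is None:
        elements = [a[0] for a in atomnames]
    return g.StructureModel(
        chain=list(chains), resnum=np.asarray(resnums), resname=list(resnames),
        atomname=list(atomnames), element=list(elements),
        mass=np.full(n, 12.0), xyz=np.asarray(xyz, float),
        occupancy=np.ones(n), altloc=[""] * n)
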