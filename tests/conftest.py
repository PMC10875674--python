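import numpy as np
import pytest

import xylokin as xk


@pytest.fixture(scope="session")
def species_records():
    return xk.load_species_table()


@pytest.fixture(scope="session")
def fitted_polys(species_records):
    return {name: xk.fit_nasa7(rec) for name, rec in species_records.items()}


@pytest.fixture(scope="session")
def thermo_map(species_records, fitted_polys):
    return {
        name: (rec.formula, fitted_polys[name])
        for name, rec in species_records.items()
    }


@pytest.fixture(scope="session")
def model1():
    return xk.build_model1()


@pytest.fixture(scope="session")
def model2():
    return xk.build_model2()


@pytest.fixture(scope="session")
def arrhenius_table():
    return xk.load_arrhenius_table().set_index("id")


@pytest.fixture(scope="session")
def barrier_table():
    return xk.load_barrier_table().set_index("id")


def element_conservation_error(traj, mech):
    """Max relative drift of per-element atom totals over a trajectory."""
    elements = sorted({e for rec in mech.species.values() for e in rec.formula})
    matrix = np.array(
        [[mech.species[s].formula.get(e, 0) for e in elements] for s in traj.species]
    )
    totals = traj.moles @ matrix
    return float(np.max(np.abs(totals - totals[0]) / totals[0]))
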