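import numpy as np
import pytest

from gcensemble.structure_io import Ensemble, Topology
from gcensemble.synthetic_data import make_toy_heterodimer


@pytest.fixture(scope="session")
def toy():
    """Two-chain helical toy heterodimer, 10 residues per chain, one frame."""
    return make_toy_heterodimer(n_residues=10, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def two_residue_topology(d_ha: bool = False) -> Topology:
    """Minimal two-chain, one-residue-per-chain topology: CA, CB (+ HA)."""
    names = ["CA", "CB"] + (["HA"] if d_ha else [])
    n = 2 * len(names)
    return Topology(
        chain_ids=np.array(["A"] * len(names) + ["B"] * len(names), dtype="U4"),
        res_ids=np.array([1] * len(names) + [1] * len(names)),
        res_names=np.array(["ALA"] * n, dtype="U4"),
        atom_names=np.array(names * 2, dtype="U6"),
        elements=np.array([nm[0] for nm in names] * 2, dtype="U4"),
        occupancies=np.ones(n),
        altlocs=np.array([""] * n, dtype="U1"),
    )
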