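import numpy as np
import pytest

from modefit.fixtures import HingeSpec, make_hinge_complex
from modefit.flexfit import FittingConfig, fit_to_native
from modefit.structure_io import Atom, Residue, Structure


def make_residue(chain_id, seq_num, res_name, atom_specs, polymer_type):
    atoms = [Atom(name, el, pos) for name, el, pos in atom_specs]
    return Residue(chain_id=chain_id, seq_num=seq_num, icode="",
                   res_name=res_name, atoms=atoms, polymer_type=polymer_type)


def single_atom_structure(chain_id, positions, res_name="GLY", atom_name="CA"):
    """One chain with one CA-only residue per position (handy toy systems)."""
    residues = [
        make_residue(chain_id, i + 1, res_name, [(atom_name, "C", p)], "protein")
        for i, p in enumerate(positions)
    ]
    return Structure(chains=[(chain_id, residues)])


@pytest.fixture(scope="session")
def hinge():
    """Default hinge fixture: unbound, bound, receptor, domain definitions."""
    return make_hinge_complex(HingeSpec(seed=7))


@pytest.fixture(scope="session")
def hinge_fit(hinge):
    """One flex-fit-to-native run on the hinge fixture, shared by the tests
    that audit convergence, stereochemistry and recovery."""
    unbound, bound, receptor, domains = hinge
    cfg = FittingConfig(
        max_iterations=500, convergence_tol=0.002, convergence_window=30, seed=7
    )
    receptor_work = receptor.copy()
    model, state = fit_to_native(
        unbound.copy(), bound, domains, receptor=receptor_work, cfg=cfg
    )
    return model, state, receptor_work


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
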