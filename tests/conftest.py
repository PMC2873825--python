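import numpy as np
import pytest

from gacontact.profile_io import CANONICAL_AA, ProfileMatrix
from gacontact.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def uniform_profile():
    """60-residue profile with every entry 0.05."""
    return ProfileMatrix(chain_id="uni", residues="A" * 60, matrix=np.full((60, 20), 0.05))


def random_profile(rng: np.random.Generator, L: int, chain_id: str = "rand") -> ProfileMatrix:
    matrix = rng.dirichlet(np.ones(20), size=L)
    residues = "".join(CANONICAL_AA[k] for k in rng.integers(0, 20, size=L))
    return ProfileMatrix(chain_id=chain_id, residues=residues, matrix=matrix)


@pytest.fixture(scope="session")
def small_dataset():
    """Six small synthetic chains shared across tests (read-only)."""
    cfg = SyntheticConfig(n_chains=6, length_range=(40, 55), contact_slope=0.8, rng_seed=7)
    return generate_dataset(cfg)


def write_pdb_lines(path, atoms):
    """Write raw PDB ATOM records.

    ``atoms``: list of (serial, name, altloc, resname, chain, resseq,
    icode, x, y, z, occupancy).
    """
    with open(path, "w") as fh:
        for serial, name, altloc, resname, chain, resseq, icode, x, y, z, occ in atoms:
            fh.write(
                f"ATOM  {serial:5d} {name:^4s}{altloc:1s}{resname:3s} {chain:1s}"
                f"{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
                f"           C\n"
            )
        fh.write("END\n")
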