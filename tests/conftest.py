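import numpy as np
import pytest

from micellekit.force_field import ForceFieldParams
from micellekit.polymer_topology import (
    TYPE_A,
    TYPE_B,
    TYPE_CION,
    ArchitectureSpec,
    Topology,
    assemble_system,
)


@pytest.fixture(scope="session")
def ff_default() -> ForceFieldParams:
    return ForceFieldParams()


def random_bonded_system(
    n_molecules: int = 5,
    arch: ArchitectureSpec | None = None,
    seed: int = 0,
    spread: float = 4.0,
):
    """Small random (non-overlapping-ish) bonded system for force checks."""
    arch = arch or ArchitectureSpec(NB=3, Ns=3, g=1, q=2, charge_A=1)
    topo = assemble_system(arch, n_molecules)
    rng = np.random.default_rng(seed)
    n_mol = arch.n_beads
    pos = np.empty((topo.n_beads, 3))
    frag_bonds = topo.bonds[: n_mol - 1]  # first molecule's bond tree
    for m in range(n_molecules):
        # random walk along the bond tree: near-equilibrium bond lengths
        block = np.empty((n_mol, 3))
        block[0] = rng.uniform(-spread, spread, 3)
        for i, j in frag_bonds:
            step = rng.standard_normal(3)
            step *= 0.97 / np.linalg.norm(step)
            block[j] = block[i] + step
        pos[m * n_mol:(m + 1) * n_mol] = block
    n_poly = topo.n_copolymer_beads
    pos[n_poly:] = rng.uniform(-2 * spread, 2 * spread,
                               (topo.n_beads - n_poly, 3))
    return topo, pos


@pytest.fixture()
def charged_random_system():
    return random_bonded_system()
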