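import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ppimodes import (AtomRecord, ComplexModel, InterfaceBlock, ResidueView,
                      ToyDimerSpec, make_toy_dimer)


def random_complex(rng: np.random.Generator, max_res: int = 60,
                   atoms_per_res: int = 4, box: float = 30.0) -> ComplexModel:
    """A random two-chain point cloud (no designed interface)."""

    def chain(chain_id, n):
        residues = []
        for i in range(1, n + 1):
            center = rng.uniform(0, box, 3)
            atoms = [AtomRecord(chain_id, i, "ALA", f"X{k}", "C",
                                center + rng.normal(0, 1.0, 3))
                     for k in range(atoms_per_res)]
            residues.append(ResidueView(chain_id, i, "A", atoms,
                                        float(rng.uniform(30, 95))))
        return residues

    la = int(rng.integers(3, max_res + 1))
    lb = int(rng.integers(3, max_res + 1))
    return ComplexModel(chain_a=chain("A", la), chain_b=chain("B", lb))


def four_mode_spec(seed: int = 0) -> ToyDimerSpec:
    """One block of each designed binding mode, clean margins."""
    return ToyDimerSpec(
        len_a=220, len_b=220,
        interface_blocks=[
            InterfaceBlock((20, 40), (20, 40), "ordered"),
            InterfaceBlock((55, 85), (55, 85), "disordered"),
            InterfaceBlock((100, 126), (100, 126), "coil_to_order"),
            InterfaceBlock((140, 172), (140, 172), "cf"),
        ],
        seed=seed)


@pytest.fixture(scope="session")
def toy_dimer():
    return make_toy_dimer(four_mode_spec())


@pytest.fixture()
def fixture_paths(toy_dimer, tmp_path):
    return toy_dimer.write_fixture(tmp_path)
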